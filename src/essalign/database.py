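"""SQLite persistence for non-redundant ESS and their provenance.

Schema (reconstructed to carry the relations the method needs):

    nrseqs(ess_id INTEGER PRIMARY KEY, seq3 TEXT UNIQUE, seq4 TEXT)
    organisms(org TEXT PRIMARY KEY, domain TEXT)
    maps(map_id TEXT PRIMARY KEY)
    links(ess_id, org, map_id, step_index, gene_id)

``nrseqs`` holds one row per distinct three-level sequence; ``links``
ties every step of every original (redundant) occurrence back to its
genes, organism and map.  The aligner also accepts plain text files
with one colon-separated ESS per line, ids assigned as 1-based line
numbers.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

from .labels import ECFormatError, format_ess, parse_ess
from .extraction import ESS, make_nonredundant

_SCHEMA = """
CREATE TABLE IF NOT EXISTS nrseqs (
    ess_id INTEGER PRIMARY KEY,
    seq3 TEXT NOT NULL UNIQUE,
    seq4 TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS organisms (
    org TEXT PRIMARY KEY,
    domain TEXT
);
CREATE TABLE IF NOT EXISTS maps (
    map_id TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS links (
    ess_id INTEGER NOT NULL REFERENCES nrseqs(ess_id),
    org TEXT,
    map_id TEXT,
    step_index INTEGER NOT NULL,
    gene_id TEXT
);
"""

_SQLITE_MAGIC = b"SQLite format 3\x00"


def write_database(
    nress: list[ESS],
    redundancy: dict[tuple[str, ...], list[ESS]] | None,
    destination,
    domains: dict[str, str] | None = None,
) -> sqlite3.Connection:
    """Persist an nrESS set (and its redundancy links) to SQLite.

    ``redundancy`` maps each representative's labels3 to every original
    occurrence; pass ``None`` to link only the representatives
    themselves.  ``domains`` optionally tags organisms with their
    superkingdom (Bacteria, Archaea, Eukarya).  Duplicate sequences
    violate the UNIQUE constraint and raise ``sqlite3.IntegrityError``.
    """
    conn = sqlite3.connect(str(destination))
    conn.executescript(_SCHEMA)
    domains = domains or {}
    with conn:
        for ess_id, ess in enumerate(nress, start=1):
            conn.execute(
                "INSERT INTO nrseqs (ess_id, seq3, seq4) VALUES (?, ?, ?)",
                (ess_id, format_ess(ess.labels3), format_ess(ess.labels4)),
            )
            originals = (
                redundancy.get(ess.labels3, [ess]) if redundancy is not None else [ess]
            )
            for orig in originals:
                if orig.organism:
                    conn.execute(
                        "INSERT OR IGNORE INTO organisms (org, domain) VALUES (?, ?)",
                        (orig.organism, domains.get(orig.organism)),
                    )
                if orig.map_id:
                    conn.execute(
                        "INSERT OR IGNORE INTO maps (map_id) VALUES (?)",
                        (orig.map_id,),
                    )
                for step_index, genes in enumerate(orig.gene_steps):
                    for gene in sorted(genes):
                        conn.execute(
                            "INSERT INTO links (ess_id, org, map_id, step_index,"
                            " gene_id) VALUES (?, ?, ?, ?, ?)",
                            (ess_id, orig.organism, orig.map_id, step_index, gene),
                        )
    return conn


def build_database(ess_list: list[ESS], destination, **kwargs) -> sqlite3.Connection:
    """Deduplicate and persist in one step."""
    nress, redundancy = make_nonredundant(ess_list)
    return write_database(nress, redundancy, destination, **kwargs)


def _is_sqlite_file(path: Path) -> bool:
    try:
        with open(path, "rb") as handle:
            return handle.read(16) == _SQLITE_MAGIC
    except OSError:
        return False


def read_database(source) -> list[tuple[int, list[str]]]:
    conn = sqlite3.connect(str(source))
    try:
        rows = conn.execute(
            "SELECT ess_id, seq3 FROM nrseqs ORDER BY ess_id"
        ).fetchall()
    finally:
        conn.close()
    return [(int(ess_id), parse_ess(seq3)) for ess_id, seq3 in rows]


def read_text(source) -> list[tuple[int, list[str]]]:
    out = []
    with open(source) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                out.append((lineno, parse_ess(line)))
            except ECFormatError as exc:
                raise ECFormatError(f"{source}: line {lineno}: {exc}") from exc
    return out


def read_sequences(source) -> list[tuple[int, list[str]]]:
    """Load (ess_id, labels3) pairs from SQLite or one-ESS-per-line text.

    Text files number sequences by line (1-based); blank lines and
    ``#`` comments are skipped but still consume line numbers.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such sequence source: {source}")
    if _is_sqlite_file(path):
        return read_database(path)
    return read_text(path)


def write_ess_text(sequences, destination) -> None:
    """Write sequences of labels (or ESS objects) one per line."""
    with open(destination, "w") as handle:
        for seq in sequences:
            labels = seq.labels3 if isinstance(seq, ESS) else seq
            handle.write(format_ess(list(labels)) + "\n")
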