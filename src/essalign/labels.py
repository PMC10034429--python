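"""EC label conventions shared across the package.

An enzymatic step is labelled by the first three levels of its Enzyme
Commission number, written ``"2.7.1"``.  Two sentinels complete the
alphabet: ``"9.9.9"`` marks an enzyme with no EC assignment, and
``"-.-.-"`` marks a gap introduced by the aligner.  A full sequence of
steps (an ESS) is serialised colon-separated, e.g.
``"2.7.1:5.3.1:5.3.1"``.
"""

from __future__ import annotations

import re

GAP = "-.-.-"
UNASSIGNED = "9.9.9"

_EC3_RE = re.compile(r"^\d+\.\d+\.\d+$")
_EC4_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


class ECFormatError(ValueError):
    """Raised when a token is not a valid EC label or ESS string."""


def is_ec3(label: str) -> bool:
    """True for a three-level EC label (``9.9.9`` counts; the gap does not)."""
    return bool(_EC3_RE.match(label))


def is_ec4(label: str) -> bool:
    return bool(_EC4_RE.match(label))


def ec3_of(ec4: str) -> str:
    """Three-level prefix of a four-level EC string (identity on ``9.9.9``)."""
    if ec4 == UNASSIGNED:
        return UNASSIGNED
    if not is_ec4(ec4):
        raise ECFormatError(f"not a four-level EC number: {ec4!r}")
    return ec4.rsplit(".", 1)[0]


def ec_sort_key(label: str) -> tuple[int, ...]:
    """Numeric sort key so that 2.7.1 < 2.10.1 (string order would not)."""
    return tuple(int(part) for part in label.split("."))


def parse_ess(text: str) -> list[str]:
    """Parse a colon-separated ESS of three-level EC labels.

    Raises :class:`ECFormatError` naming the first offending token.
    """
    tokens = [tok.strip() for tok in text.strip().split(":")]
    if not tokens or tokens == [""]:
        raise ECFormatError("empty ESS string")
    for tok in tokens:
        if not is_ec3(tok):
            raise ECFormatError(f"invalid EC label {tok!r} in ESS {text!r}")
    return tokens


def format_ess(labels: list[str] | tuple[str, ...]) -> str:
    return ":".join(labels)
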