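# Methods

## From KGML to reaction graphs

A KGML pathway file lists entries (genes/enzymes, compounds, links to
other maps), reactions with their substrate and product compounds, and
relations. `essalign.kgml` turns one map into a graph whose nodes are
reactions and whose edges carry the shared compound: an edge joins A
to B when a product of A is a substrate of B. Only strict metabolic
maps are meaningful inputs — those whose 5-digit code is below 01000;
global overview maps (≥ 01000) superimpose many pathways and are out
of scope (`is_strict_map` checks the code).

Decisions where KGML itself leaves room:

- **Node identity.** Reaction `name` strings are node ids, kept
  verbatim. Multiple entries catalysing one reaction (isoenzymes,
  complex subunits) merge into one node holding the union of their
  gene ids; a reaction with no EC assignment is labelled `9.9.9`.
- **EC assignment.** EC numbers are read from `ec:` tokens in entry
  names (the form enzyme-type entries use). Gene-type KGML entries do
  not embed EC numbers; mapping gene → EC via external annotation is
  the caller's job and out of scope here.
- **Reversibility.** From the reaction `type` attribute. In the
  directed graph an edge A→B also emits B→A when either endpoint is
  reversible: a reversible reaction can run backwards, so traversal
  must succeed in both directions across it. The undirected graph
  ignores direction entirely; its edge set is a superset of the
  direction-collapsed directed edge set.
- **Relations.** `relation` elements contribute no edges (only
  product/substrate links define connectivity). They are consulted
  once: a reaction related to a `map`-type entry is recorded as a
  cross-map link node.

## ESS extraction

Initialization nodes (BFS roots) are (1) reactions none of whose
substrates is produced by any other in-map reaction — the
any-quantifier reading; a node with several substrates qualifies only
if all are externally supplied — and (2) cross-map link nodes with
fewer than three distinct neighbours. Criterion (1) compares declared
substrates against declared products, ignoring reversibility; a pure
cycle therefore has no roots and yields no sequences.

Each root grows a breadth-first tree (forward edges only in directed
mode; neighbour order sorted by node id, so extraction is reproducible
byte for byte). Every leaf contributes one ESS — the path traced from
the leaf back to the root, then reversed so the sequence reads in the
direction of metabolic flow. A tree yields exactly as many sequences
as it has leaves. Paths shorter than `MIN_ESS_LENGTH = 2` steps are
discarded (a single step carries no order information); the parameter
is exposed for callers who want longer minima.

When a node carries several EC numbers, the step label is the
numerically smallest EC (so `2.7.1` sorts before `2.10.1`); the full
gene association of every step is preserved in the provenance and in
the database `links` table, so no information is lost — a
combinatorial expansion of all EC choices is deliberately avoided to
bound output size. Sequences are stored at both four and three EC
levels; alignment scoring is defined at three levels only.

Identical three-level sequences across maps and organisms collapse to
one nrESS representative (first occurrence wins) with a redundancy map
back to every origin. The SQLite schema —
`nrseqs(ess_id, seq3, seq4)`, `organisms(org, domain)`,
`maps(map_id)`, `links(ess_id, org, map_id, step_index, gene_id)` — is
this package's own reconstruction of the relations the method needs;
`seq3` carries a UNIQUE constraint so non-redundancy is enforced by
the database itself.

## Dissimilarity and alignment scoring

The per-level entropy is the standard Shannon form −Σ p·log₂ p
(0 or 1 for a pair of symbols). Weights (15, 10, 1) for EC levels
1–3 are the pinned defaults; they encode that a first-level
disagreement (different reaction chemistry) matters overwhelmingly
more than a third-level one. The matrix S applies the hierarchy
override — mismatch at a shallow level forces all deeper levels to
mismatch — which makes S(a,b) ≥ ECS(a,b) with equality except on
second-level mismatches. The label universe of S is whatever EC
numbers occur in the input (plus `9.9.9`); the matrix is regenerated
per database rather than shipped as a constant.

Alignment is a minimizing Needleman–Wunsch with gap cost 1 (the
maximum dissimilarity, so a gap is never cheaper than the worst
substitution by construction). Traceback ties prefer the diagonal,
then a gap in the second sequence, then in the first; on top of that,
inputs are compared in a canonical order and the result mirrored back,
which makes the reported alignment — and hence the composite score —
exactly symmetric in its arguments even when co-optimal tracebacks
exist.

Composite score = 0.95·H + 0.05·GP. H averages column dissimilarity
over the full alignment length with gap columns at 1 — terminal gaps
included, so aligning a short sequence inside a long one is still
penalized globally. GP measures gap concentration per sequence as
(internal gap blocks)/(internal gap characters): 1 when every internal
gap is isolated, approaching 0 as gaps coalesce into one long block;
terminal runs are excluded and a sequence without internal gaps
contributes 0. The `-l/--localize` mode trims the alignment to the
span between the first and last aligned step of the shorter input
(intersection of spans when both inputs have equal length) and
recomputes H and GP on the remaining columns, with gap runs that
became terminal inside the window dropping out of GP.

Reported scores are truncated — not rounded — at the fifth decimal,
matching the rendering convention of the reference outputs (0.5669872
prints as 0.56698).

## Batch alignment

`dbalign` aligns all C(k,2) unordered pairs within one database
(self-pairs excluded) or all k₁·k₂ cross pairs between two, and emits
pairs scoring at or below the threshold (default 0.27). Rows are
partitioned into contiguous blocks sent to a process pool and results
merged in block order, so the output is identical for any worker
count; rows stream to the output file rather than accumulating in
memory.

## Significance from shuffled nulls

The null model shuffles the EC-token content of the *entire* database
globally and re-deals tokens into sequences of the original lengths:
each replicate preserves the database-wide EC histogram and the
sequence-length histogram exactly while destroying within-sequence
order and family structure. (A per-sequence shuffle would preserve
each sequence's own composition, leaving most of the similarity signal
intact and the null far too conservative.) Ten replicates are the
default, replicate r seeded `base_seed + r`.

The published 0.27 cutoff belongs to a full KEGG-era database and is
not recomputable from fixtures, so `threshold_report` makes the
derivation auditable instead of hard-coding it: it reports mean ± SD
per replicate, the cumulative score-density curves of real and null
data, and the fraction of sequences left without any partner at each
candidate cutoff. The recommended threshold is the largest grid point
that (a) lies below the null band (below every replicate's mean − SD),
(b) has the real cumulative density strictly above the null mean, and
(c) loses fewer than `loss_cap` (default 1%) of sequences to extreme
dissimilarity. When real and null distributions coincide no point
qualifies and the report flags non-separability. The fixed 0.27 is
carried alongside for comparison.

## Synthetic data

`essalign.fixtures` generates all test inputs at run time. `make_kgml`
emits minimal valid KGML for four topologies whose correct extraction
output is known in closed form — chain (one source root, one ESS),
branch (one root, one ESS per arm), cycle (no roots, no ESS) and
cross-map (a chain whose last reaction links to another map, adding a
second root; in undirected mode this produces the reversed chain as a
second ESS, in directed mode nothing — the documented case where
directed extraction emits fewer sequences). These expectations are the
extraction pipeline's primary oracle. `make_ess_db` builds families of
near-identical sequences — a family base sequence with point EC
substitutions at a configurable rate (default tests use 0.1, sequence
lengths 6–10, family alphabets of 8 labels confined to one first-level
EC class, classes cycling 1–7) — giving a known similarity structure
for batch alignment and significance tests.

What the fixtures do not emulate: real KEGG map sizes and branching
statistics, EC reuse across maps, annotation errors, or the (~300+)
EC-label universe of a KEGG snapshot. Passing tests demonstrate
correctness of graph construction, extraction, scoring, alignment and
the null machinery on known structure — not biological conclusions
about real pathway similarity, and not the specific value 0.27, which
should be re-derived per database with `threshold_report`.

## Numerical and scale choices

Costs are accumulated in floats with an `isclose` comparison during
traceback; all substitution values are small rationals (0, 1/26,
11/26, 1), far from the tolerance. The DP-vs-enumeration equivalence
test covers every sequence pair up to length 3 over a 4-EC alphabet
exhaustively (≈3.6k pairs) plus 600 seeded random pairs at lengths
4–5, where the un-memoised enumeration oracle is still cheap; property
suites use 1000 seeded random pairs for score symmetry, a 50-sequence
database for the worker-count invariance check, and a 20-sequence
4-family database with 10 null replicates for separability. These
sizes exercise every code path while keeping the whole suite in the
seconds range.

## Known limitations

- Gene-type KGML entries carry no EC numbers; real-world use needs
  enzyme-annotated maps or a pre-mapping step.
- Scoring is defined at three EC levels; four-level labels are stored
  but never scored.
- Only the trim-based local-like mode is provided, not true
  Smith–Waterman local alignment; gap cost is linear, not affine.
- Multiple (>2) sequence alignment is out of scope; the column-entropy
  form `ecs_dissimilarity` accepts many labels for completeness only.
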