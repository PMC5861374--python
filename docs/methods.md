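# Methods

## Data model

The screening panel is a sparse ternary matrix: each (compound, assay)
pair is *active*, *inactive*, or absent (untested). Hit-rate statistics
only count pairs with a definite outcome, so non-binary outcome tokens
found in public extracts (`inconclusive`, `unspecified`, `probe`) are
dropped at read time and counted in the reader log. Identical duplicate
rows are tolerated (public extracts contain them); contradictory
duplicates abort, because a hit rate is ill-defined under contradiction.
Assays carry a type (primary screen vs confirmatory follow-up) and an
optional target annotation; the annotation may appear on only some rows of
an assay, and rows with conflicting annotations abort.

Compound structures are held as canonical aromatic non-stereo SMILES:
aromaticity perceived, every stereo descriptor removed, RDKit canonical
ordering. Stereochemistry is deliberately discarded because series
membership is defined on the constitution graph, and screening data rarely
resolve stereoisomers consistently.

## Compound selection

Per compound, HR = 100 · #active primary / #tested primary (percent).
Compounds never tested in a primary assay have undefined HR and are
excluded from quantile computations. The cascade:

* **Stage A** — #tested primary > `min_primary_assays` (default 257).
* **Stage B** — HR > t₁, where t₁ is either fixed or the third quartile of
  the stage-A HR distribution (default).
* **Stage C** — HR > t₂, fixed or the median of the stage-B distribution
  (default).

All comparisons are strict. Quantiles use linear interpolation between
order statistics ("type 7"); the convention is fixed and reported so that
data-derived thresholds are reproducible. The run report records, per
stage, which rule ran, the realized threshold, the survivor count and the
survivor median HR.

Confirmatory consistency is the fraction of selected compounds active in
at least one confirmatory assay. Compounds never tested in a confirmatory
assay stay in the denominator: the statistic asks how many selected
compounds have confirmatory support, not how many confirm among re-tested
ones. The alternative (restricting the denominator) is a one-line change
but inflates the statistic when confirmatory coverage is sparse.

## MMS extraction

A matching molecular series is a set of ≥ 2 compounds sharing one core
and differing only in the substituent at a single attachment point.
Extraction cuts every eligible bond of every compound — single, acyclic,
joining two heavy atoms — and groups compounds by the canonical core
fragment string (attachment point written as a `*` dummy atom).

* **Bond rules.** `all_acyclic` cuts every eligible bond and is the
  reference behaviour (it is what the exhaustive test oracle recomputes).
  `retrosynthetic` additionally requires the bond to match one of a
  configurable list of two-atom SMARTS patterns; the shipped default is a
  RECAP-style set (amide, ester, sulfonamide, amine, ether, aryl–N/O/S/C,
  biaryl), standing in for synthetically meaningful disconnections. The
  exact production rule set is an input, not a constant.
* **Size restrictions.** The substituent must have at most 13 heavy atoms
  (the common matched-molecular-pair convention) and, by default, be
  strictly smaller than the core; equal-size splits produce no
  fragmentation. Disabling the smaller-than-core rule emits both
  orientations that respect the cap.
* **Hydrogen analogs.** The unsubstituted parent (core with H at the
  attachment point) is admitted as a member with substituent `[*][H]`,
  since single-site series conventionally include the H analog. The
  convention is switchable; note that it can create additional small
  series (e.g. toluene joins a benzyl core as the H parent of
  ethylbenzene's methyl cut).
* **Determinism.** Members are sorted by compound id; series ids are
  sequential integers assigned after sorting core strings
  lexicographically, so output is independent of input order and
  platform. Two compounds mapping to the same (core, substituent) —
  duplicate structures under different ids — collapse onto the smallest
  id with a log note.

Every fragmentation satisfies a reconstruction invariant: re-attaching the
substituent to the core (RDKit `molzip`) reproduces the parent's canonical
SMILES. The test suite enforces this on every library it touches, and
checks full equivalence of the extraction against an independently coded
exhaustive single-cut oracle (RWMol bond surgery) on seeded libraries.

## Series parameters and rank fusion

For a series with member tested-assay sets Tᵢ and active sets Aᵢ:

* cumulative hit rate = 100 · |∪Aᵢ| / |∪Tᵢ|
* assay overlap = 100 · |∩Tᵢ| / |∪Tᵢ|
* inconsistent activity = 100 · (#shared assays with ≥ 1 active and ≥ 1
  inactive member) / |∩Tᵢ|

The cumulative-HR denominator is the *union* of tested assays: the
intersection is separately named "shared assays" and is the overlap
numerator, so the union reading keeps the three parameters
non-redundant. A series with no shared assays scores inconsistency 0
(logged), keeping the ranking total rather than erroring.

Ranking: cumulative HR and overlap descending, inconsistency ascending;
tied values receive the average (fractional) rank of their block
(`scipy.stats.rankdata`). The consensus rank is the 1-based position after
sorting by (rank sum, series id); the id tie-break makes the consensus a
deterministic permutation of 1..N regardless of input order. Percentages
are carried at full precision internally and rounded to 2 decimals only at
serialization.

In the pipeline, series parameters are computed over primary assays,
matching the primary-based per-compound statistics in the deposition
schema; the metric functions accept any assay-type restriction.

## Interference flags

Flagging is plain SMARTS substructure matching against an ordered filter
list (`id<TAB>SMARTS` file). A series is interference-free iff no member
matches any pattern. The packaged default list contains eight exemplar
artifact motifs (quinone, catechol, rhodanine and ene-rhodanine, azo,
Michael acceptor, nitroaromatic, hydrazone) and exists to exercise the
mechanism; a production run should supply a curated collection, whose
SHA-256 checksum the run manifest records. No aggregation or
autofluorescence modelling is attempted — pattern matching only.

## Deposition format

`AS.txt`: one row per series, ordered by consensus rank — id, rank, core
SMILES, the three parameters (2 decimals), member CIDs and member SMILES
(comma-separated, no spaces). `AS_SupportingInformation.txt`: one row per
compound–series membership — compound id and SMILES, series id/rank/core,
#primary assays tested and active, hit rate, active-target ids,
interference flag (`yes`/`no`). Writers emit LF and exact column labels;
readers tolerate CRLF, spaces after commas, case-insensitive yes/no
variants, and accept a 9-column supporting file as the older schema
version (interference = unknown). The validator recomputes summary counts
and re-checks each printed hit rate against 100·active/tested at a 0.05
percentage-point tolerance (absorbing serialization rounding), and checks
that ranks form a permutation of 1..N.

## Synthetic data generator

The generator emulates the *structure* of a public screening extract, not
its chemistry or biology:

* **Library.** Series are planted by attaching k distinct R-groups (k
  uniform in 2–17) to a core scaffold drawn from 12 attachment-position
  variants of five scaffold families (phenyl, biphenyl, benzamide, indole,
  phenylpiperidine); 72 small R-groups (≤ 5 heavy atoms, hence always
  smaller than every core) guarantee capacity for globally unique
  structures. Decoy singletons each use a distinct ring scaffold disjoint
  from the template set, so decoys can never share an MMS core with a
  planted series or with each other.
* **Panel.** 400 primary assays; each series draws a tested-assay union U
  covering 65–95% of the panel (mirroring the hundreds of assays per
  compound and the 261–592-assay series unions typical of the data being
  emulated). `ceil(overlap·U)` assays are shared by all members; the rest
  go to random proper member subsets. `ceil(hr·U)` union assays are
  active-in-series; of these, `round(inconsistency·S)` shared assays get
  mixed outcomes (a random proper subset of members active), the rest are
  active for every tester. Default targets: cumulative HR 0.058 (the
  median series HR scale of extensively tested high-HR compounds),
  overlap 0.70, inconsistency 0.05. Feasibility requires
  hr ≥ inconsistency · overlap, since every inconsistent shared assay is
  an active assay; infeasible combinations abort with an explanation.
* **Decoys and confirmatory assays.** Decoys are tested at the same
  frequency with independent 0.4% per-assay activity (the background hit
  rate of typical screening compounds). Every compound is additionally
  tested in 3–15 of 40 confirmatory assays and is confirmatory-active with
  probability 0.9.
* **Realized vs target.** Integer assay counts cannot hit arbitrary
  fractions, so the ground truth records the realized counts and
  percentages; recovery tests assert *exact* equality of measured metrics
  with realized values, and closeness to targets within one assay's
  granularity (1/U, or 1/S for inconsistency). All draws come from one
  seeded NumPy generator; identical config + seed gives byte-identical
  outputs.

What passing tests show: the pipeline's bookkeeping (set arithmetic,
ranking, serialization) is exact, and extraction recovers every planted
membership. What they do not show: behaviour on real chemistry (tautomers,
salts, charge states), real assay heterogeneity (correlated panels,
dose–response semantics), or the adequacy of any particular interference
filter list.

## Problem sizes in the shipped tests

Unit and property tests use libraries of ≤ 50 compounds and panels of a
few hundred assays; the parameter-recovery suite runs 50 seeded replicates
at 20 series each; the deposition round-trip test writes 100+ series
(generated with 2–6 members per series so that 100 structurally unique
series fit the template capacity). The acceptance script regenerates the
default 20-series study conditions from the given seed and completes in a
few seconds.

## Known limitations

* Retrosynthetic rules are a pragmatic RECAP-style default, not a curated
  reproduction of any specific published rule set.
* Multi-site analog series (two or more substitution sites) are out of
  scope by design.
* Target-based aggregation of hit rates is not implemented (the semantics
  of assay→target aggregation are not fixed by the data model); target ids
  are carried through to the deposition only.
* The selection cascade's population-scale counts depend entirely on the
  input snapshot; only the mechanism is guaranteed.
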