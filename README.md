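# analogseries

Tools for mining **analog series (ASs) with high assay hit rates** from
large compound–assay screening panels, in the style of public
high-throughput screening repositories such as PubChem BioAssay.

Compounds that light up in many unrelated assays are either genuinely
promiscuous (interesting for polypharmacology) or assay-interference
artifacts (reactive, aggregating, autofluorescent). Single compounds are
hard to judge; *series of close analogs* provide built-in controls: if all
analogs sharing a core are active across many assays, interference is
likely, while consistent activity against the same targets points to real
promiscuity. This package implements the full workflow for building such a
resource:

1. **Compound selection** — per-compound hit rate HR = 100 ·
   (#active primary assays) / (#tested primary assays), followed by a
   three-stage cascade: keep compounds tested in more than 257 primary
   assays, then HR above the third quartile of that population, then HR
   above the median of the remainder (fixed thresholds may be substituted;
   all comparisons strict).
2. **MMS extraction** — matching molecular series (analog series with a
   single substitution site) are found by cutting every eligible acyclic
   single bond of every compound and grouping compounds by the canonical
   core fragment; retrosynthetic (RECAP-style) bond rules and substituent
   size caps are configurable.
3. **Series parameters** — for each series against the panel:
   *cumulative hit rate* = |∪ active assays| / |∪ tested assays|,
   *assay overlap* = |∩ tested assays| / |∪ tested assays|, and
   *inconsistent activity* = fraction of shared assays where some members
   are active and others inactive.
4. **Rank fusion** — series are ranked per criterion (high HR, high
   overlap, low inconsistency; average ranks for ties) and prioritized by
   the smallest sum of ranks (consensus rank).
5. **Interference flags** — SMARTS substructure filters (PAINS-style) mark
   interference candidates; series with no flagged member are classified
   interference-free.
6. **Deposition I/O** — writer/reader/validator for the two-file exchange
   format (`AS.txt`, `AS_SupportingInformation.txt`).

A synthetic-data generator plants analog series with controllable
cumulative HR, overlap and inconsistency, so every stage is testable
against known ground truth without any download.

## Worked example

```sh
analogseries simulate --seed 11 --out sim/
analogseries run-all --compounds sim/compounds.smi \
    --activity sim/activity.tsv --out results/
```

The first command emits a library of 210 compounds (20 planted series plus
10 decoys) and 58,986 assay outcomes. The second runs the full pipeline and
prints:

```
{"out_dir": "results/", "n_series": 9}
```

`results/run_manifest.json` records each stage, e.g. the selection cascade

```
stage A: n_tested_primary > 257      -> 132 survivors (median HR 4.89%)
stage B: HR > 5.42% (Q3 of stage A)  ->  33 survivors
stage C: HR > 5.88% (median of B)    ->  15 survivors
```

meaning 132 compounds were tested extensively enough, and the two
data-derived HR thresholds leave the 15 most frequently active compounds,
from which 9 series are extracted, scored, rank-fused and written to
`results/AS.txt` (one row per series: id, consensus rank, core SMILES, the
three parameters, member CIDs and SMILES) and
`results/AS_SupportingInformation.txt` (one row per compound–series
membership with per-compound assay counts, hit rate, active targets and
interference flag). `analogseries validate --as results/AS.txt --support
results/AS_SupportingInformation.txt` re-parses both files and reports
zero violations.

Each subcommand (`simulate`, `select`, `extract`, `metrics`, `flag`,
`write-deposition`, `validate`, `run-all`) is a thin wrapper over the
library API (`analogseries.build_series`, `compute_series_metrics`,
`rank_series`, ...), which can be used directly from Python.

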