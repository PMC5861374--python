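"""Per-compound hit rates and the quantile-cascade compound selection.

A compound's hit rate (HR) is the percentage of primary assays with a
definite outcome in which it was active.  Extensively tested, frequently
active compounds are selected by a three-stage cascade:

* stage A keeps compounds tested in more than ``min_primary_assays``
  primary assays (default 257);
* stage B keeps survivors with HR strictly above a first threshold — either
  a fixed percentage or the third quartile of the stage-A HR distribution;
* stage C keeps survivors with HR strictly above a second threshold — fixed
  or the median of the stage-B HR distribution.

All comparisons are strict.  Quantiles use linear interpolation between
order statistics (the "type 7" convention), so data-derived thresholds are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .activity_model import ActivityMatrix, AssayType


@dataclass(frozen=True)
class CompoundHitRate:
    """Primary- and confirmatory-assay testing and activity counts."""

    cid: str
    n_tested_primary: int
    n_active_primary: int
    n_tested_confirmatory: int
    n_active_confirmatory: int

    @property
    def hr_percent(self) -> Optional[float]:
        """Primary-assay hit rate in percent; None if never tested."""
        if self.n_tested_primary == 0:
            return None
        return 100.0 * self.n_active_primary / self.n_tested_primary


@dataclass(frozen=True)
class SelectionConfig:
    """Cascade thresholds.

    ``stage1`` / ``stage2`` are either a fixed HR percentage (float) or the
    data-derived rules ``"q3"`` / ``"median"`` evaluated on the respective
    surviving population.
    """

    min_primary_assays: int = 257
    stage1: Union[float, str] = "q3"
    stage2: Union[float, str] = "median"

    def __post_init__(self) -> None:
        if self.min_primary_assays < 0:
            raise ValueError("min_primary_assays must be non-negative")
        for name, rule, keyword in (("stage1", self.stage1, "q3"),
                                    ("stage2", self.stage2, "median")):
            if isinstance(rule, str):
                if rule != keyword:
                    raise ValueError(f"{name} rule must be {keyword!r} or a "
                                     f"fixed percentage, got {rule!r}")
            elif rule < 0:
                raise ValueError(f"{name} threshold must be non-negative")


class SelectionError(ValueError):
    """A cascade stage is empty or its inputs are unusable."""


def compute_hit_rates(matrix: ActivityMatrix) -> list[CompoundHitRate]:
    """One hit-rate record per compound in the matrix, sorted by cid."""
    stats = []
    for cid in sorted(matrix.compounds):
        stats.append(CompoundHitRate(
            cid=cid,
            n_tested_primary=len(matrix.tested(cid, AssayType.PRIMARY)),
            n_active_primary=len(matrix.active(cid, AssayType.PRIMARY)),
            n_tested_confirmatory=len(matrix.tested(cid,
                                                    AssayType.CONFIRMATORY)),
            n_active_confirmatory=len(matrix.active(cid,
                                                    AssayType.CONFIRMATORY)),
        ))
    return stats


def _defined_hrs(stats: Sequence[CompoundHitRate]) -> np.ndarray:
    values = [s.hr_percent for s in stats if s.hr_percent is not None]
    return np.asarray(values, dtype=float)


def hr_quantiles(stats: Sequence[CompoundHitRate]) -> tuple[float, float]:
    """(median, third quartile) of the defined hit rates.

    Linear interpolation between order statistics; compounds never tested in
    a primary assay are excluded.
    """
    values = _defined_hrs(stats)
    if values.size == 0:
        raise SelectionError("no compound has a defined hit rate")
    return (float(np.percentile(values, 50)),
            float(np.percentile(values, 75)))


def _median(values: np.ndarray) -> float:
    return float(np.percentile(values, 50))


def cascade_select(stats: Sequence[CompoundHitRate],
                   config: SelectionConfig | None = None,
                   ) -> tuple[list[str], dict]:
    """Run the three-stage cascade; return surviving cids and a report.

    The report records, per stage, the rule that ran (fixed vs data-derived),
    the realized threshold, the survivor count and the survivor median HR.
    A stage with zero survivors raises :class:`SelectionError`.
    """
    if config is None:
        config = SelectionConfig()
    if not stats:
        raise SelectionError("empty input")

    report: dict = {"stages": []}

    stage_a = [s for s in stats
               if s.n_tested_primary > config.min_primary_assays]
    if not stage_a:
        raise SelectionError("stage A: no compound tested in more than "
                             f"{config.min_primary_assays} primary assays")
    hrs_a = _defined_hrs(stage_a)
    report["stages"].append({
        "stage": "A", "rule": f"n_tested_primary > {config.min_primary_assays}",
        "threshold": config.min_primary_assays,
        "survivors": len(stage_a),
        "median_hr_percent": _median(hrs_a),
    })

    if config.stage1 == "q3":
        t1 = float(np.percentile(hrs_a, 75))
        mode1 = "q3-of-stage-A"
    else:
        t1 = float(config.stage1)
        mode1 = "fixed"
    stage_b = [s for s in stage_a
               if s.hr_percent is not None and s.hr_percent > t1]
    if not stage_b:
        raise SelectionError(f"stage B: no compound with HR > {t1}%")
    hrs_b = _defined_hrs(stage_b)
    report["stages"].append({
        "stage": "B", "rule": mode1, "threshold": t1,
        "survivors": len(stage_b),
        "median_hr_percent": _median(hrs_b),
    })

    if config.stage2 == "median":
        t2 = _median(hrs_b)
        mode2 = "median-of-stage-B"
    else:
        t2 = float(config.stage2)
        mode2 = "fixed"
    stage_c = [s for s in stage_b
               if s.hr_percent is not None and s.hr_percent > t2]
    if not stage_c:
        raise SelectionError(f"stage C: no compound with HR > {t2}%")
    hrs_c = _defined_hrs(stage_c)
    report["stages"].append({
        "stage": "C", "rule": mode2, "threshold": t2,
        "survivors": len(stage_c),
        "median_hr_percent": _median(hrs_c),
    })
    return [s.cid for s in stage_c], report


def confirmatory_consistency(selected: Sequence[str],
                             matrix: ActivityMatrix) -> float:
    """Fraction of selected compounds active in at least one confirmatory
    assay.

    Compounds never tested in a confirmatory assay stay in the denominator:
    the quantity asks how many of the selected compounds have confirmatory
    support, not how many confirm among the re-tested.
    """
    if not selected:
        raise SelectionError("empty selection")
    n_confirmed = sum(
        1 for cid in selected
        if len(matrix.active(cid, AssayType.CONFIRMATORY)) >= 1)
    return n_confirmed / len(selected)
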