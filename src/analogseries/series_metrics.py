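"""Series-level activity parameters and rank-fusion prioritization.

Three parameters characterize an analog series against an assay panel:

1. *Cumulative series hit rate* — unique assays in which at least one member
   was active, divided by the union of unique assays in which the members
   were tested (as a percentage).
2. *Assay overlap* — shared assays (tested by every member) divided by the
   union of tested assays.
3. *Inconsistent activity* — the proportion of shared assays in which some
   members were active and others inactive.

Series worth follow-up combine a high cumulative hit rate, high overlap and
low inconsistency, so each criterion is ranked separately (1 = best;
fractional/average ranks for ties) and series are prioritized by the
smallest sum of ranks — the consensus rank, with ties broken by series id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from scipy.stats import rankdata

from .activity_model import ActivityMatrix, AssayType
from .mms_extraction import AnalogSeries

logger = logging.getLogger(__name__)


class MetricsError(ValueError):
    """Raised when a series has no tested assays to score against."""


@dataclass(frozen=True)
class SeriesMetrics:
    """The three series parameters plus rank-fusion bookkeeping."""

    as_id: int
    cumulative_hr_percent: float
    assay_overlap_percent: float
    inconsistent_activity_percent: float
    n_union_assays: int
    n_shared_assays: int
    n_active_union_assays: int
    rank_hr: float = 0.0
    rank_overlap: float = 0.0
    rank_inconsistency: float = 0.0
    rank_sum: float = 0.0
    consensus_rank: int = 0


def _member_sets(series: AnalogSeries, matrix: ActivityMatrix,
                 assay_type: Optional[AssayType]):
    tested = [matrix.tested(cid, assay_type) for cid in series.member_cids]
    active = [matrix.active(cid, assay_type) for cid in series.member_cids]
    return tested, active


def cumulative_hit_rate(series: AnalogSeries, matrix: ActivityMatrix,
                        assay_type: Optional[AssayType] = None) -> float:
    """Percentage of the series' tested-assay union with >= 1 active member."""
    tested, active = _member_sets(series, matrix, assay_type)
    union = frozenset().union(*tested)
    if not union:
        raise MetricsError(f"series {series.as_id}: no member tested in any "
                           "assay")
    active_union = frozenset().union(*active)
    return 100.0 * len(active_union) / len(union)


def assay_overlap(series: AnalogSeries, matrix: ActivityMatrix,
                  assay_type: Optional[AssayType] = None) -> float:
    """Percentage of the tested-assay union tested by *every* member."""
    tested, _ = _member_sets(series, matrix, assay_type)
    union = frozenset().union(*tested)
    if not union:
        raise MetricsError(f"series {series.as_id}: no member tested in any "
                           "assay")
    shared = frozenset.intersection(*tested)
    return 100.0 * len(shared) / len(union)


def inconsistent_activity(series: AnalogSeries, matrix: ActivityMatrix,
                          assay_type: Optional[AssayType] = None) -> float:
    """Percentage of shared assays with both active and inactive members.

    A series without shared assays scores 0 (logged), keeping the ranking
    total.
    """
    tested, active = _member_sets(series, matrix, assay_type)
    shared = frozenset.intersection(*tested)
    if not shared:
        logger.info("series %s has no shared assays; inconsistency := 0",
                    series.as_id)
        return 0.0
    n_mixed = 0
    for assay in shared:
        n_active = sum(1 for act in active if assay in act)
        if 0 < n_active < len(active):
            n_mixed += 1
    return 100.0 * n_mixed / len(shared)


def compute_series_metrics(series: AnalogSeries, matrix: ActivityMatrix,
                           assay_type: Optional[AssayType] = None,
                           ) -> SeriesMetrics:
    """All three parameters for one series (ranks left at 0)."""
    tested, active = _member_sets(series, matrix, assay_type)
    union = frozenset().union(*tested)
    if not union:
        raise MetricsError(f"series {series.as_id}: no member tested in any "
                           "assay")
    shared = frozenset.intersection(*tested)
    active_union = frozenset().union(*active)
    return SeriesMetrics(
        as_id=series.as_id,
        cumulative_hr_percent=100.0 * len(active_union) / len(union),
        assay_overlap_percent=100.0 * len(shared) / len(union),
        inconsistent_activity_percent=inconsistent_activity(
            series, matrix, assay_type),
        n_union_assays=len(union),
        n_shared_assays=len(shared),
        n_active_union_assays=len(active_union),
    )


def rank_series(metrics: Sequence[SeriesMetrics]) -> list[SeriesMetrics]:
    """Fill per-criterion ranks, rank sums and consensus ranks.

    Cumulative hit rate and assay overlap are ranked descending (highest
    value gets rank 1), inconsistency ascending (lowest gets rank 1); tied
    values share the average rank of their block.  The consensus rank is the
    1-based position after sorting by (rank sum, series id), so it is a
    permutation of ``1..N``.  Input order is preserved in the output.
    """
    if not metrics:
        raise MetricsError("no series to rank")
    hr = [m.cumulative_hr_percent for m in metrics]
    ov = [m.assay_overlap_percent for m in metrics]
    inc = [m.inconsistent_activity_percent for m in metrics]
    rank_hr = rankdata([-v for v in hr], method="average")
    rank_ov = rankdata([-v for v in ov], method="average")
    rank_inc = rankdata(inc, method="average")
    ranked = [
        replace(m,
                rank_hr=float(rank_hr[i]),
                rank_overlap=float(rank_ov[i]),
                rank_inconsistency=float(rank_inc[i]),
                rank_sum=float(rank_hr[i] + rank_ov[i] + rank_inc[i]))
        for i, m in enumerate(metrics)
    ]
    order = sorted(range(len(ranked)),
                   key=lambda i: (ranked[i].rank_sum, ranked[i].as_id))
    consensus = {idx: pos + 1 for pos, idx in enumerate(order)}
    return [replace(m, consensus_rank=consensus[i])
            for i, m in enumerate(ranked)]


def write_metrics_table(metrics: Sequence[SeriesMetrics], path) -> None:
    """TSV export: as_id, AS_HR, Assay_OV, Inconsistent_activity, ranks."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("as_id\tAS_HR\tAssay_OV\tInconsistent_activity\t"
                 "rank_sum\tconsensus_rank\n")
        for m in metrics:
            fh.write(f"{m.as_id}\t{m.cumulative_hr_percent:.2f}\t"
                     f"{m.assay_overlap_percent:.2f}\t"
                     f"{m.inconsistent_activity_percent:.2f}\t"
                     f"{m.rank_sum:g}\t{m.consensus_rank}\n")
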