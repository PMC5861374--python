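"""Writer, reader and validator for the two-file open-access deposition.

The deposition format packages a prioritized collection of analog series as
two tab-separated text files:

``AS.txt``
    One row per series: series id, consensus rank, core SMILES with
    attachment token, the three series parameters (percent, 2 decimals),
    and the comma-separated member compound ids and SMILES.

``AS_SupportingInformation.txt``
    One row per (compound, series) membership: compound id and SMILES,
    series id / rank / core, the compound's primary-assay testing and
    activity counts with its hit rate, the targets it was active against,
    and whether it matched an assay-interference filter.

Writers emit LF line endings, headers with exact column labels, and
comma-separated list fields without spaces.  Readers tolerate CRLF,
whitespace around headers and spaces after commas, and accept a 9-column
supporting file as the older schema version without the interference
column (interference then reads as ``None`` = unknown).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .activity_model import CompoundRecord
from .compound_selection import CompoundHitRate
from .interference_flags import FlagResult
from .mms_extraction import AnalogSeries
from .series_metrics import SeriesMetrics

AS_FILENAME = "AS.txt"
SUPPORT_FILENAME = "AS_SupportingInformation.txt"

AS_COLUMNS = (
    "AS_ID", "Rank", "MMS_core", "AS_HR [%]", "Assay_OV [%]",
    "Inconsistent_activity [%]", "CID", "AromaticNon-StereoSMILES",
)
SUPPORT_COLUMNS = (
    "CID", "AromaticNon-StereoSMILES", "AS_ID", "Rank", "MMS_core",
    "#primary_assays", "#active_primary_assays", "Hit_rate(%)",
    "Target_ID", "Interference CPD",
)

_YES_TOKENS = {"yes", "true", "1"}
_NO_TOKENS = {"no", "false", "0"}


class DepositionError(ValueError):
    """Fatal schema, parse or referential-integrity failure."""


@dataclass(frozen=True)
class DepositionRow:
    """One ``AS.txt`` row (column order fixed by :data:`AS_COLUMNS`)."""

    as_id: int
    rank: int
    mms_core: str
    as_hr_percent: float
    assay_ov_percent: float
    inconsistent_activity_percent: float
    cids: tuple[str, ...]
    smiles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.cids) != len(self.smiles) or len(self.cids) < 2:
            raise DepositionError(
                f"AS {self.as_id}: CID and SMILES lists must have equal "
                f"length >= 2")
        for value in (self.as_hr_percent, self.assay_ov_percent,
                      self.inconsistent_activity_percent):
            if not 0.0 <= value <= 100.0:
                raise DepositionError(
                    f"AS {self.as_id}: percentage {value} out of [0, 100]")
        if self.rank < 1:
            raise DepositionError(f"AS {self.as_id}: rank must be positive")


@dataclass(frozen=True)
class SupportRow:
    """One supporting-information row (one compound-series membership)."""

    cid: str
    smiles: str
    as_id: int
    rank: int
    mms_core: str
    n_primary_assays: int
    n_active_primary_assays: int
    hit_rate_percent: float
    target_ids: tuple[str, ...]
    interference: Optional[bool]  # None = unknown (older schema version)

    def __post_init__(self) -> None:
        if self.n_active_primary_assays > self.n_primary_assays:
            raise DepositionError(
                f"compound {self.cid}: active count exceeds tested count")


# ---------------------------------------------------------------------------
# building rows from pipeline results
# ---------------------------------------------------------------------------

def build_deposition(series_list: Sequence[AnalogSeries],
                     metrics: Mapping[int, SeriesMetrics],
                     stats: Mapping[str, CompoundHitRate],
                     flags: Mapping[str, FlagResult],
                     compounds: Mapping[str, CompoundRecord],
                     targets: Mapping[str, Sequence[str]] | None = None,
                     ) -> tuple[list[DepositionRow], list[SupportRow]]:
    """Assemble deposition and support rows, ordered by consensus rank.

    ``targets`` maps cid to the target ids the compound was active against
    (may be omitted).  Every series member must have a hit-rate record, a
    flag and a compound record, else :class:`DepositionError` names the
    offender.
    """
    targets = targets or {}
    dep_rows: list[DepositionRow] = []
    support_rows: list[SupportRow] = []
    for series in series_list:
        m = metrics.get(series.as_id)
        if m is None:
            raise DepositionError(f"series {series.as_id}: missing metrics")
        if m.consensus_rank < 1:
            raise DepositionError(
                f"series {series.as_id}: consensus rank not assigned")
        cids, smiles = [], []
        for cid in series.member_cids:
            comp = compounds.get(cid)
            if comp is None:
                raise DepositionError(
                    f"series {series.as_id}: member {cid!r} has no compound "
                    "record")
            cids.append(cid)
            smiles.append(comp.smiles)
        dep_rows.append(DepositionRow(
            as_id=series.as_id,
            rank=m.consensus_rank,
            mms_core=series.core_smiles,
            as_hr_percent=m.cumulative_hr_percent,
            assay_ov_percent=m.assay_overlap_percent,
            inconsistent_activity_percent=m.inconsistent_activity_percent,
            cids=tuple(cids),
            smiles=tuple(smiles),
        ))
        for cid in series.member_cids:
            stat = stats.get(cid)
            if stat is None:
                raise DepositionError(
                    f"series {series.as_id}: member {cid!r} has no hit-rate "
                    "record")
            flag = flags.get(cid)
            if flag is None:
                raise DepositionError(
                    f"series {series.as_id}: member {cid!r} has no "
                    "interference flag")
            support_rows.append(SupportRow(
                cid=cid,
                smiles=compounds[cid].smiles,
                as_id=series.as_id,
                rank=m.consensus_rank,
                mms_core=series.core_smiles,
                n_primary_assays=stat.n_tested_primary,
                n_active_primary_assays=stat.n_active_primary,
                hit_rate_percent=stat.hr_percent or 0.0,
                target_ids=tuple(sorted(targets.get(cid, ()))),
                interference=flag.flagged,
            ))
    dep_rows.sort(key=lambda r: r.rank)
    support_rows.sort(key=lambda r: (r.rank, r.as_id, r.cid))
    return dep_rows, support_rows


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _fmt_pct(value: float) -> str:
    return f"{value:.2f}"


def write_deposition(dep_rows: Sequence[DepositionRow],
                     support_rows: Sequence[SupportRow],
                     out_dir) -> tuple[str, str]:
    """Write ``AS.txt`` and ``AS_SupportingInformation.txt`` into *out_dir*.

    Rows are written in ascending rank order; returns the two file paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    as_path = os.path.join(out_dir, AS_FILENAME)
    support_path = os.path.join(out_dir, SUPPORT_FILENAME)
    with open(as_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(AS_COLUMNS) + "\n")
        for row in sorted(dep_rows, key=lambda r: r.rank):
            fh.write("\t".join((
                str(row.as_id), str(row.rank), row.mms_core,
                _fmt_pct(row.as_hr_percent),
                _fmt_pct(row.assay_ov_percent),
                _fmt_pct(row.inconsistent_activity_percent),
                ",".join(row.cids), ",".join(row.smiles),
            )) + "\n")
    with open(support_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SUPPORT_COLUMNS) + "\n")
        for row in sorted(support_rows, key=lambda r: (r.rank, r.as_id,
                                                       r.cid)):
            interference = {True: "yes", False: "no", None: ""}[
                row.interference]
            fh.write("\t".join((
                row.cid, row.smiles, str(row.as_id), str(row.rank),
                row.mms_core, str(row.n_primary_assays),
                str(row.n_active_primary_assays),
                _fmt_pct(row.hit_rate_percent),
                ",".join(row.target_ids), interference,
            )) + "\n")
    return as_path, support_path


def _split_list(field: str) -> tuple[str, ...]:
    if not field.strip():
        return ()
    return tuple(item.strip() for item in field.split(","))


def _parse_interference(token: str) -> Optional[bool]:
    t = token.strip().lower()
    if t in _YES_TOKENS:
        return True
    if t in _NO_TOKENS:
        return False
    if t == "":
        return None
    raise DepositionError(f"unrecognized interference token {token!r}")


def read_deposition(as_path, support_path,
                    ) -> tuple[list[DepositionRow], list[SupportRow]]:
    """Parse both files and check cross-file referential integrity.

    Every AS_ID must appear in both files, and every CID listed in an
    ``AS.txt`` row must have a support row for that AS_ID (and vice versa).
    A 9-column support file is accepted as the older schema version; its
    interference flags read as unknown.
    """
    dep_rows = _read_as_file(as_path)
    support_rows = _read_support_file(support_path)

    as_ids = {r.as_id for r in dep_rows}
    support_ids = {r.as_id for r in support_rows}
    if as_ids != support_ids:
        missing = sorted(as_ids ^ support_ids)
        raise DepositionError(
            f"AS_ID sets differ between files; unmatched ids: {missing}")
    memberships = {(r.as_id, r.cid) for r in support_rows}
    if len(memberships) != len(support_rows):
        raise DepositionError("duplicate (CID, AS_ID) support rows")
    expected = {(r.as_id, cid) for r in dep_rows for cid in r.cids}
    if memberships != expected:
        unmatched = sorted(memberships ^ expected)[:10]
        raise DepositionError(
            f"membership mismatch between files; e.g. {unmatched}")
    return dep_rows, support_rows


def _read_rows(path, expected_columns, min_fields):
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DepositionError(f"{path}: empty file (missing header)")
    header = [h.strip() for h in lines[0].split("\t")]
    n_cols = len(header)
    if header != list(expected_columns[:n_cols]) or n_cols < min_fields:
        raise DepositionError(
            f"{path}: header mismatch; expected {list(expected_columns)}, "
            f"found {header}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise DepositionError(
                f"{path}:{lineno}: expected {n_cols} fields, found "
                f"{len(fields)}")
        rows.append((lineno, fields))
    return n_cols, rows


def _read_as_file(path) -> list[DepositionRow]:
    _, raw = _read_rows(path, AS_COLUMNS, len(AS_COLUMNS))
    rows = []
    for lineno, f in raw:
        try:
            rows.append(DepositionRow(
                as_id=int(f[0]), rank=int(f[1]), mms_core=f[2],
                as_hr_percent=float(f[3]), assay_ov_percent=float(f[4]),
                inconsistent_activity_percent=float(f[5]),
                cids=_split_list(f[6]), smiles=_split_list(f[7]),
            ))
        except (ValueError, DepositionError) as exc:
            raise DepositionError(f"{path}:{lineno}: {exc}") from exc
    return rows


def _read_support_file(path) -> list[SupportRow]:
    n_cols, raw = _read_rows(path, SUPPORT_COLUMNS, len(SUPPORT_COLUMNS) - 1)
    rows = []
    for lineno, f in raw:
        try:
            interference = (_parse_interference(f[9]) if n_cols == 10
                            else None)
            rows.append(SupportRow(
                cid=f[0], smiles=f[1], as_id=int(f[2]), rank=int(f[3]),
                mms_core=f[4], n_primary_assays=int(f[5]),
                n_active_primary_assays=int(f[6]),
                hit_rate_percent=float(f[7]),
                target_ids=_split_list(f[8]),
                interference=interference,
            ))
        except (ValueError, DepositionError) as exc:
            raise DepositionError(f"{path}:{lineno}: {exc}") from exc
    return rows


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Summary statistics and violations for a parsed deposition."""

    n_series: int
    n_memberships: int
    n_unique_compounds: int
    n_compounds_in_multiple_series: int
    members_per_series_min: int
    members_per_series_max: int
    as_hr_min: float
    as_hr_max: float
    as_hr_median: float
    n_interference_free_series: int
    violations: list[str]
    warnings: list[str]

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_text(self) -> str:
        lines = ["deposition validation report"]
        for key, value in self.to_dict().items():
            if key in ("violations", "warnings"):
                continue
            lines.append(f"  {key}: {value}")
        for label in ("warnings", "violations"):
            for item in getattr(self, label):
                lines.append(f"  {label[:-1]}: {item}")
        return "\n".join(lines)


def validate_deposition(dep_rows: Sequence[DepositionRow],
                        support_rows: Sequence[SupportRow],
                        tolerance: float = 0.05) -> ValidationReport:
    """Recompute summary statistics and re-check per-row hit rates.

    ``tolerance`` is the absolute tolerance (percentage points) for
    comparing the printed hit rate against 100 x active / tested, absorbing
    serialization rounding.  Violations are listed, never raised.
    """
    import numpy as np

    violations: list[str] = []
    warnings: list[str] = []

    membership_cids = [r.cid for r in support_rows]
    unique_cids = set(membership_cids)
    from collections import Counter
    multi = sum(1 for _, n in Counter(membership_cids).items() if n >= 2)

    sizes = [len(r.cids) for r in dep_rows]
    hrs = [r.as_hr_percent for r in dep_rows]
    if not dep_rows:
        warnings.append("deposition contains zero series")

    # interference-free series: all memberships say "no"
    by_series: dict[int, list[Optional[bool]]] = {}
    for r in support_rows:
        by_series.setdefault(r.as_id, []).append(r.interference)
    n_free = sum(1 for flags in by_series.values()
                 if flags and all(f is False for f in flags))

    for r in support_rows:
        if r.n_primary_assays == 0:
            if r.hit_rate_percent != 0.0:
                violations.append(
                    f"CID {r.cid} AS {r.as_id}: nonzero hit rate with zero "
                    "tested assays")
            continue
        expected = 100.0 * r.n_active_primary_assays / r.n_primary_assays
        if abs(expected - r.hit_rate_percent) > tolerance:
            violations.append(
                f"CID {r.cid} AS {r.as_id}: Hit_rate(%) {r.hit_rate_percent}"
                f" != 100*{r.n_active_primary_assays}/{r.n_primary_assays}"
                f" = {expected:.4f}")

    ranks = sorted(r.rank for r in dep_rows)
    if ranks != list(range(1, len(dep_rows) + 1)):
        violations.append("Rank column is not a permutation of 1..N")

    return ValidationReport(
        n_series=len(dep_rows),
        n_memberships=len(support_rows),
        n_unique_compounds=len(unique_cids),
        n_compounds_in_multiple_series=multi,
        members_per_series_min=min(sizes) if sizes else 0,
        members_per_series_max=max(sizes) if sizes else 0,
        as_hr_min=min(hrs) if hrs else 0.0,
        as_hr_max=max(hrs) if hrs else 0.0,
        as_hr_median=float(np.median(hrs)) if hrs else 0.0,
        n_interference_free_series=n_free,
        violations=violations,
        warnings=warnings,
    )
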