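"""Compound and compound-assay outcome data model.

The central container is :class:`ActivityMatrix`, a sparse ternary store of
screening outcomes: each (compound, assay) pair is either *active*,
*inactive*, or absent (untested).  Hit-rate statistics only ever count pairs
with a definite outcome, so non-binary outcome tokens found in public
screening extracts (``inconclusive``, ``unspecified``, ...) are dropped at
read time and counted in the reader's log.

File formats are deliberately minimal: a two-column SMILES file for
compounds (SMILES TAB id) and a five-column TSV for outcomes
(cid, assay_id, assay_type, outcome, target_id), both UTF-8 with tab as the
only separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

logger = logging.getLogger(__name__)


class AssayType(str, Enum):
    PRIMARY = "primary"
    CONFIRMATORY = "confirmatory"


class TableFormatError(ValueError):
    """Fatal error in an input table (duplicates, conflicts, bad tokens)."""


@dataclass(frozen=True)
class CompoundRecord:
    """One screening compound: opaque id plus canonical structure.

    ``smiles`` is stored in canonical aromatic non-stereo form and must
    describe a single connected molecule; ``heavy_atoms`` is its
    non-hydrogen atom count.
    """

    cid: str
    smiles: str
    heavy_atoms: int

    @classmethod
    def from_smiles(cls, cid: str, smiles: str) -> "CompoundRecord":
        from .mms_extraction import SmilesError, canonicalize, heavy_atom_count

        canonical = canonicalize(smiles)
        if "." in canonical:
            raise SmilesError(
                f"compound {cid}: SMILES describes multiple fragments: "
                f"{smiles!r}")
        if "*" in canonical:
            raise SmilesError(
                f"compound {cid}: SMILES contains an attachment point: "
                f"{smiles!r}")
        return cls(cid=cid, smiles=canonical,
                   heavy_atoms=heavy_atom_count(canonical))


@dataclass(frozen=True)
class AssayRecord:
    """One assay: id, primary/confirmatory type, optional target id."""

    assay_id: str
    assay_type: AssayType
    target_id: Optional[str] = None


class ActivityMatrix:
    """Sparse compound x assay outcome store with assay metadata.

    Pairs absent from the outcome map are untested.  ``tested(cid)`` and
    ``active(cid)`` return frozen assay-id sets, optionally restricted to
    one assay type; ``active`` is always a subset of ``tested``.
    """

    def __init__(self) -> None:
        self._assays: dict[str, AssayRecord] = {}
        self._outcomes: dict[tuple[str, str], bool] = {}
        self._tested: dict[str, set[str]] = {}
        self._active: dict[str, set[str]] = {}

    # -- construction -----------------------------------------------------

    def add_assay(self, record: AssayRecord) -> None:
        existing = self._assays.get(record.assay_id)
        if existing is None:
            self._assays[record.assay_id] = record
            return
        if existing.assay_type != record.assay_type:
            raise TableFormatError(
                f"assay {record.assay_id}: conflicting assay types "
                f"({existing.assay_type.value} vs "
                f"{record.assay_type.value})")
        # target annotation may be present on only some rows
        if existing.target_id is None and record.target_id is not None:
            self._assays[record.assay_id] = record
        elif (existing.target_id is not None and record.target_id is not None
              and existing.target_id != record.target_id):
            raise TableFormatError(
                f"assay {record.assay_id}: conflicting target ids "
                f"({existing.target_id} vs {record.target_id})")

    def add_outcome(self, cid: str, assay_id: str, active: bool) -> bool:
        """Record one outcome; returns False for an identical duplicate.

        Raises :class:`TableFormatError` if the pair already holds the
        opposite outcome (hit rates are ill-defined under contradiction).
        """
        if assay_id not in self._assays:
            raise TableFormatError(f"unknown assay id {assay_id!r}")
        key = (cid, assay_id)
        prev = self._outcomes.get(key)
        if prev is not None:
            if prev != active:
                raise TableFormatError(
                    f"conflicting outcomes for compound {cid!r} in assay "
                    f"{assay_id!r}")
            return False
        self._outcomes[key] = active
        self._tested.setdefault(cid, set()).add(assay_id)
        if active:
            self._active.setdefault(cid, set()).add(assay_id)
        return True

    # -- queries ----------------------------------------------------------

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(self._tested)

    @property
    def assays(self) -> dict[str, AssayRecord]:
        return dict(self._assays)

    @property
    def n_outcomes(self) -> int:
        return len(self._outcomes)

    def outcome(self, cid: str, assay_id: str) -> Optional[bool]:
        return self._outcomes.get((cid, assay_id))

    def _restrict(self, ids: set[str],
                  assay_type: Optional[AssayType]) -> frozenset[str]:
        if assay_type is None:
            return frozenset(ids)
        return frozenset(a for a in ids
                         if self._assays[a].assay_type == assay_type)

    def tested(self, cid: str,
               assay_type: Optional[AssayType] = None) -> frozenset[str]:
        return self._restrict(self._tested.get(cid, set()), assay_type)

    def active(self, cid: str,
               assay_type: Optional[AssayType] = None) -> frozenset[str]:
        return self._restrict(self._active.get(cid, set()), assay_type)

    def iter_outcomes(self):
        """Yield (cid, assay_id, active) in insertion order."""
        for (cid, assay_id), active in self._outcomes.items():
            yield cid, assay_id, active


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_OUTCOME_TOKENS = {"active": True, "inactive": False}


def read_compound_table(path, on_error: str = "fail") -> list[CompoundRecord]:
    """Read a two-column SMILES file (SMILES TAB id) into compound records.

    An optional header line is detected by label tokens ("smiles", "id").
    With
    ``on_error="fail"`` (default) an unparsable SMILES aborts with the line
    number; with ``on_error="skip"`` the row is skipped and logged.
    Duplicate ids are always fatal.
    """
    from .mms_extraction import SmilesError

    if on_error not in ("fail", "skip"):
        raise ValueError("on_error must be 'fail' or 'skip'")
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    n_skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise TableFormatError(
                    f"{path}:{lineno}: expected 'SMILES<TAB>id', got "
                    f"{line!r}")
            smiles, cid = fields[0].strip(), fields[1].strip()
            if (lineno == 1 and smiles.lower() in ("smiles",)
                    and cid.lower() in ("id", "cid", "compound_id")):
                logger.info("treating first line of %s as header", path)
                continue
            try:
                record = CompoundRecord.from_smiles(cid, smiles)
            except SmilesError as exc:
                if on_error == "skip":
                    logger.warning("%s:%d: skipping row: %s", path, lineno, exc)
                    n_skipped += 1
                    continue
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
            if cid in seen:
                raise TableFormatError(
                    f"{path}:{lineno}: duplicate compound id {cid!r}")
            seen.add(cid)
            records.append(record)
    if n_skipped:
        logger.warning("%s: skipped %d unparsable rows", path, n_skipped)
    return records


def write_compound_table(records: Iterable[CompoundRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.cid}\n")


def read_activity_table(path) -> ActivityMatrix:
    """Read a five-column outcome TSV into an :class:`ActivityMatrix`.

    Columns: cid, assay_id, assay_type, outcome, target_id (may be empty).
    Rows whose outcome is neither ``active`` nor ``inactive`` are dropped
    (counted in ``matrix.n_dropped_outcomes``); identical duplicate rows are
    deduplicated (``matrix.n_duplicate_rows``); contradictory duplicates and
    unknown assay types are fatal.
    """
    matrix = ActivityMatrix()
    n_dropped = 0
    n_duplicates = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 4:
                raise TableFormatError(
                    f"{path}:{lineno}: expected at least 4 tab-separated "
                    f"columns, got {line!r}")
            cid, assay_id, type_token, outcome_token = fields[:4]
            target = fields[4] if len(fields) > 4 and fields[4] else None
            type_token_l = type_token.lower()
            outcome_l = outcome_token.lower()
            if (lineno == 1 and type_token_l not in ("primary", "confirmatory")
                    and outcome_l not in _OUTCOME_TOKENS
                    and outcome_l not in ("inconclusive", "unspecified",
                                          "probe")):
                # header line: labels in place of both data-token columns
                logger.info("treating first line of %s as header", path)
                continue
            try:
                assay_type = AssayType(type_token_l)
            except ValueError:
                raise TableFormatError(
                    f"{path}:{lineno}: unknown assay_type {type_token!r}"
                ) from None
            if outcome_l not in _OUTCOME_TOKENS:
                n_dropped += 1
                continue
            matrix.add_assay(AssayRecord(assay_id=assay_id,
                                         assay_type=assay_type,
                                         target_id=target))
            try:
                added = matrix.add_outcome(cid, assay_id,
                                           _OUTCOME_TOKENS[outcome_l])
            except TableFormatError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
            if not added:
                n_duplicates += 1
    if n_dropped:
        logger.info("%s: dropped %d rows with non-binary outcomes",
                    path, n_dropped)
    if n_duplicates:
        logger.info("%s: deduplicated %d identical rows", path, n_duplicates)
    matrix.n_dropped_outcomes = n_dropped
    matrix.n_duplicate_rows = n_duplicates
    return matrix


def write_activity_table(matrix: ActivityMatrix, path) -> None:
    """Write a matrix back to the five-column TSV format (with header)."""
    assays = matrix.assays
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cid\tassay_id\tassay_type\toutcome\ttarget_id\n")
        for cid, assay_id, active in matrix.iter_outcomes():
            rec = assays[assay_id]
            outcome = "active" if active else "inactive"
            target = rec.target_id or ""
            fh.write(f"{cid}\t{assay_id}\t{rec.assay_type.value}\t"
                     f"{outcome}\t{target}\n")
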