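"""Synthetic analog libraries and simulated assay panels with known truth.

The generator plants single-site analog series by attaching distinct
R-groups to shared core scaffolds, adds structurally unrelated decoy
singletons, and then simulates a primary-assay screening panel in which
each planted series realizes a controllable cumulative hit rate, assay
overlap and inconsistency.  Because assay counts are integers, the exact
target fractions are usually unattainable; the generator therefore records
the *realized* values (counts included) in its ground truth, and recovery
tests compare against those — the realized value is always within one
assay's granularity of the target.

Default scales mirror a large public screening extract: a panel of 400
primary assays, per-series tested-assay unions covering 65-95% of the
panel (members are each tested in hundreds of assays), series of 2-17
members, series-level cumulative hit rates near 6%, and decoys with
background hit rates below half a percent.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .activity_model import (ActivityMatrix, AssayRecord, AssayType,
                             CompoundRecord)
from .mms_extraction import SmilesError, attach

logger = logging.getLogger(__name__)

#: Core scaffolds with one open valence, used to plant analog series.
#: Five scaffold families (phenyl, biphenyl, benzamide, indole,
#: phenylpiperidine) with attachment-position variants, so that large
#: libraries of structurally unique analogs can be assembled.
DEFAULT_CORE_TEMPLATES: tuple[str, ...] = (
    "[*]c1ccccc1",                    # phenyl
    "[*]Cc1ccccc1",                   # benzyl
    "[*]c1ccc(C)cc1",                 # p-tolyl
    "[*]c1ccc(-c2ccccc2)cc1",         # biphenyl (para)
    "[*]c1cccc(-c2ccccc2)c1",         # biphenyl (meta)
    "[*]NC(=O)c1ccccc1",              # benzamide (N-substituted)
    "[*]C(=O)Nc1ccccc1",              # benzanilide-type (C-substituted)
    "[*]c1cc2ccccc2[nH]1",            # indole (2-substituted)
    "[*]c1c[nH]c2ccccc12",            # indole (3-substituted)
    "[*]c1ccc2[nH]ccc2c1",            # indole (5-substituted)
    "[*]N1CCC(c2ccccc2)CC1",          # 4-phenylpiperidine (N-substituted)
    "[*]c1ccc(N2CCCCC2)cc1",          # 1-phenylpiperidine (ring-substituted)
)

#: Small substituents (each <= 5 heavy atoms, one attachment point), kept
#: strictly smaller than every core template so extraction with the
#: smaller-than-core rule always recovers the planted cut.
DEFAULT_R_GROUPS: tuple[str, ...] = (
    "[*]C", "[*]CC", "[*]CCC", "[*]C(C)C", "[*]CCCC", "[*]C(C)(C)C",
    "[*]CC(C)C", "[*]CCCCC", "[*]C(C)CC", "[*]CC(C)(C)C",
    "[*]C1CC1", "[*]CC1CC1", "[*]C1CCC1", "[*]C1CCCC1",
    "[*]F", "[*]Cl", "[*]Br", "[*]I",
    "[*]CF", "[*]CCF", "[*]C(F)(F)F", "[*]CC(F)(F)F", "[*]C(Cl)(Cl)Cl",
    "[*]CCl", "[*]CCCl", "[*]CBr",
    "[*]O", "[*]OC", "[*]OCC", "[*]OCCC", "[*]OC(C)C", "[*]OCCCC",
    "[*]OC(C)(C)C", "[*]OCC=C", "[*]OC(C)=O",
    "[*]CO", "[*]CCO", "[*]CCCO", "[*]C(C)O",
    "[*]C(C)=O", "[*]C(=O)CC", "[*]C=O",
    "[*]C(=O)O", "[*]C(=O)OC", "[*]C(=O)OCC",
    "[*]N", "[*]NC", "[*]N(C)C", "[*]NCC", "[*]NCCC", "[*]N(C)CC",
    "[*]NC(C)C", "[*]CN", "[*]CCN", "[*]CN(C)C",
    "[*]C(=O)N", "[*]C(=O)NC", "[*]CC(N)=O", "[*]NC(C)=O",
    "[*]C#N", "[*]CC#N", "[*]CCC#N", "[*][N+](=O)[O-]",
    "[*]S", "[*]SC", "[*]SCC", "[*]SC(C)C",
    "[*]S(C)(=O)=O", "[*]S(N)(=O)=O",
    "[*]C=C", "[*]CC=C", "[*]C#C", "[*]CC#C",
)

#: Ring scaffolds for decoy singletons.  Each is used at most once per
#: library and is distinct from every core template, so decoys never share
#: an MMS core with a planted series or with each other.
DECOY_SCAFFOLDS: tuple[str, ...] = (
    "[*]C1CCCCC1", "[*]C1CCCC1", "[*]C1CCCCCC1",
    "[*]C1CCNCC1", "[*]C1CCOCC1", "[*]C1CCSCC1",
    "[*]C1CCNC1", "[*]C1CCOC1", "[*]C1CNCCN1", "[*]C1COCCO1",
    "[*]c1ccncc1", "[*]c1cccnc1", "[*]c1ccoc1", "[*]c1ccsc1",
    "[*]c1cnccn1", "[*]c1ccc2ccccc2c1", "[*]C1CCC2CCCCC2C1",
    "[*]c1cncnc1", "[*]C1CCNCC1C", "[*]c1cc[nH]c1",
    "[*]C1CCC(=O)CC1", "[*]C1CCC(O)CC1", "[*]C1CCCNC1",
)


class SyntheticError(ValueError):
    """Infeasible configuration or generation failure."""


@dataclass
class SyntheticConfig:
    """Generator parameters.

    ``target_cumulative_hr``, ``target_overlap`` and
    ``target_inconsistency`` are fractions in [0, 1]; realized values are
    the nearest attainable counts.  Consistency requires (per series)
    roughly ``target_cumulative_hr >= target_inconsistency x
    target_overlap``, because every inconsistent shared assay is an active
    assay.
    """

    n_series: int = 20
    members_min: int = 2
    members_max: int = 17
    core_templates: Sequence[str] = DEFAULT_CORE_TEMPLATES
    r_groups: Sequence[str] = DEFAULT_R_GROUPS
    n_assays: int = 400
    n_confirmatory_assays: int = 40
    union_frac_min: float = 0.65
    union_frac_max: float = 0.95
    target_cumulative_hr: float = 0.058
    target_overlap: float = 0.7
    target_inconsistency: float = 0.05
    decoy_compounds: int = 10
    decoy_hit_rate: float = 0.004
    confirmatory_active_prob: float = 0.9
    target_annotation_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.members_min <= self.members_max):
            raise SyntheticError("members range must satisfy "
                                 "2 <= min <= max")
        if len(self.r_groups) < self.members_max:
            raise SyntheticError("need at least members_max distinct "
                                 "r_groups")
        for name in ("union_frac_min", "union_frac_max",
                     "target_cumulative_hr", "target_overlap",
                     "target_inconsistency", "decoy_hit_rate",
                     "confirmatory_active_prob",
                     "target_annotation_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SyntheticError(f"{name} must be in [0, 1]")
        if self.union_frac_min > self.union_frac_max:
            raise SyntheticError("union_frac_min > union_frac_max")
        if self.target_inconsistency > 0 and self.target_overlap == 0:
            raise SyntheticError(
                "inconsistent activity requires shared assays: "
                "target_inconsistency > 0 needs target_overlap > 0")
        if self.decoy_compounds > len(DECOY_SCAFFOLDS):
            raise SyntheticError(
                f"at most {len(DECOY_SCAFFOLDS)} decoys supported "
                "(one distinct scaffold each)")


@dataclass
class SeriesTruth:
    """Planted series: membership plus target and realized parameters."""

    label: str
    core_template: str
    member_cids: tuple[str, ...]
    target_hr: float
    target_overlap: float
    target_inconsistency: float
    n_union: int = 0
    n_shared: int = 0
    n_active_union: int = 0
    n_inconsistent: int = 0
    realized_hr_percent: float = 0.0
    realized_overlap_percent: float = 0.0
    realized_inconsistency_percent: float = 0.0


@dataclass
class GroundTruth:
    """Everything the generator knows about the emitted data."""

    series: list[SeriesTruth]
    decoy_cids: tuple[str, ...]
    compound_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    # cid -> (n_tested_primary, n_active_primary), filled by simulate_assays

    def to_json(self, path) -> None:
        payload = {
            "series": [dict(s.__dict__) for s in self.series],
            "decoy_cids": list(self.decoy_cids),
            "compound_counts": {k: list(v)
                                for k, v in self.compound_counts.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def generate_library(config: SyntheticConfig,
                     ) -> tuple[list[CompoundRecord], GroundTruth]:
    """Build the compound library and the ground-truth skeleton.

    For each series a core template and k distinct R-groups are drawn and
    attached; attachment failures or duplicate structures skip to the next
    R-group.  Decoys each use a distinct ring scaffold, so they share no
    core with any planted series.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    compounds: list[CompoundRecord] = []
    truth_series: list[SeriesTruth] = []
    seen_structures: set[str] = set()
    next_cid = 1001

    templates = list(config.core_templates)
    r_groups = list(config.r_groups)

    def _grow_members(template: str, k: int) -> list[str]:
        nonlocal next_cid
        member_cids: list[str] = []
        for idx in rng.permutation(len(r_groups)):
            if len(member_cids) == k:
                break
            try:
                smiles = attach(template, r_groups[int(idx)])
            except Exception as exc:  # valence failure on attachment
                logger.info("skipping r-group %s on %s (%s)",
                            r_groups[int(idx)], template, exc)
                continue
            if smiles in seen_structures:
                continue
            cid = str(next_cid)
            next_cid += 1
            try:
                compounds.append(CompoundRecord.from_smiles(cid, smiles))
            except SmilesError:
                next_cid -= 1
                continue
            seen_structures.add(smiles)
            member_cids.append(cid)
        return member_cids

    for i in range(config.n_series):
        k = int(rng.integers(config.members_min, config.members_max + 1))
        template = templates[int(rng.integers(len(templates)))]
        def _rollback(cids: list[str]) -> None:
            nonlocal next_cid
            for _ in cids:
                comp = compounds.pop()
                seen_structures.discard(comp.smiles)
                next_cid -= 1

        member_cids = _grow_members(template, k)
        if len(member_cids) < 2:
            # core exhausted by earlier series: try the other templates
            _rollback(member_cids)
            for alt in rng.permutation(len(templates)):
                template = templates[int(alt)]
                member_cids = _grow_members(template, k)
                if len(member_cids) >= 2:
                    break
                _rollback(member_cids)
        if len(member_cids) < 2:
            raise SyntheticError(
                f"series {i + 1}: could not assemble 2 valid members from "
                "the configured core templates and r_groups")
        if len(member_cids) < k:
            logger.info("series %d: only %d of %d members available on %s",
                        i + 1, len(member_cids), k, template)
        truth_series.append(SeriesTruth(
            label=f"S{i + 1:03d}",
            core_template=template,
            member_cids=tuple(member_cids),
            target_hr=config.target_cumulative_hr,
            target_overlap=config.target_overlap,
            target_inconsistency=config.target_inconsistency,
        ))

    decoy_cids: list[str] = []
    scaffold_order = rng.permutation(len(DECOY_SCAFFOLDS))
    for j in range(config.decoy_compounds):
        scaffold = DECOY_SCAFFOLDS[int(scaffold_order[j])]
        smiles = None
        for idx in rng.permutation(len(r_groups)):
            try:
                candidate = attach(scaffold, r_groups[int(idx)])
            except Exception:
                continue
            if candidate not in seen_structures:
                smiles = candidate
                break
        if smiles is None:
            raise SyntheticError(f"decoy {j + 1}: no valid structure")
        cid = str(next_cid)
        next_cid += 1
        compounds.append(CompoundRecord.from_smiles(cid, smiles))
        seen_structures.add(smiles)
        decoy_cids.append(cid)

    return compounds, GroundTruth(series=truth_series,
                                  decoy_cids=tuple(decoy_cids))


# ---------------------------------------------------------------------------
# assay simulation
# ---------------------------------------------------------------------------

def _assign_nonshared(rng: np.random.Generator, n_assays: int,
                      k: int) -> list[np.ndarray]:
    """For each non-shared assay, a proper nonempty member subset."""
    subsets = []
    for _ in range(n_assays):
        size = int(rng.integers(1, k)) if k > 2 else 1
        subsets.append(rng.choice(k, size=size, replace=False))
    return subsets


def simulate_assays(compounds: Sequence[CompoundRecord],
                    truth: GroundTruth,
                    config: SyntheticConfig,
                    ) -> tuple[ActivityMatrix, GroundTruth]:
    """Simulate the screening panel and complete the ground truth.

    Per series the generator draws a union of U primary assays, designates
    ``ceil(target_overlap x U)`` of them as shared (tested by every
    member), spreads the rest over proper member subsets, marks
    ``ceil(target_cumulative_hr x U)`` union assays active-in-series, and
    makes ``round(target_inconsistency x S)`` shared assays show mixed
    outcomes.  Decoys get independent low-rate activity; every compound is
    additionally tested in a few confirmatory assays and is confirmatory-
    active with probability ``confirmatory_active_prob``.
    """
    rng = np.random.default_rng(config.seed + 1)
    matrix = ActivityMatrix()

    n_targets = max(1, config.n_assays // 3)
    primary_ids = []
    for i in range(config.n_assays):
        target = (f"T{int(rng.integers(n_targets)):03d}"
                  if rng.random() < config.target_annotation_fraction
                  else None)
        assay_id = f"A{i + 1:04d}"
        primary_ids.append(assay_id)
        matrix.add_assay(AssayRecord(assay_id, AssayType.PRIMARY, target))
    confirmatory_ids = []
    for i in range(config.n_confirmatory_assays):
        assay_id = f"CF{i + 1:03d}"
        confirmatory_ids.append(assay_id)
        matrix.add_assay(AssayRecord(assay_id, AssayType.CONFIRMATORY, None))
    primary_arr = np.asarray(primary_ids)

    lo = max(1, round(config.union_frac_min * config.n_assays))
    hi = max(lo, round(config.union_frac_max * config.n_assays))

    for s in truth.series:
        k = len(s.member_cids)
        U = int(rng.integers(lo, hi + 1))
        union = rng.choice(primary_arr, size=U, replace=False)
        S = math.ceil(s.target_overlap * U)
        A = min(U, math.ceil(s.target_hr * U))
        I = int(round(s.target_inconsistency * S))
        if I > A:
            raise SyntheticError(
                f"series {s.label}: infeasible targets — "
                f"{I} inconsistent shared assays would each need an active "
                f"member but only {A} active assays are budgeted; "
                "lower target_inconsistency or raise target_cumulative_hr")
        shared = union[:S]
        nonshared = union[S:]
        inconsistent = shared[:I]
        remaining_pool = np.concatenate([shared[I:], nonshared])
        consistent_active = set(remaining_pool[:A - I].tolist())
        inconsistent_set = set(inconsistent.tolist())

        subsets = _assign_nonshared(rng, len(nonshared), k)
        tested_by_member: list[set[str]] = [set(shared.tolist())
                                            for _ in range(k)]
        for assay, members in zip(nonshared.tolist(), subsets):
            for m in members:
                tested_by_member[int(m)].add(assay)
        if S == 0:
            # guarantee every member is tested somewhere
            for m in range(k):
                if not tested_by_member[m]:
                    if len(nonshared) == 0:
                        raise SyntheticError(
                            f"series {s.label}: cannot cover member {m} "
                            "with zero assays")
                    tested_by_member[m].add(
                        nonshared[int(rng.integers(len(nonshared)))])

        active_by_member: list[set[str]] = [set() for _ in range(k)]
        for assay in inconsistent_set:
            n_act = int(rng.integers(1, k)) if k > 2 else 1
            for m in rng.choice(k, size=n_act, replace=False):
                active_by_member[int(m)].add(assay)
        for m in range(k):
            for assay in tested_by_member[m]:
                if assay in consistent_active:
                    active_by_member[m].add(assay)

        for m, cid in enumerate(s.member_cids):
            for assay in tested_by_member[m]:
                matrix.add_outcome(cid, assay,
                                   assay in active_by_member[m])

        s.n_union = U
        s.n_shared = S
        s.n_active_union = A
        s.n_inconsistent = I
        s.realized_hr_percent = 100.0 * A / U
        s.realized_overlap_percent = 100.0 * S / U
        s.realized_inconsistency_percent = (100.0 * I / S) if S else 0.0

    for cid in truth.decoy_cids:
        D = int(rng.integers(lo, hi + 1))
        assays = rng.choice(primary_arr, size=D, replace=False)
        actives = rng.random(D) < config.decoy_hit_rate
        for assay, active in zip(assays.tolist(), actives.tolist()):
            matrix.add_outcome(cid, assay, bool(active))

    if config.n_confirmatory_assays:
        conf_arr = np.asarray(confirmatory_ids)
        for comp in compounds:
            c_max = min(15, config.n_confirmatory_assays)
            c = int(rng.integers(3, c_max + 1)) if c_max > 3 else c_max
            assays = rng.choice(conf_arr, size=c, replace=False)
            if rng.random() < config.confirmatory_active_prob:
                n_act = int(rng.integers(1, c + 1))
            else:
                n_act = 0
            for pos, assay in enumerate(assays.tolist()):
                matrix.add_outcome(comp.cid, assay, pos < n_act)

    for comp in compounds:
        truth.compound_counts[comp.cid] = (
            len(matrix.tested(comp.cid, AssayType.PRIMARY)),
            len(matrix.active(comp.cid, AssayType.PRIMARY)),
        )
    return matrix, truth


def generate_dataset(config: SyntheticConfig,
                     ) -> tuple[list[CompoundRecord], ActivityMatrix,
                                GroundTruth]:
    """Library + panel in one call (the CLI ``simulate`` entry point)."""
    compounds, truth = generate_library(config)
    matrix, truth = simulate_assays(compounds, truth, config)
    return compounds, matrix, truth
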