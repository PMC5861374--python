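"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import pytest
from rdkit import Chem, RDLogger

from analogseries.activity_model import (ActivityMatrix, AssayRecord,
                                         AssayType, CompoundRecord)
from analogseries.mms_extraction import AnalogSeries

RDLogger.DisableLog("rdApp.*")


def make_matrix(rows):
    """Build an ActivityMatrix from (cid, assay, type, active[, target])."""
    matrix = ActivityMatrix()
    for row in rows:
        cid, assay_id, assay_type, active = row[:4]
        target = row[4] if len(row) > 4 else None
        matrix.add_assay(AssayRecord(assay_id, AssayType(assay_type), target))
        matrix.add_outcome(cid, assay_id, active)
    return matrix


def make_series(member_cids, as_id=1, core="*C"):
    """A minimal AnalogSeries for metric tests (substituents synthetic)."""
    members = tuple((cid, f"*[{i}#]") for i, cid in enumerate(member_cids))
    return AnalogSeries(as_id=as_id, core_smiles=core, members=members)


@pytest.fixture
def two_member_matrix():
    """tested(A)={1,2,3}, tested(B)={2,3,4}; active(A)={2}, active(B)={2,4}."""
    return make_matrix([
        ("A", "1", "primary", False),
        ("A", "2", "primary", True),
        ("A", "3", "primary", False),
        ("B", "2", "primary", True),
        ("B", "3", "primary", False),
        ("B", "4", "primary", True),
    ])


# ---------------------------------------------------------------------------
# independent brute-force extraction oracle
# ---------------------------------------------------------------------------

def _cut_bond(mol, bond):
    """Break one bond with RWMol surgery and cap both ends with dummies."""
    rw = Chem.RWMol(mol)
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    rw.RemoveBond(a, b)
    da = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(a, da, Chem.BondType.SINGLE)
    db = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(b, db, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.GetMolFrags(out, asMols=True)


def _parent_of_core(core_smiles):
    mol = Chem.MolFromSmiles(core_smiles)
    parent = Chem.ReplaceSubstructs(
        mol, Chem.MolFromSmarts("[#0]"), Chem.MolFromSmiles("[H]"),
        replaceAll=True)[0]
    parent = Chem.RemoveHs(parent)
    Chem.SanitizeMol(parent)
    return Chem.MolToSmiles(parent)


def brute_force_series(records, max_substituent=13, hydrogen=True):
    """Exhaustive single-cut grouping of compounds by core string.

    Independent of the package's fragmentation path: bonds are broken one
    at a time by molecule surgery, the strictly smaller fragment (within
    the size cap) is the substituent, and cores with two or more distinct
    compounds form a series.  Returns ``{core_smiles: frozenset(cids)}``.
    """
    membership: dict[str, set[str]] = {}
    structures: dict[str, str] = {}
    for rec in sorted(records, key=lambda r: r.cid):
        structures.setdefault(rec.smiles, rec.cid)
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        for bond in mol.GetBonds():
            if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
                continue
            if min(bond.GetBeginAtom().GetAtomicNum(),
                   bond.GetEndAtom().GetAtomicNum()) <= 1:
                continue
            try:
                frags = _cut_bond(mol, bond)
            except Exception:
                continue
            if len(frags) != 2:
                continue
            heavies = [sum(1 for at in f.GetAtoms()
                           if at.GetAtomicNum() > 1) for f in frags]
            smiles = [Chem.MolToSmiles(f) for f in frags]
            for core_i, sub_i in ((0, 1), (1, 0)):
                if (heavies[sub_i] < heavies[core_i]
                        and heavies[sub_i] <= max_substituent):
                    membership.setdefault(smiles[core_i],
                                          set()).add(rec.cid)
    if hydrogen:
        for core, cids in membership.items():
            try:
                parent = _parent_of_core(core)
            except Exception:
                continue
            if parent in structures:
                cids.add(structures[parent])
    return {core: frozenset(cids) for core, cids in membership.items()
            if len(cids) >= 2}


def series_map(series_list):
    """Package output as {core: frozenset(cids)} for oracle comparison."""
    return {s.core_smiles: frozenset(s.member_cids) for s in series_list}


def build_synthetic_deposition(n_series=10, seed=0, **config_kwargs):
    """Full pipeline products for a synthetic dataset (no selection stage).

    Returns (dep_rows, support_rows, context) where context carries the
    intermediate objects for further assertions.
    """
    from analogseries.compound_selection import compute_hit_rates
    from analogseries.deposition_io import build_deposition
    from analogseries.interference_flags import FilterSet, flag_compounds
    from analogseries.mms_extraction import FragmentationPolicy, build_series
    from analogseries.series_metrics import (compute_series_metrics,
                                             rank_series)
    from analogseries.synthetic_data import SyntheticConfig, generate_dataset

    config = SyntheticConfig(n_series=n_series, seed=seed, **config_kwargs)
    compounds, matrix, truth = generate_dataset(config)
    series = build_series(compounds, FragmentationPolicy())
    metrics = rank_series([
        compute_series_metrics(s, matrix, AssayType.PRIMARY)
        for s in series])
    stats = {s.cid: s for s in compute_hit_rates(matrix)}
    by_cid = {c.cid: c for c in compounds}
    member_cids = {cid for s in series for cid in s.member_cids}
    flags = flag_compounds([by_cid[c] for c in sorted(member_cids)],
                           FilterSet.default())
    dep_rows, support_rows = build_deposition(
        series, {m.as_id: m for m in metrics}, stats, flags, by_cid)
    context = dict(compounds=compounds, matrix=matrix, truth=truth,
                   series=series, metrics=metrics, stats=stats, flags=flags)
    return dep_rows, support_rows, context
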