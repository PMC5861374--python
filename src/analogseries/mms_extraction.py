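"""Matching molecular series (MMS) extraction.

An MMS — the computational form of a single-site analog series — is a set of
two or more compounds that share one core structure and differ only by the
substituent attached at a single attachment point.  Series are found by
cutting every eligible acyclic single bond of every compound, writing each
cut as a (core, substituent) pair of fragment SMILES carrying one dummy-atom
attachment token each, and grouping compounds by canonical core string.

Two bond-eligibility rules are provided:

* ``all_acyclic`` — every acyclic single bond between heavy atoms is cut.
  Simple, exhaustive, and the reference behaviour for oracle testing.
* ``retrosynthetic`` — only bonds matching a configurable list of two-atom
  SMARTS patterns (a RECAP-style set of synthetically plausible
  disconnections: amides, esters, sulfonamides, amines, ethers, aryl
  attachments) are cut.  This emulates the restriction of series to
  typically observed medicinal-chemistry analogs.

Substituents are size-restricted (default: at most 13 heavy atoms, and
strictly smaller than the core), so that the conserved core really is the
dominant part of each analog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from .activity_model import CompoundRecord

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: SMILES token used for the substituent of an unsubstituted (core-H) parent.
HYDROGEN_SUBSTITUENT = "[*][H]"


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed or processed."""


def canonicalize(smiles: str) -> str:
    """Return the canonical aromatic, non-stereo form of *smiles*.

    Aromaticity is perceived (aromatic atoms written lowercase) and all
    stereochemical descriptors (tetrahedral tags, double-bond geometry)
    are removed.  The transform is idempotent.

    Raises
    ------
    SmilesError
        If the string does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen, non-dummy atoms in *smiles*."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


# ---------------------------------------------------------------------------
# fragmentation policy
# ---------------------------------------------------------------------------

#: RECAP-style bond disconnection patterns (two mapped atoms joined by the
#: bond to cut).  Order is cosmetic; a bond matching any pattern is eligible.
DEFAULT_RETRO_PATTERNS: tuple[str, ...] = (
    "[C;$(C=O)]-[N;!$(N=*)]",          # amide C-N
    "[C;$(C=O)]-[O;!$(O=*);!$([O-])]",  # ester C-O
    "[S;$(S(=O)=O)]-[N]",              # sulfonamide S-N
    "[C;!$(C=*)]-[N;!$(N=*)]",         # amine C-N
    "[C;!$(C=*)]-[O;!$(O=*);$(O[#6])]",  # ether C-O
    "[c]-[N;!$(N=*)]",                 # aryl amine
    "[c]-[O;!$(O=*)]",                 # aryl ether
    "[c]-[c]",                         # biaryl
    "[c]-[C]",                         # aryl-aliphatic carbon
    "[c]-[S;!$(S=*)]",                 # aryl thioether
)


@dataclass
class FragmentationPolicy:
    """Rules governing which bonds are cut and which fragments qualify.

    Parameters
    ----------
    bond_rule:
        ``"all_acyclic"`` or ``"retrosynthetic"``.
    retro_patterns:
        Two-atom SMARTS bond patterns used in retrosynthetic mode.
    max_substituent_heavy_atoms:
        Upper bound on substituent size, attachment point excluded.
    require_substituent_smaller_than_core:
        If true (default), only the strictly smaller fragment of a cut may
        be the substituent; ties produce no fragmentation.  If false, each
        orientation whose substituent respects the size cap is emitted.
    hydrogen_substituent:
        If true (default), the unsubstituted parent of a core (the compound
        equal to core-H) joins the series with substituent ``[*][H]``.
    """

    bond_rule: str = "all_acyclic"
    retro_patterns: Sequence[str] = DEFAULT_RETRO_PATTERNS
    max_substituent_heavy_atoms: int = 13
    require_substituent_smaller_than_core: bool = True
    hydrogen_substituent: bool = True

    def __post_init__(self) -> None:
        if self.bond_rule not in ("all_acyclic", "retrosynthetic"):
            raise ValueError(f"unknown bond_rule {self.bond_rule!r}")
        if self.bond_rule == "retrosynthetic" and not self.retro_patterns:
            raise ValueError("retrosynthetic mode requires retro_patterns")
        if self.max_substituent_heavy_atoms < 1:
            raise ValueError("max_substituent_heavy_atoms must be >= 1")
        self._compiled = None

    def compiled_patterns(self) -> list[Chem.Mol]:
        if self._compiled is None:
            mols = []
            for p in self.retro_patterns:
                q = Chem.MolFromSmarts(p)
                if q is None or q.GetNumAtoms() != 2:
                    raise ValueError(f"invalid two-atom bond SMARTS: {p!r}")
                mols.append(q)
            self._compiled = mols
        return self._compiled


def load_retro_patterns(path) -> list[str]:
    """Read SMARTS bond patterns, one per line.

    ``#`` at the start of a line or after whitespace begins a comment; a
    ``#`` inside a SMARTS token (as in ``[#6]``) is preserved.
    """
    patterns: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token.startswith("#"):
                continue
            for sep in ("\t#", " #"):
                if sep in token:
                    token = token.split(sep, 1)[0].rstrip()
            if token:
                patterns.append(token)
    return patterns


# ---------------------------------------------------------------------------
# single-bond fragmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragmentation:
    """One single-bond cut of a compound into core and substituent.

    Both SMILES carry exactly one ``*`` attachment token; reattaching the
    substituent to the core reproduces the parent structure.
    """

    cid: str
    core_smiles: str
    substituent_smiles: str
    substituent_heavy_atoms: int


def _eligible_bonds(mol: Chem.Mol, policy: FragmentationPolicy) -> list[int]:
    idxs = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1:
            continue
        if bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        idxs.append(bond.GetIdx())
    if policy.bond_rule == "retrosynthetic":
        matched: set[int] = set()
        for patt in policy.compiled_patterns():
            for a, b in mol.GetSubstructMatches(patt):
                bond = mol.GetBondBetweenAtoms(a, b)
                if bond is not None:
                    matched.add(bond.GetIdx())
        idxs = [i for i in idxs if i in matched]
    return idxs


def _fragment_pair(mol: Chem.Mol, bond_idx: int) -> tuple[tuple[str, int], tuple[str, int]] | None:
    """Cut one bond; return ((smiles, heavy), (smiles, heavy)) or None."""
    try:
        cut = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True,
                                   dummyLabels=[(0, 0)])
        frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    except Exception:  # sanitization failure on an exotic cut
        return None
    if len(frags) != 2:
        return None
    out = []
    for frag in frags:
        heavy = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 1)
        out.append((Chem.MolToSmiles(frag), heavy))
    return out[0], out[1]


def enumerate_cuts(compound: CompoundRecord,
                   policy: FragmentationPolicy) -> list[Fragmentation]:
    """All qualifying (core, substituent) fragmentations of one compound.

    A bond is cut if it is single, acyclic and joins two heavy atoms (and,
    in retrosynthetic mode, matches a retro pattern).  The substituent must
    respect the policy's size restrictions; a molecule with no eligible bond
    yields an empty list.
    """
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES for {compound.cid}: "
                          f"{compound.smiles!r}")
    results: dict[tuple[str, str], Fragmentation] = {}
    for bidx in _eligible_bonds(mol, policy):
        pair = _fragment_pair(mol, bidx)
        if pair is None:
            continue
        (sm_a, h_a), (sm_b, h_b) = pair
        if policy.require_substituent_smaller_than_core:
            if h_a == h_b:
                continue
            orientations = [((sm_a, h_a), (sm_b, h_b))] if h_b < h_a else \
                           [((sm_b, h_b), (sm_a, h_a))]
        else:
            orientations = [((sm_a, h_a), (sm_b, h_b)),
                            ((sm_b, h_b), (sm_a, h_a))]
        for (core_sm, _), (sub_sm, sub_h) in orientations:
            if sub_h > policy.max_substituent_heavy_atoms:
                continue
            key = (core_sm, sub_sm)
            if key not in results:
                results[key] = Fragmentation(
                    cid=compound.cid,
                    core_smiles=core_sm,
                    substituent_smiles=sub_sm,
                    substituent_heavy_atoms=sub_h,
                )
    return list(results.values())


# ---------------------------------------------------------------------------
# reassembly helpers
# ---------------------------------------------------------------------------

def attach(core_smiles: str, substituent_smiles: str) -> str:
    """Join a core and a substituent at their attachment points.

    Returns the canonical aromatic non-stereo SMILES of the assembled
    molecule.  ``[*][H]`` as substituent yields the unsubstituted parent.
    """
    if substituent_smiles == HYDROGEN_SUBSTITUENT:
        return core_to_parent(core_smiles)
    core = Chem.MolFromSmiles(core_smiles)
    sub = Chem.MolFromSmiles(substituent_smiles)
    if core is None or sub is None:
        raise SmilesError(
            f"unparsable fragment: {core_smiles!r} / {substituent_smiles!r}")
    for m in (core, sub):
        dummies = [a for a in m.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise SmilesError(
                f"fragment must carry exactly one attachment point: "
                f"{Chem.MolToSmiles(m)!r}")
        dummies[0].SetAtomMapNum(1)
    combined = Chem.CombineMols(core, sub)
    joined = Chem.molzip(combined)
    Chem.SanitizeMol(joined)
    return canonicalize(Chem.MolToSmiles(joined))


def core_to_parent(core_smiles: str) -> str:
    """Replace the attachment point of a core by hydrogen (core-H parent)."""
    mol = Chem.MolFromSmiles(core_smiles)
    if mol is None:
        raise SmilesError(f"unparsable core: {core_smiles!r}")
    rw = Chem.RWMol(mol)
    dummies = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise SmilesError(f"core must carry exactly one attachment point: "
                          f"{core_smiles!r}")
    atom = rw.GetAtomWithIdx(dummies[0])
    atom.SetAtomicNum(1)
    atom.SetIsotope(0)
    atom.SetAtomMapNum(0)
    atom.SetNoImplicit(False)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol = Chem.RemoveHs(mol)
    return canonicalize(Chem.MolToSmiles(mol))


# ---------------------------------------------------------------------------
# series construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalogSeries:
    """A single-site analog series: one core, two or more member compounds."""

    as_id: int
    core_smiles: str
    members: tuple[tuple[str, str], ...]  # (cid, substituent_smiles)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an analog series needs at least 2 members")
        cids = [cid for cid, _ in self.members]
        if len(set(cids)) != len(cids):
            raise ValueError("duplicate cid within a series")
        subs = [s for _, s in self.members]
        if len(set(subs)) != len(subs):
            raise ValueError("duplicate substituent within a series")

    @property
    def member_cids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.members)


def build_series(compounds: Iterable[CompoundRecord],
                 policy: FragmentationPolicy | None = None) -> list[AnalogSeries]:
    """Group single-bond fragmentations by core into analog series.

    Every core string produced by at least two distinct compounds becomes
    one series.  If the policy admits hydrogen substituents, a compound whose
    structure equals a core's unsubstituted parent joins that series with
    substituent ``[*][H]``.  Members are sorted by cid; series ids are
    sequential integers assigned after sorting cores lexicographically, so
    the output is deterministic and independent of input order.

    Duplicate structures (two cids mapping to the same (core, substituent))
    are collapsed onto the lexicographically smallest cid, with a log note.
    """
    if policy is None:
        policy = FragmentationPolicy()
    compounds = list(compounds)
    seen_cids = [c.cid for c in compounds]
    if len(set(seen_cids)) != len(seen_cids):
        raise ValueError("duplicate compound ids in input")

    # core -> {cid -> substituent}
    index: dict[str, dict[str, str]] = {}
    for comp in compounds:
        for frag in enumerate_cuts(comp, policy):
            members = index.setdefault(frag.core_smiles, {})
            prev = members.get(frag.cid)
            if prev is None or frag.substituent_smiles < prev:
                members[frag.cid] = frag.substituent_smiles

    if policy.hydrogen_substituent:
        by_structure: dict[str, str] = {}
        for comp in sorted(compounds, key=lambda c: c.cid):
            by_structure.setdefault(comp.smiles, comp.cid)
        for core, members in index.items():
            try:
                parent = core_to_parent(core)
            except SmilesError:
                continue
            cid = by_structure.get(parent)
            if cid is not None and cid not in members:
                members[cid] = HYDROGEN_SUBSTITUENT

    series: list[AnalogSeries] = []
    as_id = 0
    for core in sorted(index):
        members = index[core]
        # collapse duplicate structures: identical substituent on one core
        by_sub: dict[str, str] = {}
        for cid in sorted(members):
            sub = members[cid]
            if sub in by_sub:
                logger.info("duplicate structure: %s == %s on core %s; "
                            "keeping %s", cid, by_sub[sub], core, by_sub[sub])
            else:
                by_sub[sub] = cid
        if len(by_sub) < 2:
            continue
        as_id += 1
        series.append(AnalogSeries(
            as_id=as_id,
            core_smiles=core,
            members=tuple(sorted((cid, sub) for sub, cid in by_sub.items())),
        ))
    return series


def write_series_table(series: Sequence[AnalogSeries], path) -> None:
    """Write series as TSV: as_id, core, member cids, substituents."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("as_id\tcore_smiles\tmember_cids\tsubstituents\n")
        for s in series:
            cids = ",".join(cid for cid, _ in s.members)
            subs = ",".join(sub for _, sub in s.members)
            fh.write(f"{s.as_id}\t{s.core_smiles}\t{cids}\t{subs}\n")
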