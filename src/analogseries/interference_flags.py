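"""Assay-interference substructure flagging.

Compounds matching substructure patterns associated with assay artifacts
(PAINS-style motifs: quinones, catechols, rhodanines, Michael acceptors,
azo dyes, ...) tend to produce false-positive activity signals across many
assay formats.  This module matches a configurable SMARTS pattern list
against compound structures and classifies analog series as
interference-free when no member matches any pattern.

The pattern list is an input: a small default set of well-known exemplar
motifs ships with the package, but any file with one ``id<TAB>SMARTS`` line
per pattern can be substituted.  The mechanism (substructure matching and
series classification), not a particular list, is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from .activity_model import CompoundRecord
from .mms_extraction import AnalogSeries


class FilterError(ValueError):
    """Raised for malformed filter files or unparsable SMARTS."""


def _strip_comment(line: str) -> str:
    """Drop a trailing comment without touching ``#`` inside SMARTS tokens."""
    stripped = line.strip()
    if stripped.startswith("#"):
        return ""
    for sep in ("\t#", " #"):
        if sep in stripped:
            stripped = stripped.split(sep, 1)[0].rstrip()
    return stripped


@dataclass(frozen=True)
class FlagResult:
    flagged: bool
    matched: tuple[str, ...]  # pattern ids, in filter-file order


class FilterSet:
    """Named, ordered collection of (pattern_id, SMARTS) interference filters."""

    def __init__(self, name: str,
                 patterns: Sequence[tuple[str, str]]) -> None:
        self.name = name
        self.patterns: list[tuple[str, str, Chem.Mol]] = []
        seen: set[str] = set()
        for pattern_id, smarts in patterns:
            if pattern_id in seen:
                raise FilterError(f"duplicate pattern id {pattern_id!r}")
            seen.add(pattern_id)
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise FilterError(
                    f"pattern {pattern_id!r}: unparsable SMARTS {smarts!r}")
            self.patterns.append((pattern_id, smarts, query))

    def __len__(self) -> int:
        return len(self.patterns)

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "FilterSet":
        """Load ``id<TAB>SMARTS`` lines.

        ``#`` at the start of a line or after whitespace begins a comment
        (a ``#`` inside a SMARTS token, as in ``[#6]``, is preserved).
        """
        patterns: list[tuple[str, str]] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = _strip_comment(raw)
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FilterError(
                        f"{path}:{lineno}: expected 'id<TAB>SMARTS', got "
                        f"{raw.rstrip()!r}")
                patterns.append((fields[0].strip(), fields[1].strip()))
        return cls(name or str(path), patterns)

    @classmethod
    def default(cls) -> "FilterSet":
        """The packaged exemplar motif list."""
        ref = resources.files("analogseries.data") / "default_filters.smarts"
        with resources.as_file(ref) as path:
            return cls.from_file(path, name="default-exemplars")


def flag_compounds(compounds: Iterable[CompoundRecord],
                   filters: FilterSet) -> dict[str, FlagResult]:
    """Substructure-match every compound against every filter pattern.

    Returns ``cid -> FlagResult``; a compound is flagged iff at least one
    pattern matches, and the matching pattern ids are listed.
    """
    results: dict[str, FlagResult] = {}
    for comp in compounds:
        mol = Chem.MolFromSmiles(comp.smiles)
        if mol is None:
            raise FilterError(f"compound {comp.cid}: unparsable SMILES "
                              f"{comp.smiles!r}")
        matched = tuple(pid for pid, _, query in filters.patterns
                        if mol.HasSubstructMatch(query))
        results[comp.cid] = FlagResult(flagged=bool(matched), matched=matched)
    return results


def interference_free_series(series_list: Iterable[AnalogSeries],
                             flags: Mapping[str, FlagResult]) -> set[int]:
    """Ids of series in which no member matches any interference filter."""
    free: set[int] = set()
    for series in series_list:
        clean = True
        for cid in series.member_cids:
            if cid not in flags:
                raise FilterError(
                    f"series {series.as_id}: member {cid!r} has no "
                    "interference flag")
            if flags[cid].flagged:
                clean = False
        if clean:
            free.add(series.as_id)
    return free


def write_flag_table(flags: Mapping[str, FlagResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cid\tflag\tmatched_ids\n")
        for cid in sorted(flags):
            res = flags[cid]
            fh.write(f"{cid}\t{'yes' if res.flagged else 'no'}\t"
                     f"{','.join(res.matched)}\n")
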