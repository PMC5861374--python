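"""End-to-end orchestration: select -> extract -> metrics -> flag -> deposit.

:func:`run_all` reads a compound table and an activity table, selects
extensively tested high-hit-rate compounds through the quantile cascade,
extracts single-site analog series from the survivors, scores and
rank-fuses the series, flags interference compounds, and writes the
two-file deposition plus a JSON run manifest (thresholds, counts, policy,
filter-file checksum, seed) that suffices to re-execute the identical run.

The analysis pipeline itself is deterministic; randomness exists only in
the synthetic-data generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .activity_model import (AssayType, read_activity_table,
                             read_compound_table)
from .compound_selection import (SelectionConfig, cascade_select,
                                 compute_hit_rates, confirmatory_consistency)
from .deposition_io import (build_deposition, read_deposition,
                            validate_deposition, write_deposition)
from .interference_flags import (FilterSet, flag_compounds,
                                 interference_free_series)
from .mms_extraction import FragmentationPolicy, build_series
from .series_metrics import compute_series_metrics, rank_series

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    compound_table: str
    activity_table: str
    out_dir: str
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    policy: FragmentationPolicy = field(default_factory=FragmentationPolicy)
    filter_file: Optional[str] = None  # None -> packaged default list
    tolerance: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        selection = SelectionConfig(**raw.pop("selection", {}))
        policy = FragmentationPolicy(**raw.pop("policy", {}))
        return cls(selection=selection, policy=policy, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["policy"].pop("_compiled", None)
        d["policy"]["retro_patterns"] = list(self.policy.retro_patterns)
        return d


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; return the run manifest.

    On any stage failure a ``RUN.partial`` marker is left in the output
    directory and :class:`PipelineError` is raised naming the stage.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    marker = os.path.join(config.out_dir, "RUN.partial")
    with open(marker, "w", encoding="utf-8") as fh:
        fh.write("run in progress\n")
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": config.to_dict(), "stages": {}}
    try:
        stage = "read"
        for path in (config.compound_table, config.activity_table):
            if not os.path.exists(path):
                raise PipelineError(stage, f"input file not found: {path}")
        try:
            compounds = read_compound_table(config.compound_table)
            matrix = read_activity_table(config.activity_table)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"]["read"] = {
            "n_compounds": len(compounds),
            "n_assays": len(matrix.assays),
            "n_outcomes": matrix.n_outcomes,
        }

        stage = "select"
        try:
            stats = compute_hit_rates(matrix)
            selected, report = cascade_select(stats, config.selection)
            confirm = confirmatory_consistency(selected, matrix)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        report["confirmatory_consistency"] = confirm
        manifest["stages"]["select"] = report

        stage = "extract"
        try:
            by_cid = {c.cid: c for c in compounds}
            survivors = [by_cid[cid] for cid in selected if cid in by_cid]
            series = build_series(survivors, config.policy)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"]["extract"] = {
            "n_selected_with_structure": len(survivors),
            "n_series": len(series),
            "bond_rule": config.policy.bond_rule,
            "max_substituent_heavy_atoms":
                config.policy.max_substituent_heavy_atoms,
        }
        if not series:
            raise PipelineError(stage, "no analog series extracted from the "
                                       "selected compounds")

        stage = "metrics"
        try:
            metrics = rank_series([
                compute_series_metrics(s, matrix, AssayType.PRIMARY)
                for s in series])
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"]["metrics"] = {"n_series_ranked": len(metrics)}

        stage = "flag"
        try:
            if config.filter_file:
                filters = FilterSet.from_file(config.filter_file)
                checksum = _sha256(config.filter_file)
            else:
                filters = FilterSet.default()
                checksum = "packaged-default"
            member_cids = {cid for s in series for cid in s.member_cids}
            flags = flag_compounds(
                [by_cid[cid] for cid in sorted(member_cids)], filters)
            free = interference_free_series(series, flags)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"]["flag"] = {
            "filter_set": filters.name,
            "filter_checksum": checksum,
            "n_patterns": len(filters),
            "n_interference_free_series": len(free),
        }

        stage = "write-deposition"
        try:
            stats_by_cid = {s.cid: s for s in stats}
            targets = _active_targets(matrix, member_cids)
            dep_rows, support_rows = build_deposition(
                series, {m.as_id: m for m in metrics}, stats_by_cid, flags,
                by_cid, targets)
            as_path, support_path = write_deposition(dep_rows, support_rows,
                                                     config.out_dir)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = "validate"
        try:
            rows_back, support_back = read_deposition(as_path, support_path)
            report = validate_deposition(rows_back, support_back,
                                         config.tolerance)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"]["validate"] = report.to_dict()
        if report.violations:
            raise PipelineError(stage,
                                f"{len(report.violations)} violations: "
                                f"{report.violations[:3]}")
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(stage, str(exc)) from exc
    else:
        os.remove(marker)

    manifest_path = os.path.join(config.out_dir, "run_manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _active_targets(matrix, cids):
    """cid -> sorted target ids of assays the compound was active in."""
    assays = matrix.assays
    out = {}
    for cid in cids:
        targets = {assays[a].target_id for a in matrix.active(cid)
                   if assays[a].target_id}
        out[cid] = sorted(targets)
    return out
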