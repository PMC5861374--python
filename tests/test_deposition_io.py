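"""Deposition file writing, parsing and validation."""

import pytest

from analogseries.compound_selection import CompoundHitRate
from analogseries.deposition_io import (AS_COLUMNS, AS_FILENAME,
                                        SUPPORT_COLUMNS, SUPPORT_FILENAME,
                                        DepositionError, DepositionRow,
                                        SupportRow, build_deposition,
                                        read_deposition, validate_deposition,
                                        write_deposition)
from analogseries.interference_flags import FlagResult
from analogseries.series_metrics import SeriesMetrics

from conftest import build_synthetic_deposition


def tiny_inputs():
    from analogseries.activity_model import CompoundRecord
    from analogseries.mms_extraction import AnalogSeries

    series = [AnalogSeries(1, "*c1ccccc1", (("10", "*C"), ("11", "*CC")))]
    metrics = {1: SeriesMetrics(
        as_id=1, cumulative_hr_percent=12.5, assay_overlap_percent=80.0,
        inconsistent_activity_percent=0.0, n_union_assays=8,
        n_shared_assays=6, n_active_union_assays=1, rank_hr=1,
        rank_overlap=1, rank_inconsistency=1, rank_sum=3, consensus_rank=1)}
    stats = {"10": CompoundHitRate("10", 200, 10, 4, 2),
             "11": CompoundHitRate("11", 100, 1, 0, 0)}
    flags = {"10": FlagResult(False, ()), "11": FlagResult(True, ("azo",))}
    compounds = {
        "10": CompoundRecord.from_smiles("10", "Cc1ccccc1"),
        "11": CompoundRecord.from_smiles("11", "CCc1ccccc1"),
    }
    return series, metrics, stats, flags, compounds


class TestWrite:
    def test_single_series_row_counts(self, tmp_path):
        dep, support = build_deposition(*tiny_inputs())
        as_path, support_path = write_deposition(dep, support, tmp_path)
        as_lines = open(as_path).read().splitlines()
        support_lines = open(support_path).read().splitlines()
        assert len(as_lines) == 2 and len(support_lines) == 3
        assert as_lines[0].split("\t") == list(AS_COLUMNS)
        assert support_lines[0].split("\t") == list(SUPPORT_COLUMNS)
        fields = as_lines[1].split("\t")
        assert fields[:2] == ["1", "1"]
        assert fields[3] == "12.50"
        assert fields[6] == "10,11"

    def test_member_of_two_series_gets_two_support_rows(self, tmp_path):
        from analogseries.mms_extraction import AnalogSeries

        series, metrics, stats, flags, compounds = tiny_inputs()
        series.append(AnalogSeries(2, "*Cc1ccccc1",
                                   (("10", "*F"), ("11", "*C"))))
        metrics[2] = metrics[1].__class__(
            **{**metrics[1].__dict__, "as_id": 2, "consensus_rank": 2})
        dep, support = build_deposition(series, metrics, stats, flags,
                                        compounds)
        rows_for_10 = [r for r in support if r.cid == "10"]
        assert {r.as_id for r in rows_for_10} == {1, 2}

    def test_missing_flag_is_fatal(self):
        series, metrics, stats, flags, compounds = tiny_inputs()
        del flags["11"]
        with pytest.raises(DepositionError, match="11"):
            build_deposition(series, metrics, stats, flags, compounds)

    def test_target_ids_serialized(self, tmp_path):
        series, metrics, stats, flags, compounds = tiny_inputs()
        dep, support = build_deposition(series, metrics, stats, flags,
                                        compounds,
                                        targets={"10": ["T2", "T1"]})
        row = next(r for r in support if r.cid == "10")
        assert row.target_ids == ("T1", "T2")


class TestRoundTrip:
    def test_twenty_synthetic_series_field_by_field(self, tmp_path):
        dep, support, _ = build_synthetic_deposition(n_series=8, seed=5)
        as_path, support_path = write_deposition(dep, support, tmp_path)
        dep_back, support_back = read_deposition(as_path, support_path)
        assert len(dep_back) >= 8
        for a, b in zip(sorted(dep, key=lambda r: r.as_id),
                        sorted(dep_back, key=lambda r: r.as_id)):
            assert a.as_id == b.as_id and a.rank == b.rank
            assert a.mms_core == b.mms_core
            assert a.cids == b.cids and a.smiles == b.smiles
            assert a.as_hr_percent == pytest.approx(b.as_hr_percent,
                                                    abs=0.005)
            assert a.assay_ov_percent == pytest.approx(b.assay_ov_percent,
                                                       abs=0.005)
        key = lambda r: (r.as_id, r.cid)
        for a, b in zip(sorted(support, key=key), sorted(support_back,
                                                         key=key)):
            assert (a.cid, a.as_id, a.rank, a.mms_core) == \
                (b.cid, b.as_id, b.rank, b.mms_core)
            assert a.n_primary_assays == b.n_primary_assays
            assert a.n_active_primary_assays == b.n_active_primary_assays
            assert a.target_ids == b.target_ids
            assert a.interference == b.interference

    def test_round_trip_validates_clean(self, tmp_path):
        dep, support, _ = build_synthetic_deposition(n_series=6, seed=9)
        paths = write_deposition(dep, support, tmp_path)
        report = validate_deposition(*read_deposition(*paths))
        assert report.violations == []


class TestReadErrors:
    def write_valid(self, tmp_path):
        dep, support, _ = build_synthetic_deposition(n_series=4, seed=2)
        return write_deposition(dep, support, tmp_path)

    def test_header_mismatch_fatal(self, tmp_path):
        as_path, support_path = self.write_valid(tmp_path)
        lines = open(as_path).read().splitlines()
        lines[0] = lines[0].replace("MMS_core", "Core")
        open(as_path, "w").write("\n".join(lines) + "\n")
        with pytest.raises(DepositionError, match="header"):
            read_deposition(as_path, support_path)

    def test_missing_membership_row_names_keys(self, tmp_path):
        as_path, support_path = self.write_valid(tmp_path)
        lines = open(support_path).read().splitlines()
        open(support_path, "w").write("\n".join(lines[:-1]) + "\n")
        with pytest.raises(DepositionError, match="membership|AS_ID"):
            read_deposition(as_path, support_path)

    def test_truncated_line_names_line_number(self, tmp_path):
        as_path, support_path = self.write_valid(tmp_path)
        with open(as_path) as fh:
            content = fh.read().splitlines()
        last = content[-1].rsplit("\t", 3)[0]
        open(as_path, "w").write("\n".join(content[:-1] + [last]) + "\n")
        with pytest.raises(DepositionError, match=f":{len(content)}"):
            read_deposition(as_path, support_path)

    def test_nine_column_support_file_reads_as_version_one(self, tmp_path):
        as_path, support_path = self.write_valid(tmp_path)
        lines = open(support_path).read().splitlines()
        trimmed = ["\t".join(line.split("\t")[:9]) for line in lines]
        open(support_path, "w").write("\n".join(trimmed) + "\n")
        _, support_rows = read_deposition(as_path, support_path)
        assert all(r.interference is None for r in support_rows)


class TestValidate:
    def test_counts_match_generator_bookkeeping(self, tmp_path):
        dep, support, ctx = build_synthetic_deposition(n_series=10, seed=4)
        report = validate_deposition(dep, support)
        assert report.n_series == len(ctx["series"])
        assert report.n_memberships == len(support)
        cids = [r.cid for r in support]
        assert report.n_unique_compounds == len(set(cids))
        multi = sum(1 for c in set(cids) if cids.count(c) > 1)
        assert report.n_compounds_in_multiple_series == multi
        assert report.violations == []

    def test_hit_rate_mismatch_reported(self):
        dep, support, _ = build_synthetic_deposition(n_series=4, seed=6)
        bad = support[0].__class__(**{**support[0].__dict__,
                                      "hit_rate_percent": 99.0})
        report = validate_deposition(dep, [bad] + list(support[1:]))
        assert any("Hit_rate" in v for v in report.violations)

    def test_header_only_files_report_zero_series(self, tmp_path):
        as_path = tmp_path / AS_FILENAME
        support_path = tmp_path / SUPPORT_FILENAME
        as_path.write_text("\t".join(AS_COLUMNS) + "\n")
        support_path.write_text("\t".join(SUPPORT_COLUMNS) + "\n")
        report = validate_deposition(*read_deposition(as_path, support_path))
        assert report.n_series == 0
        assert report.warnings
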