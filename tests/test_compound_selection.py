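"""Hit-rate statistics and the quantile-cascade selection."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from analogseries.compound_selection import (CompoundHitRate,
                                             SelectionConfig, SelectionError,
                                             cascade_select,
                                             compute_hit_rates,
                                             confirmatory_consistency,
                                             hr_quantiles)

from conftest import make_matrix


def stat(cid, tested, active, c_tested=0, c_active=0):
    return CompoundHitRate(cid, tested, active, c_tested, c_active)


class TestHitRates:
    def test_percentages(self):
        assert stat("a", 200, 4).hr_percent == pytest.approx(2.0)
        assert stat("b", 50, 0).hr_percent == 0.0
        assert stat("c", 0, 0).hr_percent is None

    def test_matches_row_recount_on_toy_matrix(self):
        rng = np.random.default_rng(42)
        rows = []
        for cid in ["C1", "C2", "C3", "C4", "C5"]:
            for a in range(10):
                if rng.random() < 0.7:
                    rows.append((cid, f"A{a}", "primary",
                                 bool(rng.random() < 0.3)))
        matrix = make_matrix(rows)
        stats = {s.cid: s for s in compute_hit_rates(matrix)}
        for cid in {r[0] for r in rows}:
            tested = [r for r in rows if r[0] == cid]
            active = [r for r in tested if r[3]]
            assert stats[cid].n_tested_primary == len(tested)
            assert stats[cid].n_active_primary == len(active)
            assert stats[cid].hr_percent == pytest.approx(
                100 * len(active) / len(tested))

    def test_confirmatory_counted_separately(self):
        matrix = make_matrix([
            ("C1", "A1", "primary", True),
            ("C1", "F1", "confirmatory", True),
            ("C1", "F2", "confirmatory", False),
        ])
        (s,) = compute_hit_rates(matrix)
        assert (s.n_tested_primary, s.n_active_primary) == (1, 1)
        assert (s.n_tested_confirmatory, s.n_active_confirmatory) == (2, 1)


class TestQuantiles:
    def test_linear_interpolation_convention(self):
        stats = [stat(str(i), 100, v) for i, v in enumerate([1, 2, 3, 4])]
        median, q3 = hr_quantiles(stats)
        assert median == pytest.approx(2.5)
        assert q3 == pytest.approx(3.25)

    def test_single_value(self):
        median, q3 = hr_quantiles([stat("a", 100, 5)])
        assert median == q3 == pytest.approx(5.0)

    def test_empty_errors(self):
        with pytest.raises(SelectionError):
            hr_quantiles([stat("a", 0, 0)])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=100), min_size=1,
                    max_size=30))
    def test_median_never_exceeds_q3(self, actives):
        stats = [stat(str(i), 100, a) for i, a in enumerate(actives)]
        median, q3 = hr_quantiles(stats)
        assert median <= q3


class TestCascade:
    def test_stage_a_keeps_extensively_tested(self):
        stats = [stat(f"c{i}", 100 if i < 5 else 300, 10) for i in range(10)]
        selected, report = cascade_select(
            stats, SelectionConfig(min_primary_assays=257, stage1=0.0,
                                   stage2=0.0))
        assert set(selected) == {f"c{i}" for i in range(5, 10)}
        assert report["stages"][0]["survivors"] == 5

    def test_fixed_thresholds(self):
        hrs = [0.5, 1.2, 1.9, 2.5]
        stats = [stat(str(i), 1000, int(10 * v)) for i, v in enumerate(hrs)]
        selected, _ = cascade_select(
            stats, SelectionConfig(min_primary_assays=0, stage1=1.0,
                                   stage2=1.8))
        survivors = sorted(stats[int(cid)].hr_percent for cid in selected)
        assert survivors == pytest.approx([1.9, 2.5])

    def test_matches_brute_force_with_quantile_rules(self):
        rng = np.random.default_rng(7)
        stats = []
        for i in range(400):
            tested = int(rng.integers(50, 600))
            rate = rng.choice([0.004, 0.02, 0.06])
            stats.append(stat(str(i), tested,
                              int(rng.binomial(tested, rate))))
        config = SelectionConfig(min_primary_assays=257)
        selected, report = cascade_select(stats, config)

        # independent re-filter using the statistics-module quantiles
        a = [s for s in stats if s.n_tested_primary > 257]
        hrs_a = sorted(s.hr_percent for s in a)
        t1 = statistics.quantiles(hrs_a, n=4, method="inclusive")[2]
        b = [s for s in a if s.hr_percent > t1]
        t2 = statistics.quantiles(sorted(s.hr_percent for s in b), n=4,
                                  method="inclusive")[1]
        c = [s.cid for s in b if s.hr_percent > t2]
        assert selected == c
        assert report["stages"][1]["threshold"] == pytest.approx(t1)
        assert report["stages"][2]["threshold"] == pytest.approx(t2)

    def test_stage_chain_is_monotone(self):
        rng = np.random.default_rng(3)
        stats = [stat(str(i), int(rng.integers(100, 500)),
                      int(rng.integers(0, 30))) for i in range(200)]
        config = SelectionConfig(min_primary_assays=200)
        _, report = cascade_select(stats, config)
        counts = [s["survivors"] for s in report["stages"]]
        assert len(stats) >= counts[0] >= counts[1] >= counts[2] >= 1

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=8))
    def test_raising_thresholds_never_adds_survivors(self, bump):
        stats = [stat(str(i), 300, 2 * i) for i in range(30)]
        low, _ = cascade_select(stats, SelectionConfig(
            min_primary_assays=0, stage1=1.0, stage2=2.0))
        high, _ = cascade_select(stats, SelectionConfig(
            min_primary_assays=0, stage1=1.0 + bump, stage2=2.0 + bump))
        assert set(high) <= set(low)

    def test_survivor_median_exceeds_final_threshold(self):
        stats = [stat(str(i), 300, i) for i in range(40)]
        selected, report = cascade_select(stats, SelectionConfig(
            min_primary_assays=0))
        t2 = report["stages"][2]["threshold"]
        assert report["stages"][2]["median_hr_percent"] > t2

    def test_empty_stage_names_stage(self):
        stats = [stat("a", 10, 1)]
        with pytest.raises(SelectionError, match="stage A"):
            cascade_select(stats, SelectionConfig(min_primary_assays=257))


class TestConfirmatoryConsistency:
    def test_fraction_with_confirmatory_activity(self):
        rows = []
        for i, has_active in enumerate([True, True, True, False]):
            rows.append((f"c{i}", "F1", "confirmatory", has_active))
        matrix = make_matrix(rows)
        assert confirmatory_consistency(
            [f"c{i}" for i in range(4)], matrix) == pytest.approx(0.75)

    def test_no_confirmatory_data_counts_as_unconfirmed(self):
        matrix = make_matrix([("c0", "A1", "primary", True)])
        assert confirmatory_consistency(["c0"], matrix) == 0.0

    def test_recovers_generating_probability(self):
        rng = np.random.default_rng(5)
        rows = []
        cids = [f"c{i}" for i in range(500)]
        for cid in cids:
            rows.append((cid, "F1", "confirmatory",
                         bool(rng.random() < 0.9)))
        matrix = make_matrix(rows)
        frac = confirmatory_consistency(cids, matrix)
        assert abs(frac - 0.9) <= 0.04

    def test_empty_selection_errors(self):
        matrix = make_matrix([("c0", "A1", "primary", True)])
        with pytest.raises(SelectionError):
            confirmatory_consistency([], matrix)
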