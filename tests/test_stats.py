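"""Measurement-comparison statistics against hand-computed oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from jvmag.jvp_stats import (
    CATEGORIES,
    AgreementTable,
    agreement_level,
    average_raters,
    chisq_uniform,
    classify_jvp,
    paired_summary,
    run_study_analysis,
    tabulate_agreement,
    wilcoxon_signed_rank_p,
)
from jvmag.phantom import MeasurementTableSpec, simulate_measurements


def _table(rows):
    return pd.DataFrame(rows, columns=["participant_id", "modality", "rater_id",
                                       "value_cmH2O"])


class TestAverageRaters:
    def test_two_raters_mean(self):
        t = _table([("P1", "bedside", "r1", 7.06), ("P1", "bedside", "r2", 6.52)])
        out = average_raters(t)
        assert out.loc[0, "mean_value_cmH2O"] == pytest.approx(6.79)

    def test_single_rater_unchanged(self):
        t = _table([("P1", "rhc", "lab", 8.5)])
        assert average_raters(t).loc[0, "mean_value_cmH2O"] == 8.5

    def test_unknown_modality_rejected(self):
        t = _table([("P1", "ultrasound", "r1", 7.0)])
        with pytest.raises(ValueError, match="modalit"):
            average_raters(t)


class TestClassification:
    @pytest.mark.parametrize("value,expected", [
        (7.0, "normal"), (10.0, "borderline"), (10.01, "elevated"),
        (0.0, "normal"), (7.01, "borderline"), (25.0, "elevated"),
    ])
    def test_boundaries(self, value, expected):
        assert classify_jvp(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_jvp(-0.1)
        with pytest.raises(ValueError):
            classify_jvp(float("nan"))

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0, max_value=30), st.floats(min_value=0, max_value=30))
    def test_monotone_in_value(self, a, b):
        rank = {c: i for i, c in enumerate(CATEGORIES)}
        lo, hi = sorted([a, b])
        assert rank[classify_jvp(lo)] <= rank[classify_jvp(hi)]


class TestAgreementLevel:
    def test_examples(self):
        assert agreement_level("elevated", "elevated") == 0
        assert agreement_level("normal", "borderline") == 1
        assert agreement_level("normal", "elevated") == 2

    def test_symmetric_and_triangle(self):
        for a, b, c in itertools.product(CATEGORIES, repeat=3):
            assert agreement_level(a, b) == agreement_level(b, a)
            assert agreement_level(a, c) <= agreement_level(a, b) + agreement_level(b, c)


class TestTabulate:
    def test_hand_classified_pairs(self):
        table = tabulate_agreement([5, 5, 8], [12, 5, 5])
        assert table.counts == (1, 1, 1)

    def test_identical_values_all_agree(self):
        table = tabulate_agreement([5.0, 9.0, 12.0], [5.0, 9.0, 12.0])
        assert table.counts == (3, 0, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tabulate_agreement([], [])


class TestChiSquare:
    def test_perfect_uniformity(self):
        res = chisq_uniform(AgreementTable(16, 16, 16))
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_formula(self):
        table = AgreementTable(20, 15, 13)
        res = chisq_uniform(table)
        exp = 48 / 3
        brute = sum((o - exp) ** 2 / exp for o in table.counts)
        assert res.statistic == pytest.approx(brute, abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(sps.chi2.sf(brute, 2))


class TestWilcoxon:
    def test_all_positive_ranks_enumeration(self):
        # d = {1..6}: both tails have a single extreme assignment -> 2/2^6
        assert wilcoxon_signed_rank_p(np.arange(1.0, 7.0)) == pytest.approx(2 / 64)

    def test_matches_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(1, 11))
            d = rng.integers(-6, 7, size=n).astype(float)
            d = d[d != 0]
            if len(d) == 0:
                continue
            ranks = sps.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            signs = np.array(list(itertools.product([0, 1], repeat=len(d))), bool)
            ws = (signs * ranks).sum(axis=1)
            brute = min(1.0, 2 * min((ws <= w_obs + 1e-9).mean(),
                                     (ws >= w_obs - 1e-9).mean()))
            assert wilcoxon_signed_rank_p(d) == pytest.approx(brute, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=14)
        assert wilcoxon_signed_rank_p(d) == pytest.approx(
            sps.wilcoxon(d, method="exact").pvalue
        )

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.5, 1.0, size=60)
        expected = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                                method="approx").pvalue
        assert wilcoxon_signed_rank_p(d) == pytest.approx(expected)


class TestPairedSummary:
    def test_identical_pairs_degenerate(self):
        res = paired_summary([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert res.mean_diff == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert res.wilcoxon_p == 1.0

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(8)
        x = rng.normal(7, 2, size=30)
        y = rng.normal(9, 2, size=30)
        res = paired_summary(x, y)
        assert res.ci_low <= res.mean_diff <= res.ci_high

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_summary([1.0], [2.0])


def test_ci_covers_injected_bias_montecarlo():
    hits = 0
    n_rep = 60
    for seed in range(n_rep):
        spec = MeasurementTableSpec(n_participants=48, seed=seed)
        table, truth = simulate_measurements(spec)
        wide = average_raters(table).pivot(
            index="participant_id", columns="modality", values="mean_value_cmH2O"
        )
        ps = paired_summary(wide["bedside"].to_numpy(), wide["rhc"].to_numpy())
        if ps.ci_low <= truth["bias"]["bedside"] <= ps.ci_high:
            hits += 1
    assert hits / n_rep >= 0.85  # nominal 95% less Monte-Carlo error


class TestStudyAnalysis:
    def test_zero_noise_zero_bias_all_agree(self, tmp_path):
        spec = MeasurementTableSpec(
            n_participants=12,
            bias={"bedside": 0.0, "unamplified": 0.0, "amplified": 0.0},
            noise_sd={"bedside": 0.0, "unamplified": 0.0, "amplified": 0.0},
            seed=2,
        )
        table, _ = simulate_measurements(spec)
        report = run_study_analysis(table, out_dir=tmp_path)
        for m in ("bedside", "unamplified", "amplified"):
            assert report["paired"][m].mean_diff == pytest.approx(0.0)
            at = report["agreement"][m]["table"]
            assert at.counts == (12, 0, 0)
        assert (tmp_path / "tables3_4.csv").exists()
        assert (tmp_path / "summary.txt").exists()

    def test_single_participant_refuses_paired_tests(self):
        spec = MeasurementTableSpec(
            n_participants=1,
            bias={"bedside": 0.0, "unamplified": 0.0, "amplified": 0.0},
            noise_sd={"bedside": 0.0, "unamplified": 0.0, "amplified": 0.0},
            seed=3,
        )
        table, _ = simulate_measurements(spec)
        report = run_study_analysis(table)
        assert "n >= 2" in report["paired"]["bedside"]
        assert report["descriptives"]["rhc"]["n"] == 1

    def test_missing_rhc_rejected(self):
        t = _table([("P1", "bedside", "r1", 7.0)])
        with pytest.raises(ValueError, match="rhc"):
            run_study_analysis(t)
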