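"""GOLD staging, group summaries, distribution tables and correlation
statistics, each against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fissint import refdata
from fissint.cohort import (
    ALL_GROUPS,
    CohortError,
    UndefinedCorrelationError,
    classify_gold,
    correlation_table,
    distribution_counts,
    distribution_table,
    format_distribution,
    group_summary,
    pearson_r,
    severity_rank,
    spearman_rho,
    subject_table,
    table_percentages,
)
from fissint.phantom import GOLD_CATEGORIES, simulate_cohort


def _toy_table(rng, n=60):
    pairs = simulate_cohort(n, seed=int(rng.integers(1 << 30)))
    return subject_table(pairs)


# -- brute-force oracles ----------------------------------------------------

def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def midrank_oracle(v):
    """Mid-ranks (average rank for ties) by explicit enumeration."""
    v = np.asarray(v, float)
    ranks = np.empty(len(v))
    for i, vi in enumerate(v):
        less = np.sum(v < vi)
        equal = np.sum(v == vi)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


class TestClassifyGold:
    @pytest.mark.parametrize(
        "ratio,pp,expected",
        [
            (75.0, 95.0, "non-COPD"),
            (70.0, 40.0, "non-COPD"),  # ratio at the cut-point
            (60.0, 85.0, "GOLD-I"),
            (60.0, 80.0, "GOLD-I"),
            (60.0, 55.0, "GOLD-II"),
            (60.0, 50.0, "GOLD-II"),
            (55.0, 35.0, "GOLD-III"),
            (50.0, 25.0, "GOLD-IV"),
            (50.0, 29.9, "GOLD-IV"),
        ],
    )
    def test_cut_points(self, ratio, pp, expected):
        assert classify_gold(ratio, pp) == expected

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(CohortError):
            classify_gold(0.0, 50.0)
        with pytest.raises(CohortError):
            classify_gold(60.0, -1.0)


class TestGroupSummary:
    def test_hand_arithmetic_two_subjects(self):
        df = pd.DataFrame(
            {
                "gold": ["GOLD-I", "GOLD-I"],
                "rof": [80.0, 84.0],
                "rhf": [50.0, 50.0],
                "lof": [70.0, 80.0],
                "elf": [70.0, 74.0],
            }
        )
        out = group_summary(df, columns=("rof",))
        row = out[(out["group"] == "GOLD-I") & (out["fissure"] == "ROF")].iloc[0]
        assert row["n"] == 2
        assert row["mean"] == pytest.approx(82.0)
        assert row["sd"] == pytest.approx(2.828, abs=0.001)  # sample SD

    def test_single_subject_sd_configurable(self):
        df = pd.DataFrame({"gold": ["GOLD-IV"], "rof": [66.0]})
        nan_sd = group_summary(df, columns=("rof",))
        row = nan_sd[(nan_sd["group"] == "GOLD-IV")].iloc[0]
        assert np.isnan(row["sd"])
        zero_sd = group_summary(df, columns=("rof",), sd_single=0.0)
        assert zero_sd[(zero_sd["group"] == "GOLD-IV")].iloc[0]["sd"] == 0.0

    def test_cohort_means_recovered_at_scale(self):
        dist = {"ROF": (82.0, 5.0), "RHF": (62.0, 5.0), "LOF": (82.0, 5.0)}
        pairs = simulate_cohort(500, integrity_dist=dist, seed=31)
        df = subject_table(pairs)
        # whole-cohort mean: tight sampling-error bound at n=500
        assert df["rof"].mean() == pytest.approx(82.0, abs=1.0)
        out = group_summary(df, columns=("rof",))
        means = out.dropna(subset=["mean"])
        for _, row in means.iterrows():
            if row["n"] >= 30:  # per-group: 4 standard errors
                assert row["mean"] == pytest.approx(
                    82.0, abs=4.0 * 5.0 / np.sqrt(row["n"])
                )

    def test_empty_group_reported_with_n0(self):
        df = pd.DataFrame({"gold": ["non-COPD"], "rof": [80.0]})
        out = group_summary(df, columns=("rof",))
        empty = out[out["group"] == "GOLD-IV"].iloc[0]
        assert empty["n"] == 0 and np.isnan(empty["mean"])


class TestDistributionTable:
    def test_counts_match_brute_force_filtering(self, rng):
        df = _toy_table(rng, n=120)
        counts = distribution_counts(df, "rhf")
        edges = [(0, 20), (20, 40), (40, 60), (60, 80), (80, 90), (90, 100)]
        for (lo, hi), blab in zip(edges, counts.index):
            for group in GOLD_CATEGORIES:
                sub = df[df["gold"] == group]["rhf"]
                expected = sum(
                    1 for v in sub if (v > lo or (lo == 0 and v == 0)) and v <= hi
                )
                assert counts.loc[blab, group] == expected

    def test_counts_sum_to_cohort_n(self, rng):
        df = _toy_table(rng, n=80)
        counts = distribution_counts(df, "rof")
        assert counts.to_numpy().sum() == len(df)

    def test_reference_top_bin_aggregate(self):
        # per-group counts (58,19,38,19,15) with cohort n=573 -> 149/26.0%
        counts = refdata.reference_bin_counts("ROF")
        pct = table_percentages(counts)
        top = "(90%, 100%]"
        assert counts.loc[top].sum() == 149
        assert pct.loc[top, ALL_GROUPS] == pytest.approx(26.0, abs=0.05)
        formatted = format_distribution(counts)
        assert formatted.loc[top, ALL_GROUPS] == "149/26.0%"

    def test_single_bin_degenerate_cohort(self):
        df = pd.DataFrame(
            {"gold": ["non-COPD"] * 4, "rof": [100.0] * 4}
        )
        table = distribution_table(df, "rof")
        assert table.loc["(90%, 100%]", ALL_GROUPS] == "4/100.0%"
        others = table.drop(index="(90%, 100%]")[ALL_GROUPS]
        assert (others == "0/0.0%").all()

    def test_percentages_recompute_from_counts(self, rng):
        df = _toy_table(rng, n=90)
        counts = distribution_counts(df, "elf")
        pct = table_percentages(counts)
        for group in GOLD_CATEGORIES:
            total = counts[group].sum()
            if total:
                np.testing.assert_allclose(
                    pct[group].to_numpy(), 100.0 * counts[group] / total
                )


class TestCorrelations:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_matches_direct_formula_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=50)
            y = 0.3 * x + rng.normal(size=50)
            r, p = pearson_r(x, y)
            r0, p0 = pearson_oracle(x, y)
            assert abs(r - r0) < 1e-12
            assert abs(p - p0) < 1e-9

    def test_spearman_monotone_and_reversed(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        assert spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_rho(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_spearman_matches_midrank_oracle_with_ties(self, rng):
        for _ in range(5):
            x = rng.integers(0, 5, size=50).astype(float)  # heavy ties
            y = rng.normal(size=50) + 0.2 * x
            rho, _ = spearman_rho(x, y)
            r0, _ = pearson_oracle(midrank_oracle(x), midrank_oracle(y))
            assert abs(rho - r0) < 1e-12

    def test_pearson_spearman_agree_on_rank_linear_data(self):
        # distinct values whose ranks are linear in the values themselves
        ranks = np.arange(1.0, 31.0)
        y = 3.0 * ranks + 1.0
        assert pearson_r(ranks, y)[0] == pytest.approx(
            spearman_rho(ranks, y)[0], abs=1e-12
        )

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(10), np.arange(10.0))
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho(np.arange(10.0), np.full(10, 3.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(CohortError):
            pearson_r([1.0, 2.0], [3.0, 4.0])

    def test_correlation_table_shape(self, rng):
        df = _toy_table(rng, n=60)
        table = correlation_table(df)
        assert list(table["fissure"]) == ["ROF", "RHF", "LOF", "ELF"]
        assert table.notna().all().all()


class TestSeverityIndependence:
    def test_null_association_on_independent_cohort(self):
        """Integrity drawn independently of GOLD stage: Spearman |rho|
        should stay below the 5% critical value in >= 90% of replicates."""
        below = 0
        n, reps = 500, 20
        crit = stats.norm.ppf(0.975) / np.sqrt(n - 1)
        for rep in range(reps):
            pairs = simulate_cohort(n, seed=2000 + rep)
            df = subject_table(pairs)
            rho, _ = spearman_rho(
                df["elf"].to_numpy(), severity_rank(df["gold"])
            )
            if abs(rho) < crit:
                below += 1
        assert below >= 0.9 * reps
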