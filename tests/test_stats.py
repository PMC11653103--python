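"""Statistical primitives: rank tests, summary t tests, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import costria
from costria import reference
from costria.stats import (
    CorrelationResult,
    SummaryStat,
    behavior_summary,
    bonferroni,
    crossstructure_correlations,
    rank_tests,
    spearman_corr,
    subpop_behavior_correlations,
    t_from_summary,
)
from costria.synthetic import simulate_behavior


class TestTFromSummary:
    def test_equal_means_t_zero_p_one(self):
        a = SummaryStat(5.0, 1.0, 10)
        assert t_from_summary(a, a).p == pytest.approx(1.0)

    def test_reported_compartment_time_p(self):
        res = t_from_summary(SummaryStat(352.8, 12.26, 18), SummaryStat(314.1, 10.68, 18))
        assert res.p == pytest.approx(0.0231, abs=0.001)
        assert res.df == 34

    def test_matches_raw_sample_t(self, rng):
        """Construct raw samples with exactly the summarized mean/SEM; the
        summary t equals scipy's equal-variance t on those samples."""
        from scipy.stats import ttest_ind

        def sample_with(mean, sem, n):
            x = rng.normal(0, 1, n)
            x = (x - x.mean()) / x.std(ddof=1)      # exact mean 0, sd 1
            return mean + x * sem * np.sqrt(n)

        a = sample_with(10.0, 0.8, 12)
        b = sample_with(8.5, 0.6, 12)
        res = t_from_summary(
            SummaryStat(a.mean(), a.std(ddof=1) / np.sqrt(12), 12),
            SummaryStat(b.mean(), b.std(ddof=1) / np.sqrt(12), 12),
        )
        t_ref, p_ref = ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t_ref, abs=1e-9)
        assert res.p == pytest.approx(p_ref, abs=1e-9)

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValueError):
            SummaryStat(1.0, 0.0, 10)
        with pytest.raises(ValueError):
            SummaryStat(1.0, 1.0, 1)


def _hand_kw_h(samples):
    """Independent midrank Kruskal-Wallis H with tie correction."""
    pooled = np.concatenate(samples)
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty_like(pooled)
    sorted_vals = pooled[order]
    r = np.arange(1, pooled.size + 1, dtype=float)
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[i:j + 1] = r[i:j + 1].mean()
        i = j + 1
    ranks[order] = r
    n = pooled.size
    start, h = 0, 0.0
    for s in samples:
        rs = ranks[start:start + len(s)]
        h += rs.sum() ** 2 / len(s)
        start += len(s)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - ((counts ** 3 - counts).sum() / (n ** 3 - n))
    return h / tie


class TestRankTests:
    def test_identical_samples_h_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = rank_tests([x, x, x])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert all(p.p_adjusted == 1.0 for p in res.posthoc)

    def test_h_matches_hand_formula(self, rng):
        samples = [rng.integers(0, 6, 10).astype(float) for _ in range(3)]
        res = rank_tests(samples)
        assert res.statistic == pytest.approx(_hand_kw_h(samples), abs=1e-9)

    def test_p_consistent_with_exact_permutation_oracle(self, rng):
        """On n = 10 (two groups of 5, K-W reduces to the rank-sum square),
        the chi-square p approximates the exact permutation p."""
        x = np.array([1.2, 3.4, 0.5, 2.2, 4.1])
        y = np.array([2.8, 5.0, 4.4, 3.9, 6.1])
        z = np.array([0.1, 0.3, 1.1, 0.9, 0.2])
        obs = _hand_kw_h([x, y, z])
        pooled = np.concatenate([x, y, z])
        count = total = 0
        for perm in itertools.permutations(range(15), 15):
            break  # full 15! enumeration infeasible; use grouped combinations
        from itertools import combinations
        idx = set(range(15))
        for ga in combinations(range(15), 5):
            rest = idx - set(ga)
            for gb in combinations(sorted(rest), 5):
                gc = sorted(rest - set(gb))
                h = _hand_kw_h([pooled[list(ga)], pooled[list(gb)], pooled[gc]])
                count += h >= obs - 1e-12
                total += 1
        exact_p = count / total
        res = rank_tests([x, y, z])
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 4) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_tests([np.array([1.0]), np.array([])])

    def test_two_samples_use_rank_sum(self, rng):
        res = rank_tests([rng.normal(0, 1, 15), rng.normal(2.5, 1, 15)])
        assert res.test == "mannwhitney"
        assert res.p < 0.05

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=15, unique=True),
           st.lists(st.floats(-50, 50), min_size=5, max_size=15, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_invariance_under_monotone_transform(self, a, b):
        a, b = np.array(a), np.array(b)
        r1 = rank_tests([a, b])
        # x -> x / 4 is strictly monotone and exact in binary floats, so it
        # cannot collapse distinct values the way exp() can
        r2 = rank_tests([a / 4.0, b / 4.0])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-8)


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman_corr([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        down = spearman_corr([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = spearman_corr(x, y)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        rho_ref = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(rho_ref, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])

    def test_missing_pairs_dropped(self):
        res = spearman_corr([1, 2, 3, 4, np.nan], [2, 4, 6, 8, 1])
        assert res.n == 4
        assert res.rho == pytest.approx(1.0)


class TestBehaviorSummary:
    def test_single_group_summaries_only(self):
        t = pd.DataFrame({"animal_id": ["a", "b"], "group": ["control"] * 2,
                          "measure": ["contacts"] * 2, "value": [10, 12]})
        res = behavior_summary(t)
        assert res["tests"] == {}
        assert res["summaries"]["mean"].iloc[0] == 11.0

    def test_unknown_measure_rejected(self):
        t = pd.DataFrame({"animal_id": ["a"], "group": ["control"],
                          "measure": ["tail_flicks"], "value": [1.0]})
        with pytest.raises(ValueError, match="tail_flicks"):
            behavior_summary(t)

    def test_summaries_match_spreadsheet_oracle(self):
        vals = [10.0, 12.0, 14.0, 7.0, 8.0, 9.0]
        t = pd.DataFrame({
            "animal_id": list("abcdef"),
            "group": ["control"] * 3 + ["VPA"] * 3,
            "measure": ["contacts"] * 6,
            "value": vals,
        })
        res = behavior_summary(t)
        s = res["summaries"].set_index("group")
        assert s.loc["control", "mean"] == pytest.approx(12.0)
        assert s.loc["control", "sem"] == pytest.approx(2.0 / np.sqrt(3))
        assert s.loc["VPA", "mean"] == pytest.approx(8.0)

    def test_reference_contacts_contrast_significant(self):
        """Samples drawn at the reported contact summaries (effect ~4.6
        standard errors, so analytic power at alpha = 0.001 is ~0.84)
        replicate the contrast in most seeds."""
        cfg = reference.BEHAVIOR_SUMMARY.query("measure == 'contacts'")
        hits = 0
        for seed in range(20):
            t = simulate_behavior(cfg, seed=seed)
            res = behavior_summary(t)
            hits += res["tests"]["contacts"].p < 0.001
        assert hits >= 13


def _metrics_frame(rng, animals, base_short, base_long, region):
    rows = []
    for a, gain in animals.items():
        for i in range(12):
            # half the units respond with an increase, half with a decrease
            sign = 1.0 if i % 2 == 0 else -1.0
            short = sign * rng.normal(base_short * gain, 0.3)
            long = sign * rng.normal(base_long * gain, 0.3)
            row = {"unit_id": f"{region}-{a}-{i}", "animal_id": a,
                   "group": "control", "region": region}
            row.update({f"short_amp{j}": short + rng.normal(0, 0.05) for j in range(1, 6)})
            row.update({f"long_amp{j}": long + rng.normal(0, 0.05) for j in range(1, 6)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestCrossStructure:
    def test_shared_animal_gain_yields_positive_rho(self, rng):
        animals = {f"r{i}": g for i, g in enumerate(rng.uniform(0.5, 2.0, 10))}
        s1 = _metrics_frame(rng, animals, 2.0, 1.5, "S1")
        dlst = _metrics_frame(rng, animals, 1.0, 0.8, "DLSt")
        res = crossstructure_correlations(s1, dlst)
        assert res["short_increase"].rho > 0.5
        assert res["long_increase"].rho > 0.5

    def test_anticorrelated_gains_yield_negative_rho(self, rng):
        gains = rng.uniform(0.5, 2.0, 10)
        s1 = _metrics_frame(rng, {f"r{i}": g for i, g in enumerate(gains)}, 2.0, 1.5, "S1")
        dlst = _metrics_frame(rng, {f"r{i}": 2.5 - g for i, g in enumerate(gains)}, 1.0, 0.8, "DLSt")
        res = crossstructure_correlations(s1, dlst)
        assert res["short_increase"].rho < -0.5

    def test_identical_vectors_rho_one(self, rng):
        animals = {f"r{i}": g for i, g in enumerate(rng.uniform(0.5, 2.0, 8))}
        s1 = _metrics_frame(rng, animals, 2.0, 1.5, "S1")
        res = crossstructure_correlations(s1, s1)
        assert res["short_increase"].rho == pytest.approx(1.0)

    def test_too_few_shared_animals_rejected(self, rng):
        s1 = _metrics_frame(rng, {"r1": 1.0, "r2": 1.2}, 2.0, 1.5, "S1")
        dlst = _metrics_frame(rng, {"r1": 1.0, "r3": 1.2}, 1.0, 0.8, "DLSt")
        with pytest.raises(ValueError, match="animals"):
            crossstructure_correlations(s1, dlst)


class TestSubpopBehavior:
    def _counts(self, rng, n=10):
        return pd.DataFrame({
            "animal_id": [f"r{i}" for i in range(n)],
            "type1": rng.integers(5, 40, n),
            "type2": rng.integers(5, 40, n),
            "type3": rng.integers(5, 40, n),
        })

    def _behavior(self, counts, rng, coupled=None):
        rows = []
        for _, row in counts.iterrows():
            for m in ("interaction_time", "dip_time", "grooming_time"):
                v = rng.normal(50, 10)
                if coupled and m == coupled[1]:
                    v = 100 - 2.0 * row[coupled[0]] + rng.normal(0, 2)
                rows.append({"animal_id": row["animal_id"], "measure": m, "value": v})
        return pd.DataFrame(rows)

    def test_grid_dimensions(self, rng):
        counts = self._counts(rng)
        grid = subpop_behavior_correlations(counts, self._behavior(counts, rng))
        assert len(grid) == 9

    def test_negative_count_grooming_coupling_recovered(self, rng):
        counts = self._counts(rng)
        beh = self._behavior(counts, rng, coupled=("type1", "grooming_time"))
        grid = subpop_behavior_correlations(counts, beh)
        row = grid.query("unit_class == 'type1' and measure == 'grooming_time'")
        assert row["rho"].iloc[0] < -0.8

    def test_constant_counts_flagged(self, rng):
        counts = self._counts(rng)
        counts["type2"] = 7
        grid = subpop_behavior_correlations(counts, self._behavior(counts, rng))
        flagged = grid.query("unit_class == 'type2'")
        assert flagged["flag"].str.contains("constant").all()

    def test_missing_animal_named_in_error(self, rng):
        counts = self._counts(rng)
        beh = self._behavior(counts.iloc[:-1], rng)
        with pytest.raises(ValueError, match="r9"):
            subpop_behavior_correlations(counts, beh)


def test_all_pvalues_in_unit_interval(rng):
    res = rank_tests([rng.normal(size=9), rng.normal(size=9), rng.normal(size=9)])
    assert 0 <= res.p <= 1
    assert all(0 <= p.p_adjusted <= 1 for p in res.posthoc)
    assert all(p.p_adjusted >= p.p_raw for p in res.posthoc)
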