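"""Statistical primitives and behavior/correlation analyses.

Group comparisons follow the study's conventions: unpaired t tests for
behavioral and anatomical summaries (reported as mean +/- SEM),
Kruskal-Wallis with Bonferroni-corrected rank post hocs for
electrophysiological data, Mann-Whitney rank-sum as the two-sample
"Wilcoxon" test, and Spearman correlations for cross-structure and
subpopulation-behavior relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

BEHAVIOR_MEASURES = (
    "compartment_time", "contacts", "interaction_time", "distance",
    "grooming_events", "grooming_time", "dip_latency", "dip_frequency",
    "dip_time",
)


@dataclass(frozen=True)
class SummaryStat:
    """Group summary as reported in the source tables: mean +/- SEM, n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValueError("sem must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    name: str = ""


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class RankTestResult:
    statistic: float          # Kruskal-Wallis H (tie-corrected) or rank-sum U
    df: float
    p: float
    test: str                 # "kruskal" | "mannwhitney"
    posthoc: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    label: str = ""


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: p x m, capped at 1."""
    return min(1.0, p * m)


def t_from_summary(a: SummaryStat, b: SummaryStat) -> TestResult:
    """Unpaired two-sided t test reconstructed from printed mean/SEM/n.

    t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2), df = n_a + n_b - 2.
    Equivalent to the equal-per-group t test on any raw samples with these
    summaries.
    """
    t = (a.mean - b.mean) / float(np.hypot(a.sem, b.sem))
    df = a.n + b.n - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p), name="t")


def rank_tests(samples, alpha: float = 0.05, posthoc: bool = True) -> RankTestResult:
    """Kruskal-Wallis (>= 3 samples) or Mann-Whitney (2 samples) with
    Bonferroni-adjusted pairwise rank post hocs.

    ``samples`` is a sequence of 1-D arrays or a mapping name -> array.
    Ties are handled by midranks (scipy's tie correction).
    """
    if isinstance(samples, dict):
        names = list(samples)
        arrays = [np.asarray(samples[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(s, dtype=float) for s in samples]
        names = list(range(len(arrays)))
    if len(arrays) < 2:
        raise ValueError("need at least two samples")
    for nm, arr in zip(names, arrays):
        if arr.size == 0:
            raise ValueError(f"empty sample: {nm!r}")

    if len(arrays) == 2:
        res = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return RankTestResult(
            statistic=float(res.statistic), df=1.0, p=float(res.pvalue),
            test="mannwhitney",
        )

    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        # identical samples: H = 0 by construction, scipy raises instead
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    post = []
    if posthoc:
        pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
        m = len(pairs)
        for i, j in pairs:
            if np.array_equal(arrays[i], arrays[j]):
                u, pr = arrays[i].size * arrays[j].size / 2.0, 1.0
            else:
                r = sps.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
                u, pr = float(r.statistic), float(r.pvalue)
            padj = bonferroni(pr, m)
            post.append(
                PosthocResult(
                    pair=(names[i], names[j]), statistic=u,
                    p_raw=pr, p_adjusted=padj, significant=padj < alpha,
                )
            )
    return RankTestResult(
        statistic=float(h), df=float(len(arrays) - 1), p=float(p),
        test="kruskal", posthoc=tuple(post),
    )


def spearman_corr(x, y, label: str = "") -> CorrelationResult:
    """Spearman rank correlation; pairs with missing values are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=int(x.size), label=label)


def shapiro_normality(x) -> TestResult:
    """Shapiro-Wilk normality pre-check (reported, never used to auto-switch
    between parametric and rank tests)."""
    w, p = sps.shapiro(np.asarray(x, dtype=float))
    return TestResult(statistic=float(w), df=float(len(x)), p=float(p), name="shapiro")


# ---------------------------------------------------------------------------
# behavior

def behavior_summary(table: pd.DataFrame) -> dict:
    """Per-measure, per-group mean +/- SEM and unpaired t tests.

    ``table`` has columns animal_id, group, measure, value. Returns
    ``{"summaries": DataFrame, "tests": {measure: TestResult}}``; with a
    single group only the summaries are produced.
    """
    unknown = set(table["measure"]) - set(BEHAVIOR_MEASURES)
    if unknown:
        raise ValueError(
            f"unknown behavior measures {sorted(unknown)}; "
            f"valid: {BEHAVIOR_MEASURES}"
        )
    g = table.groupby(["measure", "group"])["value"]
    summaries = g.agg(
        mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count"
    ).reset_index()

    tests: dict[str, TestResult] = {}
    groups = sorted(table["group"].unique())
    if len(groups) >= 2:
        a_name, b_name = groups[0], groups[1]
        for measure in sorted(table["measure"].unique()):
            sub = table[table["measure"] == measure]
            a = sub.loc[sub["group"] == a_name, "value"].to_numpy(float)
            b = sub.loc[sub["group"] == b_name, "value"].to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = sps.ttest_ind(a, b, equal_var=True)
            tests[measure] = TestResult(
                statistic=float(t), df=float(len(a) + len(b) - 2), p=float(p),
                name=f"t:{a_name}-vs-{b_name}",
            )
    return {"summaries": summaries, "tests": tests}


# ---------------------------------------------------------------------------
# cross-structure and subpopulation correlations

_CROSS_COMPONENTS = ("short_increase", "short_decrease", "long_increase")


def _animal_components(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean amplitudes of three evoked components.

    short_increase / short_decrease: five-stimulus mean short-latency
    amplitude averaged over units with positive / negative short response;
    long_increase: mean long-latency amplitude over units with a positive
    rebound.
    """
    short_cols = [f"short_amp{i}" for i in range(1, 6)]
    long_cols = [f"long_amp{i}" for i in range(1, 6)]
    df = metrics.copy()
    df["short_mean"] = df[short_cols].mean(axis=1)
    df["long_mean"] = df[long_cols].mean(axis=1)
    out = []
    for animal, sub in df.groupby("animal_id"):
        inc = sub.loc[sub["short_mean"] > 0, "short_mean"]
        dec = sub.loc[sub["short_mean"] < 0, "short_mean"]
        reb = sub.loc[sub["long_mean"] > 0, "long_mean"]
        out.append(
            {
                "animal_id": animal,
                "short_increase": inc.mean() if len(inc) else np.nan,
                "short_decrease": dec.mean() if len(dec) else np.nan,
                "long_increase": reb.mean() if len(reb) else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("animal_id")


def crossstructure_correlations(
    metrics_s1: pd.DataFrame, metrics_dlst: pd.DataFrame
) -> dict[str, CorrelationResult]:
    """Spearman correlations of per-animal evoked components between the
    somatosensory cortex and the dorsolateral striatum.

    Both inputs are per-unit evoked-metric tables (see
    :func:`costria.evoked.evoked_metrics`) carrying an ``animal_id`` column;
    animals lacking one of the two regions are dropped.
    """
    a = _animal_components(metrics_s1)
    b = _animal_components(metrics_dlst)
    shared = a.index.intersection(b.index)
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 animals with both regions; have {len(shared)}"
        )
    results = {}
    for comp in _CROSS_COMPONENTS:
        label = f"S1-vs-DLSt {comp}"
        try:
            results[comp] = spearman_corr(
                b.loc[shared, comp], a.loc[shared, comp], label=label
            )
        except ValueError as exc:
            # a component can be empty (e.g. no units with a short-latency
            # decrease); report it as undefined rather than aborting the grid
            results[comp] = CorrelationResult(
                rho=float("nan"), p=float("nan"), n=0,
                label=f"{label} (undefined: {exc})",
            )
    return results


def subpop_behavior_correlations(
    class_counts: pd.DataFrame, behavior: pd.DataFrame,
    measures: tuple = ("interaction_time", "dip_time", "grooming_time"),
) -> pd.DataFrame:
    """Spearman grid of unit-class counts x behavioral measures per animal.

    ``class_counts``: columns animal_id plus one column per unit class
    (counts). ``behavior``: columns animal_id, measure, value. Returns a
    tidy frame with rho/p/n per (class, measure); a constant count vector
    yields a flagged row instead of a coefficient.
    """
    counts = class_counts.set_index("animal_id")
    beh = behavior.pivot_table(index="animal_id", columns="measure", values="value")
    missing = counts.index.difference(beh.index)
    if len(missing):
        raise ValueError(
            f"behavior table missing animals: {sorted(map(str, missing))}"
        )
    rows = []
    for cls in counts.columns:
        for measure in measures:
            x = counts[cls].to_numpy(float)
            y = beh.loc[counts.index, measure].to_numpy(float)
            try:
                r = spearman_corr(x, y, label=f"{cls}-vs-{measure}")
                rows.append((cls, measure, r.rho, r.p, r.n, ""))
            except ValueError as exc:
                rows.append((cls, measure, np.nan, np.nan, len(x), str(exc)))
    return pd.DataFrame(
        rows, columns=["unit_class", "measure", "rho", "p", "n", "flag"]
    )


__all__ = [
    "BEHAVIOR_MEASURES", "SummaryStat", "TestResult", "PosthocResult",
    "RankTestResult", "CorrelationResult", "bonferroni", "t_from_summary",
    "rank_tests", "spearman_corr", "shapiro_normality", "behavior_summary",
    "crossstructure_correlations", "subpop_behavior_correlations",
]
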