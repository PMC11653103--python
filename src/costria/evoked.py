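"""Peri-stimulus alignment, z-scoring, latency, and facilitation/depression.

Evoked activity is analyzed in a 1.5 s window aligned to the first pulse of
each stimulation train, z-scored per unit against the 0.3 s pre-train
baseline.  Response amplitudes are taken in two windows per pulse: the
short-latency window [t, t+80 ms) and the long-latency ("rebound") window
of 200 ms starting 80 ms after each pulse onset, rendering five values per
unit per window type.  The ordinary-least-squares slope of the five
long-latency amplitudes against pulse index classifies each unit as
facilitating (slope > 0) or depressing (slope < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import Session, StimulusProtocol, UnitRecording
from . import stats as _stats

PATTERN_WINDOW = (-0.3, 1.5)
PATTERN_BINSIZE = 0.01
LATENCY_BINSIZE = 0.005
BASELINE_WINDOW = (-0.3, 0.0)
SHORT_WINDOW = 0.08    # s after each pulse onset
LONG_WINDOW = 0.2      # s, starting SHORT_WINDOW after each pulse onset


class ZeroBaselineError(ValueError):
    """Baseline SD is zero: the unit cannot be z-scored and is excluded."""


def compute_psth(
    spike_times,
    event_times,
    window: tuple = PATTERN_WINDOW,
    binsize: float = PATTERN_BINSIZE,
):
    """Peri-event spike counts.

    Returns ``(counts, edges)`` where ``counts[i, j]`` is the number of
    spikes in ``[event_i + edge_j, event_i + edge_{j+1})``.
    """
    spikes = np.asarray(spike_times, dtype=float)
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one event")
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    if window[1] <= window[0]:
        raise ValueError("window must be well-ordered (t0 < t1)")
    n_bins = int(round((window[1] - window[0]) / binsize))
    edges = window[0] + binsize * np.arange(n_bins + 1)
    counts = np.zeros((events.size, n_bins), dtype=float)
    for i, ev in enumerate(events):
        rel = spikes[(spikes >= ev + window[0]) & (spikes < ev + edges[-1])] - ev
        idx = np.floor((rel - window[0]) / binsize).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts[i] = np.bincount(idx, minlength=n_bins)
    return counts, edges


def _summed_counts(spikes, events, window, binsize) -> np.ndarray:
    """Trial-summed evoked counts per bin (fast path; no per-trial rows)."""
    n_bins = int(round((window[1] - window[0]) / binsize))
    rel = (spikes[:, None] - events[None, :]).ravel()
    rel = rel[(rel >= window[0]) & (rel < window[0] + n_bins * binsize)]
    idx = np.floor((rel - window[0]) / binsize).astype(int)
    return np.bincount(np.clip(idx, 0, n_bins - 1), minlength=n_bins).astype(float)


def zscore_pattern(
    counts: np.ndarray,
    edges: np.ndarray,
    binsize: float,
    baseline_window: tuple = BASELINE_WINDOW,
) -> np.ndarray:
    """z-score a trial-averaged peri-event pattern against its baseline bins.

    z = (trial-mean rate - baseline mean) / baseline SD, with the baseline
    statistics taken across bins of the trial-mean trace that fall inside
    ``baseline_window``. Raises :class:`ZeroBaselineError` when the baseline
    SD is zero (silent or perfectly constant baseline).
    """
    left = edges[:-1]
    if baseline_window[0] < edges[0] - 1e-12 or baseline_window[1] > edges[-1] + 1e-12:
        raise ValueError("baseline window must lie inside the pattern span")
    rate = counts.mean(axis=0) / binsize
    base = rate[(left >= baseline_window[0]) & (left < baseline_window[1])]
    if base.size < 2:
        raise ValueError("baseline window contains fewer than 2 bins")
    mu = base.mean()
    sd = base.std(ddof=1)
    if sd == 0:
        raise ZeroBaselineError("zero baseline SD; unit excluded from z-scoring")
    return (rate - mu) / sd


@dataclass
class PatternMatrix:
    """Units x time-bins z-scored evoked activity (clustering feature space)."""

    unit_ids: list
    edges: np.ndarray           # seconds relative to the train onset
    values: np.ndarray          # (n_units, n_bins), finite
    excluded: list = field(default_factory=list)  # (unit_id, reason)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def pattern_matrix(
    session_or_units,
    region: str | None = None,
    window: tuple = PATTERN_WINDOW,
    binsize: float = PATTERN_BINSIZE,
    baseline_window: tuple = BASELINE_WINDOW,
) -> PatternMatrix:
    """Trial-averaged z-scored evoked pattern for every unit.

    Units whose baseline SD is zero are flagged in ``excluded`` (with the
    reason) rather than silently zeroed.
    """
    units, protocol = _resolve_units(session_or_units, region)
    rows, ids, excluded = [], [], []
    edges = None
    for u in units:
        counts, edges = compute_psth(u.spike_times, protocol.train_onsets, window, binsize)
        try:
            rows.append(zscore_pattern(counts, edges, binsize, baseline_window))
            ids.append(u.unit_id)
        except ZeroBaselineError as exc:
            excluded.append((u.unit_id, str(exc)))
    values = np.vstack(rows) if rows else np.empty((0, len(edges) - 1))
    return PatternMatrix(unit_ids=ids, edges=edges, values=values, excluded=excluded)


def _resolve_units(session_or_units, region):
    if isinstance(session_or_units, Session):
        session = session_or_units
        units = session.units_in(region) if region else session.units
        if region and not units:
            raise ValueError(f"region {region!r} absent from session")
        return units, session.protocol
    units, protocol = session_or_units
    return list(units), protocol


def first_stim_latency(
    z: np.ndarray,
    edges: np.ndarray,
    threshold: float = 2.0,
    min_bins: int = 2,
    search_window: tuple = (0.0, 0.05),
) -> float | None:
    """Latency of the response to the first pulse, in ms, or None.

    The latency is the left edge of the first bin starting inside
    ``search_window`` where z > threshold for at least ``min_bins``
    consecutive bins; None when the criterion is never met.
    """
    left = edges[:-1]
    above = z > threshold
    candidates = np.flatnonzero((left >= search_window[0]) & (left < search_window[1]))
    for i in candidates:
        if i + min_bins <= above.size and above[i:i + min_bins].all():
            return float(left[i] * 1e3)
    return None


def stimulus_amplitudes(
    z: np.ndarray,
    edges: np.ndarray,
    protocol: StimulusProtocol,
    short_window: float = SHORT_WINDOW,
    long_window: float = LONG_WINDOW,
):
    """Per-pulse response amplitudes (mean z per half-open window).

    For a pulse at offset t (relative to the train onset) the short-latency
    window is [t, t+0.08) and the long-latency window [t+0.08, t+0.28).
    Returns ``(short_amp, long_amp)``, five values each.
    """
    offsets = protocol.pulse_offsets
    if np.any(np.diff(offsets) < short_window + long_window):
        raise ValueError(
            "long-latency windows overlap the next pulse under this protocol "
            f"(pulse interval {protocol.pulse_interval:.3f} s < "
            f"{short_window + long_window:.3f} s)"
        )
    if offsets[-1] + short_window + long_window > edges[-1] + 1e-12:
        raise ValueError("amplitude windows do not fit inside the pattern span")
    centers = (edges[:-1] + edges[1:]) / 2.0
    short_amp = np.empty(len(offsets))
    long_amp = np.empty(len(offsets))
    for p, off in enumerate(offsets):
        s_mask = (centers >= off) & (centers < off + short_window)
        l_mask = (centers >= off + short_window) & (centers < off + short_window + long_window)
        short_amp[p] = z[s_mask].mean()
        long_amp[p] = z[l_mask].mean()
    return short_amp, long_amp


def adaptation_slope(long_amp) -> tuple[float, str]:
    """OLS slope of the five long-latency amplitudes against pulse index.

    Returns ``(slope, class)`` with class facilitating (slope > 0),
    depressing (slope < 0) or flat (slope == 0).
    """
    y = np.asarray(long_amp, dtype=float)
    if y.size != 5:
        raise ValueError("expected exactly 5 amplitudes")
    if not np.all(np.isfinite(y)):
        raise ValueError("amplitudes must be finite")
    x = np.arange(1.0, 6.0)
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum())
    cls = "facilitating" if slope > 0 else "depressing" if slope < 0 else "flat"
    return slope, cls


def evoked_metrics(
    session_or_units,
    region: str | None = None,
    latency_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-unit evoked metrics table.

    Columns: unit_id, animal_id, group, region, latency_ms,
    short_amp1..5, long_amp1..5, slope, adaptation_class.
    """
    units, protocol = _resolve_units(session_or_units, region)
    pm = pattern_matrix((units, protocol))
    excluded = {uid for uid, _ in pm.excluded}
    by_id = {u.unit_id: u for u in units}
    rows = []
    for uid, z in zip(pm.unit_ids, pm.values):
        u = by_id[uid]
        counts5, edges5 = compute_psth(
            u.spike_times, protocol.train_onsets, PATTERN_WINDOW, LATENCY_BINSIZE
        )
        try:
            z5 = zscore_pattern(counts5, edges5, LATENCY_BINSIZE)
            latency = first_stim_latency(z5, edges5, threshold=latency_threshold)
        except ZeroBaselineError:
            latency = None
        short_amp, long_amp = stimulus_amplitudes(z, pm.edges, protocol)
        slope, cls = adaptation_slope(long_amp)
        row = {
            "unit_id": uid, "animal_id": u.animal_id, "group": u.group,
            "region": u.region, "latency_ms": latency,
        }
        row.update({f"short_amp{i + 1}": short_amp[i] for i in range(5)})
        row.update({f"long_amp{i + 1}": long_amp[i] for i in range(5)})
        row.update({"slope": slope, "adaptation_class": cls})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = list(pm.excluded) + [
        (uid, "excluded before metrics") for uid in excluded if uid not in set(pm.unit_ids)
    ]
    return df


def train_response_stats(
    metrics: pd.DataFrame,
    group_col: str = "group",
    alpha: float = 0.05,
    min_units: int = 3,
) -> dict:
    """Intra-group (pulse 1 vs pulses 2-5) and inter-group per-pulse
    comparisons of the long-latency amplitudes.

    Rank tests with Bonferroni adjustment; groups with fewer than
    ``min_units`` units are flagged and skipped. Returns
    ``{"intra": {group: [PosthocResult x4]}, "inter": {pulse: RankTestResult},
    "skipped": [...]}``.
    """
    long_cols = [f"long_amp{i}" for i in range(1, 6)]
    groups = sorted(metrics[group_col].unique())
    usable, skipped = [], []
    for g in groups:
        n = int((metrics[group_col] == g).sum())
        (usable if n >= min_units else skipped).append((g, n))
    usable_names = [g for g, _ in usable]
    if len(usable_names) < 2 and len(usable_names) * 5 < 2:
        raise ValueError("need >= 2 groups or >= 2 pulses with enough units")

    intra: dict = {}
    for g in usable_names:
        sub = metrics.loc[metrics[group_col] == g, long_cols].to_numpy(float)
        res = []
        m = 4
        for j in range(1, 5):
            if np.array_equal(sub[:, 0], sub[:, j]):
                u, p = sub.shape[0] ** 2 / 2.0, 1.0
            else:
                from scipy.stats import mannwhitneyu
                r = mannwhitneyu(sub[:, 0], sub[:, j], alternative="two-sided")
                u, p = float(r.statistic), float(r.pvalue)
            padj = _stats.bonferroni(p, m)
            res.append(
                _stats.PosthocResult(
                    pair=("pulse1", f"pulse{j + 1}"), statistic=u,
                    p_raw=p, p_adjusted=padj, significant=padj < alpha,
                )
            )
        intra[g] = res

    inter: dict = {}
    if len(usable_names) >= 2:
        for j, col in enumerate(long_cols, start=1):
            samples = {
                g: metrics.loc[metrics[group_col] == g, col].to_numpy(float)
                for g in usable_names
            }
            res = _stats.rank_tests(samples, alpha=alpha, posthoc=len(samples) > 2)
            padj = _stats.bonferroni(res.p, 5)
            inter[j] = {"result": res, "p_adjusted": padj, "significant": padj < alpha}
    return {"intra": intra, "inter": inter, "skipped": skipped}


__all__ = [
    "PATTERN_WINDOW", "PATTERN_BINSIZE", "LATENCY_BINSIZE", "BASELINE_WINDOW",
    "SHORT_WINDOW", "LONG_WINDOW", "ZeroBaselineError",
    "compute_psth", "zscore_pattern", "PatternMatrix", "pattern_matrix",
    "first_stim_latency", "stimulus_amplitudes", "adaptation_slope",
    "evoked_metrics", "train_response_stats",
]
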