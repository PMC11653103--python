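"""Population PC trajectories and the spike-shift surrogate null.

The population's trial-averaged z-scored evoked activity (units x time
bins over [0, 1.5) s from the train onset, 10 ms bins) is decomposed by
PCA across time bins; the first three component timecourses are the
population trajectories.  The null distribution for stimulus locking is
built by rigidly and circularly shifting every unit's whole spike train by
an independent uniform draw in +/-5 s, recomputing the population matrix,
and extracting its principal components (signs aligned to the real data's
loadings); the pointwise 2.5-97.5 percentile envelope over the surrogates
is the confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .session import Session
from .evoked import BASELINE_WINDOW, ZeroBaselineError, compute_psth, zscore_pattern

TRAJECTORY_WINDOW = (0.0, 1.5)
TRAJECTORY_BINSIZE = 0.01
SURROGATE_SHIFT_RANGE = 5.0   # +/- seconds
N_COMPONENTS = 3


def population_matrix(
    session: Session,
    region: str,
    window: tuple = TRAJECTORY_WINDOW,
    binsize: float = TRAJECTORY_BINSIZE,
):
    """Units x bins trial-averaged z matrix plus a peak-time sort order.

    The sort order (argsort of each unit's peak-z time, ties broken by unit
    index) is returned separately; the matrix itself is never reordered.
    Zero-baseline units are dropped and reported.
    """
    units = session.units_in(region)
    if len(units) < 4:
        raise ValueError(f"region {region!r}: need >= 4 units, have {len(units)}")
    onsets = session.protocol.train_onsets
    full_window = (min(BASELINE_WINDOW[0], window[0]), window[1])
    rows, ids, excluded = [], [], []
    for u in units:
        counts, edges = compute_psth(u.spike_times, onsets, full_window, binsize)
        try:
            z = zscore_pattern(counts, edges, binsize)
        except ZeroBaselineError as exc:
            excluded.append((u.unit_id, str(exc)))
            continue
        keep = (edges[:-1] >= window[0] - 1e-12) & (edges[:-1] < window[1] - 1e-12)
        rows.append(z[keep])
        ids.append(u.unit_id)
    if len(rows) < 4:
        raise ValueError("fewer than 4 z-scorable units in region")
    matrix = np.vstack(rows)
    n_bins = matrix.shape[1]
    centers = window[0] + binsize * (np.arange(n_bins) + 0.5)
    peak_times = centers[matrix.argmax(axis=1)]
    order = np.argsort(peak_times, kind="stable")
    return matrix, ids, centers, order, excluded


@dataclass
class TrajectoryResult:
    """Population PC timecourses with optional surrogate envelopes."""

    timecourses: np.ndarray          # (3, n_bins)
    variance_fractions: np.ndarray   # (3,)
    loadings: np.ndarray             # (n_units, 3)
    bin_centers: np.ndarray
    bin_mean: np.ndarray             # per-unit mean over bins (centering)
    envelope: np.ndarray | None = None   # (3, 2, n_bins): low, high
    surrogates: np.ndarray | None = None  # (n_surrogates, 3, n_bins)
    unit_ids: list = field(default_factory=list)


def pc_trajectories(matrix: np.ndarray, bin_centers=None, unit_ids=None) -> TrajectoryResult:
    """First three PC timecourses of a units x bins population matrix.

    PCA is taken over time bins (bins are observations, units variables);
    timecourses are the projections of the population vector at each bin
    onto the loadings. A flat matrix yields zero trajectories.
    """
    M = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("population matrix must be finite")
    n_units, n_bins = M.shape
    if bin_centers is None:
        bin_centers = np.arange(n_bins, dtype=float)
    X = M.T                                   # bins x units
    mean = X.mean(axis=0)
    centered = X - mean
    if not centered.any():
        return TrajectoryResult(
            timecourses=np.zeros((N_COMPONENTS, n_bins)),
            variance_fractions=np.zeros(N_COMPONENTS),
            loadings=np.zeros((n_units, N_COMPONENTS)),
            bin_centers=np.asarray(bin_centers, float),
            bin_mean=mean,
            unit_ids=list(unit_ids or []),
        )
    pca = PCA(n_components=N_COMPONENTS, svd_solver="full")
    scores = pca.fit_transform(X)             # bins x 3
    return TrajectoryResult(
        timecourses=scores.T,
        variance_fractions=pca.explained_variance_ratio_.copy(),
        loadings=pca.components_.T,           # units x 3
        bin_centers=np.asarray(bin_centers, float),
        bin_mean=mean,
        unit_ids=list(unit_ids or []),
    )


def project_matrix(matrix: np.ndarray, result: TrajectoryResult) -> np.ndarray:
    """Project a units x bins matrix onto an existing result's loadings."""
    X = np.asarray(matrix, dtype=float).T - result.bin_mean
    return (X @ result.loadings).T


def _fast_z_matrix(shifted_spikes_per_unit, onsets, window, binsize, n_base_bins):
    """Trial-mean z matrix from pre-shifted spike trains (surrogate path)."""
    n_trials = onsets.size
    full_t0 = window[0] - n_base_bins * binsize
    n_bins = int(round((window[1] - window[0]) / binsize))
    total_bins = n_base_bins + n_bins
    rows = np.empty((len(shifted_spikes_per_unit), n_bins))
    for i, spikes in enumerate(shifted_spikes_per_unit):
        rel = (spikes[:, None] - onsets[None, :]).ravel()
        rel = rel[(rel >= full_t0) & (rel < window[1])]
        idx = np.floor((rel - full_t0) / binsize).astype(int)
        counts = np.bincount(np.clip(idx, 0, total_bins - 1), minlength=total_bins)
        rate = counts / (binsize * n_trials)
        base = rate[:n_base_bins]
        sd = base.std(ddof=1)
        rows[i] = 0.0 if sd == 0 else (rate[n_base_bins:] - base.mean()) / sd
    return rows


def surrogate_band(
    session: Session,
    region: str,
    result: TrajectoryResult | None = None,
    n_surrogates: int = 1000,
    shift_range: float = SURROGATE_SHIFT_RANGE,
    seed: int = 0,
    window: tuple = TRAJECTORY_WINDOW,
    binsize: float = TRAJECTORY_BINSIZE,
    quantiles: tuple = (2.5, 97.5),
    project_on: str = "surrogate",
) -> TrajectoryResult:
    """Surrogate confidence band for the population PC trajectories.

    Each surrogate shifts every unit's entire spike train rigidly by an
    independent uniform draw in [-shift_range, +shift_range] s with
    circular wrap over the session duration (spike counts are conserved
    exactly), recomputes the z matrix, and extracts its first principal
    components (signs aligned to the original loadings), so real and
    surrogate trajectories are directly comparable max-variance
    projections; ``project_on="original"`` projects surrogates onto the
    real data's loadings instead. The envelope is the pointwise
    [2.5, 97.5] percentile across surrogates. Fewer than 100 surrogates
    triggers a warning; fewer than 2 is rejected.
    """
    if project_on not in ("surrogate", "original"):
        raise ValueError("project_on must be 'surrogate' or 'original'")
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    if n_surrogates < 100:
        import warnings
        warnings.warn(
            f"only {n_surrogates} surrogates; envelope quantiles will be noisy",
            stacklevel=2,
        )
    if session.duration <= 2 * shift_range:
        raise ValueError("recording too short for circular shifting over the range")
    if result is None:
        matrix, ids, centers, _, _ = population_matrix(session, region, window, binsize)
        result = pc_trajectories(matrix, centers, ids)
    keep_ids = set(result.unit_ids)
    units = [u for u in session.units_in(region) if u.unit_id in keep_ids]
    spikes_per_unit = [u.spike_times for u in units]
    onsets = session.protocol.train_onsets
    n_base_bins = int(round((BASELINE_WINDOW[1] - BASELINE_WINDOW[0]) / binsize))
    n_bins = result.timecourses.shape[1]

    rng = np.random.default_rng(seed)
    surr = np.empty((n_surrogates, N_COMPONENTS, n_bins))
    for s in range(n_surrogates):
        shifts = rng.uniform(-shift_range, shift_range, len(units))
        shifted = [
            np.sort(np.mod(sp + d, session.duration))
            for sp, d in zip(spikes_per_unit, shifts)
        ]
        Z = _fast_z_matrix(shifted, onsets, window, binsize, n_base_bins)
        if project_on == "original":
            surr[s] = ((Z.T - result.bin_mean) @ result.loadings).T
        else:
            # per-surrogate PCA, components sign-aligned to the original
            # loadings, so real and surrogate trajectories are both
            # max-variance projections and the envelope is unbiased under
            # the null (a fixed-direction projection understates surrogate
            # variance relative to the data's own first components)
            X = Z.T - Z.T.mean(axis=0)
            u_, sv, vt = np.linalg.svd(X, full_matrices=False)
            scores = u_[:, :N_COMPONENTS] * sv[:N_COMPONENTS]
            signs = np.sign(
                np.einsum("uc,uc->c", vt[:N_COMPONENTS].T, result.loadings)
            )
            signs[signs == 0] = 1.0
            surr[s] = (scores * signs).T

    lo, hi = np.percentile(surr, quantiles, axis=0)
    result.envelope = np.stack([lo, hi], axis=1)
    result.surrogates = surr
    return result


def envelope_coverage(result: TrajectoryResult, component: int = 0) -> float:
    """Fraction of bins where the real trajectory lies inside the envelope."""
    if result.envelope is None:
        raise ValueError("result has no surrogate envelope")
    tc = result.timecourses[component]
    lo, hi = result.envelope[component]
    return float(np.mean((tc >= lo) & (tc <= hi)))


def count_cycles(timecourse: np.ndarray, prominence: float | None = None) -> int:
    """Number of oscillation cycles in a PC timecourse, by peak detection."""
    from scipy.signal import find_peaks
    tc = np.asarray(timecourse, dtype=float)
    if prominence is None:
        prominence = 0.25 * (tc.max() - tc.min())
        if prominence == 0:
            return 0
    sign = 1.0 if abs(tc.max()) >= abs(tc.min()) else -1.0
    peaks, _ = find_peaks(sign * tc, prominence=prominence)
    return int(peaks.size)


def trajectory_speed_amplitude(timecourses: np.ndarray, binsize: float):
    """Average speed and amplitude per component.

    speed = mean |delta value| / binsize over the window (PC-units/s);
    amplitude = max - min (PC-units). Accepts (n_bins,), (n_pc, n_bins) or
    (n_pc, n_trains, n_bins) arrays; speed/amplitude are computed along the
    last axis so per-train distributions pass through unchanged.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.shape[-1] < 2:
        raise ValueError("need at least 2 bins")
    speed = np.abs(np.diff(tc, axis=-1)).mean(axis=-1) / binsize
    amplitude = tc.max(axis=-1) - tc.min(axis=-1)
    return speed, amplitude


def train_projections(
    session: Session,
    region: str,
    result: TrajectoryResult,
    window: tuple = TRAJECTORY_WINDOW,
    binsize: float = TRAJECTORY_BINSIZE,
) -> np.ndarray:
    """Per-train PC projections, shape (3, n_trains, n_bins).

    Single-train population vectors are z-scored with each unit's
    trial-averaged baseline statistics, then projected on the result's
    loadings; feeds per-train speed/amplitude distributions for group tests.
    """
    keep_ids = set(result.unit_ids)
    units = [u for u in session.units_in(region) if u.unit_id in keep_ids]
    onsets = session.protocol.train_onsets
    full_window = (BASELINE_WINDOW[0], window[1])
    n_base = int(round((BASELINE_WINDOW[1] - BASELINE_WINDOW[0]) / binsize))
    per_unit = []
    for u in units:
        counts, edges = compute_psth(u.spike_times, onsets, full_window, binsize)
        rate = counts / binsize
        base = rate.mean(axis=0)[:n_base]
        sd = base.std(ddof=1)
        z = np.zeros_like(rate[:, n_base:]) if sd == 0 else (rate[:, n_base:] - base.mean()) / sd
        per_unit.append(z)
    tensor = np.stack(per_unit)                      # units x trains x bins
    centered = tensor - result.bin_mean[:, None, None]
    return np.einsum("utb,uc->ctb", centered, result.loadings)


__all__ = [
    "TRAJECTORY_WINDOW", "TRAJECTORY_BINSIZE", "SURROGATE_SHIFT_RANGE",
    "TrajectoryResult", "population_matrix", "pc_trajectories",
    "project_matrix", "surrogate_band", "envelope_coverage", "count_cycles",
    "trajectory_speed_amplitude", "train_projections",
]
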