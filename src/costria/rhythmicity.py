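"""Spike-train autocorrelograms, shape classification, and band power.

Each unit's autocorrelogram (ACG) is the histogram of ordered spike-pair
lags within +/-0.5 s (5 ms bins, zero-lag self-pairs excluded), normalized
to rate units (coincidences per spike per second).  ACG shapes are
classified with the same PCA/silhouette engine used for evoked patterns;
rhythmicity is quantified as the fraction of the ACG's spectral power in
conventional frequency bands (delta through low gamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cluster as _cluster

DEFAULT_MAX_LAG = 0.5
DEFAULT_BINSIZE = 0.005

#: conventional band edges in Hz (delta, theta, alpha, beta, low gamma);
#: overridable wherever bands are taken.
DEFAULT_BANDS = ((1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 80.0))


@dataclass
class Autocorrelogram:
    """Symmetric lag histogram of a unit with itself, zero-lag excluded."""

    edges: np.ndarray      # lag bin edges, symmetric about 0 (seconds)
    values: np.ndarray     # normalized counts per bin (rate units)
    unit_id: str = ""

    @property
    def binsize(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def lags(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def autocorrelogram(
    spike_times,
    max_lag: float = DEFAULT_MAX_LAG,
    binsize: float = DEFAULT_BINSIZE,
    unit_id: str = "",
) -> Autocorrelogram:
    """Autocorrelogram of a spike train.

    Counts ordered spike pairs whose lag falls in each half-open bin
    ``[m*binsize, (m+1)*binsize)`` (and the mirror bins for negative lags),
    excluding zero-lag self-pairs, then normalizes by (n_spikes * binsize)
    so values are conditional rates in Hz. Fewer than 2 spikes yield an
    all-zero ACG.
    """
    if not max_lag > binsize > 0:
        raise ValueError("need max_lag > binsize > 0")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    n_bins = int(round(max_lag / binsize))
    edges = binsize * np.arange(-n_bins, n_bins + 1)
    pos = np.zeros(n_bins)
    if spikes.size >= 2:
        hi = np.searchsorted(spikes, spikes + n_bins * binsize, side="left")
        for i in range(spikes.size):
            lags = spikes[i + 1:hi[i]] - spikes[i]
            if lags.size:
                pos += np.bincount(
                    np.floor(lags / binsize).astype(int), minlength=n_bins
                )[:n_bins]
        pos /= spikes.size * binsize
    values = np.concatenate([pos[::-1], pos])
    return Autocorrelogram(edges=edges, values=values, unit_id=unit_id)


def acg_band_fractions(
    acg: Autocorrelogram,
    bands=DEFAULT_BANDS,
    taper: str = "hann",
) -> np.ndarray:
    """Fraction of the ACG's spectral power per frequency band.

    The mean-subtracted ACG trace (Hann-tapered by default) is Fourier
    transformed; each band's power is divided by the total power over the
    union of the analyzed bands, so fractions over disjoint, tiling bands
    sum to 1. Bands must lie below the Nyquist frequency of the ACG binning.
    """
    nyquist = 0.5 / acg.binsize
    for lo, hi in bands:
        if hi > nyquist:
            raise ValueError(f"band ({lo}, {hi}) Hz exceeds Nyquist ({nyquist:.1f} Hz)")
        if hi <= lo:
            raise ValueError("band edges must be increasing")
    lows = np.array([b[0] for b in bands])
    highs = np.array([b[1] for b in bands])
    order = np.argsort(lows)
    if np.any(lows[order][1:] < highs[order][:-1]):
        raise ValueError("bands must be disjoint")

    trace = acg.values - acg.values.mean()
    if taper == "hann":
        trace = trace * np.hanning(trace.size)
    elif taper not in (None, "none", "boxcar"):
        raise ValueError(f"unknown taper {taper!r}")
    spectrum = np.abs(np.fft.rfft(trace)) ** 2
    freqs = np.fft.rfftfreq(trace.size, d=acg.binsize)

    band_power = np.array(
        [spectrum[(freqs >= lo) & (freqs < hi)].sum() for lo, hi in bands]
    )
    total = band_power.sum()
    if total == 0:
        return np.zeros(len(bands))
    return band_power / total


def spontaneous_spikes(spike_times, protocol, evoked_window: float = 1.5) -> np.ndarray:
    """Spikes outside the stimulation-train windows (spontaneous epochs).

    Drops every spike within ``[onset, onset + evoked_window)`` of a train
    onset, so autocorrelograms reflect intrinsic firing structure rather
    than stimulus locking.
    """
    spikes = np.asarray(spike_times, dtype=float)
    onsets = protocol.train_onsets
    if spikes.size == 0 or onsets.size == 0:
        return spikes
    idx = np.searchsorted(onsets, spikes, side="right") - 1
    rel = spikes - onsets[np.clip(idx, 0, None)]
    keep = (idx < 0) | (rel >= evoked_window)
    return spikes[keep]


def acg_matrix(units, max_lag: float = DEFAULT_MAX_LAG,
               binsize: float = DEFAULT_BINSIZE, normalize: bool = True,
               protocol=None):
    """Stack per-unit ACGs into a units x lag-bins feature matrix.

    With ``normalize`` each row is z-scored across lags so the clustering
    sees shape, not firing rate; rows with zero variance (silent or
    single-spike units) are excluded and reported. With ``protocol`` given,
    spikes inside the stimulation-train windows are excluded first, so the
    matrix describes spontaneous firing.
    """
    rows, ids, excluded = [], [], []
    edges = None
    for u in units:
        spikes = u.spike_times
        if protocol is not None:
            spikes = spontaneous_spikes(spikes, protocol)
        acg = autocorrelogram(spikes, max_lag, binsize, unit_id=u.unit_id)
        edges = acg.edges
        v = acg.values
        if normalize:
            sd = v.std()
            if sd == 0:
                excluded.append((u.unit_id, "zero-variance autocorrelogram"))
                continue
            v = (v - v.mean()) / sd
        rows.append(v)
        ids.append(u.unit_id)
    matrix = np.vstack(rows) if rows else np.empty((0, 0))
    return matrix, ids, edges, excluded


def classify_acg_shapes(
    units,
    groups=None,
    animals=None,
    k_range=_cluster.DEFAULT_K_RANGE,
    n_iter: int = _cluster.DEFAULT_N_ITER,
    seed: int = 0,
    protocol=None,
) -> dict:
    """Classify autocorrelogram shapes and compare prevalences by group.

    Delegates to the PCA/silhouette engine on the normalized ACG matrix.
    A population with no real shape structure (best median silhouette below
    the low-separation threshold) is flagged and assigned the lowest
    scanned k rather than an arbitrary argmax.
    """
    units = list(units)
    if len(units) < 10:
        raise ValueError("need at least 10 units to classify ACG shapes")
    matrix, ids, edges, excluded = acg_matrix(units, protocol=protocol)
    scan = _cluster.classify_patterns(
        matrix, k_range=k_range, n_iter=n_iter, seed=seed, feature_tag="acg"
    )
    if scan.low_separation:
        k = min(scan.k_range)
        scan.selected_k = k
        scan.labels = scan.best_labels_per_k[k]
        scan.cluster_means = np.vstack(
            [matrix[scan.labels == c].mean(axis=0) for c in range(1, k + 1)]
        )
    out = {"scan": scan, "unit_ids": ids, "edges": edges, "excluded": excluded}
    if groups is not None:
        keep = {uid: i for i, uid in enumerate(ids)}
        g = np.asarray([groups[i] for i, u in enumerate(units) if u.unit_id in keep])
        a = None
        if animals is not None:
            a = np.asarray([animals[i] for i, u in enumerate(units) if u.unit_id in keep])
        out["prevalence"] = _cluster.prevalence_by_group(scan.labels, g, animals=a)
    return out


__all__ = [
    "DEFAULT_MAX_LAG", "DEFAULT_BINSIZE", "DEFAULT_BANDS",
    "Autocorrelogram", "autocorrelogram", "acg_band_fractions",
    "acg_matrix", "classify_acg_shapes", "spontaneous_spikes",
]
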