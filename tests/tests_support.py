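"""Shared brute-force oracles used by multiple test modules."""

import numpy as np


def brute_force_acg(spikes, max_lag=0.5, binsize=0.005):
    """O(n^2) autocorrelogram reference: ordered pair lags in half-open
    bins, zero-lag self-pairs excluded, normalized to rate units."""
    spikes = np.asarray(spikes, float)
    n_bins = int(round(max_lag / binsize))
    pos = np.zeros(n_bins)
    for i in range(len(spikes)):
        for j in range(len(spikes)):
            if i == j:
                continue
            lag = spikes[j] - spikes[i]
            if 0 < lag < max_lag or (lag == 0 and j > i):
                b = int(lag // binsize)
                if b < n_bins:
                    pos[b] += 1
    pos /= len(spikes) * binsize
    return np.concatenate([pos[::-1], pos])
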