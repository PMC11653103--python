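"""Autocorrelogram shapes and band power of spontaneous firing.

Computes each unit's +/-0.5 s autocorrelogram from the spontaneous
epochs (stimulation windows masked), classifies the shapes with the
PCA/silhouette engine, and reports the relative spectral power per
conventional frequency band. The generator draws four firing styles
(tonic, slow-oscillatory, bursty, refractory), so a correct scan
selects k = 4.
"""

import numpy as np

import costria
from costria import rhythmicity

session = costria.simulate_session(costria.default_config("DLSt", n_units=150, seed=5))
res = rhythmicity.classify_acg_shapes(
    session.units, n_iter=200, seed=5, protocol=session.protocol
)
scan = res["scan"]
print(f"selected k = {scan.selected_k} (4 generative firing styles)")
sizes = np.bincount(scan.labels)[1:]
print("cluster sizes:", dict(enumerate(sizes, start=1)))

bands = rhythmicity.DEFAULT_BANDS
fractions = []
for u in session.units[:100]:
    spikes = rhythmicity.spontaneous_spikes(u.spike_times, session.protocol)
    acg = rhythmicity.autocorrelogram(spikes)
    fractions.append(rhythmicity.acg_band_fractions(acg, bands))
mean_fr = np.mean(fractions, axis=0)
for (lo, hi), f in zip(bands, mean_fr):
    print(f"  {lo:>4.0f}-{hi:<3.0f} Hz: {100 * f:5.1f}% of autocorrelogram power")
print("fractions sum to", round(float(mean_fr.sum()), 6),
      "— delta power reflects the slow shapes (pauses, 2.5 Hz modulation),"
      " low-gamma power the sharp burst peaks")
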