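# Methods

`costria` analyzes somatosensory-evoked spiking in the primary
somatosensory cortex (S1) and dorsolateral striatum (DLSt) under a
stimulation protocol of 50 trains of five 5 ms pulses at 3.3 Hz, one train
every 5 s. This note documents the models, parameters, and numerical
choices; every empirical number quoted here is computed by the test suite
or by `scripts/acceptance.py`.

## Evoked-response quantification

Spike counts are aligned to each train onset in a window of [-0.3, 1.5) s
(10 ms bins; 5 ms bins for latency estimation). All bins and windows are
half-open, times are seconds, indices 0-based. Each unit's trial-averaged
rate trace is z-scored against its own baseline: the mean and SD are taken
across the bins of the [-0.3, 0) s pre-train epoch, the only
stimulus-free span at 5 s train spacing. Units whose baseline SD is zero
(silent or perfectly constant) cannot be z-scored and are excluded with a
recorded reason, never silently zeroed.

Derived per-unit metrics:

- **Latency** — left edge of the first 5 ms bin with z > 2 for at least 2
  consecutive bins, searched within 50 ms of the first pulse; undefined
  when never crossed. The threshold/persistence rule is a package choice;
  only the 50 ms comparison window is externally constrained.
- **Per-pulse amplitudes** — mean z over the short-latency window
  [t, t+80 ms) and the long-latency ("rebound") window of 200 ms starting
  80 ms after each pulse onset t, five values per window type.
- **Adaptation slope** — ordinary least-squares slope of the five
  long-latency amplitudes against pulse index 1..5 (z-units per stimulus).
  Facilitating: slope > 0; depressing: slope < 0; an exact 0 is reported
  as its own `flat` class rather than folded into either side (ties are
  measure-zero but must be deterministic).

Group comparisons of amplitudes use Kruskal–Wallis / Mann–Whitney rank
tests with Bonferroni adjustment; groups with fewer than 3 units are
flagged and skipped.

## Pattern classification (PCA + repeated k-means + silhouette)

One engine serves three feature spaces: z-scored evoked patterns,
normalized autocorrelogram shapes, and mean spike waveforms. Features are
centered and reduced to their first three principal components. For each
candidate cluster count k = 3..8, k-means (random-point initialization,
Euclidean metric in the 3-PC space, at most 100 Lloyd iterations, per-run
RNG derived from (seed, k, iteration)) is run many times — 1,000 by
default, 200 in the tests and acceptance script, which leaves the
selection distribution essentially unchanged. Each run is scored by its
mean silhouette, computed in the same 3-PC space from a precomputed
distance matrix (cross-checked against scikit-learn on fixtures);
singleton clusters score 0, a run that leaves a cluster empty scores -1
and is not resampled.

**Selection statistic.** The selected k maximizes the 75th percentile of
the per-run mean silhouettes (ties to the smaller k); labels come from the
best single run of the selected k, relabeled 1..k in order of first
appearance. The upper quartile, rather than the median, is used because
random-point initialization frequently fails to seed every true cluster —
especially with unequal cluster sizes such as the ~30% non-responsive
striatal class — so the median scores the correct k largely by its failed
runs and drifts toward k+1; the upper quartile scores each k by its
well-converged runs. With the median the striatal 6-class recovery
succeeded in only 12/20 seeds; with the upper quartile all four spaces
(S1 evoked 4, DLSt evoked 6, waveform 3, autocorrelogram 4) recover their
generative count in 20/20 seeds.

A scan whose best upper-quartile silhouette stays below 0.4 indicates no
real shape structure (pure-noise 3-PC embeddings score ~0.25–0.30 at any
k); `classify_acg_shapes` then flags the result and reports the lowest
scanned k instead of an arbitrary argmax.

Prevalence comparisons: with per-unit animal ids, per-animal cluster
percentages are compared by Kruskal–Wallis across the group x cluster
cells (pooled factor coding); without animal ids a chi-square test of
independence on the contingency table is used.

## Rhythmicity

Autocorrelograms (ACGs) count ordered spike-pair lags in half-open 5 ms
bins over ±0.5 s, excluding zero-lag self-pairs, normalized by
(n_spikes x binsize) to conditional rate units. The streaming
implementation is oracle-equivalent to the O(n²) double loop. ACG
classification operates on **spontaneous epochs** — spikes inside the
[onset, onset+1.5 s) stimulation windows are masked first — because
stimulus-locked firing otherwise imprints the 0.303 s train periodicity
on the ACG and splits the tonic class by evoked archetype. Rows are
z-normalized across lags so clustering sees shape, not rate; zero-variance
rows are excluded and reported.

Band power: the mean-subtracted, Hann-tapered ACG trace is Fourier
transformed; each band's power is divided by the total over the analyzed
bands. Default bands are the conventional 1–4, 4–8, 8–13, 13–30, 30–80 Hz
(no external constraint fixes the edges; they are config-overridable).
Parseval consistency (total spectral power = trace variance) is tested on
the untapered path.

## Population trajectories and the surrogate null

The population matrix stacks trial-averaged z patterns over [0, 1.5) s
(10 ms bins); the peak-time sort order used for display is returned
separately and never silently reorders the analysis matrix. PCA is taken
across time bins (bins as observations, units as variables); the first
three score timecourses are the population trajectories. Speed is the
mean |Δvalue|/binsize and amplitude the max–min of a timecourse; both can
be evaluated per train via single-train projections for group testing.

The null for stimulus locking shifts every unit's whole spike train
rigidly by an independent uniform draw in ±5 s with circular wrap (a
bijection, so spike counts are conserved exactly; the rigid shift
preserves each unit's ISI structure and is the conservative null; a
per-spike independent shift is not offered because it destroys ISI
structure along with locking). Each of the 1,000 surrogates is
re-binned, re-z-scored, and decomposed by its own PCA with component
signs aligned to the real data's loadings; the envelope is the pointwise
[2.5, 97.5] percentile. Per-surrogate PCA (rather than projection on the
real loadings) is required for a calibrated band: the real trajectory is
by construction a max-variance projection, and projecting surrogates onto
a fixed direction understates their variance, so under a
no-stimulus-locking generator the real PC1 would sit outside a
fixed-projection band at ~70% of bins. With matched projections the null
coverage is ~93–95%, and responsive populations still exit the band
within 80 ms of every pulse. Fixed-loading projection remains available
(`project_on="original"`).

## Histology and behavior statistics

Densities are exact count/area (cells/mm²) per animal x slice (four
rostrocaudal slices, ~+1.80 to −0.12 mm from bregma) x region
(DLSt/DMSt/VSt) x marker (ChAT/PV). Group summaries are mean ± SEM over
animals (per-animal region density = total count / total area across
slices), compared by two-sided equal-variance unpaired t tests (Welch
behind a flag); identical constant groups are reported as t = 0, p = 1
rather than NaN. Percent decrease is 100 x (reference − treated) /
reference — reference-anchored, not antisymmetric. Rostrocaudal gradients
are OLS slopes of density against slice index.

`t_from_summary` rebuilds the unpaired t from printed mean/SEM/n:
t = Δmean / √(sem₁² + sem₂²), df = n₁ + n₂ − 2; it is exactly the
equal-variance t for any raw samples with those summaries. The two-sample
"Wilcoxon" convention is read as the Mann–Whitney rank-sum test.
Shapiro–Wilk is provided as a pre-check utility but never auto-switches
test families. Spearman correlations (midrank-based, t approximation)
serve the cross-structure (S1 vs DLSt evoked components, paired by
animal) and subpopulation-vs-behavior grids; undefined cells (constant
vectors, empty components) are flagged, not fabricated.

## Synthetic-data generator

The generator defines the study conditions for every test; its defaults
are the package's operating point and are not tuned per run.

**Spike trains.** Each unit draws a base train from its autocorrelogram
class — Poisson (`tonic`), dead-time Poisson with a 50 ms refractory
period (`refractory`), Poisson bursts of ~4 spikes at 6 ms intervals
(`bursty`), or a sinusoidally rate-modulated Poisson (`oscillatory`,
fixed 2.5 Hz, random per-unit phase) — then applies the archetype gain by
thinning where gain < 1 and superposing Poisson spikes at rate
baseline x (gain − 1) where gain > 1. For the Poisson base this is
exactly an inhomogeneous Poisson process with rate
baseline x gain(t − preceding train onset). The 2.5 Hz oscillation flips
phase between successive 5 s trains, so trial averaging cancels it and
units remain mutually incoherent — a coherent population oscillation
would be stimulus-independent shared structure that the spike-shift null
(correctly) removes, and it is not a feature these analyses target.

**Archetypes.** Multiplicative gain kernels are piecewise-constant per
pulse with per-pulse scale factors s1..s5 acting on the excursion
(gain − 1): S1 has sustained (gain 1.8 over 8–300 ms), pause (0.04 over
15–260 ms), triphasic (2.2 onset / 0.08 pause / 1.9 rebound), and sharp
(4.5 over 5–28 ms with a brief 0.45 after-pause) classes; DLSt adds a
facilitating sharp class (s1..s5 = 0.45..1.75) and a flat (gain ≡ 1)
non-responsive class at 30% weight. Kernel magnitudes are free
calibration parameters; they are set so that (i) the four spaces'
generative class counts are recovered by the default scan, (ii) PC1
carries ~25% of S1 population variance with one cycle per pulse, and
(iii) facilitating units' growth-rate median is ~0.11 z-units per
stimulus with quartiles near 0.03/0.23. Pairwise gain-curve correlations
stay below 0.8.

**Rates.** Baseline rates are log-normal (median 5 Hz, log-SD 0.25). The
evoked z amplitude of a fixed gain scales as (gain − 1)√rate, which would
smear each class into an elongated cone along its own direction, so by
default the generator divides each unit's gain excursion by
√(rate/median) (`rate_compensated`), making class amplitude homogeneous;
this is a statement about what defines a response class (its z-pattern),
not about biophysics.

**Group contrasts.** The VPA-like group gets +20% median baseline rate, a
twice-deeper evoked pause, and mixture weight shifted toward the pause
(S1) or facilitating (DLSt) class — directional contrasts only, with
magnitudes as calibration knobs. Waveform mixtures put 55.5 / 61.5 /
52.9% of units on the wide (putative medium-spiny-neuron) template for
the control / VPA-like / PV-depleted groups. Histology tables draw
per-animal densities from Normal(mean, noise_sd) left-censored at 0
(counts are fractional so the zero-noise table sits exactly on the
configured means); behavior tables draw per-animal values from
Normal(mean, SEM·√n). The published group summaries (density tables,
behavior means ± SEM with n = 18 per group — the social-interaction n,
also assumed for the open-field/hole-board cohorts whose n is not
printed) ship in `costria.reference` as generator inputs.

**Determinism.** Every unit has its own RNG stream derived from
(session seed, unit index), so unit k is bit-identical under population
resizing; identical config + seed reproduces sessions, histology, and
behavior tables exactly.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: baseline-rate
offsets, train-locked response archetypes with facilitation/depression,
waveform and ACG class mixtures, group-level density and behavior
summaries. It does not emulate biophysical membrane dynamics, spike
waveform voltage beyond template + Gaussian noise, local field
potentials, electrode drift, sorting errors, correlated noise across
units, or non-stationary anesthesia states. Passing recovery tests
therefore shows the pipeline is correct and calibrated under these
idealized conditions, not that real recordings will be classified with
the same accuracy.

## Problem sizes

Tests and the acceptance script run 200 scan iterations per k (the
engine's default remains 1,000), 250-unit sessions (150 for ACG scans),
20 seeds for recovery rates, and 1,000 surrogates at 200 units for the
null-coverage check; these sizes hold the full suite to a few minutes
while leaving the selection statistics stable.

## Known limitations

- Neurons are pooled across animals in rank tests, following the source
  convention; no mixed-effects modeling of the nested animal/neuron
  structure.
- The silhouette selection quantile (75th) is a bias correction for
  random-point initialization; with k-means++-style seeding the median
  would likely suffice, but that initialization is deliberately not used.
- The exact factor coding behind some published Kruskal–Wallis degrees of
  freedom is ambiguous; the grouping is therefore always explicit in the
  API rather than inferred.
- Latency estimates at 5 ms resolution are floor-biased by up to one bin.
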