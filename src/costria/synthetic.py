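"""Synthetic corticostriatal sessions, histology tables, and behavior tables.

The generator emulates the statistical structure the downstream analyses
assume: units fire with log-normal baseline rates (slightly elevated in the
VPA-like group), respond to 5-pulse 3.3 Hz stimulation trains according to a
small library of multiplicative rate-gain archetypes (4 cortical shapes; 6
striatal shapes including a non-responsive class), carry one of three mean
spike-waveform templates and one of four autocorrelogram firing styles, and
every unit records its generative labels so parameter-recovery tests can
score the classification pipeline.

Spike trains are built from a base train per autocorrelogram class (Poisson,
dead-time/refractory, bursty, or slow-oscillatory), thinned where the archetype
gain dips below 1 and superposed with Poisson spikes at rate
``baseline * (gain - 1)`` where it exceeds 1.  For the Poisson base this is
exactly an inhomogeneous Poisson process with rate
``baseline * gain(t - nearest preceding train onset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .session import (
    GROUPS,
    REFERENCE_TRAIN_PERIOD,
    Session,
    StimulusProtocol,
    UnitRecording,
)

ACG_CLASSES = ("tonic", "oscillatory", "bursty", "refractory")
WAVEFORM_CLASSES = ("msn", "other", "fsi")

TRAIN_WINDOW = 1.5  # seconds of evoked response modelled after a train onset


# ---------------------------------------------------------------------------
# archetype kernels

@dataclass(frozen=True)
class ResponseSegment:
    """One gain segment relative to a pulse onset: gain over [start, end)."""

    start: float
    end: float
    gain: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")


@dataclass(frozen=True)
class ArchetypeKernel:
    """Multiplicative rate-gain profile over the 1.5 s train window.

    ``segments`` describe the response to a single pulse; ``pulse_scales``
    (s1..s5, strictly positive) scale the *deviation from 1* of each pulse's
    segments, implementing facilitation (increasing) or depression
    (decreasing) across the train.  Gain is 1 outside all segments and is
    clipped at 0 from below.
    """

    name: str
    segments: tuple = ()
    pulse_scales: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.pulse_scales):
            raise ValueError("pulse scales must be strictly positive")

    def gain(self, t, pulse_offsets) -> np.ndarray:
        """Gain at times ``t`` (seconds relative to the train onset)."""
        t = np.asarray(t, dtype=float)
        g = np.ones_like(t)
        for p, offset in enumerate(pulse_offsets):
            s = self.pulse_scales[min(p, len(self.pulse_scales) - 1)]
            for seg in self.segments:
                mask = (t >= offset + seg.start) & (t < offset + seg.end)
                g[mask] = max(0.0, 1.0 + s * (seg.gain - 1.0))
        return g

    @property
    def max_gain(self) -> float:
        best = 1.0
        for s in self.pulse_scales:
            for seg in self.segments:
                best = max(best, 1.0 + s * (seg.gain - 1.0))
        return best

    def sampled(self, pulse_offsets, resolution: float = 0.001) -> np.ndarray:
        """Gain curve sampled over [0, 1.5) at ``resolution`` seconds."""
        t = np.arange(0.0, TRAIN_WINDOW, resolution)
        return self.gain(t, pulse_offsets)


def _s1_kernels() -> list[ArchetypeKernel]:
    return [
        ArchetypeKernel(
            "sustained",
            (ResponseSegment(0.008, 0.300, 1.8),),
            (0.80, 0.90, 1.0, 1.10, 1.20),
        ),
        ArchetypeKernel(
            "pause",
            (ResponseSegment(0.015, 0.260, 0.04),),
            (0.75, 0.9, 1.0, 1.1, 1.25),
        ),
        ArchetypeKernel(
            "triphasic",
            (
                ResponseSegment(0.006, 0.030, 2.2),
                ResponseSegment(0.030, 0.100, 0.08),
                ResponseSegment(0.100, 0.300, 1.9),
            ),
            (0.78, 0.89, 1.0, 1.11, 1.22),
        ),
        ArchetypeKernel(
            "sharp",
            (
                ResponseSegment(0.005, 0.028, 4.5),
                ResponseSegment(0.028, 0.075, 0.45),
            ),
            (1.30, 1.15, 1.0, 0.85, 0.70),
        ),
    ]


def _dlst_kernels() -> list[ArchetypeKernel]:
    return [
        ArchetypeKernel(
            "triphasic",
            (
                ResponseSegment(0.008, 0.035, 4.2),
                ResponseSegment(0.035, 0.115, 0.12),
                ResponseSegment(0.115, 0.280, 1.9),
            ),
            (0.85, 0.92, 1.0, 1.08, 1.15),
        ),
        ArchetypeKernel(
            "sharp",
            (
                ResponseSegment(0.006, 0.030, 7.5),
                ResponseSegment(0.030, 0.080, 0.40),
            ),
            (1.35, 1.17, 1.0, 0.82, 0.65),
        ),
        ArchetypeKernel(
            "pause",
            (ResponseSegment(0.018, 0.260, 0.04),),
            (0.8, 0.9, 1.0, 1.1, 1.2),
        ),
        ArchetypeKernel(
            "facilitating",
            (ResponseSegment(0.010, 0.075, 3.2),),
            (0.45, 0.75, 1.05, 1.40, 1.75),
        ),
        ArchetypeKernel(
            "sustained",
            (ResponseSegment(0.010, 0.300, 2.2),),
            (0.9, 0.95, 1.0, 1.05, 1.1),
        ),
        ArchetypeKernel("flat"),
    ]


def build_archetype_library(region_tag: str) -> list[ArchetypeKernel]:
    """Default archetype kernels: 4 cortical shapes for S1, 6 striatal for
    DLSt (one of which, ``flat``, is the non-responsive class, gain == 1)."""
    if region_tag == "S1":
        return _s1_kernels()
    if region_tag == "DLSt":
        return _dlst_kernels()
    raise ValueError(f"unknown region tag {region_tag!r}; valid tags: ('S1', 'DLSt')")


# ---------------------------------------------------------------------------
# waveform templates

WAVEFORM_N_SAMPLES = 40
WAVEFORM_SAMPLING_RATE = 25_000.0


def waveform_template(cls: str) -> np.ndarray:
    """Mean spike waveform templates: wide (putative MSN), intermediate
    (other), narrow (putative fast-spiking interneuron). Amplitude is
    normalized to a trough of -1."""
    t = np.arange(WAVEFORM_N_SAMPLES) / WAVEFORM_SAMPLING_RATE * 1e3  # ms
    trough = 0.4
    params = {
        "msn": (0.18, 0.45, 0.50, 0.45),   # trough w, after-wave delay, w, amp
        "other": (0.13, 0.32, 0.30, 0.35),
        "fsi": (0.07, 0.20, 0.16, 0.50),
    }
    try:
        tw, delay, pw, pa = params[cls]
    except KeyError:
        raise ValueError(f"unknown waveform class {cls!r}; valid: {WAVEFORM_CLASSES}")
    w = -np.exp(-0.5 * ((t - trough) / tw) ** 2)
    w += pa * np.exp(-0.5 * ((t - trough - delay) / pw) ** 2)
    return w / abs(w.min())


# ---------------------------------------------------------------------------
# spike-train generation

def _base_train(rate: float, duration: float, rng, acg_class: str) -> np.ndarray:
    """Baseline spike train with the ISI structure of an ACG class."""
    if rate == 0:
        return np.empty(0)
    if acg_class == "tonic":
        n = rng.poisson(rate * duration)
        return np.sort(rng.uniform(0.0, duration, n))
    if acg_class == "refractory":
        # dead-time Poisson: fixed-position central ACG trough, mean rate kept
        dead = min(0.05, 0.5 / rate)
        lam = 1.0 / (1.0 / rate - dead)
        n = int(rate * duration * 1.5) + 20
        isi = dead + rng.exponential(1.0 / lam, n)
        t = np.cumsum(isi)
        return t[t < duration]
    if acg_class == "bursty":
        spikes_per_burst = 4.0
        onset_rate = rate / spikes_per_burst
        n_bursts = rng.poisson(onset_rate * duration)
        onsets = rng.uniform(0.0, duration, n_bursts)
        counts = 1 + rng.poisson(spikes_per_burst - 1.0, n_bursts)
        offsets = np.concatenate(
            [np.arange(c) * 0.006 + rng.normal(0, 5e-4, c) for c in counts]
        ) if n_bursts else np.empty(0)
        t = np.repeat(onsets, counts) + np.abs(offsets)
        return np.sort(t[t < duration])
    if acg_class == "oscillatory":
        # random per-unit phase: units are mutually incoherent, and the
        # 2.5 Hz rhythm flips phase between successive 5 s trains so the
        # trial-averaged evoked pattern is free of spurious oscillation
        freq = 2.5
        phase = rng.uniform(0.0, 2 * np.pi)
        depth = 0.8
        peak = rate * (1 + depth)
        n = rng.poisson(peak * duration)
        cand = np.sort(rng.uniform(0.0, duration, n))
        keep = rng.uniform(size=n) < (
            1 + depth * np.sin(2 * np.pi * freq * cand + phase)
        ) / (1 + depth)
        return cand[keep]
    raise ValueError(f"unknown ACG class {acg_class!r}; valid: {ACG_CLASSES}")


def _gain_at(kernel: ArchetypeKernel, times: np.ndarray, protocol: StimulusProtocol) -> np.ndarray:
    """Archetype gain at absolute times, relative to the nearest preceding
    train onset (gain 1 before the first train or past the train window)."""
    onsets = protocol.train_onsets
    g = np.ones_like(times)
    if onsets.size == 0 or not kernel.segments:
        return g
    idx = np.searchsorted(onsets, times, side="right") - 1
    valid = idx >= 0
    rel = np.where(valid, times - onsets[np.clip(idx, 0, None)], np.inf)
    inside = valid & (rel < TRAIN_WINDOW)
    if np.any(inside):
        g[inside] = kernel.gain(rel[inside], protocol.pulse_offsets)
    return g


def _evoked_extra_spikes(
    kernel: ArchetypeKernel, rate: float, protocol: StimulusProtocol, rng
) -> np.ndarray:
    """Poisson spikes at rate ``rate * (gain - 1)`` wherever gain > 1."""
    extra = []
    offsets = protocol.pulse_offsets
    for onset in protocol.train_onsets:
        for p, off in enumerate(offsets):
            s = kernel.pulse_scales[min(p, len(kernel.pulse_scales) - 1)]
            for seg in kernel.segments:
                g = max(0.0, 1.0 + s * (seg.gain - 1.0))
                if g <= 1.0:
                    continue
                lam = rate * (g - 1.0) * (seg.end - seg.start)
                n = rng.poisson(lam)
                if n:
                    extra.append(onset + off + rng.uniform(seg.start, seg.end, n))
    return np.concatenate(extra) if extra else np.empty(0)


def simulate_spike_train(
    kernel: ArchetypeKernel,
    baseline_rate: float,
    protocol: StimulusProtocol,
    duration: float,
    rng,
    acg_class: str = "tonic",
) -> np.ndarray:
    """Stimulus-modulated spike train (seconds, sorted ascending)."""
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    base = _base_train(baseline_rate, duration, rng, acg_class)
    if base.size:
        g = _gain_at(kernel, base, protocol)
        keep = rng.uniform(size=base.size) < np.minimum(g, 1.0)
        base = base[keep]
    extra = _evoked_extra_spikes(kernel, baseline_rate, protocol, rng)
    extra = extra[(extra >= 0) & (extra < duration)]
    return np.sort(np.concatenate([base, extra]))


def simulate_unit(
    kernel: ArchetypeKernel,
    baseline_rate: float,
    protocol: StimulusProtocol,
    duration: float,
    seed: int,
    acg_class: str = "tonic",
    waveform_class: str = "msn",
    unit_id: str = "u0",
    region: str = "S1",
    group: str = "control",
    animal_id: str = "a0",
    depth: float = 1.0,
    waveform_noise_sd: float = 0.05,
) -> UnitRecording:
    """Simulate a single unit; the same seed reproduces it bit-identically."""
    rng = np.random.default_rng(seed)
    spikes = simulate_spike_train(kernel, baseline_rate, protocol, duration, rng, acg_class)
    wf = waveform_template(waveform_class) + rng.normal(0, waveform_noise_sd, WAVEFORM_N_SAMPLES)
    return UnitRecording(
        unit_id=unit_id, region=region, group=group, animal_id=animal_id,
        depth=depth, spike_times=spikes, waveform=wf,
        truth_labels={
            "archetype": kernel.name, "waveform": waveform_class, "acg": acg_class,
        },
    )


# ---------------------------------------------------------------------------
# population config + session generation

#: default archetype mixture weights per region; the striatal ``flat``
#: weight of 0.30 encodes the reported share of non-responsive units.
DEFAULT_ARCHETYPE_WEIGHTS = {
    "S1": {"sustained": 0.28, "pause": 0.20, "triphasic": 0.28, "sharp": 0.24},
    "DLSt": {
        "triphasic": 0.16, "sharp": 0.15, "pause": 0.13,
        "facilitating": 0.13, "sustained": 0.13, "flat": 0.30,
    },
}

#: waveform-class mixture: wide/putative-MSN share per group follows the
#: reported 55.5 / 61.5 / 52.9 %.
DEFAULT_WAVEFORM_WEIGHTS = {
    "control": {"msn": 0.555, "other": 0.270, "fsi": 0.175},
    "VPA": {"msn": 0.615, "other": 0.240, "fsi": 0.145},
    "PV-depleted": {"msn": 0.529, "other": 0.366, "fsi": 0.105},
}

DEFAULT_ACG_WEIGHTS = {"tonic": 0.40, "oscillatory": 0.22, "bursty": 0.20, "refractory": 0.18}


@dataclass(frozen=True)
class PopulationConfig:
    """Study conditions for one synthetic population.

    Baseline rates are log-normal; the VPA-like group gets a +20% median
    shift and a mildly deeper stimulus-evoked pause, the directional
    contrasts the analyses are meant to detect.
    """

    region: str = "S1"
    group: str = "control"
    n_units: int = 250
    seed: int = 0
    baseline_log_mean: float = float(np.log(5.0))
    baseline_log_sd: float = 0.25
    archetype_weights: dict = field(default_factory=dict)
    waveform_weights: dict = field(default_factory=dict)
    acg_weights: dict = field(default_factory=dict)
    waveform_noise_sd: float = 0.05
    pause_gain_scale: float = 1.0   # < 1 deepens all sub-unity gain segments
    response_strength: float = 1.0  # global scale of every (gain - 1) excursion
    rate_compensated: bool = True   # scale gains so z amplitude is rate-free
    response_gain_sd: float = 0.0   # per-unit log-normal jitter of (gain - 1)
    response_latency_jitter: float = 0.0  # per-unit segment time shift SD (s)
    n_trains: int = 50
    train_period: float = REFERENCE_TRAIN_PERIOD
    animal_id: str = "synthetic-1"

    def resolved(self) -> "PopulationConfig":
        """Fill empty mixtures with the region/group defaults."""
        arch = dict(self.archetype_weights) or dict(DEFAULT_ARCHETYPE_WEIGHTS[self.region])
        wf = dict(self.waveform_weights) or dict(
            DEFAULT_WAVEFORM_WEIGHTS.get(self.group, DEFAULT_WAVEFORM_WEIGHTS["control"])
        )
        acg = dict(self.acg_weights) or dict(DEFAULT_ACG_WEIGHTS)
        return replace(
            self, archetype_weights=arch, waveform_weights=wf, acg_weights=acg
        )


def _jitter_kernel(kernel: ArchetypeKernel, rng, gain_sd: float,
                   latency_sd: float) -> ArchetypeKernel:
    """Per-unit idiosyncratic kernel: every segment's excursion from gain 1
    is scaled by an independent log-normal factor and the whole response is
    shifted by a small latency offset, emulating unit-to-unit response
    variability around each archetype."""
    if not kernel.segments or (gain_sd == 0 and latency_sd == 0):
        return kernel
    dt = abs(rng.normal(0.0, latency_sd)) if latency_sd else 0.0
    segs = []
    for s in kernel.segments:
        factor = rng.lognormal(0.0, gain_sd) if gain_sd else 1.0
        gain = max(0.0, 1.0 + factor * (s.gain - 1.0))
        segs.append(ResponseSegment(s.start + dt, s.end + dt, gain))
    return replace(kernel, segments=tuple(segs))


def _scale_strength(kernel: ArchetypeKernel, c: float) -> ArchetypeKernel:
    if c == 1.0 or not kernel.segments:
        return kernel
    segs = tuple(
        ResponseSegment(s.start, s.end, max(0.0, 1.0 + c * (s.gain - 1.0)))
        for s in kernel.segments
    )
    return replace(kernel, segments=segs)


def _scale_pauses(kernel: ArchetypeKernel, scale: float) -> ArchetypeKernel:
    if scale == 1.0 or not kernel.segments:
        return kernel
    segs = tuple(
        ResponseSegment(s.start, s.end, s.gain * scale if s.gain < 1 else s.gain)
        for s in kernel.segments
    )
    return replace(kernel, segments=segs)


def _shift_weight(weights: dict, source: str, target: str, frac: float) -> dict:
    out = dict(weights)
    moved = out[source] * frac
    out[source] -= moved
    out[target] += moved
    return out


def default_config(region: str, group: str = "control", n_units: int = 250,
                   seed: int = 0, **overrides) -> PopulationConfig:
    """Study-condition defaults per region and group.

    The VPA-like group gets the directional contrasts the analyses target:
    +20% median baseline rate, a twice-deeper evoked pause, and a shift of
    mixture weight toward the pause class (S1) or the facilitating sharp
    class (DLSt).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; valid: {GROUPS}")
    build_archetype_library(region)  # validates the region tag
    log_mean = float(np.log(5.0))
    extra = {}
    if group == "VPA":
        log_mean += float(np.log(1.2))  # slightly higher baseline rates
        extra["pause_gain_scale"] = 0.5
        arch = dict(DEFAULT_ARCHETYPE_WEIGHTS[region])
        if region == "S1":
            arch = _shift_weight(arch, "sustained", "pause", 0.30)
            arch = _shift_weight(arch, "sharp", "pause", 0.20)
        else:
            arch = _shift_weight(arch, "triphasic", "facilitating", 0.35)
        extra["archetype_weights"] = arch
    extra.setdefault("baseline_log_mean", log_mean)
    extra.update(overrides)
    cfg = PopulationConfig(
        region=region, group=group, n_units=n_units, seed=seed, **extra,
    )
    return cfg.resolved()


def load_config(path) -> PopulationConfig:
    """Read a PopulationConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PopulationConfig(**raw).resolved()


def _check_weights(weights: dict, names, what: str) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"{what} mixture weights sum to {total}, not 1")
    unknown = set(weights) - set(names)
    if unknown:
        raise ValueError(f"unknown {what} classes: {sorted(unknown)}")
    if any(w < 0 for w in weights.values()):
        raise ValueError(f"{what} mixture weights must be nonnegative")


def reference_protocol(n_trains: int = 50, first_onset: float = 2.5,
                       train_period: float = REFERENCE_TRAIN_PERIOD) -> StimulusProtocol:
    """50 trains of five pulses at 3.3 Hz, one train every 5 s."""
    return StimulusProtocol(train_onsets=first_onset + train_period * np.arange(n_trains))


def simulate_session(config: PopulationConfig) -> Session:
    """Generate a full synthetic session; identical config + seed yields a
    bit-identical session. Each unit draws from its own RNG stream derived
    from (session seed, unit index), so unit k is stable under resizing."""
    config = config.resolved()
    if config.n_units <= 0:
        raise ValueError("n_units must be positive")
    _check_weights(config.archetype_weights, [k.name for k in
                   build_archetype_library(config.region)], "archetype")
    _check_weights(config.waveform_weights, WAVEFORM_CLASSES, "waveform")
    _check_weights(config.acg_weights, ACG_CLASSES, "autocorrelogram")

    kernels = {
        k.name: _scale_pauses(_scale_strength(k, config.response_strength),
                              config.pause_gain_scale)
        for k in build_archetype_library(config.region)
    }
    protocol = reference_protocol(config.n_trains, train_period=config.train_period)
    duration = float(protocol.train_onsets[-1] + config.train_period)

    arch_names = sorted(config.archetype_weights)
    arch_p = np.array([config.archetype_weights[n] for n in arch_names])
    wf_names = sorted(config.waveform_weights)
    wf_p = np.array([config.waveform_weights[n] for n in wf_names])
    acg_names = sorted(config.acg_weights)
    acg_p = np.array([config.acg_weights[n] for n in acg_names])

    units = []
    for i in range(config.n_units):
        rng = np.random.default_rng([config.seed, i])
        arch = arch_names[rng.choice(len(arch_names), p=arch_p)]
        wf_cls = wf_names[rng.choice(len(wf_names), p=wf_p)]
        acg_cls = acg_names[rng.choice(len(acg_names), p=acg_p)]
        rate = float(rng.lognormal(config.baseline_log_mean, config.baseline_log_sd))
        depth = float(rng.uniform(0.9, 1.5) if config.region == "S1" else rng.uniform(3.0, 5.0))
        kernel = _jitter_kernel(
            kernels[arch], rng, config.response_gain_sd, config.response_latency_jitter
        )
        if config.rate_compensated:
            # evoked z amplitude scales as (gain - 1) * sqrt(rate); dividing
            # the excursion by sqrt(rate / median rate) keeps a class's z
            # amplitude homogeneous across its rate distribution
            kernel = _scale_strength(
                kernel, float(np.sqrt(np.exp(config.baseline_log_mean) / rate))
            )
        spikes = simulate_spike_train(kernel, rate, protocol, duration, rng, acg_cls)
        wf = waveform_template(wf_cls) + rng.normal(0, config.waveform_noise_sd, WAVEFORM_N_SAMPLES)
        units.append(
            UnitRecording(
                unit_id=f"u{i:04d}", region=config.region, group=config.group,
                animal_id=config.animal_id, depth=depth, spike_times=spikes,
                waveform=wf,
                truth_labels={"archetype": arch, "waveform": wf_cls, "acg": acg_cls,
                              "baseline_rate": rate},
            )
        )
    return Session(
        units=units, protocol=protocol, duration=duration,
        waveform_sampling_rate=WAVEFORM_SAMPLING_RATE,
        manifest={"group": config.group, "region": config.region,
                  "seed": config.seed, "generator": "costria.synthetic"},
    )


# ---------------------------------------------------------------------------
# histology and behavior tables

DEFAULT_REGION_AREAS = {"DLSt": 4.0, "DMSt": 3.5, "VSt": 4.5}  # mm^2 per slice


def simulate_histology(
    means: pd.DataFrame,
    noise_sd: float,
    n_animals: int,
    seed: int,
    areas: dict | None = None,
    n_slices: int = 4,
) -> pd.DataFrame:
    """Per-animal, per-slice region count table drawn around target densities.

    ``means`` columns: group, region, marker, density (cells/mm^2), and
    optionally slice (else the density applies to all ``n_slices`` slices).
    Each animal's density is Normal(mean, noise_sd) left-censored at 0;
    counts are density x area and therefore fractional, which keeps the
    zero-noise table exactly on the configured means.
    """
    if n_animals < 2:
        raise ValueError("need n_animals >= 2 (group statistics undefined otherwise)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if (means["density"] < 0).any():
        raise ValueError("mean densities must be nonnegative")
    areas = dict(DEFAULT_REGION_AREAS, **(areas or {}))
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in means.sort_values(list(means.columns)).iterrows():
        slices = [int(r["slice"])] if "slice" in means.columns else list(range(1, n_slices + 1))
        for sl in slices:
            for a in range(n_animals):
                dens = max(0.0, r["density"] + (rng.normal(0, noise_sd) if noise_sd else 0.0))
                area = areas[r["region"]]
                rows.append(
                    {
                        "animal_id": f"{r['group']}-{a + 1}",
                        "group": r["group"],
                        "slice": sl,
                        "region": r["region"],
                        "marker": r["marker"],
                        "area_mm2": area,
                        "count": dens * area,
                    }
                )
    return pd.DataFrame(rows)


def simulate_behavior(config: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Per-animal behavior draws matching configured group summaries.

    ``config`` columns: measure, group, mean, sem, n. Draws are
    Normal(mean, sem * sqrt(n)), so group mean and SEM converge to the
    configured values as n grows; sem = 0 collapses every animal onto the
    mean. Returns a tidy table (animal_id, group, measure, value).
    """
    if (config["sem"] < 0).any():
        raise ValueError("sem must be nonnegative")
    if (config["n"] < 2).any():
        raise ValueError("need n >= 2 per group")
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in config.iterrows():
        n = int(r["n"])
        sd = r["sem"] * np.sqrt(n)
        values = r["mean"] + (rng.normal(0, sd, n) if sd > 0 else np.zeros(n))
        for a, v in enumerate(values):
            rows.append(
                {
                    "animal_id": f"{r['group']}-{a + 1}",
                    "group": r["group"],
                    "measure": r["measure"],
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "ACG_CLASSES", "WAVEFORM_CLASSES", "TRAIN_WINDOW",
    "ResponseSegment", "ArchetypeKernel", "build_archetype_library",
    "waveform_template", "WAVEFORM_N_SAMPLES", "WAVEFORM_SAMPLING_RATE",
    "simulate_spike_train", "simulate_unit", "PopulationConfig",
    "default_config", "load_config", "reference_protocol", "simulate_session",
    "DEFAULT_ARCHETYPE_WEIGHTS", "DEFAULT_WAVEFORM_WEIGHTS", "DEFAULT_ACG_WEIGHTS",
    "simulate_histology", "simulate_behavior", "DEFAULT_REGION_AREAS",
]
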