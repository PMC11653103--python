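"""Session data model, on-disk format, and validation.

A session is a directory holding one anesthetized recording: spike-sorted
units (spike times in seconds, region/group/depth metadata, mean spike
waveforms) plus the somatosensory stimulation protocol (trains of five
pulses at 3.3 Hz, one train every 5 s).

On-disk layout (all plain text)::

    session/
      manifest.json        format version, metadata, protocol, inventory
      units.csv            one row per unit: ids, labels, depth, counts
      events.csv           train onsets, one per line (seconds)
      waveforms.csv        unit x sample matrix of mean spike waveforms
      spikes/<unit_id>.csv one spike time per line (seconds)

Times are seconds written with 9 fractional digits; bins and windows are
half-open ``[t0, t1)``; indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = "costria-session-1"

REGIONS = ("S1", "DLSt")
GROUPS = ("control", "VPA", "PV-depleted")

#: reference somatosensory stimulation protocol: trains of five 5 ms pulses
#: at 3.3 Hz, one train every 5 s.
REFERENCE_N_PULSES = 5
REFERENCE_PULSE_INTERVAL = 1.0 / 3.3
REFERENCE_PULSE_WIDTH = 0.005
REFERENCE_TRAIN_PERIOD = 5.0


class SessionFormatError(ValueError):
    """Raised when a session directory violates the on-disk contract."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulation-train timing: onsets plus within-train pulse layout."""

    train_onsets: np.ndarray
    n_pulses: int = REFERENCE_N_PULSES
    pulse_interval: float = REFERENCE_PULSE_INTERVAL
    pulse_width: float = REFERENCE_PULSE_WIDTH

    def __post_init__(self) -> None:
        onsets = np.asarray(self.train_onsets, dtype=float)
        object.__setattr__(self, "train_onsets", onsets)
        if onsets.ndim != 1:
            raise ValueError("train_onsets must be a 1-D array of seconds")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("train_onsets must be strictly increasing")
        if self.n_pulses < 1 or self.pulse_interval <= 0:
            raise ValueError("need n_pulses >= 1 and pulse_interval > 0")
        span = (self.n_pulses - 1) * self.pulse_interval + self.pulse_width
        if onsets.size > 1 and np.any(np.diff(onsets) < span):
            raise ValueError("pulse trains overlap: onsets closer than train span")

    @property
    def pulse_offsets(self) -> np.ndarray:
        """Pulse onset times relative to the train onset (seconds)."""
        return np.arange(self.n_pulses) * self.pulse_interval

    def pulse_times(self) -> np.ndarray:
        """All pulse onsets, shape (n_trains, n_pulses), absolute seconds."""
        return self.train_onsets[:, None] + self.pulse_offsets[None, :]


@dataclass
class UnitRecording:
    """One spike-sorted unit."""

    unit_id: str
    region: str
    group: str
    animal_id: str
    depth: float                      # mm below the brain surface
    spike_times: np.ndarray           # seconds, sorted ascending
    waveform: np.ndarray              # mean spike waveform, amplitude samples
    truth_labels: dict | None = None  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.waveform = np.asarray(self.waveform, dtype=float)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class Session:
    """An in-memory recording session: units + protocol + manifest metadata."""

    units: list[UnitRecording]
    protocol: StimulusProtocol
    duration: float
    waveform_sampling_rate: float = 25_000.0
    manifest: dict = field(default_factory=dict)

    def units_in(self, region: str) -> list[UnitRecording]:
        return [u for u in self.units if u.region == region]


# ---------------------------------------------------------------------------
# validation

def validate_session(session: Session) -> list[str]:
    """Return a report listing *all* contract violations (empty iff valid)."""
    report: list[str] = []
    if session.duration <= 0:
        report.append("session duration must be positive")
    onsets = session.protocol.train_onsets
    if onsets.size and (onsets[0] < 0 or onsets[-1] > session.duration):
        report.append("train onsets fall outside the session duration")
    wf_lens = {u.waveform.size for u in session.units}
    if len(wf_lens) > 1:
        report.append(f"waveform length not uniform across units: {sorted(wf_lens)}")
    seen: set[str] = set()
    for u in session.units:
        tag = f"unit {u.unit_id!r}"
        if u.unit_id in seen:
            report.append(f"{tag}: duplicate unit_id")
        seen.add(u.unit_id)
        if u.region not in REGIONS:
            report.append(f"{tag}: unknown region {u.region!r}; valid: {REGIONS}")
        if u.group not in GROUPS:
            report.append(f"{tag}: unknown group {u.group!r}; valid: {GROUPS}")
        st = u.spike_times
        if st.size:
            if np.any(np.diff(st) < 0):
                report.append(f"{tag}: spike times not sorted ascending")
            if st[0] < 0:
                report.append(f"{tag}: negative spike time {st[0]:.6f}")
            if st[-1] > session.duration:
                report.append(f"{tag}: spike at {st[-1]:.6f} s beyond duration")
        if not np.all(np.isfinite(u.waveform)):
            report.append(f"{tag}: non-finite waveform samples")
    return report


# ---------------------------------------------------------------------------
# on-disk format

def _fmt(x: float) -> str:
    return f"{x:.9f}"


def write_session(session: Session, path: str | Path) -> Path:
    """Write ``session`` to a directory; returns the manifest path.

    File ordering and float formatting are deterministic, so re-writing the
    same session produces identical bytes.
    """
    report = validate_session(session)
    if report:
        raise SessionFormatError("invalid session: " + "; ".join(report))
    path = Path(path)
    (path / "spikes").mkdir(parents=True, exist_ok=True)

    rows = []
    for u in session.units:
        truth = u.truth_labels or {}
        rows.append(
            {
                "unit_id": u.unit_id,
                "region": u.region,
                "group": u.group,
                "animal_id": u.animal_id,
                "depth_mm": u.depth,
                "n_spikes": u.n_spikes,
                "truth_archetype": truth.get("archetype", ""),
                "truth_waveform": truth.get("waveform", ""),
                "truth_acg": truth.get("acg", ""),
            }
        )
    units_df = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "region", "group", "animal_id", "depth_mm",
            "n_spikes", "truth_archetype", "truth_waveform", "truth_acg",
        ],
    )
    units_df.to_csv(path / "units.csv", index=False, float_format="%.9f")

    with open(path / "events.csv", "w") as fh:
        fh.write("train_onset_s\n")
        for t in session.protocol.train_onsets:
            fh.write(_fmt(t) + "\n")

    n_samples = session.units[0].waveform.size if session.units else 0
    with open(path / "waveforms.csv", "w") as fh:
        fh.write(",".join(["unit_id"] + [f"s{i}" for i in range(n_samples)]) + "\n")
        for u in session.units:
            fh.write(",".join([u.unit_id] + [_fmt(v) for v in u.waveform]) + "\n")

    for u in session.units:
        with open(path / "spikes" / f"{u.unit_id}.csv", "w") as fh:
            fh.write("spike_time_s\n")
            for t in u.spike_times:
                fh.write(_fmt(t) + "\n")

    manifest = {
        "format_version": FORMAT_VERSION,
        "duration_s": session.duration,
        "waveform_sampling_rate_hz": session.waveform_sampling_rate,
        "n_units": len(session.units),
        "protocol": {
            "n_pulses": session.protocol.n_pulses,
            "pulse_interval_s": session.protocol.pulse_interval,
            "pulse_width_s": session.protocol.pulse_width,
        },
        "files": {
            "units": "units.csv",
            "events": "events.csv",
            "waveforms": "waveforms.csv",
            "spikes_dir": "spikes",
        },
        "metadata": dict(session.manifest),
    }
    manifest_path = path / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


def read_session(path: str | Path) -> Session:
    """Read and fully validate a session directory.

    Unsorted or negative spike times are rejected, not silently repaired.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SessionFormatError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise SessionFormatError(
            f"unknown format version {version!r}; expected {FORMAT_VERSION!r}"
        )
    files = manifest["files"]
    for key in ("units", "events", "waveforms"):
        if not (path / files[key]).exists():
            raise SessionFormatError(f"missing file referenced by manifest: {files[key]}")

    units_df = pd.read_csv(path / files["units"], dtype={"unit_id": str}, keep_default_na=False)
    events = pd.read_csv(path / files["events"])["train_onset_s"].to_numpy(float)
    wf_df = pd.read_csv(path / files["waveforms"], dtype={"unit_id": str})
    waveforms = {
        str(r["unit_id"]): r.drop("unit_id").to_numpy(float)
        for _, r in wf_df.iterrows()
    }

    proto = manifest["protocol"]
    protocol = StimulusProtocol(
        train_onsets=events,
        n_pulses=int(proto["n_pulses"]),
        pulse_interval=float(proto["pulse_interval_s"]),
        pulse_width=float(proto["pulse_width_s"]),
    )

    units: list[UnitRecording] = []
    for _, row in units_df.iterrows():
        uid = str(row["unit_id"])
        spike_path = path / files["spikes_dir"] / f"{uid}.csv"
        if not spike_path.exists():
            raise SessionFormatError(f"missing file referenced by manifest: {spike_path.name}")
        spikes = pd.read_csv(spike_path)["spike_time_s"].to_numpy(float)
        if spikes.size and np.any(np.diff(spikes) < 0):
            raise SessionFormatError(f"unit {uid!r}: spike times not sorted ascending")
        if row["region"] not in REGIONS:
            raise SessionFormatError(
                f"unit {uid!r}: unknown region {row['region']!r}; valid: {REGIONS}"
            )
        if row["group"] not in GROUPS:
            raise SessionFormatError(
                f"unit {uid!r}: unknown group {row['group']!r}; valid: {GROUPS}"
            )
        truth = {
            k: row[f"truth_{k}"]
            for k in ("archetype", "waveform", "acg")
            if str(row.get(f"truth_{k}", "")) != ""
        }
        units.append(
            UnitRecording(
                unit_id=uid,
                region=str(row["region"]),
                group=str(row["group"]),
                animal_id=str(row["animal_id"]),
                depth=float(row["depth_mm"]),
                spike_times=spikes,
                waveform=waveforms[uid],
                truth_labels=truth or None,
            )
        )

    session = Session(
        units=units,
        protocol=protocol,
        duration=float(manifest["duration_s"]),
        waveform_sampling_rate=float(manifest["waveform_sampling_rate_hz"]),
        manifest=dict(manifest.get("metadata", {})),
    )
    report = validate_session(session)
    if report:
        raise SessionFormatError("invalid session on disk: " + "; ".join(report))
    return session


__all__ = [
    "FORMAT_VERSION", "REGIONS", "GROUPS",
    "REFERENCE_N_PULSES", "REFERENCE_PULSE_INTERVAL", "REFERENCE_PULSE_WIDTH",
    "REFERENCE_TRAIN_PERIOD",
    "SessionFormatError", "StimulusProtocol", "UnitRecording", "Session",
    "read_session", "write_session", "validate_session",
]
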