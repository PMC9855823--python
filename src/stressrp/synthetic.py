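"""Seeded generator for labeled multichannel stress recordings.

Real stress-monitoring datasets pair continuous autonomic channels — skin
conductance at two sites (foot and hand) and heart rate — with annotated
stressed/relaxed episodes.  This module emulates that structure with a
minimal physiological model:

* **GSR** (both sites): a tonic conductance level that rises additively under
  stress, plus superposed phasic skin-conductance responses (SCRs) arriving
  as a Poisson process whose rate is higher under stress.  Each SCR is an
  exponential rise/decay bump.  The hand and foot phasic drives share a
  configurable fraction of events (sympathetic co-activation).
* **HR**: a baseline in beats per minute that shifts upward under stress,
  plus AR(1) autocorrelated variability whose spread *shrinks* under stress
  (reduced vagally-mediated variability).

The generator is fully determined by ``(params, schedule, seed)``; per-channel
Gaussian sensor noise is added last.  Datasets round-trip through a plain CSV
dialect (one signal file per recording, one shared labels file, a JSON
manifest) so downstream stages can also consume externally supplied data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

CHANNELS = ("fgsr", "hgsr", "hr")
STATES = ("stressed", "relaxed")

__all__ = [
    "CHANNELS",
    "STATES",
    "SimParams",
    "Recording",
    "RecordingSet",
    "alternating_schedule",
    "simulate_recording",
    "simulate_cohort",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    Units: conductance channels are in arbitrary microsiemens-like units,
    heart rate in beats per minute, times in seconds, SCR rates in events
    per minute.
    """

    sampling_rate: float = 16.0
    recording_duration: float = 600.0
    episode_length: float = 60.0
    gsr_tonic_base: float = 5.0
    gsr_tonic_stress_shift: float = 3.0
    scr_rate_relaxed: float = 1.0
    scr_rate_stressed: float = 12.0
    scr_amplitude_mean: float = 1.0
    scr_rise_s: float = 1.5
    scr_decay_s: float = 4.0
    hr_base_bpm: float = 70.0
    hr_stress_shift_bpm: float = 15.0
    hr_variability_relaxed: float = 6.0
    hr_variability_stressed: float = 2.0
    gsr_noise_sd: float = 0.02
    hr_noise_sd: float = 0.3
    hand_foot_correlation: float = 0.7

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "recording_duration", "episode_length",
                     "scr_amplitude_mean", "scr_rise_s", "scr_decay_s",
                     "hr_base_bpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimParams.{name} must be strictly positive")
        for name in ("scr_rate_relaxed", "scr_rate_stressed",
                     "hr_variability_relaxed", "hr_variability_stressed",
                     "gsr_noise_sd", "hr_noise_sd", "hr_stress_shift_bpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimParams.{name} must be nonnegative")
        if self.scr_rate_stressed < self.scr_rate_relaxed:
            raise ValueError("scr_rate_stressed must be >= scr_rate_relaxed")
        if not 0.0 <= self.hand_foot_correlation <= 1.0:
            raise ValueError("hand_foot_correlation must lie in [0, 1]")
        n = self.sampling_rate * self.recording_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "sampling_rate * recording_duration must be an integer "
                f"sample count, got {n}")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.recording_duration))


@dataclass
class Recording:
    """One subject session: three time-aligned channels plus interval labels.

    ``labels`` is an ordered list of half-open ``(start_s, end_s, state)``
    intervals with ``state`` in ``{"stressed", "relaxed"}``.
    """

    recording_id: str
    channels: dict[str, np.ndarray]
    sampling_rate: float
    labels: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def duration(self) -> float:
        return len(next(iter(self.channels.values()))) / self.sampling_rate

    def validate(self) -> None:
        missing = set(CHANNELS) - set(self.channels)
        if missing:
            raise ValueError(
                f"recording {self.recording_id!r}: missing channels {sorted(missing)}")
        lengths = {name: len(v) for name, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(
                f"recording {self.recording_id!r}: channel lengths differ: {lengths}")
        dur = self.duration
        prev_end = None
        for i, (start, end, state) in enumerate(self.labels):
            if state not in STATES:
                raise ValueError(
                    f"recording {self.recording_id!r}, label {i}: unknown state {state!r}")
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"recording {self.recording_id!r}, label {i}: interval "
                    f"[{start}, {end}) outside [0, {dur}]")
            if prev_end is not None and start < prev_end - 1e-9:
                raise ValueError(
                    f"recording {self.recording_id!r}, label {i}: interval "
                    f"[{start}, {end}) overlaps previous end {prev_end}")
            prev_end = end

    def state_at(self, t: float) -> str | None:
        """State of the interval containing time ``t``, or None if unlabeled."""
        for start, end, state in self.labels:
            if start <= t < end:
                return state
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.recording_id == other.recording_id
            and self.sampling_rate == other.sampling_rate
            and self.labels == other.labels
            and set(self.channels) == set(other.channels)
            and all(np.array_equal(self.channels[c], other.channels[c])
                    for c in self.channels)
        )

    def allclose(self, other: "Recording", atol: float = 1e-6) -> bool:
        """Equality up to numeric tolerance on channel values."""
        return (
            self.recording_id == other.recording_id
            and self.sampling_rate == other.sampling_rate
            and len(self.labels) == len(other.labels)
            and all(a[2] == b[2] and abs(a[0] - b[0]) < atol and abs(a[1] - b[1]) < atol
                    for a, b in zip(self.labels, other.labels))
            and set(self.channels) == set(other.channels)
            and all(np.allclose(self.channels[c], other.channels[c], atol=atol)
                    for c in self.channels)
        )


@dataclass
class RecordingSet:
    """A cohort of recordings with its generation or load provenance."""

    recordings: list[Recording]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.recordings:
            raise ValueError("RecordingSet must be non-empty")
        ids = [r.recording_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate recording ids: {ids}")

    @property
    def ids(self) -> list[str]:
        return [r.recording_id for r in self.recordings]

    def __getitem__(self, recording_id: str) -> Recording:
        for r in self.recordings:
            if r.recording_id == recording_id:
                return r
        raise KeyError(recording_id)


def alternating_schedule(duration: float, episode_length: float,
                         first_state: str = "relaxed",
                         ) -> list[tuple[float, float, str]]:
    """Tile [0, duration) with alternating fixed-length episodes.

    A trailing partial episode is kept (labeled) so the schedule covers the
    whole recording.
    """
    if first_state not in STATES:
        raise ValueError(f"unknown state {first_state!r}")
    other = "stressed" if first_state == "relaxed" else "relaxed"
    out: list[tuple[float, float, str]] = []
    t, i = 0.0, 0
    while t < duration - 1e-9:
        end = min(t + episode_length, duration)
        out.append((t, end, first_state if i % 2 == 0 else other))
        t, i = end, i + 1
    return out


def _state_mask(schedule: list[tuple[float, float, str]], n: int,
                fs: float) -> np.ndarray:
    """Boolean per-sample mask: True where the state is 'stressed'."""
    t = np.arange(n) / fs
    mask = np.zeros(n, dtype=bool)
    for start, end, state in schedule:
        if state == "stressed":
            mask |= (t >= start) & (t < end)
    return mask


def _scr_kernel(params: SimParams) -> np.ndarray:
    """Unit-peak exponential rise/decay SCR shape sampled at the signal rate."""
    fs = params.sampling_rate
    length = int(round((params.scr_rise_s + 6 * params.scr_decay_s) * fs))
    t = np.arange(max(length, 2)) / fs
    shape = (1.0 - np.exp(-t / params.scr_rise_s)) * np.exp(-t / params.scr_decay_s)
    peak = shape.max()
    return shape / peak if peak > 0 else shape


def _phasic_impulses(rng: np.random.Generator, mask: np.ndarray,
                     params: SimParams) -> np.ndarray:
    """Poisson impulse train with state-dependent rate and random amplitudes."""
    fs = params.sampling_rate
    rate_per_sample = np.where(mask, params.scr_rate_stressed,
                               params.scr_rate_relaxed) / 60.0 / fs
    events = rng.random(len(mask)) < rate_per_sample
    amps = np.zeros(len(mask))
    k = int(events.sum())
    if k:
        amps[events] = rng.exponential(params.scr_amplitude_mean, size=k)
    return amps


def simulate_recording(params: SimParams,
                       schedule: list[tuple[float, float, str]],
                       seed: int,
                       recording_id: str = "rec") -> Recording:
    """Simulate one three-channel recording under a given state schedule.

    The same ``(params, schedule, seed)`` triple always reproduces the exact
    same sample values.  The hand/foot phasic coupling is realized by a
    shared Poisson event stream at rate ``c * r`` plus independent per-site
    streams at rate ``(1 - c) * r``, so each site keeps marginal rate ``r``
    while sharing fraction ``c`` of its events.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(seed)
    n = params.n_samples
    mask = _state_mask(schedule, n, params.sampling_rate)

    tonic = params.gsr_tonic_base + params.gsr_tonic_stress_shift * mask
    kernel = _scr_kernel(params)

    c = params.hand_foot_correlation
    shared = dataclasses.replace(
        params,
        scr_rate_relaxed=c * params.scr_rate_relaxed,
        scr_rate_stressed=c * params.scr_rate_stressed)
    solo = dataclasses.replace(
        params,
        scr_rate_relaxed=(1 - c) * params.scr_rate_relaxed,
        scr_rate_stressed=(1 - c) * params.scr_rate_stressed)
    common = _phasic_impulses(rng, mask, shared)
    foot_only = _phasic_impulses(rng, mask, solo)
    hand_only = _phasic_impulses(rng, mask, solo)

    def phasic(impulses: np.ndarray) -> np.ndarray:
        return np.convolve(impulses, kernel)[:n]

    fgsr = tonic + phasic(common + foot_only) + rng.normal(0, params.gsr_noise_sd, n)
    hgsr = tonic + phasic(common + hand_only) + rng.normal(0, params.gsr_noise_sd, n)

    # AR(1) variability: decorrelation time ~2 s, stationary SD set per state.
    phi = np.exp(-1.0 / (2.0 * params.sampling_rate))
    sd = np.where(mask, params.hr_variability_stressed,
                  params.hr_variability_relaxed)
    innovations = rng.normal(0, 1, n) * sd * np.sqrt(1 - phi**2)
    v = lfilter([1.0], [1.0, -phi], innovations)
    hr = (params.hr_base_bpm + params.hr_stress_shift_bpm * mask + v
          + rng.normal(0, params.hr_noise_sd, n))

    return Recording(
        recording_id=recording_id,
        channels={"fgsr": fgsr, "hgsr": hgsr, "hr": hr},
        sampling_rate=params.sampling_rate,
        labels=list(schedule),
    )


def simulate_cohort(n_recordings: int, params: SimParams | None = None,
                    seed: int = 0) -> RecordingSet:
    """Simulate a cohort for leave-one-recording-out cross-validation.

    Per-recording seeds are spawned deterministically from the master seed.
    Schedules alternate stressed/relaxed episodes with a per-recording phase
    offset (odd-indexed recordings start stressed).
    """
    if n_recordings < 2:
        raise ValueError(
            "n_recordings must be >= 2 (leave-one-recording-out is undefined "
            "for a single recording)")
    params = params or SimParams()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_recordings) % (2**31)
    recordings = []
    for i in range(n_recordings):
        first = "relaxed" if i % 2 == 0 else "stressed"
        schedule = alternating_schedule(params.recording_duration,
                                        params.episode_length, first)
        recordings.append(simulate_recording(
            params, schedule, int(child_seeds[i]),
            recording_id=f"rec{i + 1:02d}"))
    return RecordingSet(
        recordings=recordings,
        provenance={"seed": int(seed), "n_recordings": n_recordings,
                    "params": dataclasses.asdict(params)},
    )


_MANIFEST = "manifest.json"
_LABELS = "labels.csv"


def write_dataset(recording_set: RecordingSet, directory: str | Path) -> Path:
    """Write a RecordingSet as CSV files plus a JSON manifest.

    Layout: one ``<id>.csv`` per recording with columns
    ``time_s,fgsr,hgsr,hr``; one ``labels.csv`` with columns
    ``recording_id,start_s,end_s,state``; ``manifest.json`` listing files,
    sampling rate and provenance.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    label_rows = []
    for rec in recording_set.recordings:
        n = len(rec.channels["fgsr"])
        df = pd.DataFrame({
            "time_s": np.arange(n) / rec.sampling_rate,
            "fgsr": rec.channels["fgsr"],
            "hgsr": rec.channels["hgsr"],
            "hr": rec.channels["hr"],
        })
        fname = f"{rec.recording_id}.csv"
        df.to_csv(directory / fname, index=False, float_format="%.6f")
        files[rec.recording_id] = fname
        for start, end, state in rec.labels:
            label_rows.append((rec.recording_id, start, end, state))
    pd.DataFrame(label_rows,
                 columns=["recording_id", "start_s", "end_s", "state"]
                 ).to_csv(directory / _LABELS, index=False)
    manifest = {
        "files": files,
        "labels": _LABELS,
        "sampling_rate": recording_set.recordings[0].sampling_rate,
        "provenance": recording_set.provenance,
    }
    manifest_path = directory / _MANIFEST
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_dataset(directory: str | Path) -> RecordingSet:
    """Load a dataset written by :func:`write_dataset`, validating invariants."""
    directory = Path(directory)
    manifest_path = directory / _MANIFEST
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    fs = float(manifest["sampling_rate"])
    labels_df = pd.read_csv(directory / manifest.get("labels", _LABELS))

    recordings = []
    for rec_id, fname in manifest["files"].items():
        path = directory / fname
        df = pd.read_csv(path)
        for col in ("fgsr", "hgsr", "hr"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing channel column {col!r}")
        sub = labels_df[labels_df["recording_id"] == rec_id]
        labels = [(float(r.start_s), float(r.end_s), str(r.state))
                  for r in sub.itertuples()]
        try:
            recordings.append(Recording(
                recording_id=rec_id,
                channels={c: df[c].to_numpy(dtype=float)
                          for c in ("fgsr", "hgsr", "hr")},
                sampling_rate=fs,
                labels=labels,
            ))
        except ValueError as exc:
            raise ValueError(f"{directory / _LABELS}: {exc}") from exc
    return RecordingSet(recordings=recordings,
                        provenance=manifest.get("provenance", {}))
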