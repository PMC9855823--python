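"""Windowing, normalization, class rebalancing and time-domain features.

Recordings are cut into fixed-length windows (10 s or 30 s by default
elsewhere in the pipeline); a window inherits the label of the single
stressed/relaxed interval that fully contains it, and windows straddling an
interval boundary are dropped so every label is unambiguous.  Class
rebalancing operates on lists of windows and never fabricates samples:
undersampling discards majority windows, oversampling duplicates existing
ones with replacement.  For classical (non-neural) baselines each window is
reduced to a fixed-order vector of per-channel time-domain statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from stressrp.synthetic import CHANNELS, STATES, Recording

__all__ = [
    "SignalWindow",
    "FeatureVector",
    "FEATURE_NAMES",
    "resample_channel",
    "segment_windows",
    "minmax_normalize",
    "undersample_majority",
    "oversample_with_replacement",
    "extract_tabular_features",
]


@dataclass(eq=False)
class SignalWindow:
    """A fixed-length labeled slice of one recording across all channels."""

    recording_id: str
    window_index: int
    start_s: float
    length_s: float
    sampling_rate: float
    channels: dict[str, np.ndarray]
    label: str

    def __post_init__(self) -> None:
        if self.label not in STATES:
            raise ValueError(f"unknown label {self.label!r}")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("channel arrays must have equal length")


def resample_channel(series: np.ndarray, fs_in: float,
                     fs_out: float) -> np.ndarray:
    """Linear-interpolation resampling onto a uniform output time grid.

    Output length is ``round(len(series) * fs_out / fs_in)``.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot resample an empty series")
    if fs_in == fs_out:
        return series.copy()
    n_out = int(round(len(series) * fs_out / fs_in))
    t_in = np.arange(len(series)) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, series)


def segment_windows(recording: Recording, length_s: float,
                    stride_s: float | None = None) -> list[SignalWindow]:
    """Slide a window over a recording and keep unambiguously labeled slices.

    A window spanning ``[t, t + length_s)`` gets the label of the interval
    that fully contains it; windows that straddle interval boundaries or
    fall on unlabeled time are dropped.  Default stride is the window
    length (non-overlapping windows, avoiding train/test leakage between
    overlapping slices).
    """
    if stride_s is None:
        stride_s = length_s
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    if length_s > recording.duration + 1e-9:
        raise ValueError("window length exceeds recording duration")
    fs = recording.sampling_rate
    win_n = int(round(length_s * fs))
    total_n = len(recording.channels["fgsr"])

    windows: list[SignalWindow] = []
    index = 0
    t = 0.0
    while True:
        i0 = int(round(t * fs))
        if i0 + win_n > total_n:
            break
        label = _containing_label(recording.labels, t, t + length_s)
        if label is not None:
            windows.append(SignalWindow(
                recording_id=recording.recording_id,
                window_index=index,
                start_s=t,
                length_s=length_s,
                sampling_rate=fs,
                channels={c: recording.channels[c][i0:i0 + win_n].copy()
                          for c in CHANNELS},
                label=label,
            ))
        index += 1
        t += stride_s
    return windows


def _containing_label(labels, start: float, end: float) -> str | None:
    for s, e, state in labels:
        if s - 1e-9 <= start and end <= e + 1e-9:
            return state
    return None


def minmax_normalize(series: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant series maps to all zeros."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot normalize an empty series")
    lo, hi = series.min(), series.max()
    if hi == lo:
        return np.zeros_like(series)
    return (series - lo) / (hi - lo)


def _split_by_class(windows: list[SignalWindow]) -> dict[str, list[int]]:
    by_class: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_class.setdefault(w.label, []).append(i)
    return by_class


def undersample_majority(windows: list[SignalWindow],
                         seed: int) -> list[SignalWindow]:
    """Equalize class counts by seeded uniform subsampling of the majority.

    The minority class is untouched; majority windows are drawn without
    replacement.  Output preserves the original ordering of kept windows.
    """
    by_class = _split_by_class(windows)
    if len(by_class) < 2:
        raise ValueError(
            f"undersampling needs both classes, got {sorted(by_class)}")
    rng = np.random.default_rng(seed)
    target = min(len(v) for v in by_class.values())
    keep: set[int] = set()
    for label in sorted(by_class):
        idx = by_class[label]
        if len(idx) == target:
            keep.update(idx)
        else:
            keep.update(rng.choice(idx, size=target, replace=False))
    return [w for i, w in enumerate(windows) if i in keep]


def oversample_with_replacement(windows: list[SignalWindow],
                                target_per_class: int,
                                seed: int) -> list[SignalWindow]:
    """Grow every class to ``target_per_class`` by seeded duplication.

    Each class is padded with uniform draws (with replacement) from its own
    windows; no window values are ever synthesized.
    """
    by_class = _split_by_class(windows)
    counts = {k: len(v) for k, v in by_class.items()}
    if target_per_class < max(counts.values()):
        raise ValueError(
            f"target_per_class={target_per_class} below existing class "
            f"counts {counts}")
    rng = np.random.default_rng(seed)
    out = list(windows)
    for label in sorted(by_class):
        idx = by_class[label]
        extra = target_per_class - len(idx)
        if extra > 0:
            out.extend(windows[i] for i in rng.choice(idx, size=extra,
                                                      replace=True))
    return out


#: Per-channel feature order; the full vector concatenates these for
#: fgsr, hgsr, hr in that order.
FEATURE_NAMES = (
    "n_peaks", "mean", "median", "sum", "rms", "skewness", "kurtosis",
    "amplitude", "max", "min", "iqr", "sd", "mean_abs_succ_diff",
)


@dataclass
class FeatureVector:
    """Named time-domain statistics for one window, all channels."""

    names: tuple[str, ...]
    values: np.ndarray
    label: str
    recording_id: str

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def _count_strict_peaks(x: np.ndarray) -> int:
    if len(x) < 3:
        return 0
    return int(np.sum((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])))


def _channel_features(x: np.ndarray) -> list[float]:
    sd = float(np.std(x))
    constant = sd == 0.0
    # zero-variance skewness/kurtosis defined as 0 for degenerate windows
    skew = 0.0 if constant else float(stats.skew(x))
    kurt = 0.0 if constant else float(stats.kurtosis(x))
    diffs = np.abs(np.diff(x))
    return [
        float(_count_strict_peaks(x)),
        float(np.mean(x)),
        float(np.median(x)),
        float(np.sum(x)),
        float(np.sqrt(np.mean(x**2))),
        skew,
        kurt,
        float(np.max(x) - np.min(x)),
        float(np.max(x)),
        float(np.min(x)),
        float(np.percentile(x, 75) - np.percentile(x, 25)),
        sd,
        float(np.mean(diffs)) if diffs.size else 0.0,
    ]


def extract_tabular_features(window: SignalWindow) -> FeatureVector:
    """Compute the time-domain statistics of every channel of a window.

    Peaks are strict local maxima; `mean_abs_succ_diff` is the mean absolute
    successive difference.  Ordering is ``FEATURE_NAMES`` per channel, with
    channels in fgsr, hgsr, hr order.
    """
    names: list[str] = []
    values: list[float] = []
    for channel in CHANNELS:
        names.extend(f"{channel}_{f}" for f in FEATURE_NAMES)
        values.extend(_channel_features(np.asarray(window.channels[channel],
                                                   dtype=float)))
    return FeatureVector(
        names=tuple(names),
        values=np.array(values, dtype=float),
        label=window.label,
        recording_id=window.recording_id,
    )


def class_counts(windows: list[SignalWindow]) -> dict[str, int]:
    """Label histogram of a window list."""
    return dict(Counter(w.label for w in windows))


def save_windows(windows: list[SignalWindow], path) -> None:
    """Archive windows as an .npz with a JSON sidecar of ids and labels.

    The sidecar (``<path>.json``) makes the archive auditable without
    loading the arrays; downstream stages can rerun from the archive
    without re-windowing.
    """
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {}
    meta = []
    for i, w in enumerate(windows):
        for c in CHANNELS:
            arrays[f"w{i}_{c}"] = w.channels[c]
        meta.append({"recording_id": w.recording_id,
                     "window_index": w.window_index, "start_s": w.start_s,
                     "length_s": w.length_s, "sampling_rate": w.sampling_rate,
                     "label": w.label})
    np.savez_compressed(path, **arrays)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_windows(path) -> list[SignalWindow]:
    """Inverse of :func:`save_windows`."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    archive = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    data = np.load(archive)
    return [SignalWindow(channels={c: data[f"w{i}_{c}"] for c in CHANNELS},
                         **entry)
            for i, entry in enumerate(meta)]
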