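"""Continuous (unthresholded) recurrence-plot images of signal windows.

A recurrence plot visualizes when a trajectory revisits a region of its
phase space.  The classic binary plot thresholds pairwise distances; the
continuous variant used here keeps the raw Euclidean distance matrix
between (optionally delay-embedded) points, rendered as a grayscale image:
larger distance maps to a brighter pixel, the main diagonal is zero, and
the matrix is symmetric.  Per-window min-max scaling makes the image
invariant to affine rescaling of the input signal, which matches the
per-window normalization applied to the channels upstream.

Defaults are embedding dimension 1 with delay 1: a 10-30 s window at a
modest sampling rate leaves few samples, and higher-dimensional embeddings
only shrink the matrix further; both parameters stay configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EmbeddingConfig",
    "RPImage",
    "delay_embed",
    "cont_rp",
    "rp_to_image",
    "window_to_rp_images",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters: dimension ``m`` and delay ``tau`` (samples)."""

    m: int = 1
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("embedding dimension and delay must be >= 1")

    def n_points(self, n_samples: int) -> int:
        return n_samples - (self.m - 1) * self.tau


@dataclass
class RPImage:
    """Square grayscale rendering of a continuous recurrence plot."""

    pixels: np.ndarray
    channel: str
    recording_id: str
    window_index: int
    config: EmbeddingConfig

    def __post_init__(self) -> None:
        h, w = self.pixels.shape
        if h != w:
            raise ValueError("RPImage must be square")
        if self.pixels.min() < -1e-6 or self.pixels.max() > 1 + 1e-6:
            raise ValueError("pixel values must lie in [0, 1]")


def delay_embed(series: np.ndarray, config: EmbeddingConfig) -> np.ndarray:
    """Map a scalar series to m-dimensional delay vectors.

    Point ``i`` is ``(x_i, x_{i+tau}, ..., x_{i+(m-1)tau})``; the result has
    ``N - (m-1)*tau`` rows.
    """
    series = np.asarray(series, dtype=float)
    n_pts = config.n_points(len(series))
    if n_pts < 2:
        raise ValueError(
            f"series of length {len(series)} too short for m={config.m}, "
            f"tau={config.tau} (need at least {(config.m - 1) * config.tau + 2})")
    cols = [series[i * config.tau: i * config.tau + n_pts]
            for i in range(config.m)]
    return np.stack(cols, axis=1)


def cont_rp(series: np.ndarray,
            config: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Continuous recurrence plot: pairwise Euclidean distance matrix.

    No threshold is applied; the matrix is symmetric with a zero diagonal.
    """
    points = delay_embed(series, config)
    return squareform(pdist(points, metric="euclidean"))


def rp_to_image(matrix: np.ndarray, out_size: int,
                channel: str = "", recording_id: str = "",
                window_index: int = 0,
                config: EmbeddingConfig = EmbeddingConfig()) -> RPImage:
    """Min-max scale a distance matrix to [0, 1] and bilinear-resize it.

    A constant matrix renders as all zeros.  Larger distance means brighter
    pixel (no polarity inversion).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"distance matrix must be square, got {matrix.shape}")
    if out_size < 1:
        raise ValueError("out_size must be >= 1")
    lo, hi = matrix.min(), matrix.max()
    scaled = np.zeros_like(matrix) if hi == lo else (matrix - lo) / (hi - lo)
    if matrix.shape[0] != out_size:
        img = Image.fromarray(scaled.astype(np.float32), mode="F")
        img = img.resize((out_size, out_size), resample=Image.BILINEAR)
        scaled = np.asarray(img, dtype=np.float64)
        scaled = np.clip(scaled, 0.0, 1.0)
    return RPImage(pixels=scaled, channel=channel, recording_id=recording_id,
                   window_index=window_index, config=config)


def window_to_rp_images(window, out_size: int = 64,
                        config: EmbeddingConfig = EmbeddingConfig(),
                        normalize: bool = True) -> dict[str, RPImage]:
    """Render every channel of a SignalWindow as a Cont-RP image.

    Channels are min-max normalized per window first (the rendered image is
    unchanged by this for non-constant windows, but it fixes the distance
    scale for any downstream use of the raw matrices).
    """
    from stressrp.preprocess import minmax_normalize

    out = {}
    for channel, values in window.channels.items():
        series = minmax_normalize(values) if normalize else values
        out[channel] = rp_to_image(
            cont_rp(series, config), out_size, channel=channel,
            recording_id=window.recording_id,
            window_index=window.window_index, config=config)
    return out
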