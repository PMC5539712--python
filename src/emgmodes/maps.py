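"""Windowing and RMS activation maps.

A recording is cut into consecutive non-overlapping windows (150 ms by
default) and each window is summarised as an activation map: a 2-D image on
the electrode grid whose pixel (i, j) is the RMS amplitude of channel (i, j)
over the window,

    AM[i, j] = sqrt( (1/N) * sum_n EMG[i, j][n]^2 ),

with N the number of samples per window. Maps are then segmented into
per-muscle sub-maps using the array's muscle masks; the forearm array yields
three muscles, each upper-arm array one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ElectrodeArray, Pos, Recording, ValidationError
from .preprocess import interpolate_outliers


@dataclass
class ActivationMap:
    """Per-window RMS image on the electrode grid (microvolts)."""

    values: np.ndarray  # (n_rows, n_cols), >= 0
    window_index: int
    window_ms: float
    array: ElectrodeArray
    interpolated: set[Pos] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.array.n_rows, self.array.n_cols):
            raise ValidationError("map shape does not match array geometry")
        if (self.values < 0).any():
            raise ValidationError("activation map values must be non-negative")


@dataclass
class SegmentedActivationMap:
    """The pixels of one activation map lying inside one muscle's mask."""

    muscle: str
    pixels: list[tuple[Pos, float]]

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValidationError(f"segmented map for {self.muscle!r} has no pixels")
        if any(v < 0 for _, v in self.pixels):
            raise ValidationError("segmented map values must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.pixels])

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.pixels], dtype=float)


def window_samples(window_ms: float, fs: float) -> int:
    """Samples per window, N = round(window_ms * fs / 1000)."""
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    return int(round(window_ms * fs / 1000.0))


def window_recording(rec: Recording, window_ms: float = 150.0) -> list[np.ndarray]:
    """Cut into consecutive non-overlapping windows; trailing remainder dropped."""
    n = window_samples(window_ms, rec.fs)
    if rec.n_samples < n:
        raise ValidationError(
            f"recording ({rec.n_samples} samples) shorter than one {window_ms} ms window"
        )
    n_windows = rec.n_samples // n
    return [rec.samples[:, i * n : (i + 1) * n] for i in range(n_windows)]


def rms_map(
    window: np.ndarray,
    array: ElectrodeArray,
    window_index: int = 0,
    window_ms: float = 150.0,
    extra_outliers: set[Pos] | None = None,
    ms_scale: bool = False,
    interpolate: bool = True,
) -> ActivationMap:
    """Activation map of one window; outlier pixels repaired by triangular
    interpolation.

    ``ms_scale=True`` leaves pixels on the mean-square scale instead of
    taking the square root (the two are monotonically related).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != array.n_channels:
        raise ValidationError("window must be (n_channels, n) for this array")
    if window.shape[1] < 1:
        raise ValidationError("window must contain at least one sample")
    ms = np.mean(window**2, axis=1)
    values = ms if ms_scale else np.sqrt(ms)
    amap = ActivationMap(
        values=values.reshape(array.n_rows, array.n_cols),
        window_index=window_index,
        window_ms=window_ms,
        array=array,
    )
    flagged = set(array.outlier_channels) | set(extra_outliers or ())
    if interpolate and flagged:
        amap = interpolate_outliers(amap, flagged)
    return amap


def segment_map(amap: ActivationMap) -> list[SegmentedActivationMap]:
    """One segmented map per muscle mask; pixels outside all masks discarded."""
    if not amap.array.muscle_masks:
        raise ValidationError("array has no muscle masks")
    out = []
    for muscle, mask in amap.array.muscle_masks.items():
        pixels = [((r, c), float(amap.values[r, c])) for (r, c) in sorted(mask)]
        out.append(SegmentedActivationMap(muscle=muscle, pixels=pixels))
    return out
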