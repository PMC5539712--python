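"""Band-pass filtering, outlier-channel detection and map-pixel repair.

Filtering follows the usual surface-EMG practice: a 4th-order Butterworth
band-pass (15-350 Hz by default) applied forward and reverse so the net
phase is zero. Outlier channels (poor electrode contact, shorts, dead
inputs) are found by a robust log-RMS screen and their activation-map pixels
are repaired by linear interpolation over a Delaunay triangulation of the
remaining pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from .data_io import Pos, Recording, ValidationError


@dataclass
class FilterSpec:
    """Butterworth band-pass specification (defaults: 4th order, 15-350 Hz)."""

    order: int = 4
    low_hz: float = 15.0
    high_hz: float = 350.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise ValueError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) < fs/2 ({fs / 2})"
            )


@dataclass
class OutlierReport:
    """Per-channel scores and the set of flagged (row, col) positions."""

    channel_scores: np.ndarray
    flagged: set[Pos]
    method: str
    threshold: float


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward and reverse (``sosfiltfilt``), which cancels
    phase distortion at the cost of doubling the effective attenuation slope.
    Output length equals input length.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    sos = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=rec.fs, output="sos"
    )
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def detect_outliers(rec: Recording, k_mad: float = 5.0) -> OutlierReport:
    """Flag channels whose log-RMS deviates from the array median by > k_mad MADs.

    Deterministic and permutation-equivariant. An all-constant recording
    yields an empty flag set with a warning (no amplitude scale to screen
    against).
    """
    if rec.n_channels < 8:
        raise ValidationError("outlier detection needs at least 8 channels")
    rms = np.sqrt(np.mean(rec.samples**2, axis=1))
    tiny = np.finfo(float).tiny
    scores = np.log10(np.maximum(rms, tiny))
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    if mad == 0.0:
        if np.allclose(scores, scores[0]):
            warnings.warn("all channels identical; no outlier screen possible")
            return OutlierReport(scores, set(), "log_rms_mad", k_mad)
        # degenerate spread: fall back to a small absolute deviation floor
        mad = 1e-12
    positions = rec.array.positions()
    flagged = {positions[i] for i in np.nonzero(np.abs(scores - med) > k_mad * mad)[0]}
    return OutlierReport(scores, flagged, "log_rms_mad", k_mad)


def interpolate_outliers(amap, flagged: set[Pos]):
    """Replace flagged map pixels by triangular (Delaunay piecewise-linear)
    interpolation of the non-flagged pixels.

    Flagged pixels outside the convex hull of good pixels take the value of
    the nearest good pixel. Non-flagged pixels are returned bit-exact.
    """
    from .maps import ActivationMap  # local import to avoid a cycle

    flagged = {(int(r), int(c)) for (r, c) in flagged}
    values = np.array(amap.values, dtype=float, copy=True)
    n_rows, n_cols = values.shape
    for r, c in flagged:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValidationError(f"flagged position {(r, c)} outside map")
    if not flagged:
        return amap
    good = [(r, c) for r in range(n_rows) for c in range(n_cols) if (r, c) not in flagged]
    if len(good) < 3:
        raise ValidationError("need at least 3 non-flagged pixels to interpolate")
    pts = np.array(good, dtype=float)
    # collinearity check: rank of centered coordinates must be 2
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValidationError("non-flagged pixels are collinear; cannot triangulate")
    vals = np.array([values[r, c] for r, c in good])
    interp = LinearNDInterpolator(pts, vals)
    bad = np.array(sorted(flagged), dtype=float)
    filled = interp(bad)
    missing = ~np.isfinite(filled)
    if missing.any():  # outside the convex hull: nearest good pixel
        tree = cKDTree(pts)
        _, nearest = tree.query(bad[missing])
        filled[missing] = vals[nearest]
    for (r, c), v in zip(sorted(flagged), filled):
        values[int(r), int(c)] = v
    return ActivationMap(
        values=values,
        window_index=amap.window_index,
        window_ms=amap.window_ms,
        array=amap.array,
        interpolated=set(amap.interpolated) | flagged,
    )
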