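"""Baseline feature sets: intensity, center of gravity, Hudgins time-domain
statistics, and single-differential RMS.

Intensity of a segmented activation map is the log mean pixel value,
I = log10(mean SAM), one value per muscle. The center of gravity is the
intensity-weighted mean (row, col) of a muscle's pixels, two values per
muscle; I + CG over five muscles gives the 15-dimensional ICG vector. The
Hudgins time-domain set (RMS, mean absolute value, zero crossings, waveform
length, slope-sign changes) is computed per channel and PCA-reduced; the
Diff baseline is the RMS of one adjacent-electrode differential signal per
muscle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ElectrodeArray, FeatureVector, ValidationError
from .maps import SegmentedActivationMap
from .spatial_features import PcaReducer, apply_reducer

MUSCLES = ("biceps", "triceps", "brachioradialis", "anconeus", "pronator_teres")
TD_STATS = ("rms", "mav", "zc", "wl", "ssc")


@dataclass
class TdSpec:
    """Deadzone thresholds for the zero-crossing and slope-sign-change counts."""

    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.zc_threshold) and np.isfinite(self.ssc_threshold)):
            raise ValueError("thresholds must be finite")
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ValueError("thresholds must be >= 0")


def intensity(sam: SegmentedActivationMap) -> float:
    """I = log10(mean pixel value) of one muscle's segmented map."""
    vals = sam.values
    mean = vals.mean()
    if mean <= 0:
        raise ValidationError(f"degenerate window: all-zero map for {sam.muscle!r}")
    return float(np.log10(mean))


def center_of_gravity(sam: SegmentedActivationMap) -> tuple[float, float]:
    """Intensity-weighted mean (row, col) of one muscle's pixels."""
    vals = sam.values
    total = vals.sum()
    if total <= 0:
        raise ValidationError(f"zero total intensity for {sam.muscle!r}")
    pos = sam.positions
    cg = (vals[:, None] * pos).sum(axis=0) / total
    return float(cg[0]), float(cg[1])


def intensity_vector(segmented: list[SegmentedActivationMap]) -> FeatureVector:
    """Five per-muscle intensities, tagged I."""
    _check_muscles(segmented)
    names = [f"I_{s.muscle}" for s in segmented]
    values = [intensity(s) for s in segmented]
    return FeatureVector(names=names, values=np.array(values), provenance="I")


def icg_vector(segmented: list[SegmentedActivationMap]) -> FeatureVector:
    """Five intensities + five (row, col) centers of gravity = 15 values."""
    _check_muscles(segmented)
    names, values = [], []
    for s in segmented:
        names.append(f"I_{s.muscle}")
        values.append(intensity(s))
    for s in segmented:
        r, c = center_of_gravity(s)
        names += [f"cg_row_{s.muscle}", f"cg_col_{s.muscle}"]
        values += [r, c]
    return FeatureVector(names=names, values=np.array(values), provenance="ICG")


def _check_muscles(segmented: list[SegmentedActivationMap]) -> None:
    got = {s.muscle for s in segmented}
    if got != set(MUSCLES):
        raise ValidationError(f"expected muscles {sorted(MUSCLES)}, got {sorted(got)}")


def td_features(x: np.ndarray, spec: TdSpec | None = None) -> np.ndarray:
    """Hudgins time-domain statistics of one channel window.

    Returns (RMS, MAV, ZC, WL, SSC). ZC counts sign changes whose amplitude
    step exceeds the deadzone threshold; SSC counts slope-sign changes
    exceeding its threshold.
    """
    spec = spec or TdSpec()
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("window must contain at least 2 samples")
    rms = float(np.sqrt(np.mean(x**2)))
    mav = float(np.mean(np.abs(x)))
    step = np.abs(np.diff(x))
    sign_change = x[:-1] * x[1:] < 0
    zc = int(np.sum(sign_change & (step > spec.zc_threshold)))
    wl = float(np.sum(step))
    if x.size >= 3:
        d1 = x[1:-1] - x[:-2]
        d2 = x[1:-1] - x[2:]
        ssc = int(np.sum((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) > spec.ssc_threshold)))
    else:
        ssc = 0
    return np.array([rms, mav, zc, wl, ssc])


def td_matrix(window: np.ndarray, spec: TdSpec | None = None) -> np.ndarray:
    """Per-channel TD features concatenated channel-major: length 5*n_channels.

    Vectorized across channels; agrees with :func:`td_features` per channel.
    """
    spec = spec or TdSpec()
    x = np.asarray(window, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("window must be (n_channels, >=2 samples)")
    rms = np.sqrt(np.mean(x**2, axis=1))
    mav = np.mean(np.abs(x), axis=1)
    step = np.abs(np.diff(x, axis=1))
    zc = np.sum((x[:, :-1] * x[:, 1:] < 0) & (step > spec.zc_threshold), axis=1)
    wl = np.sum(step, axis=1)
    if x.shape[1] >= 3:
        d1 = x[:, 1:-1] - x[:, :-2]
        d2 = x[:, 1:-1] - x[:, 2:]
        ssc = np.sum(
            (d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) > spec.ssc_threshold), axis=1
        )
    else:
        ssc = np.zeros(x.shape[0])
    return np.column_stack([rms, mav, zc, wl, ssc]).ravel()


def td_set(
    window: np.ndarray, reducer: PcaReducer, spec: TdSpec | None = None
) -> FeatureVector:
    """PCA-reduced per-channel TD features of one window, tagged TD."""
    raw = td_matrix(window, spec)
    reduced = np.atleast_1d(apply_reducer(reducer, raw))
    names = [f"td_pc{i}" for i in range(reducer.n_kept)]
    return FeatureVector(names=names, values=reduced, provenance="TD")


def diff_feature(window: np.ndarray, array: ElectrodeArray, muscle: str) -> float:
    """RMS of the single-differential signal of one muscle's electrode pair."""
    if muscle not in array.diff_pairs:
        raise ValidationError(f"array {array.name!r} has no diff pair for {muscle!r}")
    a, b = array.diff_pairs[muscle]
    idx = array.channel_index()
    diff = window[idx[a]] - window[idx[b]]
    return float(np.sqrt(np.mean(np.asarray(diff, dtype=float) ** 2)))


def diff_vector(
    windows_by_array: dict[str, np.ndarray], arrays: dict[str, ElectrodeArray]
) -> FeatureVector:
    """Five single-differential RMS values (one per muscle), tagged Diff."""
    names, values = [], []
    for muscle in MUSCLES:
        for arr_name, array in arrays.items():
            if muscle in array.diff_pairs:
                names.append(f"diff_{muscle}")
                values.append(diff_feature(windows_by_array[arr_name], array, muscle))
                break
        else:
            raise ValidationError(f"no array provides a diff pair for {muscle!r}")
    return FeatureVector(names=names, values=np.array(values), provenance="Diff")
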