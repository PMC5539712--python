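"""Synthetic HD-EMG forward model.

Surface EMG is modeled as band-limited Gaussian noise (4th-order
Butterworth-shaped spectrum, 15-350 Hz) whose per-channel standard
deviation follows a task- and effort-dependent spatial topography: each of
five muscles contributes a 2-D Gaussian RMS blob on its electrode array,
mixed by per-task coordination weights and scaled linearly with effort
(% MVC). Sensor noise is added at a configured SNR, and per-channel slow
gain drift emulates electrode-contact changes. Endurance (fatigue) trials
additionally grow the RMS and compress the spectrum linearly over the
trial — the two canonical myoelectric fatigue signs.

The generator only reproduces the second-order statistics the feature
pipeline consumes (spatial RMS topography, band-limited spectra); it does
not model motor-unit action potentials, conduction velocity, or
volume-conductor physics.

Default study conditions mirror the experimental design the pipeline is
meant for: three arrays (two 8x15 upper-arm, one 6x18 forearm), 2048 Hz,
four isometric tasks x three effort levels (10/30/50% MVC) of 10 s each,
plus one endurance trial per task at 50% MVC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data_io import EFFORTS, TASKS, ElectrodeArray, Recording, ValidationError

ARRAY_ORDER = ("biceps", "triceps", "forearm")
SESSIONS = ("short_term", "endurance")


@dataclass
class MuscleBlob:
    """2-D Gaussian RMS profile of one muscle on its array."""

    array: str
    center: tuple[float, float]  # (row, col)
    widths: tuple[float, float]  # (sigma_row, sigma_col)

    def profile(self, n_rows: int, n_cols: int) -> np.ndarray:
        r, c = np.mgrid[0:n_rows, 0:n_cols]
        sr, sc = self.widths
        return np.exp(
            -((r - self.center[0]) ** 2 / (2 * sr**2) + (c - self.center[1]) ** 2 / (2 * sc**2))
        )


def default_arrays() -> dict[str, ElectrodeArray]:
    """Two 8x15 upper-arm arrays and one 6x18 forearm array with ground-truth
    muscle masks and SENIAM-style adjacent diff pairs at the blob centers."""
    upper_mask = {(r, c) for r in range(1, 7) for c in range(2, 13)}
    biceps = ElectrodeArray(
        name="biceps",
        n_rows=8,
        n_cols=15,
        muscle_masks={"biceps": upper_mask},
        diff_pairs={"biceps": ((3, 7), (3, 8))},
    )
    triceps = ElectrodeArray(
        name="triceps",
        n_rows=8,
        n_cols=15,
        muscle_masks={"triceps": set(upper_mask)},
        diff_pairs={"triceps": ((3, 7), (3, 8))},
    )
    forearm = ElectrodeArray(
        name="forearm",
        n_rows=6,
        n_cols=18,
        muscle_masks={
            "brachioradialis": {(r, c) for r in range(6) for c in range(0, 6)},
            "anconeus": {(r, c) for r in range(6) for c in range(6, 12)},
            "pronator_teres": {(r, c) for r in range(6) for c in range(12, 18)},
        },
        diff_pairs={
            "brachioradialis": ((2, 2), (2, 3)),
            "anconeus": ((2, 8), (2, 9)),
            "pronator_teres": ((2, 14), (2, 15)),
        },
    )
    return {"biceps": biceps, "triceps": triceps, "forearm": forearm}


def default_blobs() -> dict[str, MuscleBlob]:
    return {
        "biceps": MuscleBlob("biceps", (3.5, 7.0), (1.6, 2.8)),
        "triceps": MuscleBlob("triceps", (3.5, 7.0), (1.6, 2.8)),
        "brachioradialis": MuscleBlob("forearm", (2.5, 2.5), (1.3, 1.6)),
        "anconeus": MuscleBlob("forearm", (2.5, 8.5), (1.3, 1.6)),
        "pronator_teres": MuscleBlob("forearm", (2.5, 14.5), (1.3, 1.6)),
    }


def default_coordination() -> dict[str, dict[str, float]]:
    """Per-task muscle activation weights; each task has a distinct agonist."""
    return {
        "flexion": {
            "biceps": 1.00, "triceps": 0.20, "brachioradialis": 0.45,
            "anconeus": 0.20, "pronator_teres": 0.25,
        },
        "extension": {
            "biceps": 0.20, "triceps": 1.00, "brachioradialis": 0.20,
            "anconeus": 0.45, "pronator_teres": 0.20,
        },
        "supination": {
            "biceps": 0.55, "triceps": 0.20, "brachioradialis": 0.85,
            "anconeus": 0.35, "pronator_teres": 0.20,
        },
        "pronation": {
            "biceps": 0.25, "triceps": 0.25, "brachioradialis": 0.25,
            "anconeus": 0.45, "pronator_teres": 0.95,
        },
    }


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark."""

    arrays: dict[str, ElectrodeArray] = field(default_factory=default_arrays)
    fs: float = 2048.0
    tasks: tuple = TASKS
    efforts: tuple = EFFORTS
    muscle_blobs: dict[str, MuscleBlob] = field(default_factory=default_blobs)
    coordination: dict[str, dict[str, float]] = field(default_factory=default_coordination)
    base_rms_uv: float = 100.0
    noise_band_hz: tuple[float, float] = (15.0, 350.0)
    snr: float = 50.0  # agonist-peak signal amplitude over sensor-noise amplitude
    drift: float = 0.05  # slow per-channel gain modulation amplitude
    fatigue: tuple[float, float] = (0.4, 0.35)  # (rms growth, spectral compression)
    trial_s: float = 10.0
    endurance_trial_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for task in self.tasks:
            weights = self.coordination[task]
            if any(w < 0 for w in weights.values()):
                raise ValidationError("coordination weights must be >= 0")
        argmaxes = [max(self.coordination[t], key=self.coordination[t].get) for t in self.tasks]
        if len(set(argmaxes)) != len(self.tasks):
            raise ValidationError("each task must have a distinct agonist muscle")
        for muscle, blob in self.muscle_blobs.items():
            arr = self.arrays[blob.array]
            r, c = blob.center
            if not (0 <= r <= arr.n_rows - 1 and 0 <= c <= arr.n_cols - 1):
                raise ValidationError(f"blob center of {muscle!r} outside its array")
        if any(rate < 0 for rate in self.fatigue):
            raise ValidationError("fatigue rates must be >= 0")


def _band_noise(rng: np.random.Generator, shape: tuple, fs: float, low: float, high: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, per channel."""
    w = rng.standard_normal(shape)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, w, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def channel_amplitudes(cfg: SynthConfig, task: str, effort: int) -> dict[str, np.ndarray]:
    """Per-array vector of signal RMS amplitudes (row-major channel order)."""
    weights = cfg.coordination[task]
    out = {}
    for a_name in cfg.arrays:
        arr = cfg.arrays[a_name]
        topo = np.zeros((arr.n_rows, arr.n_cols))
        for muscle, blob in cfg.muscle_blobs.items():
            if blob.array == a_name:
                topo += weights.get(muscle, 0.0) * blob.profile(arr.n_rows, arr.n_cols)
        out[a_name] = (cfg.base_rms_uv * (effort / 50.0) * topo).ravel()
    return out


def _trial_rng(cfg: SynthConfig, task: str, effort: int, session: str, replicate: int) -> np.random.Generator:
    t_idx = list(cfg.tasks).index(task)
    s_idx = SESSIONS.index(session)
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), t_idx, int(effort), s_idx, int(replicate)])
    )


def generate_trial(
    cfg: SynthConfig,
    task: str,
    effort: int,
    session: str = "short_term",
    replicate: int = 0,
) -> dict[str, Recording]:
    """One labeled trial: a Recording per electrode array, simultaneous.

    Deterministic per (cfg.seed, task, effort, session, replicate).
    Endurance trials apply the fatigue model (RMS gain growing and the upper
    band edge shrinking linearly over the trial, in 1 s blocks).
    """
    if task not in cfg.tasks:
        raise ValidationError(f"unknown task {task!r}")
    if effort not in cfg.efforts:
        raise ValidationError(f"unknown effort {effort!r}")
    if session not in SESSIONS:
        raise ValidationError(f"unknown session {session!r}")
    rng = _trial_rng(cfg, task, effort, session, replicate)
    duration = cfg.endurance_trial_s if session == "endurance" else cfg.trial_s
    n = int(round(duration * cfg.fs))
    low, high = cfg.noise_band_hz
    amps = channel_amplitudes(cfg, task, effort)
    noise_sd = cfg.base_rms_uv / cfg.snr
    growth, compression = cfg.fatigue if session == "endurance" else (0.0, 0.0)
    recordings = {}
    for a_name in cfg.arrays:
        arr = cfg.arrays[a_name]
        n_ch = arr.n_channels
        if session == "endurance" and (growth > 0 or compression > 0):
            block = int(round(cfg.fs))  # 1 s fatigue blocks
            parts = []
            for start in range(0, n, block):
                m = min(block, n - start)
                t_mid = (start + m / 2) / cfg.fs
                frac = t_mid / duration
                hi = max(high * (1 - compression * frac), low * 2)
                x = _band_noise(rng, (n_ch, m), cfg.fs, low, hi)
                parts.append(x * (1.0 + growth * frac))
            sig = np.concatenate(parts, axis=1)
        else:
            sig = _band_noise(rng, (n_ch, n), cfg.fs, low, high)
        sig = sig * amps[a_name][:, None]
        if cfg.drift > 0:
            # drift is an electrode-contact property: phases are fixed per
            # (session, array), shared across the session's trials
            a_idx = list(cfg.arrays).index(a_name)
            drift_rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.seed), SESSIONS.index(session), a_idx, 97])
            )
            t = np.arange(n) / cfg.fs
            phase = drift_rng.uniform(0, 2 * np.pi, size=n_ch)
            sig = sig * (1.0 + cfg.drift * np.sin(2 * np.pi * 0.05 * t[None, :] + phase[:, None]))
        sensor = noise_sd * _band_noise(rng, (n_ch, n), cfg.fs, low, high)
        recordings[a_name] = Recording(
            samples=sig + sensor,
            fs=cfg.fs,
            array=arr,
            task=task,
            effort_pct_mvc=effort,
            session=session,
        )
    return recordings


@dataclass
class Benchmark:
    """Everything needed to run every evaluation protocol end to end."""

    short_term: list[dict[str, Recording]]
    endurance: list[dict[str, Recording]]
    arrays: dict[str, ElectrodeArray]
    config: SynthConfig


def generate_benchmark(cfg: SynthConfig | None = None) -> Benchmark:
    """Default benchmark: 4 tasks x 3 efforts short-term trials plus one
    endurance trial per task at 50% MVC. Ground-truth muscle masks and diff
    pairs travel with the arrays."""
    cfg = cfg or SynthConfig()
    short_term = [
        generate_trial(cfg, task, effort, "short_term")
        for task in cfg.tasks
        for effort in cfg.efforts
    ]
    endurance = [generate_trial(cfg, task, 50, "endurance") for task in cfg.tasks]
    return Benchmark(short_term=short_term, endurance=endurance, arrays=cfg.arrays, config=cfg)


def single_blob_map(
    rng: np.random.Generator,
    n_rows: int = 8,
    n_cols: int = 15,
    center: tuple[int, int] | None = None,
    snr: float = 5.0,
    sigma: float = 2.0,
    jitter: float = 0.04,
):
    """A synthetic single-blob activation map for mode-recovery experiments.

    Emulates one real RMS window: a flat sensor-noise floor of unit level
    with multiplicative estimation jitter (RMS over ~300 samples varies by
    a few percent) plus a Gaussian blob whose peak is ``snr`` times the
    floor. Returns (map, center).
    """
    from .maps import ActivationMap
    from .data_io import ElectrodeArray

    if center is None:
        center = (int(rng.integers(1, n_rows - 1)), int(rng.integers(1, n_cols - 1)))
    r, c = np.mgrid[0:n_rows, 0:n_cols]
    blob = snr * np.exp(-((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2 * sigma**2))
    floor = np.abs(1.0 + jitter * rng.standard_normal((n_rows, n_cols)))
    values = (1.0 + blob) * floor
    arr = ElectrodeArray(name="synthetic_blob", n_rows=n_rows, n_cols=n_cols)
    amap = ActivationMap(values=values, window_index=0, window_ms=150.0, array=arr)
    return amap, center
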