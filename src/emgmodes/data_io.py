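"""Domain types and on-disk formats shared by all pipeline stages.

A recording is a channel x sample matrix of monopolar HD-EMG (microvolts)
plus an electrode-array layout. Matrices are stored in HDF5 (dataset
``"emg"``) or, as a fallback, delimited text; all metadata (sampling rate,
array geometry, muscle masks, outliers, labels) lives in a JSON sidecar next
to the data file. Feature tables are plain CSV.

Coordinate convention (shared by every module): electrode positions are
0-based ``(row, col)``; channels are flattened row-major over ``(row, col)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Pos = tuple[int, int]

TASKS = ("extension", "flexion", "pronation", "supination")
EFFORTS = (10, 30, 50)
FEATURE_SETS = ("IMS", "ICG", "I", "TD", "Diff")


class FormatError(ValueError):
    """A file on disk does not match the expected layout."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


def _as_pos(p: Iterable[int]) -> Pos:
    r, c = p
    return (int(r), int(c))


@dataclass
class ElectrodeArray:
    """Geometry of one 2-D electrode grid plus its muscle segmentation.

    ``muscle_masks`` maps muscle names to sets of ``(row, col)`` positions;
    ``diff_pairs`` maps muscle names to an ordered pair of adjacent positions
    used for the single-differential baseline feature.
    """

    name: str
    n_rows: int
    n_cols: int
    inter_electrode_mm: float = 10.0
    muscle_masks: dict[str, set[Pos]] = field(default_factory=dict)
    outlier_channels: set[Pos] = field(default_factory=set)
    diff_pairs: dict[str, tuple[Pos, Pos]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValidationError("array dimensions must be positive")
        if self.inter_electrode_mm <= 0:
            raise ValidationError("inter-electrode distance must be positive")
        self.muscle_masks = {
            m: {_as_pos(p) for p in mask} for m, mask in self.muscle_masks.items()
        }
        self.outlier_channels = {_as_pos(p) for p in self.outlier_channels}
        self.diff_pairs = {
            m: (_as_pos(a), _as_pos(b)) for m, (a, b) in self.diff_pairs.items()
        }
        for pos in self.outlier_channels:
            self._check_pos(pos, "outlier")
        for m, mask in self.muscle_masks.items():
            if not mask:
                raise ValidationError(f"muscle mask {m!r} is empty")
            for pos in mask:
                self._check_pos(pos, f"mask {m!r}")
        masks = list(self.muscle_masks.values())
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if masks[i] & masks[j]:
                    raise ValidationError("muscle masks must be disjoint")
        for m, (a, b) in self.diff_pairs.items():
            self._check_pos(a, f"diff pair {m!r}")
            self._check_pos(b, f"diff pair {m!r}")
            if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
                raise ValidationError(
                    f"diff pair for {m!r} must be two distinct adjacent electrodes"
                )

    def _check_pos(self, pos: Pos, what: str) -> None:
        r, c = pos
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise ValidationError(f"{what} position {pos} outside {self.n_rows}x{self.n_cols} grid")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def positions(self) -> list[Pos]:
        """All electrode positions in row-major order."""
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def channel_index(self) -> dict[Pos, int]:
        """Bijection (row, col) -> matrix row, row-major."""
        return {pos: i for i, pos in enumerate(self.positions())}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "inter_electrode_mm": self.inter_electrode_mm,
            "muscle_masks": {m: sorted(mask) for m, mask in self.muscle_masks.items()},
            "outlier_channels": sorted(self.outlier_channels),
            "diff_pairs": {m: [list(a), list(b)] for m, (a, b) in self.diff_pairs.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ElectrodeArray":
        return cls(
            name=d["name"],
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            inter_electrode_mm=float(d.get("inter_electrode_mm", 10.0)),
            muscle_masks={m: {_as_pos(p) for p in v} for m, v in d.get("muscle_masks", {}).items()},
            outlier_channels={_as_pos(p) for p in d.get("outlier_channels", [])},
            diff_pairs={
                m: (_as_pos(a), _as_pos(b)) for m, (a, b) in d.get("diff_pairs", {}).items()
            },
        )


@dataclass
class Recording:
    """One monopolar HD-EMG recording on a single electrode array.

    ``samples`` has shape (n_channels, n_samples) in microvolts; channel i is
    the electrode at the i-th row-major position of ``array``.
    """

    samples: np.ndarray
    fs: float
    array: ElectrodeArray
    task: str | None = None
    effort_pct_mvc: int | None = None
    subject: str = "synthetic"
    session: str = "short_term"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (channels x samples) matrix")
        if self.samples.shape[0] != self.array.n_channels:
            raise ValidationError(
                f"{self.samples.shape[0]} channels but array has {self.array.n_channels} positions"
            )
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValidationError("samples contain non-finite values")
        if self.effort_pct_mvc is not None and self.effort_pct_mvc not in EFFORTS:
            raise ValidationError(f"effort must be one of {EFFORTS}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, pos: Pos) -> np.ndarray:
        return self.samples[self.array.channel_index()[_as_pos(pos)]]


@dataclass
class FeatureVector:
    """Named feature values extracted from one time window."""

    names: list[str]
    values: np.ndarray
    provenance: str = "IMS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.names) != self.values.size:
            raise ValidationError("names and values differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite feature values")


@dataclass
class LabeledDataset:
    """A feature table with task/effort labels, one row per time window."""

    feature_names: list[str]
    X: np.ndarray  # (n_obs, n_features)
    task_labels: np.ndarray
    effort_labels: np.ndarray
    window_index: np.ndarray
    source_ids: np.ndarray
    provenance: str = "IMS"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValidationError("feature matrix does not match feature names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")
        n = self.X.shape[0]
        for arr_name in ("task_labels", "effort_labels", "window_index", "source_ids"):
            arr = np.asarray(getattr(self, arr_name))
            if arr.shape != (n,):
                raise ValidationError(f"{arr_name} length != number of observations")
            setattr(self, arr_name, arr)

    def __len__(self) -> int:
        return self.X.shape[0]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.feature_names.index(n) for n in names]
        return self.X[:, idx]

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            feature_names=list(self.feature_names),
            X=self.X[rows],
            task_labels=self.task_labels[rows],
            effort_labels=self.effort_labels[rows],
            window_index=self.window_index[rows],
            source_ids=self.source_ids[rows],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["task"] = self.task_labels
        df["effort_pct_mvc"] = self.effort_labels
        df["window_index"] = self.window_index
        df["source_id"] = self.source_ids
        return df


def from_frame(df: pd.DataFrame, provenance: str = "IMS") -> LabeledDataset:
    label_cols = ["task", "effort_pct_mvc", "window_index", "source_id"]
    feature_names = [c for c in df.columns if c not in label_cols]
    return LabeledDataset(
        feature_names=feature_names,
        X=df[feature_names].to_numpy(dtype=float),
        task_labels=df["task"].to_numpy(),
        effort_labels=df["effort_pct_mvc"].to_numpy(),
        window_index=df["window_index"].to_numpy(),
        source_ids=df["source_id"].to_numpy(),
        provenance=provenance,
    )


def concat_datasets(datasets: Sequence[LabeledDataset]) -> LabeledDataset:
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.feature_names != first.feature_names:
            raise ValidationError("datasets have differing feature-name lists")
    return LabeledDataset(
        feature_names=list(first.feature_names),
        X=np.vstack([ds.X for ds in datasets]),
        task_labels=np.concatenate([ds.task_labels for ds in datasets]),
        effort_labels=np.concatenate([ds.effort_labels for ds in datasets]),
        window_index=np.concatenate([ds.window_index for ds in datasets]),
        source_ids=np.concatenate([ds.source_ids for ds in datasets]),
        provenance=first.provenance,
    )


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path) -> Path:
    """Write a recording to HDF5 (or CSV if the path ends in .csv) + JSON sidecar."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory {path.parent} does not exist")
    if not np.isfinite(rec.samples).all():
        raise ValidationError("refusing to write non-finite samples")
    if path.suffix == ".csv":
        np.savetxt(path, rec.samples, delimiter=",", fmt="%.17g")
    else:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("emg", data=rec.samples)
    meta = {
        "fs": rec.fs,
        "array": rec.array.to_dict(),
        "task": rec.task,
        "effort_pct_mvc": rec.effort_pct_mvc,
        "subject": rec.subject,
        "session": rec.session,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if path.suffix == ".csv":
        samples = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        import h5py

        with h5py.File(path, "r") as f:
            if "emg" not in f:
                raise FormatError('HDF5 file has no "emg" dataset')
            samples = f["emg"][()]
    array = ElectrodeArray.from_dict(meta["array"])
    effort = meta.get("effort_pct_mvc")
    return Recording(
        samples=samples,
        fs=float(meta["fs"]),
        array=array,
        task=meta.get("task"),
        effort_pct_mvc=int(effort) if effort is not None else None,
        subject=meta.get("subject", "unknown"),
        session=meta.get("session", "short_term"),
    )


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

def write_feature_table(ds: LabeledDataset, path, window_metadata: bool = True) -> Path:
    """Write the dataset as CSV: feature columns plus task/effort labels.

    With ``window_metadata=True`` (default) the window index and source
    recording id are stored too, which the long-term and fatigue protocols
    need. Values round-trip to at least 12 significant digits.
    """
    path = Path(path)
    df = ds.to_frame()
    if not window_metadata:
        df = df.drop(columns=["window_index", "source_id"])
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path, provenance: str = "IMS") -> LabeledDataset:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:  # ragged rows etc.
        raise FormatError(str(e)) from e
    if not {"task", "effort_pct_mvc"}.issubset(df.columns):
        raise FormatError("feature table missing task/effort label columns")
    if "window_index" not in df.columns:
        df["window_index"] = np.arange(len(df))
    if "source_id" not in df.columns:
        df["source_id"] = ""
    return from_frame(df, provenance=provenance)
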