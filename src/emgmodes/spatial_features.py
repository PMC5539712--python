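"""Mean-shift spatial features from HD-EMG activation maps.

This is the package's core method. Each activation map is turned into a
3-D point cloud — one point per electrode, coordinates (x = column,
y = row, v = RMS intensity) — standardized to zero mean and unit variance
per dimension so that a single spherical bandwidth applies to all three.
Flat-kernel mean shift then seeks the modes of the underlying density:

    y_{i+1} = mean{ x_j : ||x_j - y_i|| <= h }

iterated to a fixed point from every data point, with converged centroids
within h of each other merged. The bandwidth h is data driven: the k-th
nearest-neighbour distance (k = 50% of the points, self excluded) averaged
over all points, times a bandwidth factor (0.5 by default).

Each detected mode is snapped to the nearest electrode, giving a binary
image per array with one nonzero entry per mode (collisions merge). The
binary images of all arrays, flattened row-major and concatenated, form the
spatial feature vector, which PCA reduces at 90% cumulative explained
variance. Concatenating the reduced spatial vector with the five per-muscle
log-intensity features yields the IMS feature vector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .data_io import ElectrodeArray, FeatureVector, ValidationError
from .maps import ActivationMap, SegmentedActivationMap


@dataclass
class MapPointCloud:
    """Standardized (x, y, v) points of one activation map.

    ``transform`` holds the per-dimension (mean, std) used for
    standardization; degenerate (zero-variance) dimensions are centered but
    not scaled (std recorded as 1).
    """

    points: np.ndarray  # (n, 3) standardized
    transform: np.ndarray  # (2, 3): row 0 means, row 1 stds
    source: str = ""

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class BandwidthSpec:
    """k-NN bandwidth rule: h = factor * mean over points of the k-th
    nearest-neighbour distance, k = round(k_fraction * n)."""

    k_fraction: float = 0.5
    factor: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.k_fraction <= 1):
            raise ValueError("k_fraction must lie in (0, 1]")
        if self.factor <= 0:
            raise ValueError("bandwidth factor must be positive")


@dataclass
class ModeSet:
    """Converged mean-shift modes (standardized space) and bookkeeping."""

    modes: np.ndarray  # (n_modes, dim)
    densities: np.ndarray  # points within h of each mode
    h: float
    tol: float
    converged: np.ndarray  # bool per mode
    grid: np.ndarray | None = None  # filled by modes_to_grid

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


def to_point_cloud(amap: ActivationMap) -> MapPointCloud:
    """One point per pixel: (x = col, y = row, v = intensity), standardized."""
    n_rows, n_cols = amap.values.shape
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    raw = np.column_stack([cols.ravel(), rows.ravel(), amap.values.ravel()]).astype(float)
    means = raw.mean(axis=0)
    stds = raw.std(axis=0)
    stds_safe = np.where(stds > 0, stds, 1.0)  # degenerate dims: center only
    points = (raw - means) / stds_safe
    transform = np.vstack([means, stds_safe])
    return MapPointCloud(points=points, transform=transform, source=amap.array.name)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_bandwidth(cloud: MapPointCloud, spec: BandwidthSpec | None = None) -> float:
    """Average k-th nearest-neighbour distance (self excluded) times the factor."""
    spec = spec or BandwidthSpec()
    pts = cloud.points
    n = pts.shape[0]
    if n < 2:
        raise ValidationError("bandwidth estimation needs at least 2 points")
    k = min(max(_round_half_up(spec.k_fraction * n), 1), n - 1)
    d = cdist(pts, pts)
    d_sorted = np.sort(d, axis=1)  # column 0 is the self distance (0)
    kth = d_sorted[:, k]
    h = spec.factor * float(kth.mean())
    if h <= 0:
        raise ValidationError("all points identical: zero bandwidth")
    return h


def mean_shift(
    cloud: MapPointCloud,
    h: float,
    tol: float | None = None,
    max_iter: int = 300,
) -> ModeSet:
    """Flat-kernel mean shift seeded deterministically from every data point.

    Each seed iterates y <- mean of points within distance h of y; with the
    flat kernel the iteration reaches an exact fixed point in finitely many
    steps (the within-h membership set stabilises), so seeds are run to
    machine-precision convergence, well inside ``tol`` (default 1e-3 * h,
    the guaranteed fixed-point accuracy). Converged centroids within h of
    each other are merged, keeping the representative supported by the most
    points (ties broken by seed order). Seeds that hit ``max_iter`` are
    kept but flagged.
    """
    if h <= 0:
        raise ValidationError("bandwidth must be positive")
    tol = 1e-3 * h if tol is None else tol
    step_tol = min(tol, 1e-10 * h)
    pts = cloud.points
    n = pts.shape[0]
    Y = pts.copy()
    active = np.ones(n, dtype=bool)
    n_iter = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        if not active.any():
            break
        d = cdist(Y[active], pts)
        within = d <= h
        counts = within.sum(axis=1)
        counts = np.maximum(counts, 1)  # every seed is itself a data point
        new = within @ pts / counts[:, None]
        step = np.linalg.norm(new - Y[active], axis=1)
        idx = np.nonzero(active)[0]
        Y[idx] = new
        n_iter[idx] += 1
        active[idx[step <= step_tol]] = False
    if active.any():
        warnings.warn(f"{active.sum()} mean-shift seeds did not converge in {max_iter} iterations")
    seed_converged = ~active

    # merge centroids within h, keeping the densest representative
    density = (cdist(Y, pts) <= h).sum(axis=1)
    order = np.argsort(-density, kind="stable")
    modes: list[np.ndarray] = []
    mode_density: list[int] = []
    mode_conv: list[bool] = []
    for i in order:
        if any(np.linalg.norm(Y[i] - m) <= h for m in modes):
            continue
        modes.append(Y[i])
        mode_density.append(int(density[i]))
        mode_conv.append(bool(seed_converged[i]))
    return ModeSet(
        modes=np.array(modes),
        densities=np.array(mode_density),
        h=h,
        tol=tol,
        converged=np.array(mode_conv),
    )


def modes_to_grid(ms: ModeSet, transform: np.ndarray, array: ElectrodeArray) -> np.ndarray:
    """Snap each mode to its nearest electrode; binary grid, one per mode.

    Modes are mapped back from standardized space via the recorded
    (mean, std); only the spatial (x = col, y = row) plane is used for the
    snap — the intensity dimension is ignored. Two modes snapping to the
    same electrode leave a single nonzero entry.
    """
    if ms.n_modes == 0:
        raise ValidationError("mode set is empty")
    grid = np.zeros((array.n_rows, array.n_cols), dtype=int)
    means, stds = transform
    for mode in ms.modes:
        x, y = mode[0] * stds[0] + means[0], mode[1] * stds[1] + means[1]
        col = int(np.clip(_round_half_up(x), 0, array.n_cols - 1))
        row = int(np.clip(_round_half_up(y), 0, array.n_rows - 1))
        grid[row, col] = 1
    ms.grid = grid
    return grid


def mode_grid_for_map(
    amap: ActivationMap, spec: BandwidthSpec | None = None
) -> np.ndarray:
    """Convenience: map -> cloud -> bandwidth -> mean shift -> binary grid."""
    cloud = to_point_cloud(amap)
    h = estimate_bandwidth(cloud, spec)
    ms = mean_shift(cloud, h)
    return modes_to_grid(ms, cloud.transform, amap.array)


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class PcaReducer:
    """PCA basis keeping the smallest number of components whose cumulative
    explained-variance fraction reaches ``var_threshold`` (default 0.90)."""

    component_basis: np.ndarray  # (n_kept, n_features)
    variance_fractions: np.ndarray
    n_kept: int
    var_threshold: float
    training_means: np.ndarray

    def to_dict(self) -> dict:
        return {
            "component_basis": self.component_basis.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_kept": self.n_kept,
            "var_threshold": self.var_threshold,
            "training_means": self.training_means.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaReducer":
        return cls(
            component_basis=np.array(d["component_basis"], dtype=float),
            variance_fractions=np.array(d["variance_fractions"], dtype=float),
            n_kept=int(d["n_kept"]),
            var_threshold=float(d["var_threshold"]),
            training_means=np.array(d["training_means"], dtype=float),
        )


def fit_reducer(train_vectors: np.ndarray, var_threshold: float = 0.90) -> PcaReducer:
    """Fit PCA on training vectors only; keep the minimal q with
    cumulative variance >= var_threshold."""
    X = np.asarray(train_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need at least 2 training vectors")
    if not (0 < var_threshold <= 1):
        raise ValueError("var_threshold must lie in (0, 1]")
    total_var = X.var(axis=0).sum()
    if total_var == 0:
        warnings.warn("zero-variance training matrix: reducer keeps no components")
        return PcaReducer(
            component_basis=np.zeros((0, X.shape[1])),
            variance_fractions=np.zeros(0),
            n_kept=0,
            var_threshold=var_threshold,
            training_means=X.mean(axis=0),
        )
    pca = PCA(n_components=min(X.shape)).fit(X)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    n_kept = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_kept = min(n_kept, len(frac))
    return PcaReducer(
        component_basis=pca.components_[:n_kept],
        variance_fractions=frac[:n_kept],
        n_kept=n_kept,
        var_threshold=var_threshold,
        training_means=pca.mean_,
    )


def apply_reducer(reducer: PcaReducer, vectors: np.ndarray) -> np.ndarray:
    """Center by the training means and project onto the kept axes."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[1] != reducer.training_means.size:
        raise ValidationError(
            f"vector length {X.shape[1]} != reducer dimension {reducer.training_means.size}"
        )
    out = (X - reducer.training_means) @ reducer.component_basis.T
    return out[0] if np.asarray(vectors).ndim == 1 else out


# ---------------------------------------------------------------------------
# IMS composition
# ---------------------------------------------------------------------------

def spatial_mode_vector(
    maps: list[ActivationMap], spec: BandwidthSpec | None = None
) -> np.ndarray:
    """Binary mode grids of all arrays, flattened row-major and concatenated.

    The resulting length equals the total channel count over the arrays.
    """
    return np.concatenate([mode_grid_for_map(m, spec).ravel() for m in maps])


def extract_ims(
    maps: list[ActivationMap],
    segmented: list[SegmentedActivationMap],
    reducer: PcaReducer,
    spec: BandwidthSpec | None = None,
) -> FeatureVector:
    """Reduced spatial mode vector + five per-muscle intensities, tagged IMS.

    ``maps`` must be given in the fixed array order used when fitting the
    reducer (biceps array, triceps array, forearm array).
    """
    from .classic_features import intensity  # avoid import cycle

    spatial = spatial_mode_vector(maps, spec)
    reduced = apply_reducer(reducer, spatial)
    names = [f"ms_pc{i}" for i in range(reducer.n_kept)]
    values = list(np.atleast_1d(reduced))
    for sam in segmented:
        names.append(f"I_{sam.muscle}")
        values.append(intensity(sam))
    return FeatureVector(names=names, values=np.array(values), provenance="IMS")
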