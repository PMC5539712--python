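"""LDA classification, the two-step task/effort architecture, and the
short-term, long-term, and fatigue evaluation protocols.

Task identification uses a linear discriminant classifier over a feature
table. High-dimensional feature blocks (binary mode grids, per-channel TD
statistics — column names prefixed ``mode_`` / ``td_``) are PCA-reduced at
90% cumulative variance; reducers and discriminants are always fit on
training rows only. The two-step classifier first identifies the task
(efforts pooled), then the effort level with a per-task classifier
restricted to the muscles involved in that task.

Performance is reported per class as sensitivity S = TP/(TP+FN) and
precision P = TP/(TP+FP), averaged over repeated stratified holdout splits
(70% train, N = 20 by default).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data_io import ElectrodeArray, LabeledDataset, ValidationError
from .spatial_features import PcaReducer, apply_reducer, fit_reducer

#: muscles feeding the effort-level classifier of each task
EFFORT_MUSCLES = {
    "flexion": ("biceps", "triceps"),
    "extension": ("biceps", "triceps"),
    "supination": ("biceps", "brachioradialis", "anconeus"),
    "pronation": ("pronator_teres", "anconeus"),
}

#: arrays whose spatial modes feed the effort-level classifier; forearm
#: muscles always use the modes of the whole forearm array
EFFORT_ARRAYS = {
    "flexion": ("biceps", "triceps"),
    "extension": ("biceps", "triceps"),
    "supination": ("biceps", "forearm"),
    "pronation": ("forearm",),
}

REDUCIBLE_PREFIXES = ("mode_", "td_")

_TD_COL = re.compile(r"^td_(?P<array>.+)_r(?P<r>\d+)_c(?P<c>\d+)_(?P<stat>\w+)$")
_MODE_COL = re.compile(r"^mode_(?P<array>.+)_r\d+_c\d+$")


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """Linear discriminant model with Ledoit-Wolf-shrunk pooled covariance."""

    class_names: list
    class_means: np.ndarray
    pooled_covariance: np.ndarray
    priors: np.ndarray
    feature_names: list[str]
    coef: np.ndarray
    intercept: np.ndarray

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = X @ self.coef.T + self.intercept
        if scores.ndim == 2 and scores.shape[1] == 1:  # binary: sklearn convention
            scores = np.column_stack([-scores[:, 0], scores[:, 0]])
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        # ties broken by class order (class_names are sorted at fit time)
        idx = np.argmax(scores, axis=1)
        return np.asarray(self.class_names, dtype=object)[idx]

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
            "feature_names": list(self.feature_names),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LdaModel":
        return cls(
            class_names=d["class_names"],
            class_means=np.array(d["class_means"], dtype=float),
            pooled_covariance=np.array(d["pooled_covariance"], dtype=float),
            priors=np.array(d["priors"], dtype=float),
            feature_names=list(d["feature_names"]),
            coef=np.array(d["coef"], dtype=float),
            intercept=np.array(d["intercept"], dtype=float),
        )


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    shrinkage: float | str = "auto",
    feature_names: list[str] | None = None,
) -> LdaModel:
    """Fit an LDA with shrinkage-regularized pooled covariance.

    Shrinkage ("auto" = Ledoit-Wolf) keeps the fit well-posed when the
    feature block is rank deficient (e.g. collinear binary mode columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("LDA needs at least 2 classes")
    if (counts < 2).any():
        raise ValidationError("every class needs at least 2 training observations")
    est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage, store_covariance=True)
    est.fit(X, y.astype(str) if y.dtype.kind not in "USO" else y)
    return LdaModel(
        class_names=list(est.classes_),
        class_means=est.means_,
        pooled_covariance=est.covariance_,
        priors=est.priors_,
        feature_names=list(feature_names or [f"f{i}" for i in range(X.shape[1])]),
        coef=np.atleast_2d(est.coef_),
        intercept=np.atleast_1d(est.intercept_),
    )


# ---------------------------------------------------------------------------
# Column handling: PCA block + passthrough
# ---------------------------------------------------------------------------

def split_columns(names: list[str]) -> tuple[list[str], list[str]]:
    """Reducible (mode_/td_) columns vs passthrough columns."""
    reducible = [n for n in names if n.startswith(REDUCIBLE_PREFIXES)]
    passthrough = [n for n in names if not n.startswith(REDUCIBLE_PREFIXES)]
    return reducible, passthrough


@dataclass
class BlockLda:
    """PCA reduction of the high-dimensional block followed by LDA."""

    lda: LdaModel
    reducer: PcaReducer | None
    reducible_cols: list[str]
    passthrough_cols: list[str]

    def transform(self, ds: LabeledDataset) -> np.ndarray:
        parts = []
        if self.reducer is not None and self.reducer.n_kept > 0:
            parts.append(np.atleast_2d(apply_reducer(self.reducer, ds.columns(self.reducible_cols))))
        if self.passthrough_cols:
            parts.append(ds.columns(self.passthrough_cols))
        if not parts:
            raise ValidationError("no usable feature columns")
        return np.hstack(parts)

    def predict(self, ds: LabeledDataset) -> np.ndarray:
        return self.lda.predict(self.transform(ds))

    def to_dict(self) -> dict:
        return {
            "lda": self.lda.to_dict(),
            "reducer": self.reducer.to_dict() if self.reducer is not None else None,
            "reducible_cols": list(self.reducible_cols),
            "passthrough_cols": list(self.passthrough_cols),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockLda":
        return cls(
            lda=LdaModel.from_dict(d["lda"]),
            reducer=PcaReducer.from_dict(d["reducer"]) if d["reducer"] is not None else None,
            reducible_cols=list(d["reducible_cols"]),
            passthrough_cols=list(d["passthrough_cols"]),
        )


def fit_block_lda(
    ds: LabeledDataset,
    rows: np.ndarray,
    labels: np.ndarray,
    columns: list[str] | None = None,
    pca_var: float = 0.90,
) -> BlockLda:
    """Fit PCA (training rows only) on the reducible block, then LDA."""
    columns = list(columns) if columns is not None else list(ds.feature_names)
    reducible, passthrough = split_columns(columns)
    train = ds.subset(rows)
    reducer = None
    parts = []
    if reducible:
        reducer = fit_reducer(train.columns(reducible), var_threshold=pca_var)
        if reducer.n_kept > 0:
            parts.append(np.atleast_2d(apply_reducer(reducer, train.columns(reducible))))
    if passthrough:
        parts.append(train.columns(passthrough))
    if not parts:
        raise ValidationError("no usable feature columns")
    X = np.hstack(parts)
    names = [f"pc{i}" for i in range(parts[0].shape[1])] if reducible and reducer.n_kept else []
    names = names + passthrough if reducible else passthrough
    lda = fit_lda(X, labels, feature_names=names)
    return BlockLda(lda=lda, reducer=reducer, reducible_cols=reducible, passthrough_cols=passthrough)


def select_effort_columns(
    feature_names: list[str],
    task: str,
    arrays: dict[str, ElectrodeArray] | None = None,
) -> list[str]:
    """Feature columns feeding the effort classifier of one task.

    Intensity/CG/Diff columns are filtered by muscle, spatial mode columns
    by array (whole forearm array for supination/pronation), and TD columns
    by membership of the channel in a selected muscle's mask.
    """
    if task not in EFFORT_MUSCLES:
        raise ValidationError(f"unknown task {task!r}")
    muscles = set(EFFORT_MUSCLES[task])
    arr_names = set(EFFORT_ARRAYS[task])
    mask_union: dict[str, set] = {}
    if arrays:
        for a_name, arr in arrays.items():
            mask_union[a_name] = set().union(
                *[m for mu, m in arr.muscle_masks.items() if mu in muscles] or [set()]
            )
    keep = []
    for name in feature_names:
        if name.startswith(("I_", "diff_")):
            muscle = name.split("_", 1)[1]
            if muscle in muscles:
                keep.append(name)
        elif name.startswith(("cg_row_", "cg_col_")):
            muscle = name.split("_", 2)[2]
            if muscle in muscles:
                keep.append(name)
        elif name.startswith("mode_"):
            m = _MODE_COL.match(name)
            if m and m.group("array") in arr_names:
                keep.append(name)
        elif name.startswith("td_"):
            m = _TD_COL.match(name)
            if not m:
                continue
            a_name = m.group("array")
            if a_name not in arr_names:
                continue
            if arrays and a_name in mask_union:
                if (int(m.group("r")), int(m.group("c"))) in mask_union[a_name]:
                    keep.append(name)
            else:
                keep.append(name)
    if not keep:
        raise ValidationError(f"no feature columns selected for task {task!r}")
    return keep


# ---------------------------------------------------------------------------
# Two-step model
# ---------------------------------------------------------------------------

@dataclass
class TwoStepModel:
    """Step 1: task (efforts pooled). Step 2: per-task effort classifier."""

    task_model: BlockLda
    effort_models: dict[str, BlockLda]

    def predict(self, ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
        tasks = self.task_model.predict(ds)
        efforts = np.empty(len(ds), dtype=object)
        for t in np.unique(tasks):
            rows = np.nonzero(tasks == t)[0]
            efforts[rows] = self.effort_models[str(t)].predict(ds.subset(rows))
        return tasks, efforts

    def to_dict(self) -> dict:
        return {
            "task_model": self.task_model.to_dict(),
            "effort_models": {t: m.to_dict() for t, m in self.effort_models.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStepModel":
        return cls(
            task_model=BlockLda.from_dict(d["task_model"]),
            effort_models={t: BlockLda.from_dict(m) for t, m in d["effort_models"].items()},
        )


def fit_two_step(
    train: LabeledDataset,
    arrays: dict[str, ElectrodeArray] | None = None,
    pca_var: float = 0.90,
) -> TwoStepModel:
    """Fit the two-step classifier on a training dataset."""
    tasks = np.unique(train.task_labels)
    if set(tasks.astype(str)) != set(EFFORT_MUSCLES):
        raise ValidationError(f"training set must contain exactly the tasks {sorted(EFFORT_MUSCLES)}")
    all_rows = np.arange(len(train))
    task_model = fit_block_lda(train, all_rows, train.task_labels, pca_var=pca_var)
    effort_models = {}
    for t in tasks:
        rows = np.nonzero(train.task_labels == t)[0]
        cols = select_effort_columns(train.feature_names, str(t), arrays)
        effort_models[str(t)] = fit_block_lda(
            train, rows, train.effort_labels[rows].astype(str), columns=cols, pca_var=pca_var
        )
    return TwoStepModel(task_model=task_model, effort_models=effort_models)


def predict_two_step(model: TwoStepModel, ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(ds)


# ---------------------------------------------------------------------------
# Holdout splitting
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_holdout(
    labels: np.ndarray,
    train_frac: float = 0.70,
    n_rep: int = 20,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified random splits (default 70% train, N = 20).

    Per class the train count is round-half-up(train_frac * n_class),
    clamped to leave at least one observation on each side; a deterministic
    adjustment pass then nudges counts (smallest fractional part first,
    later-sorted classes first on ties) so the global train count equals
    round-half-up(train_frac * n_total).
    """
    labels = np.asarray(labels)
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValidationError("every class needs at least 2 observations to split")
    targets = {}
    frac_part = {}
    for cls_name, n_c in zip(classes, counts):
        raw = train_frac * n_c
        targets[cls_name] = min(max(_round_half_up(raw), 1), n_c - 1)
        frac_part[cls_name] = raw - math.floor(raw)
    global_target = _round_half_up(train_frac * labels.size)
    order_dec = sorted(classes, key=lambda c: (frac_part[c], -list(classes).index(c)))
    order_inc = sorted(classes, key=lambda c: (-frac_part[c], list(classes).index(c)))
    count_of = dict(zip(classes, counts))
    i = 0
    while sum(targets.values()) > global_target:
        c = order_dec[i % len(classes)]
        if targets[c] > 1:
            targets[c] -= 1
        i += 1
    i = 0
    while sum(targets.values()) < global_target:
        c = order_inc[i % len(classes)]
        if targets[c] < count_of[c] - 1:
            targets[c] += 1
        i += 1
    splits = []
    for rep in range(n_rep):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        train_idx, test_idx = [], []
        for cls_name in classes:
            rows = np.nonzero(labels == cls_name)[0]
            perm = rng.permutation(rows)
            n_train = targets[cls_name]
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        splits.append((np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))))
    return splits


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    classes: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValidationError("confusion matrix must be a non-negative classes x classes grid")


def confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: list) -> ConfusionMatrix:
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts)


def metrics(cm: ConfusionMatrix) -> dict:
    """Per-class sensitivity S = TP/(TP+FN) and precision P = TP/(TP+FP).

    P is NaN for a class that is never predicted.
    """
    tp = np.diag(cm.counts).astype(float)
    row = cm.counts.sum(axis=1).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(row > 0, tp / row, np.nan)
        P = np.where(col > 0, tp / col, np.nan)
    return {c: (S[i], P[i]) for i, c in enumerate(cm.classes)}


@dataclass
class EvalResult:
    """Confusion matrices over repetitions plus summary S/P statistics."""

    protocol: str
    classes: list
    confusions: list[ConfusionMatrix]
    sensitivity: np.ndarray = field(init=False)  # (n_rep, n_classes)
    precision: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S, P = [], []
        for cm in self.confusions:
            m = metrics(cm)
            S.append([m[c][0] for c in self.classes])
            P.append([m[c][1] for c in self.classes])
        self.sensitivity = np.array(S)
        self.precision = np.array(P)

    @property
    def n_rep(self) -> int:
        return len(self.confusions)

    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    def mean_precision(self) -> float:
        return float(np.nanmean(self.precision))

    def summary(self) -> dict:
        return {
            "protocol": self.protocol,
            "classes": [str(c) for c in self.classes],
            "n_rep": self.n_rep,
            "sensitivity_mean": np.nanmean(self.sensitivity, axis=0).tolist(),
            "sensitivity_std": np.nanstd(self.sensitivity, axis=0).tolist(),
            "precision_mean": np.nanmean(self.precision, axis=0).tolist(),
            "precision_std": np.nanstd(self.precision, axis=0).tolist(),
            "mean_sensitivity": self.mean_sensitivity(),
            "mean_precision": self.mean_precision(),
        }


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

def evaluate_task(
    ds: LabeledDataset,
    n_rep: int = 20,
    train_frac: float = 0.70,
    seed: int = 0,
    pca_var: float = 0.90,
    permute_labels: bool = False,
    protocol: str = "short_term",
) -> EvalResult:
    """Task identification (efforts pooled) by repeated stratified holdout.

    ``permute_labels=True`` shuffles the task labels independently in each
    repetition before splitting/training — the chance-level control.
    """
    labels = ds.task_labels.astype(str)
    classes = sorted(np.unique(labels))
    splits = stratified_holdout(labels, train_frac, n_rep, seed)
    cms = []
    for rep, (tr, te) in enumerate(splits):
        y = labels
        if permute_labels:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10_000 + rep]))
            y = rng.permutation(labels)
        model = fit_block_lda(ds, tr, y[tr], pca_var=pca_var)
        pred = model.predict(ds.subset(te))
        cms.append(confusion(y[te], pred, classes))
    return EvalResult(protocol=protocol, classes=classes, confusions=cms)


def joint_label(task, effort) -> str:
    return f"{task}@{effort}"


def evaluate_two_step(
    ds: LabeledDataset,
    arrays: dict[str, ElectrodeArray] | None = None,
    n_rep: int = 20,
    train_frac: float = 0.70,
    seed: int = 0,
    pca_var: float = 0.90,
) -> EvalResult:
    """Joint task + effort identification with the two-step classifier.

    Scored on the 12 joint (task, effort) classes; a step-1 task error
    propagates, as the effort is then decided by the wrong task's model.
    """
    joint = np.array([joint_label(t, e) for t, e in zip(ds.task_labels, ds.effort_labels)])
    classes = sorted(np.unique(joint))
    splits = stratified_holdout(joint, train_frac, n_rep, seed)
    cms = []
    for tr, te in splits:
        model = fit_two_step(ds.subset(tr), arrays=arrays, pca_var=pca_var)
        t_pred, e_pred = model.predict(ds.subset(te))
        pred = np.array([joint_label(t, e) for t, e in zip(t_pred, e_pred)])
        cms.append(confusion(joint[te], pred, classes))
    return EvalResult(protocol="short_term_two_step", classes=classes, confusions=cms)


def evaluate_long_term(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    test_seconds: float = 2.0,
    window_ms: float = 150.0,
    pca_var: float = 0.90,
) -> EvalResult:
    """Train on one session, test on the first seconds of a later session.

    Only the first ``test_seconds`` of each test recording are used
    (floor(test_seconds / window_s) windows), limiting fatigue
    contamination; a single train/test evaluation, no resampling.
    """
    max_windows = int(test_seconds * 1000.0 / window_ms)
    keep = np.nonzero(test_ds.window_index < max_windows)[0]
    if keep.size == 0:
        raise ValidationError("restricted test set is empty")
    test = test_ds.subset(keep)
    labels = train_ds.task_labels.astype(str)
    classes = sorted(np.unique(labels))
    model = fit_block_lda(train_ds, np.arange(len(train_ds)), labels, pca_var=pca_var)
    pred = model.predict(test)
    cm = confusion(test.task_labels.astype(str), pred, classes)
    return EvalResult(protocol="long_term", classes=classes, confusions=[cm])


def epoch_of_windows(ds: LabeledDataset, n_epochs: int) -> np.ndarray:
    """Equal-duration epoch index of each observation, per source recording."""
    epochs = np.zeros(len(ds), dtype=int)
    for src in np.unique(ds.source_ids):
        rows = np.nonzero(ds.source_ids == src)[0]
        n_win = ds.window_index[rows].max() + 1
        epochs[rows] = np.minimum(
            (ds.window_index[rows] * n_epochs) // max(n_win, 1), n_epochs - 1
        )
    return epochs


def evaluate_fatigue(
    endurance: LabeledDataset,
    n_epochs: int = 5,
    pca_var: float = 0.90,
) -> list[EvalResult]:
    """Train on the first epoch (0-20% of the recording duration), test on
    every epoch; returns one single-repetition EvalResult per epoch."""
    if n_epochs < 2:
        raise ValueError("n_epochs must be >= 2")
    labels = endurance.task_labels.astype(str)
    classes = sorted(np.unique(labels))
    epochs = epoch_of_windows(endurance, n_epochs)
    train_rows = np.nonzero(epochs == 0)[0]
    model = fit_block_lda(endurance, train_rows, labels[train_rows], pca_var=pca_var)
    results = []
    for e in range(n_epochs):
        rows = np.nonzero(epochs == e)[0]
        pred = model.predict(endurance.subset(rows))
        cm = confusion(labels[rows], pred, classes)
        results.append(EvalResult(protocol=f"fatigue_epoch_{e}", classes=classes, confusions=[cm]))
    return results
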