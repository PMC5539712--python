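"""End-to-end orchestration: simulate -> preprocess -> maps -> features ->
train -> evaluate, with reproducible JSON reports.

``extract_features`` is the workhorse used by every protocol: it filters
each trial, screens outlier channels, windows the recordings, builds the
per-window activation maps of the three arrays, and emits a labeled feature
table for the requested feature set (IMS, ICG, I, TD or Diff). The
high-dimensional blocks of IMS (binary mode grids) and TD (per-channel
statistics) are stored unreduced with provenance-bearing column names;
PCA happens inside classification, fit on training rows only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify_eval
from .classic_features import (
    MUSCLES,
    TD_STATS,
    TdSpec,
    center_of_gravity,
    diff_feature,
    intensity,
    td_matrix,
)
from .data_io import (
    FEATURE_SETS,
    ElectrodeArray,
    LabeledDataset,
    Recording,
    ValidationError,
    concat_datasets,
)
from .maps import rms_map, segment_map, window_recording
from .preprocess import FilterSpec, bandpass, detect_outliers
from .spatial_features import BandwidthSpec, mode_grid_for_map
from .synth import ARRAY_ORDER, Benchmark, SynthConfig, generate_benchmark


def trial_source_id(recs: dict[str, Recording]) -> str:
    r = next(iter(recs.values()))
    return f"{r.session}:{r.task}:{r.effort_pct_mvc}"


def _feature_names(
    feature_set: str, arrays: dict[str, ElectrodeArray], array_order: tuple
) -> list[str]:
    if feature_set == "I":
        return [f"I_{m}" for m in MUSCLES]
    if feature_set == "ICG":
        names = [f"I_{m}" for m in MUSCLES]
        for m in MUSCLES:
            names += [f"cg_row_{m}", f"cg_col_{m}"]
        return names
    if feature_set == "Diff":
        return [f"diff_{m}" for m in MUSCLES]
    if feature_set == "TD":
        names = []
        for a in array_order:
            arr = arrays[a]
            for r in range(arr.n_rows):
                for c in range(arr.n_cols):
                    names += [f"td_{a}_r{r}_c{c}_{s}" for s in TD_STATS]
        return names
    if feature_set == "IMS":
        names = []
        for a in array_order:
            arr = arrays[a]
            names += [
                f"mode_{a}_r{r}_c{c}" for r in range(arr.n_rows) for c in range(arr.n_cols)
            ]
        return names + [f"I_{m}" for m in MUSCLES]
    raise ValidationError(f"unknown feature set {feature_set!r} (choose from {FEATURE_SETS})")


def extract_features(
    trials: list[dict[str, Recording]],
    feature_set: str = "IMS",
    window_ms: float = 150.0,
    filter_spec: FilterSpec | None = None,
    bandwidth: BandwidthSpec | None = None,
    td_spec: TdSpec | None = None,
    auto_outliers: bool = True,
    ms_scale: bool = False,
    array_order: tuple = ARRAY_ORDER,
) -> LabeledDataset:
    """Labeled per-window feature table over a list of simultaneous trials."""
    filter_spec = filter_spec or FilterSpec()
    bandwidth = bandwidth or BandwidthSpec()
    datasets = []
    for trial in trials:
        arrays = {a: trial[a].array for a in array_order}
        names = _feature_names(feature_set, arrays, array_order)
        meta = next(iter(trial.values()))
        windows_by_array = {}
        outliers_by_array = {}
        for a in array_order:
            rec = bandpass(trial[a], filter_spec)
            flagged = set(rec.array.outlier_channels)
            if auto_outliers:
                flagged |= detect_outliers(rec).flagged
            outliers_by_array[a] = flagged
            windows_by_array[a] = window_recording(rec, window_ms)
        n_windows = min(len(w) for w in windows_by_array.values())
        rows = []
        for w in range(n_windows):
            maps = {
                a: rms_map(
                    windows_by_array[a][w],
                    arrays[a],
                    window_index=w,
                    window_ms=window_ms,
                    extra_outliers=outliers_by_array[a],
                    ms_scale=ms_scale,
                )
                for a in array_order
            }
            segmented = {s.muscle: s for a in array_order for s in segment_map(maps[a])}
            values: list[float] = []
            if feature_set == "I":
                values = [intensity(segmented[m]) for m in MUSCLES]
            elif feature_set == "ICG":
                values = [intensity(segmented[m]) for m in MUSCLES]
                for m in MUSCLES:
                    values += list(center_of_gravity(segmented[m]))
            elif feature_set == "Diff":
                for m in MUSCLES:
                    a = next(a for a in array_order if m in arrays[a].diff_pairs)
                    values.append(diff_feature(windows_by_array[a][w], arrays[a], m))
            elif feature_set == "TD":
                for a in array_order:
                    values += list(td_matrix(windows_by_array[a][w], td_spec))
            elif feature_set == "IMS":
                for a in array_order:
                    values += list(mode_grid_for_map(maps[a], bandwidth).ravel())
                values += [intensity(segmented[m]) for m in MUSCLES]
            rows.append(values)
        n = len(rows)
        datasets.append(
            LabeledDataset(
                feature_names=names,
                X=np.array(rows, dtype=float),
                task_labels=np.array([meta.task] * n, dtype=object),
                effort_labels=np.array([meta.effort_pct_mvc] * n),
                window_index=np.arange(n),
                source_ids=np.array([trial_source_id(trial)] * n, dtype=object),
                provenance=feature_set,
            )
        )
    return concat_datasets(datasets)


# ---------------------------------------------------------------------------
# Pipeline configuration and runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved parameters of a full simulate-to-report run."""

    seed: int = 0
    feature_set: str = "IMS"
    protocol: str = "short_term"  # short_term | two_step | long_term | fatigue
    window_ms: float = 150.0
    filter_low_hz: float = 15.0
    filter_high_hz: float = 350.0
    filter_order: int = 4
    bandwidth_factor: float = 0.5
    k_fraction: float = 0.5
    pca_var: float = 0.90
    train_frac: float = 0.70
    n_rep: int = 20
    n_epochs: int = 5
    test_seconds: float = 2.0
    trial_s: float = 10.0
    endurance_trial_s: float = 30.0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _benchmark_hash(bench: Benchmark) -> str:
    h = hashlib.sha256()
    for trial in bench.short_term + bench.endurance:
        for a in sorted(trial):
            h.update(np.ascontiguousarray(trial[a].samples).tobytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, report_path=None) -> dict:
    """Execute the full pipeline on the synthetic benchmark and return the
    report dict (optionally written as deterministic JSON)."""
    synth_cfg = SynthConfig(
        seed=cfg.seed, trial_s=cfg.trial_s, endurance_trial_s=cfg.endurance_trial_s
    )
    bench = generate_benchmark(synth_cfg)
    fspec = FilterSpec(order=cfg.filter_order, low_hz=cfg.filter_low_hz, high_hz=cfg.filter_high_hz)
    bw = BandwidthSpec(k_fraction=cfg.k_fraction, factor=cfg.bandwidth_factor)

    def features(trials):
        return extract_features(
            trials,
            feature_set=cfg.feature_set,
            window_ms=cfg.window_ms,
            filter_spec=fspec,
            bandwidth=bw,
        )

    if cfg.protocol == "short_term":
        ds = features(bench.short_term)
        result = classify_eval.evaluate_task(
            ds, n_rep=cfg.n_rep, train_frac=cfg.train_frac, seed=cfg.seed, pca_var=cfg.pca_var
        )
        results = [result.summary()]
    elif cfg.protocol == "two_step":
        ds = features(bench.short_term)
        result = classify_eval.evaluate_two_step(
            ds,
            arrays=bench.arrays,
            n_rep=cfg.n_rep,
            train_frac=cfg.train_frac,
            seed=cfg.seed,
            pca_var=cfg.pca_var,
        )
        results = [result.summary()]
    elif cfg.protocol == "long_term":
        train_ds = features(bench.short_term)
        test_ds = features(bench.endurance)
        result = classify_eval.evaluate_long_term(
            train_ds, test_ds, test_seconds=cfg.test_seconds,
            window_ms=cfg.window_ms, pca_var=cfg.pca_var,
        )
        results = [result.summary()]
    elif cfg.protocol == "fatigue":
        ds = features(bench.endurance)
        per_epoch = classify_eval.evaluate_fatigue(ds, n_epochs=cfg.n_epochs, pca_var=cfg.pca_var)
        results = [r.summary() for r in per_epoch]
    else:
        raise ValidationError(f"unknown protocol {cfg.protocol!r}")

    report = {
        "config": asdict(cfg),
        "input_sha256": _benchmark_hash(bench),
        "results": results,
    }
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
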