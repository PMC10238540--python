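"""Area-ratio performance metric and leave-one-out cross-validation.

The continuous decoder index is scored per trial as a duration-weighted
mean of per-window correct-area ratios:

    %PI = 100 * sum_i (t_i / t_T) * A_i

where the sum runs over the effective analysis windows, t_i is each
window's duration, t_T their total, and A_i the mean index value inside
the window (for target-1 windows) or the mean of one minus the index (for
target-0 windows).  Transition spans never enter the metric because only
epochs fully contained in a window contribute.

Leave-one-out evaluation holds out one trial at a time: CSP filters,
feature standardization and classifiers are refitted on the remaining
trials, the held-out trial's continuous epochs are decoded and smoothed,
and %PI is computed against its effective windows.  For the attention
paradigm the same fold's motor-imagery models supply the cascade gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import (
    CascadeModel,
    LDAModel,
    fit_cascade,
    fit_lda,
    predict_binary,
    predict_cascade,
)
from .errors import EvaluationError, EvaluationWarning
from .features import (
    ATT_BANDS,
    DEFAULT_EPOCH_LENGTH,
    DEFAULT_M,
    DEFAULT_SHIFT,
    MI_BANDS,
    FeatureModel,
    FilterBankSpec,
    apply_filter_bank,
    design_filter_bank,
    epoch_signal,
    extract_features_from_covariances,
    fit_feature_model_from_covariances,
)
from .index import DEFAULT_SMOOTHING_K, IndexTrace, smooth_index
from .io import DatasetLayout, TrialRef, read_trial, slopes_condition_semantics
from .protocol import (
    AnalysisWindow,
    ProtocolSpec,
    assign_targets,
    experience_windows,
    extract_events,
    slopes_windows,
)

_CONTAIN_TOL = 1e-9


@dataclass
class PIMetric:
    """Eq.-style area-ratio accuracy for one trial."""

    n_periods: int
    durations: np.ndarray
    total_time: float
    area_ratios: np.ndarray
    pi_percent: float
    skipped: list[str] = field(default_factory=list)


def compute_pi(trace: IndexTrace, windows: list[AnalysisWindow]) -> PIMetric:
    """Duration-weighted correct-area ratio of an index over targeted windows.

    Windows that contain no fully-enclosed epoch are skipped with a warning
    and excluded from the total analyzed time.
    """
    durations, ratios, skipped = [], [], []
    starts = np.asarray(trace.starts)
    ends = starts + trace.epoch_length
    for w in windows:
        if w.target is None:
            raise EvaluationError(f"window {w.task!r} has no target; run assign_targets first")
        inside = (starts >= w.start - _CONTAIN_TOL) & (ends <= w.end + _CONTAIN_TOL)
        if not inside.any():
            msg = f"window {w.task!r} [{w.start:.2f}, {w.end:.2f}] s contains no epoch; skipped"
            warnings.warn(msg, EvaluationWarning, stacklevel=2)
            skipped.append(msg)
            continue
        values = trace.values[inside]
        ratios.append(float(np.mean(values if w.target == 1 else 1.0 - values)))
        durations.append(w.duration)

    durations = np.asarray(durations)
    ratios = np.asarray(ratios)
    total = float(durations.sum())
    pi = 100.0 * float(np.sum(durations / total * ratios)) if total > 0 else float("nan")
    return PIMetric(
        n_periods=len(durations),
        durations=durations,
        total_time=total,
        area_ratios=ratios,
        pi_percent=pi,
        skipped=skipped,
    )


@dataclass
class PipelineConfig:
    """Every tunable of the decoding pipeline, with the standard defaults."""

    mi_bands: tuple[tuple[float, float], ...] = MI_BANDS
    att_bands: tuple[tuple[float, float], ...] = ATT_BANDS
    filter_order: int = 4
    causal: bool = True
    epoch_length: float = DEFAULT_EPOCH_LENGTH
    shift: float = DEFAULT_SHIFT
    m: int = DEFAULT_M
    smoothing_k: int = DEFAULT_SMOOTHING_K
    lda_ridge: float = 1e-6
    log_variance: bool = False
    gate: str = "raw"  # "raw" epoch decisions or "smoothed" MI index >= 0.5
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)


@dataclass
class LOOResult:
    """Per-fold %PI values and their per-subject summary."""

    scenario: str
    paradigm: str
    subject_id: str
    fold_trials: list[tuple[int, int]]
    fold_pi: np.ndarray
    train_sizes: list[int]
    mean: float
    sd: float
    traces: list[IndexTrace] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.fold_pi)


def _summary_stats(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


@dataclass
class _TrialData:
    """Precomputed per-trial material shared by all folds."""

    ref: TrialRef
    windows: dict[str, list[AnalysisWindow]]          # paradigm -> targeted windows
    labeled_covs: dict[str, dict]                     # paradigm -> band -> (n, C, C)
    labeled_targets: dict[str, np.ndarray]
    labeled_tasks: dict[str, list[str]]
    continuous_covs: dict[str, dict]
    continuous_starts: np.ndarray
    epoch_length: float
    shift: float


def _prepare_trial(
    ref: TrialRef,
    scenario: str,
    paradigms: list[str],
    config: PipelineConfig,
) -> _TrialData:
    recording, meta = read_trial(ref.csv_path, ref.json_path)
    fs = meta.sampling_rate
    events = extract_events(recording.labels, meta)
    if scenario == "experience":
        base_windows = experience_windows(events, config.protocol, fs)
    else:
        base_windows = slopes_windows(events, config.protocol, fs)

    banks = {"mi": config.mi_bands, "att": config.att_bands}
    needed = set(paradigms) | ({"mi"} if "att" in paradigms else set())

    windows, labeled_covs, labeled_targets, labeled_tasks, continuous_covs = {}, {}, {}, {}, {}
    continuous_starts = None
    for paradigm in sorted(needed):
        spec = FilterBankSpec(bands=banks[paradigm], order=config.filter_order, causal=config.causal)
        bank = design_filter_bank(spec, fs)
        filtered = apply_filter_bank(recording, bank)
        targeted = assign_targets(base_windows, paradigm)
        labeled, continuous = epoch_signal(
            filtered, targeted, config.epoch_length, config.shift, fs
        )
        windows[paradigm] = targeted
        labeled_covs[paradigm] = labeled.covariances()
        labeled_targets[paradigm] = labeled.targets
        labeled_tasks[paradigm] = list(labeled.tasks)
        continuous_covs[paradigm] = continuous.covariances()
        continuous_starts = continuous.starts
    return _TrialData(
        ref=ref,
        windows=windows,
        labeled_covs=labeled_covs,
        labeled_targets=labeled_targets,
        labeled_tasks=labeled_tasks,
        continuous_covs=continuous_covs,
        continuous_starts=continuous_starts,
        epoch_length=config.epoch_length,
        shift=config.shift,
    )


def _stack_covs(trials: list[_TrialData], paradigm: str) -> tuple[dict, np.ndarray, np.ndarray]:
    bands = list(trials[0].labeled_covs[paradigm])
    covs = {
        band: np.concatenate([t.labeled_covs[paradigm][band] for t in trials]) for band in bands
    }
    targets = np.concatenate([t.labeled_targets[paradigm] for t in trials])
    tasks = np.concatenate([np.asarray(t.labeled_tasks[paradigm], dtype=object) for t in trials])
    return covs, targets, tasks


def _fit_mi_models(
    train: list[_TrialData], config: PipelineConfig
) -> tuple[FeatureModel, LDAModel]:
    covs, targets, _ = _stack_covs(train, "mi")
    feature_model, train_feats = fit_feature_model_from_covariances(
        covs, targets, m=config.m, log_variance=config.log_variance
    )
    lda = fit_lda(train_feats, targets, ridge=config.lda_ridge)
    return feature_model, lda


def _mi_decisions(
    trial: _TrialData, feature_model: FeatureModel, lda: LDAModel
) -> np.ndarray:
    feats = extract_features_from_covariances(trial.continuous_covs["mi"], feature_model)
    return predict_binary(lda, feats)


def _fit_att_models(
    train: list[_TrialData], config: PipelineConfig
) -> tuple[FeatureModel, CascadeModel]:
    covs, targets, tasks = _stack_covs(train, "att")
    feature_model, train_feats = fit_feature_model_from_covariances(
        covs, targets, m=config.m, log_variance=config.log_variance
    )
    cascade = fit_cascade(train_feats, tasks)
    return feature_model, cascade


def _loo(
    trials: list[_TrialData],
    fold_refs: list[TrialRef],
    scenario: str,
    paradigm: str,
    subject_id: str,
    config: PipelineConfig,
) -> LOOResult:
    fold_pi, fold_ids, train_sizes, traces = [], [], [], []
    by_ref = {t.ref: t for t in trials}
    for ref in fold_refs:
        test = by_ref[ref]
        train = [t for t in trials if t.ref != ref]
        if paradigm == "mi":
            feature_model, lda = _fit_mi_models(train, config)
            decisions = _mi_decisions(test, feature_model, lda)
        else:
            feature_model, cascade = _fit_att_models(train, config)
            mi_feature_model, mi_lda = _fit_mi_models(train, config)
            gate = _mi_decisions(test, mi_feature_model, mi_lda)
            if config.gate == "smoothed":
                gate_trace = smooth_index(
                    gate, k=config.smoothing_k, starts=test.continuous_starts,
                    epoch_length=config.epoch_length, shift=config.shift, paradigm="mi",
                )
                gate = (gate_trace.values >= 0.5).astype(int)
            feats = extract_features_from_covariances(test.continuous_covs["att"], feature_model)
            decisions = predict_cascade(cascade, feats, gate)
        trace = smooth_index(
            decisions,
            k=config.smoothing_k,
            starts=test.continuous_starts,
            epoch_length=config.epoch_length,
            shift=config.shift,
            paradigm=paradigm,
        )
        metric = compute_pi(trace, test.windows[paradigm])
        fold_pi.append(metric.pi_percent)
        fold_ids.append((ref.condition, ref.run))
        train_sizes.append(len(train))
        traces.append(trace)
    mean, sd = _summary_stats(np.asarray(fold_pi))
    return LOOResult(
        scenario=scenario,
        paradigm=paradigm,
        subject_id=subject_id,
        fold_trials=fold_ids,
        fold_pi=np.asarray(fold_pi),
        train_sizes=train_sizes,
        mean=mean,
        sd=sd,
        traces=traces,
    )


def loo_experience(
    layout: DatasetLayout, paradigm: str, config: PipelineConfig | None = None
) -> LOOResult:
    """Leave-one-out evaluation over the sixteen mental-task trials.

    Baseline conditions 1 and 2 are ignored; every condition-3 trial is
    tested once with models trained on the remaining ones.
    """
    config = config or PipelineConfig()
    if config.protocol.scenario != "experience":
        config = replace(config, protocol=replace(config.protocol, scenario="experience"))
    refs = layout.select(condition=3)
    if len(refs) < 2:
        raise EvaluationError(
            f"leave-one-out needs at least 2 condition-3 trials, found {len(refs)}"
        )
    if len(refs) != 16:
        warnings.warn(
            f"expected 16 condition-3 trials, found {len(refs)}; evaluating anyway",
            EvaluationWarning,
            stacklevel=2,
        )
    trials = [_prepare_trial(ref, "experience", [paradigm], config) for ref in refs]
    return _loo(trials, refs, "experience", paradigm, layout.subject_id, config)


def loo_slopes(
    layout: DatasetLayout, paradigm: str, config: PipelineConfig | None = None
) -> LOOResult:
    """Leave-one-out evaluation over the ramp trials.

    The MI paradigm folds over the eight motor-imagery trials (odd
    conditions), each trained on the other seven; the attention paradigm
    folds over all sixteen trials.
    """
    config = config or PipelineConfig()
    if config.protocol.scenario != "slopes":
        config = replace(config, protocol=replace(config.protocol, scenario="slopes"))
    refs = layout.trials
    if not refs:
        raise EvaluationError("empty slopes layout")
    mi_refs = [r for r in refs if slopes_condition_semantics(r.condition, r.run)[1] == "mi"]
    if paradigm == "mi":
        if len(mi_refs) < 2:
            raise EvaluationError(f"need at least 2 MI trials, found {len(mi_refs)}")
        if len(mi_refs) != 8:
            warnings.warn(
                f"expected 8 MI trials, found {len(mi_refs)}",
                EvaluationWarning,
                stacklevel=2,
            )
        trials = [_prepare_trial(ref, "slopes", ["mi"], config) for ref in mi_refs]
        return _loo(trials, mi_refs, "slopes", "mi", layout.subject_id, config)
    if len(refs) != 16:
        warnings.warn(
            f"expected 16 slopes trials, found {len(refs)}",
            EvaluationWarning,
            stacklevel=2,
        )
    trials = [_prepare_trial(ref, "slopes", ["att"], config) for ref in refs]
    return _loo(trials, refs, "slopes", "att", layout.subject_id, config)


def summarize(results: list[LOOResult]) -> pd.DataFrame:
    """Per-subject mean +/- SD table with grand averages per scenario/paradigm.

    Mirrors the conventional accuracy-table layout: one row per
    (scenario, paradigm, subject) plus an ``average`` row per
    scenario/paradigm group.  Single-fold results carry ``single_fold``
    True and SD 0.
    """
    if not results:
        return pd.DataFrame(
            columns=["scenario", "paradigm", "subject", "n_folds", "mean_pi", "sd_pi", "single_fold"]
        )
    rows = [
        {
            "scenario": r.scenario,
            "paradigm": r.paradigm,
            "subject": r.subject_id,
            "n_folds": r.n_folds,
            "mean_pi": r.mean,
            "sd_pi": r.sd,
            "single_fold": r.n_folds == 1,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    averages = []
    for (scenario, paradigm), group in table.groupby(["scenario", "paradigm"], sort=True):
        means = group["mean_pi"].to_numpy()
        averages.append(
            {
                "scenario": scenario,
                "paradigm": paradigm,
                "subject": "average",
                "n_folds": int(group["n_folds"].sum()),
                "mean_pi": float(np.mean(means)),
                "sd_pi": float(np.std(means, ddof=1)) if len(means) > 1 else 0.0,
                "single_fold": bool((group["n_folds"] == 1).all()),
            }
        )
    return pd.concat([table, pd.DataFrame(averages)], ignore_index=True)
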