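"""Filter-bank decomposition, epoching, CSP spatial filtering and features.

The feature path is shared by both paradigms: the 27-channel EEG is passed
through a causal Butterworth band-pass bank (four alpha/beta bands for the
motor-imagery paradigm, six gamma sub-bands for the attention paradigm),
cut into 1.5 s epochs advanced every 0.5 s, spatially filtered per band
with two-class Common Spatial Patterns, and summarized per epoch as the
z-scored variance of the first and last ``m`` CSP components.

CSP solves the simultaneous diagonalization of the two class-mean
covariances: whiten with the composite covariance, then rotate onto the
eigenbasis of the whitened class-1 covariance.  Columns are sorted by
class-1 eigenvalue (descending), so the leading filters maximize class-1
variance and the trailing ones class-0 variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .errors import AlignmentError, EpochWarning, FilterDesignError, TrainingError
from .io import N_EEG, Recording
from .protocol import AnalysisWindow

#: Default motor-imagery bank covering the alpha and beta rhythms (Hz).
MI_BANDS: tuple[tuple[float, float], ...] = ((8.0, 12.0), (12.0, 18.0), (18.0, 24.0), (24.0, 30.0))
#: Default attention bank: six gamma sub-bands, skipping 48-52 Hz because
#: the recordings carry a 50 Hz notch.
ATT_BANDS: tuple[tuple[float, float], ...] = (
    (30.0, 36.0), (36.0, 42.0), (42.0, 48.0), (52.0, 58.0), (58.0, 64.0), (64.0, 70.0),
)

DEFAULT_EPOCH_LENGTH = 1.5  # s
DEFAULT_SHIFT = 0.5         # s
DEFAULT_M = 4               # CSP components kept per side


@dataclass(frozen=True)
class FilterBankSpec:
    """Band edges plus filter family parameters for one bank."""

    bands: tuple[tuple[float, float], ...]
    order: int = 4
    causal: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        previous_low = -np.inf
        for low, high in self.bands:
            if not 0.0 < low < high:
                raise FilterDesignError(f"band edges must satisfy 0 < low < high, got ({low}, {high})")
            if high >= nyquist:
                raise FilterDesignError(
                    f"band ({low}, {high}) Hz exceeds the Nyquist frequency "
                    f"{nyquist} Hz at {sampling_rate} Hz sampling"
                )
            if low < previous_low:
                raise FilterDesignError("bands must be ordered by their low edge")
            previous_low = low


@dataclass
class FilterBank:
    """Realized second-order-section filters for one sampling rate.

    The filters are causal (forward-only) by default and need a short
    convergence time after onset; the protocol's 5 s lead-in covers it.
    """

    spec: FilterBankSpec
    sampling_rate: float
    sos: dict[tuple[float, float], np.ndarray]

    @property
    def bands(self) -> tuple[tuple[float, float], ...]:
        return self.spec.bands


def design_filter_bank(spec: FilterBankSpec, sampling_rate: float) -> FilterBank:
    """Design one causal Butterworth band-pass filter per band."""
    spec.validate(sampling_rate)
    sos = {
        band: scipy.signal.butter(
            spec.order, band, btype="bandpass", fs=sampling_rate, output="sos"
        )
        for band in spec.bands
    }
    return FilterBank(spec=spec, sampling_rate=sampling_rate, sos=sos)


def apply_filter_bank(
    recording: Recording | np.ndarray, bank: FilterBank
) -> dict[tuple[float, float], np.ndarray]:
    """Band-pass the 27 EEG channels; EOG is never filtered or used here."""
    data = recording.eeg if isinstance(recording, Recording) else np.asarray(recording)
    if data.ndim != 2 or data.shape[1] != N_EEG:
        raise AlignmentError(f"expected a (samples, {N_EEG}) EEG matrix, got shape {data.shape}")
    out = {}
    for band, sos in bank.sos.items():
        if bank.spec.causal:
            out[band] = scipy.signal.sosfilt(sos, data, axis=0)
        else:
            out[band] = scipy.signal.sosfiltfilt(sos, data, axis=0)
    return out


@dataclass
class EpochSet:
    """Per-band epoch tensors with aligned timing and labels.

    ``band_data`` maps each band to an (n_epochs, n_channels, n_samples)
    array.  ``targets`` holds the paradigm target per epoch (NaN when the
    epoch is outside every analysis window); ``tasks`` the task name or
    ``None``.  Labeled sets are tiled from each window's start; continuous
    sets tile the whole trial for index rendering.
    """

    band_data: dict[tuple[float, float], np.ndarray]
    starts: np.ndarray
    tasks: list[str | None]
    targets: np.ndarray
    epoch_length: float
    shift: float
    sampling_rate: float
    _covariances: dict[tuple[float, float], np.ndarray] | None = field(default=None, repr=False)

    @property
    def n_epochs(self) -> int:
        return len(self.starts)

    @property
    def bands(self) -> tuple[tuple[float, float], ...]:
        return tuple(self.band_data)

    def covariances(self) -> dict[tuple[float, float], np.ndarray]:
        """Per-epoch mean-removed channel covariances, (n_epochs, C, C) per band.

        The same stack backs CSP fitting (after trace normalization) and the
        projected-variance features, since var(w'x) = w' Cov(x) w.
        """
        if self._covariances is None:
            covs = {}
            for band, data in self.band_data.items():
                centered = data - data.mean(axis=2, keepdims=True)
                denom = max(data.shape[2] - 1, 1)
                covs[band] = np.einsum("ecs,eds->ecd", centered, centered) / denom
            self._covariances = covs
        return self._covariances


def _epoch_starts(t0: float, t1: float, epoch_length: float, shift: float) -> np.ndarray:
    n = int(np.floor((t1 - t0 - epoch_length) / shift + 1e-9)) + 1
    if n <= 0:
        return np.empty(0)
    return t0 + shift * np.arange(n)


def _slice_epochs(
    filtered: dict[tuple[float, float], np.ndarray],
    starts: np.ndarray,
    n_per_epoch: int,
    sampling_rate: float,
) -> dict[tuple[float, float], np.ndarray]:
    out = {}
    for band, data in filtered.items():
        idx = np.round(starts * sampling_rate).astype(int)
        epochs = np.stack([data[i : i + n_per_epoch].T for i in idx]) if len(idx) else np.empty(
            (0, data.shape[1], n_per_epoch)
        )
        out[band] = epochs
    return out


def epoch_signal(
    filtered: dict[tuple[float, float], np.ndarray],
    windows: list[AnalysisWindow],
    epoch_length: float = DEFAULT_EPOCH_LENGTH,
    shift: float = DEFAULT_SHIFT,
    sampling_rate: float = 200.0,
) -> tuple[EpochSet, EpochSet]:
    """Cut band-filtered signal into labeled and continuous epoch sets.

    Returns ``(labeled, continuous)``.  Labeled epochs are tiled from each
    window's start and inherit its task and target; only epochs fully
    inside a window are labeled.  The continuous set tiles the whole trial
    from t = 0 regardless of windows, for index rendering.
    """
    if epoch_length <= 0 or shift <= 0:
        raise AlignmentError("epoch_length and shift must be positive")
    n_samples = next(iter(filtered.values())).shape[0]
    n_per_epoch = int(round(epoch_length * sampling_rate))
    duration = n_samples / sampling_rate

    lab_starts, lab_tasks, lab_targets = [], [], []
    for w in windows:
        starts = _epoch_starts(w.start, w.end, epoch_length, shift)
        if len(starts) == 0:
            warnings.warn(
                f"window {w.task!r} of {w.duration:.2f} s is shorter than one "
                f"{epoch_length} s epoch; no labeled epochs",
                EpochWarning,
                stacklevel=2,
            )
            continue
        lab_starts.append(starts)
        lab_tasks.extend([w.task] * len(starts))
        lab_targets.append(np.full(len(starts), np.nan if w.target is None else w.target))
    lab_starts = np.concatenate(lab_starts) if lab_starts else np.empty(0)
    lab_targets = np.concatenate(lab_targets) if lab_targets else np.empty(0)

    labeled = EpochSet(
        band_data=_slice_epochs(filtered, lab_starts, n_per_epoch, sampling_rate),
        starts=lab_starts,
        tasks=lab_tasks,
        targets=lab_targets,
        epoch_length=epoch_length,
        shift=shift,
        sampling_rate=sampling_rate,
    )

    cont_starts = _epoch_starts(0.0, duration, epoch_length, shift)
    continuous = EpochSet(
        band_data=_slice_epochs(filtered, cont_starts, n_per_epoch, sampling_rate),
        starts=cont_starts,
        tasks=[None] * len(cont_starts),
        targets=np.full(len(cont_starts), np.nan),
        epoch_length=epoch_length,
        shift=shift,
        sampling_rate=sampling_rate,
    )
    return labeled, continuous


@dataclass
class CSPModel:
    """Fitted spatial filters for one band.

    ``filters`` columns are the spatial filters sorted by class-1
    eigenvalue descending; ``eigenvalues`` are the class-1 generalized
    eigenvalues (class-0 eigenvalues are their complement to 1);
    ``selected`` are the first-``m`` and last-``m`` column indices kept.
    """

    band: tuple[float, float] | None
    filters: np.ndarray
    eigenvalues: np.ndarray
    selected: np.ndarray
    m: int


def _mean_normalized_cov(covs: np.ndarray) -> np.ndarray:
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise TrainingError("zero-variance epoch encountered while averaging covariances")
    return (covs / traces[:, None, None]).mean(axis=0)


def csp_from_covariances(
    covs0: np.ndarray,
    covs1: np.ndarray,
    m: int = DEFAULT_M,
    band: tuple[float, float] | None = None,
    ridge: float = 1e-8,
) -> CSPModel:
    """Fit two-class CSP from per-epoch covariance stacks.

    Each epoch covariance is trace-normalized before class averaging.  The
    composite covariance is whitened (ridge-regularized if near-singular)
    and the whitened class-1 covariance diagonalized; the returned filters
    satisfy W' (C0 + C1) W = I.
    """
    for covs, label in ((covs0, "class 0"), (covs1, "class 1")):
        if covs.ndim != 3 or covs.shape[1] != covs.shape[2]:
            raise TrainingError(f"{label} covariances must be (n, C, C), got {covs.shape}")
        if covs.shape[0] < 2:
            raise TrainingError(f"need at least 2 epochs for {label}, got {covs.shape[0]}")
    n_channels = covs0.shape[1]
    if n_channels < 2 * m:
        raise TrainingError(f"{n_channels} channels cannot support 2m = {2 * m} CSP components")

    c0 = _mean_normalized_cov(covs0)
    c1 = _mean_normalized_cov(covs1)
    composite = c0 + c1

    eigvals, eigvecs = scipy.linalg.eigh(composite)
    if eigvals[0] <= eigvals[-1] * 1e-10:
        composite = composite + ridge * np.trace(composite) / n_channels * np.eye(n_channels)
        eigvals, eigvecs = scipy.linalg.eigh(composite)
        if eigvals[0] <= 0:
            raise TrainingError("composite covariance not positive definite after regularization")
    whitener = eigvecs / np.sqrt(eigvals)

    s1 = whitener.T @ c1 @ whitener
    s1 = (s1 + s1.T) / 2.0
    mu, rotation = scipy.linalg.eigh(s1)
    order = np.argsort(mu)[::-1]
    filters = whitener @ rotation[:, order]
    eigenvalues = mu[order]

    selected = np.concatenate([np.arange(m), np.arange(n_channels - m, n_channels)])
    return CSPModel(band=band, filters=filters, eigenvalues=eigenvalues, selected=selected, m=m)


def fit_csp(epochs: EpochSet, band: tuple[float, float], m: int = DEFAULT_M) -> CSPModel:
    """Fit CSP for one band from a labeled two-class epoch set."""
    covs = epochs.covariances()[band]
    targets = np.asarray(epochs.targets)
    mask0, mask1 = targets == 0, targets == 1
    if not (mask0.any() and mask1.any()):
        raise TrainingError("fit_csp needs epochs of both classes (targets 0 and 1)")
    return csp_from_covariances(covs[mask0], covs[mask1], m=m, band=band)


def csp_variances(covs: np.ndarray, model: CSPModel) -> np.ndarray:
    """Variance of each selected CSP component, from epoch covariances."""
    if covs.shape[1] != model.filters.shape[0]:
        raise AlignmentError(
            f"epochs have {covs.shape[1]} channels, CSP model expects {model.filters.shape[0]}"
        )
    w = model.filters[:, model.selected]
    return np.einsum("ck,ecd,dk->ek", w, covs, w)


@dataclass
class FeatureModel:
    """Per-band CSP models plus the training standardization parameters."""

    csp: dict[tuple[float, float], CSPModel]
    mean: np.ndarray
    std: np.ndarray
    columns: list[str]
    m: int
    log_variance: bool = False


def _raw_features(
    covariances: dict[tuple[float, float], np.ndarray],
    csp_models: dict[tuple[float, float], CSPModel],
    log_variance: bool,
) -> np.ndarray:
    blocks = [csp_variances(covariances[band], model) for band, model in csp_models.items()]
    feats = np.hstack(blocks)
    if log_variance:
        feats = np.log(np.maximum(feats, np.finfo(float).tiny))
    return feats


def fit_feature_model_from_covariances(
    covariances: dict[tuple[float, float], np.ndarray],
    targets: np.ndarray,
    m: int = DEFAULT_M,
    log_variance: bool = False,
) -> tuple[FeatureModel, np.ndarray]:
    """Fit per-band CSP + feature standardization from covariance stacks.

    Returns the fitted model and the standardized training feature matrix.
    """
    targets = np.asarray(targets)
    mask0, mask1 = targets == 0, targets == 1
    if not (mask0.any() and mask1.any()):
        raise TrainingError("feature fitting needs both target classes present")
    csp_models = {
        band: csp_from_covariances(covs[mask0], covs[mask1], m=m, band=band)
        for band, covs in covariances.items()
    }
    feats = _raw_features(covariances, csp_models, log_variance)
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    columns = [
        f"{band[0]:g}-{band[1]:g}Hz_csp{idx}"
        for band, model in csp_models.items()
        for idx in model.selected
    ]
    model = FeatureModel(
        csp=csp_models, mean=mean, std=std, columns=columns, m=m, log_variance=log_variance
    )
    return model, (feats - mean) / std


def fit_feature_model(
    epochs: EpochSet, m: int = DEFAULT_M, log_variance: bool = False
) -> tuple[FeatureModel, np.ndarray]:
    """Fit the filter-bank CSP feature extractor on a labeled epoch set."""
    return fit_feature_model_from_covariances(
        epochs.covariances(), epochs.targets, m=m, log_variance=log_variance
    )


def extract_features_from_covariances(
    covariances: dict[tuple[float, float], np.ndarray], model: FeatureModel
) -> np.ndarray:
    """Standardized variance features for epoch covariance stacks."""
    missing = set(model.csp) - set(covariances)
    if missing:
        raise AlignmentError(f"epoch set lacks bands required by the model: {sorted(missing)}")
    feats = _raw_features(covariances, model.csp, model.log_variance)
    return (feats - model.mean) / model.std


def extract_features(epochs: EpochSet, model: FeatureModel) -> np.ndarray:
    """Standardized variance features, one row per epoch."""
    return extract_features_from_covariances(epochs.covariances(), model)
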