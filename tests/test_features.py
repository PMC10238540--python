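"""Filter bank, epoching, CSP and standardized-variance feature contracts."""

import numpy as np
import pytest
import scipy.linalg

from exodecode import (
    ATT_BANDS,
    MI_BANDS,
    FilterBankSpec,
    apply_filter_bank,
    design_filter_bank,
    epoch_signal,
    extract_features,
    fit_feature_model,
)
from exodecode.errors import EpochWarning, FilterDesignError, TrainingError
from exodecode.features import (
    EpochSet,
    csp_from_covariances,
    csp_variances,
)
from exodecode.io import N_EEG
from exodecode.protocol import AnalysisWindow

FS = 200.0


def sinusoid_eeg(freq, duration=20.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, N_EEG))


def random_covs(rng, n, channels):
    """Random SPD per-epoch covariance stacks."""
    a = rng.standard_normal((n, channels, channels * 4))
    return np.einsum("ecs,eds->ecd", a, a) / (channels * 4)


class TestFilterBank:
    def test_default_bank_sizes(self):
        assert len(design_filter_bank(FilterBankSpec(MI_BANDS), FS).sos) == 4
        assert len(design_filter_bank(FilterBankSpec(ATT_BANDS), FS).sos) == 6

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(FilterDesignError, match="Nyquist"):
            design_filter_bank(FilterBankSpec(((90.0, 120.0),)), FS)

    def test_inverted_band_edges_rejected(self):
        with pytest.raises(FilterDesignError):
            design_filter_bank(FilterBankSpec(((12.0, 8.0),)), FS)

    def test_in_band_sinusoid_passes(self):
        bank = design_filter_bank(FilterBankSpec(((8.0, 12.0),)), FS)
        out = apply_filter_bank(sinusoid_eeg(10.0), bank)[(8.0, 12.0)]
        steady = out[int(10 * FS):, 0]
        assert np.max(np.abs(steady)) == pytest.approx(1.0, rel=0.10)

    def test_out_of_band_sinusoid_blocked(self):
        bank = design_filter_bank(FilterBankSpec(((30.0, 36.0),)), FS)
        out = apply_filter_bank(sinusoid_eeg(10.0), bank)[(30.0, 36.0)]
        assert np.max(np.abs(out[int(10 * FS):, 0])) < 0.05

    def test_zero_in_zero_out(self):
        bank = design_filter_bank(FilterBankSpec(MI_BANDS), FS)
        out = apply_filter_bank(np.zeros((1000, N_EEG)), bank)
        assert all(np.all(v == 0) for v in out.values())


class TestEpoching:
    def filtered(self, duration):
        rng = np.random.default_rng(0)
        return {(8.0, 12.0): rng.standard_normal((int(duration * FS), N_EEG))}

    @pytest.mark.parametrize("window_s,expected", [(10.0, 18), (20.0, 38)])
    def test_labeled_epoch_counts(self, window_s, expected):
        # oracle: brute-force enumeration of epoch start times
        starts = [s / 10 for s in range(0, int(window_s * 10))
                  if s / 10 + 1.5 <= window_s + 1e-9 and (s % 5 == 0)]
        assert len(starts) == expected
        windows = [AnalysisWindow("mi", 2.0, 2.0 + window_s, target=1)]
        labeled, _ = epoch_signal(self.filtered(40.0), windows, 1.5, 0.5, FS)
        assert labeled.n_epochs == expected
        assert np.all(labeled.targets == 1)

    def test_short_window_warns_and_yields_nothing(self):
        windows = [AnalysisWindow("relax", 0.0, 1.0, target=0)]
        with pytest.warns(EpochWarning):
            labeled, _ = epoch_signal(self.filtered(10.0), windows, 1.5, 0.5, FS)
        assert labeled.n_epochs == 0

    def test_continuous_tiling_covers_trial(self):
        _, continuous = epoch_signal(self.filtered(80.0), [], 1.5, 0.5, FS)
        assert continuous.n_epochs == 158
        assert continuous.starts[0] == 0.0
        assert continuous.starts[-1] + 1.5 <= 80.0 + 1e-9

    def test_epochs_lie_inside_their_window(self):
        windows = [AnalysisWindow("mi", 3.0, 13.0, target=1)]
        labeled, _ = epoch_signal(self.filtered(20.0), windows, 1.5, 0.5, FS)
        assert np.all(labeled.starts >= 3.0 - 1e-9)
        assert np.all(labeled.starts + 1.5 <= 13.0 + 1e-9)


class TestCSP:
    def test_identical_classes_give_half_eigenvalues(self):
        rng = np.random.default_rng(1)
        covs = random_covs(rng, 8, 10)
        model = csp_from_covariances(covs, covs.copy(), m=4)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-8)

    def test_planted_two_channel_problem(self):
        """Class 1 has 10x the variance on channel 0: the leading filter
        must align with channel 0 (closed-form 2x2 eigenproblem)."""
        rng = np.random.default_rng(2)
        base = np.array([[1.0, 0.0], [0.0, 1.0]])
        boosted = np.array([[10.0, 0.0], [0.0, 1.0]])
        covs0 = np.stack([base + 1e-3 * np.diag(rng.random(2)) for _ in range(6)])
        covs1 = np.stack([boosted + 1e-3 * np.diag(rng.random(2)) for _ in range(6)])
        model = csp_from_covariances(covs0, covs1, m=1)
        lead = model.filters[:, 0]
        cosine = abs(lead[0]) / np.linalg.norm(lead)
        assert cosine > 0.99

    def test_matches_generalized_eigenvalue_oracle(self):
        """Whitening+rotation equals a dense generalized eigensolver."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            covs0, covs1 = random_covs(rng, 10, 6), random_covs(rng, 10, 6)
            model = csp_from_covariances(covs0, covs1, m=2)
            c0 = np.mean(covs0 / np.trace(covs0, axis1=1, axis2=2)[:, None, None], axis=0)
            c1 = np.mean(covs1 / np.trace(covs1, axis1=1, axis2=2)[:, None, None], axis=0)
            oracle = np.sort(scipy.linalg.eigh(c1, c0 + c1, eigvals_only=True))[::-1]
            np.testing.assert_allclose(model.eigenvalues, oracle, atol=1e-6)

    def test_whitening_normalization(self):
        rng = np.random.default_rng(4)
        covs0, covs1 = random_covs(rng, 10, 8), random_covs(rng, 10, 8)
        model = csp_from_covariances(covs0, covs1, m=2)
        c0 = np.mean(covs0 / np.trace(covs0, axis1=1, axis2=2)[:, None, None], axis=0)
        c1 = np.mean(covs1 / np.trace(covs1, axis1=1, axis2=2)[:, None, None], axis=0)
        gram = model.filters.T @ (c0 + c1) @ model.filters
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)
        # paired class-0/class-1 eigenvalues sum to one
        gram1 = model.filters.T @ c1 @ model.filters
        np.testing.assert_allclose(np.diag(gram1) + np.diag(model.filters.T @ c0 @ model.filters),
                                   1.0, atol=1e-8)

    def test_too_few_channels_for_2m_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(TrainingError, match="channels"):
            csp_from_covariances(random_covs(rng, 4, 4), random_covs(rng, 4, 4), m=4)


def labeled_epoch_set(rng, n_per_class=12, channels=N_EEG, bands=MI_BANDS, scale1=2.0):
    """Two-class epoch set where class 1 carries extra variance on channel 0."""
    length = 300
    data = {}
    for band in bands:
        epochs = rng.standard_normal((2 * n_per_class, channels, length))
        epochs[n_per_class:, 0, :] *= scale1
        data[band] = epochs
    return EpochSet(
        band_data=data,
        starts=0.5 * np.arange(2 * n_per_class),
        tasks=["relax"] * n_per_class + ["mi"] * n_per_class,
        targets=np.concatenate([np.zeros(n_per_class), np.ones(n_per_class)]),
        epoch_length=1.5,
        shift=0.5,
        sampling_rate=FS,
    )


class TestFeatures:
    def test_feature_count_and_standardization(self):
        epochs = labeled_epoch_set(np.random.default_rng(6))
        model, train_feats = fit_feature_model(epochs, m=4)
        assert train_feats.shape == (24, len(MI_BANDS) * 8)
        np.testing.assert_allclose(train_feats.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(train_feats.std(axis=0), 1.0, atol=1e-6)
        assert len(model.columns) == 32

    def test_training_epochs_reproduce_training_features(self):
        epochs = labeled_epoch_set(np.random.default_rng(7))
        model, train_feats = fit_feature_model(epochs, m=4)
        again = extract_features(epochs, model)
        np.testing.assert_allclose(again, train_feats, atol=1e-10)
        assert np.isfinite(again).all()

    def test_constant_epoch_gives_finite_features(self):
        epochs = labeled_epoch_set(np.random.default_rng(8))
        model, _ = fit_feature_model(epochs, m=4)
        flat = EpochSet(
            band_data={band: np.zeros((1, N_EEG, 300)) for band in MI_BANDS},
            starts=np.zeros(1),
            tasks=[None],
            targets=np.array([np.nan]),
            epoch_length=1.5,
            shift=0.5,
            sampling_rate=FS,
        )
        feats = extract_features(flat, model)
        assert np.isfinite(feats).all()

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(9)
        epochs = labeled_epoch_set(rng, bands=MI_BANDS[:1])
        perm = rng.permutation(N_EEG)
        permuted = EpochSet(
            band_data={b: d[:, perm, :] for b, d in epochs.band_data.items()},
            starts=epochs.starts,
            tasks=epochs.tasks,
            targets=epochs.targets,
            epoch_length=1.5,
            shift=0.5,
            sampling_rate=FS,
        )
        _, feats = fit_feature_model(epochs, m=2)
        _, feats_perm = fit_feature_model(permuted, m=2)
        np.testing.assert_allclose(feats, feats_perm, atol=1e-8)

    def test_global_scale_invariance(self):
        epochs = labeled_epoch_set(np.random.default_rng(10), bands=MI_BANDS[:2])
        scaled = EpochSet(
            band_data={b: 7.3 * d for b, d in epochs.band_data.items()},
            starts=epochs.starts,
            tasks=epochs.tasks,
            targets=epochs.targets,
            epoch_length=1.5,
            shift=0.5,
            sampling_rate=FS,
        )
        _, feats = fit_feature_model(epochs, m=2)
        _, feats_scaled = fit_feature_model(scaled, m=2)
        np.testing.assert_allclose(feats, feats_scaled, atol=1e-8)

    def test_leading_component_maximizes_class1_variance_ratio(self):
        epochs = labeled_epoch_set(np.random.default_rng(11), bands=MI_BANDS[:1])
        band = MI_BANDS[0]
        model, _ = fit_feature_model(epochs, m=4)
        covs = epochs.covariances()[band]
        variances = csp_variances(covs, model.csp[band])
        targets = epochs.targets
        v1 = variances[targets == 1].mean(axis=0)
        v0 = variances[targets == 0].mean(axis=0)
        ratio = v1 / (v0 + v1)
        assert np.argmax(ratio) == 0
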