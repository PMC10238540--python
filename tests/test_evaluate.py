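"""Area-ratio metric, LOO drivers, and the summary table."""

import numpy as np
import pytest

from exodecode import (
    IndexTrace,
    PipelineConfig,
    SyntheticConfig,
    compute_pi,
    generate_session,
    loo_experience,
    loo_slopes,
    summarize,
)
from exodecode.errors import EvaluationError, EvaluationWarning
from exodecode.protocol import AnalysisWindow


def make_trace(values, shift=0.5, epoch_length=1.5):
    values = np.asarray(values, dtype=float)
    return IndexTrace(
        values=values,
        starts=shift * np.arange(len(values)),
        epoch_length=epoch_length,
        shift=shift,
        paradigm="mi",
        k=5,
    )


def brute_force_pi(trace, windows):
    """Independent epoch-by-epoch accumulation of the duration-weighted
    correct-area ratio."""
    total, acc = 0.0, 0.0
    for w in windows:
        correct = []
        for start, value in zip(trace.starts, trace.values):
            if start >= w.start - 1e-9 and start + trace.epoch_length <= w.end + 1e-9:
                correct.append(value if w.target == 1 else 1.0 - value)
        if correct:
            total += w.duration
            acc += w.duration * float(np.mean(correct))
    return 100.0 * acc / total


class TestComputePI:
    def test_perfect_index_scores_100(self):
        trace = make_trace(np.ones(50))
        windows = [AnalysisWindow("mi", 2.0, 12.0, target=1)]
        assert compute_pi(trace, windows).pi_percent == pytest.approx(100.0)

    def test_neutral_index_scores_50(self):
        trace = make_trace(np.full(60, 0.5))
        windows = [
            AnalysisWindow("relax", 0.0, 8.0, target=0),
            AnalysisWindow("mi", 10.0, 25.0, target=1),
        ]
        assert compute_pi(trace, windows).pi_percent == pytest.approx(50.0)

    def test_two_window_weighted_example_is_75(self):
        values = np.empty(60)
        values[:] = np.nan
        starts = 0.5 * np.arange(60)
        in_w1 = (starts >= 0.0) & (starts + 1.5 <= 10.0)
        in_w2 = (starts >= 12.0) & (starts + 1.5 <= 22.0)
        values[in_w1] = 0.8
        values[in_w2] = 0.3
        values[np.isnan(values)] = 0.0
        trace = make_trace(values)
        windows = [
            AnalysisWindow("mi", 0.0, 10.0, target=1),
            AnalysisWindow("relax", 12.0, 22.0, target=0),
        ]
        assert compute_pi(trace, windows).pi_percent == pytest.approx(75.0)

    def test_matches_brute_force_oracle_on_random_input(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            trace = make_trace(rng.random(rng.integers(40, 120)))
            edges = np.sort(rng.uniform(0, 40, size=6))
            windows = [
                AnalysisWindow("w", float(a), float(b), target=int(rng.integers(0, 2)))
                for a, b in zip(edges[::2], edges[1::2])
                if b - a > 2.0
            ]
            if not windows:
                continue
            metric = compute_pi(trace, windows)
            assert metric.pi_percent == pytest.approx(
                brute_force_pi(trace, windows), abs=1e-10
            )
            # Eq. consistency: %PI recomputable from its own parts
            recomputed = 100.0 * np.sum(
                metric.durations / metric.total_time * metric.area_ratios
            )
            assert metric.pi_percent == pytest.approx(recomputed, abs=1e-10)

    def test_window_split_invariance(self):
        # constant index inside the span, so the epochs an interior split
        # point drops (those straddling it) cannot change either mean and
        # the duration-weighted identity is exact
        values = np.zeros(80)
        starts = 0.5 * np.arange(80)
        values[(starts >= 2.0) & (starts + 1.5 <= 22.0)] = 0.65
        trace = make_trace(values)
        whole = [AnalysisWindow("mi", 2.0, 22.0, target=1)]
        split = [
            AnalysisWindow("mi", 2.0, 12.0, target=1),
            AnalysisWindow("mi", 12.0, 22.0, target=1),
        ]
        assert compute_pi(trace, whole).pi_percent == pytest.approx(
            compute_pi(trace, split).pi_percent, abs=1e-10
        )

    def test_complement_symmetry(self):
        rng = np.random.default_rng(2)
        trace = make_trace(rng.random(80))
        flipped = make_trace(1.0 - trace.values)
        windows = [
            AnalysisWindow("relax", 0.0, 10.0, target=0),
            AnalysisWindow("mi", 12.0, 30.0, target=1),
        ]
        mirrored = [
            AnalysisWindow("relax", 0.0, 10.0, target=1),
            AnalysisWindow("mi", 12.0, 30.0, target=0),
        ]
        assert compute_pi(trace, windows).pi_percent == pytest.approx(
            compute_pi(flipped, mirrored).pi_percent, abs=1e-10
        )

    def test_empty_window_skipped_with_warning(self):
        trace = make_trace(np.ones(50))
        windows = [
            AnalysisWindow("mi", 2.0, 12.0, target=1),
            AnalysisWindow("relax", 24.9, 25.0, target=0),
        ]
        with pytest.warns(EvaluationWarning, match="no epoch"):
            metric = compute_pi(trace, windows)
        assert metric.n_periods == 1
        assert metric.total_time == pytest.approx(10.0)


class TestLOOExperience:
    def test_sixteen_folds_each_trained_on_fifteen(self, default_mi_result):
        assert default_mi_result.n_folds == 16
        assert all(size == 15 for size in default_mi_result.train_sizes)
        assert all(c == 3 for c, _ in default_mi_result.fold_trials)

    def test_baselines_are_ignored(self, default_mi_result, default_experience_session):
        evaluated = {(c, r) for c, r in default_mi_result.fold_trials}
        assert all(c == 3 for c, _ in evaluated)
        assert default_experience_session.select(1) and default_experience_session.select(2)

    def test_two_trial_session_warns(self, tmp_path):
        cfg = SyntheticConfig(seed=9, n_trials=2, baseline_duration=20.0)
        layout = generate_session(cfg, tmp_path)
        with pytest.warns(EvaluationWarning, match="16"):
            result = loo_experience(layout, "mi")
        assert result.n_folds == 2

    def test_single_trial_session_rejected(self, tmp_path):
        cfg = SyntheticConfig(seed=9, n_trials=1, baseline_duration=20.0)
        layout = generate_session(cfg, tmp_path)
        with pytest.raises(EvaluationError):
            loo_experience(layout, "mi")


class TestLOOSlopes:
    @pytest.fixture(scope="class")
    def slopes_results(self, slopes_session):
        return (
            loo_slopes(slopes_session, "mi", PipelineConfig()),
            loo_slopes(slopes_session, "att", PipelineConfig()),
        )

    def test_mi_folds_over_eight_mi_trials(self, slopes_results):
        mi, _ = slopes_results
        assert mi.n_folds == 8
        assert all(size == 7 for size in mi.train_sizes)
        assert all(c % 2 == 1 for c, _ in mi.fold_trials)

    def test_att_folds_over_all_sixteen(self, slopes_results):
        _, att = slopes_results
        assert att.n_folds == 16
        assert all(size == 15 for size in att.train_sizes)

    def test_default_effects_recovered_on_slopes(self, slopes_results):
        mi, att = slopes_results
        assert mi.mean > 70.0
        assert att.mean > 70.0


class TestSummarize:
    def test_mean_and_sample_sd(self):
        from exodecode.evaluate import LOOResult

        result = LOOResult(
            scenario="experience",
            paradigm="mi",
            subject_id="subject_01",
            fold_trials=[(3, 1), (3, 2), (3, 3)],
            fold_pi=np.array([80.0, 70.0, 90.0]),
            train_sizes=[2, 2, 2],
            mean=80.0,
            sd=10.0,
        )
        table = summarize([result])
        row = table[table.subject == "subject_01"].iloc[0]
        assert row.mean_pi == pytest.approx(80.0)
        assert row.sd_pi == pytest.approx(10.0)  # sample SD, ddof=1
        assert not row.single_fold

    def test_single_fold_flagged_with_zero_sd(self):
        from exodecode.evaluate import LOOResult

        result = LOOResult(
            scenario="experience",
            paradigm="mi",
            subject_id="s",
            fold_trials=[(3, 1)],
            fold_pi=np.array([81.0]),
            train_sizes=[1],
            mean=81.0,
            sd=0.0,
        )
        table = summarize([result])
        assert bool(table.iloc[0].single_fold)
        assert table.iloc[0].sd_pi == 0.0

    def test_empty_input_empty_table(self):
        assert summarize([]).empty

    def test_grand_average_row_present(self, default_mi_result):
        table = summarize([default_mi_result])
        assert "average" in set(table.subject)
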