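"""Decoder: trial extraction, regularised logistic fit, cross-validation,
weight maps, and the paired accuracy comparison."""

import numpy as np
import pytest
from scipy.stats import binom

from restdecode.core import FINGER, REST, WRIST, Run
from restdecode.decoder import (
    TrialSet,
    compare_to_control,
    extract_trials,
    loo_cv_accuracy,
    normalize_scan,
    predict,
    threshold_weight_map,
    train_decoder,
)
from restdecode.preprocess import preprocess_task_run
from restdecode.synthgen import SimConfig, generate_subject


class TestNormalizeScan:
    @pytest.mark.parametrize(
        "x, expected",
        [((3.0, 4.0), (0.6, 0.8)), ((-3.0, 4.0), (-0.6, 0.8)), ((1.0, 0.0), (1.0, 0.0))],
    )
    def test_examples(self, x, expected):
        out = normalize_scan(np.array(x))
        np.testing.assert_allclose(out, expected)
        assert np.linalg.norm(out) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize_scan(np.zeros(3))


class TestExtractTrials:
    def test_block_arithmetic_six_scans_mean_of_last_four(self, rng):
        # one 18 s block at TR 3 s: 6 scans, first 2 dropped
        labels = np.array([REST] * 3 + [WRIST] * 6 + [REST] * 3, dtype=object)
        data = rng.standard_normal((12, 5))
        trials = extract_trials(Run(data=data, session_id=2), labels)
        assert trials.n_trials == 1
        expected = np.mean([normalize_scan(s) for s in data[5:9]], axis=0)
        np.testing.assert_allclose(trials.patterns[0], expected)
        assert trials.labels[0] == WRIST
        assert trials.session_ids[0] == 2

    def test_default_session_gives_4_plus_4_trials(self, subject):
        trials = extract_trials(subject.task_runs[0], subject.schedules[0])
        assert trials.n_trials == 8
        assert np.sum(trials.labels == WRIST) == 4
        assert np.sum(trials.labels == FINGER) == 4

    def test_zero_scan_in_block_rejected(self):
        labels = np.array([WRIST] * 6, dtype=object)
        data = np.ones((6, 4))
        data[3] = 0.0
        with pytest.raises(ValueError):
            extract_trials(Run(data=data), labels)

    def test_short_block_rejected(self, rng):
        labels = np.array([FINGER] * 2, dtype=object)
        with pytest.raises(ValueError):
            extract_trials(Run(data=rng.standard_normal((2, 3))), labels, drop_initial=2)


def toy_trials(n_per_class=2, sep=1.0, session_ids=None):
    pats = np.array(
        [[sep, 0.0]] * n_per_class + [[-sep, 0.0]] * n_per_class
    )
    labels = np.array([FINGER] * n_per_class + [WRIST] * n_per_class, dtype=object)
    sess = session_ids if session_ids is not None else np.zeros(2 * n_per_class)
    return TrialSet(patterns=pats, labels=labels, session_ids=sess)


class TestTrainDecoder:
    def test_separable_toy_fits_perfectly(self):
        trials = toy_trials(sep=1.0)
        model = train_decoder(trials, lam=1e-4)
        _, pred = predict(model, trials.patterns)
        assert np.all(pred == trials.labels)
        assert model.w[0] > 0  # Finger is the positive class

    def test_heavy_regularisation_shrinks_to_chance(self):
        trials = toy_trials()
        model = train_decoder(trials, lam=1e6)
        assert np.linalg.norm(model.w) <= 1e-4
        prob, _ = predict(model, trials.patterns)
        np.testing.assert_allclose(prob, 0.5, atol=1e-3)

    def test_label_swap_negates_solution(self):
        rng = np.random.default_rng(3)
        pats = rng.standard_normal((8, 4))
        labels = np.array([FINGER, WRIST] * 4, dtype=object)
        swapped = np.array([WRIST, FINGER] * 4, dtype=object)
        sess = np.zeros(8)
        m1 = train_decoder(TrialSet(pats, labels, sess), lam=0.5)
        m2 = train_decoder(TrialSet(pats, swapped, sess), lam=0.5)
        np.testing.assert_allclose(m1.w, -m2.w, atol=1e-6)
        assert m1.b == pytest.approx(-m2.b, abs=1e-6)

    def test_single_class_rejected(self):
        pats = np.ones((4, 2))
        labels = np.array([WRIST] * 4, dtype=object)
        with pytest.raises(ValueError):
            train_decoder(TrialSet(pats, labels, np.zeros(4)))

    def test_scale_equivariance(self):
        """Scaling patterns by c with lam scaled by c^2 leaves predictions
        unchanged."""
        rng = np.random.default_rng(4)
        pats = rng.standard_normal((10, 3))
        labels = np.array([FINGER, WRIST] * 5, dtype=object)
        sess = np.zeros(10)
        c = 2.5
        m1 = train_decoder(TrialSet(pats, labels, sess), lam=1.0)
        m2 = train_decoder(TrialSet(c * pats, labels, sess), lam=c**2)
        p1, _ = predict(m1, pats)
        p2, _ = predict(m2, c * pats)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_matches_sklearn_reference(self):
        """Independent cross-check: sklearn's L2 logistic regression with
        C = 1/lam minimises the same objective."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        pats = rng.standard_normal((20, 6)) + np.outer(
            np.r_[np.ones(10), -np.ones(10)], np.r_[1.0, np.zeros(5)]
        )
        labels = np.array([FINGER] * 10 + [WRIST] * 10, dtype=object)
        model = train_decoder(TrialSet(pats, labels, np.zeros(20)), lam=2.0)
        ref = LogisticRegression(C=1.0 / 2.0, tol=1e-10, max_iter=5000)
        ref.fit(pats, (labels == FINGER).astype(int))
        np.testing.assert_allclose(model.w, ref.coef_.ravel(), atol=1e-4)
        assert model.b == pytest.approx(float(ref.intercept_[0]), abs=1e-4)


class TestPredict:
    def test_closed_form_probabilities(self):
        from restdecode.decoder import DecoderModel

        model = DecoderModel(w=np.array([1.0]), b=0.0, lam=1.0, n_train=4)
        prob, label = predict(model, np.array([[0.0]]))
        assert prob[0] == pytest.approx(0.5)
        assert label[0] == WRIST  # tie goes to Wrist
        prob, label = predict(model, np.array([[np.log(3.0)]]))
        assert prob[0] == pytest.approx(0.75)
        assert label[0] == FINGER
        prob, _ = predict(model, np.array([[1000.0]]))
        assert prob[0] == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self, trained_model):
        with pytest.raises(ValueError):
            predict(trained_model, np.ones((2, trained_model.w.size + 1)))


class TestLooCv:
    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_high_snr_subject_is_perfectly_decoded(self, seed):
        """Decoder-level property: with task signal far above the noise the
        held-out trials are all classified correctly (trials built from the
        raw runs, so only the decoder is under test)."""
        cfg = SimConfig(
            n_voxels=80, n_sessions=4, task_amplitude=8.0, noise_sd=0.3,
            nuisance_gain=0.0, rest_scans=60, seed=seed,
        )
        ds = generate_subject(cfg)
        trials = None
        for run, labels in zip(ds.task_runs, ds.schedules):
            ts = extract_trials(run, labels)
            trials = ts if trials is None else trials.concat(ts)
        acc, folds = loo_cv_accuracy(trials)
        assert acc == 1.0

    def test_denominator_counts_all_heldout_trials(self, subject_trials):
        acc, folds = loo_cv_accuracy(subject_trials)
        assert sum(f["n_test"] for f in folds) == subject_trials.n_trials
        assert 0.0 <= acc <= 1.0

    def test_two_sessions_required(self):
        trials = toy_trials(n_per_class=4)
        with pytest.raises(ValueError):
            loo_cv_accuracy(trials)

    def test_decoder_recovers_pattern_geometry(self):
        """At high SNR the weight vector aligns with the finger - wrist
        pattern contrast."""
        cfg = SimConfig(
            n_voxels=100, n_sessions=6, task_amplitude=8.0, noise_sd=0.3,
            rest_scans=60, seed=22,
        )
        ds = generate_subject(cfg)
        trials = None
        for run, labels, nuis in zip(ds.task_runs, ds.schedules, ds.task_nuisance):
            ts = extract_trials(preprocess_task_run(run, nuis), labels)
            trials = ts if trials is None else trials.concat(ts)
        model = train_decoder(trials)
        contrast = ds.truth.finger_pattern - ds.truth.wrist_pattern
        r = np.corrcoef(model.w, contrast)[0, 1]
        assert r > 0.8


class TestWeightMap:
    def test_top_fraction_count(self):
        w = np.arange(1.0, 11.0)  # 10 distinct magnitudes
        finger, wrist = threshold_weight_map(w, fraction=0.10)
        assert len(finger) + len(wrist) == 1
        assert finger.tolist() == [9]

    def test_sign_partitions_classes(self):
        w = np.array([5.0, -4.0, 0.1, 0.05, -0.01])
        finger, wrist = threshold_weight_map(w, fraction=0.4)
        assert finger.tolist() == [0]
        assert wrist.tolist() == [1]

    def test_equal_magnitudes_tie_break_low_index(self):
        w = np.ones(10)
        finger, wrist = threshold_weight_map(w, fraction=0.3)
        assert finger.tolist() == [0, 1, 2]
        assert wrist.size == 0


class TestCompareToControl:
    def test_identical_samples_not_significant(self):
        acc = np.full(10, 0.8)
        p, sig = compare_to_control(acc, acc)
        assert p == 1.0
        assert not sig

    def test_uniform_large_advantage_is_significant(self, rng):
        """All 21 paired differences positive: exact signed-rank two-sided
        tail is 2/2^21, far below 0.001 even after the 8-fold correction."""
        ctl = 0.5 + 0.01 * rng.standard_normal(21)
        roi = ctl + 0.3 + 0.01 * rng.random(21)
        p, sig = compare_to_control(roi, ctl)
        assert p < 0.001
        assert sig

    def test_bonferroni_factor_and_cap(self, rng):
        ctl = rng.random(12)
        roi = ctl + 0.02 * rng.standard_normal(12)
        from scipy.stats import wilcoxon

        p_raw = wilcoxon(roi, ctl, alternative="two-sided").pvalue
        p_adj, _ = compare_to_control(roi, ctl, n_rois=8)
        assert p_adj == pytest.approx(min(1.0, p_raw * 8))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_to_control(np.ones(6), np.ones(7))
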