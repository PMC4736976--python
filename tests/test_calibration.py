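"""Templates, AUROC scoring, stepwise reduction, and the calibration wrapper."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from p300shape import (
    CalibrationParams,
    CalibrationProfile,
    EpochSet,
    NONP300,
    P300,
    auroc,
    average_auroc,
    build_template,
    calibrate,
    encode_chain,
    feature_pair,
    n_folds,
    select_electrodes,
    stepwise_select,
    simulate_dataset,
    SimulationConfig,
)
from p300shape.calibration import _run_iteration

from conftest import build_epochs
from oracles import auroc_pairwise, stepwise_path


def _waveform_epochs(waveform, n_p300, n_nonp300=0, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = n_p300 + n_nonp300
    data = np.tile(waveform, (n, 1, 1))[:, None, :].reshape(n, 1, waveform.size)
    data = data + jitter * rng.standard_normal(data.shape)
    labels = np.array([P300] * n_p300 + [NONP300] * n_nonp300, dtype=object)
    return EpochSet(data, labels, ("Cz",), 256.0, waveform.size / 256 * 1000)


class TestBuildTemplate:
    def test_single_trial_template_is_that_trials_chain(self):
        e = build_epochs(n_p300=6, n_nonp300=0, n_electrodes=1, n_samples=64, seed=1)
        curve, chain, idx = build_template(e, 1, 8, seed=3)
        assert idx.size == 1
        assert chain == encode_chain(
            __import__("p300shape").Curve(np.arange(1, 65), e.data[idx[0], 0]), 8
        )

    def test_identical_trials_reproduce_the_waveform_chain(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 64))
        e = _waveform_epochs(w, n_p300=20)
        curve, chain, _ = build_template(e, 10, 8, seed=0)
        from p300shape import Curve

        assert chain == encode_chain(Curve(np.arange(1, 65), w), 8)

    def test_reference_regime_leaves_cross_validation_pool(self):
        e = build_epochs(n_p300=480, n_nonp300=0, n_electrodes=1, n_samples=8)
        _, _, idx = build_template(e, 180, 4, seed=0)
        assert idx.size == 180
        assert 480 - idx.size == 300  # 20 folds of 15 remain
        assert n_folds(480, 180, 15) == 20


class TestFeaturePair:
    def test_candidate_equal_to_template_gives_zero_features(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 64)) * 5
        e = _waveform_epochs(w, n_p300=30)
        curve, chain, idx = build_template(e, 10, 8, seed=0)
        vec, _ = feature_pair(curve, chain, e, P300, 5, 8, seed=1, exclude=idx)
        assert vec.distance == 0.0
        assert vec.area_diff_sum == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(vec.area_diffs, 0.0, atol=1e-12)

    def test_reference_dimension_and_determinism(self):
        e = build_epochs(n_p300=200, n_nonp300=0, n_electrodes=1, n_samples=204, seed=2)
        curve, chain, idx = build_template(e, 50, 16, seed=0)
        v1, i1 = feature_pair(curve, chain, e, P300, 15, 16, seed=9, exclude=idx)
        v2, i2 = feature_pair(curve, chain, e, P300, 15, 16, seed=9, exclude=idx)
        assert len(v1) == 34
        np.testing.assert_array_equal(v1.to_array(), v2.to_array())
        np.testing.assert_array_equal(i1, i2)
        assert not set(i1.tolist()) & set(idx.tolist())


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2], [0.9, 1.0]) == 1.0

    def test_identical_samples_give_half(self):
        assert auroc([0.3, 0.5, 0.7], [0.3, 0.5, 0.7]) == 0.5

    def test_interleaved_example_matches_pair_count(self):
        # exhaustive count: 6 of the 9 (P, N) pairs have the smaller P distance
        expected = auroc_pairwise([0.1, 0.4, 0.6], [0.3, 0.5, 0.7], exact=True)
        assert float(expected) == pytest.approx(6 / 9)
        assert auroc([0.1, 0.4, 0.6], [0.3, 0.5, 0.7]) == pytest.approx(float(expected))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            auroc([], [0.1])

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=8),
        st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    def test_exact_rational_oracle_with_ties(self, dp, dn):
        expected = auroc_pairwise(dp, dn, exact=True)
        assert auroc(dp, dn) == pytest.approx(float(expected), abs=1e-12)

    @given(st.integers(0, 200))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        dp, dn = rng.uniform(0, 1, 6), rng.uniform(0, 1, 7)
        base = auroc(dp, dn)
        assert auroc(np.exp(3 * dp), np.exp(3 * dn)) == pytest.approx(base)

    def test_cross_check_against_sklearn(self):
        rng = np.random.default_rng(0)
        dp, dn = rng.normal(0.4, 0.2, 50), rng.normal(0.8, 0.2, 60)
        # smaller distance means P300: score with the negated distance
        y = np.r_[np.ones(50), np.zeros(60)]
        expected = roc_auc_score(y, -np.r_[dp, dn])
        assert auroc(dp, dn) == pytest.approx(expected)


class TestAverageAurocAndSelection:
    def test_all_ones(self):
        np.testing.assert_array_equal(average_auroc(np.ones((4, 3))), [1, 1, 1])

    def test_column_mean_example(self):
        Z = np.array([[0.6], [0.8], [1.0]])
        assert average_auroc(Z)[0] == pytest.approx(0.8)

    def test_random_matrix_matches_direct_mean(self):
        rng = np.random.default_rng(3)
        Z = rng.uniform(0, 1, (10, 7))
        np.testing.assert_allclose(average_auroc(Z), Z.mean(axis=0))

    def test_accept_branch(self):
        sel, status = select_electrodes(np.array([0.9, 0.85, 0.4]))
        assert sel.tolist() == [0, 1] and status == "accept"

    def test_fallback_branch(self):
        sel, status = select_electrodes(np.array([0.7, 0.65, 0.5]))
        assert sel.tolist() == [0, 1] and status == "fallback"

    def test_unsuitable_branch(self):
        sel, status = select_electrodes(np.array([0.5, 0.4]))
        assert sel.size == 0 and status == "unsuitable"


class TestStepwise:
    def test_label_column_enters_first(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(20), -np.ones(20)]
        X = rng.standard_normal((40, 5))
        X[:, 2] = y
        res = stepwise_select(X, y)
        assert 2 in res.selected_indices
        # and it is the strongest single predictor by partial p-value
        assert res.selected_indices.tolist()[0] == 2 or res.mask[2]

    def test_all_constant_columns_give_empty_mask(self):
        X = np.ones((20, 4))
        y = np.r_[np.ones(10), -np.ones(10)]
        res = stepwise_select(X, y)
        assert res.mask.sum() == 0 and res.features.shape[1] == 0

    @given(st.integers(0, 40))
    def test_path_matches_statsmodels_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(20), -np.ones(20)]
        X = rng.standard_normal((40, 3))
        X[:, 0] += 0.8 * y
        res = stepwise_select(X, y)
        assert res.selected_indices.tolist() == stepwise_path(X, y)

    def test_weights_reproduce_least_squares_fit(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(25), -np.ones(25)]
        X = rng.standard_normal((50, 4))
        X[:, 1] += y
        res = stepwise_select(X, y)
        sel = res.selected_indices
        design = np.column_stack([np.ones(50), X[:, sel]])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(res.weights, beta[1:], atol=1e-10)
        assert res.intercept == pytest.approx(beta[0])


# high-SNR miniature subject: unit tests here exercise mechanics, not detection power
SMALL_SIM = dict(
    n_electrodes=3,
    electrode_names=("Cz", "Pz", "Oz"),
    amplitude_profile=(1.0, 1.0, 0.0),
    p300_amplitude_uV=30.0,
    n_p300_train=40,
    n_nonp300_train=160,
    n_p300_valid=20,
    n_nonp300_valid=80,
)
SMALL_PARAMS = dict(
    trials_per_template=12,
    max_stimulations=4,
    templates_per_electrode=2,
    max_folds=5,
)


class TestCalibrate:
    def test_bit_reproducible_for_fixed_master_seed(self):
        train, _, _ = simulate_dataset(SimulationConfig(seed=11, **SMALL_SIM))
        p1 = calibrate(train, CalibrationParams(master_seed=11, **SMALL_PARAMS))
        p2 = calibrate(train, CalibrationParams(master_seed=11, **SMALL_PARAMS))
        assert p1.to_dict() == p2.to_dict()

    def test_profile_roundtrips_through_json_and_text(self, tmp_path):
        train, _, _ = simulate_dataset(SimulationConfig(seed=11, **SMALL_SIM))
        prof = calibrate(train, CalibrationParams(master_seed=11, **SMALL_PARAMS))
        prof.save_json(tmp_path / "p.json")
        back = CalibrationProfile.load_json(tmp_path / "p.json")
        assert back.electrodes == prof.electrodes
        assert back.optimum_stimulations == prof.optimum_stimulations
        for name in prof.electrodes:
            assert back.per_electrode[name].template_chain == prof.per_electrode[
                name
            ].template_chain
            np.testing.assert_allclose(
                back.per_electrode[name].weights, prof.per_electrode[name].weights
            )
        prof.save_text(tmp_path / "p.txt")
        text = (tmp_path / "p.txt").read_text()
        assert "optimum_stimulations" in text and prof.electrodes[0] in text

    def test_preconditions_checked(self):
        train, _, _ = simulate_dataset(SimulationConfig(seed=1, **SMALL_SIM))
        with pytest.raises(ValueError, match="P300"):
            calibrate(train, CalibrationParams(trials_per_template=100))

    def test_injected_electrodes_outscore_noise_electrodes(self):
        # screening property: signal electrodes dominate in every seeded replicate
        wins = 0
        for seed in range(5):
            train, _, _ = simulate_dataset(SimulationConfig(seed=seed, **SMALL_SIM))
            it = _run_iteration(
                train, CalibrationParams(master_seed=seed, **SMALL_PARAMS), 4, 5
            )
            phi = it["phi"]
            wins += phi[:2].min() >= phi[2]
        assert wins >= 5 * 0.95 - 1e-9

    def test_template_and_folds_are_disjoint(self):
        e = build_epochs(n_p300=60, n_nonp300=60, n_electrodes=1, n_samples=64, seed=4)
        curve, chain, t_idx = build_template(e, 20, 8, seed=0)
        used = set(t_idx.tolist())
        for u in range(8):
            _, idx = feature_pair(curve, chain, e, P300, 5, 8, seed=u, exclude=used)
            assert not set(idx.tolist()) & used
            used.update(idx.tolist())
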