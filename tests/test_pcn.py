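"""Predictive-coding network: dynamics, relaxation, Hebbian updates."""

import warnings

import numpy as np
import pytest

from predcoding import (
    MLPArchitecture,
    PCNParams,
    RelaxationConfig,
    WeightMatrices,
    ann_forward,
    ann_deltas,
    epsilon_recursion,
    feedforward_init,
    make_sigma,
    pcn_epsilon,
    pcn_free_energy,
    pcn_mu,
    pcn_relax,
    pcn_train_step,
    pcn_velocity,
    pcn_weight_update,
)
from predcoding.pcn import PCNState, _build_state

from conftest import glorot_network


def prediction_relax(params, s_in, config=RelaxationConfig()):
    clamps = [None] * (params.arch.l_max + 1)
    clamps[params.arch.l_max] = s_in
    return pcn_relax(params, clamps, config=config)


def learning_relax(params, s_in, s_out, config=RelaxationConfig()):
    arch = params.arch
    clamps = [None] * (arch.l_max + 1)
    clamps[0] = s_out
    clamps[arch.l_max] = s_in
    ff = feedforward_init(params, s_in)
    init = [None] + [ff[l] for l in range(1, arch.l_max)] + [None]
    return pcn_relax(params, clamps, init, config)


class TestMuEpsilonF:
    def test_mu_mirrors_ann_preactivations(self, small_pcn):
        # setting x to the ANN activities makes mu the ANN layer inputs
        rng = np.random.default_rng(0)
        s_in = rng.normal(size=2)
        fs = ann_forward(small_pcn.theta, small_pcn.arch, s_in)
        mu = pcn_mu(small_pcn, fs.y)
        for l in range(small_pcn.arch.l_max):
            np.testing.assert_allclose(mu[l], fs.y[l], rtol=1e-12)

    def test_zero_theta_and_bias_only(self):
        arch = MLPArchitecture((2, 2), "tanh", has_bias=True)
        params = PCNParams.from_weights(arch, WeightMatrices.zeros(arch), 1.0)
        x = [np.zeros(2), np.array([0.7, -0.7])]
        assert np.all(pcn_mu(params, x)[0] == 0)
        params.theta[1][:, 0] = [0.3, -0.4]  # bias only
        np.testing.assert_allclose(pcn_mu(params, x)[0], [0.3, -0.4])

    def test_epsilon_linearity_in_sigma(self):
        x, mu = np.array([1.0, 2.0]), np.array([0.7, 1.7])
        e1 = pcn_epsilon(x, mu, np.ones(2))
        np.testing.assert_allclose(e1, [0.3, 0.3])
        e100 = pcn_epsilon(x, mu, 100 * np.ones(2))
        np.testing.assert_allclose(e100, e1 / 100)

    def test_epsilon_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="positive"):
            pcn_epsilon(np.ones(2), np.ones(2), np.array([1.0, 0.0]))

    def test_free_energy_values(self, small_pcn):
        arch = small_pcn.arch
        rng = np.random.default_rng(1)
        x = [rng.normal(size=arch.n(l)) for l in range(arch.l_max + 1)]
        state = _build_state(small_pcn, x, [False] * (arch.l_max + 1))
        # naive loop oracle
        total = 0.0
        for l in range(arch.l_max):
            for i in range(arch.n(l)):
                total += (state.x[l][i] - state.mu[l][i]) ** 2 / small_pcn.sigma[l][i]
        assert pcn_free_energy(state, small_pcn) == pytest.approx(-0.5 * total, rel=1e-12)
        assert pcn_free_energy(state, small_pcn) <= 0
        # perfect consistency gives exactly zero
        x_ff = ann_forward(small_pcn.theta, arch, x[arch.l_max]).y
        perfect = _build_state(small_pcn, x_ff, [False] * (arch.l_max + 1))
        assert pcn_free_energy(perfect, small_pcn) == 0.0

    def test_single_node_mismatch(self):
        arch = MLPArchitecture((1, 1), "linear")
        params = PCNParams.from_weights(arch, WeightMatrices.zeros(arch), 1.0)
        state = _build_state(params, [np.array([0.2]), np.array([0.0])], [False, False])
        assert pcn_free_energy(state, params) == pytest.approx(-0.02)


class TestVelocity:
    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_matches_free_energy_gradient(self, seed):
        # the node dynamics are exactly dF/dx for every unclamped node
        arch, weights, rng = glorot_network(seed, max_layers=3, max_nodes=4)
        params = PCNParams.from_weights(arch, weights,
                                        [rng.uniform(0.5, 2.0)] * arch.l_max)
        x = [rng.normal(size=arch.n(l)) for l in range(arch.l_max + 1)]
        clamped = [False] * arch.l_max + [True]
        state = _build_state(params, x, clamped)
        vel = pcn_velocity(state, params)
        h = 1e-6
        for l in range(arch.l_max + 1):
            if clamped[l]:
                assert np.all(vel[l] == 0)
                continue
            for b in range(arch.n(l)):
                Fs = []
                for sign in (+1, -1):
                    x2 = [xi.copy() for xi in x]
                    x2[l][b] += sign * h
                    Fs.append(pcn_free_energy(_build_state(params, x2, clamped), params))
                fd = (Fs[0] - Fs[1]) / (2 * h)
                assert vel[l][b] == pytest.approx(fd, abs=1e-5)

    def test_zero_errors_mean_zero_velocity(self, small_pcn):
        arch = small_pcn.arch
        s_in = np.array([0.4, -0.2])
        x = ann_forward(small_pcn.theta, arch, s_in).y
        state = _build_state(small_pcn, x, [False, False, True])
        for v in pcn_velocity(state, small_pcn):
            np.testing.assert_allclose(v, 0, atol=1e-14)


class TestRelaxation:
    def test_prediction_mode_reaches_ann_forward_pass(self):
        for seed in range(8):
            arch, weights, rng = glorot_network(seed)
            params = PCNParams.from_weights(arch, weights, 1.0)
            s_in = rng.normal(size=arch.n(arch.l_max))
            fs = ann_forward(weights, arch, s_in)
            st = prediction_relax(params, s_in)
            assert st.converged
            diff = max(float(np.max(np.abs(st.x[l] - fs.y[l])))
                       for l in range(arch.l_max + 1))
            assert diff < 1e-5
            assert max(float(np.max(np.abs(e))) for e in st.eps) < 1e-5
            assert abs(pcn_free_energy(st, params)) < 1e-8

    def test_perfectly_predicted_pair_is_a_fixed_point(self, small_pcn):
        s_in = np.array([0.4, -0.9])
        ff = ann_forward(small_pcn.theta, small_pcn.arch, s_in)
        st = learning_relax(small_pcn, s_in, ff.y[0].copy())
        assert st.iterations == 0  # already at the fixed point
        for l in range(small_pcn.arch.l_max + 1):
            np.testing.assert_allclose(st.x[l], ff.y[l], atol=1e-12)

    def test_free_energy_nondecreasing_along_trajectory(self, small_pcn):
        rng = np.random.default_rng(5)
        st = learning_relax(small_pcn, rng.normal(size=2), rng.normal(size=2))
        st2 = pcn_relax(small_pcn, [st.x[0], None, st.x[2]], None,
                        RelaxationConfig(), record_trace=True)
        F = [row[2] for row in st2.trace]
        assert all(b >= a - 1e-9 * max(1, abs(a)) for a, b in zip(F, F[1:]))

    def test_iteration_cap_returns_warning_flag(self, small_pcn):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            st = prediction_relax(small_pcn, np.array([3.0, -1.0]),
                                  RelaxationConfig(max_iterations=3))
        assert not st.converged
        assert st.iterations == 3
        assert any("iteration cap" in str(x.message) for x in w)

    def test_fixed_steps_mode_runs_exactly_that_many(self, small_pcn):
        st = learning_relax(small_pcn, np.array([0.2, 0.1]), np.array([1.0, -1.0]),
                            RelaxationConfig(fixed_steps=20))
        assert st.iterations == 20

    def test_batched_relaxation_matches_per_sample(self, small_pcn):
        rng = np.random.default_rng(8)
        S_in = rng.normal(size=(4, 2))
        fs = ann_forward(small_pcn.theta, small_pcn.arch, S_in)
        st = prediction_relax(small_pcn, S_in)
        for l in range(3):
            np.testing.assert_allclose(st.x[l], fs.y[l], atol=2e-5)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RelaxationConfig(initial_step=-1)
        with pytest.raises(ValueError):
            RelaxationConfig(shrink_factor=1.5)
        with pytest.raises(ValueError):
            RelaxationConfig(fixed_steps=0)


class TestWeightUpdate:
    def test_zero_errors_zero_increment(self, small_pcn):
        s_in = np.array([1.0, -1.0])
        st = prediction_relax(small_pcn, s_in)
        inc = pcn_weight_update(st, small_pcn)
        assert np.max(np.abs(inc.flatten())) < 1e-5

    @pytest.mark.parametrize("seed", [2, 9])
    def test_matches_dF_dtheta_finite_differences(self, seed):
        # holding x* fixed, the Hebbian increment is exactly dF/dtheta
        arch, weights, rng = glorot_network(seed, max_layers=3, max_nodes=4)
        params = PCNParams.from_weights(arch, weights, 1.0)
        s_in = rng.normal(size=arch.n(arch.l_max))
        s_out = rng.normal(size=arch.n(0))
        st = learning_relax(params, s_in, s_out)
        inc = pcn_weight_update(st, params, alpha=1.0)
        h = 1e-5
        for a in range(1, arch.l_max + 1):
            for idx in np.ndindex(*params.theta[a].shape):
                Fs = []
                for sign in (+1, -1):
                    p2 = params.copy()
                    p2.theta[a][idx] += sign * h
                    s2 = _build_state(p2, st.x, st.clamped)
                    Fs.append(pcn_free_energy(s2, p2))
                fd = (Fs[0] - Fs[1]) / (2 * h)
                assert inc[a][idx] == pytest.approx(fd, abs=1e-4)

    def test_sigma0_scaling_recovers_unscaled_magnitude(self, small_pcn):
        rng = np.random.default_rng(3)
        s_in, s_out = rng.normal(size=2), rng.normal(size=2)
        p100 = small_pcn.copy()
        p100.sigma[0] = np.full(2, 100.0)
        st = learning_relax(p100, s_in, s_out)
        raw = pcn_weight_update(st, p100, scale_by_sigma0=False)
        scaled = pcn_weight_update(st, p100, scale_by_sigma0=True)
        np.testing.assert_allclose(scaled.flatten(), 100.0 * raw.flatten(), rtol=1e-12)


class TestSigmaScaling:
    def test_uniform_variance_scaling_rescales_errors_exactly(self):
        # scaling the variances of *all* levels by k leaves the fixed
        # point unchanged and divides every prediction error by k exactly
        arch, weights, rng = glorot_network(12, activation="linear")
        s_in = rng.normal(size=arch.n(arch.l_max))
        s_out = rng.normal(size=arch.n(0))
        eps_by_sigma = {}
        for k in (1.0, 10.0):
            params = PCNParams.from_weights(arch, weights, k)
            st = learning_relax(params, s_in, s_out,
                                RelaxationConfig(tolerance=1e-10))
            eps_by_sigma[k] = np.concatenate([e.ravel() for e in st.eps])
        np.testing.assert_allclose(eps_by_sigma[10.0], eps_by_sigma[1.0] / 10.0,
                                   rtol=1e-6, atol=1e-10)

    def test_output_variance_rescales_errors_asymptotically(self):
        # scaling Sigma(0) alone also moves the fixed point, so the 1/k
        # error rescaling holds only in the large-variance limit: between
        # Sigma(0) = 100 and 1000 the ratio is 10 to within ~10%
        arch, weights, rng = glorot_network(12, activation="linear")
        s_in = rng.normal(size=arch.n(arch.l_max))
        s_out = rng.normal(size=arch.n(0))
        eps_by_sigma = {}
        for k in (100.0, 1000.0):
            params = PCNParams.from_weights(arch, weights,
                                            [k] + [1.0] * (arch.l_max - 1))
            st = learning_relax(params, s_in, s_out,
                                RelaxationConfig(tolerance=1e-10))
            eps_by_sigma[k] = np.concatenate([e.ravel() for e in st.eps])
        np.testing.assert_allclose(eps_by_sigma[1000.0], eps_by_sigma[100.0] / 10.0,
                                   rtol=0.1, atol=1e-12)


class TestTrainStep:
    def test_perfect_pair_and_zero_alpha_leave_params(self, small_pcn):
        s_in = np.array([0.5, 0.5])
        s_out = ann_forward(small_pcn.theta, small_pcn.arch, s_in).y[0].copy()
        out = pcn_train_step(small_pcn, s_in, s_out, alpha=0.1)
        np.testing.assert_allclose(out.theta.flatten(), small_pcn.theta.flatten(),
                                   atol=1e-7)
        rng = np.random.default_rng(4)
        out = pcn_train_step(small_pcn, s_in, rng.normal(size=2), alpha=0.0)
        np.testing.assert_array_equal(out.theta.flatten(), small_pcn.theta.flatten())

    def test_repeated_steps_drive_free_energy_to_zero(self):
        arch = MLPArchitecture((1, 1, 1), "tanh")
        params = PCNParams.from_weights(
            arch, WeightMatrices([np.array([[0.3]]), np.array([[0.5]])]), 1.0)
        s_in, s_out = np.array([1.5]), np.array([np.tanh(np.tanh(1.5))])
        F_hist = []
        for _ in range(200):
            st = learning_relax(params, s_in, s_out)
            F_hist.append(pcn_free_energy(st, params))
            params = pcn_train_step(params, s_in, s_out, alpha=0.2)
        assert F_hist[-1] > F_hist[0]
        assert abs(F_hist[-1]) < 1e-4


class TestEpsilonRecursion:
    def test_fixed_point_satisfies_recursion(self, small_pcn):
        rng = np.random.default_rng(6)
        s_in, s_out = rng.normal(size=2), rng.normal(size=2)
        st = learning_relax(small_pcn, s_in, s_out, RelaxationConfig(tolerance=1e-9))
        rec = epsilon_recursion(small_pcn, st.x, s_out)
        for l in range(small_pcn.arch.l_max):
            np.testing.assert_allclose(st.eps[l], rec[l], atol=1e-6)

    def test_predicted_output_gives_zero_errors(self, small_pcn):
        s_in = np.array([0.1, 0.9])
        x = ann_forward(small_pcn.theta, small_pcn.arch, s_in).y
        mu0 = pcn_mu(small_pcn, x)[0]
        rec = epsilon_recursion(small_pcn, x, mu0)
        for e in rec:
            np.testing.assert_allclose(e, 0, atol=1e-14)

    def test_unit_sigma_recursion_equals_backprop_deltas(self):
        # with Sigma = 1 and ANN activities substituted for x*, the error
        # recursion is the backprop delta recursion
        arch, weights, rng = glorot_network(13)
        params = PCNParams.from_weights(arch, weights, 1.0)
        s_in = rng.normal(size=arch.n(arch.l_max))
        s_out = rng.normal(size=arch.n(0))
        fs = ann_forward(weights, arch, s_in)
        deltas = ann_deltas(weights, fs, s_out)
        rec = epsilon_recursion(params, fs.y, s_out)
        for l in range(arch.l_max):
            np.testing.assert_allclose(rec[l], deltas[l], rtol=1e-12, atol=1e-12)


def test_make_sigma_shorthand_and_validation():
    arch = MLPArchitecture((2, 3, 1), "tanh")
    sig = make_sigma(arch, 2.5)
    assert [s.shape for s in sig] == [(2,), (3,)]
    sig = make_sigma(arch, [100.0, 1.0])
    assert sig[0][0] == 100.0 and sig[1][0] == 1.0
    with pytest.raises(ValueError, match="positive"):
        make_sigma(arch, -1.0)
    with pytest.raises(ValueError):
        make_sigma(arch, [1.0])
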