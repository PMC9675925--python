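"""Surrogate network: activation, forward pass, printed coefficients,
fit statistics, K-fold splitting and training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nlcopt
from nlcopt.errors import InfeasibleSplitError, ValidationError
from nlcopt.surrogate import FitReport, TrainConfig, fit_statistics, tanh_half

from conftest import random_network

#: the reported optimal composition, actual units
OPTIMUM = np.array([4.80, 30.00, 3.50, 1.65])


class TestTanhHalf:
    def test_values(self):
        assert tanh_half(0.0) == 0.0
        assert tanh_half(2.0) == pytest.approx(math.tanh(1.0))
        assert tanh_half(-2.0) == pytest.approx(-math.tanh(1.0))

    @given(st.floats(-15, 15, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_odd_bounded_monotone(self, z):
        v = tanh_half(z)
        assert -1.0 < v < 1.0
        assert tanh_half(-z) == pytest.approx(-v)
        assert tanh_half(z + 0.1) > v


class TestForward:
    def test_zero_weights_returns_output_bias(self, rng):
        net = random_network(rng, (4, 3, 2))
        zeroed = nlcopt.NeuralSurrogate(
            layer_sizes=net.layer_sizes,
            weights=tuple(np.zeros_like(W) for W in net.weights),
            biases=net.biases,
            activations=net.activations,
            input_names=net.input_names,
            response_names=net.response_names,
        )
        out = zeroed.forward(np.ones(4))
        assert out == pytest.approx(zeroed.biases[-1])

    def test_identity_net_is_affine_composition(self, rng):
        W1 = rng.normal(size=(3, 2))
        b1 = rng.normal(size=3)
        W2 = rng.normal(size=(1, 3))
        b2 = rng.normal(size=1)
        net = nlcopt.NeuralSurrogate(
            layer_sizes=(2, 3, 1),
            weights=(W1, W2),
            biases=(b1, b2),
            activations=("identity", "identity"),
            input_names=("X1", "X2"),
            response_names=("Y1",),
        )
        x = rng.normal(size=2)
        expected = W2 @ (W1 @ x + b1) + b2
        assert net.forward(x) == pytest.approx(expected)

    def test_dimension_mismatch_raises(self, printed_net):
        with pytest.raises(ValidationError):
            printed_net.forward(np.ones(3))

    def test_batch_matches_pointwise(self, printed_net, rng):
        X = rng.uniform(0.5, 6.0, size=(5, 4))
        batch = printed_net.forward(X)
        for i in range(5):
            assert batch[i] == pytest.approx(printed_net.forward(X[i]))


def _oracle_printed_forward(x):
    """Independent literal transcription of the published layer equations."""
    X1, X2, X3, X4 = x
    T = lambda z: math.tanh(0.5 * z)
    H = [
        T(0.69 * X1 - 0.09 * X2 - 0.28 * X3 - 2.79 * X4 + 3.07),
        T(-0.66 * X1 - 0.26 * X2 - 1.99 * X3 - 0.62 * X4 + 18.45),
        T(-0.24 * X1 + 0.07 * X2 - 0.07 * X3 - 2.57 * X4 + 0.50),
        T(0.22 * X1 + 0.26 * X2 - 0.29 * X3 - 1.00 * X4 - 4.35),
        T(0.05 * X1 - 0.22 * X2 + 0.74 * X3 + 2.24 * X4 + 1.08),
        T(0.09 * X1 + 0.05 * X2 - 1.88 * X3 + 4.23 * X4 - 2.99),
        T(0.05 * X1 - 0.14 * X2 - 1.91 * X3 + 2.81 * X4 + 7.28),
        T(-1.22 * X1 + 0.13 * X2 + 0.66 * X3 + 0.01 * X4 + 2.31),
        T(-0.92 * X1 - 0.08 * X2 - 1.42 * X3 - 2.40 * X4 + 14.92),
    ]
    HH = [
        T(-2.47 * H[0] + 1.80 * H[1] - 1.04 * H[2] + 0.17 * H[3] + 2.64 * H[4]
          + 2.81 * H[5] + 2.45 * H[6] + 0.76 * H[7] - 4.03 * H[8] + 1.97),
        T(-0.58 * H[0] + 3.96 * H[1] - 0.95 * H[2] + 1.12 * H[3] - 2.31 * H[4]
          - 2.05 * H[5] + 1.00 * H[6] - 1.42 * H[7] + 0.14 * H[8] - 0.61),
        T(-0.55 * H[0] + 2.30 * H[1] + 0.51 * H[2] + 0.31 * H[3] - 1.62 * H[4]
          + 0.14 * H[5] + 0.49 * H[6] - 0.77 * H[7] + 4.15 * H[8] - 1.34),
        T(0.81 * H[0] - 0.25 * H[1] + 0.48 * H[2] - 5.18 * H[3] + 0.60 * H[4]
          - 0.70 * H[5] - 0.78 * H[6] + 1.88 * H[7] + 2.67 * H[8] + 0.34),
        T(2.41 * H[0] - 1.86 * H[1] - 1.43 * H[2] + 1.12 * H[3] - 1.49 * H[4]
          - 0.55 * H[5] + 3.74 * H[6] - 1.08 * H[7] - 0.14 * H[8] + 2.29),
        T(0.12 * H[0] + 2.43 * H[1] - 1.94 * H[2] - 0.92 * H[3] - 1.63 * H[4]
          - 2.39 * H[5] + 1.14 * H[6] - 1.90 * H[7] + 0.50 * H[8] - 0.97),
        T(-0.64 * H[0] - 0.17 * H[1] - 1.41 * H[2] - 0.68 * H[3] + 0.32 * H[4]
          - 2.35 * H[5] + 0.73 * H[6] - 1.95 * H[7] - 0.18 * H[8] - 0.92),
        T(0.10 * H[0] + 0.87 * H[1] - 1.34 * H[2] - 1.35 * H[3] - 0.56 * H[4]
          - 3.26 * H[5] + 1.15 * H[6] - 0.77 * H[7] - 0.94 * H[8] - 0.82),
        T(-1.09 * H[0] - 2.39 * H[1] - 2.54 * H[2] - 0.35 * H[3] + 0.40 * H[4]
          - 1.37 * H[5] - 0.10 * H[6] + 0.05 * H[7] + 1.26 * H[8] - 1.94),
    ]
    y1 = (18.19 * HH[0] - 40.03 * HH[1] + 26.22 * HH[2] - 146.97 * HH[3]
          - 78.91 * HH[4] + 180.00 * HH[5] + 121.12 * HH[6] - 112.00 * HH[7]
          - 102.29 * HH[8] + 170.31)
    y2 = (-0.02 * HH[0] + 0.09 * HH[1] - 0.04 * HH[2] - 0.07 * HH[3]
          - 0.10 * HH[4] + 0.20 * HH[5] + 0.03 * HH[6] - 0.13 * HH[7]
          + 0.13 * HH[8] + 0.30)
    y3 = (-2.54 * HH[0] + 0.15 * HH[1] - 1.86 * HH[2] + 0.35 * HH[3]
          + 0.94 * HH[4] + 2.50 * HH[5] - 0.33 * HH[6] - 0.10 * HH[7]
          + 3.16 * HH[8] - 10.73)
    y4 = (3.90 * HH[0] + 29.57 * HH[1] - 10.98 * HH[2] - 1.71 * HH[3]
          - 5.88 * HH[4] - 18.64 * HH[5] - 12.30 * HH[6] + 14.02 * HH[7]
          + 11.59 * HH[8] + 61.43)
    return np.array([y1, y2, y3, y4])


class TestPrintedNetwork:
    def test_architecture(self, printed_net):
        assert printed_net.layer_sizes == (4, 9, 9, 4)
        assert printed_net.input_space == "actual"
        assert printed_net.activations == ("tanh_half", "tanh_half", "identity")

    def test_spot_coefficients(self, printed_net):
        assert printed_net.biases[0][1] == pytest.approx(18.45)   # second hidden unit
        assert printed_net.biases[-1][0] == pytest.approx(170.31)  # size output bias

    def test_ee_prediction_at_reported_optimum(self, printed_net):
        y4 = printed_net.forward(OPTIMUM)[3]
        assert y4 == pytest.approx(85.49, abs=1.0)

    def test_forward_matches_independent_transcription(self, printed_net, rng):
        pts = [OPTIMUM] + [rng.uniform([0.25, 0, 0.5, 0.13],
                                       [13.25, 60, 6.5, 2.63]) for _ in range(10)]
        for x in pts:
            assert printed_net.forward(x) == pytest.approx(
                _oracle_printed_forward(x), rel=1e-12, abs=1e-12
            )

    def test_hidden_units_span_both_saturation_signs(self, printed_net, factors):
        """Over the corners of the coded box each hidden unit must activate in
        both directions — evidence the coefficients act on actual units."""
        signs_grid = np.array(list(np.ndindex(2, 2, 2, 2))) * 2 - 1
        corners = np.array(
            [[f.center + s * 2 * f.step for f, s in zip(factors, row)]
             for row in signs_grid]
        )
        z = corners @ printed_net.weights[0].T + printed_net.biases[0]
        assert (z.max(axis=0) > 0).all() and (z.min(axis=0) < 0).all()

    def test_checksum_guard(self, tmp_path, monkeypatch):
        import json
        import importlib.resources as res

        import nlcopt.surrogate as sg

        src = res.files("nlcopt.data") / "printed_network.json"
        d = json.loads(src.read_text())
        d["weights"][0][0][0] += 1.0
        bad = tmp_path / "printed_network.json"
        bad.write_text(json.dumps(d))

        class FakeFiles:
            def __truediv__(self, name):
                return bad

        monkeypatch.setattr(sg._resources, "files", lambda pkg: FakeFiles())
        with pytest.raises(nlcopt.errors.CorruptedFixtureError):
            nlcopt.printed_network()


class TestFitStatistics:
    def test_reproduces_reported_training_row(self):
        """SSE 9980.6204 over 24 runs pins RMSE and the Gaussian-MLE -logL."""
        sse, n = 9980.6204, 24
        obs = np.zeros(n)
        obs[0] = 1.0  # any non-constant vector with the target SSE
        pred = obs - np.sqrt(sse / n)
        st = fit_statistics(obs, pred)
        assert st.sse == pytest.approx(sse, rel=1e-9)
        assert st.rmse == pytest.approx(20.3926, abs=1e-4)
        assert st.neg_log_lik == pytest.approx(106.4187, abs=1e-4)

    def test_perfect_fit(self):
        st = fit_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (st.r_squared, st.rmse, st.mad, st.sse) == (1.0, 0.0, 0.0, 0.0)

    def test_rmse_sse_consistency(self, rng):
        obs = rng.normal(size=50)
        pred = obs + rng.normal(size=50)
        st = fit_statistics(obs, pred)
        assert st.rmse**2 * st.n == pytest.approx(st.sse, rel=1e-6)

    def test_zero_variance_flag(self):
        st = fit_statistics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert st.r_squared == -np.inf

    def test_insufficient_data(self):
        with pytest.raises(ValidationError):
            fit_statistics([1.0], [1.0])


class TestKFold:
    def test_thirty_runs_five_folds_is_24_6(self):
        folds = nlcopt.kfold_split(30, 5, seed=3)
        for f in range(5):
            assert len(folds.train_indices(f)) == 24
            assert len(folds.test_indices(f)) == 6

    def test_disjoint_cover(self):
        folds = nlcopt.kfold_split(17, 4, seed=0)
        all_test = np.concatenate([folds.test_indices(f) for f in range(4)])
        assert sorted(all_test) == list(range(17))
        sizes = [len(folds.test_indices(f)) for f in range(4)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic(self):
        a = nlcopt.kfold_split(30, 5, seed=11)
        b = nlcopt.kfold_split(30, 5, seed=11)
        assert (a.fold_of_run == b.fold_of_run).all()

    def test_infeasible(self):
        with pytest.raises(InfeasibleSplitError):
            nlcopt.kfold_split(10, 11, seed=0)


class TestTraining:
    def test_recovers_realizable_function(self):
        """Noiseless data from a fixed network is fit to R^2 >= 0.999
        everywhere: the target function is exactly realizable and the model
        has enough capacity to interpolate 24 points."""
        sim = nlcopt.simulate_dataset(
            nlcopt.SimulationConfig(noise_sd=[0, 0, 0, 0], seed=0))
        net, rep = nlcopt.train(sim, config=TrainConfig(n_restarts=8), seed=0)
        for r in ("Y1", "Y2", "Y3", "Y4"):
            assert rep.stat(r, "training", "r_squared") >= 0.999

    def test_seeded_determinism(self, dataset):
        cfg = TrainConfig(n_restarts=3, max_iter=150)
        n1, r1 = nlcopt.train(dataset, config=cfg, seed=42)
        n2, r2 = nlcopt.train(dataset, config=cfg, seed=42)
        for W1, W2 in zip(n1.weights, n2.weights):
            assert (W1 == W2).all()
        assert r1.rows.equals(r2.rows)

    def test_training_partition_sizes(self, dataset):
        _, rep = nlcopt.train(dataset, config=TrainConfig(n_restarts=2,
                                                          max_iter=100), seed=0)
        assert rep.stat("Y1", "training", "n") == 24
        assert rep.stat("Y1", "testing", "n") == 6

    def test_report_rmse_sse_identity(self, dataset):
        _, rep = nlcopt.train(dataset, config=TrainConfig(n_restarts=2,
                                                          max_iter=100), seed=1)
        for _, row in rep.rows.iterrows():
            assert row.rmse**2 * row.n == pytest.approx(row.sse, rel=1e-6)

    def test_noiseless_function_recovery_heldout_particle_size(self):
        """Retraining on noiseless truth-surface data generalizes for the
        particle-size response: pooled 5-fold cross-validated R^2 (every run
        predicted while held out) reaches 0.9 in the median over seeds."""
        vals = []
        for seed in range(3):
            sim = nlcopt.simulate_dataset(
                nlcopt.SimulationConfig(noise_sd=[0, 0, 0, 0], seed=seed))
            Y = sim.response_means[:, 0]
            results, folds = nlcopt.cross_validate(
                sim, config=TrainConfig(n_restarts=9, per_response=True),
                seed=seed)
            pred = np.zeros_like(Y)
            for f, (net, _) in enumerate(results):
                te = folds.test_indices(f)
                pred[te] = net.forward(sim.actual[te])[:, 0]
            vals.append(1 - np.sum((Y - pred) ** 2)
                        / np.sum((Y - Y.mean()) ** 2))
        assert np.median(vals) >= 0.9
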