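import numpy as np
import pytest

from contits.gsgmdh import (GsGmdhConfig, SeriesGsGmdh, fit_neuron,
                            grow_network, monomial_basis, napc, predict)
from contits.series_core import ValidationError


class TestMonomialBasis:
    def test_quadratic_two_inputs_matches_canonical_form(self):
        terms = monomial_basis(2, 2)
        # {1, x_i, x_j, x_i^2, x_j^2, x_i x_j} as exponent tuples
        assert len(terms) == 6
        assert set(terms) == {(0, 0), (1, 0), (0, 1), (2, 0), (0, 2), (1, 1)}
        assert terms[0] == (0, 0)

    @pytest.mark.parametrize("m,deg,count", [(3, 3, 20), (3, 2, 10),
                                             (2, 3, 10), (2, 2, 6)])
    def test_counts(self, m, deg, count):
        assert len(monomial_basis(m, deg)) == count

    def test_domain(self):
        with pytest.raises(ValidationError):
            monomial_basis(4, 2)


class TestNapc:
    @pytest.mark.parametrize("n,expected", [(5, 10), (2, 1)])
    def test_values(self, n, expected):
        assert napc(n) == expected

    def test_matches_enumeration(self):
        from itertools import combinations
        for n in range(2, 13):
            assert napc(n) == len(list(combinations(range(n), 2)))

    def test_domain(self):
        with pytest.raises(ValidationError):
            napc(1)


class TestFitNeuron:
    def test_exact_polynomial_recovery(self, rng):
        X = rng.normal(size=(50, 2))
        y = 1 + 2 * X[:, 0] - X[:, 1] + 0.5 * X[:, 0] ** 2
        spec = fit_neuron(X, y, 2)
        pred = spec.eval([X[:, 0], X[:, 1]])
        assert float(np.sum((y - pred) ** 2)) < 1e-18
        coef = dict(zip(spec.exponents, spec.coefficients))
        assert coef[(0, 0)] == pytest.approx(1.0, abs=1e-8)
        assert coef[(1, 0)] == pytest.approx(2.0, abs=1e-8)
        assert coef[(0, 1)] == pytest.approx(-1.0, abs=1e-8)
        assert coef[(2, 0)] == pytest.approx(0.5, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(80, 2))
        y = rng.normal(size=80)
        spec = fit_neuron(X, y, 2)
        from contits.gsgmdh import _design
        Z = _design(X, spec.exponents)
        oracle = np.linalg.solve(Z.T @ Z, Z.T @ y)
        np.testing.assert_allclose(spec.coefficients, oracle, atol=1e-8)

    def test_constant_target_minimum_norm(self):
        X = np.zeros((20, 2))  # rank-deficient design
        y = np.full(20, 4.0)
        spec = fit_neuron(X, y, 2)
        coef = dict(zip(spec.exponents, spec.coefficients))
        assert coef[(0, 0)] == pytest.approx(4.0)
        for e, c in coef.items():
            if e != (0, 0):
                assert c == pytest.approx(0.0, abs=1e-10)

    def test_too_few_rows(self, rng):
        with pytest.raises(ValidationError):
            fit_neuron(rng.normal(size=(4, 2)), rng.normal(size=4), 2)


class TestGrowNetwork:
    def test_exact_quadratic_of_two_inputs(self, rng):
        X = rng.normal(size=(120, 5))
        y = 2 + X[:, 1] - 0.5 * X[:, 3] ** 2 + X[:, 1] * X[:, 3]
        model = grow_network(X, y, GsGmdhConfig(mni=2, im=0, pd=2, seed=0))
        assert model.nl == 1
        assert np.sqrt(model.mse) < 1e-8
        out = [n for n in model.neurons if n.name == model.output_name][0]
        assert set(out.input_refs) == {"x2", "x4"}

    def test_two_layer_composition_beats_one_layer(self):
        wins = 0
        for s in range(10):
            r = np.random.default_rng(s)
            X = r.normal(size=(240, 3))
            g = 1 + X[:, 0] * X[:, 1] - X[:, 0] ** 2
            y = g ** 2 + 0.5 * g * X[:, 2] + 0.05 * r.normal(size=240)
            Xtr, ytr, Xte, yte = X[:180], y[:180], X[180:], y[180:]
            deep = grow_network(Xtr, ytr, GsGmdhConfig(mni=2, im=1, pd=2,
                                                       max_layers=3, seed=s))
            shallow = grow_network(Xtr, ytr, GsGmdhConfig(mni=2, im=0, pd=2,
                                                          max_layers=1, seed=s))
            err_d = np.mean((yte - predict(deep, Xte)) ** 2)
            err_s = np.mean((yte - predict(shallow, Xte)) ** 2)
            wins += (deep.nl >= 2 and err_d < err_s)
        assert wins >= 9

    def test_classical_mode_structure(self, rng):
        X = rng.normal(size=(150, 4))
        y = X[:, 0] + X[:, 1] * X[:, 2] + 0.1 * rng.normal(size=150)
        model = grow_network(X, y, GsGmdhConfig(mni=2, im=0, pd=2,
                                                max_layers=3, seed=1))
        for nr in model.neurons:
            assert len(nr.input_refs) == 2
            assert len(nr.coefficients) == 6
            # adjacent wiring only: inputs come from the layer directly below
            for ref in nr.input_refs:
                src_layer = 0 if ref.startswith("x") else int(ref[1])
                assert src_layer == nr.layer - 1

    def test_comp_bookkeeping(self, rng):
        X = rng.normal(size=(150, 4))
        y = np.tanh(X[:, 0]) + X[:, 1] ** 2 + 0.2 * rng.normal(size=150)
        model = grow_network(X, y, GsGmdhConfig(seed=2))
        assert model.comp == model.nl + model.ntn
        assert model.ntn == len(model.neurons)

    def test_dag_acyclic(self, rng):
        X = rng.normal(size=(200, 4))
        y = X[:, 0] * X[:, 1] + np.sin(X[:, 2]) + 0.1 * rng.normal(size=200)
        model = grow_network(X, y, GsGmdhConfig(mni=3, im=1, pd=3, seed=3))
        seen = set(model.input_names)
        for nr in model.neurons:
            assert all(ref in seen for ref in nr.input_refs)
            seen.add(nr.name)

    def test_single_layer_matches_exhaustive_enumeration(self, rng):
        """With max_layers=1 the selected neuron equals the AICC-best of a
        direct enumeration over all pairs/triples and degrees."""
        from itertools import combinations
        from contits.gsgmdh import _design
        from contits.stochastic import aicc as aicc_fn
        X = rng.normal(size=(100, 5))
        y = X[:, 0] - X[:, 2] ** 2 + 0.3 * rng.normal(size=100)
        cfg = GsGmdhConfig(mni=3, im=0, pd=3, max_layers=1,
                           selection_split=0.25, seed=4)
        model = grow_network(X, y, cfg)
        n_sel = 25
        best = np.inf
        for k in (2, 3):
            for combo in combinations(range(5), k):
                for deg in (2, 3):
                    exps = monomial_basis(k, deg)
                    Z = _design(X[:, combo], exps)
                    coef, *_ = np.linalg.lstsq(Z[:75], y[:75], rcond=None)
                    mse = float(np.mean((y[75:] - (Z @ coef)[75:]) ** 2))
                    best = min(best, aicc_fn(n_sel, max(mse, 1e-300), 2))
        out = [n for n in model.neurons if n.name == model.output_name][0]
        Z = _design(X[:, [int(r[1]) - 1 for r in out.input_refs]], out.exponents)
        coef, *_ = np.linalg.lstsq(Z[:75], y[:75], rcond=None)
        mse = float(np.mean((y[75:] - (Z @ coef)[75:]) ** 2))
        assert aicc_fn(n_sel, max(mse, 1e-300), 2) == pytest.approx(best, abs=1e-9)

    def test_too_few_rows_layer1(self, rng):
        with pytest.raises(ValidationError):
            grow_network(rng.normal(size=(6, 3)), rng.normal(size=6),
                         GsGmdhConfig(seed=0))


class TestPredict:
    def test_reproduces_fitted_values(self, rng):
        X = rng.normal(size=(120, 4))
        y = X[:, 0] ** 2 - X[:, 3] + 0.1 * rng.normal(size=120)
        model = grow_network(X, y, GsGmdhConfig(seed=5))
        np.testing.assert_allclose(predict(model, X), model.fitted, atol=1e-10)

    def test_row_permutation_equivariance(self, rng):
        X = rng.normal(size=(100, 4))
        y = X[:, 1] + 0.1 * rng.normal(size=100)
        model = grow_network(X, y, GsGmdhConfig(seed=6))
        perm = rng.permutation(100)
        np.testing.assert_allclose(predict(model, X[perm]),
                                   predict(model, X)[perm], atol=1e-12)

    def test_missing_columns_error(self, rng):
        X = rng.normal(size=(100, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=100)
        model = grow_network(X, y, GsGmdhConfig(seed=7))
        with pytest.raises(ValidationError):
            predict(model, X[:, :3])


class TestSeriesWrapper:
    def test_recovery_rmse_approaches_noise_floor(self):
        """Held-out RMSE of a single-neuron generative law approaches the
        noise level as the sample grows."""
        errs = {}
        for n in (100, 1000):
            r = np.random.default_rng(0)
            X = r.normal(size=(n, 2))
            y = 1 + X[:, 0] + X[:, 0] * X[:, 1] + 0.1 * r.normal(size=n)
            model = grow_network(X[: n // 2], y[: n // 2],
                                 GsGmdhConfig(mni=2, im=0, pd=2, seed=0))
            errs[n] = float(np.sqrt(np.mean(
                (y[n // 2:] - predict(model, X[n // 2:])) ** 2)))
        assert errs[1000] < errs[100]
        assert errs[1000] < 0.15  # close to sigma = 0.1

    def test_forecast_bounded_and_deterministic(self, rng):
        x = np.sin(np.arange(200) * 0.3) + 0.1 * rng.normal(size=200)
        gm = SeriesGsGmdh.fit(x, GsGmdhConfig(mni=2, im=0, pd=2, seed=1))
        f1 = gm.forecast(12)
        f2 = gm.forecast(12)
        np.testing.assert_array_equal(f1, f2)
        assert np.all(np.abs(f1) < 50)
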