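"""Generalized-structure GMDH polynomial network.

Classical GMDH grows a layered network of small quadratic regressions
(Kolmogorov–Gabor / Volterra expansion), each neuron combining two inputs
from the adjacent layer. The generalized structure relaxes all three
classical restrictions: neurons may take two *or three* inputs (MNI), may be
wired to non-adjacent layers and to the original inputs (IM), and may use
degree-2 *or* degree-3 polynomials (PD). That yields four modes, mode 1
(two inputs, degree 2, adjacent wiring) being classical GMDH.

Each candidate neuron is fitted by ordinary least squares on a fit split and
scored on a held-out selection split with the corrected AIC, whose
complexity term for a network is Comp = NL + NTN (layers + total neurons).
Growth stops when the best candidate stops improving; the best neuron
overall becomes the output and its ancestor subgraph is refitted on the full
training rows.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .series_core import TimeSeries, ValidationError, lag_matrix
from .stochastic import aicc

__all__ = ["NeuronSpec", "GsGmdhConfig", "GsGmdhModel", "monomial_basis",
           "napc", "fit_neuron", "grow_network", "predict", "SeriesGsGmdh"]

log = logging.getLogger(__name__)

_MSE_FLOOR = 1e-300  # exact fits: keep AICC finite instead of erroring


def monomial_basis(m: int, degree: int) -> list[tuple[int, ...]]:
    """Exponent tuples of all monomials of total degree ≤ degree in m
    variables, graded-lexicographic, constant first.

    Counts are C(m+degree, degree): 6 for (2,2), 10 for (3,2) and (2,3),
    20 for (3,3).
    """
    if m not in (2, 3) or degree not in (2, 3):
        raise ValidationError("m and degree must each be 2 or 3")
    terms = []
    for total in range(degree + 1):
        level = [
            e for e in itertools.product(range(total + 1), repeat=m)
            if sum(e) == total
        ]
        level.sort(reverse=True)  # lexicographic within the grade
        terms.extend(level)
    return terms


def napc(n: int) -> int:
    """Number of unordered input pairs, n(n−1)/2."""
    if n < 2:
        raise ValidationError("need at least 2 inputs")
    return n * (n - 1) // 2


@dataclass
class NeuronSpec:
    """One polynomial neuron: named inputs, degree, and OLS coefficients
    over the monomial basis."""

    name: str
    input_refs: list[str]
    degree: int
    exponents: list[tuple[int, ...]]
    coefficients: np.ndarray
    layer: int = 0

    def eval(self, cols: list[np.ndarray]) -> np.ndarray:
        Z = _design(np.column_stack(cols), self.exponents)
        return Z @ self.coefficients


def _design(X: np.ndarray, exponents: list[tuple[int, ...]]) -> np.ndarray:
    cols = [np.prod([X[:, i] ** e for i, e in enumerate(exp)], axis=0)
            if any(exp) else np.ones(X.shape[0])
            for exp in exponents]
    return np.column_stack(cols)


def fit_neuron(X: np.ndarray, y: np.ndarray, degree: int) -> NeuronSpec:
    """Least-squares polynomial neuron on the given input columns.

    Rank-deficient systems get the minimum-norm solution (with a logged
    conditioning warning) rather than being dropped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    m = X.shape[1]
    exps = monomial_basis(m, degree)
    if X.shape[0] < len(exps):
        raise ValidationError(
            f"{X.shape[0]} rows < {len(exps)} coefficients for m={m}, degree={degree}"
        )
    Z = _design(X, exps)
    coef, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < len(exps):
        log.warning("rank-deficient neuron design (rank %d < %d); "
                    "minimum-norm solution used", rank, len(exps))
    return NeuronSpec("", [f"x{i+1}" for i in range(m)], degree, exps, coef)


@dataclass
class GsGmdhConfig:
    """Structural controls of the generalized GMDH.

    mni: max inputs per neuron (2 or 3; 3 tries both sizes).
    im: 0 = adjacent-layer wiring only, 1 = earlier layers and original
        inputs are also eligible.
    mnn: surviving neurons per layer; defaults to the number of inputs
        (double it for complex problems).
    pd: polynomial degree cap (2 or 3; 3 tries both degrees).
    """

    mni: int = 3
    im: int = 1
    mnn: int | None = None
    pd: int = 3
    max_layers: int = 4
    selection_split: float = 0.25
    candidate_budget: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mni not in (2, 3) or self.pd not in (2, 3):
            raise ValidationError("mni and pd must each be 2 or 3")
        if self.im not in (0, 1):
            raise ValidationError("im must be 0 or 1")
        if not 0.05 <= self.selection_split <= 0.5:
            raise ValidationError("selection_split must lie in [0.05, 0.5]")
        if self.max_layers < 1:
            raise ValidationError("max_layers must be >= 1")


@dataclass
class GsGmdhModel:
    """A grown network pruned to the output neuron's ancestor subgraph."""

    input_names: list[str]
    neurons: list[NeuronSpec]        # topological order, output last
    output_name: str
    nl: int
    ntn: int
    aicc: float
    mse: float
    fitted: np.ndarray
    input_lags: list[int] | None = None

    @property
    def comp(self) -> int:
        return self.nl + self.ntn

    def to_dict(self) -> dict:
        return {
            "input_names": self.input_names,
            "input_lags": self.input_lags,
            "output": self.output_name,
            "nl": self.nl, "ntn": self.ntn, "comp": self.comp,
            "aicc": self.aicc, "mse": self.mse,
            "neurons": [
                {"name": nr.name, "inputs": nr.input_refs, "degree": nr.degree,
                 "layer": nr.layer,
                 "exponents": [list(e) for e in nr.exponents],
                 "coefficients": nr.coefficients.tolist()}
                for nr in self.neurons
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _score(n_sel: int, mse_sel: float, comp: int, floor: float = _MSE_FLOOR) -> float:
    # exact fits bottom out at a data-scaled floor so that "improvements"
    # below numerical noise cannot justify extra layers
    return aicc(n_sel, max(mse_sel, floor), comp)


def grow_network(
    X: np.ndarray,
    y: np.ndarray,
    config: GsGmdhConfig,
    input_names: list[str] | None = None,
) -> GsGmdhModel:
    """Grow a generalized GMDH network layer by layer.

    Per layer, every 2-subset (and 3-subset when MNI=3) of the eligible
    source nodes is fitted at each allowed degree on the fit split and scored
    by AICC on the selection split with Comp = NL + NTN of the subnetwork
    ending at the candidate. The best MNN candidates survive; growth stops
    when the layer's best score fails to improve on the best so far. The
    winning neuron's ancestor chain is refitted on all training rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValidationError("need at least 2 input columns")
    names = list(input_names) if input_names else [f"x{i+1}" for i in range(m)]
    if len(names) != m:
        raise ValidationError("input_names length mismatch")
    mnn = config.mnn if config.mnn is not None else m
    rng = np.random.default_rng(config.seed)

    mse_floor = max(float(np.var(y)), 1e-30) * 1e-20
    n_sel = max(int(round(config.selection_split * n)), 2)
    fit_sl = slice(0, n - n_sel)
    sel_sl = slice(n - n_sel, n)

    node_vals: dict[str, np.ndarray] = {nm: X[:, i] for i, nm in enumerate(names)}
    node_spec: dict[str, NeuronSpec] = {}
    node_layer: dict[str, int] = {nm: 0 for nm in names}
    prev_layer_names = list(names)
    best_name, best_score = None, np.inf
    scores: dict[str, float] = {}

    sizes = [2, 3] if config.mni == 3 else [2]
    degrees = [2, 3] if config.pd == 3 else [2]

    for layer in range(1, config.max_layers + 1):
        if config.im == 1:
            sources = list(node_vals.keys())
        else:
            sources = prev_layer_names
        pool = [
            (combo, deg)
            for k in sizes if len(sources) >= k
            for combo in itertools.combinations(sources, k)
            for deg in degrees
        ]
        # at least one genuinely new wire per neuron: skip pure-input repeats
        if layer > 1:
            pool = [(c, dg) for c, dg in pool
                    if any(node_layer[s] > 0 for s in c)]
        if len(pool) > config.candidate_budget:
            keep = rng.choice(len(pool), config.candidate_budget, replace=False)
            pool = [pool[i] for i in sorted(keep)]

        candidates = []
        for combo, deg in pool:
            exps = monomial_basis(len(combo), deg)
            if (fit_sl.stop or n) - (fit_sl.start or 0) < len(exps):
                continue
            cols = [node_vals[s] for s in combo]
            Z = _design(np.column_stack(cols), exps)
            coef, *_ = np.linalg.lstsq(Z[fit_sl], y[fit_sl], rcond=None)
            pred = Z @ coef
            mse_sel = float(np.mean((y[sel_sl] - pred[sel_sl]) ** 2))
            ancestors = _ancestor_neurons(combo, node_spec)
            comp = layer + len(ancestors) + 1  # NL + NTN incl. the candidate
            try:
                score = _score(n_sel, mse_sel, comp, mse_floor)
            except ValidationError:
                continue
            candidates.append((score, combo, deg, exps, coef, pred))
        if not candidates:
            if layer == 1:
                raise ValidationError("no fittable candidate at layer 1 "
                                      "(too few rows)")
            break
        candidates.sort(key=lambda c: c[0])
        layer_best = candidates[0][0]
        if layer_best >= best_score:
            break
        survivors = candidates[:mnn]
        new_names = []
        for i, (score, combo, deg, exps, coef, pred) in enumerate(survivors):
            nm = f"L{layer}N{i}"
            node_vals[nm] = pred
            node_spec[nm] = NeuronSpec(nm, list(combo), deg, exps, coef, layer)
            node_layer[nm] = layer
            scores[nm] = score
            new_names.append(nm)
        prev_layer_names = new_names
        if layer_best < best_score:
            best_score = layer_best
            best_name = new_names[0]

    if best_name is None:
        raise ValidationError("network growth selected no neuron")

    # prune to the output's ancestor subgraph and refit on all rows
    retained = _ancestor_neurons(
        [best_name], node_spec) | {best_name}
    ordered = sorted(retained, key=lambda nm: (node_spec[nm].layer, nm))
    refit_vals: dict[str, np.ndarray] = {nm: X[:, i] for i, nm in enumerate(names)}
    final_neurons = []
    for nm in ordered:
        spec = node_spec[nm]
        cols = [refit_vals[s] for s in spec.input_refs]
        Z = _design(np.column_stack(cols), spec.exponents)
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        refit = NeuronSpec(nm, spec.input_refs, spec.degree, spec.exponents,
                           coef, spec.layer)
        refit_vals[nm] = Z @ coef
        final_neurons.append(refit)
    fitted = refit_vals[best_name]
    mse = float(np.mean((y - fitted) ** 2))
    nl = node_spec[best_name].layer
    ntn = len(final_neurons)
    return GsGmdhModel(
        input_names=names, neurons=final_neurons, output_name=best_name,
        nl=nl, ntn=ntn, aicc=_score(n, mse, nl + ntn, mse_floor), mse=mse,
        fitted=fitted,
    )


def _ancestor_neurons(combo, node_spec) -> set[str]:
    out: set[str] = set()
    stack = [s for s in combo if s in node_spec]
    while stack:
        nm = stack.pop()
        if nm in out:
            continue
        out.add(nm)
        stack.extend(s for s in node_spec[nm].input_refs if s in node_spec)
    return out


def predict(model: GsGmdhModel, X: np.ndarray) -> np.ndarray:
    """Deterministic topological evaluation of the network on new rows.

    ``X`` must supply the original input columns in ``model.input_names``
    order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.input_names):
        raise ValidationError(
            f"expected {len(model.input_names)} input columns, got {X.shape[1]}"
        )
    vals: dict[str, np.ndarray] = {
        nm: X[:, i] for i, nm in enumerate(model.input_names)
    }
    for nr in model.neurons:
        missing = [s for s in nr.input_refs if s not in vals]
        if missing:
            raise ValidationError(f"missing input column(s) {missing}")
        vals[nr.name] = nr.eval([vals[s] for s in nr.input_refs])
    return vals[model.output_name]


@dataclass
class SeriesGsGmdh:
    """A GMDH network driven by a series' own lags, for autoregression.

    Default lags {1, 2, 3}: short-memory series need at most a few recent
    values, consistent with correlogram-bounded order selection.
    """

    model: GsGmdhModel
    lags: list[int]
    train_values: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray | TimeSeries, config: GsGmdhConfig,
            lags=(1, 2, 3)) -> "SeriesGsGmdh":
        x = values.values if isinstance(values, TimeSeries) else np.asarray(values, float)
        lags = sorted(set(int(l) for l in lags))
        X, y = lag_matrix(x, lags)
        model = grow_network(X, y, config,
                             input_names=[f"lag{l}" for l in lags])
        model.input_lags = lags
        return cls(model=model, lags=lags, train_values=x)

    def onestep(self, full_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One-step predictions on an extension of the training series.

        Returns (positions, predictions): position ``t`` is predicted from
        observed values at ``t − lag``.
        """
        x = np.asarray(full_values, dtype=float)
        X, _ = lag_matrix(x, self.lags)
        preds = predict(self.model, X)
        positions = np.arange(max(self.lags), x.size)
        return positions, preds

    def forecast(self, horizon: int) -> np.ndarray:
        """Recursive forecast, feeding predictions back through the lags."""
        if horizon < 1:
            raise ValidationError("horizon must be >= 1")
        window = list(self.train_values[-max(self.lags):])
        out = []
        for _ in range(horizon):
            row = np.array([[window[-l] for l in self.lags]])
            val = float(predict(self.model, row)[0])
            out.append(val)
            window.append(val)
        return np.asarray(out)
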