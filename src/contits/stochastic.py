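"""Linear stochastic modeling: subset ARMA/ARIMA selected by a continuous GA.

The model class is ARIMA(p, d, q) with optional seasonal AR/MA lags at
multiples of the period ω. Rather than fixing contiguous orders, each
candidate is a *subset* model: an explicit set of active AR and MA lags
(excluded lags constrained to zero), estimated by exact Gaussian maximum
likelihood. Candidate subsets are scored with the corrected Akaike
information criterion

    AICC = N ln(MSE) + 2 Comp + 2 Comp (Comp + 1) / (N − Comp − 1),

where Comp counts active lags plus the constant term, and the search over
the 2^(p_max+q_max) − 1 subset space is driven by a real-coded (continuous)
genetic algorithm whose chromosome entries in [0, 1] are thresholded at 0.5
into lag-inclusion flags.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .series_core import TimeSeries, ValidationError
from .preprocess import DecompositionRecord

__all__ = ["ArmaSpec", "ArmaModel", "GaConfig", "aicc", "fit_arma",
           "cga_search", "exhaustive_search", "forecast"]

log = logging.getLogger(__name__)


def order_bound_from_acf(train: TimeSeries | np.ndarray, cap: int = 10) -> int:
    """Candidate-order bound from the correlogram: the highest lag outside
    the ±1.96/√N white-noise band, capped (default 10) and at least 1."""
    from .series_core import acf

    x = train.values if isinstance(train, TimeSeries) else np.asarray(train, float)
    max_lag = min(cap, x.size - 2)
    r, band = acf(x, max_lag)
    outside = [k for k in range(1, max_lag + 1) if abs(r[k]) > band]
    return max(outside) if outside else 1


def aicc(n: int, mse: float, comp: int) -> float:
    """Corrected AIC from sample size, mean squared error and complexity."""
    if mse <= 0:
        raise ValidationError("mse must be > 0")
    if n <= comp + 1:
        raise ValidationError(f"need n > comp + 1 (n={n}, comp={comp})")
    return n * math.log(mse) + 2 * comp + 2 * comp * (comp + 1) / (n - comp - 1)


@dataclass(frozen=True)
class ArmaSpec:
    """Subset ARMA/ARIMA specification: explicit active lags per polynomial."""

    ar_lags: frozenset[int] = frozenset()
    ma_lags: frozenset[int] = frozenset()
    sar_lags: frozenset[int] = frozenset()
    sma_lags: frozenset[int] = frozenset()
    d: int = 0
    constant: bool = True
    period: int = 1

    def __post_init__(self) -> None:
        if self.d not in (0, 1, 2):
            raise ValidationError("d must be in {0, 1, 2}")
        for s in (self.ar_lags, self.ma_lags, self.sar_lags, self.sma_lags):
            if any(l < 1 for l in s):
                raise ValidationError("lags must be positive")
        if (self.sar_lags or self.sma_lags) and self.period < 2:
            raise ValidationError("seasonal lags require period >= 2")

    @property
    def comp(self) -> int:
        """Complexity: active (p, q, P, Q) terms plus constant if present."""
        return (len(self.ar_lags) + len(self.ma_lags) + len(self.sar_lags)
                + len(self.sma_lags) + int(self.constant))

    def effective_lags(self) -> tuple[list[int], list[int]]:
        """Non-seasonal + seasonal lags folded into plain AR/MA lag lists."""
        ar = sorted(set(self.ar_lags) | {self.period * l for l in self.sar_lags})
        ma = sorted(set(self.ma_lags) | {self.period * l for l in self.sma_lags})
        return ar, ma

    def key(self) -> tuple:
        return (tuple(sorted(self.ar_lags)), tuple(sorted(self.ma_lags)),
                tuple(sorted(self.sar_lags)), tuple(sorted(self.sma_lags)),
                self.d, self.constant)


@dataclass
class ArmaModel:
    """A fitted subset ARMA/ARIMA model with its AICC bookkeeping."""

    spec: ArmaSpec
    phi: dict[int, float]
    theta: dict[int, float]
    constant: float
    residuals: np.ndarray
    fitted: np.ndarray
    mse: float
    comp: int
    aicc: float
    n_train: int
    converged: bool = True
    _results: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "ar_lags": sorted(self.spec.ar_lags),
                "ma_lags": sorted(self.spec.ma_lags),
                "sar_lags": sorted(self.spec.sar_lags),
                "sma_lags": sorted(self.spec.sma_lags),
                "d": self.spec.d, "constant": self.spec.constant,
                "period": self.spec.period,
            },
            "phi": {str(k): v for k, v in self.phi.items()},
            "theta": {str(k): v for k, v in self.theta.items()},
            "constant": self.constant,
            "mse": self.mse, "comp": self.comp, "aicc": self.aicc,
            "n_train": self.n_train, "converged": self.converged,
        }


class FitFailure(Exception):
    """Persistent estimation failure; the GA treats this as −∞ fitness."""


def fit_arma(train: TimeSeries | np.ndarray, spec: ArmaSpec) -> ArmaModel:
    """Exact Gaussian ML fit of a subset ARMA/ARIMA model.

    Only the lags named in ``spec`` receive free coefficients. Residuals are
    taken after the differencing burn-in, so MSE and AICC use N − d
    effective observations.
    """
    x = train.values if isinstance(train, TimeSeries) else np.asarray(train, float)
    ar, ma = spec.effective_lags()
    n_eff = x.size - spec.d
    if n_eff <= spec.comp + 10:
        raise ValidationError("too few observations for this specification")

    from statsmodels.tsa.statespace.sarimax import SARIMAX

    order = (ar if ar else 0, spec.d, ma if ma else 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            x, order=order, trend="c" if spec.constant else "n",
            concentrate_scale=True,
        )
        try:
            res = model.fit(disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged:
                res = model.fit(disp=0, method="nm", maxiter=500,
                                start_params=res.params)
                converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:
            raise FitFailure(str(exc)) from exc

    resid = np.asarray(res.resid, dtype=float)[spec.d:]
    fitted = np.asarray(res.fittedvalues, dtype=float)[spec.d:]
    mse = float(np.mean(resid ** 2))
    comp = spec.comp
    if mse <= 0 or not np.isfinite(mse):
        raise FitFailure("degenerate residual variance")

    params = dict(zip(res.model.param_names, np.asarray(res.params, float)))
    phi = {lag: params.get(f"ar.L{lag}", 0.0) for lag in ar}
    theta = {lag: params.get(f"ma.L{lag}", 0.0) for lag in ma}
    const = float(params.get("intercept", 0.0))
    return ArmaModel(
        spec=spec, phi=phi, theta=theta, constant=const, residuals=resid,
        fitted=fitted, mse=mse, comp=comp,
        aicc=aicc(n_eff, mse, comp), n_train=x.size, converged=converged,
        _results=res,
    )


@dataclass
class GaConfig:
    """Continuous-GA settings for the subset search.

    Chromosome length is p_max + q_max (+ P_max + Q_max when seasonal) + 1
    (constant flag); entries live in [0, 1] and decode to inclusion at the
    0.5 threshold.
    """

    population: int = 40
    generations: int = 60
    crossover: float = 0.8
    mutation: float = 0.1
    seed: int = 0
    p_max: int = 10
    q_max: int = 10
    P_max: int = 0
    Q_max: int = 0
    elitism: int = 2
    tournament: int = 3
    immigrants: int = 2  # fresh random chromosomes per generation

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1:
            raise ValidationError("population and generations must be positive")
        for r in (self.crossover, self.mutation):
            if not 0 <= r <= 1:
                raise ValidationError("rates must lie in [0, 1]")


def _decode(chrom: np.ndarray, ga: GaConfig, d: int, period: int) -> ArmaSpec:
    bits = chrom >= 0.5
    idx = 0
    ar = frozenset(i + 1 for i in range(ga.p_max) if bits[idx + i]); idx += ga.p_max
    ma = frozenset(i + 1 for i in range(ga.q_max) if bits[idx + i]); idx += ga.q_max
    sar = frozenset(i + 1 for i in range(ga.P_max) if bits[idx + i]); idx += ga.P_max
    sma = frozenset(i + 1 for i in range(ga.Q_max) if bits[idx + i]); idx += ga.Q_max
    const = bool(bits[idx])
    return ArmaSpec(ar, ma, sar, sma, d=d, constant=const,
                    period=period if (sar or sma) else max(period, 1))


class _FitCache:
    """Memoized subset fits on one training series (shared GA/exhaustive)."""

    def __init__(self, train):
        self.train = train
        self.cache: dict[tuple, ArmaModel | None] = {}

    def fit(self, spec: ArmaSpec) -> ArmaModel | None:
        key = spec.key()
        if key not in self.cache:
            try:
                self.cache[key] = fit_arma(self.train, spec)
            except (FitFailure, ValidationError) as exc:
                log.debug("fit failed for %s: %s", key, exc)
                self.cache[key] = None
        return self.cache[key]


def cga_search(
    train: TimeSeries | np.ndarray,
    ga: GaConfig,
    d: int = 0,
    seasonal: bool = False,
    period: int = 1,
    _cache: "_FitCache | None" = None,
) -> ArmaModel:
    """Continuous-GA subset selection minimizing training AICC.

    Tournament selection, whole-arithmetic crossover and Gaussian mutation on
    real chromosomes in [0, 1]; fitness is −AICC of the decoded subset model.
    Deterministic under a fixed seed; the best spec per generation is logged
    and the best model found is returned (an all-zero chromosome decodes to a
    constant-only model, which is valid).
    """
    x = train.values if isinstance(train, TimeSeries) else np.asarray(train, float)
    if x.size < 30:
        raise ValidationError("CGA search needs training length >= 30")
    if not seasonal:
        ga = GaConfig(**{**ga.__dict__, "P_max": 0, "Q_max": 0})
    rng = np.random.default_rng(ga.seed)
    nbits = ga.p_max + ga.q_max + ga.P_max + ga.Q_max + 1
    cache = _cache if _cache is not None else _FitCache(x)

    def fitness(chrom: np.ndarray) -> tuple[float, ArmaModel | None]:
        spec = _decode(chrom, ga, d, period)
        model = cache.fit(spec)
        if model is None:
            return -np.inf, None
        return -model.aicc, model

    pop = rng.random((ga.population, nbits))
    scores = np.empty(ga.population)
    models: list[ArmaModel | None] = [None] * ga.population
    for i in range(ga.population):
        scores[i], models[i] = fitness(pop[i])
    best_i = int(np.argmax(scores))
    best_score, best_model = scores[best_i], models[best_i]
    history = []

    for gen in range(ga.generations):
        order = np.argsort(scores)[::-1]
        new_pop = [pop[i].copy() for i in order[: ga.elitism]]
        while len(new_pop) < ga.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population, ga.tournament)
                parents.append(pop[contenders[np.argmax(scores[contenders])]])
            a, b = parents
            if rng.random() < ga.crossover:
                w = rng.random(nbits)
                c1 = w * a + (1 - w) * b
                c2 = w * b + (1 - w) * a
            else:
                c1, c2 = a.copy(), b.copy()
            for child in (c1, c2):
                mask = rng.random(nbits) < ga.mutation
                child[mask] = np.clip(child[mask] + rng.normal(0, 0.35, mask.sum()),
                                      0.0, 1.0)
                new_pop.append(child)
        pop = np.array(new_pop[: ga.population])
        if ga.immigrants:
            # random immigrants guard against premature convergence
            pop[-ga.immigrants:] = rng.random((ga.immigrants, nbits))
        for i in range(ga.population):
            scores[i], models[i] = fitness(pop[i])
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best_score, best_model = scores[gen_best], models[gen_best]
        if models[gen_best] is not None:
            history.append((gen, models[gen_best].spec.key(),
                            models[gen_best].aicc))
            log.debug("generation %d best %s aicc=%.4f", gen,
                      models[gen_best].spec.key(), models[gen_best].aicc)

    if best_model is None:
        # every evaluated spec failed; fall back to constant-only
        best_model = cache.fit(ArmaSpec(d=d, constant=True, period=period))
        if best_model is None:
            raise FitFailure("no specification could be fitted")
    return best_model


def exhaustive_search(
    train: TimeSeries | np.ndarray,
    p_max: int,
    q_max: int,
    d: int = 0,
    constant: bool = True,
    _cache: "_FitCache | None" = None,
) -> ArmaModel:
    """Enumerate every lag subset (2^(p_max+q_max) models) and return the
    AICC-best fit; tractable only for small bounds, used as the GA oracle."""
    x = train.values if isinstance(train, TimeSeries) else np.asarray(train, float)
    cache = _cache if _cache is not None else _FitCache(x)
    best = None
    for mask in range(2 ** (p_max + q_max)):
        ar = frozenset(i + 1 for i in range(p_max) if (mask >> i) & 1)
        ma = frozenset(i + 1 for i in range(q_max) if (mask >> (p_max + i)) & 1)
        model = cache.fit(ArmaSpec(ar, ma, d=d, constant=constant))
        if model is not None and (best is None or model.aicc < best.aicc):
            best = model
    if best is None:
        raise FitFailure("no specification could be fitted")
    return best


def forecast(
    model: ArmaModel, horizon: int, record: DecompositionRecord | None = None
) -> np.ndarray:
    """Recursive multi-step forecast (future shocks at zero), mapped back to
    the original outcome scale when a preprocessing record is supplied."""
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    if model._results is None:
        raise ValidationError("model carries no fitted state")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = np.asarray(model._results.forecast(steps=horizon), dtype=float)
    if record is not None:
        z = record.invert_forecast(z, model.n_train)
    return z


def onestep_predictions(model: ArmaModel, full_series: np.ndarray) -> np.ndarray:
    """One-step-ahead predictions over a series extending the training data.

    The fitted parameters are applied (no refit) to ``full_series`` — the
    training series followed by held-out continuation values on the same
    (transformed) scale. Returns the one-step predicted mean at every
    position, aligned with ``full_series``.
    """
    if model._results is None:
        raise ValidationError("model carries no fitted state")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        applied = model._results.apply(np.asarray(full_series, dtype=float))
        pred = applied.get_prediction(start=0, end=len(full_series) - 1)
    return np.asarray(pred.predicted_mean, dtype=float)
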