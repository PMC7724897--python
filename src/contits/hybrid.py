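"""Hybrid stochastic + polynomial-network model of an interrupted series.

The combination models the linear, short-memory structure with a GA-selected
subset ARMA/ARIMA on the preprocessed series, then treats the training
residuals of that linear model as a new series and fits a generalized GMDH
network on the residuals' own lags. Forecasts are the sum of the two stages,
mapped back to the original outcome scale.

Because the pipeline never receives a change-point or lag argument, the
approach is lag-agnostic by construction: an intervention whose effect is
delayed simply alters the series the diagnostics and models see, not the API.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .series_core import TimeSeries, SplitSpec, ValidationError, split_train_test
from .preprocess import DecompositionRecord, fit_linear_trend, normalize
from .diagnostics import kpss
from .stochastic import (ArmaModel, GaConfig, cga_search, forecast,
                         onestep_predictions)
from .gsgmdh import GsGmdhConfig, SeriesGsGmdh

__all__ = ["HybridModel", "fit_hybrid", "forecast_hybrid", "predict_onestep"]

log = logging.getLogger(__name__)

_DEGENERATE_VAR = 1e-12


@dataclass
class HybridModel:
    """Fitted linear stage, preprocessing record, and residual network."""

    linear: ArmaModel
    record: DecompositionRecord
    nonlinear: SeriesGsGmdh | None
    residual_lags: list[int]
    model_kind: str
    n_train: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "n_train": self.n_train,
            "degenerate": self.degenerate,
            "residual_lags": self.residual_lags,
            "linear": self.linear.to_dict(),
            "record": json.loads(self.record.to_json()),
            "nonlinear": (self.nonlinear.model.to_dict()
                          if self.nonlinear is not None else None),
        }


def fit_hybrid(
    ts: TimeSeries,
    split: SplitSpec,
    model_kind: str = "arma",
    ga: GaConfig | None = None,
    gs: GsGmdhConfig | None = None,
    residual_lags=(1, 2, 3),
) -> HybridModel:
    """Fit the two-stage hybrid on the training window.

    ``model_kind='arma'`` pairs with the detrending scenario (fit and remove
    a linear trend, then model with d=0); ``'arima'`` pairs with the
    differencing scenario (d=1 inside the stochastic stage). The linear
    stage's training residuals — exactly, not a re-computation — become the
    nonlinear stage's training series. Near-constant residuals degrade the
    hybrid to its linear stage with a logged notice.
    """
    if model_kind not in ("arma", "arima"):
        raise ValidationError("model_kind must be 'arma' or 'arima'")
    ga = ga if ga is not None else GaConfig()
    gs = gs if gs is not None else GsGmdhConfig()
    train, _ = split_train_test(ts, split)
    if split.n_train < 40:
        raise ValidationError("hybrid fitting needs training length >= 40")

    if model_kind == "arma":
        # scenario 1: remove the fitted line, then normalize; model with d=0
        _, _, detrended, trend_rec = fit_linear_trend(train)
        z_train, norm_rec = normalize(detrended)
        record = DecompositionRecord(
            steps=trend_rec.steps + [s for s in norm_rec.steps if s[0] != "none"]
        )
        try:
            if kpss(z_train, "level").reject:
                log.warning("detrended series still rejects KPSS; "
                            "proceeding flagged")
                record.warnings.append("kpss-reject-after-detrend")
        except ValidationError:
            pass
        d = 0
    else:
        # scenario 2: differencing happens inside the stochastic stage (d=1)
        z_train, record = normalize(train)
        record.steps = [s for s in record.steps if s[0] != "none"]
        d = 1

    linear = cga_search(z_train, ga, d=d, period=ts.period)
    resid = linear.residuals
    if float(np.var(resid)) < _DEGENERATE_VAR:
        log.info("linear residuals are near-constant; hybrid degenerates "
                 "to the linear model")
        return HybridModel(linear, record, None, sorted(residual_lags),
                           model_kind, split.n_train, degenerate=True)
    nonlinear = SeriesGsGmdh.fit(resid, gs, lags=residual_lags)
    return HybridModel(linear, record, nonlinear, sorted(residual_lags),
                       model_kind, split.n_train)


def forecast_hybrid(model: HybridModel, horizon: int) -> np.ndarray:
    """Multi-step forecast: linear forecast plus recursive residual forecast,
    inverse-preprocessed to the original outcome scale.

    Beyond one step the residual network feeds its own predictions back
    through the lags; with a zero nonlinear component this equals the linear
    forecast exactly.
    """
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    lin = forecast(model.linear, horizon)  # transformed scale, d integrated
    if model.nonlinear is not None:
        lin = lin + model.nonlinear.forecast(horizon)
    return model.record.invert_forecast(lin, model.n_train)


def predict_onestep(
    model: HybridModel, full: TimeSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling one-step-ahead predictions over the full series.

    ``full`` is the training series followed by held-out continuation values.
    The linear stage is applied (fixed parameters, no refit) to the
    transformed full series; the residual network predicts each step's
    residual from *observed* previous residuals; the sum is inverted to the
    outcome scale. Returns (positions, predictions) aligned with ``full``;
    positions before max(residual_lags) carry the linear prediction alone.
    """
    if "difference" in model.record.tags:
        raise ValidationError(
            "one-step inversion expects a difference-free record; "
            "differencing lives inside the stochastic stage"
        )
    z_full = model.record.apply(full.values)
    lin_pred = onestep_predictions(model.linear, z_full)
    combined = lin_pred.copy()
    if model.nonlinear is not None:
        resid_full = z_full - lin_pred
        pos, eps_hat = model.nonlinear.onestep(resid_full)
        combined[pos] += eps_hat
    original = model.record.invert(combined)
    positions = np.arange(len(full))
    return positions, original
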