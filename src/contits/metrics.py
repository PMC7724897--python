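"""Forecast-verification indices and Taylor-diagram coordinates.

The index suite used throughout: Pearson correlation R, scatter index SI
(RMSE over the observed mean, a fraction), MAPE (percent), RMSE on the
outcome scale, RMSRE (the mean-normalized RMSE in percent, the convention
behind results tables that report "RMSRE"), performance index ρ = SI/(1+R),
Nash–Sutcliffe efficiency E_NS, and a residual-variance AICC variant used
for model reporting. Taylor coordinates (model SD, R, centered RMSE) satisfy
the law-of-cosines identity crmse² = sd_o² + sd_m² − 2·sd_o·sd_m·R.

Two AICC forms coexist in the package and are never interchanged: the
model-selection form N·ln(MSE) + complexity penalty (``stochastic.aicc``)
and the residual-variance form computed here when ``k`` is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .series_core import ValidationError

__all__ = ["MetricsReport", "TaylorPoint", "evaluate", "taylor_coordinates"]


@dataclass(frozen=True)
class MetricsReport:
    """All verification indices for one (observed, predicted) pair.

    Indices whose denominator is degenerate on a given input (e.g. R on a
    constant observed series) are reported as ``nan`` while the others are
    still computed.
    """

    r: float
    si: float          # fraction
    mape: float        # percent
    rmse: float        # outcome units
    rmsre: float       # percent (mean-normalized RMSE)
    rho: float         # fraction, SI / (1 + R)
    e_ns: float
    aicc_residual: float | None
    sd_obs: float
    sd_model: float
    centered_rmse: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "r", "si", "mape", "rmse", "rmsre", "rho", "e_ns",
            "aicc_residual", "sd_obs", "sd_model", "centered_rmse", "n")}


class TaylorPoint(NamedTuple):
    sd: float
    r: float
    centered_rmse: float


def evaluate(obs, pred, k: int | None = None,
             sigma_as_std: bool = False) -> MetricsReport:
    """Compute the full verification suite for one prediction series.

    ``k`` enables the residual-variance AICC. ``sigma_as_std`` switches that
    variant's σ²ε term from residual variance (default) to residual standard
    deviation, for comparability with reports using the other reading.
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValidationError("obs and pred must be equal-length 1-d arrays")
    n = o.size
    if n < 2:
        raise ValidationError("need at least 2 points")

    err = o - p
    mse = float(np.mean(err ** 2))
    rmse = math.sqrt(mse)
    obar = float(o.mean())
    pbar = float(p.mean())

    oc = o - obar
    pc = p - pbar
    so = math.sqrt(float(np.mean(oc ** 2)))
    sp = math.sqrt(float(np.mean(pc ** 2)))
    if so > 0 and sp > 0:
        # a perfect prediction yields the identity exactly, not to rounding
        r = 1.0 if mse == 0.0 else float(np.dot(oc, pc) / (n * so * sp))
    else:
        r = float("nan")

    si = rmse / obar if obar != 0 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        ape = np.abs(err) / np.abs(o)
    mape = float(100.0 * np.mean(ape)) if np.all(o != 0) else float("nan")
    rmsre = 100.0 * si if np.isfinite(si) else float("nan")
    rho = (si / (1.0 + r)
           if np.isfinite(si) and np.isfinite(r) and r > -1.0 else float("nan"))

    sso = float(np.sum(oc ** 2))
    e_ns = 1.0 - float(np.sum(err ** 2)) / sso if sso > 0 else float("nan")

    aicc_res = None
    if k is not None:
        resid = err
        sig2 = float(np.std(resid)) if sigma_as_std else float(np.var(resid))
        if sig2 > 0 and n - k - 1 > 0:
            aicc_res = (2 * k * n + n * math.log(sig2) * (n - k - 1)) / (n - k - 1)
        else:
            aicc_res = float("nan")

    crmse = math.sqrt(float(np.mean((pc - oc) ** 2)))
    return MetricsReport(
        r=r, si=si, mape=mape, rmse=rmse, rmsre=rmsre, rho=rho, e_ns=e_ns,
        aicc_residual=aicc_res, sd_obs=so, sd_model=sp, centered_rmse=crmse,
        n=n,
    )


def taylor_coordinates(obs, preds: dict[str, np.ndarray]) -> dict[str, TaylorPoint]:
    """Per-model Taylor coordinates (SD, R, centered RMSE) against ``obs``.

    Population (divide-by-N) standard deviations are used so the
    law-of-cosines identity holds exactly.
    """
    o = np.asarray(obs, dtype=float)
    out = {}
    for name, p in preds.items():
        rep = evaluate(o, np.asarray(p, dtype=float))
        out[name] = TaylorPoint(rep.sd_model, rep.r, rep.centered_rmse)
    return out
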