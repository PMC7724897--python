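"""Deterministic-term, stationarity and normality test battery.

Before stochastic modeling, the series is screened for the three removable
deterministic terms — trend (Mann–Kendall, seasonal Mann–Kendall), jump
(Mann–Whitney rank test on two sub-periods) and period (Fisher's test on the
periodogram) — plus overall stationarity (KPSS) and marginal normality
(Jarque–Bera). Residual independence of fitted models is checked with the
Ljung–Box statistic. Every test returns a uniform :class:`TestResult`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .series_core import TimeSeries, ValidationError, _acf_values

__all__ = [
    "TestResult",
    "BatteryReport",
    "mann_kendall",
    "seasonal_mann_kendall",
    "mann_whitney_jump",
    "fisher_period",
    "kpss",
    "jarque_bera",
    "ljung_box",
    "deterministic_battery",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """Statistic + decision container shared by all diagnostic tests.

    ``reject`` is a pure function of the statistic or p-value against the
    critical value or level per each test's decision rule. ``details`` holds
    named intermediates (e.g. the raw MK score and its variance).
    """

    test_name: str
    statistic: float
    p_value: float | None
    alpha: float
    reject: bool
    critical_value: float | None = None
    details: dict = field(default_factory=dict)


def _values(ts) -> np.ndarray:
    return ts.values if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=float)


# ---------------------------------------------------------------------------
# trend


def _mk_score_var(x: np.ndarray) -> tuple[float, float]:
    """Raw Mann–Kendall score and its variance with the tie-group correction."""
    n = x.size
    sgn = np.sign(x[None, :] - x[:, None])
    mk = float(np.triu(sgn, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return mk, float(var)


def _mk_standardize(mk: float, var: float) -> float:
    if var <= 0:
        return 0.0
    if mk > 0:
        return (mk - 1) / math.sqrt(var)
    if mk < 0:
        return (mk + 1) / math.sqrt(var)
    return 0.0


def mann_kendall(ts, alpha: float = 0.05) -> TestResult:
    """Non-parametric test for a monotone (gradual) trend.

    The score S = ΣΣ sgn(x_j − x_i) over ordered pairs is standardized with a
    continuity correction and compared two-sided against normal quantiles.
    A constant series yields S = 0 and no trend (not an error).
    """
    x = _values(ts)
    if x.size < 4:
        raise ValidationError("Mann–Kendall needs length >= 4")
    mk, var = _mk_score_var(x)
    u = _mk_standardize(mk, var)
    p = 2 * stats.norm.sf(abs(u))
    crit = stats.norm.ppf(1 - alpha / 2)
    return TestResult(
        "mann_kendall", u, float(p), alpha, bool(abs(u) > crit), float(crit),
        {"MK": mk, "var_MK": var, "n": x.size},
    )


def seasonal_mann_kendall(ts, omega: int | None = None, alpha: float = 0.05) -> TestResult:
    """Seasonal Mann–Kendall: per-season scores aggregated across seasons.

    Cross-season covariances are taken as zero (independent-seasons
    assumption). The continuity correction is applied once to the aggregate
    score (the standard convention; a per-season correction shrinks the
    statistic and makes the test measurably conservative); with ω=1 the
    statistic reduces exactly to the non-seasonal test.
    """
    x = _values(ts)
    if omega is None:
        omega = ts.period if isinstance(ts, TimeSeries) else 1
    if omega == 1:
        res = mann_kendall(x, alpha)
        return TestResult("seasonal_mann_kendall", res.statistic, res.p_value,
                          alpha, res.reject, res.critical_value, res.details)
    if omega < 2:
        raise ValidationError("omega must be >= 1")
    if x.size < 3 * omega:
        raise ValidationError("seasonal Mann–Kendall needs >= 3 complete cycles")
    if x.size % omega:
        log.warning(
            "series length %d is not a multiple of omega=%d; trailing partial "
            "cycle enters its seasons with one extra observation", x.size, omega,
        )
    smk = 0.0
    var = 0.0
    s_ks = []
    for k in range(omega):
        xk = x[k::omega]
        s_k, v_k = _mk_score_var(xk)
        s_ks.append(s_k)
        smk += s_k
        var += v_k
    u = _mk_standardize(smk, var)
    p = 2 * stats.norm.sf(abs(u))
    crit = stats.norm.ppf(1 - alpha / 2)
    return TestResult(
        "seasonal_mann_kendall", float(u), float(p), alpha, bool(abs(u) > crit),
        float(crit), {"SMK": float(smk), "var_SMK": float(var), "S_k": s_ks,
                      "omega": omega},
    )


# ---------------------------------------------------------------------------
# jump


def mann_whitney_jump(ts, split_index: int, alpha: float = 0.05) -> TestResult:
    """Rank test for an abrupt level shift between two sub-periods.

    The full series is ranked (average ranks for ties) and the standardized
    rank-sum of the leading ``split_index`` points is compared two-sided
    against the normal distribution. The split point is a parameter: the
    intervention date when known, otherwise the midpoint.
    """
    x = _values(ts)
    n = x.size
    if not (2 <= split_index <= n - 2):
        raise ValidationError(f"split_index {split_index} outside [2, {n - 2}]")
    n1 = split_index
    n2 = n - n1
    ranks = stats.rankdata(x)
    u = (ranks[:n1].sum() - n1 * (n1 + n2 + 1) / 2.0) / math.sqrt(
        n1 * n2 * (n1 + n2 + 1) / 12.0
    )
    p = 2 * stats.norm.sf(abs(u))
    crit = stats.norm.ppf(1 - alpha / 2)
    return TestResult(
        "mann_whitney", float(u), float(p), alpha, bool(abs(u) > crit), float(crit),
        {"n1": n1, "n2": n2, "rank_sum_1": float(ranks[:n1].sum())},
    )


# ---------------------------------------------------------------------------
# period


def _periodogram_coeffs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier coefficients a_z, b_z at harmonics z = 1..⌊(N−1)/2⌋."""
    n = x.size
    k = (n - 1) // 2
    t = np.arange(1, n + 1)
    z = np.arange(1, k + 1)
    ang = 2 * np.pi * np.outer(z, t) / n
    a = (2.0 / n) * np.cos(ang) @ x
    b = (2.0 / n) * np.sin(ang) @ x
    return a, b, z


def _fisher_g_pvalue(g: float, k: int) -> float:
    """Exact null tail probability of Fisher's g (max ordinate / total)."""
    if g <= 0:
        return 1.0
    jmax = min(k, int(math.floor(1.0 / g)))
    p = 0.0
    for j in range(1, jmax + 1):
        term = math.comb(k, j) * (1 - j * g) ** (k - 1)
        p += term if j % 2 == 1 else -term
    return float(min(max(p, 0.0), 1.0))


def fisher_period(ts, alpha: float = 0.05) -> TestResult:
    """Fisher's test for a significant periodic component.

    The harmonic with the largest periodogram ordinate a_z²+b_z² is tested.
    The reported statistic is the harmonic-regression F ratio
    N(N−2)(a²+b²)/(4·RSS) at that harmonic; the decision uses the exact null
    distribution of Fisher's g (the maximal ordinate over the ordinate sum),
    which is size-correct for a maximum over harmonics. The F(2, N−2)
    critical value is reported alongside for the conventional readout.
    """
    x = _values(ts)
    n = x.size
    if n < 8:
        raise ValidationError("Fisher period test needs length >= 8")
    a, b, z = _periodogram_coeffs(x)
    ordin = a ** 2 + b ** 2
    k = ordin.size
    imax = int(np.argmax(ordin))
    t = np.arange(1, n + 1)
    omega_z = 2 * np.pi * z[imax] / n
    resid = x - x.mean() - a[imax] * np.cos(omega_z * t) - b[imax] * np.sin(omega_z * t)
    rss = float(np.dot(resid, resid))
    f_star = n * (n - 2) * ordin[imax] / (4 * rss) if rss > 0 else np.inf
    g = float(ordin[imax] / ordin.sum()) if ordin.sum() > 0 else 0.0
    p = _fisher_g_pvalue(g, k)
    f_crit = float(stats.f.ppf(1 - alpha, 2, n - 2))
    return TestResult(
        "fisher", float(f_star), p, alpha, bool(p < alpha), f_crit,
        {"g": g, "harmonic": int(z[imax]), "frequency": float(z[imax] / n),
         "alpha_z": float(a[imax]), "beta_z": float(b[imax]), "n_harmonics": k},
    )


# ---------------------------------------------------------------------------
# stationarity


def kpss(ts, variant: str = "level", truncation_lag: int | str = "auto",
         alpha: float = 0.05) -> TestResult:
    """KPSS stationarity test (null: stationary around a level or a trend).

    Long-run variance uses Bartlett weights 1 − s/(l+1); default truncation
    l = ⌊4(n/100)^0.25⌋. The p-value is interpolated in the published
    critical-value table, so it is censored to [0.01, 0.10]. Stationary iff
    p > alpha.
    """
    x = _values(ts)
    n = x.size
    if n < 10:
        raise ValidationError("KPSS needs length >= 10")
    if variant not in ("level", "trend"):
        raise ValidationError("variant must be 'level' or 'trend'")
    if truncation_lag == "auto":
        nlags = int(4 * (n / 100.0) ** 0.25)
    else:
        nlags = int(truncation_lag)
        if nlags >= n:
            raise ValidationError("truncation lag must be < length")
    from statsmodels.tsa.stattools import kpss as sm_kpss

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p, used_lags, crit = sm_kpss(
            x, regression="c" if variant == "level" else "ct", nlags=nlags
        )
    return TestResult(
        "kpss", float(stat), float(p), alpha, bool(p < alpha),
        float(crit.get("5%")), {"variant": variant, "lags": int(used_lags),
                                "critical_values": crit},
    )


# ---------------------------------------------------------------------------
# normality


def jarque_bera(ts, alpha: float = 0.05) -> TestResult:
    """Jarque–Bera normality test from sample skewness and kurtosis."""
    x = _values(ts)
    n = x.size
    if n < 8:
        raise ValidationError("Jarque–Bera needs length >= 8")
    m = x.mean()
    c = x - m
    m2 = float(np.mean(c ** 2))
    if m2 == 0:
        raise ValidationError("zero variance: moments undefined")
    s_k = float(np.mean(c ** 3)) / m2 ** 1.5
    k_u = float(np.mean(c ** 4)) / m2 ** 2
    jb = n * (s_k ** 2 / 6.0 + (k_u - 3.0) ** 2 / 24.0)
    p = float(stats.chi2.sf(jb, 2))
    return TestResult(
        "jarque_bera", float(jb), p, alpha, bool(p < alpha),
        float(stats.chi2.ppf(1 - alpha, 2)),
        {"skewness": s_k, "kurtosis": k_u, "n": n},
    )


# ---------------------------------------------------------------------------
# residual independence


def ljung_box(residuals, n_lags: int | str = "auto", alpha: float = 0.05,
              model_df: int = 0) -> TestResult:
    """Ljung–Box portmanteau test for residual autocorrelation.

    Q = N(N+2) Σ_{h=1}^{m} r_h²/(N−h), compared against χ² with m − model_df
    degrees of freedom. Default lag count m = round(ln N). Residuals are
    white noise (model adequate) iff p > alpha.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 8:
        raise ValidationError("Ljung–Box needs length >= 8")
    m = int(round(math.log(n))) if n_lags == "auto" else int(n_lags)
    if m >= n:
        raise ValidationError("n_lags must be < length")
    if m < 1:
        raise ValidationError("n_lags must be >= 1")
    r = _acf_values(x, m)[1:]
    q = n * (n + 2) * float(np.sum(r ** 2 / (n - np.arange(1, m + 1))))
    dof = max(m - model_df, 1)
    p = float(stats.chi2.sf(q, dof))
    return TestResult(
        "ljung_box", float(q), p, alpha, bool(p < alpha),
        float(stats.chi2.ppf(1 - alpha, dof)),
        {"m": m, "dof": dof, "r_h": r.tolist()},
    )


# ---------------------------------------------------------------------------
# battery


@dataclass
class BatteryReport:
    """Ordered report of the full test battery with per-term verdicts."""

    results: dict[str, TestResult | None]
    errors: dict[str, str]
    verdicts: dict[str, bool]
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.results.items():
            if res is None:
                rows.append({"test": name, "error": self.errors.get(name, "")})
            else:
                rows.append({
                    "test": name, "statistic": res.statistic,
                    "p_value": res.p_value, "critical_value": res.critical_value,
                    "alpha": res.alpha, "reject": res.reject,
                })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {"label": self.label, "verdicts": self.verdicts, "tests": {}}
        for name, res in self.results.items():
            if res is None:
                out["tests"][name] = {"error": self.errors.get(name, "")}
            else:
                out["tests"][name] = {
                    "statistic": res.statistic, "p_value": res.p_value,
                    "critical_value": res.critical_value, "alpha": res.alpha,
                    "reject": res.reject,
                }
        return out


def battery_table(ts: TimeSeries, alpha: float = 0.05,
                  jump_alpha: float | None = None) -> pd.DataFrame:
    """Battery p-values for the main, detrended and differenced variants.

    One row per series variant, one column per test — the conventional
    preprocessing-screen layout used to decide which deterministic terms to
    remove.
    """
    from .preprocess import difference, fit_linear_trend

    variants = {"main": ts}
    _, _, detr, _ = fit_linear_trend(ts)
    variants["detrended"] = detr
    variants["differenced"] = difference(ts, 1)[0]
    rows = []
    for name, variant in variants.items():
        rep = deterministic_battery(variant, alpha=alpha, jump_alpha=jump_alpha)
        row = {"series": name}
        for tname, res in rep.results.items():
            row[tname] = res.p_value if res is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def deterministic_battery(
    ts: TimeSeries,
    alpha: float = 0.05,
    jump_alpha: float | None = None,
    split_index: int | None = None,
    omega: int | None = None,
) -> BatteryReport:
    """Run the full screen: trend, seasonal trend, jump, period,
    stationarity and normality; individual failures are recorded and the
    battery continues.

    ``jump_alpha`` defaults to ``alpha`` (the case study used a stricter 0.01
    for the jump test). ``split_index`` defaults to the series midpoint; pass
    the intervention date when known.
    """
    x = ts.values
    omega = omega if omega is not None else ts.period
    split = split_index if split_index is not None else len(ts) // 2
    jump_alpha = jump_alpha if jump_alpha is not None else alpha

    plan = {
        "mann_kendall": lambda: mann_kendall(ts, alpha),
        "seasonal_mann_kendall": lambda: seasonal_mann_kendall(ts, omega, alpha),
        "mann_whitney": lambda: mann_whitney_jump(ts, split, jump_alpha),
        "fisher": lambda: fisher_period(ts, alpha),
        "kpss": lambda: kpss(ts, "level", "auto", alpha),
        "jarque_bera": lambda: jarque_bera(ts, alpha),
    }
    results: dict[str, TestResult | None] = {}
    errors: dict[str, str] = {}
    for name, fn in plan.items():
        try:
            results[name] = fn()
        except Exception as exc:  # keep going; propagate in the report
            results[name] = None
            errors[name] = str(exc)
            log.warning("battery test %s failed: %s", name, exc)

    def _rej(name):
        r = results.get(name)
        return bool(r.reject) if r is not None else False

    verdicts = {
        "trend": _rej("mann_kendall"),
        "seasonal_trend": _rej("seasonal_mann_kendall"),
        "jump": _rej("mann_whitney"),
        "period": _rej("fisher"),
        "stationary": not _rej("kpss"),
        "normal": not _rej("jarque_bera"),
    }
    return BatteryReport(results, errors, verdicts, label=ts.label)
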