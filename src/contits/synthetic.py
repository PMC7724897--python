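"""Synthetic interrupted-time-series fixtures with known ground truth.

An intervention at a change point can alter the post-period series in nine
canonical ways: a level (intercept) change — immediate (a), after a lag (b)
or temporary (c); a slope (trend) change — immediate (d), after a lag (e) or
temporary (f); or both level and slope — immediate (g), after a lag (h) or
temporary (i). The generator composes any of these with a linear trend,
a weak sinusoidal seasonal cycle, stationary ARMA noise and an optional
nonlinear lagged-noise term, and returns the exact component breakdown so
recovery tests can compare against ground truth.

The 'acute-coronary-events-like' preset emulates a monthly standardized-rate
admissions series of the kind used in smoking-ban evaluations: 59 months,
a mild positive trend near 0.48 per month around a level of ~202, weak
annual periodicity, short-memory ARMA(1,1) noise and a level drop when the
ban takes effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series_core import TimeSeries, ValidationError

__all__ = ["SyntheticSpec", "generate_its", "generate_arma", "generate_ace_like",
           "PATTERNS"]

#: pattern tag → (applies level delta, applies slope delta, lagged, temporary)
PATTERNS = {
    "a": (True, False, False, False),
    "b": (True, False, True, False),
    "c": (True, False, False, True),
    "d": (False, True, False, False),
    "e": (False, True, True, False),
    "f": (False, True, False, True),
    "g": (True, True, False, False),
    "h": (True, True, True, False),
    "i": (True, True, False, True),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of an interrupted time series."""

    n: int = 120
    omega: int = 12
    trend_slope: float = 0.0
    trend_intercept: float = 0.0
    season_amplitude: float = 0.0
    arma_phi: tuple[float, ...] = ()
    arma_theta: tuple[float, ...] = ()
    noise_sd: float = 1.0
    nonlinear: str = "none"            # none | quadratic-lag | sin-lag
    nonlinear_strength: float = 0.0
    intervention: str | None = None    # pattern tag a..i
    change_point: int = 0
    lag: int = 0
    level_delta: float = 0.0
    slope_delta: float = 0.0
    temporary_duration: int = 0
    temporary_ramp: bool = False       # hard window by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValidationError("n must be >= 4")
        if self.intervention is not None:
            if self.intervention not in PATTERNS:
                raise ValidationError(
                    f"unknown intervention pattern {self.intervention!r}"
                )
            if self.change_point + self.lag + self.temporary_duration > self.n:
                raise ValidationError(
                    "change_point + lag + temporary_duration exceeds n"
                )
        if self.nonlinear not in ("none", "quadratic-lag", "sin-lag"):
            raise ValidationError(f"unknown nonlinear kind {self.nonlinear!r}")


def _check_stationary_ar(phi) -> None:
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        return
    # roots of 1 - φ1 z - ... - φp z^p must lie outside the unit circle
    roots = np.roots(np.r_[-phi[::-1], 1.0])
    bad = roots[np.abs(roots) <= 1.0 + 1e-10]
    if bad.size:
        raise ValidationError(f"non-stationary AR polynomial; roots {bad}")


def _arma_with_innovations(n, phi, theta, sd, rng):
    _check_stationary_ar(phi)
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p, q = phi.size, theta.size
    burn = 10 * max(p, q, 1)
    eps = rng.normal(0.0, sd, n + burn)
    x = np.zeros(n + burn)
    for t in range(n + burn):
        ar = sum(phi[i] * x[t - i - 1] for i in range(min(p, t)))
        ma = sum(theta[j] * eps[t - j - 1] for j in range(min(q, t)))
        x[t] = ar + ma + eps[t]
    return x[burn:], eps[burn:]


def generate_arma(n: int, phi=(), theta=(), sd: float = 1.0,
                  seed: int | None = 0,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate a stationary, invertible-by-construction ARMA path.

    A burn-in of 10× the maximum lag is discarded; the AR polynomial is
    checked for stationarity via its root condition.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    return _arma_with_innovations(n, phi, theta, sd, rng)[0]


def _intervention_component(spec: SyntheticSpec) -> np.ndarray:
    out = np.zeros(spec.n)
    if spec.intervention is None:
        return out
    use_level, use_slope, lagged, temporary = PATTERNS[spec.intervention]
    start = spec.change_point + (spec.lag if lagged else 0)
    end = start + spec.temporary_duration if temporary else spec.n
    t = np.arange(spec.n)
    window = (t >= start) & (t < end)
    if use_level:
        out[window] += spec.level_delta
    if use_slope:
        out[window] += spec.slope_delta * (t[window] - start)
    if temporary and spec.temporary_ramp:
        # optional linear fade-out over the window instead of a hard edge
        dur = max(spec.temporary_duration, 1)
        out[window] *= 1.0 - (t[window] - start) / dur
    return out


def generate_its(spec: SyntheticSpec) -> tuple[TimeSeries, dict[str, np.ndarray]]:
    """Generate a series and its exact component breakdown.

    y(t) = intercept + slope·t + amplitude·sin(2πt/ω) + ARMA noise
           + nonlinear lagged-noise term + intervention effect.
    The breakdown values sum to the emitted series exactly; the same seed
    reproduces the same series bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n, dtype=float)
    trend = spec.trend_intercept + spec.trend_slope * t
    season = (spec.season_amplitude * np.sin(2 * np.pi * t / spec.omega)
              if spec.omega > 1 else np.zeros(spec.n))
    noise, innov = _arma_with_innovations(
        spec.n, spec.arma_phi, spec.arma_theta, spec.noise_sd, rng)
    nonlin = np.zeros(spec.n)
    if spec.nonlinear != "none" and spec.nonlinear_strength != 0.0:
        # nonlinear moving-average term in the lagged innovation: visible to
        # a residual-based model but invisible to any linear projection
        sd = spec.noise_sd if spec.noise_sd > 0 else 1.0
        e = innov / sd
        if spec.nonlinear == "quadratic-lag":
            nonlin[1:] = spec.nonlinear_strength * sd * (e[:-1] ** 2 - 1.0)
        else:  # sin-lag
            nonlin[1:] = spec.nonlinear_strength * sd * np.sin(1.5 * e[:-1])
    interv = _intervention_component(spec)
    values = trend + season + noise + nonlin + interv
    breakdown = {"trend": trend, "season": season, "noise": noise,
                 "nonlinear": nonlin, "intervention": interv}
    ts = TimeSeries(values, period=spec.omega,
                    label=f"synthetic[{spec.intervention or 'none'}]")
    return ts, breakdown


def generate_ace_like(seed: int = 0) -> TimeSeries:
    """Synthetic monthly admissions-rate series emulating the smoking-ban
    case study's qualitative structure.

    59 monthly values, slope ≈ 0.48/month around level ≈ 202, weak annual
    cycle, ARMA(1,1) noise, and a level drop at month index 37 (the ban
    month). Parameters are calibrated so the diagnostic battery typically
    finds: trend present, no jump, weak periodicity, non-stationary overall,
    and a normal marginal distribution — the qualitative profile of the real
    series, not its exact statistics.
    """
    spec = SyntheticSpec(
        n=59, omega=12,
        trend_slope=0.4792, trend_intercept=201.72,
        season_amplitude=2.0,
        arma_phi=(0.35,), arma_theta=(0.25,), noise_sd=6.0,
        intervention="a", change_point=37, level_delta=-8.0,
        seed=seed,
    )
    ts, _ = generate_its(spec)
    return TimeSeries(ts.values, period=12, label="ace-like synthetic")
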