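"""Time-series container and shared utilities.

The package works on a single uniformly spaced outcome series (e.g. a monthly
standardized rate of acute coronary events). Everything downstream — the
diagnostic battery, the stochastic and polynomial-network models and the
hybrid — consumes the :class:`TimeSeries` container defined here, together
with train/test splitting, correlogram estimation and lagged design-matrix
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "SplitSpec",
    "CorrelogramResult",
    "load_series",
    "write_series",
    "split_train_test",
    "acf",
    "pacf",
    "lag_matrix",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly spaced univariate outcome series.

    Parameters
    ----------
    values
        Ordered outcome values (rate or count scale).
    start_index
        Integer time origin of the first observation (0-based internally;
        reports print 1-based time).
    period
        Seasonal length ω (12 for monthly data with an annual cycle;
        1 = non-seasonal).
    label
        Free-text description.
    """

    values: np.ndarray
    start_index: int = 0
    period: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise ValidationError("series values must be one-dimensional")
        if vals.size < 2:
            raise ValidationError(f"series length must be >= 2, got {vals.size}")
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValidationError(f"non-finite value at row {bad[0]}")
        if self.period < 1:
            raise ValidationError("period must be >= 1")
        if self.period > 1 and self.period > vals.size / 2:
            raise ValidationError(
                f"period {self.period} exceeds half the series length {vals.size}"
            )

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: Sequence[float], **kw) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    def time_index(self) -> np.ndarray:
        """Absolute 0-based time positions of the observations."""
        return np.arange(self.start_index, self.start_index + len(self))


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/test split sizes (leading / trailing counts)."""

    n_train: int
    n_test: int

    def __post_init__(self) -> None:
        if self.n_train < 1:
            raise ValidationError("n_train must be >= 1")
        if self.n_test < 0:
            raise ValidationError("n_test must be >= 0")


class CorrelogramResult(NamedTuple):
    """ACF/PACF values by lag together with the ±1.96/√N significance band."""

    values: np.ndarray
    band: float


def load_series(
    path,
    time_column: str = "time",
    value_column: str = "value",
    period: int = 1,
    label: str = "",
) -> TimeSeries:
    """Read a two-column CSV (time, value) into a :class:`TimeSeries`.

    The time column may hold ISO dates or integer indices; spacing must be
    uniform. The seasonal period comes from configuration, never from the
    data.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (time_column, value_column):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r} in {path}")
    vals = pd.to_numeric(df[value_column], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise ValidationError(f"non-finite value at row {bad[0]} of {path}")
    times = df[time_column]
    numeric_t = pd.to_numeric(times, errors="coerce")
    if numeric_t.notna().all():
        steps = np.diff(numeric_t.to_numpy(dtype=float))
    else:
        parsed = pd.to_datetime(times, errors="coerce")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax())
            raise ValidationError(f"unparseable timestamp at row {row} of {path}")
        # monthly data is uniform in months, not days
        steps = np.diff(parsed.dt.year * 12 + parsed.dt.month)
        if not np.all(steps == steps[0]):
            steps = np.diff(parsed.view("int64"))
    if len(steps) and not np.allclose(steps, steps[0]):
        row = int(np.flatnonzero(~np.isclose(steps, steps[0]))[0]) + 1
        raise ValidationError(f"non-uniform time spacing at row {row} of {path}")
    return TimeSeries(vals, period=period, label=label or str(path))


def write_series(ts: TimeSeries, path, time_column: str = "time",
                 value_column: str = "value") -> None:
    """Write a series back to the two-column CSV layout of :func:`load_series`."""
    pd.DataFrame({time_column: ts.time_index(), value_column: ts.values}).to_csv(
        path, index=False
    )


def split_train_test(ts: TimeSeries, spec: SplitSpec) -> tuple[TimeSeries, TimeSeries | None]:
    """Chronological, non-overlapping split; concatenation reproduces ``ts``."""
    if spec.n_train + spec.n_test != len(ts):
        raise ValidationError(
            f"split {spec.n_train}+{spec.n_test} inconsistent with length {len(ts)}"
        )
    def _slice_period(n):
        # a short holdout window cannot carry a full seasonal cycle; keep the
        # metadata only where the invariant allows it
        return ts.period if ts.period == 1 or n >= 2 * ts.period else 1

    train = ts.with_values(ts.values[: spec.n_train],
                           period=_slice_period(spec.n_train))
    if spec.n_test == 0:
        return train, None
    test = ts.with_values(
        ts.values[spec.n_train:], start_index=ts.start_index + spec.n_train,
        period=_slice_period(spec.n_test)
    )
    return train, test


def _acf_values(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        # constant series: correlation undefined; conventionally 1 at lag 0, 0 after
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = float(np.dot(xc[: n - k], xc[k:])) / denom
    return out


def acf(ts: TimeSeries | np.ndarray, max_lag: int) -> CorrelogramResult:
    """Sample autocorrelation by lag 0..max_lag (biased divide-by-N estimator).

    Returns the correlations and the ±1.96/√N white-noise significance band
    used to bound candidate model orders.
    """
    x = ts.values if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=float)
    if max_lag >= x.size:
        raise ValidationError(f"max_lag {max_lag} must be < length {x.size}")
    if max_lag < 0:
        raise ValidationError("max_lag must be >= 0")
    return CorrelogramResult(_acf_values(x, max_lag), 1.96 / np.sqrt(x.size))


def pacf(ts: TimeSeries | np.ndarray, max_lag: int) -> CorrelogramResult:
    """Partial autocorrelation via the Durbin–Levinson recursion."""
    x = ts.values if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=float)
    if max_lag >= x.size:
        raise ValidationError(f"max_lag {max_lag} must be < length {x.size}")
    rho = _acf_values(x, max_lag)
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    if max_lag == 0:
        return CorrelogramResult(out, 1.96 / np.sqrt(x.size))
    phi_prev = np.array([rho[1]])
    out[1] = rho[1]
    for k in range(2, max_lag + 1):
        num = rho[k] - float(np.dot(phi_prev, rho[k - 1:0:-1]))
        den = 1.0 - float(np.dot(phi_prev, rho[1:k]))
        phi_kk = num / den if den != 0 else 0.0
        out[k] = phi_kk
        phi = np.empty(k)
        phi[:-1] = phi_prev - phi_kk * phi_prev[::-1]
        phi[-1] = phi_kk
        phi_prev = phi
    return CorrelogramResult(out, 1.96 / np.sqrt(x.size))


def significant_lags(ts: TimeSeries | np.ndarray, max_lag: int) -> list[int]:
    """Lags 1..max_lag whose ACF exceeds the white-noise band (order bounding)."""
    r, band = acf(ts, max_lag)
    return [k for k in range(1, max_lag + 1) if abs(r[k]) > band]


def lag_matrix(
    ts: TimeSeries | np.ndarray, lags: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix and aligned target vector.

    Row ``t`` of the matrix holds the value at ``t − lag`` for each requested
    lag; the first ``max(lags)`` rows are dropped so every row is complete.
    """
    x = ts.values if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=float)
    lags = sorted(set(int(l) for l in lags))
    if not lags:
        raise ValidationError("lag set must be non-empty")
    if min(lags) < 1:
        raise ValidationError("lags must be positive")
    m = max(lags)
    if m >= x.size:
        raise ValidationError(f"max lag {m} must be < length {x.size}")
    y = x[m:]
    X = np.column_stack([x[m - l: x.size - l] for l in lags])
    return X, y
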