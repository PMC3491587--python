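"""Forward transpiration prediction and seasonal accumulation.

E'(t) = G'(tau) * delta_pw(T, RH) evaluated on a regular grid resampled
from the weather stream; accumulation uses the left-rectangle rule so that
outputs can simply be summed. Only T and RH are consumed: windspeed and
radiation are accepted in the stream and ignored, per the identified model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conductance import SeasonalConductanceModel, interpolate_conductance
from .errors import ComparisonError, CoverageError, DomainError, GapError, InterpolationWarning
from .vapour import STANDARD_PRESSURE_PA, delta_pw

#: Default prediction window in days after full bloom; the conductance
#: model was fitted on days 23-140 and limited extrapolation is allowed.
DEFAULT_WINDOW = (10.0, 150.0)


@dataclass
class CumulativeSeries:
    """Predicted transpiration on a regular grid with running cumulative.

    ``E_pred`` is in mmol cm^-2 h^-1 per grid point; ``cum`` is the running
    cumulative transpiration in mmol cm^-2 (per unit fruit surface area);
    ``step`` is the grid spacing in hours.
    """

    timestamps: pd.DatetimeIndex
    tau: np.ndarray
    E_pred: np.ndarray
    cum: np.ndarray
    step: float

    @property
    def total(self) -> float:
        return float(self.cum[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "tau_days": self.tau,
                "E_pred": self.E_pred,
                "cum": self.cum,
            }
        )


@dataclass(frozen=True)
class ComparisonReport:
    """Log-log regression of predicted on measured transpiration.

    ``slope`` is the exponent and ``scale`` the multiplicative coefficient
    of E' = scale * E^slope; ``r2`` is on the log scale.
    """

    n: int
    slope: float
    scale: float
    r2: float


def predict_E(model: SeasonalConductanceModel, tau, T, RH, P=STANDARD_PRESSURE_PA):
    """Instantaneous predicted transpiration E' = G'(tau) * delta_pw.

    Always non-negative; zero exactly at RH = 100.
    """
    return interpolate_conductance(model, tau) * delta_pw(T, RH, P)


def _check_gaps(ts: np.ndarray, max_gap_hours: float) -> None:
    diff_h = np.diff(ts).astype("timedelta64[s]").astype(float) / 3600.0
    if diff_h.size == 0:
        return
    cadence = np.median(diff_h)
    long = diff_h > max_gap_hours
    if np.any(long):
        first = pd.DatetimeIndex(ts[:-1][long])
        raise GapError(
            f"{int(long.sum())} weather gap(s) exceed {max_gap_hours} h, "
            f"starting at: {list(first[:5])}"
        )
    if np.any(diff_h > 1.5 * cadence):
        warnings.warn(
            "short weather gaps filled by linear interpolation",
            InterpolationWarning,
            stacklevel=3,
        )


def predict_series(
    model: SeasonalConductanceModel,
    weather: pd.DataFrame,
    full_bloom,
    step_minutes: int = 15,
    window: tuple[float, float] | None = None,
    max_gap_hours: float = 3.0,
    pressure: float = STANDARD_PRESSURE_PA,
) -> CumulativeSeries:
    """Predict E' on a regular grid and accumulate it over the season.

    The weather stream is resampled to the grid by linear interpolation of
    T and RH. ``window`` is a (start, end) pair in days after full bloom;
    ``None`` uses the full weather span. The grid is inclusive of both
    window endpoints where weather covers them. cum[k] is the left-rectangle
    running sum E'[0..k] * step.

    Raises :class:`GapError` for weather gaps longer than ``max_gap_hours``
    and :class:`CoverageError` when the requested window extends outside
    the weather span.
    """
    if 60 % step_minutes != 0:
        raise DomainError("step_minutes must divide 60")
    ts = pd.to_datetime(weather["timestamp"]).to_numpy(dtype="datetime64[ns]")
    _check_gaps(ts, max_gap_hours)

    bloom = pd.Timestamp(full_bloom)
    # each weather record is taken to cover the cadence interval it opens,
    # so the stream spans [first, last + cadence)
    cadence = pd.Timedelta(np.median(np.diff(ts))) if len(ts) > 1 else pd.Timedelta(0)
    span_end = pd.Timestamp(ts[-1]) + cadence
    if window is None:
        start, end = pd.Timestamp(ts[0]), span_end
    else:
        start = bloom + pd.Timedelta(days=window[0])
        end = bloom + pd.Timedelta(days=window[1])
        if start < pd.Timestamp(ts[0]) or end > span_end:
            raise CoverageError(
                f"window [{start}, {end}] not covered by weather span "
                f"[{pd.Timestamp(ts[0])}, {span_end}]"
            )

    step = pd.Timedelta(minutes=step_minutes)
    n = int(np.ceil((end - start) / step))  # half-open grid [start, end)
    if n < 1:
        raise CoverageError("empty prediction window")
    grid = pd.DatetimeIndex(start + step * np.arange(n))

    t_num = ts.astype("int64").astype(float)
    g_num = grid.to_numpy(dtype="datetime64[ns]").astype("int64").astype(float)
    T = np.interp(g_num, t_num, weather["T_C"].to_numpy(dtype=float))
    RH = np.interp(g_num, t_num, weather["RH_pct"].to_numpy(dtype=float))

    tau = (grid - bloom) / pd.Timedelta(days=1)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0.0):
        raise DomainError("prediction grid extends to or before full bloom")

    E = predict_E(model, tau, T, RH, pressure)
    step_h = step_minutes / 60.0
    cum = np.cumsum(E * step_h)
    return CumulativeSeries(
        timestamps=grid, tau=tau, E_pred=np.asarray(E), cum=cum, step=step_h
    )


def compare(pred, meas) -> ComparisonReport:
    """Regress log predicted on log measured transpiration.

    Pairs with non-positive or non-finite values on either side are
    dropped; fewer than 3 surviving pairs raise :class:`ComparisonError`.
    One predicted value may legitimately pair with several replicate
    measurements from the same hour.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ComparisonError("pred and meas must have the same length")
    ok = np.isfinite(pred) & np.isfinite(meas) & (pred > 0.0) & (meas > 0.0)
    if ok.sum() < 3:
        raise ComparisonError(f"need >= 3 positive pairs, got {int(ok.sum())}")
    x, y = np.log(meas[ok]), np.log(pred[ok])
    res = stats.linregress(x, y)
    return ComparisonReport(
        n=int(ok.sum()),
        slope=float(res.slope),
        scale=float(np.exp(res.intercept)),
        r2=float(res.rvalue**2),
    )
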