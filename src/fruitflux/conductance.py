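"""Skin-conductance estimation and the seasonal power-law decline model.

The conductance dataset is built by inverting the Fick's-law flux model
(G = E / delta_pw) over per-interval gravimetric flux observations, then a
power law G'(tau) = alpha * tau^beta is fitted by ordinary least squares on
the log-log scale, with 95 % confidence intervals from a bias-corrected
accelerated (BCa) bootstrap over subsamples drawn with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DomainError,
    ExtrapolationWarning,
    FitError,
    PairingError,
    PercentileFallbackWarning,
    UndefinedConductanceError,
    ValidationError,
)
from .vapour import (
    STANDARD_PRESSURE_PA,
    WATER_MOLAR_MASS,
    delta_pw,
    fruit_surface_area,
    weight_loss_to_flux,
)

#: Minimum dimensionless driving force for a record to enter the log-log fit.
#: Prevents division blow-up for near-saturated air (RH ~ 100 %).
DPW_MIN_DEFAULT = 1e-4

#: Columns of the flux-observation table (delimited-text interface).
OBSERVATION_COLUMNS = [
    "fruit_id",
    "timestamp",
    "tau_days",
    "E_mmol_cm2_h",
    "delta_pw",
    "G",
    "W_ms",
    "R_kJ_m2",
    "included",
    "reason",
]


@dataclass
class SeasonalConductanceModel:
    """Fitted power-law conductance decline G'(tau) = alpha * tau^beta.

    ``alpha`` is in mmol cm^-2 h^-1 (times day^-beta); ``beta`` is
    dimensionless and negative for declining conductance. Confidence
    intervals are attached by :func:`bootstrap_ci` and are ``None`` until
    then.
    """

    alpha: float
    beta: float
    adj_r2: float
    n_obs: int
    tau_range: tuple[float, float]
    alpha_ci: tuple[float, float] | None = None
    beta_ci: tuple[float, float] | None = None
    n_boot: int | None = None
    frac: float | None = None
    seed: int | None = None

    def conductance(self, tau):
        """Alias for :func:`interpolate_conductance` on this model."""
        return interpolate_conductance(self, tau)


def infer_conductance(E, dpw):
    """Invert the flux model: G = E / delta_pw (mmol cm^-2 h^-1).

    Raises :class:`UndefinedConductanceError` for non-positive driving
    force; callers exclude such records rather than fabricating values.
    """
    dpw = np.asarray(dpw, dtype=float)
    if np.any(dpw <= 0.0):
        raise UndefinedConductanceError(
            "conductance undefined for non-positive driving force"
        )
    out = np.asarray(E, dtype=float) / dpw
    return out if out.ndim else float(out)


def interval_mean_weather(weather: pd.DataFrame, starts, ends) -> pd.DataFrame:
    """Mean T, RH, W, R over half-open intervals [start, end) of a stream.

    Uses prefix sums over the sorted weather records; intervals containing
    no record are filled by linear interpolation at the interval midpoint.
    Intervals whose midpoint falls outside the weather span are returned as
    NaN rows (the caller decides whether that is an error).
    """
    ts = weather["timestamp"].to_numpy(dtype="datetime64[ns]")
    starts = pd.to_datetime(starts).to_numpy(dtype="datetime64[ns]")
    ends = pd.to_datetime(ends).to_numpy(dtype="datetime64[ns]")

    cols = ["T_C", "RH_pct", "W_ms", "R_kJ_m2"]
    vals = weather[cols].to_numpy(dtype=float)
    csum = np.vstack([np.zeros(vals.shape[1]), np.cumsum(vals, axis=0)])

    i0 = np.searchsorted(ts, starts, side="left")
    i1 = np.searchsorted(ts, ends, side="left")
    count = (i1 - i0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = (csum[i1] - csum[i0]) / count[:, None]

    empty = count == 0
    if np.any(empty):
        mid = starts[empty] + (ends[empty] - starts[empty]) / 2
        t_num = ts.astype("int64").astype(float)
        mid_num = mid.astype("int64").astype(float)
        inside = (mid >= ts[0]) & (mid <= ts[-1])
        interp = np.full((mid.size, len(cols)), np.nan)
        for j in range(len(cols)):
            interp[inside, j] = np.interp(mid_num[inside], t_num, vals[:, j])
        means[empty] = interp

    return pd.DataFrame(means, columns=cols)


def build_conductance_dataset(
    weighings: pd.DataFrame,
    weather: pd.DataFrame,
    full_bloom,
    *,
    pressure: float = STANDARD_PRESSURE_PA,
    dpw_min: float = DPW_MIN_DEFAULT,
    a_coef: float | None = None,
    b_coef: float | None = None,
    molar_mass: float = WATER_MOLAR_MASS,
) -> pd.DataFrame:
    """Derive per-interval flux observations and inferred conductances.

    Each consecutive pair of weighings of the same fruit defines one
    interval; its transpiration rate comes from the weight loss and fruit
    surface area, and its driving force from the mean weather over the
    interval. Records failing the inclusion filter (E > 0 and
    delta_pw > ``dpw_min``) are retained with ``included = False`` and a
    reason code, so exclusion decisions stay auditable.

    Parameters
    ----------
    weighings : DataFrame with columns fruit_id, timestamp, weight_g,
        length_cm, width_cm.
    weather : DataFrame with columns timestamp, T_C, RH_pct, W_ms, R_kJ_m2,
        timestamps strictly increasing.
    full_bloom : date or datetime of full bloom; tau is measured from it in
        real-valued days.

    Returns
    -------
    DataFrame with :data:`OBSERVATION_COLUMNS`, one row per interval,
    timestamped at the interval start.
    """
    required = {"fruit_id", "timestamp", "weight_g", "length_cm", "width_cm"}
    missing = required - set(weighings.columns)
    if missing:
        raise ValidationError(f"weighings missing column(s): {sorted(missing)}")
    if weighings.empty:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)

    kwargs = {}
    if a_coef is not None:
        kwargs["a_coef"] = a_coef
    if b_coef is not None:
        kwargs["b_coef"] = b_coef

    full_bloom = pd.Timestamp(full_bloom)

    rows = []
    for fruit_id, grp in weighings.groupby("fruit_id", sort=False):
        grp = grp.sort_values("timestamp")
        if len(grp) < 2:
            continue
        t = pd.to_datetime(grp["timestamp"]).to_numpy()
        w = grp["weight_g"].to_numpy(dtype=float)
        area = fruit_surface_area(
            grp["length_cm"].iloc[0], grp["width_cm"].iloc[0], **kwargs
        )
        dt_h = (t[1:] - t[:-1]) / np.timedelta64(1, "h")
        E = weight_loss_to_flux(w[:-1], w[1:], dt_h, area, molar_mass)
        rows.append(
            pd.DataFrame(
                {
                    "fruit_id": fruit_id,
                    "timestamp": t[:-1],
                    "end": t[1:],
                    "E_mmol_cm2_h": E,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    obs = pd.concat(rows, ignore_index=True)

    met = interval_mean_weather(weather, obs["timestamp"], obs["end"])
    orphans = met["T_C"].isna()
    if orphans.any():
        bad = obs.loc[orphans, ["fruit_id", "timestamp"]]
        raise PairingError(
            f"{int(orphans.sum())} interval(s) have no overlapping weather, "
            f"first few:\n{bad.head().to_string(index=False)}"
        )

    dpw = delta_pw(met["T_C"].to_numpy(), met["RH_pct"].to_numpy(), pressure)
    dpw = np.asarray(dpw, dtype=float)
    E = obs["E_mmol_cm2_h"].to_numpy()

    reason = np.full(len(obs), "", dtype=object)
    reason[E <= 0.0] = "nonpositive flux"
    reason[dpw <= dpw_min] = "zero driving force"
    included = reason == ""

    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(dpw > 0.0, E / np.where(dpw > 0.0, dpw, 1.0), np.nan)

    tau = (pd.to_datetime(obs["timestamp"]) - full_bloom) / pd.Timedelta(days=1)

    return pd.DataFrame(
        {
            "fruit_id": obs["fruit_id"],
            "timestamp": obs["timestamp"],
            "tau_days": tau.to_numpy(),
            "E_mmol_cm2_h": E,
            "delta_pw": dpw,
            "G": G,
            "W_ms": met["W_ms"].to_numpy(),
            "R_kJ_m2": met["R_kJ_m2"].to_numpy(),
            "included": included,
            "reason": reason,
        }
    )


def observations_from_conductance(
    tau, G, fruit_id: str = "synthetic", dpw: float = 0.01
) -> pd.DataFrame:
    """Wrap raw (tau, G) samples as an included flux-observation table.

    Useful when conductance values are available directly (e.g. from a
    published dataset or a generator) rather than via gravimetric inversion;
    E is back-filled as G * dpw with a nominal constant driving force.
    """
    tau = np.asarray(tau, dtype=float)
    G = np.asarray(G, dtype=float)
    n = tau.size
    return pd.DataFrame(
        {
            "fruit_id": fruit_id,
            "timestamp": pd.NaT,
            "tau_days": tau,
            "E_mmol_cm2_h": G * dpw,
            "delta_pw": dpw,
            "G": G,
            "W_ms": np.nan,
            "R_kJ_m2": np.nan,
            "included": np.ones(n, dtype=bool),
            "reason": "",
        }
    )


def _included_logs(obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    inc = obs[obs["included"].astype(bool)]
    tau = inc["tau_days"].to_numpy(dtype=float)
    G = inc["G"].to_numpy(dtype=float)
    if len(tau) < 3:
        raise FitError(f"need >= 3 included observations, got {len(tau)}")
    if np.any(tau <= 0.0) or np.any(G <= 0.0):
        raise FitError("included observations must have positive tau and G")
    logt, logg = np.log(tau), np.log(G)
    if np.ptp(logt) == 0.0:
        raise FitError("zero variance in log tau; need >= 2 distinct tau values")
    return tau, logt, logg


def _ols_loglog(logt: np.ndarray, logg: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of OLS of logg on logt (closed form)."""
    n = logt.size
    sx, sy = logt.sum(), logg.sum()
    sxx, sxy = (logt * logt).sum(), (logt * logg).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return slope, intercept


def fit_seasonal_model(obs: pd.DataFrame) -> SeasonalConductanceModel:
    """Fit G'(tau) = alpha * tau^beta by OLS of log G on log tau.

    Natural logs are used internally; the point estimates are invariant to
    the log base. Back-transform: alpha = exp(intercept), beta = slope.
    The adjusted R^2 is computed on the log scale.
    """
    tau, logt, logg = _included_logs(obs)
    n = logt.size
    res = sm.OLS(logg, sm.add_constant(logt)).fit()
    intercept, beta = res.params
    ss_tot = float(((logg - logg.mean()) ** 2).sum())
    adj_r2 = 1.0 if ss_tot == 0.0 else float(res.rsquared_adj)
    return SeasonalConductanceModel(
        alpha=float(np.exp(intercept)),
        beta=float(beta),
        adj_r2=float(adj_r2),
        n_obs=int(n),
        tau_range=(float(tau.min()), float(tau.max())),
    )


def _jackknife_estimates(logt: np.ndarray, logg: np.ndarray) -> np.ndarray:
    """Leave-one-out (slope, intercept) pairs via O(1) prefix-sum updates."""
    n = logt.size
    sx, sy = logt.sum(), logg.sum()
    sxx, sxy = (logt * logt).sum(), (logt * logg).sum()
    m = n - 1
    sx_i = sx - logt
    sy_i = sy - logg
    sxx_i = sxx - logt * logt
    sxy_i = sxy - logt * logg
    denom = m * sxx_i - sx_i * sx_i
    slope = (m * sxy_i - sx_i * sy_i) / denom
    intercept = (sy_i - slope * sx_i) / m
    return np.column_stack([slope, intercept])


def _bca_interval(theta_hat, theta_boot, theta_jack, level=0.95):
    """BCa percentile interval; falls back to plain percentiles when the
    bias-correction z-value is unbounded (all resamples on one side)."""
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    prop = np.mean(theta_boot < theta_hat)
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn(
            "BCa bias-correction unbounded; returning percentile interval",
            PercentileFallbackWarning,
            stacklevel=3,
        )
        lo, hi = np.quantile(theta_boot, [lo_q, hi_q])
        return float(lo), float(hi)
    z0 = stats.norm.ppf(prop)
    d = theta_jack.mean() - theta_jack
    denom = 6.0 * (d @ d) ** 1.5
    a = float((d**3).sum() / denom) if denom > 0.0 else 0.0
    z = stats.norm.ppf([lo_q, hi_q])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    lo, hi = np.quantile(theta_boot, adj)
    return float(lo), float(hi)


def bootstrap_ci(
    obs: pd.DataFrame,
    n_boot: int = 100,
    frac: float = 0.8,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """BCa bootstrap confidence intervals for (alpha, beta).

    Draws ``n_boot`` subsamples of size round(frac * n) with replacement
    from the included observations, refits the log-log regression on each,
    and returns bias-corrected accelerated intervals; acceleration comes
    from a leave-one-out jackknife. Deterministic given ``seed`` (resample
    index draws are consumed in loop order from one generator stream).

    Degenerate resamples (a single distinct tau) are redrawn, with a hard
    cap of 10 * n_boot total attempts.
    """
    if n_boot < 2:
        raise DomainError("n_boot must be >= 2")
    if not 0.0 < frac <= 1.0:
        raise DomainError("frac must be in (0, 1]")
    _, logt, logg = _included_logs(obs)
    n = logt.size
    m = int(round(frac * n))
    beta_hat, inter_hat = _ols_loglog(logt, logg)
    alpha_hat = np.exp(inter_hat)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 2))
    attempts = 0
    b = 0
    while b < n_boot:
        attempts += 1
        if attempts > 10 * n_boot:
            raise FitError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=m)
        xt = logt[idx]
        if np.ptp(xt) == 0.0:
            continue
        boot[b] = _ols_loglog(xt, logg[idx])
        b += 1
    jack = _jackknife_estimates(logt, logg)

    beta_ci = _bca_interval(beta_hat, boot[:, 0], jack[:, 0], level)
    alpha_ci = _bca_interval(
        alpha_hat, np.exp(boot[:, 1]), np.exp(jack[:, 1]), level
    )
    return alpha_ci, beta_ci


def fit_with_bootstrap(
    obs: pd.DataFrame, n_boot: int = 100, frac: float = 0.8, seed: int = 0
) -> SeasonalConductanceModel:
    """Convenience: point fit plus BCa intervals in one call."""
    model = fit_seasonal_model(obs)
    alpha_ci, beta_ci = bootstrap_ci(obs, n_boot=n_boot, frac=frac, seed=seed)
    return replace(
        model,
        alpha_ci=alpha_ci,
        beta_ci=beta_ci,
        n_boot=n_boot,
        frac=frac,
        seed=seed,
    )


def interpolate_conductance(model: SeasonalConductanceModel, tau):
    """Evaluate G'(tau) = alpha * tau^beta (mmol cm^-2 h^-1).

    Emits :class:`ExtrapolationWarning` (not an error) outside the fitted
    tau range; limited extrapolation is permitted.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0.0):
        raise DomainError("tau must be positive")
    lo, hi = model.tau_range
    if np.any(tau_arr < lo) or np.any(tau_arr > hi):
        warnings.warn(
            f"tau outside fitted range [{lo:g}, {hi:g}] days; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = model.alpha * tau_arr**model.beta
    return out if out.ndim else float(out)
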