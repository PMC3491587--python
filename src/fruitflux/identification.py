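"""Screen for windspeed and radiation effects on inferred conductance.

Per measurement period, inferred G is regressed on windspeed W and,
separately, on total solar radiation R. Significant slopes would indicate
that a boundary-layer conductance term (W) or a fruit-heating term (R) is
needed; non-significance across all regressions supports the plain
flux model E = G * delta_pw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError

DRIVERS = {"W": "W_ms", "R": "R_kJ_m2"}


@dataclass(frozen=True)
class IdentificationResult:
    """One per-period regression of G on a candidate driver."""

    period: int
    driver: str
    slope: float
    slope_p: float
    n: int
    skipped: bool = False


@dataclass(frozen=True)
class IdentificationSummary:
    """All per-period regressions plus the accept/reject conclusion."""

    results: tuple[IdentificationResult, ...]
    threshold: float
    min_p: float
    max_p: float
    any_significant: bool
    conclusion: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "period": r.period,
                    "driver": r.driver,
                    "slope": r.slope,
                    "slope_p": r.slope_p,
                    "n": r.n,
                    "skipped": r.skipped,
                }
                for r in self.results
            ]
        )


def assign_periods(tau, gap_days: float = 2.0) -> np.ndarray:
    """Group tau values into measurement periods separated by gaps.

    Observations closer than ``gap_days`` belong to the same campaign
    occasion; each period is labelled by the rounded smallest tau in it.
    """
    tau = np.asarray(tau, dtype=float)
    order = np.argsort(tau)
    labels = np.empty(tau.size, dtype=int)
    current = None
    prev = None
    for i in order:
        if prev is None or tau[i] - prev > gap_days:
            current = int(round(tau[i]))
        labels[i] = current
        prev = tau[i]
    return labels


def _slope_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope of y on x and its two-sided t-test P-value."""
    if np.var(y) == 0.0:
        return 0.0, 1.0
    res = stats.linregress(x, y)
    p = res.pvalue
    if np.isnan(p):
        p = 1.0
    return float(res.slope), float(p)


def identify(
    obs: pd.DataFrame,
    threshold: float = 0.05,
    gap_days: float = 2.0,
) -> IdentificationSummary:
    """Run the per-period G-vs-W and G-vs-R regressions and summarise.

    Only included observations (defined G) enter the regressions. A period
    whose driver has zero variance (e.g. all-zero night radiation) is
    skipped and flagged rather than fabricated. The conclusion reports
    "no significant driver effect" when no slope P-value falls below
    ``threshold``.
    """
    inc = obs[obs["included"].astype(bool)].copy()
    if inc.empty:
        raise FitError("no included observations to identify on")
    inc["period"] = assign_periods(inc["tau_days"].to_numpy(), gap_days)

    results: list[IdentificationResult] = []
    for period, grp in inc.groupby("period", sort=True):
        G = grp["G"].to_numpy(dtype=float)
        for name, col in DRIVERS.items():
            x = grp[col].to_numpy(dtype=float)
            if len(grp) < 3 or np.ptp(x) == 0.0:
                results.append(
                    IdentificationResult(
                        int(period), name, np.nan, np.nan, len(grp), skipped=True
                    )
                )
                continue
            slope, p = _slope_test(x, G)
            results.append(
                IdentificationResult(int(period), name, slope, p, len(grp))
            )

    pvals = np.array([r.slope_p for r in results if not r.skipped])
    if pvals.size == 0:
        raise FitError("every identification regression was degenerate")
    min_p, max_p = float(pvals.min()), float(pvals.max())
    any_sig = bool(min_p < threshold)
    conclusion = (
        "significant driver effect detected; flux-model extension warranted"
        if any_sig
        else "no significant driver effect; flux model accepted unextended"
    )
    return IdentificationSummary(
        results=tuple(results),
        threshold=threshold,
        min_p=min_p,
        max_p=max_p,
        any_significant=any_sig,
        conclusion=conclusion,
    )
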