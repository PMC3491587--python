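"""Validated delimited-text readers and writers for every pipeline stage.

Dialect is pinned: comma separator, period decimal mark, UTF-8, header row
required. Timestamps are ISO-8601 local civil time without timezone
arithmetic.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conductance import OBSERVATION_COLUMNS, SeasonalConductanceModel
from .errors import ValidationError
from .identification import IdentificationSummary
from .prediction import ComparisonReport, CumulativeSeries
from .vapour import validate_rh

WEATHER_COLUMNS = ["timestamp", "T_C", "RH_pct", "W_ms", "R_kJ_m2"]
WEIGHING_COLUMNS = ["fruit_id", "timestamp", "weight_g", "length_cm", "width_cm"]


def _read_csv(path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{label} file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{label} file {path} missing column(s): {missing}")
    return df


def _parse_timestamps(df: pd.DataFrame, path, label: str) -> pd.DataFrame:
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{label} file {path}: unparseable timestamp ({exc})")
    return df


def read_weather(path) -> pd.DataFrame:
    """Read and validate a weather stream.

    Checks: required columns, parseable strictly-increasing timestamps,
    RH in [0, 100] after overshoot clamping, non-negative W and R.
    """
    df = _parse_timestamps(_read_csv(path, WEATHER_COLUMNS, "weather"), path, "weather")
    ts = df["timestamp"].to_numpy()
    if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
        rows = np.flatnonzero(~(ts[1:] > ts[:-1])) + 1
        raise ValidationError(
            f"weather file {path}: timestamps not strictly increasing at row(s) "
            f"{rows[:5].tolist()}"
        )
    df["RH_pct"] = validate_rh(df["RH_pct"].to_numpy(dtype=float))
    for col in ("W_ms", "R_kJ_m2"):
        bad = np.flatnonzero(df[col].to_numpy(dtype=float) < 0.0)
        if bad.size:
            raise ValidationError(
                f"weather file {path}: negative {col} at row(s) {bad[:5].tolist()}"
            )
    return df


def read_weighings(path) -> pd.DataFrame:
    df = _parse_timestamps(
        _read_csv(path, WEIGHING_COLUMNS, "weighings"), path, "weighings"
    )
    for col in ("weight_g", "length_cm", "width_cm"):
        bad = np.flatnonzero(~(df[col].to_numpy(dtype=float) > 0.0))
        if bad.size:
            raise ValidationError(
                f"weighings file {path}: non-positive {col} at row(s) "
                f"{bad[:5].tolist()}"
            )
    return df


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False, columns=[c for c in OBSERVATION_COLUMNS if c in obs])


def read_observations(path) -> pd.DataFrame:
    df = _parse_timestamps(
        _read_csv(
            path,
            ["fruit_id", "timestamp", "tau_days", "E_mmol_cm2_h", "delta_pw",
             "G", "included", "reason"],
            "observations",
        ),
        path,
        "observations",
    )
    df["included"] = df["included"].astype(bool)
    df["reason"] = df["reason"].fillna("")
    return df


def write_model(model: SeasonalConductanceModel, path) -> None:
    """Write a fitted model as a flat key-value text file."""
    lines = [
        f"alpha={model.alpha!r}",
        f"beta={model.beta!r}",
        f"adj_r2={model.adj_r2!r}",
        f"n_obs={model.n_obs}",
        f"tau_min={model.tau_range[0]!r}",
        f"tau_max={model.tau_range[1]!r}",
    ]
    if model.alpha_ci is not None:
        lines += [
            f"alpha_lo={model.alpha_ci[0]!r}",
            f"alpha_hi={model.alpha_ci[1]!r}",
            f"beta_lo={model.beta_ci[0]!r}",
            f"beta_hi={model.beta_ci[1]!r}",
            f"n_boot={model.n_boot}",
            f"frac={model.frac!r}",
            f"seed={model.seed}",
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_model(path) -> SeasonalConductanceModel:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"model file not found: {path}")
    kv: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    try:
        model = SeasonalConductanceModel(
            alpha=float(kv["alpha"]),
            beta=float(kv["beta"]),
            adj_r2=float(kv["adj_r2"]),
            n_obs=int(kv["n_obs"]),
            tau_range=(float(kv["tau_min"]), float(kv["tau_max"])),
        )
    except KeyError as exc:
        raise ValidationError(f"model file {path} missing key: {exc}")
    if "alpha_lo" in kv:
        model = replace(
            model,
            alpha_ci=(float(kv["alpha_lo"]), float(kv["alpha_hi"])),
            beta_ci=(float(kv["beta_lo"]), float(kv["beta_hi"])),
            n_boot=int(kv.get("n_boot", 0)) or None,
            frac=float(kv.get("frac", "nan")),
            seed=int(kv["seed"]) if "seed" in kv else None,
        )
    return model


def write_series(series: CumulativeSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(path) -> pd.DataFrame:
    return _parse_timestamps(
        _read_csv(path, ["timestamp", "tau_days", "E_pred", "cum"], "series"),
        path,
        "series",
    )


def write_identification(summary: IdentificationSummary, path) -> None:
    """12-row delimited report plus a conclusion block (comment lines)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        summary.to_frame().to_csv(fh, index=False)
        fh.write(f"# threshold={summary.threshold!r}\n")
        fh.write(f"# min_p={summary.min_p!r} max_p={summary.max_p!r}\n")
        fh.write(f"# conclusion: {summary.conclusion}\n")


def write_comparison(report: ComparisonReport, path) -> None:
    Path(path).write_text(
        f"n={report.n}\nslope={report.slope!r}\nscale={report.scale!r}\n"
        f"r2={report.r2!r}\n",
        encoding="utf-8",
    )


def read_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return cfg
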