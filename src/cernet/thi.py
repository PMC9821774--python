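"""Temperature-humidity index (THI) for livestock heat-load classification.

THI = (1.8 T + 32) - (0.55 - 0.55 RH) (1.8 T - 26)

with T the dry-bulb temperature in degrees Celsius and RH the relative
humidity as a fraction in [0, 1]. At RH = 1 the second term vanishes and
THI is the Fahrenheit temperature; at T = 26/1.8 C the humidity factor is
multiplied by zero and THI = 58 regardless of RH. Inputs given as
percentages (values in (1, 100]) are auto-scaled to fractions with a
logged note.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Temperature (C) at which THI becomes insensitive to humidity.
HUMIDITY_NEUTRAL_T = 26.0 / 1.8


def _as_fraction(relative_humidity):
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ConfigurationError("relative humidity must lie in [0, 1] (or [0, 100] percent)")
    if np.any(rh > 1.0):
        logger.info("relative humidity given in percent; dividing by 100")
        rh = np.where(rh > 1.0, rh / 100.0, rh)
    return rh


def compute_thi(temperature_c, relative_humidity):
    """Evaluate the THI formula; scalar or elementwise on arrays."""
    t = np.asarray(temperature_c, dtype=float)
    rh = _as_fraction(relative_humidity)
    thi = (1.8 * t + 32.0) - (0.55 - 0.55 * rh) * (1.8 * t - 26.0)
    if thi.ndim == 0:
        return float(thi)
    return thi


def thi_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``thi`` column to a (temperature_c, relative_humidity) table."""
    for col in ("temperature_c", "relative_humidity"):
        if col not in table.columns:
            raise ConfigurationError(f"missing column {col!r}")
    out = table.copy()
    out["thi"] = compute_thi(
        out["temperature_c"].to_numpy(), out["relative_humidity"].to_numpy()
    )
    return out


def thi_summary(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Mean +/- SEM of THI per group."""
    if "thi" not in table.columns:
        table = thi_table(table)
    grouped = table.groupby(group_col)["thi"] if group_col in table.columns else [
        ("all", table["thi"])
    ]
    rows = []
    for name, vals in grouped:
        vals = np.asarray(vals, dtype=float)
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append({"group": name, "n": len(vals), "mean_thi": vals.mean(), "sem_thi": sem})
    return pd.DataFrame(rows)
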