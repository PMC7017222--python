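"""Temperature-humidity index (THI) for dairy-cattle heat-load assessment.

The THI combines ambient temperature (AT, °C) and relative humidity
(RH, percent) into a single dimensionless heat-load score:

    THI = (1.8·AT + 32) − (0.55 − 0.0055·RH) · (1.8·AT − 26)

Values of 68 or more indicate heat stress for high-yielding lactating cows;
the screening study this package supports targets an August mean near 86.

RH must be supplied in percent (0–100). Values at or below 1 are rejected as
probable fractions to prevent a silent 100-fold error; THI is never rounded
internally — display rounding is left to the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError

__all__ = ["EnvRecord", "ThiSummary", "thi_value", "summarize_thi", "env_series"]


@dataclass(frozen=True)
class EnvRecord:
    """One timestamped environment reading."""

    timestamp: pd.Timestamp
    at_c: float
    rh_pct: float


@dataclass(frozen=True)
class ThiSummary:
    """Mean/min/max THI over one observation period."""

    period: str
    mean_thi: float
    min_thi: float
    max_thi: float
    n_records: int


def _validate(at, rh) -> tuple[np.ndarray, np.ndarray]:
    at = np.asarray(at, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if not np.all(np.isfinite(at)):
        raise DomainError("AT: ambient temperature must be finite")
    if not np.all(np.isfinite(rh)):
        raise DomainError("RH: relative humidity must be finite")
    if np.any((rh < 0) | (rh > 100)):
        raise DomainError("RH: relative humidity must lie in [0, 100] percent")
    # fraction guard: RH in (0, 1] almost certainly means a 0-1 fraction
    if np.any((rh > 0) & (rh <= 1.0)):
        raise DomainError(
            "RH: values in (0, 1] look like fractions; supply percent (0-100)"
        )
    return at, rh


def thi_value(at_c, rh_pct):
    """Temperature-humidity index for AT in °C and RH in percent.

    Accepts scalars or arrays (broadcast); returns the same shape.
    Strictly increasing in AT at every RH because
    d(THI)/d(AT) = 1.8·(0.45 + 0.0055·RH) > 0.
    """
    at, rh = _validate(at_c, rh_pct)
    out = (1.8 * at + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * at - 26.0)
    if out.ndim == 0:
        return float(out)
    return out


def env_series(records: Iterable[EnvRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce records to the canonical environment frame.

    Columns: ``timestamp``, ``at_c``, ``rh_pct``; one row per reading.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        missing = {"timestamp", "at_c", "rh_pct"} - set(df.columns)
        if missing:
            raise DomainError(
                f"environment series missing column(s): {sorted(missing)}"
            )
    else:
        df = pd.DataFrame(
            [(r.timestamp, r.at_c, r.rh_pct) for r in records],
            columns=["timestamp", "at_c", "rh_pct"],
        )
    return df


def summarize_thi(series, period: str) -> ThiSummary:
    """Element-wise THI over a period's readings, then mean/min/max.

    Order-invariant: a permutation of the rows gives an identical summary.

    Parameters
    ----------
    series
        Environment frame (or iterable of :class:`EnvRecord`) with columns
        ``timestamp``, ``at_c``, ``rh_pct``.
    period
        Label carried into the summary (e.g. ``"august"``).
    """
    df = env_series(series)
    if len(df) == 0:
        raise EmptyInputError(f"period {period!r}: environment series is empty")
    thi = np.asarray(thi_value(df["at_c"].to_numpy(), df["rh_pct"].to_numpy()))
    thi = np.atleast_1d(thi)
    return ThiSummary(
        period=period,
        mean_thi=float(thi.mean()),
        min_thi=float(thi.min()),
        max_thi=float(thi.max()),
        n_records=int(thi.size),
    )
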