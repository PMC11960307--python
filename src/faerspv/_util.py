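"""Shared helpers: date handling for YYYYMMDD integers and decimal rounding."""

from __future__ import annotations

import datetime as _dt
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

AGE_BANDS = ("<18", "18-44", "45-64", ">=65")
AGE_BAND_UNK = "UNK"
# age-band thresholds in years
_AGE_EDGES = (18.0, 45.0, 65.0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed percentage tables do.

    Centralised so every exported percentage reproduces to the same 2 d.p.
    """
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def yyyymmdd_to_date(value) -> _dt.date | None:
    """Parse a YYYYMMDD integer to a date.

    Returns None for missing values and for partial dates (month or day 00),
    which FAERS emits when only part of the date is known.
    """
    if value is None or (isinstance(value, float) and value != value) or value is pd.NA:
        return None
    v = int(value)
    y, m, d = v // 10000, (v // 100) % 100, v % 100
    if m == 0 or d == 0:
        return None
    try:
        return _dt.date(y, m, d)
    except ValueError:
        return None


def is_partial_date(value) -> bool:
    """True when the YYYYMMDD value is present but month or day is 00."""
    if value is None or (isinstance(value, float) and value != value) or value is pd.NA:
        return False
    v = int(value)
    return (v // 100) % 100 == 0 or v % 100 == 0


def date_to_yyyymmdd(date: _dt.date) -> int:
    return date.year * 10000 + date.month * 100 + date.day


def age_band_of(age_years) -> str:
    """Pure function age → band with thresholds at 18, 45 and 65 years."""
    if age_years is None or age_years != age_years:
        return AGE_BAND_UNK
    a = float(age_years)
    if a < _AGE_EDGES[0]:
        return AGE_BANDS[0]
    if a < _AGE_EDGES[1]:
        return AGE_BANDS[1]
    if a < _AGE_EDGES[2]:
        return AGE_BANDS[2]
    return AGE_BANDS[3]


def age_bands_vector(age_years: pd.Series) -> pd.Series:
    a = pd.to_numeric(age_years, errors="coerce")
    out = pd.Series(AGE_BAND_UNK, index=age_years.index, dtype=object)
    out[a < _AGE_EDGES[0]] = AGE_BANDS[0]
    out[(a >= _AGE_EDGES[0]) & (a < _AGE_EDGES[1])] = AGE_BANDS[1]
    out[(a >= _AGE_EDGES[1]) & (a < _AGE_EDGES[2])] = AGE_BANDS[2]
    out[a >= _AGE_EDGES[2]] = AGE_BANDS[3]
    return out


def normalize_age_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Convert FAERS (AGE, AGE_COD) pairs to years.

    YR is taken as-is, MON divided by 12, DEC multiplied by 10; any other or
    missing unit code yields a missing age.
    """
    a = pd.to_numeric(age, errors="coerce").astype(float)
    cod = age_cod.fillna("").astype(str).str.strip().str.upper()
    out = pd.Series(np.nan, index=age.index, dtype=float)
    out[cod == "YR"] = a[cod == "YR"]
    out[cod == "MON"] = a[cod == "MON"] / 12.0
    out[cod == "DEC"] = a[cod == "DEC"] * 10.0
    return out
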