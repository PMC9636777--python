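"""Small shared helpers: rounding, date arithmetic, deterministic IO."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches the printing convention used in
    the report tables.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = 100.0 * numerator / denominator
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up(value: float, decimals: int = 1) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def age_at(birth_date: pd.Series, on_date: pd.Series) -> pd.Series:
    """Whole-year age on ``on_date`` (calendar convention, vectorized)."""
    birth_date = pd.to_datetime(birth_date)
    on_date = pd.to_datetime(on_date)
    years = on_date.dt.year.to_numpy() - birth_date.dt.year.to_numpy()
    before_birthday = (on_date.dt.month.to_numpy() < birth_date.dt.month.to_numpy()) | (
        (on_date.dt.month.to_numpy() == birth_date.dt.month.to_numpy())
        & (on_date.dt.day.to_numpy() < birth_date.dt.day.to_numpy())
    )
    return pd.Series(years - before_birthday.astype(int), index=on_date.index)


def days_between(later: pd.Series, earlier: pd.Series) -> pd.Series:
    """Whole calendar days from ``earlier`` to ``later`` (may be negative)."""
    return (pd.to_datetime(later) - pd.to_datetime(earlier)).dt.days


def sorted_frame(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Deterministically ordered copy (stable sort, reset index)."""
    return df.sort_values(by, kind="mergesort").reset_index(drop=True)


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def rng_from_seed(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
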