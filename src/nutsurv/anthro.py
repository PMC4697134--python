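"""Anthropometric z-scores (LMS method) and malnutrition case definitions.

Growth references such as the WHO 2006 child growth standards express each
measurement's reference distribution at a given sex and age through three
parameters: a Box-Cox power ``L``, a median ``M`` and a coefficient of
variation ``S``.  The z-score of a measurement ``x`` is

    z = ((x / M)**L - 1) / (L * S)        for L != 0
    z = ln(x / M) / S                     for L == 0

Case definitions follow the standard survey thresholds: a child is *wasted*
when the weight-for-height z-score is below -2, *stunted* when the
height-for-age z-score is below -2, and has *low MUAC* when the mid-upper
arm circumference is below 125 mm.  All three thresholds are strict: a child
sitting exactly on the boundary is a non-case.

Reference tables are pluggable: :class:`LMSReference` loads a CSV with
columns ``sex, age_months, L, M, S`` so real WHO tables can be supplied by
the user, while tests ship a small synthetic table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CaseFlags",
    "LMSReference",
    "classify",
    "lms_zscore",
    "lms_inverse",
    "validate_muac",
]

#: MUAC outside this window (in millimetres) is treated as a unit error,
#: e.g. a value recorded in centimetres.
MUAC_MIN_MM = 50.0
MUAC_MAX_MM = 300.0

WASTING_Z_THRESHOLD = -2.0
STUNTING_Z_THRESHOLD = -2.0
LOW_MUAC_THRESHOLD_MM = 125.0

# Below this |L| the generic Box-Cox formula's O(L) truncation error
# exceeds the analytic L -> 0 limit's; switch to ln(x/M)/S there.
_L_EPS = 1e-5


def lms_zscore(x, L, M, S):
    """z-score of measurement ``x`` under an LMS reference point.

    Parameters
    ----------
    x : float or array
        Measurement (must be > 0; same units as ``M``).
    L, M, S : float or array
        Box-Cox power, median (> 0) and coefficient of variation (> 0).

    Returns
    -------
    float or ndarray
        The z-score; continuous in ``x`` and in ``L`` across ``L = 0``.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0):
        raise ValueError("measurement x must be positive")
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("LMS parameters require M > 0 and S > 0")
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(L) < _L_EPS,
            np.log(ratio) / S,
            (np.power(ratio, np.where(np.abs(L) < _L_EPS, 1.0, L)) - 1.0)
            / (np.where(np.abs(L) < _L_EPS, 1.0, L) * S),
        )
    if z.ndim == 0:
        return float(z)
    return z


def lms_inverse(z, L, M, S):
    """Measurement whose LMS z-score is ``z`` (inverse of :func:`lms_zscore`)."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("LMS parameters require M > 0 and S > 0")
    safe_L = np.where(np.abs(L) < _L_EPS, 1.0, L)
    x = np.where(
        np.abs(L) < _L_EPS,
        M * np.exp(S * z),
        M * np.power(1.0 + safe_L * S * z, 1.0 / safe_L),
    )
    if x.ndim == 0:
        return float(x)
    return x


@dataclass(frozen=True)
class CaseFlags:
    """Binary malnutrition indicators derived from z-scores and MUAC."""

    wasted: bool
    stunted: bool
    low_muac: bool


def validate_muac(muac_mm: float) -> float:
    """Return ``muac_mm`` unchanged, rejecting values that look like unit errors."""
    if not math.isfinite(muac_mm):
        raise ValueError("MUAC is missing or non-finite")
    if not (MUAC_MIN_MM <= muac_mm <= MUAC_MAX_MM):
        raise ValueError(
            f"MUAC {muac_mm} mm outside plausible range "
            f"[{MUAC_MIN_MM}, {MUAC_MAX_MM}] mm; check units (mm expected)"
        )
    return muac_mm


def classify(whz: float, haz: float, muac_mm: float) -> CaseFlags:
    """Apply the case definitions to one child's measurements.

    All thresholds are strict ("below"): ``whz = -2.0`` exactly is not
    wasted and ``muac_mm = 125.0`` exactly is not low MUAC.  Missing (NaN)
    inputs raise rather than silently classifying as non-cases; exclusion
    of incomplete records is the caller's responsibility.
    """
    for name, v in (("whz", whz), ("haz", haz), ("muac_mm", muac_mm)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is missing or non-finite; exclude the record upstream")
    validate_muac(muac_mm)
    return CaseFlags(
        wasted=whz < WASTING_Z_THRESHOLD,
        stunted=haz < STUNTING_Z_THRESHOLD,
        low_muac=muac_mm < LOW_MUAC_THRESHOLD_MM,
    )


class LMSReference:
    """LMS reference table keyed by (sex, age in months).

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``sex`` (``male``/``female``), ``age_months``, ``L``, ``M``,
        ``S``.  ``M`` and ``S`` must be positive.
    """

    REQUIRED_COLUMNS = ("sex", "age_months", "L", "M", "S")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"LMS table missing columns: {missing}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("LMS table requires M > 0 and S > 0")
        self._table = (
            table.loc[:, list(self.REQUIRED_COLUMNS)]
            .astype({"age_months": int, "L": float, "M": float, "S": float})
            .set_index(["sex", "age_months"])
            .sort_index()
        )

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def lookup(self, sex: str, age_months: int):
        """Return (L, M, S) for a sex/age key; KeyError if uncovered."""
        row = self._table.loc[(sex, int(age_months))]
        return float(row["L"]), float(row["M"]), float(row["S"])

    def zscore(self, x: float, sex: str, age_months: int) -> float:
        L, M, S = self.lookup(sex, age_months)
        return lms_zscore(x, L, M, S)

    def inverse(self, z: float, sex: str, age_months: int) -> float:
        L, M, S = self.lookup(sex, age_months)
        return lms_inverse(z, L, M, S)

    def __len__(self) -> int:
        return len(self._table)
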