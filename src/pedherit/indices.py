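"""Pediatric Metabolic Index, HOMA-IR and Matsuda insulin sensitivity index.

The Pediatric Metabolic Index (PMI) is a composite screening score for
children: a BMI z-score (adipose distribution) plus the product of waist,
triglyceride and HDL ratios against sex- and age-stratified reference medians
from normal-weight Mexican children (adipose dysfunction). Inputs are in the
units the index was defined in: waist circumference in cm, triglycerides and
HDL cholesterol in mmol/L. At the reference values the product term equals 1,
so PMI = bmi_z + 1; the index rises with central adiposity and triglycerides
and falls with HDL.

Ages below 10 years and 10 years or above select different lipid reference
medians; age exactly 10 is assigned to the older stratum (the original
strata "<10" / ">10" leave 10 unassigned, so a half-open boundary is needed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: (wc_intercept, wc_age_slope, tg_ref mmol/L, hdl_ref mmol/L) per (sex, stratum)
_PMI_REFS = {
    ("female", "young"): (36.13, 2.30, 0.88, 1.32),
    ("female", "old"): (36.13, 2.30, 1.04, 1.34),
    ("male", "young"): (44.08, 1.48, 0.77, 1.38),
    ("male", "old"): (44.08, 1.48, 1.06, 1.30),
}

_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male", 1: "male",
    "female": "female", "f": "female", "2": "female", 2: "female",
}


def _canon_sex(sex) -> str:
    key = sex.lower() if isinstance(sex, str) else sex
    if key not in _SEX_ALIASES:
        raise ValueError(f"sex must be male/female (or 1/2), got {sex!r}")
    return _SEX_ALIASES[key]


def pmi(bmi_z, wc, tg, hdl, age, sex) -> float | np.ndarray:
    """Pediatric Metabolic Index.

    PMI = bmi_z + (wc / wc_ref(age)) * (tg / tg_ref) * (hdl_ref / hdl)
    with sex- and age-stratified references; ``wc`` in cm, ``tg`` and ``hdl``
    in mmol/L, ``age`` in years within [2, 20]. Accepts scalars or aligned
    arrays (``sex`` as "male"/"female" or 1/2).
    """
    scalar = np.isscalar(bmi_z) or np.ndim(bmi_z) == 0
    bmi_z, wc, tg, hdl, age = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (bmi_z, wc, tg, hdl, age))
    )
    sexes = np.broadcast_to(np.asarray(sex, dtype=object), bmi_z.shape)
    if np.any(wc <= 0) or np.any(tg <= 0) or np.any(hdl <= 0):
        raise ValueError("wc, tg and hdl must all be positive")
    if np.any(age < 2) or np.any(age > 20):
        raise ValueError("PMI is defined for ages 2-20 years")
    out = np.empty(bmi_z.shape)
    for i in np.ndindex(bmi_z.shape):
        stratum = "young" if age[i] < 10 else "old"
        wc0, slope, tg_ref, hdl_ref = _PMI_REFS[(_canon_sex(sexes[i]), stratum)]
        wc_ref = wc0 + slope * age[i]
        out[i] = bmi_z[i] + (wc[i] / wc_ref) * (tg[i] / tg_ref) * (hdl_ref / hdl[i])
    return float(out[()]) if scalar else out


def homa_ir(glucose0, insulin0) -> float | np.ndarray:
    """HOMA-IR = fasting glucose (mg/dl) x fasting insulin (uIU/ml) / 405."""
    glucose0 = np.asarray(glucose0, dtype=float)
    insulin0 = np.asarray(insulin0, dtype=float)
    if np.any(glucose0 <= 0) or np.any(insulin0 <= 0):
        raise ValueError("glucose and insulin must be positive")
    out = glucose0 * insulin0 / 405.0
    return float(out) if out.ndim == 0 else out


def matsuda_isi(glucose, insulin) -> float | np.ndarray:
    """Whole-body (Matsuda) insulin sensitivity index from an OGTT.

    ``ISI = 10000 / sqrt(G0 * I0 * Gmean * Imean)`` where the means run over
    all timepoints including fasting; glucose in mg/dl, insulin in uIU/ml.
    The first entry along the last axis must be the fasting value and at
    least two post-load timepoints are required.
    """
    glucose = np.atleast_2d(np.asarray(glucose, dtype=float))
    insulin = np.atleast_2d(np.asarray(insulin, dtype=float))
    if glucose.shape != insulin.shape:
        raise ValueError("glucose and insulin profiles must align")
    if glucose.shape[-1] < 3:
        raise ValueError("need fasting plus at least two post-load timepoints")
    if np.any(glucose <= 0) or np.any(insulin <= 0):
        raise ValueError("OGTT values must be positive")
    g0, i0 = glucose[..., 0], insulin[..., 0]
    out = 10000.0 / np.sqrt(g0 * i0 * glucose.mean(axis=-1) * insulin.mean(axis=-1))
    return float(out[0]) if out.size == 1 else out


#: conversion divisors to the PMI working units
_CONVERSIONS = {
    "tg": 88.57,   # mg/dl -> mmol/L
    "hdl": 38.67,  # mg/dl -> mmol/L
    "wc": 10.0,    # mm -> cm
}


def unit_convert(value, quantity: str):
    """Convert tg/hdl (mg/dl -> mmol/L) or wc (mm -> cm) to PMI units."""
    if quantity not in _CONVERSIONS:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of {sorted(_CONVERSIONS)}")
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ValueError("values must be positive")
    out = value / _CONVERSIONS[quantity]
    return float(out) if out.ndim == 0 else out


def bmi_z_from_lms(bmi, age, sex, lms: pd.DataFrame) -> float | np.ndarray:
    """BMI z-score from an LMS growth-reference table.

    ``lms`` must have columns (sex, age, L, M, S); L, M, S are interpolated
    linearly in age within sex. z = ((BMI/M)^L - 1) / (L * S), with the
    log-normal limit log(BMI/M)/S as L -> 0.
    """
    scalar = np.isscalar(bmi)
    bmi = np.atleast_1d(np.asarray(bmi, dtype=float))
    age = np.broadcast_to(np.atleast_1d(np.asarray(age, dtype=float)), bmi.shape)
    sexes = np.broadcast_to(np.atleast_1d(np.asarray(sex, dtype=object)), bmi.shape)
    out = np.empty(bmi.shape)
    for i in range(bmi.size):
        s = _canon_sex(sexes[i])
        sub = lms[lms["sex"].map(_canon_sex) == s].sort_values("age")
        if sub.empty:
            raise ValueError(f"LMS table has no rows for sex {s!r}")
        L = np.interp(age[i], sub["age"], sub["L"])
        M = np.interp(age[i], sub["age"], sub["M"])
        S = np.interp(age[i], sub["age"], sub["S"])
        if abs(L) < 1e-8:
            out[i] = np.log(bmi[i] / M) / S
        else:
            out[i] = ((bmi[i] / M) ** L - 1.0) / (L * S)
    return float(out[0]) if scalar else out
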