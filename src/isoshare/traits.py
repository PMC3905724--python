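"""Phenotype derivation and transformation for lipid-trait association.

Implements the standard preparation chain for serum-lipid phenotypes:
unit harmonisation (mg/dl <-> mmol/l), Friedewald LDL derivation, 5-SD
outlier removal, natural-log and rank-based inverse-normal transforms, and
HDL dichotomisation.  The fixed order of operations is::

    unit harmonisation -> LDL derivation -> outlier removal
        -> transformation -> dichotomisation
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# conversion factors mg/dl per mmol/l
CHOLESTEROL_MGDL_PER_MMOL = 38.67  # HDL, LDL, total cholesterol
TRIGLYCERIDE_MGDL_PER_MMOL = 88.57

LDL_TG_EXCLUSION_MGDL = 400.0


@dataclass
class TransformSpec:
    """Per-trait transformation plan."""

    transforms: dict[str, str] = field(default_factory=dict)  # none|natural_log|inverse_normal
    outlier_sd: float = 5.0
    ldl_tg_exclusion_mgdl: float = LDL_TG_EXCLUSION_MGDL

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        for trait, kind in self.transforms.items():
            if kind not in ("none", "natural_log", "inverse_normal"):
                raise ValueError(f"unknown transform {kind!r} for {trait}")


def to_mgdl(values, trait: str, unit: str):
    """Convert a lipid measurement to mg/dl from its tagged unit."""
    values = np.asarray(values, dtype=float)
    if unit == "mg/dl":
        return values
    if unit != "mmol/l":
        raise ValueError(f"unknown unit {unit!r}")
    factor = (
        TRIGLYCERIDE_MGDL_PER_MMOL
        if trait.lower().startswith("trig")
        else CHOLESTEROL_MGDL_PER_MMOL
    )
    return values * factor


def to_mmoll(values, trait: str, unit: str):
    """Convert a lipid measurement to mmol/l from its tagged unit."""
    values = np.asarray(values, dtype=float)
    if unit == "mmol/l":
        return values
    if unit != "mg/dl":
        raise ValueError(f"unknown unit {unit!r}")
    factor = (
        TRIGLYCERIDE_MGDL_PER_MMOL
        if trait.lower().startswith("trig")
        else CHOLESTEROL_MGDL_PER_MMOL
    )
    return values / factor


def friedewald_ldl(tc_mgdl, hdl_mgdl, tg_mgdl):
    """LDL cholesterol by the Friedewald equation (all values mg/dl).

    LDL = TC - HDL - TG/5.  The formula is invalid at high triglycerides, so
    LDL is returned missing (NaN) wherever TG > 400 mg/dl.
    """
    tc = np.asarray(tc_mgdl, dtype=float)
    hdl = np.asarray(hdl_mgdl, dtype=float)
    tg = np.asarray(tg_mgdl, dtype=float)
    if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
        raise ValueError("lipid inputs must be non-negative")
    ldl = tc - hdl - tg / 5.0
    ldl = np.where(tg > LDL_TG_EXCLUSION_MGDL, np.nan, ldl)
    return ldl if ldl.ndim else float(ldl)


def remove_outliers(values, sd_mult: float = 5.0):
    """Set values more than ``sd_mult`` standard deviations from the mean to
    missing.

    The mean and SD are computed once over the non-missing input (single
    pass; no re-iteration after removal).  Strict inequality: a value exactly
    at the boundary is retained.
    """
    v = np.asarray(values, dtype=float).copy()
    ok = ~np.isnan(v)
    if ok.sum() == 0:
        return v
    if ok.sum() < 2:
        raise ValueError("need at least two non-missing values")
    mean = v[ok].mean()
    sd = v[ok].std(ddof=1)
    if sd == 0 or np.isinf(sd_mult):
        return v
    out = np.abs(v - mean) > sd_mult * sd
    v[out & ok] = np.nan
    return v


def transform(values, kind: str, sample_ids=None):
    """Apply a trait transformation.

    ``natural_log``: elementwise ln (positive values required).
    ``inverse_normal``: rank-based normal scores with the Blom offset
    (r - 3/8) / (n + 1/4); ties get the average rank; missing propagate.
    """
    v = np.asarray(values, dtype=float)
    if kind == "none":
        return v.copy()
    if kind == "natural_log":
        bad = ~np.isnan(v) & (v <= 0)
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            label = sample_ids[idx] if sample_ids is not None else f"index {idx}"
            raise ValueError(f"non-positive value under natural_log at {label}")
        return np.log(v)
    if kind == "inverse_normal":
        out = np.full_like(v, np.nan)
        ok = ~np.isnan(v)
        n = ok.sum()
        if n == 0:
            return out
        ranks = stats.rankdata(v[ok], method="average")
        out[ok] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
        return out
    raise ValueError(f"unknown transform kind {kind!r}")


def dichotomize_hdl(hdl_mgdl):
    """Classify HDL (mg/dl): >=60 'high', <40 'low', otherwise 'neither';
    missing propagates as None."""
    v = np.asarray(hdl_mgdl, dtype=float)

    def one(x: float):
        if np.isnan(x):
            return None
        if x >= 60.0:
            return "high"
        if x < 40.0:
            return "low"
        return "neither"

    if v.ndim == 0:
        return one(float(v))
    return np.array([one(x) for x in v], dtype=object)


def prepare_lipid_table(
    pheno: pd.DataFrame,
    units: dict[str, str],
    spec: TransformSpec | None = None,
) -> pd.DataFrame:
    """Run the full preparation chain on a phenotype table.

    ``units`` maps each lipid column to its unit tag.  Output columns keep
    their names; LDL is (re)derived by Friedewald whenever TC, HDL and TG are
    all present; derived columns ``hdl_high`` / ``hdl_low`` are appended.
    All lipids are returned in mg/dl.
    """
    spec = spec or TransformSpec()
    out = pheno.copy()
    lipid_cols = [c for c in ("total_cholesterol", "HDL", "LDL", "triglycerides") if c in out]
    for c in lipid_cols:
        out[c] = to_mgdl(out[c].to_numpy(float), c, units.get(c, "mg/dl"))
    if all(c in out for c in ("total_cholesterol", "HDL", "triglycerides")):
        out["LDL"] = friedewald_ldl(
            out["total_cholesterol"].to_numpy(float),
            out["HDL"].to_numpy(float),
            out["triglycerides"].to_numpy(float),
        )
    numeric = [
        c
        for c in out.columns
        if c not in ("sample_id", "sex") and pd.api.types.is_numeric_dtype(out[c])
    ]
    for c in numeric:
        out[c] = remove_outliers(out[c].to_numpy(float), spec.outlier_sd)
    if "HDL" in out:
        out["hdl_high"] = [
            None if cls is None else float(cls == "high")
            for cls in dichotomize_hdl(out["HDL"].to_numpy(float))
        ]
        out["hdl_low"] = [
            None if cls is None else float(cls == "low")
            for cls in dichotomize_hdl(out["HDL"].to_numpy(float))
        ]
    ids = out["sample_id"].tolist() if "sample_id" in out else None
    for c, kind in spec.transforms.items():
        if c in out:
            out[c] = transform(out[c].to_numpy(float), kind, sample_ids=ids)
    return out
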