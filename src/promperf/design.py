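"""Shared design-matrix construction for the case-mix covariates.

One canonical dummy coding is used by the data generator, the imputation
models and the analysis model, so that configured coefficients, imputation
predictors and fitted coefficients all refer to the same columns.

Covariate coding in patient frames (integer categories):
  age_band           0 = under 55, 1 = 55-65, 2 = 65-75, 3 = over 75
  male               0/1
  nonwhite           0/1 (ethnicity; may be missing)
  comorbidity_band   0 = none, 1 = one, 2 = two or more
  imd_quintile       0 = most deprived ... 4 = least deprived
  symptom_duration   0 = up to 1 year, 1 = 1-5 years, 2 = over 5 years (may be missing)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# (term name, source column, category it indicates); reference categories omitted
CASE_MIX_TERMS: list[tuple[str, str, int]] = [
    ("age_55_65", "age_band", 1),
    ("age_65_75", "age_band", 2),
    ("age_over75", "age_band", 3),
    ("male", "male", 1),
    ("nonwhite", "nonwhite", 1),
    ("comorb_1", "comorbidity_band", 1),
    ("comorb_2plus", "comorbidity_band", 2),
    ("imd_2", "imd_quintile", 1),
    ("imd_3", "imd_quintile", 2),
    ("imd_4", "imd_quintile", 3),
    ("imd_least", "imd_quintile", 4),
    ("dur_1_5y", "symptom_duration", 1),
    ("dur_over5y", "symptom_duration", 2),
]

CASE_MIX_NAMES = [name for name, _, _ in CASE_MIX_TERMS]


def case_mix_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded case-mix covariates (no intercept column).

    Raises if any required covariate is missing in any row: callers must
    pass completed data (or subset to complete cases first).
    """
    cols = {}
    for name, src, level in CASE_MIX_TERMS:
        vals = df[src].to_numpy()
        if pd.isna(vals).any():
            raise ValueError(f"case-mix covariate '{src}' has missing values; complete the data first")
        cols[name] = (vals.astype(int) == level).astype(float)
    return pd.DataFrame(cols, index=df.index)


def linear_predictor(df: pd.DataFrame, intercept: float, coefficients: dict[str, float]) -> np.ndarray:
    """intercept + X beta for coefficients keyed by term or raw column name."""
    out = np.full(len(df), float(intercept))
    dummies = case_mix_matrix(df) if any(k in CASE_MIX_NAMES for k in coefficients) else None
    for name, coef in coefficients.items():
        if dummies is not None and name in dummies.columns:
            out += coef * dummies[name].to_numpy()
        else:
            out += coef * df[name].to_numpy(dtype=float)
    return out
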