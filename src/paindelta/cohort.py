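"""Cohort preparation: inclusion/exclusion rules and derived analysis covariates.

The study population is newly admitted nursing-home residents aged 50+ with a
valid cognition measure and at least one valid pain item. Cognitive status is
taken from the Brief Interview for Mental Status (BIMS, 0-15, higher = less
impaired) when completed, otherwise from the Cognitive Performance Scale
(CPS, 0-6, higher = more impaired). Physical functioning uses the ADL
hierarchy score (0-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import schema as S

__all__ = [
    "ExclusionTally", "apply_inclusion_filters", "classify_cognition",
    "classify_adl", "derive_covariates", "prepare_cohort",
    "read_cohort_csv", "write_cohort_csv",
]

_INT_COLUMNS = ([S.BIMS, S.CPS] + S.RES_PAIN_ITEMS + S.STAFF_BEHAVIORS
                + [S.STAFF_FREQ, S.PAIN_MGMT])


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table; empty fields become NA on the coded columns."""
    df = pd.read_csv(path)
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class ExclusionTally:
    """Counts removed by each rule, in application order."""

    input_count: int = 0
    age_under_50: int = 0
    not_first_admission: int = 0
    comatose: int = 0
    invalid_cognition: int = 0
    no_valid_pain_item: int = 0
    retained: int = 0

    def removed(self) -> int:
        return (self.age_under_50 + self.not_first_admission + self.comatose
                + self.invalid_cognition + self.no_valid_pain_item)

    def as_dict(self) -> dict:
        return asdict(self)


def classify_cognition(bims=None, cps=None) -> str:
    """Three-level cognitive category from BIMS, falling back to CPS.

    Cutoffs: no/mild impairment BIMS 13-15 or CPS 0-2; moderate BIMS 8-12 or
    CPS 3-4; severe BIMS 0-7 or CPS 5-6. BIMS takes precedence when both are
    present (the interview is only skipped when it cannot be completed).
    """
    bims_missing = bims is None or (isinstance(bims, float) and np.isnan(bims)) or bims is pd.NA
    cps_missing = cps is None or (isinstance(cps, float) and np.isnan(cps)) or cps is pd.NA
    if not bims_missing:
        b = int(bims)
        if not 0 <= b <= 15:
            raise ValueError(f"BIMS score {b} outside 0-15")
        if b >= 13:
            return "no_mild"
        if b >= 8:
            return "moderate"
        return "severe"
    if not cps_missing:
        c = int(cps)
        if not 0 <= c <= 6:
            raise ValueError(f"CPS score {c} outside 0-6")
        if c <= 2:
            return "no_mild"
        if c <= 4:
            return "moderate"
        return "severe"
    raise ValueError("neither BIMS nor CPS available")


def classify_adl(score) -> str:
    """ADL hierarchy category: 0-2 no/minimal, 3-4 moderate, 5-6 severe."""
    s = int(score)
    if not 0 <= s <= 6:
        raise ValueError(f"ADL hierarchy score {s} outside 0-6")
    if s <= 2:
        return "no_minimal"
    if s <= 4:
        return "moderate"
    return "severe"


def _classify_cognition_vec(df: pd.DataFrame) -> pd.Series:
    """Vectorised cognition classification; NA where neither score is valid."""
    bims = pd.to_numeric(df[S.BIMS], errors="coerce")
    cps = pd.to_numeric(df[S.CPS], errors="coerce")
    out = pd.Series(pd.NA, index=df.index, dtype="object")
    has_b = bims.notna()
    out[has_b & (bims >= 13)] = "no_mild"
    out[has_b & (bims >= 8) & (bims <= 12)] = "moderate"
    out[has_b & (bims <= 7)] = "severe"
    use_c = ~has_b & cps.notna()
    out[use_c & (cps <= 2)] = "no_mild"
    out[use_c & (cps >= 3) & (cps <= 4)] = "moderate"
    out[use_c & (cps >= 5)] = "severe"
    return out


def _has_valid_pain_item(df: pd.DataFrame) -> pd.Series:
    cols = S.RES_PAIN_ITEMS + S.STAFF_BEHAVIORS + [S.STAFF_FREQ]
    return df[cols].notna().any(axis=1)


def apply_inclusion_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the study inclusion/exclusion rules in a fixed, documented order.

    Order: age >= 50; first admission per resident; not comatose; valid
    cognition (BIMS or CPS); at least one valid pain item. The order affects
    the per-rule tally, not the final set. Idempotent.
    """
    tally = ExclusionTally(input_count=len(records))
    df = records

    keep = df[S.AGE_YEARS] >= 50
    tally.age_under_50 = int((~keep).sum())
    df = df[keep]

    keep = df[S.ADMISSION_SEQ] == 1
    tally.not_first_admission = int((~keep).sum())
    df = df[keep]

    keep = df[S.COMATOSE] != 1
    tally.comatose = int((~keep).sum())
    df = df[keep]

    keep = _classify_cognition_vec(df).notna() if len(df) else pd.Series(dtype=bool)
    tally.invalid_cognition = int((~keep).sum()) if len(df) else 0
    df = df[keep] if len(df) else df

    keep = _has_valid_pain_item(df) if len(df) else pd.Series(dtype=bool)
    tally.no_valid_pain_item = int((~keep).sum()) if len(df) else 0
    df = df[keep] if len(df) else df

    tally.retained = len(df)
    return df.copy(), tally


def derive_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Attach derived analysis columns: cognitive category, ADL category,
    staff-assessed pain presence (any of the four pain behaviors)."""
    df = records.copy()
    df[S.COG_CAT] = _classify_cognition_vec(df)
    df[S.ADL_CAT] = pd.cut(
        pd.to_numeric(df[S.ADL_SCORE]), bins=[-0.5, 2.5, 4.5, 6.5],
        labels=S.ADL_CATS,
    ).astype("object")
    beh = df[S.STAFF_BEHAVIORS]
    any_yes = (beh == 1).any(axis=1)
    any_valid = beh.notna().any(axis=1)
    staff = pd.Series(pd.NA, index=df.index, dtype="object")
    staff[any_valid] = 0
    staff[any_yes] = 1
    df[S.STAFF_PRESENCE] = staff.astype("Int64")
    return df


def prepare_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Filter then derive: the standard entry point for raw cohort tables."""
    filtered, tally = apply_inclusion_filters(records)
    return derive_covariates(filtered), tally
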