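"""Counterfactual imputable-variable construction.

The counterfactual question — what pain would a cognitively impaired resident
have documented absent the impairment? — is operationalised as a missing-data
problem: for every resident-reported pain item an "imputable" copy is created
that retains the documented value for residents with no/mild impairment and is
set to missing for residents with moderate/severe impairment. Two combined
variables (presence, frequency) additionally fall back to the staff-assessed
channel when a no/mild resident could not self-report, so that the imputation
model is trained on the full unimpaired stratum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import schema as S

__all__ = [
    "ColumnMeta", "ImputableFrame", "apply_no_pain_defaults",
    "build_item_imputables", "build_combined_pain", "build_imputable_frame",
    "screen_covariates", "A_PRIORI_COVARIATES", "SCREENING_CANDIDATES",
    "IMPUTABLE_ITEMS", "COMBINED_ITEMS", "DEFAULT_IMPUTABLE_ORDER",
]

# Always-retained imputation covariates: demographics, physical functioning,
# and potentially painful conditions (substantive knowledge, not screening).
A_PRIORI_COVARIATES = [
    S.AGE_GROUP, S.GENDER, S.RACE, S.MARITAL, S.ADL_CAT,
    "arthritis", "fracture", "cancer", "osteoporosis",
]
# Broader candidate set offered to stepwise screening.
SCREENING_CANDIDATES = [c for c in S.COMORBIDITIES
                        if c not in A_PRIORI_COVARIATES] + S.PHQ_ITEMS

# imputable column -> (source column, kind, levels/bounds)
IMPUTABLE_ITEMS = {
    "imp_presence": (S.RES_PRESENCE, "binary", (0, 1)),
    "imp_freq": (S.RES_FREQ, "ordinal", (0, 1, 2, 3, 4)),
    "imp_effect": (S.RES_EFFECT, "binary", (0, 1)),
    "imp_numeric": (S.RES_NUMERIC, "continuous", (0, 10)),
    "imp_verbal": (S.RES_VERBAL, "ordinal", (0, 1, 2, 3, 4)),
}
COMBINED_ITEMS = {
    "comb_presence": ("binary", (0, 1)),
    "comb_freq": ("ordinal", (0, 1, 2, 3, 4)),
}

# Default cycle order: presence before the detail items it gates, and each
# combined item directly after its source item so that, under the sequential
# predictor default, a combined item is conditioned on its source item and
# the covariates rather than on the later severity details.
DEFAULT_IMPUTABLE_ORDER = [
    "imp_presence", "comb_presence", "imp_freq", "comb_freq",
    "imp_effect", "imp_numeric", "imp_verbal",
]

_COVARIATE_KINDS = {
    S.AGE_GROUP: ("nominal", (0, 1, 2, 3)),
    S.GENDER: ("binary", (0, 1)),
    S.RACE: ("nominal", (0, 1, 2, 3)),
    S.MARITAL: ("nominal", (0, 1, 2, 3, 4)),
    S.ADL_CAT: ("nominal", tuple(S.ADL_CATS)),
}


@dataclass(frozen=True)
class ColumnMeta:
    name: str
    kind: str            # binary | nominal | ordinal | continuous
    role: str            # imputable | predictor | stratum | block | id
    levels: tuple | None = None
    bounds: tuple | None = None


@dataclass
class ImputableFrame:
    """Rectangular analysis matrix with per-column metadata.

    Invariants: every imputable cell of a moderate/severe resident is missing;
    every imputable cell of a no/mild resident equals its source value (source
    missingness preserved for item-level imputables).
    """

    data: pd.DataFrame
    meta: dict

    def columns_with_role(self, role: str) -> list:
        return [c for c, m in self.meta.items() if m.role == role]

    @property
    def imputable_columns(self) -> list:
        return self.columns_with_role("imputable")

    @property
    def predictor_columns(self) -> list:
        return self.columns_with_role("predictor")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data[self.imputable_columns].isna()

    def to_files(self, csv_path, meta_path) -> None:
        self.data.to_csv(csv_path, index=False)
        with open(meta_path, "w") as fh:
            json.dump({c: asdict(m) for c, m in self.meta.items()}, fh, indent=1)

    @classmethod
    def from_files(cls, csv_path, meta_path) -> "ImputableFrame":
        with open(meta_path) as fh:
            raw = json.load(fh)
        meta = {c: ColumnMeta(name=v["name"], kind=v["kind"], role=v["role"],
                              levels=tuple(v["levels"]) if v["levels"] else None,
                              bounds=tuple(v["bounds"]) if v["bounds"] else None)
                for c, v in raw.items()}
        data = pd.read_csv(csv_path)
        for c, m in meta.items():
            if m.kind in ("binary", "nominal", "ordinal") and data[c].dtype != object:
                data[c] = data[c].astype("Int64")
        return cls(data=data, meta=meta)


def apply_no_pain_defaults(records: pd.DataFrame) -> pd.DataFrame:
    """Default resident-reported detail items to "no pain" where implied.

    A missing frequency / verbal descriptor is set to the "no pain" level, and
    a missing numeric rating to 0, when the resident-reported presence item is
    "no" — or, when presence itself is missing, when the staff-assessed
    channel documented no pain. Explicit documented values are never changed.
    """
    df = records.copy()
    res_no = df[S.RES_PRESENCE] == 0
    staff_no = df[S.RES_PRESENCE].isna() & (df[S.STAFF_PRESENCE] == 0)
    no_pain = (res_no | staff_no).fillna(False).astype(bool)
    for col, fill in ((S.RES_FREQ, 0), (S.RES_VERBAL, 0), (S.RES_NUMERIC, 0)):
        target = df[col].isna() & no_pain
        df.loc[target, col] = fill
    return df


def build_item_imputables(records: pd.DataFrame) -> pd.DataFrame:
    """Item-level imputables: copies of the resident-reported items for
    no/mild residents, missing for moderate/severe residents."""
    no_mild = records[S.COG_CAT] == "no_mild"
    out = pd.DataFrame(index=records.index)
    for imp_col, (src, _, _) in IMPUTABLE_ITEMS.items():
        vals = records[src].where(no_mild, other=pd.NA)
        out[imp_col] = vals.astype("Int64")
    return out


def build_combined_pain(records: pd.DataFrame) -> pd.DataFrame:
    """Combined presence/frequency imputables with staff-channel fallback.

    For no/mild residents: the resident-reported value when available,
    otherwise the staff-assessed value (presence = any of the four observed
    pain behaviors; staff frequency 1-2 days / 3-4 days / daily maps onto the
    resident scale as rarely / occasionally / frequently). Missing for
    moderate/severe residents.
    """
    no_mild = records[S.COG_CAT] == "no_mild"
    presence = records[S.RES_PRESENCE].copy()
    use_staff = presence.isna()
    presence[use_staff] = records.loc[use_staff, S.STAFF_PRESENCE]

    freq = records[S.RES_FREQ].copy()
    staff_freq = records[S.STAFF_FREQ]  # identity codes onto the resident scale
    fallback = freq.isna()
    freq[fallback] = staff_freq[fallback]
    # staff channel documented "no pain" (behaviors assessed, none observed)
    staff_none = fallback & freq.isna() & (records[S.STAFF_PRESENCE] == 0)
    freq[staff_none] = 0

    out = pd.DataFrame(index=records.index)
    out["comb_presence"] = presence.where(no_mild, other=pd.NA).astype("Int64")
    out["comb_freq"] = freq.where(no_mild, other=pd.NA).astype("Int64")
    return out


def build_imputable_frame(records: pd.DataFrame, covariates=None,
                          imputables=None) -> ImputableFrame:
    """Assemble the analysis matrix consumed by the FCS engine.

    ``records`` must already carry the derived columns (cognitive category,
    ADL category, staff presence); the "no pain" defaulting rule is applied
    here before construction. ``covariates`` defaults to the a-priori set;
    ``imputables`` restricts which imputable columns are built (default all).
    """
    if covariates is None:
        covariates = list(A_PRIORI_COVARIATES)
    rec = apply_no_pain_defaults(records)
    items = build_item_imputables(rec)
    combined = build_combined_pain(rec)
    wanted = list(DEFAULT_IMPUTABLE_ORDER) if imputables is None \
        else list(imputables)

    data = pd.DataFrame(index=rec.index)
    meta: dict[str, ColumnMeta] = {}
    data[S.ID] = rec[S.ID]
    meta[S.ID] = ColumnMeta(S.ID, "continuous", "id")
    for col in wanted:
        if col in IMPUTABLE_ITEMS:
            src, kind, lv = IMPUTABLE_ITEMS[col]
            data[col] = items[col]
        else:
            kind, lv = COMBINED_ITEMS[col]
            data[col] = combined[col]
        levels = lv if kind != "continuous" else None
        bounds = lv if kind == "continuous" else None
        meta[col] = ColumnMeta(col, kind, "imputable", levels=levels, bounds=bounds)
    for cov in covariates:
        kind, levels = _COVARIATE_KINDS.get(cov, ("binary", (0, 1)))
        if cov in S.PHQ_ITEMS:
            kind, levels = "ordinal", (0, 1, 2, 3)
        data[cov] = rec[cov]
        meta[cov] = ColumnMeta(cov, kind, "predictor", levels=tuple(levels))
    data[S.COG_CAT] = rec[S.COG_CAT]
    meta[S.COG_CAT] = ColumnMeta(S.COG_CAT, "nominal", "stratum", levels=tuple(S.STRATA))
    if S.BLOCK in rec:
        data[S.BLOCK] = rec[S.BLOCK]
        meta[S.BLOCK] = ColumnMeta(S.BLOCK, "nominal", "block")
    return ImputableFrame(data=data, meta=meta)


# ---------------------------------------------------------------------------
# Covariate screening

def _fit_logit(y, X):
    model = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                   family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def screen_covariates(records: pd.DataFrame, outcome: str, candidates,
                      a_priori=None, method: str = "pvalue",
                      p_enter: float = 0.15, p_remove: float = 0.15) -> list:
    """Forward-backward stepwise screening of imputation-model covariates.

    The a-priori set is always retained. Candidates are entered/removed
    against a binary pain indicator by Wald p-value (inclusion criterion
    0.15 by default) or by AIC minimisation. Deterministic: candidates are
    evaluated in their given order with ties broken by that order. Constant
    (degenerate) candidates are dropped with a warning.
    """
    if a_priori is None:
        a_priori = list(A_PRIORI_COVARIATES)
    overlap = set(a_priori) & set(candidates)
    if overlap:
        raise ValueError(f"candidates overlap the a-priori set: {sorted(overlap)}")

    rows = records[records[outcome].notna()]
    y = rows[outcome].astype(float).to_numpy()
    usable = []
    for c in candidates:
        col = pd.to_numeric(rows[c], errors="coerce")
        if col.nunique(dropna=True) < 2:
            warnings.warn(f"dropping constant screening candidate {c!r}")
        else:
            usable.append(c)

    def design(cols):
        mats = []
        for c in a_priori:
            kind, _ = _COVARIATE_KINDS.get(c, ("binary", None))
            if kind == "nominal":
                mats.append(pd.get_dummies(rows[c], prefix=c, drop_first=True)
                            .astype(float))
            else:
                mats.append(pd.to_numeric(rows[c]).astype(float).rename(c).to_frame())
        for c in cols:
            mats.append(pd.to_numeric(rows[c]).astype(float).rename(c).to_frame())
        return pd.concat(mats, axis=1)

    selected: list = []
    improved = True
    base_fit = _fit_logit(y, design(selected))
    steps = 0
    max_steps = 2 * len(usable) + 10  # guard against enter/remove cycling
    while improved and steps < max_steps:
        steps += 1
        improved = False
        # forward step
        best = None
        for c in usable:
            if c in selected:
                continue
            fit = _fit_logit(y, design(selected + [c]))
            if method == "aic":
                score = fit.aic
                ok = score < base_fit.aic - 1e-9
            else:
                score = fit.pvalues[c]
                ok = score < p_enter
            if ok and (best is None or score < best[1]):
                best = (c, score, fit)
        if best is not None:
            selected.append(best[0])
            base_fit = best[2]
            improved = True
        # backward step
        worst = None
        for c in selected:
            if method == "aic":
                fit = _fit_logit(y, design([x for x in selected if x != c]))
                if fit.aic < base_fit.aic - 1e-9 and (worst is None or fit.aic < worst[1]):
                    worst = (c, fit.aic, fit)
            else:
                p = base_fit.pvalues[c]
                if p > p_remove and (worst is None or p > worst[1]):
                    worst = (c, p, None)
        if worst is not None:
            selected.remove(worst[0])
            base_fit = worst[2] if worst[2] is not None else _fit_logit(y, design(selected))
            improved = True
    return list(a_priori) + selected
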