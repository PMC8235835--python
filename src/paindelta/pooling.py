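"""Observed-minus-expected deltas and Rubin's-rules pooling.

For each pain indicator, stratum, and subgroup, the per-resident difference
d_i = observed_i - imputed_i is averaged (x100 for categorical indicators,
giving percentage points) within each completed dataset, then the M
per-imputation estimates are pooled: Qbar = mean(Q_m), within-variance
W = mean(W_m), between-variance B = var(Q_m), total T = W + (1 + 1/M) B,
degrees of freedom df = (M-1)(1 + W/((1+1/M)B))^2, and a t-based 95% CI.
A negative delta means pain was documented less often than the imputed
counterfactual expects.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import schema as S
from .fcs import ImputationResult
from .imputables import apply_no_pain_defaults

__all__ = [
    "PooledDelta", "compute_delta", "pool_rubin", "stratified_deltas",
    "delta_table", "summarize_documented", "INDICATORS", "SUBGROUPS",
]


# indicator name -> (observed column, imputed column, kind, levels)
INDICATORS = {
    "any_pain_staff": (S.STAFF_PRESENCE, "comb_presence", "binary", (1,)),
    "any_pain_resident": (S.RES_PRESENCE, "comb_presence", "binary", (1,)),
    "pain_frequency": (S.RES_FREQ, "imp_freq", "categorical", (0, 1, 2, 3, 4)),
    "pain_numeric": (S.RES_NUMERIC, "imp_numeric", "numeric", None),
    "pain_verbal": (S.RES_VERBAL, "imp_verbal", "categorical", (0, 1, 2, 3, 4)),
}

SUBGROUPS = {
    "overall": None,
    "gender": S.GENDER,
    "pain_mgmt": S.PAIN_MGMT,
    "fracture": "fracture",
    "arthritis": "arthritis",
}


@dataclass
class PooledDelta:
    indicator: str
    level: object
    stratum: str
    subgroup: str
    subgroup_level: object
    n: int
    estimate: float
    within: float
    between: float
    total: float
    df: float
    ci_low: float
    ci_high: float
    flag: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


_DELTA_COLUMNS = ["indicator", "level", "stratum", "subgroup", "subgroup_level",
                  "n", "estimate", "within", "between", "total", "df",
                  "ci_low", "ci_high", "flag"]


def compute_delta(observed: pd.Series, imputed: pd.Series, mask,
                  kind: str = "binary", level=1) -> tuple:
    """Mean observed-minus-imputed difference within one completed frame.

    ``mask`` selects the analysis rows (stratum members with a valid observed
    response). Categorical indicators are indicator-coded at ``level`` and
    reported in percentage points; numeric indicators in scale units.
    Returns ``(estimate, within_variance, n)`` on the reporting scale.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty stratum: no residents with a valid response")
    obs = pd.to_numeric(observed[mask], errors="coerce").to_numpy(dtype=float)
    imp = pd.to_numeric(imputed[mask], errors="coerce").to_numpy(dtype=float)
    if kind == "numeric":
        d = obs - imp
    else:
        d = (obs == level).astype(float) - (imp == level).astype(float)
        d *= 100.0
    est = float(d.mean())
    within = float(d.var(ddof=1) / n) if n > 1 else 0.0
    return est, within, n


def pool_rubin(estimates, within_vars) -> dict:
    """Rubin's rules over M per-imputation (estimate, within-variance) pairs.

    Returns Qbar, W, B, T = W + (1+1/M)B, df, and the 95% t-interval.
    B = 0 degenerates to df = inf and a normal interval.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(within_vars, dtype=float)
    m = q.shape[0]
    if m < 2:
        raise ValueError("Rubin pooling requires M >= 2 imputations")
    qbar = float(q.mean())
    W = float(w.mean())
    B = float(q.var(ddof=1))
    # identical estimates leave rounding dust (~1e-30) in the variance;
    # snap it to zero so the documented B = 0 branch applies
    if B <= 1e-12 * max(W, 1.0):
        B = 0.0
    T = W + (1.0 + 1.0 / m) * B
    if B <= 0.0:
        df = np.inf
        crit = stats.norm.ppf(0.975)
    else:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        crit = stats.t.ppf(0.975, df)
    half = crit * np.sqrt(T)
    return {"estimate": qbar, "within": W, "between": B, "total": T,
            "df": float(df), "ci_low": qbar - half, "ci_high": qbar + half}


def delta_table(records: pd.DataFrame, result: ImputationResult,
                strata=None, indicators=None) -> pd.DataFrame:
    """Pooled deltas per indicator x level x stratum (the headline table).

    ``records`` is the prepared cohort (documented values); imputed values
    come from the completed frames, aligned by resident id. Each indicator
    uses its own denominator: stratum members with a valid observed response.
    """
    rows = [d.as_dict() for d in _iter_deltas(records, result,
                                              strata=strata,
                                              indicators=indicators,
                                              subgroups={"overall": None})]
    return pd.DataFrame(rows, columns=_DELTA_COLUMNS)


def stratified_deltas(records: pd.DataFrame, result: ImputationResult,
                      strata=None, indicators=None,
                      subgroups=None) -> pd.DataFrame:
    """Pooled deltas additionally stratified by resident characteristics
    (gender, pharmacologic pain management, fracture, arthritis)."""
    rows = [d.as_dict() for d in _iter_deltas(records, result, strata=strata,
                                              indicators=indicators,
                                              subgroups=subgroups)]
    return pd.DataFrame(rows, columns=_DELTA_COLUMNS)


def _iter_deltas(records, result, strata=None, indicators=None, subgroups=None):
    if strata is None:
        strata = list(S.IMPAIRED_STRATA)
    if indicators is None:
        indicators = {k: v for k, v in INDICATORS.items()
                      if v[1] in result.frames[0].columns}
    if subgroups is None:
        subgroups = dict(SUBGROUPS)

    # Observed detail items follow the table convention: missing details are
    # defaulted to "no pain"/0 when the presence item documents no pain.
    rec = apply_no_pain_defaults(records).reset_index(drop=True)
    frames = [f.reset_index(drop=True) for f in result.frames]
    if not (rec[S.ID].to_numpy() == frames[0][S.ID].to_numpy()).all():
        id_pos = {rid: i for i, rid in enumerate(frames[0][S.ID])}
        order = [id_pos[rid] for rid in rec[S.ID]]
        frames = [f.iloc[order].reset_index(drop=True) for f in frames]

    for name, (obs_col, imp_col, kind, levels) in indicators.items():
        observed = rec[obs_col]
        valid = observed.notna().to_numpy()
        for stratum in strata:
            in_stratum = (rec[S.COG_CAT] == stratum).to_numpy()
            for sub_name, sub_col in subgroups.items():
                sub_levels = [None] if sub_col is None else \
                    sorted(rec[sub_col].dropna().unique())
                for sub_level in sub_levels:
                    mask = valid & in_stratum
                    if sub_col is not None:
                        mask = mask & (rec[sub_col] == sub_level).to_numpy()
                    for level in (levels or (None,)):
                        yield _one_pooled(name, level, stratum, sub_name,
                                          sub_level, observed, frames,
                                          imp_col, kind, mask)


def _one_pooled(name, level, stratum, sub_name, sub_level, observed, frames,
                imp_col, kind, mask) -> PooledDelta:
    n = int(mask.sum())
    if n == 0:
        return PooledDelta(indicator=name, level=level, stratum=stratum,
                           subgroup=sub_name, subgroup_level=sub_level, n=0,
                           estimate=np.nan, within=np.nan, between=np.nan,
                           total=np.nan, df=np.nan, ci_low=np.nan,
                           ci_high=np.nan, flag="empty_subgroup")
    ests, wvars = [], []
    for f in frames:
        e, wv, _ = compute_delta(observed, f[imp_col], mask, kind=kind,
                                 level=level)
        ests.append(e)
        wvars.append(wv)
    pooled = pool_rubin(ests, wvars)
    return PooledDelta(indicator=name, level=level, stratum=stratum,
                       subgroup=sub_name, subgroup_level=sub_level, n=n,
                       estimate=pooled["estimate"], within=pooled["within"],
                       between=pooled["between"], total=pooled["total"],
                       df=pooled["df"], ci_low=pooled["ci_low"],
                       ci_high=pooled["ci_high"])


# ---------------------------------------------------------------------------
# Documented-distribution summary

def summarize_documented(records: pd.DataFrame) -> pd.DataFrame:
    """Distribution of documented pain indicators by cognition stratum.

    One row per indicator level and stratum with the item-specific
    denominator (residents lacking a valid response to an item are excluded
    from that item's denominator only). Percentages to one decimal; the
    numeric rating is summarised by median and quartiles.
    """
    records = apply_no_pain_defaults(records)
    rows = []
    cat_items = [
        ("staff_assessed_pain", S.STAFF_PRESENCE, {1: "yes", 0: "no"}),
        ("resident_reported_pain", S.RES_PRESENCE, {1: "yes", 0: "no"}),
        ("pain_frequency", S.RES_FREQ,
         dict(enumerate(S.FREQ_LABELS))),
        ("pain_verbal", S.RES_VERBAL, dict(enumerate(S.VERBAL_LABELS))),
        ("pain_management", S.PAIN_MGMT, dict(enumerate(S.PAIN_MGMT_LABELS))),
    ]
    for stratum in S.STRATA:
        sub = records[records[S.COG_CAT] == stratum]
        for item, col, labels in cat_items:
            valid = sub[sub[col].notna()]
            n_item = len(valid)
            for code, label in labels.items():
                count = int((valid[col] == code).sum())
                pct = round(100.0 * count / n_item, 1) if n_item else np.nan
                rows.append({"stratum": stratum, "indicator": item,
                             "level": label, "n_item": n_item,
                             "count": count, "percent": pct})
        numeric = pd.to_numeric(sub[S.RES_NUMERIC], errors="coerce").dropna()
        q25, q50, q75 = (numeric.quantile([0.25, 0.5, 0.75])
                         if len(numeric) else (np.nan,) * 3)
        rows.append({"stratum": stratum, "indicator": "pain_numeric",
                     "level": "median_iqr", "n_item": int(len(numeric)),
                     "count": np.nan,
                     "percent": np.nan, "median": float(q50),
                     "q25": float(q25), "q75": float(q75)})
    return pd.DataFrame(rows)
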