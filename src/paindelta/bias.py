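"""Sensitivity analyses for the counterfactual imputation deltas.

Two complementary tools bound how much residual bias would be needed to
explain an observed-minus-expected pain delta away:

* the e-value — the minimum strength of association (on the risk-ratio
  scale, conditional on the measured covariates) that an unmeasured
  confounder would need with both cognitive impairment and pain to fully
  account for the observed risk ratio; and
* sensitivity/specificity quantitative bias analysis of the imputed
  counterfactual itself, treating the imputation as a misclassified binary
  measurement and applying the standard apparent-prevalence identity
  ``apparent = pi * Se + (1 - pi) * (1 - Sp)`` (Rogan-Gladen).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "BiasScenario", "e_value", "delta_to_rr", "qba_corrected_prevalence",
    "qba_specificity_threshold", "bias_report",
]


@dataclass(frozen=True)
class BiasScenario:
    """One misclassification/confounding scenario for a binary indicator."""

    apparent: float          # imputed (counterfactual) prevalence
    reference: float         # documented prevalence
    sensitivity: float
    specificity: float
    rr: float
    e_value: float

    def as_dict(self) -> dict:
        return asdict(self)


def e_value(rr: float) -> float:
    """E-value for a risk ratio: RR + sqrt(RR (RR - 1)), with RR < 1 first
    inverted. 1.0 at the null; grows without bound with |log RR|."""
    if rr <= 0:
        raise ValueError("risk ratio must be positive")
    r = rr if rr >= 1.0 else 1.0 / rr
    return float(r + np.sqrt(r * (r - 1.0)))


def delta_to_rr(observed_prevalence: float, delta_points: float) -> float:
    """Risk ratio implied by a documented prevalence and a pooled delta.

    For an under-documentation delta of -d points the imputed counterfactual
    prevalence is observed + d/100, and RR = counterfactual / observed.
    """
    if not 0.0 < observed_prevalence < 1.0:
        raise ValueError("observed prevalence must be in (0, 1)")
    counterfactual = observed_prevalence + abs(delta_points) / 100.0
    if not 0.0 < counterfactual < 1.0:
        raise ValueError("implied counterfactual prevalence outside (0, 1)")
    return counterfactual / observed_prevalence


def qba_corrected_prevalence(apparent: float, se: float, sp: float) -> tuple:
    """Rogan-Gladen corrected prevalence (apparent + Sp - 1)/(Se + Sp - 1).

    Returns ``(corrected, flag)``; the value is clamped to [0, 1] and the
    flag set when the raw solution falls outside.
    """
    if se + sp <= 1.0:
        raise ValueError("requires Se + Sp > 1")
    raw = (apparent + sp - 1.0) / (se + sp - 1.0)
    clamped = min(1.0, max(0.0, raw))
    return clamped, ("out_of_range" if raw != clamped else "")


def qba_specificity_threshold(apparent: float, reference: float,
                              se: float) -> tuple:
    """Specificity below which imputation false-positives alone explain the
    gap between the imputed (apparent) and documented (reference) prevalence.

    Solves ``apparent = pi Se + (1 - pi)(1 - Sp)`` for Sp with
    ``pi = reference``. Returns ``(sp, flag)``; flagged when no Sp in [0, 1]
    can explain the difference under the given sensitivity.
    """
    for name, v in (("apparent", apparent), ("reference", reference), ("se", se)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    sp = 1.0 - (apparent - reference * se) / (1.0 - reference)
    flag = ""
    if not 0.0 <= sp <= 1.0:
        flag = "scenario cannot explain the difference"
    return float(sp), flag


def bias_report(delta_rows, se_grid=(0.85, 0.9, 0.95)) -> list:
    """Per-indicator bias summary from pooled binary delta rows.

    ``delta_rows``: iterable of dicts with keys ``indicator``, ``stratum``,
    ``observed_prevalence`` (proportion) and ``estimate`` (delta in points).
    For each row the implied RR and e-value are reported together with the
    QBA specificity threshold over the sensitivity grid.
    """
    out = []
    for row in delta_rows:
        obs = row["observed_prevalence"]
        delta = row["estimate"]
        rr = delta_to_rr(obs, delta)
        ev = round(e_value(rr), 2)
        apparent = obs + abs(delta) / 100.0
        entry = {"indicator": row["indicator"], "stratum": row["stratum"],
                 "observed_prevalence": obs, "imputed_prevalence": apparent,
                 "delta": delta, "rr": rr, "e_value": ev, "qba": []}
        for se in se_grid:
            sp, flag = qba_specificity_threshold(apparent, obs, se)
            entry["qba"].append({"sensitivity": se,
                                 "specificity_threshold": sp, "flag": flag})
        out.append(entry)
    return out
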