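"""Transfusion treatments, baseline factuals and counterfactual covariates.

The actionable variable is the pre-operative hematocrit (HCT, a volume
percentage).  One standard 300cc bag of blood raises HCT by roughly 3
percentage points, and at most 3 bags are considered safe, so the treatment
domain is b in {0, 1, 2, 3} bags, i.e. HCT increases of {0, 3, 6, 9}
points.

Registry data record only *whether* a pre-operative transfusion occurred
(TRANSFUS), not how much blood was given.  The baseline factual rule
reconstructs a plausible dose from the recorded HCT: patients above the
common transfusion trigger of 30 are assumed to have received at most one
bag, with extra bags added as HCT falls, aiming to bring the patient back
above 30:

    TRANSFUS = 0            -> 0 bags
    TRANSFUS = 1, HCT > 30  -> 1 bag
    TRANSFUS = 1, 27<HCT<30 -> 2 bags
    TRANSFUS = 1, HCT < 27  -> 3 bags

(boundary values receive the fewer-bags arm — conservative transfusion).

A transfusion moves more than HCT.  The counterfactual model screens the
other pre-operative variables for |Pearson correlation with HCT| above a
cut-off (default 0.1) and fits a univariate regression of each on HCT —
ordinary least squares on the natural scale, or on the logit scale for
bounded-probability variables so adjusted values stay inside (0, 1).  When
a treatment shifts HCT by delta, each correlated variable is shifted by
slope * delta on its link scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import PRE_OP, CohortTable

logger = logging.getLogger(__name__)

HCT_POINTS_PER_BAG = 3.0
MAX_BAGS = 3
BAG_CHOICES = (0, 1, 2, 3)
_EPS = 1e-6


@dataclass(frozen=True)
class Treatment:
    """A pre-operative transfusion of ``bags`` standard 300cc bags."""

    bags: int

    def __post_init__(self) -> None:
        if self.bags not in BAG_CHOICES:
            raise ValueError(f"bags must be one of {BAG_CHOICES}")

    @property
    def hct_delta(self) -> float:
        """HCT increase in percentage points (3 per bag, capped at 9)."""
        return HCT_POINTS_PER_BAG * self.bags


def assign_baseline_factuals(hct, transfus) -> np.ndarray:
    """Reconstruct assumed factual bag counts from (HCT, TRANSFUS).

    Vectorized; boundary values (HCT exactly 30 or 27 with TRANSFUS = 1)
    receive the fewer-bags arm.
    """
    hct = np.asarray(hct, dtype=float)
    transfus = np.asarray(transfus)
    if np.isnan(hct).any():
        raise ValueError("factual assignment requires observed HCT")
    if not np.isin(transfus, (0, 1)).all():
        raise ValueError("TRANSFUS must be binary 0/1")
    bags = np.where(hct >= 30, 1, np.where(hct >= 27, 2, 3))
    bags = np.where(transfus == 1, bags, 0)
    return bags.astype(int)


def hct_after(hct, treatment: Treatment | int) -> np.ndarray | float:
    """HCT after a transfusion: + 3 points per bag (max +9)."""
    bags = treatment.bags if isinstance(treatment, Treatment) else int(treatment)
    if bags not in BAG_CHOICES:
        raise ValueError(f"bags must be one of {BAG_CHOICES}")
    return hct + HCT_POINTS_PER_BAG * bags


# ---------------------------------------------------------------------------
# counterfactual covariate model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjustedVariable:
    var: str
    link: str           # 'identity' or 'logit'
    intercept: float
    slope: float        # per raw HCT point, on the link scale
    train_corr: float


@dataclass
class CounterfactualModel:
    """Propagates an HCT shift to the variables correlated with HCT.

    Fitted on *unscaled* training rows so slopes keep physical units.
    ``toggle_transfus`` controls whether the counterfactual record also sets
    the TRANSFUS indicator when bags > 0.
    """

    adjusted: list[AdjustedVariable]
    corr_cutoff: float = 0.1
    toggle_transfus: bool = True

    @property
    def adjusted_vars(self) -> list[str]:
        return [a.var for a in self.adjusted]

    def to_json(self) -> str:
        return json.dumps({
            "corr_cutoff": self.corr_cutoff,
            "toggle_transfus": self.toggle_transfus,
            "adjusted": [vars(a) for a in self.adjusted],
        })

    @classmethod
    def from_json(cls, text: str) -> "CounterfactualModel":
        d = json.loads(text)
        return cls([AdjustedVariable(**a) for a in d["adjusted"]],
                   d["corr_cutoff"], d["toggle_transfus"])


def fit_counterfactual_model(
    train: CohortTable,
    corr_cutoff: float = 0.1,
    toggle_transfus: bool = True,
) -> CounterfactualModel:
    """Screen pre-op variables by |corr with HCT| and regress each on HCT.

    Pearson correlations and regressions use unscaled training values,
    pairwise-complete over missingness.  Bounded-probability variables are
    regressed on the logit scale (values clamped away from exactly 0/1,
    with a warning).  HCT itself and the TRANSFUS indicator are excluded —
    TRANSFUS is handled by the counterfactual toggle, not a regression.
    """
    if train.scaled:
        raise ValueError("fit the counterfactual model on unscaled values")
    hct_col = train.roles.hct
    hct = train.data[hct_col].to_numpy(dtype=float)
    bounded = set(train.roles.bounded_probability)
    skip = {hct_col, train.roles.transfus}
    adjusted: list[AdjustedVariable] = []
    for col in train.data.columns:
        if col in skip or train.var_class[col] != PRE_OP:
            continue
        v = train.data[col].to_numpy(dtype=float)
        ok = ~np.isnan(v) & ~np.isnan(hct)
        if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(hct[ok]) == 0:
            continue
        r = float(np.corrcoef(hct[ok], v[ok])[0, 1])
        if abs(r) <= corr_cutoff:
            continue
        target = v[ok]
        link = "identity"
        if col in bounded:
            link = "logit"
            if (target <= 0).any() or (target >= 1).any():
                warnings.warn(
                    f"{col}: values at 0/1 clamped to [{_EPS}, {1 - _EPS}] "
                    "before logit transform")
            target = logit(np.clip(target, _EPS, 1 - _EPS))
        slope, intercept = np.polyfit(hct[ok], target, 1)
        adjusted.append(AdjustedVariable(col, link, float(intercept),
                                         float(slope), r))
        logger.debug("counterfactual %s: link=%s slope=%.4g corr=%.3f",
                     col, link, slope, r)
    return CounterfactualModel(adjusted, corr_cutoff, toggle_transfus)


def apply_counterfactual(
    record: pd.DataFrame,
    bags,
    model: CounterfactualModel,
    hct_col: str,
    transfus_col: str | None = None,
) -> pd.DataFrame:
    """Counterfactual records after transfusing ``bags`` (scalar or per-row).

    ``record`` holds unscaled values.  HCT moves by 3 points per bag; each
    adjusted variable moves by slope * delta on its link scale (identity or
    logit); everything else is untouched.  Patients with 0 bags are
    returned unchanged.
    """
    out = record.copy()
    bags = np.broadcast_to(np.asarray(bags, dtype=float), (len(record),))
    if ((bags < 0) | (bags > MAX_BAGS)).any():
        raise ValueError(f"bags must lie in [0, {MAX_BAGS}]")
    delta = HCT_POINTS_PER_BAG * bags
    out[hct_col] = out[hct_col].to_numpy(dtype=float) + delta
    for adj in model.adjusted:
        if adj.var not in out.columns:
            continue
        v = out[adj.var].to_numpy(dtype=float)
        if adj.link == "identity":
            out[adj.var] = v + adj.slope * delta
        else:
            z = logit(np.clip(v, _EPS, 1 - _EPS)) + adj.slope * delta
            out[adj.var] = expit(z)
    if model.toggle_transfus and transfus_col is not None \
            and transfus_col in out.columns:
        tr = out[transfus_col].to_numpy(dtype=float)
        out[transfus_col] = np.where(bags > 0, 1.0, tr)
    return out
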