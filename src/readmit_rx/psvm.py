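"""Prescriptive SVM: fix a sparse hyperplane, then dose HCT per patient.

Stage 1 trains a sparse linear SVM risk score (see :mod:`.classify`) and a
prevalence-matched threshold.  Stage 2 holds that hyperplane fixed and, for
every transfusion candidate (pre-operative HCT below 30), picks the number
of bags b in {0..3} minimizing

    predicted-readmission loss(score after shifting HCT by 3b) + lam_rx * 3b

i.e. a trade-off between flipping the readmission prediction and the size
of the HCT change, with ``lam_rx`` the penalty per hematocrit point.  The
objective is separable across patients, so the optimum is found exactly by
enumerating the four treatments per patient.  The default loss is the hard
0/1 indicator of a predicted readmission; a hinge-margin relaxation is
available behind ``loss="hinge"``.

By default stage 2 moves only the HCT coordinate of the score (the
correlated-covariate adjustments enter at *evaluation* time through the
counterfactual model); ``include_covariate_shifts=True`` folds them into
the stage-2 score as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import LinearModel, ThresholdRule
from .cohort import ScalingParams
from .transfusion import (
    BAG_CHOICES,
    HCT_POINTS_PER_BAG,
    CounterfactualModel,
    apply_counterfactual,
)

CANDIDATE_HCT_CUTOFF = 30.0


@dataclass
class PsvmPolicy:
    """Per-patient transfusion policy built on a fixed linear risk score."""

    base: LinearModel
    scaler: ScalingParams
    rule: ThresholdRule
    lam_rx: float
    hct_col: str
    loss: str = "indicator"                 # or "hinge"
    include_covariate_shifts: bool = False
    cf_model: CounterfactualModel | None = None
    transfus_col: str | None = None
    candidate_cutoff: float = CANDIDATE_HCT_CUTOFF

    def prescribe(self, records: pd.DataFrame) -> np.ndarray:
        return prescribe_psvm(self, records)

    def to_json(self) -> str:
        return json.dumps({
            "base": json.loads(self.base.to_json()),
            "rule": {"threshold": self.rule.threshold,
                     "target_prevalence": self.rule.target_prevalence},
            "lam_rx": self.lam_rx,
            "hct_col": self.hct_col,
            "loss": self.loss,
            "include_covariate_shifts": self.include_covariate_shifts,
            "candidate_cutoff": self.candidate_cutoff,
            "scaler": {"minimum": self.scaler.minimum.to_dict(),
                       "range": self.scaler.range_.to_dict()},
        })


def train_psvm(
    base: LinearModel,
    scaler: ScalingParams,
    lam_rx: float,
    rule: ThresholdRule,
    hct_col: str,
    loss: str = "indicator",
    include_covariate_shifts: bool = False,
    cf_model: CounterfactualModel | None = None,
    transfus_col: str | None = None,
) -> PsvmPolicy:
    """Build the stage-2 policy around a trained hyperplane.

    Because the stage-2 objective separates across patients and the
    treatment set has four elements, no further optimization is stored:
    prescription is exact per-patient enumeration at call time.
    """
    if hct_col not in base.var_names:
        raise ValueError(f"{hct_col!r} is not among the model variables")
    if loss not in ("indicator", "hinge"):
        raise ValueError("loss must be 'indicator' or 'hinge'")
    if lam_rx < 0:
        raise ValueError("lam_rx must be >= 0")
    if include_covariate_shifts and cf_model is None:
        raise ValueError("include_covariate_shifts requires a fitted cf_model")
    return PsvmPolicy(base=base, scaler=scaler, rule=rule, lam_rx=lam_rx,
                      hct_col=hct_col, loss=loss,
                      include_covariate_shifts=include_covariate_shifts,
                      cf_model=cf_model, transfus_col=transfus_col)


def _scores_per_treatment(policy: PsvmPolicy, records: pd.DataFrame) -> np.ndarray:
    """(n, 4) base scores after each treatment's HCT (and optional covariate) shift."""
    n = len(records)
    out = np.empty((n, len(BAG_CHOICES)))
    if policy.include_covariate_shifts:
        for j, b in enumerate(BAG_CHOICES):
            shifted = apply_counterfactual(
                records, b, policy.cf_model, policy.hct_col,
                policy.transfus_col)
            out[:, j] = policy.base.score(policy.scaler.transform(shifted))
    else:
        s0 = policy.base.score(policy.scaler.transform(records))
        w_h = policy.base.weight_of(policy.hct_col)
        for j, b in enumerate(BAG_CHOICES):
            delta_scaled = policy.scaler.delta_scaled(
                policy.hct_col, HCT_POINTS_PER_BAG * b)
            out[:, j] = s0 + w_h * delta_scaled
    return out


def treatment_costs(policy: PsvmPolicy, records: pd.DataFrame) -> np.ndarray:
    """(n, 4) stage-2 objective values, one column per bag count."""
    scores = _scores_per_treatment(policy, records)
    tau = policy.rule.threshold
    if policy.loss == "indicator":
        loss = (scores > tau).astype(float)
    else:
        loss = np.maximum(0.0, 1.0 + (scores - tau))
    deltas = HCT_POINTS_PER_BAG * np.asarray(BAG_CHOICES, dtype=float)
    return loss + policy.lam_rx * deltas


def prescribe_psvm(policy: PsvmPolicy, records: pd.DataFrame) -> np.ndarray:
    """Exact per-patient enumeration over the four treatments.

    Non-candidates (HCT at or above the cut-off) receive 0 bags.  Ties in
    the objective break toward fewer bags.
    """
    hct = records[policy.hct_col].to_numpy(dtype=float)
    if np.isnan(hct).any():
        raise ValueError("prescription requires observed HCT")
    costs = treatment_costs(policy, records)
    bags = np.argmin(costs, axis=1)  # argmin returns first = fewest bags
    bags[hct >= policy.candidate_cutoff] = 0
    return bags.astype(int)


def tune_lambda_rx(
    base: LinearModel,
    scaler: ScalingParams,
    rule: ThresholdRule,
    train_records: pd.DataFrame,
    hct_col: str,
    grid: np.ndarray | None = None,
    target_avg_bags: float = 1.0,
    **policy_kwargs,
) -> float:
    """Choose lam_rx so average bags among candidates is closest to target.

    The intended operating point is an average dose of about one bag
    among HCT<30 candidates; the grid spans generous orders of magnitude
    by default.
    """
    if grid is None:
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 13)])
    hct = train_records[hct_col].to_numpy(dtype=float)
    cand = hct < CANDIDATE_HCT_CUTOFF
    if not cand.any():
        raise ValueError("no transfusion candidates in the training records")
    best_lam, best_gap = float(grid[0]), np.inf
    for lam in grid:
        pol = train_psvm(base, scaler, float(lam), rule, hct_col,
                         **policy_kwargs)
        avg = float(prescribe_psvm(pol, train_records)[cand].mean())
        gap = abs(avg - target_avg_bags)
        if gap < best_gap - 1e-12:
            best_lam, best_gap = float(lam), gap
    return best_lam
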