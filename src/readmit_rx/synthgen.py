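"""Synthetic surgical-registry cohort generator with known ground truth.

Real surgical-registry extracts are proprietary, so every stage of the
pipeline is exercised on cohorts drawn from a fully specified generative
model that mirrors the published cohort facts where they exist:

* 30-day readmission prevalence ~5.49%, driven by a sparse logistic model;
* pre-operative hematocrit (HCT) normal with mean 39.67 and sd 6, with a
  *protective* (negative) logistic coefficient, so readmitted patients run
  about 2 points lower;
* laboratory covariates correlated with HCT (creatinine-, INR-,
  prothrombin-time- and albumin-like), plus two bounded-probability
  variables (estimated mortality/morbidity) generated through a logit link
  on HCT;
* a TRANSFUS indicator consistent with the baseline factual rules: low-HCT
  patients are transfused with a configurable adherence probability;
* post-operative complication variables that leak outcome information, so
  post-operative models outperform pre-operative ones;
* completely-at-random missingness (an at-random switch exists for stress
  tests) and one almost-entirely-missing lab to exercise the sparse-
  variable filter.

The returned :class:`GroundTruth` exposes the true coefficient vector and
the true counterfactual readmission probability of every patient under
each of the four transfusion arms, which is what parameter-recovery and
policy-efficiency tests check against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import POST_OP, PRE_OP, CohortTable, VariableRoles
from .transfusion import BAG_CHOICES, HCT_POINTS_PER_BAG, assign_baseline_factuals

HCT_MEAN = 39.67
HCT_SD = 6.0
TARGET_PREVALENCE = 0.0549


@dataclass
class SyntheticSpec:
    """All dials of the generative model, with cohort-calibrated defaults."""

    n: int = 10_000
    p_pre: int = 30                  # total pre-operative variables
    q_post: int = 10                 # total post-operative variables
    target_prevalence: float = TARGET_PREVALENCE
    hct_mean: float = HCT_MEAN
    hct_sd: float = HCT_SD
    # sparse logistic outcome model (per-unit log-odds); HCT protective
    beta: dict = field(default_factory=lambda: {
        "HCT": -0.05, "AGE": 0.02, "ASA": 0.45,
        "SUBGROUP": 0.40, "MORBPROB": 4.0,
    })
    # extra per-HCT-point treatment benefit inside the responsive subgroup
    treatment_responsive_subgroup: bool = True
    subgroup_rate: float = 0.30
    subgroup_gamma: float = -0.05
    # per-HCT-point log-odds effect of transfusion OUTSIDE the subgroup
    # (positive = adverse, reflecting transfusion-related risks); 0 keeps the
    # globally protective default where every candidate benefits via HCT
    complement_gamma: float = 0.0
    # logit-scale slopes of the bounded-probability variables on HCT
    mortprob_slope: float = -0.08
    morbprob_slope: float = -0.06
    # identity-link lab slopes on HCT (per HCT point)
    lab_slopes: dict = field(default_factory=lambda: {
        "CREAT": -0.02, "INR": -0.004, "PT": -0.10, "ALBUMIN": 0.04,
    })
    transfusion_adherence: float = 0.85   # P(TRANSFUS=1 | HCT < 30)
    transfusion_background: float = 0.05  # P(TRANSFUS=1 | HCT >= 30)
    missing_rate: float = 0.05
    missing_mechanism: str = "mcar"       # or "mar" (age-dependent)
    sparse_var_missing_frac: float = 0.90
    died_no_readmit_rate: float = 0.01

    def validate(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target prevalence must lie in (0, 1)")
        if self.p_pre < 12:
            raise ValueError("p_pre must be >= 12 (named variables)")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar'")


@dataclass
class GroundTruth:
    """Generator-side truth: coefficients and per-arm outcome probabilities."""

    beta: dict
    intercept: float
    subgroup_gamma: float
    subgroup: np.ndarray            # bool, treatment-responsive membership
    factual_bags: np.ndarray
    hct: np.ndarray
    prob_by_arm: np.ndarray         # (n, 4): P(y=1 | do(b)) for b = 0..3

    def take_rows(self, idx: np.ndarray) -> "GroundTruth":
        """Align the ground truth with a row-subset of the cohort."""
        return GroundTruth(beta=self.beta, intercept=self.intercept,
                           subgroup_gamma=self.subgroup_gamma,
                           subgroup=self.subgroup[idx],
                           factual_bags=self.factual_bags[idx],
                           hct=self.hct[idx],
                           prob_by_arm=self.prob_by_arm[idx])

    def to_json(self) -> str:
        return json.dumps({
            "beta": self.beta, "intercept": self.intercept,
            "subgroup_gamma": self.subgroup_gamma,
            "subgroup": self.subgroup.astype(int).tolist(),
            "factual_bags": self.factual_bags.tolist(),
            "hct": self.hct.tolist(),
            "prob_by_arm": self.prob_by_arm.tolist(),
        })


def _linear_predictor(spec: SyntheticSpec, df: pd.DataFrame,
                      subgroup: np.ndarray, extra_hct_points: np.ndarray
                      ) -> np.ndarray:
    """Log-odds (without intercept) under an extra HCT shift of given points.

    The shift propagates causally: HCT itself moves, and the morbidity
    probability (generated from HCT) moves on its logit scale.
    """
    hct = df["HCT"].to_numpy() + extra_hct_points
    morb = expit(logit(np.clip(df["MORBPROB"].to_numpy(), 1e-9, 1 - 1e-9))
                 + spec.morbprob_slope * extra_hct_points)
    eta = (spec.beta["HCT"] * hct
           + spec.beta["AGE"] * df["AGE"].to_numpy()
           + spec.beta["ASA"] * df["ASA"].to_numpy()
           + spec.beta["SUBGROUP"] * subgroup
           + spec.beta["MORBPROB"] * morb)
    if spec.treatment_responsive_subgroup:
        eta = eta + spec.subgroup_gamma * subgroup * extra_hct_points
    if spec.complement_gamma:
        eta = eta + spec.complement_gamma * (1 - subgroup) * extra_hct_points
    return eta


def generate_cohort(spec: SyntheticSpec, seed: int = 0
                    ) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort; deterministic (byte-identical CSV) given the seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n

    # -- pre-operative covariates ------------------------------------
    hct = rng.normal(spec.hct_mean, spec.hct_sd, n)
    hct = np.clip(hct, 12.0, 58.0)
    age = np.clip(rng.normal(56.4, 16.0, n), 18, 95).round(0)
    asa = np.clip(rng.normal(2.43 + 0.0 * hct, 0.7, n), 1, 5).round(0)
    subgroup = (rng.random(n) < spec.subgroup_rate).astype(float)

    cols: dict[str, np.ndarray] = {"HCT": hct, "AGE": age, "ASA": asa,
                                   "SUBGROUP": subgroup}
    centered = hct - spec.hct_mean
    lab_base = {"CREAT": 0.99, "INR": 1.07, "PT": 13.5, "ALBUMIN": 3.95}
    lab_noise = {"CREAT": 0.25, "INR": 0.08, "PT": 1.2, "ALBUMIN": 0.35}
    for name, slope in spec.lab_slopes.items():
        cols[name] = (lab_base[name] + slope * centered
                      + rng.normal(0, lab_noise[name], n))
    cols["MORTPROB"] = expit(-4.6 + spec.mortprob_slope * centered
                             + rng.normal(0, 0.5, n))
    cols["MORBPROB"] = expit(-2.6 + spec.morbprob_slope * centered
                             + rng.normal(0, 0.5, n))

    named_pre = list(cols) + ["TRANSFUS", "PRE_SPARSE_LAB"]
    n_noise = spec.p_pre - len(named_pre)
    for j in range(n_noise):
        if j % 2 == 0:
            cols[f"PRE_NOISE_{j + 1:02d}"] = rng.normal(0, 1, n)
        else:
            cols[f"PRE_NOISE_{j + 1:02d}"] = (rng.random(n) < 0.2).astype(float)

    # -- transfusion indicator and factual bags ----------------------
    low = hct < 30
    p_tr = np.where(low, spec.transfusion_adherence,
                    spec.transfusion_background)
    transfus = (rng.random(n) < p_tr).astype(float)
    cols["TRANSFUS"] = transfus
    bags = assign_baseline_factuals(hct, transfus)

    df_pre = pd.DataFrame(cols)

    # -- outcome: sparse logistic with treatment effect already applied
    eta_factual = _linear_predictor(spec, df_pre, subgroup,
                                    HCT_POINTS_PER_BAG * bags)

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta_factual))) - spec.target_prevalence

    b0 = brentq(gap, -40.0, 20.0, xtol=1e-10)
    y = (rng.random(n) < expit(b0 + eta_factual)).astype(int)

    prob_by_arm = np.column_stack([
        expit(b0 + _linear_predictor(
            spec, df_pre, subgroup,
            np.full(n, HCT_POINTS_PER_BAG * b))) for b in BAG_CHOICES])

    # -- post-operative variables (outcome-informative) ---------------
    post: dict[str, np.ndarray] = {}
    post["OPTIME"] = np.clip(rng.normal(111 + 38 * y, 35, n), 10, None)
    post["DAYS_TO_DISCHARGE"] = np.clip(rng.normal(2.8 + 1.7 * y, 1.5, n),
                                        0, None)
    n_compl = spec.q_post - 2
    for j in range(n_compl):
        rate = 0.02 + (0.18 if j < 4 else 0.05) * y
        post[f"POST_COMPL_{j + 1:02d}"] = (rng.random(n) < rate).astype(float)
    df_post = pd.DataFrame(post)

    df = pd.concat([df_pre, df_post], axis=1)

    # -- missingness ---------------------------------------------------
    protected = {"HCT", "TRANSFUS"}
    if spec.missing_rate > 0:
        if spec.missing_mechanism == "mcar":
            row_p = np.full(n, spec.missing_rate)
        else:  # age-dependent missingness
            q = (age - age.min()) / max(age.max() - age.min(), 1e-9)
            row_p = spec.missing_rate * (0.5 + 1.0 * q)
        for col in df.columns:
            if col in protected:
                continue
            mask = rng.random(n) < row_p
            if mask.all():  # keep at least one observation per variable
                mask[int(rng.integers(n))] = False
            df.loc[mask, col] = np.nan
    # the nearly-all-missing lab exercising the sparse-variable filter
    sparse_lab = rng.normal(70, 20, n)
    miss = rng.random(n) < spec.sparse_var_missing_frac
    sparse_lab[miss] = np.nan
    df["PRE_SPARSE_LAB"] = sparse_lab

    died = ((rng.random(n) < spec.died_no_readmit_rate) & (y == 0)).astype(int)

    var_class = {c: PRE_OP for c in df_pre.columns}
    var_class["PRE_SPARSE_LAB"] = PRE_OP
    var_class.update({c: POST_OP for c in df_post.columns})
    roles = VariableRoles(hct="HCT", transfus="TRANSFUS",
                          bounded_probability=("MORTPROB", "MORBPROB"))
    # column order: deterministic
    order = [c for c in df.columns]
    table = CohortTable(data=df[order], outcome=y, var_class=var_class,
                        roles=roles, died_no_readmit=died)
    gt = GroundTruth(beta=dict(spec.beta), intercept=float(b0),
                     subgroup_gamma=float(spec.subgroup_gamma
                                          if spec.treatment_responsive_subgroup
                                          else 0.0),
                     subgroup=subgroup.astype(bool), factual_bags=bags,
                     hct=hct, prob_by_arm=prob_by_arm)
    return table, gt


def true_effect(gt: GroundTruth, policy_bags: np.ndarray,
                candidate_cutoff: float = 30.0) -> float:
    """Mean true reduction in readmission probability among candidates.

    Averages P(y=1 | do(0 bags)) - P(y=1 | do(policy bags)) over patients
    with HCT below the candidate cut-off, using the generator's own model.
    """
    bags = np.asarray(policy_bags, dtype=int)
    cand = gt.hct < candidate_cutoff
    if not cand.any():
        return 0.0
    idx = np.flatnonzero(cand)
    reduction = gt.prob_by_arm[idx, 0] - gt.prob_by_arm[idx, bags[idx]]
    return float(reduction.mean())


def linear_rule_dataset(n: int = 2000, n_signal: int = 3, n_noise: int = 20,
                        flip: float = 0.05, seed: int = 0
                        ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Planted sparse linear rule for support-recovery tests.

    Features are uniform on [0, 1] (already on the model scale); the label
    is the sign of a 3-variable linear rule with a small label-flip rate.
    Returns (X, y, names of the true-support variables).
    """
    rng = np.random.default_rng(seed)
    p = n_signal + n_noise
    X = rng.random((n, p))
    names = [f"V{j + 1:02d}" for j in range(p)]
    w = np.zeros(p)
    w[:n_signal] = [2.0, -2.0, 1.5][:n_signal]
    z = (X - 0.5) @ w
    y = (z > 0).astype(int)
    flips = rng.random(n) < flip
    y[flips] = 1 - y[flips]
    return pd.DataFrame(X, columns=names), y, names[:n_signal]
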