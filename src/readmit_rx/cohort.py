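"""Cohort construction, cleaning, imputation, scaling and group comparison.

The central container is :class:`CohortTable`: one row per surgery, one
column per variable, with ``NaN`` marking missing entries.  Variables are
partitioned into *pre-operative* (known before the incision) and
*post-operative* classes; a small set of special roles identifies the
actionable hematocrit variable (HCT, in percentage points), the
pre-operative transfusion indicator (TRANSFUS) and any bounded-probability
variables such as estimated mortality/morbidity probabilities.

Cleaning follows the usual registry-data recipe: drop patients who died
within 30 days without a readmission, drop variables that are almost
entirely missing, impute the remainder with a cluster-restricted k-nearest
neighbour scheme, and min-max scale to [0, 1] using training-set statistics
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

PRE_OP = "pre_op"
POST_OP = "post_op"


@dataclass(frozen=True)
class VariableRoles:
    """Names of the columns with a special meaning in the pipeline."""

    hct: str
    transfus: str
    bounded_probability: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "bounded_probability", tuple(self.bounded_probability))


@dataclass
class CohortTable:
    """Patient x variable table with outcome, missingness and variable classes.

    Parameters
    ----------
    data:
        DataFrame of shape (n_patients, n_variables); ``NaN`` encodes a
        missing entry and is never used in computation.
    outcome:
        Binary vector, 1 = readmitted within 30 days of discharge.
    var_class:
        Maps every column of ``data`` to ``"pre_op"`` or ``"post_op"``.
    roles:
        Which columns play the HCT / TRANSFUS / bounded-probability roles.
    died_no_readmit:
        Binary vector marking patients who died within 30 days without a
        readmission; consumed only by :func:`filter_cohort`.
    """

    data: pd.DataFrame
    outcome: np.ndarray
    var_class: dict[str, str]
    roles: VariableRoles
    died_no_readmit: np.ndarray | None = None
    scaled: bool = False  # True once min-max scaled; relaxes raw-unit checks

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome)
        if self.died_no_readmit is not None:
            self.died_no_readmit = np.asarray(self.died_no_readmit)
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def var_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()

    def validate(self) -> None:
        if len(self.outcome) != len(self.data):
            raise ValueError("outcome length does not match number of rows")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcome must be binary 0/1")
        missing_class = [c for c in self.data.columns if c not in self.var_class]
        if missing_class:
            raise ValueError(f"variables without a pre/post class: {missing_class}")
        bad = {c: v for c, v in self.var_class.items()
               if c in self.data.columns and v not in (PRE_OP, POST_OP)}
        if bad:
            raise ValueError(f"invalid variable classes: {bad}")
        for col in (self.roles.hct, self.roles.transfus):
            if col not in self.data.columns:
                raise ValueError(f"role column {col!r} not in table")
        if not self.scaled:
            hct = self.data[self.roles.hct]
            if ((hct <= 0) | (hct >= 100)).any():
                raise ValueError("observed HCT values must lie in (0, 100)")
            tr = self.data[self.roles.transfus].dropna()
            if not tr.isin((0, 1)).all():
                raise ValueError("TRANSFUS must be binary 0/1")

    def take_rows(self, idx: np.ndarray) -> "CohortTable":
        """Row-subset (positional indices); row order follows ``idx``."""
        return replace(
            self,
            data=self.data.iloc[idx].reset_index(drop=True),
            outcome=self.outcome[idx],
            died_no_readmit=None if self.died_no_readmit is None
            else self.died_no_readmit[idx],
        )

    def select_vars(self, names: list[str]) -> "CohortTable":
        return replace(
            self,
            data=self.data[names].copy(),
            var_class={c: self.var_class[c] for c in names},
        )

    @property
    def hct(self) -> np.ndarray:
        return self.data[self.roles.hct].to_numpy(dtype=float)

    @property
    def transfus(self) -> np.ndarray:
        return self.data[self.roles.transfus].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------

def filter_cohort(raw: CohortTable) -> CohortTable:
    """Drop patients who died within 30 days of surgery without readmission.

    Keeps every row except those with ``died_no_readmit == 1`` and
    ``outcome == 0``; row order is preserved.
    """
    if raw.died_no_readmit is None:
        raise ValueError("filter_cohort requires the died_no_readmit column")
    drop = (raw.died_no_readmit == 1) & (raw.outcome == 0)
    keep = np.flatnonzero(~drop)
    out = raw.take_rows(keep)
    out.died_no_readmit = np.zeros(len(keep), dtype=int)
    return out


def drop_sparse_variables(t: CohortTable, max_missing_frac: float = 0.80) -> CohortTable:
    """Remove variables whose missing fraction strictly exceeds the cut-off.

    The boundary is strict: a variable missing exactly 80% of its entries is
    retained at the default cut-off.
    """
    if not 0 < max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in (0, 1]")
    frac = t.data.isna().mean()
    protected = {t.roles.hct, t.roles.transfus}
    dropped = [c for c in t.data.columns
               if frac[c] > max_missing_frac and c not in protected]
    if dropped:
        logger.info("dropping %d sparse variables: %s", len(dropped), dropped)
    keep = [c for c in t.data.columns if c not in dropped]
    return t.select_vars(keep)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(
    t: CohortTable,
    k: int = 5,
    n_clusters: int = 10,
    seed: int = 0,
) -> CohortTable:
    """Fill missing entries by cluster-restricted k-nearest-neighbour means.

    Patients are first clustered (k-means, seeded) on the fully observed
    variables, min-max scaled so no single variable dominates the distance.
    A missing entry is then imputed as the mean of the variable over the k
    nearest donors *within the same cluster* that observe it; equidistant
    donors at the cut-off are all averaged.  If a cluster has no donor for a
    variable the search falls back to the whole cohort.

    Observed entries are never altered, and every imputed value lies within
    the observed min/max of its variable.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = t.missing_mask
    if not mask.any():
        return t
    all_missing = np.flatnonzero(mask.all(axis=1))
    if all_missing.size:
        raise ValueError(f"rows with every entry missing: {all_missing.tolist()}")
    full_vars = [c for c, m in zip(t.data.columns, mask.any(axis=0)) if not m]
    if not full_vars:
        raise ValueError("imputation needs at least one fully observed variable")

    feats = t.data[full_vars].to_numpy(dtype=float)
    lo, span = feats.min(axis=0), np.ptp(feats, axis=0)
    span[span == 0] = 1.0
    z = (feats - lo) / span

    n_clusters = max(1, min(n_clusters, len(z)))
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(z)

    data = t.data.copy()
    for j, col in enumerate(t.data.columns):
        miss_rows = np.flatnonzero(mask[:, j])
        if miss_rows.size == 0:
            continue
        observed = ~mask[:, j]
        col_vals = t.data[col].to_numpy(dtype=float)
        for i in miss_rows:
            donors = np.flatnonzero(observed & (labels == labels[i]))
            if donors.size == 0:
                donors = np.flatnonzero(observed)
            d = np.linalg.norm(z[donors] - z[i], axis=1)
            if donors.size > k:
                cut = np.sort(d)[k - 1]
                donors = donors[d <= cut + 1e-12]
            data.iloc[i, j] = float(col_vals[donors].mean())
    return replace(t, data=data)


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingParams:
    """Per-variable training minimum and range for [0, 1] min-max scaling.

    Variables with zero range map to the constant 0.  Values outside the
    training min/max (e.g. on a test split) are *not* clipped, which keeps
    the transform affine and order-preserving.
    """

    minimum: pd.Series
    range_: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df[self.minimum.index].astype(float).copy()
        safe = self.range_.replace(0.0, 1.0)
        out = (out - self.minimum) / safe
        zero = self.range_.index[self.range_ == 0]
        out[zero] = 0.0
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df[self.minimum.index].astype(float) * self.range_ + self.minimum
        return out

    def delta_scaled(self, var: str, delta_raw: float) -> float:
        """Convert a raw-unit shift of ``var`` into scaled units."""
        r = float(self.range_[var])
        return 0.0 if r == 0 else delta_raw / r


def fit_scaler(t: CohortTable | pd.DataFrame) -> ScalingParams:
    """Fit min-max parameters; call on training rows only."""
    df = t.data if isinstance(t, CohortTable) else t
    mn = df.min(axis=0, skipna=True)
    rng = df.max(axis=0, skipna=True) - mn
    return ScalingParams(minimum=mn.astype(float), range_=rng.astype(float))


def apply_scaler(t: CohortTable, s: ScalingParams) -> CohortTable:
    return replace(t, data=s.transform(t.data), scaled=True)


# ---------------------------------------------------------------------------
# variable partition
# ---------------------------------------------------------------------------

def partition_variables(t: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Split into (pre-operative only, pre+post) views; outcome kept in both."""
    pre_vars = [c for c in t.data.columns if t.var_class[c] == PRE_OP]
    if not pre_vars:
        raise ValueError("no pre-operative variables: prescriptive pipeline undefined")
    return t.select_vars(pre_vars), t.select_vars(t.var_names)


# ---------------------------------------------------------------------------
# Welch comparison
# ---------------------------------------------------------------------------

def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sample Welch t-test: statistic, Welch-Satterthwaite df, two-tailed p.

    No equal-variance assumption.  Degenerate zero-variance-in-both samples
    with equal means return (0, n_x + n_y - 2, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohort_comparison(t: CohortTable) -> pd.DataFrame:
    """Readmitted-vs-non-readmitted comparison, sorted by ascending p-value.

    Means are reported on *unnormalized* values; for indicator variables the
    mean is the fraction of patients satisfying the condition.  Missing
    entries are excluded variable-wise.  Raw (uncorrected) two-tailed Welch
    p-values are reported.
    """
    y = t.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("cohort comparison requires both outcome classes")
    rows = []
    for col in t.data.columns:
        v = t.data[col]
        obs = v.notna().to_numpy()
        xr = v.to_numpy(dtype=float)[obs & (y == 1)]
        xn = v.to_numpy(dtype=float)[obs & (y == 0)]
        if len(xr) < 2 or len(xn) < 2:
            continue
        try:
            t_stat, df, p = welch_t(xr, xn)
        except ValueError:
            continue
        rows.append({
            "var_name": col,
            "mean_all": float(v.mean()),
            "mean_readmitted": float(xr.mean()),
            "mean_non_readmitted": float(xn.mean()),
            "t_stat": t_stat,
            "welch_df": df,
            "p_two_tailed": p,
        })
    out = pd.DataFrame(rows)
    return out.sort_values("p_two_tailed", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV / schema round-trip
# ---------------------------------------------------------------------------

def load_cohort(csv_path, schema_path) -> CohortTable:
    """Read a cohort CSV plus a YAML schema describing column roles.

    The schema declares the outcome column, the optional died-without-
    readmission column, a ``variables`` map (column -> pre_op/post_op) and a
    ``roles`` block naming HCT, TRANSFUS and bounded-probability columns.
    Missing cells may be empty strings or any pandas-recognized NA token.
    """
    with open(schema_path) as fh:
        schema = yaml.safe_load(fh)
    df = pd.read_csv(csv_path)
    outcome_col = schema["outcome"]
    outcome = df.pop(outcome_col).to_numpy(dtype=int)
    died = None
    died_col = schema.get("died_no_readmit")
    if died_col is not None and died_col in df.columns:
        died = df.pop(died_col).to_numpy(dtype=int)
    var_class = dict(schema["variables"])
    roles = VariableRoles(
        hct=schema["roles"]["hct"],
        transfus=schema["roles"]["transfus"],
        bounded_probability=tuple(schema["roles"].get("bounded_probability", ())),
    )
    data = df[[c for c in df.columns if c in var_class]].astype(float)
    return CohortTable(data=data, outcome=outcome, var_class=var_class,
                       roles=roles, died_no_readmit=died)


def save_cohort(t: CohortTable, csv_path, schema_path,
                outcome_col: str = "READMIT30",
                died_col: str = "DIED_NO_READMIT") -> None:
    df = t.data.copy()
    df[outcome_col] = t.outcome
    if t.died_no_readmit is not None:
        df[died_col] = t.died_no_readmit
    df.to_csv(csv_path, index=False)
    schema = {
        "outcome": outcome_col,
        "died_no_readmit": died_col if t.died_no_readmit is not None else None,
        "variables": dict(t.var_class),
        "roles": {
            "hct": t.roles.hct,
            "transfus": t.roles.transfus,
            "bounded_probability": list(t.roles.bounded_probability),
        },
    }
    with open(schema_path, "w") as fh:
        yaml.safe_dump(schema, fh, sort_keys=False)
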