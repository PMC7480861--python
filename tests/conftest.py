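"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

import readmit_rx as rx
from readmit_rx.pipeline import PreprocessConfig, preprocess_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Raw synthetic cohort (n=2500) with ground truth, deaths disabled."""
    spec = rx.SyntheticSpec(n=2500, died_no_readmit_rate=0.0)
    table, gt = rx.generate_cohort(spec, seed=11)
    return table, gt


@pytest.fixture(scope="session")
def clean_cohort(small_cohort):
    """Preprocessed (sparse-dropped, imputed) version of the small cohort."""
    table, gt = small_cohort
    clean = preprocess_cohort(table, PreprocessConfig(), seed=0)
    return clean, gt


@pytest.fixture(scope="session")
def clean_pre(clean_cohort):
    """Pre-operative view with fitted scaler and scaled design matrix."""
    clean, gt = clean_cohort
    pre, _ = rx.partition_variables(clean)
    scaler = rx.fit_scaler(pre)
    X = scaler.transform(pre.data)
    return pre, scaler, X, gt


def toy_table(data: pd.DataFrame, outcome, var_class=None, died=None,
              hct="HCT", transfus="TRANSFUS", bounded=()):
    """Hand-rolled CohortTable for unit fixtures."""
    if var_class is None:
        var_class = {c: "pre_op" for c in data.columns}
    roles = rx.VariableRoles(hct=hct, transfus=transfus,
                             bounded_probability=bounded)
    return rx.CohortTable(data=data, outcome=np.asarray(outcome),
                          var_class=var_class, roles=roles,
                          died_no_readmit=None if died is None
                          else np.asarray(died))
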