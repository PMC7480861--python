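"""Cohort construction, cleaning, imputation, scaling and comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import readmit_rx as rx
from conftest import toy_table


def _frame(hct, transfus, extra=None):
    d = {"HCT": hct, "TRANSFUS": transfus}
    if extra:
        d.update(extra)
    return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterCohort:
    def test_no_deaths_is_identity(self):
        t = toy_table(_frame([35.0] * 5, [0] * 5), [0, 1, 0, 1, 0],
                      died=[0] * 5)
        out = rx.filter_cohort(t)
        assert out.n == 5

    def test_drops_only_died_without_readmission(self):
        t = toy_table(_frame([35.0] * 3, [0] * 3), [0, 1, 0],
                      died=[1, 1, 0])
        out = rx.filter_cohort(t)
        # (died=1, y=0) dropped; (died=1, y=1) and (died=0, y=0) retained
        assert out.n == 2
        assert out.outcome.tolist() == [1, 0]

    def test_empty_table(self):
        t = toy_table(_frame([], []), [], died=[])
        assert rx.filter_cohort(t).n == 0

    def test_requires_died_column(self):
        t = toy_table(_frame([35.0], [0]), [0])
        with pytest.raises(ValueError, match="died_no_readmit"):
            rx.filter_cohort(t)

    def test_idempotent(self):
        t = toy_table(_frame([35.0] * 4, [0] * 4), [0, 1, 1, 0],
                      died=[1, 0, 1, 0])
        once = rx.filter_cohort(t)
        twice = rx.filter_cohort(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


# ---------------------------------------------------------------------------
# sparse-variable filter
# ---------------------------------------------------------------------------

class TestDropSparse:
    def _table(self, n_missing):
        n = 100
        lab = np.arange(n, dtype=float)
        lab[:n_missing] = np.nan
        data = _frame([35.0] * n, [0] * n, {"LAB": lab})
        return toy_table(data, [0, 1] * 50)

    def test_above_cutoff_dropped(self):
        out = rx.drop_sparse_variables(self._table(81))
        assert "LAB" not in out.var_names

    def test_boundary_retained(self):
        # exactly 80% missing is retained: the cut-off is strict
        out = rx.drop_sparse_variables(self._table(80))
        assert "LAB" in out.var_names

    def test_no_missingness_all_retained(self):
        out = rx.drop_sparse_variables(self._table(0))
        assert out.var_names == ["HCT", "TRANSFUS", "LAB"]

    def test_idempotent(self):
        once = rx.drop_sparse_variables(self._table(90))
        twice = rx.drop_sparse_variables(once)
        assert once.var_names == twice.var_names


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class TestImputeMissing:
    def test_complete_table_unchanged(self):
        t = toy_table(_frame([30.0, 40.0], [0, 1]), [0, 1])
        out = rx.impute_missing(t, seed=0)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_identical_neighbors_force_value(self):
        lab = np.array([7.0, 7.0, 7.0, 7.0, 7.0, np.nan])
        t = toy_table(_frame([35.0] * 6, [0] * 6, {"LAB": lab}),
                      [0, 1, 0, 1, 0, 1])
        out = rx.impute_missing(t, k=5, n_clusters=1, seed=0)
        assert out.data["LAB"].iloc[-1] == pytest.approx(7.0)

    def test_observed_cells_never_altered_and_within_range(self):
        rng = np.random.default_rng(4)
        n = 120
        lab = rng.normal(50, 5, n)
        miss = rng.random(n) < 0.2
        lab_na = lab.copy()
        lab_na[miss] = np.nan
        t = toy_table(_frame(rng.uniform(30, 50, n), [0] * n,
                             {"LAB": lab_na, "X": rng.normal(0, 1, n)}),
                      rng.integers(0, 2, n))
        out = rx.impute_missing(t, seed=0)
        assert not out.data.isna().any().any()
        np.testing.assert_allclose(out.data["LAB"][~miss], lab[~miss])
        assert out.data["LAB"].min() >= np.nanmin(lab_na)
        assert out.data["LAB"].max() <= np.nanmax(lab_na)

    def test_cluster_structure_beats_global_mean(self):
        # two clusters with distinct LAB levels, identified by observed vars
        rng = np.random.default_rng(7)
        n = 200
        grp = rng.integers(0, 2, n)
        x1 = grp * 5.0 + rng.normal(0, 0.3, n)
        x2 = grp * 5.0 + rng.normal(0, 0.3, n)
        lab_true = np.where(grp == 1, 20.0, 10.0) + rng.normal(0, 0.5, n)
        miss = rng.random(n) < 0.25
        lab = lab_true.copy()
        lab[miss] = np.nan
        t = toy_table(_frame(rng.uniform(30, 50, n), [0] * n,
                             {"X1": x1, "X2": x2, "LAB": lab}),
                      rng.integers(0, 2, n))
        out = rx.impute_missing(t, k=5, n_clusters=4, seed=0)
        err_knn = np.abs(out.data["LAB"][miss] - lab_true[miss]).mean()
        err_mean = np.abs(np.nanmean(lab) - lab_true[miss]).mean()
        assert err_knn < err_mean

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        n = 80
        lab = rng.normal(0, 1, n)
        lab[rng.random(n) < 0.3] = np.nan
        t = toy_table(_frame(rng.uniform(30, 50, n), [0] * n, {"LAB": lab}),
                      rng.integers(0, 2, n))
        a = rx.impute_missing(t, seed=3).data
        b = rx.impute_missing(t, seed=3).data
        pd.testing.assert_frame_equal(a, b)

    def test_all_missing_row_errors(self):
        data = pd.DataFrame({"A": [1.0, np.nan], "B": [2.0, np.nan]})
        t = rx.CohortTable(data=data, outcome=np.array([0, 1]),
                           var_class={"A": "pre_op", "B": "pre_op"},
                           roles=rx.VariableRoles(hct="A", transfus="B"),
                           scaled=True)
        with pytest.raises(ValueError, match="every entry missing"):
            rx.impute_missing(t, seed=0)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

class TestScaling:
    def test_basic_min_max(self):
        t = toy_table(_frame([35.0] * 3, [0] * 3, {"V": [10.0, 20.0, 30.0]}),
                      [0, 1, 0])
        s = rx.fit_scaler(t)
        out = rx.apply_scaler(t, s)
        assert out.data["V"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_variable_maps_to_zero(self):
        t = toy_table(_frame([35.0] * 3, [0] * 3, {"V": [7.0, 7.0, 7.0]}),
                      [0, 1, 0])
        out = rx.apply_scaler(t, rx.fit_scaler(t))
        assert out.data["V"].tolist() == [0.0, 0.0, 0.0]

    def test_test_values_not_clipped(self):
        train = toy_table(_frame([35.0] * 2, [0] * 2, {"V": [10.0, 30.0]}),
                          [0, 1])
        s = rx.fit_scaler(train)
        out = s.transform(pd.DataFrame({"HCT": [35.0], "TRANSFUS": [0.0],
                                        "V": [40.0]}))
        assert out["V"].iloc[0] == pytest.approx(1.5)

    def test_round_trip_recovers_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            df = pd.DataFrame(rng.normal(0, 10, (15, 4)),
                              columns=list("ABCD"))
            s = rx.fit_scaler(df)
            back = s.inverse(s.transform(df))
            np.testing.assert_allclose(back.to_numpy(), df.to_numpy(),
                                       rtol=1e-9, atol=1e-9)

    def test_delta_scaled(self):
        df = pd.DataFrame({"HCT": [20.0, 60.0]})
        s = rx.fit_scaler(df)
        assert s.delta_scaled("HCT", 3.0) == pytest.approx(3.0 / 40.0)


# ---------------------------------------------------------------------------
# variable partition
# ---------------------------------------------------------------------------

class TestPartition:
    def test_pre_and_all(self):
        data = _frame([35.0] * 2, [0] * 2,
                      {"A": [1.0, 2.0], "P1": [0.0, 1.0], "P2": [3.0, 4.0]})
        vc = {"HCT": "pre_op", "TRANSFUS": "pre_op", "A": "pre_op",
              "P1": "post_op", "P2": "post_op"}
        t = toy_table(data, [0, 1], var_class=vc)
        pre, full = rx.partition_variables(t)
        assert pre.var_names == ["HCT", "TRANSFUS", "A"]
        assert len(full.var_names) == 5
        assert pre.outcome.tolist() == full.outcome.tolist() == [0, 1]

    def test_all_pre_gives_identical_partitions(self):
        t = toy_table(_frame([35.0] * 2, [0] * 2), [0, 1])
        pre, full = rx.partition_variables(t)
        assert pre.var_names == full.var_names

    def test_no_pre_op_vars_errors(self):
        t = toy_table(_frame([35.0] * 2, [0] * 2),
                      [0, 1], var_class={"HCT": "post_op",
                                         "TRANSFUS": "post_op"})
        with pytest.raises(ValueError, match="pre-operative"):
            rx.partition_variables(t)

    def test_idempotent(self):
        t = toy_table(_frame([35.0] * 2, [0] * 2, {"P": [1.0, 2.0]}),
                      [0, 1], var_class={"HCT": "pre_op",
                                         "TRANSFUS": "pre_op",
                                         "P": "post_op"})
        pre1, _ = rx.partition_variables(t)
        pre2, _ = rx.partition_variables(pre1)
        assert pre1.var_names == pre2.var_names


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def welch_oracle(x, y):
    """Textbook Welch formula: statistic, Welch-Satterthwaite df, p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (nx - 1) + vy ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_closed_form_example(self):
        t, df, p = rx.welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_identical_samples(self):
        t, df, p = rx.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_swap_negates_t_keeps_p(self):
        t1, _, p1 = rx.welch_t([1, 5, 2], [4, 4, 9])
        t2, _, p2 = rx.welch_t([4, 4, 9], [1, 5, 2])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_textbook_oracle_on_random_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           rng.integers(3, 20))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           rng.integers(3, 20))
            got = rx.welch_t(x, y)
            want = welch_oracle(x, y)
            np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            rx.welch_t([1.0], [1, 2, 3])


# ---------------------------------------------------------------------------
# comparison table
# ---------------------------------------------------------------------------

class TestCohortComparison:
    def _table(self):
        rng = np.random.default_rng(5)
        n = 300
        y = np.array([1] * 60 + [0] * 240)
        strong = np.where(y == 1, 5.0, 0.0) + rng.normal(0, 0.5, n)
        flat = rng.normal(0, 1, n)
        binary = (rng.random(n) < 0.3).astype(float)
        return toy_table(_frame(rng.uniform(30, 50, n), [0] * n,
                                {"STRONG": strong, "FLAT": flat,
                                 "BIN": binary}), y), y, binary

    def test_injected_difference_ranks_first(self):
        t, _, _ = self._table()
        comp = rx.cohort_comparison(t)
        assert comp["var_name"].iloc[0] == "STRONG"

    def test_binary_mean_is_class_fraction(self):
        t, y, binary = self._table()
        comp = rx.cohort_comparison(t).set_index("var_name")
        assert comp.loc["BIN", "mean_readmitted"] == pytest.approx(
            binary[y == 1].mean())
        assert comp.loc["BIN", "mean_all"] == pytest.approx(binary.mean())

    def test_sorted_ascending_by_p(self):
        t, _, _ = self._table()
        p = rx.cohort_comparison(t)["p_two_tailed"]
        assert (p.diff().dropna() >= 0).all()

    def test_single_class_outcome_errors(self):
        t = toy_table(_frame([35.0] * 4, [0] * 4), [0, 0, 0, 0])
        with pytest.raises(ValueError, match="both outcome classes"):
            rx.cohort_comparison(t)

    def test_identical_across_classes_sorted_last(self):
        data = _frame([35.0] * 6, [0] * 6, {"CONST": [2.0] * 6})
        t = toy_table(data, [1, 1, 0, 0, 0, 0])
        comp = rx.cohort_comparison(t)
        assert comp["var_name"].iloc[-1] == "CONST"
        assert comp["p_two_tailed"].iloc[-1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# CSV/schema round-trip
# ---------------------------------------------------------------------------

def test_save_load_round_trip(tmp_path, small_cohort):
    table, _ = small_cohort
    csv, schema = tmp_path / "c.csv", tmp_path / "s.yaml"
    rx.save_cohort(table, csv, schema)
    back = rx.load_cohort(csv, schema)
    assert back.n == table.n
    assert back.var_names == table.var_names
    assert back.var_class == table.var_class
    assert back.roles == table.roles
    np.testing.assert_array_equal(back.outcome, table.outcome)
    np.testing.assert_allclose(back.data.to_numpy(), table.data.to_numpy(),
                               rtol=1e-12, equal_nan=True)
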