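"""Metrics, cohort comparison, stratified errors, BMI OLS, panel overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methage.errors import ValidationError
from methage.clock_eval import (
    PredictionSet,
    bmi_effect,
    clock_overlap,
    compare_cohorts,
    compute_metrics,
    mann_whitney,
    stratified_errors,
)


def make_preds(true, pred, **cols):
    n = len(true)
    frame = pd.DataFrame(
        {"sample_id": [f"S{i}" for i in range(n)], "true_age": true, "predicted_age": pred}
    )
    for k, v in cols.items():
        frame[k] = v
    return PredictionSet(frame)


def brute_force_metrics(true, pred):
    """Independently coded metric formulas (the dual-implementation oracle)."""
    true, pred = np.asarray(true, float), np.asarray(pred, float)
    err = true - pred
    medae = float(np.median(np.abs(err)))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    ct, cp = true - true.mean(), pred - pred.mean()
    r = float(np.sum(ct * cp) / np.sqrt(np.sum(ct**2) * np.sum(cp**2)))
    return medae, mae, rmse, r2, r


class TestComputeMetrics:
    def test_perfect_predictions(self):
        rep = compute_metrics(make_preds([10.0, 20.0, 30.0], [10.0, 20.0, 30.0]))
        assert (rep.medae, rep.mae, rep.rmse) == (0.0, 0.0, 0.0)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        rep = compute_metrics(make_preds([10, 20, 30], [11, 22, 27]))
        assert rep.medae == pytest.approx(2.0)
        assert rep.mae == pytest.approx(2.0)
        assert rep.rmse == pytest.approx(np.sqrt(14 / 3))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            true = rng.uniform(0, 100, 1000)
            pred = true + rng.normal(0, 5, 1000)
            rep = compute_metrics(make_preds(true, pred))
            medae, mae, rmse, r2, r = brute_force_metrics(true, pred)
            assert abs(rep.medae - medae) < 1e-12
            assert abs(rep.mae - mae) < 1e-12
            assert abs(rep.rmse - rmse) < 1e-12
            assert abs(rep.r_squared - r2) < 1e-12
            assert abs(rep.pearson_r - r) < 1e-12

    def test_single_sample_has_undefined_correlation(self):
        rep = compute_metrics(make_preds([60.0], [50.41]))
        assert rep.medae == pytest.approx(9.59)
        assert rep.pearson_r is None and rep.r_squared is None

    def test_zero_variance_predictions_warn(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            rep = compute_metrics(make_preds([10, 20, 30], [15, 15, 15]))
        assert rep.pearson_r is None

    def test_reordering_invariance(self):
        rng = np.random.default_rng(1)
        true = rng.uniform(20, 80, 50)
        pred = true + rng.normal(0, 3, 50)
        rep1 = compute_metrics(make_preds(true, pred))
        perm = rng.permutation(50)
        rep2 = compute_metrics(make_preds(true[perm], pred[perm]))
        assert rep1.medae == rep2.medae
        # correlation may differ by float summation order only
        assert rep1.pearson_r == pytest.approx(rep2.pearson_r, abs=1e-12)

    def test_subgroup_breakdown(self):
        rep = compute_metrics(
            make_preds([10, 20, 30, 40], [11, 21, 29, 44],
                       cohort=["control", "control", "case", "case"]),
            by=["cohort"],
        )
        assert rep.subgroups["cohort=case"]["mae"] == pytest.approx(2.5)
        assert rep.subgroups["cohort=control"]["mae"] == pytest.approx(1.0)


class TestMannWhitney:
    def test_matches_exact_enumeration_small_n(self):
        # hand-rolled U-statistic null enumeration, independent of the
        # implementation's own exact path
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.8, 1, 6)
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            mu = len(x) * len(y) / 2
            d_obs = abs(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2 - mu)
            count = sum(
                abs(ranks[list(c)].sum() - len(x) * (len(x) + 1) / 2 - mu) >= d_obs - 1e-9
                for c in itertools.combinations(range(11), 5)
            )
            expected = count / 462
            assert mann_whitney(x, y) == pytest.approx(expected, abs=1e-12)

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 25)
        assert mann_whitney(x, y) == pytest.approx(mann_whitney(y, x))

    def test_agrees_with_scipy_at_large_n(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 3, 120), rng.normal(1, 3, 110)
        ours = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestCompareCohorts:
    def _preds(self, ctrl_err, case_err):
        n1, n2 = len(ctrl_err), len(case_err)
        true = np.full(n1 + n2, 50.0)
        pred = true + np.concatenate([ctrl_err, case_err])
        return make_preds(true, pred, cohort=["control"] * n1 + ["case"] * n2)

    def test_identical_cohorts_not_significant(self):
        errs = np.array([1.0, -2.0, 0.5, 3.0, -1.5, 2.5, 0.1, -0.7, 1.9])
        comp = compare_cohorts(self._preds(errs, errs), seed=0)
        assert comp.p_value > 0.05

    def test_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 3, 40), rng.normal(2, 3, 35)
        p_ab = compare_cohorts(self._preds(a, b), seed=1).p_value
        p_ba = compare_cohorts(self._preds(b, a), seed=1).p_value
        assert p_ab == pytest.approx(p_ba)

    def test_mean_errors_reported_per_cohort(self):
        comp = compare_cohorts(self._preds(np.array([1.0, 1.0]), np.array([4.0, 4.0, 4.0])), seed=0)
        assert comp.mean_error_control == pytest.approx(1.0)
        assert comp.mean_error_case == pytest.approx(4.0)
        assert (comp.n_control, comp.n_case) == (2, 3)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            compare_cohorts(make_preds([50.0], [51.0], cohort=["control"]), seed=0)

    def test_detects_implanted_shift(self):
        rng = np.random.default_rng(7)
        comp = compare_cohorts(
            self._preds(rng.normal(0, 3, 139), rng.normal(2.1, 3, 140)), seed=0
        )
        assert comp.p_value < 0.05
        assert comp.p_value_permuted > 0.05


class TestStratifiedErrors:
    def test_all_zero_errors(self):
        rng = np.random.default_rng(8)
        true = rng.uniform(21, 74, 200)
        sex = rng.choice(["male", "female"], 200)
        table = stratified_errors(make_preds(true, true, sex=sex))
        assert (table["mean_error"].dropna() == 0).all()
        assert (table["p_value_mw"].dropna() > 0.05).all()

    def test_single_sex_bracket_skipped(self):
        true = np.array([30.0, 40.0])
        table = stratified_errors(make_preds(true, true + 1, sex=["male", "male"]))
        row = table[(table["bracket"] == "(20, 45]") & (table["sex"] == "male")].iloc[0]
        assert row["n"] == 2 and np.isnan(row["p_value_mw"])

    def test_brackets_are_left_open_right_closed(self):
        true = np.array([45.0, 45.5])  # 45 belongs to (20,45], not (45,55]
        table = stratified_errors(make_preds(true, true, sex=["male", "female"]))
        b1 = table[table["bracket"] == "(20, 45]"]
        assert b1["n"].sum() == 1
        b2 = table[table["bracket"] == "(45, 55]"]
        assert b2["n"].sum() == 1

    def test_shifted_bracket_flagged(self):
        # +1.5 y error for females only in (45,55]; adequate n per cell
        rng = np.random.default_rng(9)
        rows = []
        for lo, hi in [(20, 45), (45, 55), (55, 65)]:
            for sex in ("male", "female"):
                ages = rng.uniform(lo + 0.5, hi, 120)
                shift = 1.5 if (sex == "female" and lo == 45) else 0.0
                rows.append(pd.DataFrame({
                    "true_age": ages,
                    "predicted_age": ages + shift + rng.normal(0, 1.0, 120),
                    "sex": sex,
                }))
        df = pd.concat(rows, ignore_index=True)
        df["sample_id"] = [f"S{i}" for i in range(len(df))]
        table = stratified_errors(PredictionSet(df))
        flagged = table[table["p_value_mw"] < 0.05]["bracket"].unique()
        assert "(45, 55]" in flagged
        assert "(20, 45]" not in flagged and "(55, 65]" not in flagged

    def test_overlapping_brackets_rejected(self):
        preds = make_preds([30.0], [30.0], sex=["male"])
        with pytest.raises(ValidationError):
            stratified_errors(preds, age_brackets=[(20, 50), (40, 60)])


class TestBmiEffect:
    def _simulate(self, n=94, bmi_coef=0.2, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(24, 45, n)
        bmi = rng.uniform(16, 36, n)
        z = lambda v: (v - v.mean()) / v.std()
        pred_z = 0.8 * z(age) + bmi_coef * z(bmi) + rng.normal(0, 0.3, n)
        pred = pred_z * 10 + 35
        return make_preds(age, pred, sex=rng.choice(["male", "female"], n), bmi=bmi)

    def test_recovers_implanted_coefficient(self):
        fits = [bmi_effect(self._simulate(seed=s)) for s in range(20)]
        coefs = np.array([f.params["BMI"] for f in fits])
        assert (coefs > 0).mean() >= 0.9
        assert np.abs(coefs - 0.2).mean() < 0.1

    def test_null_p_values_roughly_uniform(self):
        ps = [
            bmi_effect(self._simulate(bmi_coef=0.0, seed=s)).pvalues["BMI"]
            for s in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_bmi_is_singular(self):
        preds = self._simulate()
        preds.frame["bmi"] = 25.0
        with pytest.raises(ValidationError):
            bmi_effect(preds)

    def test_missing_bmi_dropped_with_warning(self):
        preds = self._simulate(n=40)
        preds.frame.loc[:4, "bmi"] = np.nan
        with pytest.warns(UserWarning, match="dropped 5"):
            fit = bmi_effect(preds)
        assert int(fit.nobs) == 35


class TestClockOverlap:
    def test_basic_counts(self):
        assert clock_overlap({"A", "B", "C"}, {"B", "C", "D"}) == (3, 3, 2)

    def test_disjoint_and_identical(self):
        assert clock_overlap({"A"}, {"B"})[2] == 0
        assert clock_overlap({"A", "B"}, {"B", "A"}) == (2, 2, 2)

    def test_duplicates_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            assert clock_overlap(["A", "A", "B"], ["B"]) == (2, 1, 1)
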