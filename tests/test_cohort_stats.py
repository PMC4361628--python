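"""Stratification rule and longitudinal mixed models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nawmperf import (
    adjusted_group_model,
    baseline_comparison,
    fit_random_intercept_model,
    marginal_group_means,
    percent_change,
    stratify_subject,
)

VISIT_OFFSETS = np.array([0.0, -0.2, -0.6, -0.9])


# --- stratification ---------------------------------------------------------

def test_stratify_examples():
    assert stratify_subject([1, 2, 0, 1]) == "HI"
    assert stratify_subject([0, 0, 0, 0]) == "LI"
    with pytest.raises(ValueError):
        stratify_subject([])


def test_stratify_exhaustive_truth_table():
    """All 16 binary 4-visit patterns vs brute-force counting."""
    n_hi = 0
    for pattern in itertools.product([0, 1], repeat=4):
        expected = "HI" if sum(pattern) >= 3 else "LI"
        assert stratify_subject(pattern) == expected
        n_hi += expected == "HI"
    assert n_hi == 5  # patterns with >= 3 ones


# --- baseline comparisons ---------------------------------------------------

def _subject_frame(hi_vals, li_vals, var="age"):
    rows = [{"subject_id": f"H{i}", "group": "HI", var: v, "sex": "F"}
            for i, v in enumerate(hi_vals)]
    rows += [{"subject_id": f"L{i}", "group": "LI", var: v, "sex": "F"}
             for i, v in enumerate(li_vals)]
    return pd.DataFrame(rows)


def test_pooled_t_test_hand_computation():
    # {1,2,3} vs {4,5,6}: pooled SD = 1, t = -3 / (1 * sqrt(2/3)) = -3.674
    out = baseline_comparison(_subject_frame([1, 2, 3], [4, 5, 6]),
                              continuous=("age",))
    row = out[out["variable"] == "age"].iloc[0]
    assert row["statistic"] == pytest.approx(-3.674, abs=1e-3)
    assert row["df"] == 4
    assert row["p"] == pytest.approx(0.0214, abs=5e-4)


def test_identical_groups_give_t_zero_p_one():
    out = baseline_comparison(_subject_frame([1, 2, 3], [1, 2, 3]),
                              continuous=("age",))
    row = out[out["variable"] == "age"].iloc[0]
    assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
    assert row["p"] == pytest.approx(1.0)


def test_sex_chi_squared_without_continuity_correction():
    rows = ([{"subject_id": f"H{i}", "group": "HI", "age": 30.0,
              "sex": "F" if i < 10 else "M"} for i in range(13)]
            + [{"subject_id": f"L{i}", "group": "LI", "age": 30.0,
                "sex": "F" if i < 16 else "M"} for i in range(20)])
    out = baseline_comparison(pd.DataFrame(rows), continuous=())
    row = out[out["variable"] == "sex"].iloc[0]
    import scipy.stats
    tab = np.array([[10, 3], [16, 4]])
    chi2, p, _, _ = scipy.stats.chi2_contingency(tab, correction=False)
    assert row["statistic"] == pytest.approx(chi2)
    assert row["p"] == pytest.approx(p)
    assert row["p"] > 0.5  # clearly non-significant


# --- mixed models -----------------------------------------------------------

def _balanced_cohort(n_hi=6, n_li=8, noise=0.0, seed=0,
                     group_means=(9.1, 7.6)):
    """Deterministic cohort built for exact fixed-effect recovery.

    Subjects come in pairs with intercepts +-0.3 and a deterministic
    +-0.05 residual pattern, both orthogonal to the intercept, group and
    visit columns (and to any subject-pair-constant covariate), so the
    mixed model's fixed effects equal the generating values to solver
    precision while all variance components stay strictly positive.
    """
    assert n_hi % 2 == 0 and n_li % 2 == 0
    rng = np.random.default_rng(seed)
    resid_pattern = np.array([1.0, -1.0, -1.0, 1.0])
    rows = []
    for i in range(n_hi + n_li):
        hi = i < n_hi
        marg = group_means[0] if hi else group_means[1]
        k = i if hi else i - n_hi
        pair, sign = divmod(k, 2)
        b = 0.3 if sign == 0 else -0.3
        for v in range(4):
            y = (marg - VISIT_OFFSETS.mean() + VISIT_OFFSETS[v] + b
                 + (1 if sign == 0 else -1) * 0.05 * resid_pattern[v])
            if noise:
                y += rng.normal(0, noise)
            rows.append(dict(subject_id=f"S{i:02d}", visit=v + 1,
                             group="HI" if hi else "LI", y=y, pair=pair,
                             age=30.0 + 2 * pair + (0 if hi else 40),
                             sex="F" if pair % 2 else "M"))
    return pd.DataFrame(rows)


def test_exact_visit_effect_recovery_on_noiseless_cohort():
    df = _balanced_cohort()
    m = fit_random_intercept_model(df, "y", ("visit",))
    for v in (2, 3, 4):
        assert m.visit_coefficient(v).beta == pytest.approx(
            VISIT_OFFSETS[v - 1], abs=1e-6)


def test_exact_group_effect_and_marginal_means():
    df = _balanced_cohort()
    m = fit_random_intercept_model(df, "y", ("group", "visit"))
    assert m.group_coefficient().beta == pytest.approx(1.5, abs=1e-6)
    mm = marginal_group_means(m, df)
    assert mm["HI"][0] == pytest.approx(9.1, abs=1e-6)
    assert mm["LI"][0] == pytest.approx(7.6, abs=1e-6)
    # difference of marginal means equals the group coefficient
    assert mm["HI"][0] - mm["LI"][0] == pytest.approx(
        m.group_coefficient().beta, abs=1e-9)


def test_row_permutation_invariance():
    df = _balanced_cohort(noise=0.3, seed=5)
    m1 = fit_random_intercept_model(df, "y", ("group", "visit"))
    m2 = fit_random_intercept_model(
        df.sample(frac=1.0, random_state=7).reset_index(drop=True),
        "y", ("group", "visit"))
    for k in m1.coefficients:
        assert m1.coefficients[k].beta == pytest.approx(
            m2.coefficients[k].beta, abs=1e-8)


def test_single_group_marginal_mean_is_grand_mean():
    df = _balanced_cohort(n_hi=0, n_li=8)
    m = fit_random_intercept_model(df, "y", ("group", "visit"))
    mm = marginal_group_means(m, df)
    assert set(mm) == {"LI"}
    assert mm["LI"][0] == pytest.approx(df["y"].mean(), abs=1e-6)


def test_duplicated_subject_visit_rejected():
    df = _balanced_cohort()
    with pytest.raises(ValueError):
        fit_random_intercept_model(pd.concat([df, df.iloc[:1]]), "y")


def test_adjusted_model_exact_recovery_and_location_invariance():
    # enough subject pairs that the pair-constant covariates do not span
    # the between-pair space (which would make the group term collinear)
    df = _balanced_cohort(n_hi=12, n_li=16, noise=0.0)
    rng = np.random.default_rng(3)
    # covariates constant within each subject pair: orthogonal to the
    # +-0.3 / +-0.05 error patterns, so no covariate absorbs any error
    pair_key = df["group"] + df["pair"].astype(str)
    for col, scale in [("t2_lv", 3.0), ("t1_lv", 0.5), ("gd_lv", 0.1),
                       ("wmv", 30.0), ("gmv", 50.0), ("edss", 1.0)]:
        vals = {k: rng.normal(5, 1) * scale for k in pair_key.unique()}
        df[col] = pair_key.map(vals)
    df = df.rename(columns={"y": "cbv_nawm"})
    m = adjusted_group_model(df, "cbv_nawm")
    # no covariate enters the outcome: group effect recovered exactly
    assert m.group_coefficient().beta == pytest.approx(1.5, abs=1e-5)
    shifted = df.assign(age=df["age"] + 100.0)
    m2 = adjusted_group_model(shifted, "cbv_nawm")
    assert m2.group_coefficient().beta == pytest.approx(
        m.group_coefficient().beta, abs=1e-6)


def test_log_scale_model_and_percent_change():
    # multiplicative visit decay on a positive outcome
    decay = 0.391
    rows = []
    for i in range(10):
        base = 0.2 + 0.05 * (i % 4)
        for v in range(4):
            rows.append(dict(subject_id=f"S{i}", visit=v + 1,
                             gd_lv=base * decay**v))
    df = pd.DataFrame(rows)
    m = fit_random_intercept_model(df, "gd_lv", ("visit",), scale="log")
    beta2 = m.visit_coefficient(2).beta
    est = percent_change(beta2)
    # the 0.001 mL log offset shifts the recovered decay slightly
    assert est == pytest.approx(60.9, abs=1.0)


def test_percent_change_values():
    assert percent_change(0.0) == 0.0
    assert percent_change(np.log(0.391)) == pytest.approx(60.9, abs=0.01)
    assert percent_change(-0.1) == pytest.approx(9.516, abs=1e-3)
    est, lo, hi = percent_change(np.log(0.391), np.log(0.2), np.log(0.759))
    assert lo == pytest.approx(24.1, abs=0.1)   # order-reversed bounds
    assert hi == pytest.approx(80.0, abs=0.1)
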