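"""Inflammatory-group stratification and longitudinal mixed-model statistics.

Subjects are stratified into a high-inflammatory (HI) and low-inflammatory
(LI) group by the count of *newly emerged* contrast-enhancing lesions:
HI iff at least ``min_new_per_visit`` new lesions appeared in at least
``min_visits_with_new`` of the scans (defaults: >=1 new lesion in >=3 of 4
monthly MRIs).

Longitudinal outcomes (NAWM CBV/CBF, lesion volumes) are modelled with
linear mixed models with a subject-level random intercept (REML), time as
a categorical factor with the first MRI as reference, and Wald 95%
confidence intervals.  Right-skewed lesion volumes are analysed on the log
scale, ln(x + eps), and log-scale visit coefficients are reported as
percentage change.  Group effect sizes are reported as estimated marginal
means: the model prediction per group averaged over visit levels at the
sample means of all other covariates, with delta-method intervals.

statsmodels MixedLM provides the REML machinery; model specification,
marginal means and reporting conventions live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "Coefficient",
    "MixedModelResult",
    "stratify_subject",
    "baseline_comparison",
    "subject_level_table",
    "fit_random_intercept_model",
    "adjusted_group_model",
    "percent_change",
    "marginal_group_means",
]

#: offset added before log-transforming lesion volumes that may be zero (mL)
EPS_LOG = 0.001

#: covariates of the adjusted group model, in reporting order
ADJUSTED_TERMS = ("group", "t2_lv", "t1_lv", "gd_lv", "wmv", "gmv",
                  "edss", "visit", "age", "sex")


class Coefficient(NamedTuple):
    beta: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class MixedModelResult:
    """Fixed-effect estimates of a random-intercept model."""

    outcome: str
    coefficients: dict[str, Coefficient]
    model_scale: str
    n_obs: int
    n_subjects: int
    converged: bool
    _sm: object = field(default=None, repr=False)

    def _find(self, *fragments) -> Coefficient:
        for name, coef in self.coefficients.items():
            if all(f in name for f in fragments):
                return coef
        raise KeyError(f"no coefficient matching {fragments}")

    def group_coefficient(self) -> Coefficient:
        """HI-vs-LI fixed effect."""
        return self._find("group", "[T.HI]")

    def visit_coefficient(self, visit: int) -> Coefficient:
        """Visit-vs-MRI-1 fixed effect for a later visit."""
        return self._find("visit", f"[T.{visit}]")

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, c.beta, c.ci_low, c.ci_high, c.p)
                for k, c in self.coefficients.items()]
        return pd.DataFrame(rows, columns=["term", "beta", "ci_low", "ci_high", "p"])


def stratify_subject(n_new_gd_per_visit, min_visits_with_new: int = 3,
                     min_new_per_visit: int = 1) -> str:
    """HI/LI assignment from per-visit counts of newly emerged Gd lesions."""
    counts = np.asarray(n_new_gd_per_visit)
    if counts.size == 0:
        raise ValueError("need at least one visit count")
    if np.any(counts < 0):
        raise ValueError("lesion counts cannot be negative")
    qualifying = int(np.sum(counts >= min_new_per_visit))
    return "HI" if qualifying >= min_visits_with_new else "LI"


def subject_level_table(long_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a visit-level table to one row per subject.

    Imaging variables are averaged across visits (mirroring a baseline
    table built from all acquired examinations); demographics are constant
    within subject and taken from the first row.
    """
    first_cols = [c for c in ("group", "age", "sex", "edss", "disease_duration",
                              "gmv", "wmv") if c in long_table.columns]
    mean_cols = [c for c in ("t2_lv", "t1_lv", "gd_lv", "cbv_nawm", "cbf_nawm")
                 if c in long_table.columns]
    agg = {c: "first" for c in first_cols} | {c: "mean" for c in mean_cols}
    return long_table.groupby("subject_id", sort=True).agg(agg).reset_index()


def baseline_comparison(subject_table: pd.DataFrame,
                        continuous=("age", "disease_duration", "edss", "t2_lv",
                                    "t1_lv", "gd_lv", "gmv", "wmv"),
                        group_col: str = "group") -> pd.DataFrame:
    """Group comparison of baseline characteristics.

    Pooled-variance two-sample t-tests for continuous variables and a
    chi-squared test (no continuity correction) for sex.  Variables with
    fewer than 2 subjects in a group are skipped with a warning.
    """
    groups = subject_table[group_col].unique()
    if len(groups) != 2:
        raise ValueError("baseline comparison needs exactly two groups")
    g_hi = subject_table[subject_table[group_col] == "HI"]
    g_lo = subject_table[subject_table[group_col] == "LI"]
    rows = []
    for var in continuous:
        if var not in subject_table.columns:
            continue
        a = g_hi[var].dropna().to_numpy(float)
        b = g_lo[var].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"skipping {var}: a group has < 2 subjects")
            continue
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        rows.append((var, "t", float(t), len(a) + len(b) - 2, float(p)))
    if "sex" in subject_table.columns:
        tab = pd.crosstab(subject_table[group_col], subject_table["sex"])
        if tab.shape == (2, 2):
            chi2, p, dof, _ = scipy.stats.chi2_contingency(tab, correction=False)
            rows.append(("sex", "chi2", float(chi2), int(dof), float(p)))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "df", "p"])


def _term_to_patsy(term: str, table: pd.DataFrame) -> str | None:
    """Formula fragment for one model term; None drops single-level factors."""
    if term == "visit":
        return "C(visit)" if table["visit"].nunique() > 1 else None
    if term == "group":
        if table["group"].nunique() < 2:
            return None
        return "C(group, Treatment('LI'))"
    if term == "sex":
        return "C(sex)" if table["sex"].nunique() > 1 else None
    return term


def fit_random_intercept_model(table: pd.DataFrame, outcome: str,
                               fixed_terms=("visit",),
                               scale: str = "identity",
                               eps_log: float = EPS_LOG) -> MixedModelResult:
    """REML linear mixed model with a subject random intercept.

    Parameters
    ----------
    table : DataFrame
        Visit-level long table; must contain ``subject_id``, the outcome and
        every fixed term.  Unbalanced panels (missing visits) are allowed.
    outcome : str
        Column to model.
    fixed_terms : sequence of str
        Fixed-effect terms; ``visit``, ``group`` and ``sex`` are coded as
        categoricals (MRI-1 and LI as reference levels).
    scale : {"identity", "log"}
        ``log`` models ln(outcome + eps_log).

    Wald 95% confidence intervals and p-values are reported per fixed
    coefficient.  Non-convergence is flagged, not raised.
    """
    if scale not in ("identity", "log"):
        raise ValueError("scale must be 'identity' or 'log'")
    if table.duplicated(["subject_id", "visit"]).any():
        raise ValueError("duplicated (subject, visit) rows")
    n_per_subject = table.groupby("subject_id")["visit"].nunique()
    if (n_per_subject >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 visits")
    df = table.copy()
    yname = outcome
    if scale == "log":
        yname = f"_log_{outcome}"
        df[yname] = np.log(df[outcome] + eps_log)
    terms = [t for t in (_term_to_patsy(t, df) for t in fixed_terms) if t]
    formula = f"{yname} ~ " + (" + ".join(terms) if terms else "1")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject_id"])
        try:
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except Exception:
            res = None
            converged = False
    if res is None:
        return MixedModelResult(outcome=outcome, coefficients={},
                                model_scale=scale, n_obs=len(df),
                                n_subjects=df["subject_id"].nunique(),
                                converged=False)
    k_fe = model.k_fe
    names = model.exog_names[:k_fe]
    params = np.asarray(res.params)[:k_fe]
    bse = np.asarray(res.bse)[:k_fe]
    pvals = np.asarray(res.pvalues)[:k_fe]
    z = scipy.stats.norm.ppf(0.975)
    coefs = {
        name: Coefficient(float(b), float(b - z * s), float(b + z * s), float(p))
        for name, b, s, p in zip(names, params, bse, pvals)
    }
    return MixedModelResult(outcome=outcome, coefficients=coefs,
                            model_scale=scale, n_obs=len(df),
                            n_subjects=df["subject_id"].nunique(),
                            converged=converged, _sm=res)


def adjusted_group_model(table: pd.DataFrame, outcome: str) -> MixedModelResult:
    """Fully adjusted perfusion model (Table-2 layout).

    Fixed effects: group, T2/T1/Gd lesion volumes, WMV, GMV, EDSS,
    categorical visit, age and sex; subject random intercept; LI and MRI-1
    as reference levels.
    """
    missing = [c for c in ADJUSTED_TERMS if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    return fit_random_intercept_model(table, outcome, fixed_terms=ADJUSTED_TERMS)


def percent_change(beta: float, ci_low: float | None = None,
                   ci_high: float | None = None):
    """Log-scale coefficient as percentage decrease, (1 - exp(beta)) * 100.

    The CI transforms the same way; for decreases the order reverses, so the
    returned interval is sorted.  Returns a float when no CI is given, else
    (estimate, ci_low, ci_high).
    """
    est = (1.0 - np.exp(beta)) * 100.0
    if ci_low is None or ci_high is None:
        return float(est)
    bounds = sorted(((1.0 - np.exp(ci_high)) * 100.0,
                     (1.0 - np.exp(ci_low)) * 100.0))
    return float(est), float(bounds[0]), float(bounds[1])


def marginal_group_means(result: MixedModelResult, table: pd.DataFrame):
    """Estimated marginal mean per group, averaged over visit levels.

    The fixed-effect design row is the sample-mean row with the visit
    dummies replaced by equal level weights and the group dummy switched
    per group; the interval is the delta-method (Wald) interval from the
    fixed-effect covariance.  Returns {group: (estimate, ci_low, ci_high)}.
    """
    if not result.converged or result._sm is None:
        raise ValueError("marginal means require a converged model")
    res = result._sm
    model = res.model
    k_fe = model.k_fe
    names = model.exog_names[:k_fe]
    exog = np.asarray(model.exog)[:, :k_fe]
    fe = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    xbar = exog.mean(axis=0)

    visit_cols = [i for i, n in enumerate(names) if n.startswith("C(visit)")]
    n_levels = table["visit"].nunique()
    for i in visit_cols:
        xbar[i] = 1.0 / n_levels

    group_cols = [i for i, n in enumerate(names)
                  if "group" in n and "[T.HI]" in n]
    z = scipy.stats.norm.ppf(0.975)
    out = {}
    levels = sorted(table["group"].unique())
    for g in levels:
        x = xbar.copy()
        for i in group_cols:
            x[i] = 1.0 if g == "HI" else 0.0
        est = float(x @ fe)
        se = float(np.sqrt(x @ cov @ x))
        out[g] = (est, est - z * se, est + z * se)
    return out
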