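"""Per-animal regression and paired analyses of acoustic profiles.

All models here operate on one row per animal (the per-animal averaging that
removes pseudo-replication from repeated notes): multiple linear regression
(least-squares and robust IRLS with bisquare weights) of a profile response
on age, sex, dominance and treatment; exploratory ANCOVA age x factor
interaction tests; Benjamini-Hochberg / Bonferroni multiplicity adjustment;
and dominant-vs-subordinate paired t-tests over housing dyads (the
subordinates of a triad are averaged into a single value).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "PairedTestResult",
    "fit_profile_regression",
    "ancova_interaction",
    "adjust_pvalues",
    "dyad_paired_test",
    "profile_regression_table",
    "PROFILE_RESPONSES",
]

PROFILE_RESPONSES = [
    "grand_mean_f",
    "sd_mean_f",
    "cv_mean_f",
    "grand_mean_s",
    "sd_mean_s",
    "cv_mean_s",
]


@dataclass
class RegressionResult:
    response: str
    method: str
    coefficients: pd.DataFrame  # term, b, t, p
    r_squared: float | None
    f_statistic: float | None
    f_pvalue: float | None
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "b"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "p"])


@dataclass
class PairedTestResult:
    mean_difference: float
    t: float
    df: int
    p: float
    n_pairs: int


def _treatment_groups(metadata: pd.DataFrame, coding: str) -> pd.Series:
    """Treatment groupings (several are supported to trade resolution for
    statistical power at small n): 'four_level' keeps the raw groups;
    'two_level' folds gonadectomized animals into the hormone groups by sex
    and controls stay separate; 'control_vs_treated' is binary."""
    t = metadata["treatment"].astype(str)
    if coding == "four_level":
        return t
    if coding == "two_level":
        folded = t.copy()
        gdx = t == "gonadectomized"
        folded[gdx & (metadata["sex"] == "female")] = "anti_estrogen"
        folded[gdx & (metadata["sex"] == "male")] = "anti_androgen"
        return folded
    if coding == "control_vs_treated":
        return pd.Series(
            np.where(t == "control", "control", "treated"), index=t.index
        )
    raise ValueError(f"unknown treatment coding {coding!r}")


def _design_frame(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    response: str,
    treatment_coding: str,
) -> pd.DataFrame:
    df = profiles.merge(metadata, on="animal_id", validate="one_to_one")
    if response not in df:
        raise ValueError(f"unknown response {response!r}")
    out = pd.DataFrame(
        {
            "y": df[response].astype(float),
            "age": df["age"].astype(float),
            "sex_male": (df["sex"] == "male").astype(float),
            "dominance_sub": (df["dominance"] == "subordinate").astype(float),
            "treatment": _treatment_groups(df, treatment_coding),
        }
    )
    return out


def fit_profile_regression(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    response: str,
    method: str = "ols",
    treatment_coding: str = "four_level",
) -> RegressionResult:
    """Multiple regression of a per-animal profile response on age, sex,
    dominance and treatment.

    Coefficients keep the response's natural units (Hz/yr for age on a Hz
    response). ``method='robust'`` fits IRLS with Tukey bisquare weights
    (tuning constant 4.685). Aliased (collinear) predictors raise with the
    offending terms named.
    """
    data = _design_frame(profiles, metadata, response, treatment_coding)
    formula = "y ~ age + sex_male + dominance_sub + C(treatment)"
    if data["treatment"].nunique() < 2:
        formula = "y ~ age + sex_male + dominance_sub"
    if method == "ols":
        fit = smf.ols(formula, data=data).fit()
    elif method == "robust":
        fit = smf.rlm(
            formula, data=data, M=sm.robust.norms.TukeyBiweight(c=4.685)
        ).fit()
    else:
        raise ValueError(f"unknown method {method!r}")
    rank = np.linalg.matrix_rank(fit.model.exog)
    if rank < fit.model.exog.shape[1]:
        names = fit.model.exog_names
        raise ValueError(f"collinear predictors in design: {names}")
    coef = pd.DataFrame(
        {
            "term": fit.params.index,
            "b": fit.params.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    is_ols = method == "ols"
    return RegressionResult(
        response=response,
        method=method,
        coefficients=coef,
        r_squared=float(fit.rsquared) if is_ols else None,
        f_statistic=float(fit.fvalue) if is_ols else None,
        f_pvalue=float(fit.f_pvalue) if is_ols else None,
        n_obs=int(fit.nobs),
    )


def ancova_interaction(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    response: str,
    factor: str,
    treatment_coding: str = "four_level",
) -> tuple[float, tuple[int, int], float]:
    """F-test of the age x factor interaction (separate slopes per level).

    Age enters as a scale covariate; the factor must have >= 2 levels with
    >= 2 animals each. Returns (F, (df_num, df_den), p).
    """
    data = _design_frame(profiles, metadata, response, treatment_coding)
    col = {"sex": "sex_male", "dominance": "dominance_sub", "treatment": "treatment"}
    if factor not in col:
        raise ValueError(f"unknown factor {factor!r}")
    fcol = col[factor]
    levels = data[fcol].value_counts()
    if len(levels) < 2 or levels.min() < 2:
        raise ValueError(
            f"factor {factor!r} needs >= 2 levels with >= 2 animals each "
            f"(got {dict(levels)})"
        )
    fit = smf.ols(f"y ~ age * C({fcol})", data=data).fit()
    table = anova_lm(fit, typ=2)
    row = [i for i in table.index if i.startswith("age:")]
    if not row:
        raise ValueError("interaction term missing from ANOVA table")
    r = table.loc[row[0]]
    df_num = int(r["df"])
    df_den = int(table.loc["Residual", "df"])
    return float(r["F"]), (df_num, df_den), float(r["PR(>F)"])


def adjust_pvalues(pvals, method: str = "bh_fdr") -> np.ndarray:
    """Benjamini-Hochberg step-up FDR or Bonferroni adjustment, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    key = {"bh_fdr": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in key:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key[method])[1]


def dyad_paired_test(
    profiles: pd.DataFrame, metadata: pd.DataFrame, response: str
) -> PairedTestResult:
    """Paired t-test of (subordinate - dominant) across housing groups.

    Each dyad must contain exactly one dominant; in a triad the two
    subordinates are averaged into a single subordinate value, so every
    housing group contributes one pair. The difference is oriented
    subordinate minus dominant, so a positive mean difference means
    subordinates have the larger value.
    """
    df = profiles.merge(metadata, on="animal_id", validate="one_to_one")
    if response not in df:
        raise ValueError(f"unknown response {response!r}")
    dom_vals, sub_vals = [], []
    for dyad_id, grp in df.groupby("dyad_id", sort=True):
        doms = grp[grp["dominance"] == "dominant"]
        subs = grp[grp["dominance"] == "subordinate"]
        if len(doms) != 1 or len(subs) == 0:
            raise ValueError(
                f"housing group {dyad_id} needs exactly one dominant and >= 1 "
                f"subordinate (got {len(doms)} / {len(subs)})"
            )
        dom_vals.append(float(doms[response].iloc[0]))
        sub_vals.append(float(subs[response].mean()))
    diffs = np.asarray(sub_vals) - np.asarray(dom_vals)
    n = len(diffs)
    if n < 2:
        raise ValueError("need >= 2 housing groups for a paired test")
    if np.std(diffs, ddof=1) == 0:
        # degenerate: identical differences everywhere
        t, p = (0.0, 1.0) if np.mean(diffs) == 0 else (np.inf, 0.0)
    else:
        t, p = stats.ttest_1samp(diffs, 0.0)
    return PairedTestResult(
        mean_difference=float(np.mean(diffs)),
        t=float(t),
        df=n - 1,
        p=float(p),
        n_pairs=n,
    )


def profile_regression_table(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    treatment_coding: str = "four_level",
) -> tuple[pd.DataFrame, dict]:
    """Regression summary over the six profile responses.

    One OLS fit per response; model p-values are FDR-adjusted across the six
    responses. The age x dominance ANCOVA interaction is tested only for
    responses where age is a significant main effect (Bonferroni across the
    factors tested). Returns (long-format table, JSON-serialisable dict).
    """
    results = {
        resp: fit_profile_regression(
            profiles, metadata, resp, "ols", treatment_coding
        )
        for resp in PROFILE_RESPONSES
    }
    model_p = [results[r].f_pvalue for r in PROFILE_RESPONSES]
    model_p_fdr = adjust_pvalues(model_p, "bh_fdr")
    rows = []
    report: dict = {"responses": {}}
    for i, resp in enumerate(PROFILE_RESPONSES):
        res = results[resp]
        entry = {
            "r_squared": res.r_squared,
            "f_statistic": res.f_statistic,
            "p_model": res.f_pvalue,
            "p_model_fdr": float(model_p_fdr[i]),
            "age_b": res.coef("age"),
            "age_t": float(res.coefficients.set_index("term").loc["age", "t"]),
            "age_p": res.pvalue("age"),
            "dominance_t": float(
                res.coefficients.set_index("term").loc["dominance_sub", "t"]
            ),
            "dominance_p": res.pvalue("dominance_sub"),
            "sex_p": res.pvalue("sex_male"),
        }
        if entry["age_p"] < alpha:
            F, (d1, d2), p_int = ancova_interaction(
                profiles, metadata, resp, "dominance", treatment_coding
            )
            entry["age_x_dominance_F"] = F
            entry["age_x_dominance_df"] = [d1, d2]
            entry["age_x_dominance_p"] = p_int
        report["responses"][resp] = entry
        rows.append({"response": resp, **entry})
    table = pd.DataFrame(rows)
    return table, report
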