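"""Preregistered statistical analyses.

The primary behavioral hypothesis (H1: performance differs with dose) is
tested by a staged decision tree: a first-stage ANCOVA of mean NCS on dose
as a graded (ordinal 0/1/2) variable with typing speed as covariate; if
null, a second-stage model with dose as a categorical factor at a
Bonferroni-corrected level; if that is significant, a third-stage Tukey HSD
contrast between the 4 and 6 mA arms decides between a reversing and a
saturating dose response.  The outcome is one of four labels: monotonic,
reversing, saturating, or no_effect.

H2 (excitability) is an ordinary linear model of the post/pre MEP ratio on
graded dose, with the intercept separately tested against 1.  H3
(performance-excitability association) is a mixed model of mean NCS on MEP
ratio with a subject random intercept, which with one observation per
subject degenerates — deliberately and with a flag — to ordinary least
squares.  Null results are quantified by a Jeffreys-Zellner-Siow Bayes
factor computed by quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats


class ModelError(ValueError):
    pass


@dataclass
class TermTest:
    statistic: float
    df: tuple
    p: float


@dataclass
class ModelResult:
    params: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)  # name -> TermTest
    notes: tuple = ()


@dataclass
class StagedResult:
    label: str                      # monotonic | reversing | saturating | no_effect
    stage1: TermTest
    stage2: TermTest | None = None
    stage3: dict | None = None      # Tukey 4 vs 6: diff, ci, p_adj
    alpha: float = 0.05
    alpha_stage2: float = 0.025
    alpha_stage3: float = 0.025


def graded_dose(group_ma, levels=None) -> np.ndarray:
    """Ordinal 0/1/2 coding of the three current arms."""
    g = np.asarray(group_ma, dtype=float)
    levels = np.sort(np.unique(g)) if levels is None else np.asarray(levels)
    codes = np.searchsorted(levels, g).astype(float)
    return codes


# -- fast OLS core (shared with the power simulations) ----------------------

def ols_fit(X: np.ndarray, y: np.ndarray):
    """Least squares with coefficient SEs; returns (beta, se, rss, dof)."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = int(n - rank)
    if dof <= 0:
        raise ModelError("no residual degrees of freedom")
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    return beta, se, rss, dof


def ols_t_test(X: np.ndarray, y: np.ndarray, j: int,
               value: float = 0.0) -> TermTest:
    """Two-sided t-test of coefficient ``j`` against ``value``."""
    beta, se, _, dof = ols_fit(X, y)
    diff = beta[j] - value
    if abs(diff) <= 1e-8 * max(1.0, abs(value), abs(beta[j])):
        return TermTest(0.0, (1, dof), 1.0)
    if se[j] == 0:
        return TermTest(np.inf, (1, dof), 0.0)
    t = diff / se[j]
    p = 2 * stats.t.sf(abs(t), dof)
    return TermTest(float(t), (1, dof), float(p))


def ols_f_test(X_full: np.ndarray, X_null: np.ndarray,
               y: np.ndarray) -> TermTest:
    """Partial F-test of the full against the nested null design."""
    _, _, rss_full, dof_full = ols_fit(X_full, y)
    _, _, rss_null, _ = ols_fit(X_null, y)
    df_num = X_full.shape[1] - X_null.shape[1]
    if df_num <= 0:
        raise ModelError("models are not strictly nested")
    scale = max(float(y @ y), 1.0e-300)
    if rss_full <= 1e-20 * scale:
        # perfect fit: decisive only if the term actually improved the fit
        if rss_null <= 1e-20 * scale:
            return TermTest(0.0, (df_num, dof_full), 1.0)
        return TermTest(np.inf, (df_num, dof_full), 0.0)
    F = (rss_null - rss_full) / df_num / (rss_full / dof_full)
    p = stats.f.sf(F, df_num, dof_full)
    return TermTest(float(F), (df_num, dof_full), float(p))


def _design(n, *cols):
    return np.column_stack([np.ones(n)] + [np.asarray(c, float) for c in cols])


# -- H1 staged decision tree -------------------------------------------------

def staged_h1(mean_ncs, typing_wpm, group_ma, alpha: float = 0.05,
              bonferroni_factor: float = 2.0) -> StagedResult:
    """Staged dose-response analysis of the behavioral outcome.

    Stage 1: ANCOVA, graded dose + typing covariate; significant -> monotonic.
    Stage 2: categorical dose + typing covariate at ``alpha/bonferroni_factor``;
    null -> no_effect.  Stage 3: Tukey HSD between the 4 and 6 mA arms at the
    same corrected level; significant -> reversing, else saturating.
    """
    y = np.asarray(mean_ncs, float)
    w = np.asarray(typing_wpm, float)
    g = np.asarray(group_ma, float)
    if y.size != w.size or y.size != g.size:
        raise ModelError("inputs must be aligned")
    if np.isnan(w).any() or np.isnan(y).any():
        raise ModelError("missing outcome or covariate values")
    levels = np.sort(np.unique(g))
    if levels.size != 3:
        raise ModelError("exactly three dose arms required")
    for lv in levels:
        if (g == lv).sum() < 2:
            raise ModelError("at least 2 subjects per group required")
    x = graded_dose(g, levels)
    n = y.size

    stage1 = ols_f_test(_design(n, x, w), _design(n, w), y)
    alpha2 = alpha / bonferroni_factor
    if stage1.p < alpha:
        return StagedResult("monotonic", stage1, alpha=alpha,
                            alpha_stage2=alpha2, alpha_stage3=alpha2)

    d1 = (g == levels[1]).astype(float)
    d2 = (g == levels[2]).astype(float)
    stage2 = ols_f_test(_design(n, d1, d2, w), _design(n, w), y)
    if stage2.p >= alpha2:
        return StagedResult("no_effect", stage1, stage2, alpha=alpha,
                            alpha_stage2=alpha2, alpha_stage3=alpha2)

    tuk = stats.tukey_hsd(*[y[g == lv] for lv in levels])
    # arms are ordered (0, 4, 6) mA; the 4-vs-6 contrast is pair (1, 2)
    ci = tuk.confidence_interval(confidence_level=1 - alpha2)
    stage3 = {
        "diff": float(np.mean(y[g == levels[1]]) - np.mean(y[g == levels[2]])),
        "ci": (float(ci.low[1, 2]), float(ci.high[1, 2])),
        "p_adj": float(tuk.pvalue[1, 2]),
    }
    label = "reversing" if stage3["p_adj"] < alpha2 else "saturating"
    return StagedResult(label, stage1, stage2, stage3, alpha=alpha,
                        alpha_stage2=alpha2, alpha_stage3=alpha2)


# -- H2 -----------------------------------------------------------------------

def h2_model(mep_ratio, group_ma) -> ModelResult:
    """Linear model of the post/pre MEP ratio on graded dose.

    Reports the dose-slope F-test and, separately on the ratio scale, a
    t-test of the intercept against 1 (a ratio of 1 means no overall change).
    """
    r = np.asarray(mep_ratio, float)
    g = np.asarray(group_ma, float)
    keep = np.isfinite(r)
    r, g = r[keep], g[keep]
    levels = np.sort(np.unique(g))
    for lv in levels:
        if (g == lv).sum() < 3:
            raise ModelError("at least 3 defined ratios per group required")
    x = graded_dose(g, levels)
    X = _design(r.size, x)
    beta, se, _, dof = ols_fit(X, r)
    slope = ols_f_test(X, _design(r.size), r)
    intercept = ols_t_test(X, r, 0, value=1.0)
    return ModelResult(
        params={"intercept": float(beta[0]), "dose_slope": float(beta[1])},
        se={"intercept": float(se[0]), "dose_slope": float(se[1])},
        tests={"dose_slope": slope, "intercept_vs_1": intercept},
    )


# -- H3 -----------------------------------------------------------------------

def h3_mixed_model(mean_ncs, mep_ratio, subject=None) -> ModelResult:
    """Mixed model of performance on MEP ratio with subject random intercept.

    With a single observation per subject the random-intercept variance is
    unidentified; the fit then degenerates to ordinary regression and says so.
    """
    y = np.asarray(mean_ncs, float)
    m = np.asarray(mep_ratio, float)
    keep = np.isfinite(y) & np.isfinite(m)
    y, m = y[keep], m[keep]
    if y.size < 4:
        raise ModelError("too few paired observations")
    notes = []
    if subject is not None:
        subject = np.asarray(subject)[keep]
        _, counts = np.unique(subject, return_counts=True)
        repeated = counts.max() > 1
    else:
        repeated = False

    if repeated:
        import statsmodels.formula.api as smf
        df = pd.DataFrame({"y": y, "m": m, "subject": subject})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("y ~ m", df, groups=df["subject"]).fit(reml=True)
        t = float(fit.tvalues["m"])
        p = float(fit.pvalues["m"])
        return ModelResult(
            params={"intercept": float(fit.params["Intercept"]),
                    "mep_slope": float(fit.params["m"]),
                    "re_var": float(fit.cov_re.iloc[0, 0])},
            se={"mep_slope": float(fit.bse["m"])},
            tests={"mep_slope": TermTest(t, (1, y.size - 2), p)},
            notes=("mixed",),
        )
    notes.append("single observation per subject: random intercept "
                 "unidentified, reduced to OLS")
    X = _design(y.size, m)
    beta, se, _, dof = ols_fit(X, y)
    test = ols_t_test(X, y, 1)
    return ModelResult(
        params={"intercept": float(beta[0]), "mep_slope": float(beta[1]),
                "re_var": 0.0},
        se={"mep_slope": float(se[1])},
        tests={"mep_slope": test},
        notes=tuple(notes),
    )


# -- Bayes factor -------------------------------------------------------------

def bayes_factor_01(y, x, covariates=None,
                    prior_scale: float = np.sqrt(2) / 2) -> float:
    """JZS Bayes factor in favor of the null for one added regressor.

    ``y`` and ``x`` are residualized on an intercept plus optional nuisance
    covariates; the Zellner-Siow mixture-of-g integral is evaluated by
    quadrature on the resulting (partial) correlation:

        BF10 = ∫ (1+g)^((n-2)/2) (1+(1-r²)g)^(-(n-1)/2) π(g) dg

    with g ~ InverseGamma(1/2, n·s²/2) induced by a Cauchy(s) slope prior.
    ``prior_scale=1`` reproduces the classic JZS correlation Bayes factor.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.size
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(n), C])
    # residualize on nuisance design
    proj = Z @ np.linalg.pinv(Z)
    ry = y - proj @ y
    rx = x - proj @ x
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        return 1.0  # the comparison is between identical models
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r2 = min(r * r, 1 - 1e-12)
    s2 = prior_scale**2

    # log of InverseGamma(1/2, n*s^2/2) density times the marginal ratio
    log_prior_norm = 0.5 * np.log(n * s2 / 2.0) - special.gammaln(0.5)

    def log_integrand(g):
        return ((n - 2) / 2 * np.log1p(g)
                - (n - 1) / 2 * np.log1p((1 - r2) * g)
                + log_prior_norm - 1.5 * np.log(g) - n * s2 / (2 * g))

    # peak-shift for numerical stability
    opt = optimize.minimize_scalar(lambda u: -log_integrand(np.exp(u)) - u,
                                   bounds=(-10, 25), method="bounded")
    shift = -opt.fun
    val, _ = integrate.quad(
        lambda g: np.exp(log_integrand(g) - shift),
        0, np.inf, limit=200)
    log_bf10 = shift + np.log(max(val, 1e-300))
    return float(np.exp(-log_bf10))


# -- sensation confound model -------------------------------------------------

def sensation_model(data: pd.DataFrame, active_only: bool = False,
                    interaction: bool = True) -> ModelResult:
    """Mixed model of mean NCS on sensation and current (continuous fixed
    effects) with a subject random intercept.

    ``data`` is long format with columns subject_id, mean_ncs, sensation,
    current_mA (repeated rows per subject allowed, e.g. one per sensation
    timepoint).  ``active_only`` drops the 0 mA arm to probe sensation
    effects within active stimulation only.
    """
    df = data.copy()
    required = {"subject_id", "mean_ncs", "sensation", "current_mA"}
    if not required <= set(df.columns):
        raise ModelError(f"need columns {sorted(required)}")
    if df["sensation"].min() < 0 or df["sensation"].max() > 10:
        raise ModelError("sensation ratings must be on the 0-10 scale")
    if active_only:
        df = df[df["current_mA"] > 0]
    counts = df["subject_id"].value_counts()
    repeated = counts.max() > 1
    terms = ["sensation", "current_mA"] + (["sens_x_cur"] if interaction else [])
    df = df.assign(sens_x_cur=df["sensation"] * df["current_mA"])

    if repeated:
        import statsmodels.formula.api as smf
        formula = "mean_ncs ~ " + " + ".join(terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, df, groups=df["subject_id"]).fit(reml=True)
        tests = {t: TermTest(float(fit.tvalues[t]),
                             (1, int(df.shape[0] - len(terms) - 1)),
                             float(fit.pvalues[t])) for t in terms}
        params = {t: float(fit.params[t]) for t in terms}
        params["intercept"] = float(fit.params["Intercept"])
        return ModelResult(params=params,
                           se={t: float(fit.bse[t]) for t in terms},
                           tests=tests, notes=("mixed",))

    y = df["mean_ncs"].to_numpy(float)
    X = _design(len(df), *[df[t].to_numpy(float) for t in terms])
    beta, se, _, _ = ols_fit(X, y)
    tests = {t: ols_t_test(X, y, j + 1) for j, t in enumerate(terms)}
    params = {"intercept": float(beta[0])}
    params.update({t: float(beta[j + 1]) for j, t in enumerate(terms)})
    return ModelResult(params=params,
                       se={t: float(se[j + 1]) for j, t in enumerate(terms)},
                       tests=tests,
                       notes=("single observation per subject: reduced to OLS",))


def pearson_with_df(x, y) -> tuple[float, int, float]:
    """Pearson correlation reported as (r, df, p) with df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ModelError("need at least 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ModelError("inputs must be finite")
    res = stats.pearsonr(x, y)
    return float(res.statistic), x.size - 2, float(res.pvalue)
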