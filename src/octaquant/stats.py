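"""Cohort-level statistics for regional vessel density and FAZ metrics.

The analysis pattern: regional skeletonized vessel densities are repeated
measures — each subject contributes two eyes, each eye four quadrants and
(for the ONH) two rings — so group comparisons use linear mixed-effects
models with diagnosis, quadrant, their interaction, ring (until collapsed),
age and sex as fixed effects and random intercepts for subject and for eye
nested within subject.  The inferior quadrant is the reference level.  If
the ring fixed effect is not significant the inner and outer rings are
collapsed (averaged) and the model refit.  Post hoc contrast tests estimate
the control - SSD density difference at each quadrant, with
Benjamini-Hochberg adjustment across the four quadrant contrasts.

Wald p-values use the normal (z) approximation to the sampling distribution
of the fixed effects, which is accurate at the cluster counts this design
targets (tens of subjects per group); see the methods note for the
degrees-of-freedom discussion.

Demographics are compared with Welch two-sample t-tests (continuous) and
Pearson chi-square tests without continuity correction (categorical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

QUADRANTS = ("superior", "nasal", "inferior", "temporal")
REFERENCE_QUADRANT = "inferior"


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def chi_square_independence(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, p, df) with df = (r - 1)(c - 1).  Zero-expected
    cells raise, matching scipy's contingency-table contract.
    """
    table = np.asarray(table, dtype=float)
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p), int(dof)


def demographics_table(cohort: pd.DataFrame,
                       continuous: tuple[str, ...] = ("age",),
                       categorical: tuple[str, ...] = ("sex",)) -> pd.DataFrame:
    """Group comparisons of cohort covariates, one row per variable.

    Continuous variables get Welch t-tests, categorical ones Pearson
    chi-square.  Variables with no variation in either group are reported
    with a warning and no p-value (e.g. a quality index constant across the
    cohort).  The cohort table may be per-eye; subject-level variables are
    deduplicated on the ``subject`` column first.
    """
    subj = cohort.drop_duplicates("subject") if "subject" in cohort else cohort
    ctrl = subj[subj["diagnosis"] == "control"]
    ssd = subj[subj["diagnosis"] == "ssd"]
    rows = []
    for var in continuous:
        if var not in subj:
            continue
        x, y = ctrl[var].dropna().to_numpy(), ssd[var].dropna().to_numpy()
        if np.std(np.concatenate([x, y])) == 0:
            warnings.warn(f"{var}: no variation in the data; t-test not computed")
            rows.append({"variable": var, "test": "welch_t",
                         "control_mean": float(np.mean(x)), "ssd_mean": float(np.mean(y)),
                         "statistic": np.nan, "p": np.nan})
            continue
        t, p = welch_t(x, y)
        rows.append({"variable": var, "test": "welch_t",
                     "control_mean": float(np.mean(x)), "ssd_mean": float(np.mean(y)),
                     "statistic": t, "p": p})
    for var in categorical:
        if var not in subj:
            continue
        tab = pd.crosstab(subj["diagnosis"], subj[var])
        if tab.shape[1] < 2:
            warnings.warn(f"{var}: no variation in the data; chi-square not computed")
            rows.append({"variable": var, "test": "chi_square",
                         "control_mean": np.nan, "ssd_mean": np.nan,
                         "statistic": np.nan, "p": np.nan})
            continue
        stat, p, _ = chi_square_independence(tab.to_numpy())
        rows.append({"variable": var, "test": "chi_square",
                     "control_mean": np.nan, "ssd_mean": np.nan,
                     "statistic": stat, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    ``adj[i] = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


# ---------------------------------------------------------------------------
# mixed-effects density model
# ---------------------------------------------------------------------------

@dataclass
class DensityFit:
    """A fitted mixed model plus the bookkeeping needed for contrasts."""

    result: object
    records: pd.DataFrame
    site: str
    include_ring: bool
    converged: bool
    singular_fallback: bool = False

    @property
    def fixed_effects(self) -> pd.DataFrame:
        res = self.result
        return pd.DataFrame({"estimate": res.fe_params,
                             "se": res.bse_fe,
                             "p": res.pvalues[res.fe_params.index]})


def _model_formula(include_ring: bool) -> str:
    f = ("density ~ C(diagnosis, Treatment('control'))"
         " * C(quadrant, Treatment('inferior')) + age + C(sex)")
    if include_ring:
        f += " + C(ring)"
    return f


def _regional(records: pd.DataFrame) -> pd.DataFrame:
    """Drop site-summary rows; keep one row per quadrant x ring."""
    return records[records["quadrant"].isin(QUADRANTS)].copy()


def fit_density_model(records: pd.DataFrame, site: str | None = None,
                      include_ring: bool | None = None) -> DensityFit:
    """REML fit of the diagnosis x quadrant mixed model.

    Random structure: subject intercept plus an eye variance component
    nested within subject.  If that fit is singular or fails to converge, the
    model is refit with the subject intercept only (flagged on the result).
    """
    df = _regional(records)
    site = site or df["site"].iloc[0]
    if include_ring is None:
        include_ring = site == "onh" and set(df["ring"]) >= {"inner", "outer"}
    if df["diagnosis"].nunique() < 2:
        raise ValueError("both diagnoses must be present")
    if df["quadrant"].nunique() < 2:
        raise ValueError("need at least two quadrant levels")
    formula = _model_formula(include_ring)

    def _fit(vc, method):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = smf.mixedlm(formula, df, groups=df["subject"], re_formula="1",
                                vc_formula=vc)
            result = model.fit(reml=True, method=method)
        if (not result.converged or not np.isfinite(result.llf)
                or not np.all(np.isfinite(result.bse_fe))):
            raise RuntimeError("singular or non-converged fit")
        return result

    # fallback ladder: full nested structure -> subject-only intercept ->
    # plain OLS (exact when the variance components are truly zero)
    singular = False
    result = None
    for vc, method in (({"eye": "0 + C(eye)"}, "lbfgs"),
                       (None, "lbfgs"), (None, "powell")):
        try:
            result = _fit(vc, method)
            break
        except Exception:
            singular = True
    if result is None:
        result = _OlsAdapter(smf.ols(formula, df).fit())
    return DensityFit(result=result, records=df, site=site, include_ring=include_ring,
                      converged=bool(result.converged), singular_fallback=singular)


class _OlsAdapter:
    """Expose an OLS fit through the slice of the MixedLM result API we use.

    Last rung of the fallback ladder: when every mixed fit is singular the
    variance components are indistinguishable from zero and OLS gives the
    identical fixed effects.
    """

    converged = True

    def __init__(self, ols_result):
        self._res = ols_result
        self.fe_params = ols_result.params
        self.bse_fe = ols_result.bse
        self.pvalues = ols_result.pvalues

    def cov_params(self):
        return self._res.cov_params()


def ring_effect_p(fit: DensityFit) -> float:
    """P-value of the inner/outer ring fixed effect (ONH models)."""
    if not fit.include_ring:
        raise ValueError("model was fit without a ring term")
    names = [n for n in fit.result.fe_params.index if n.startswith("C(ring)")]
    return float(fit.result.pvalues[names[0]])


def collapse_rings(records: pd.DataFrame, fit: DensityFit | None = None,
                   alpha: float = 0.05) -> tuple[pd.DataFrame, bool, float]:
    """Average inner/outer rings per quadrant if the ring effect is not significant.

    Returns ``(records', collapsed, ring_p)``.  When collapsed, each
    subject x eye x quadrant keeps a single ``ring = "collapsed"`` record
    whose density is the mean of the inner and outer densities; otherwise
    the records pass through unchanged.
    """
    df = _regional(records)
    if set(df["ring"]) < {"inner", "outer"}:
        return records, False, float("nan")
    if fit is None:
        fit = fit_density_model(df, include_ring=True)
    p = ring_effect_p(fit)
    if p < alpha:
        return records, False, p
    keys = [c for c in ("subject", "eye", "diagnosis", "age", "sex", "site", "quadrant")
            if c in df.columns]
    collapsed = (df.groupby(keys, as_index=False, sort=False)["density"].mean())
    collapsed["ring"] = "collapsed"
    return collapsed, True, p


def _contrast_vector(fit: DensityFit, quadrant: str) -> np.ndarray:
    """L such that L @ beta = (SSD - control) marginal density at ``quadrant``."""
    names = list(fit.result.fe_params.index)
    L = np.zeros(len(names))
    diag_term = "C(diagnosis, Treatment('control'))[T.ssd]"
    L[names.index(diag_term)] = 1.0
    if quadrant != REFERENCE_QUADRANT:
        inter = (f"C(diagnosis, Treatment('control'))[T.ssd]:"
                 f"C(quadrant, Treatment('inferior'))[T.{quadrant}]")
        L[names.index(inter)] = 1.0
    return L


def quadrant_contrasts(fit: DensityFit) -> pd.DataFrame:
    """Post hoc control - SSD contrast per quadrant with BH-adjusted p-values."""
    fe = fit.result.fe_params.to_numpy()
    cov = np.asarray(fit.result.cov_params())[: len(fe), : len(fe)]
    rows = []
    for q in QUADRANTS:
        L = _contrast_vector(fit, q)
        ssd_minus_control = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        z = ssd_minus_control / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"quadrant": q, "estimate": -ssd_minus_control, "se": se,
                     "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def interaction_table(fit: DensityFit) -> pd.DataFrame:
    """Diagnosis x quadrant interaction coefficients with BH-adjusted p-values."""
    fe = fit.fixed_effects
    inter = fe[fe.index.str.contains(":")].copy()
    inter["quadrant"] = [n.split("[T.")[-1].rstrip("]") for n in inter.index]
    inter["p_adjusted"] = bh_adjust(inter["p"].to_numpy())
    return inter[["quadrant", "estimate", "se", "p", "p_adjusted"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# full per-site analysis, age stratification
# ---------------------------------------------------------------------------

@dataclass
class SiteAnalysis:
    fit: DensityFit
    contrasts: pd.DataFrame
    interactions: pd.DataFrame
    ring_collapsed: bool
    ring_p: float


def analyze_site(records: pd.DataFrame, site: str | None = None) -> SiteAnalysis:
    """Fit, collapse rings if warranted, refit, and run the quadrant contrasts."""
    df = _regional(records)
    site = site or df["site"].iloc[0]
    if site == "onh" and set(df["ring"]) >= {"inner", "outer"}:
        full_fit = fit_density_model(df, site=site, include_ring=True)
        df2, collapsed, ring_p = collapse_rings(df, fit=full_fit)
        fit = fit_density_model(df2, site=site, include_ring=False) if collapsed else full_fit
    else:
        fit = fit_density_model(df, site=site, include_ring=False)
        collapsed, ring_p = False, float("nan")
    return SiteAnalysis(fit=fit, contrasts=quadrant_contrasts(fit),
                        interactions=interaction_table(fit),
                        ring_collapsed=collapsed, ring_p=ring_p)


@dataclass
class StratifiedResult:
    young: SiteAnalysis
    old: SiteAnalysis
    cutoff: float
    age_interaction_coef: float
    age_interaction_p: float


def age_stratified_analysis(records: pd.DataFrame, cutoff: float = 30.0) -> StratifiedResult:
    """Refit the full analysis within age strata (young: age <= cutoff).

    Also fits a pooled model of the temporal-quadrant densities with a
    diagnosis x continuous-age interaction, testing whether the diagnosis
    effect varies with age rather than depending on the cutoff.
    """
    df = _regional(records)
    young = df[df["age"] <= cutoff]
    old = df[df["age"] > cutoff]
    for name, stratum in (("young", young), ("old", old)):
        if stratum.empty or stratum["diagnosis"].nunique() < 2:
            raise ValueError(f"empty or single-diagnosis {name} stratum")
    temporal = df[df["quadrant"] == "temporal"].copy()
    # center age for conditioning; the interaction slope and its test are unchanged
    temporal["age_c"] = temporal["age"] - temporal["age"].mean()
    formula = "density ~ C(diagnosis, Treatment('control')) * age_c + C(sex)"
    res = None
    for method in ("lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = smf.mixedlm(formula, temporal, groups=temporal["subject"],
                                    re_formula="1")
                res = model.fit(reml=True, method=method)
            if np.all(np.isfinite(res.bse_fe)):
                break
        except Exception:
            res = None
    if res is None:
        res = _OlsAdapter(smf.ols(formula, temporal).fit())
    term = "C(diagnosis, Treatment('control'))[T.ssd]:age_c"
    return StratifiedResult(
        young=analyze_site(young),
        old=analyze_site(old),
        cutoff=cutoff,
        age_interaction_coef=float(res.fe_params[term]),
        age_interaction_p=float(res.pvalues[term]),
    )


# ---------------------------------------------------------------------------
# FAZ regression and density-RNFL correlations
# ---------------------------------------------------------------------------

def faz_group_regression(faz_table: pd.DataFrame, response: str = "area_mm2") -> dict:
    """Per-eye linear regression of a FAZ metric on diagnosis.

    Returns group means +/- SD (computed per eye), the SSD regression
    coefficient relative to the control group, and its p-value.
    """
    for grp in ("control", "ssd"):
        if (faz_table["diagnosis"] == grp).sum() < 3:
            raise ValueError("need at least 3 eyes per group")
    y = faz_table[response]
    if y.nunique() == 1:
        raise ValueError("constant response: regression undefined")
    fit = smf.ols(f"{response} ~ C(diagnosis, Treatment('control'))", faz_table).fit()
    term = "C(diagnosis, Treatment('control'))[T.ssd]"
    ctrl = faz_table.loc[faz_table["diagnosis"] == "control", response]
    ssd = faz_table.loc[faz_table["diagnosis"] == "ssd", response]
    return {
        "response": response,
        "control_mean": float(ctrl.mean()), "control_sd": float(ctrl.std(ddof=1)),
        "ssd_mean": float(ssd.mean()), "ssd_sd": float(ssd.std(ddof=1)),
        "coef": float(fit.params[term]), "p": float(fit.pvalues[term]),
    }


def density_rnfl_correlation(records: pd.DataFrame, cutoff: float = 30.0) -> pd.DataFrame:
    """Pearson density-RNFL correlation per quadrant, diagnosis and age stratum."""
    df = _regional(records).dropna(subset=["rnfl_thickness"])
    rows = []
    df = df.assign(age_group=np.where(df["age"] <= cutoff, "young", "old"))
    for (diagnosis, age_group, quadrant), g in df.groupby(
            ["diagnosis", "age_group", "quadrant"], sort=False):
        if len(g) < 3:
            continue
        x, y = g["density"].to_numpy(), g["rnfl_thickness"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"diagnosis": diagnosis, "age_group": age_group,
                         "quadrant": quadrant, "n": len(g), "r": np.nan, "p": np.nan,
                         "degenerate": True})
            continue
        r, p = sps.pearsonr(x, y)
        rows.append({"diagnosis": diagnosis, "age_group": age_group,
                     "quadrant": quadrant, "n": len(g), "r": float(r), "p": float(p),
                     "degenerate": False})
    return pd.DataFrame(rows)
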