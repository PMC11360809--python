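"""Provenance-variation mixed models and Pearson correlation tables.

The variation model for a trait X observed on tree m of provenance j,
block k, year l is

    X_jklm = mu + P_j + B_k + Y_l + (P x Y)_jl + e_jklm

with provenance and provenance-by-year random, block and year fixed.
Each random effect is tested with a REML likelihood-ratio test against
the model without that effect.  Because the null value of a variance
component lies on the boundary of its parameter space, the LRT is
referred by default to the 50:50 mixture of a point mass at zero and
chi-square(1) (Self & Liang); the plain chi-square(1) reference, which
is roughly twice as conservative, is available via
``boundary_mixture=False``.  Fixed-effect mean squares come from the
ordinary ANOVA decomposition of the fixed part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


def significance_stars(p: float) -> str:
    """Three-tier convention: * at 5%, ** at 1%, *** at 0.1%."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class VarianceTestResult:
    """LRT statistics for the random effects and mean squares for the fixed ones."""

    response: str
    lrt_provenance: float
    p_provenance: float
    lrt_prov_year: float
    p_prov_year: float
    ms_block: float
    p_block: float
    ms_year: float
    p_year: float
    variance_components: dict = field(default_factory=dict)
    singular: bool = False

    @property
    def stars_provenance(self) -> str:
        return significance_stars(self.p_provenance)

    @property
    def stars_prov_year(self) -> str:
        return significance_stars(self.p_prov_year)


def _fit_mixed(formula: str, data: pd.DataFrame, groups: str,
               random_intercept: bool, vc: dict | None):
    model = smf.mixedlm(formula, data, groups=groups,
                        re_formula="1" if random_intercept else "0",
                        vc_formula=vc)
    # Powell is markedly more reliable than the gradient optimizers on the
    # near-boundary fits this model produces; fall back to lbfgs if it fails.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(reml=True, method="powell", maxiter=1000)
        except Exception:
            return model.fit(reml=True, method="lbfgs", maxiter=200)


def _boundary_p(lrt: float, mixture: bool) -> float:
    if lrt <= 0:
        return 1.0
    p = float(stats.chi2.sf(lrt, 1))
    return 0.5 * p if mixture else p


def fit_variation_model(data: pd.DataFrame, response: str,
                        provenance: str = "provenance_id", block: str = "block_id",
                        year: str = "year", include_prov_year: bool = True,
                        boundary_mixture: bool = True) -> VarianceTestResult:
    """REML fit of the variation model and LRTs for the random effects.

    ``data`` is tidy: one row per tree x year with the response and the
    provenance/block/year labels.  Unbalanced designs are handled by REML
    directly.  A response with no variance short-circuits to an all-zero
    result.  Fits where a variance component collapses to (near) zero are
    flagged ``singular`` but the LRTs remain defined.
    """
    df = data[[response, provenance, block, year]].dropna().copy()
    for c in (provenance, block, year):
        if df[c].nunique() < 2:
            raise ValueError(f"factor {c!r} needs at least 2 levels")
    df[provenance] = df[provenance].astype(str)

    if np.std(df[response].to_numpy(dtype=float)) == 0:
        return VarianceTestResult(response=response, lrt_provenance=0.0, p_provenance=1.0,
                                  lrt_prov_year=0.0, p_prov_year=1.0,
                                  ms_block=0.0, p_block=1.0, ms_year=0.0, p_year=1.0,
                                  variance_components={"provenance": 0.0,
                                                       "prov_year": 0.0, "residual": 0.0})

    fixed = f"{response} ~ C({block}) + C({year})"
    vc = {"prov_year": f"0 + C({year})"} if include_prov_year else None

    full = _fit_mixed(fixed, df, provenance, True, vc)
    no_prov = _fit_mixed(fixed, df, provenance, False, vc)
    lrt_p = max(0.0, 2.0 * (full.llf - no_prov.llf))
    if include_prov_year:
        no_py = _fit_mixed(fixed, df, provenance, True, None)
        lrt_py = max(0.0, 2.0 * (full.llf - no_py.llf))
    else:
        lrt_py = 0.0

    resid_var = float(full.scale)
    prov_var = float(np.asarray(full.cov_re).ravel()[0]) if full.cov_re.size else 0.0
    vc_var = float(full.vcomp[0]) if include_prov_year and len(full.vcomp) else 0.0
    singular = (prov_var < 1e-8 * resid_var) or (
        include_prov_year and vc_var < 1e-8 * resid_var)

    # fixed-effect mean squares from the ANOVA decomposition of the fixed part
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = anova_lm(smf.ols(fixed, df).fit(), typ=2)
    ms_block = float(anova.loc[f"C({block})", "sum_sq"] / anova.loc[f"C({block})", "df"])
    ms_year = float(anova.loc[f"C({year})", "sum_sq"] / anova.loc[f"C({year})", "df"])

    return VarianceTestResult(
        response=response,
        lrt_provenance=lrt_p, p_provenance=_boundary_p(lrt_p, boundary_mixture),
        lrt_prov_year=lrt_py,
        p_prov_year=(_boundary_p(lrt_py, boundary_mixture)
                     if include_prov_year else np.nan),
        ms_block=ms_block, p_block=float(anova.loc[f"C({block})", "PR(>F)"]),
        ms_year=ms_year, p_year=float(anova.loc[f"C({year})", "PR(>F)"]),
        variance_components={"provenance": prov_var, "prov_year": vc_var,
                             "residual": resid_var},
        singular=singular)


def correlation_table(data: pd.DataFrame, x_vars=None, y_vars=None) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided t-test p-values and stars.

    With ``x_vars``/``y_vars`` given, correlates each x with each y;
    otherwise all distinct column pairs.  Variables are used untransformed.
    Pairs with fewer than 3 complete observations or a zero-variance
    member get r = NaN.
    """
    cols = list(data.columns)
    if x_vars is None and y_vars is None:
        pairs = [(cols[i], cols[j]) for i in range(len(cols))
                 for j in range(i + 1, len(cols))]
    else:
        x_vars = list(x_vars) if x_vars is not None else cols
        y_vars = list(y_vars) if y_vars is not None else cols
        pairs = [(a, b) for a in x_vars for b in y_vars if a != b]
    rows = []
    for a, b in pairs:
        sub = data[[a, b]].dropna()
        n = len(sub)
        if n < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rows.append({"var_a": a, "var_b": b, "r": np.nan, "n": n,
                         "p": np.nan, "stars": ""})
            continue
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"var_a": a, "var_b": b, "r": float(r), "n": n,
                     "p": float(p), "stars": significance_stars(p)})
    return pd.DataFrame(rows)
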