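"""Linear modelling of growth rate after evolution.

Fits an ordinary least-squares model of the evolved growth rate on biological
covariates of the deleted gene (ancestral growth rate, network module /
submodule, interaction counts, conservation, paralog/complex membership ...),
quantifies each variable's explained variance by drop-one ANOVA, and
provides the Mann-Whitney U comparison of module groups against wild type.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelReport",
    "fit_linear_model",
    "drop_one_anova",
    "mann_whitney_u",
    "read_covariates_tsv",
    "write_report_json",
]

#: categorical covariates are dummy-coded against these reference levels
DEFAULT_REFERENCE = {"module": "wild_type", "submodule": "wild_type"}


@dataclass
class ModelReport:
    """Fitted OLS model with raw and standardized coefficient tables.

    ``coefficients`` columns: coef, ci_low, ci_high, p, std_coef (the
    coefficient after centering/scaling continuous covariates).
    """

    coefficients: pd.DataFrame
    r_squared: float
    n_obs: int
    terms: dict  # variable -> list of design-matrix columns
    _fit: object = None
    _design: pd.DataFrame = None
    _y: np.ndarray = None


def _build_design(
    X: pd.DataFrame, categorical: tuple[str, ...], reference: dict
) -> tuple[pd.DataFrame, dict]:
    cols = {}
    terms: dict[str, list[str]] = {}
    for var in X.columns:
        if var in categorical:
            levels = pd.unique(X[var].astype(str))
            ref = reference.get(var)
            if ref is None or ref not in levels:
                ref = sorted(levels)[0]
            dummies = []
            for lvl in sorted(levels):
                if lvl == ref:
                    continue
                name = f"{var}[{lvl}]"
                cols[name] = (X[var].astype(str) == lvl).astype(float)
                dummies.append(name)
            terms[var] = dummies
        else:
            cols[var] = X[var].astype(float)
            terms[var] = [var]
    design = pd.DataFrame(cols, index=X.index)
    return design, terms


def _check_rank(design: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    rank = np.linalg.matrix_rank(mat)
    if rank == mat.shape[1]:
        return
    aliased = []
    for j, col in enumerate(design.columns):
        reduced = np.delete(mat, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            aliased.append(col)
    raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def fit_linear_model(
    y,
    X: pd.DataFrame,
    categorical: tuple[str, ...] = ("module", "submodule"),
    reference: dict | None = None,
) -> ModelReport:
    """OLS fit of evolved growth rate on a covariate table.

    Categorical covariates are dummy-coded against the wild-type reference
    level (configurable), so module coefficients read as contrasts to the
    wild type.  Standardized coefficients (continuous covariates centered and
    scaled to unit SD) are reported alongside the raw ones, and 95% normal
    CIs for both.  Raises on a rank-deficient design, naming aliased terms.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X length mismatch")
    reference = {**DEFAULT_REFERENCE, **(reference or {})}
    categorical = tuple(c for c in categorical if c in X.columns)
    design, terms = _build_design(X, categorical, reference)
    if len(y) <= design.shape[1] + 1:
        raise ValueError("more parameters than observations")
    _check_rank(design)

    exog = sm.add_constant(design)
    fit = sm.OLS(y, exog).fit()
    ci = fit.conf_int(alpha=0.05)

    # standardized fit: scale continuous covariates only
    design_std = design.copy()
    cat_cols = {c for var in categorical for c in terms[var]}
    for col in design.columns:
        if col not in cat_cols:
            sd = design[col].std(ddof=1)
            if sd > 0:
                design_std[col] = (design[col] - design[col].mean()) / sd
    fit_std = sm.OLS(y, sm.add_constant(design_std)).fit()
    ci_std = fit_std.conf_int(alpha=0.05)

    coef = pd.DataFrame(
        {
            "coef": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
            "std_coef": fit_std.params,
            "std_ci_low": ci_std[0],
            "std_ci_high": ci_std[1],
        }
    )
    return ModelReport(
        coefficients=coef,
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
        terms=terms,
        _fit=fit,
        _design=design,
        _y=y,
    )


def drop_one_anova(report: ModelReport) -> pd.DataFrame:
    """Per-variable explained variance and F-test against the full model.

    Each variable (a categorical variable as a block of dummies) is dropped
    in turn; explained variance is (RSS_reduced - RSS_full) / TSS and the
    p-value is the nested-model F-test.
    """
    fit = report._fit
    y = report._y
    design = report._design
    tss = float(((y - y.mean()) ** 2).sum())
    rss_full = float(fit.ssr)
    df_full = int(fit.df_resid)
    rows = []
    for var, cols in report.terms.items():
        reduced_cols = [c for c in design.columns if c not in cols]
        exog_red = sm.add_constant(design[reduced_cols]) if reduced_cols else np.ones((len(y), 1))
        fit_red = sm.OLS(y, exog_red).fit()
        rss_red = float(fit_red.ssr)
        df_num = len(cols)
        explained = max(rss_red - rss_full, 0.0) / tss
        if rss_full > 0 and df_full > 0:
            f = ((rss_red - rss_full) / df_num) / (rss_full / df_full)
            p = float(stats.f.sf(max(f, 0.0), df_num, df_full))
        else:
            f, p = np.inf, 0.0
        rows.append(
            {"variable": var, "explained_variance": explained, "F": f, "p": p}
        )
    return pd.DataFrame(rows).set_index("variable").sort_values(
        "explained_variance", ascending=False
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: # pairs with a > b, ties counting 1/2."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(
    group_a,
    group_b,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test; exact by enumeration for small samples.

    With combined n <= 20 (``method="auto"``) the null distribution of U is
    enumerated over all assignments of the pooled values, which handles ties
    exactly; larger samples use the normal approximation with tie correction.
    Returns (U of group_a, p).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if method == "auto":
        method = "exact" if a.size + b.size <= 20 else "asymptotic"
    u_obs = _u_statistic(a, b)
    if method == "exact":
        # With midranks r, U_a = sum(r over a) - n_a(n_a+1)/2 exactly matches
        # the pairwise count with ties at 1/2, so enumeration reduces to
        # rank-sums over all C(n, n_a) subsets.
        pooled = np.concatenate([a, b])
        n = pooled.size
        r = stats.rankdata(pooled)
        combs = np.fromiter(
            (i for c in combinations(range(n), a.size) for i in c),
            dtype=np.intp,
            count=comb(n, a.size) * a.size,
        ).reshape(-1, a.size)
        us = r[combs].sum(axis=1) - a.size * (a.size + 1) / 2.0
        eps = 1e-9
        p_ge = np.mean(us >= u_obs - eps)
        p_le = np.mean(us <= u_obs + eps)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        elif alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_ge, p_le))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return u_obs, float(p)
    if method == "asymptotic":
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# File interfaces


def read_covariates_tsv(rates_path, covariates_path, key: str = "genotype"):
    """Join a rates TSV (genotype/lineage, evolved_rate) with a covariate
    TSV keyed by genotype; returns (y array, X DataFrame)."""
    rates = pd.read_csv(rates_path, sep="\t")
    cov = pd.read_csv(covariates_path, sep="\t")
    merged = rates.merge(cov, on=key, how="inner")
    y = merged.pop("evolved_rate").to_numpy(float)
    drop = [c for c in (key, "lineage") if c in merged.columns]
    return y, merged.drop(columns=drop)


def write_report_json(report: ModelReport, anova: pd.DataFrame | None, path) -> None:
    import json

    payload = {
        "r_squared": report.r_squared,
        "n_obs": report.n_obs,
        "coefficients": report.coefficients.round(6).to_dict(orient="index"),
    }
    if anova is not None:
        payload["anova"] = anova.round(6).to_dict(orient="index")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
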