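"""Diversity of evolutionary outcomes per genotype.

For each deletion genotype, the replicate lineages that evolved from it are
compared pairwise: phenotypic distance is the mean Euclidean distance between
their relative-fitness-change profiles across the phenotyping conditions, and
mutational distance is the mean Jaccard distance between their binary
mutation profiles (mutated genes and GO categories, over the feature space of
everything mutated at least once across all clones).  The per-genotype mean
distances are then related to the deleted gene's genetic-interaction degree
and to its phenotypic potential (an external per-gene measurement of
within-strain cell-to-cell variability), with ROUT outlier removal before
the final linear fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "phenotypic_distance",
    "mutational_distance",
    "build_distance_report",
    "distance_vs_degree",
    "rout_outliers",
    "distance_vs_potential",
    "LinearFit",
    "read_phenotypes_tsv",
    "write_distance_report_tsv",
]


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    r: float  # Pearson correlation on the fitted points
    n: int
    n_removed: int = 0


def _profile_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        return profiles.to_numpy(dtype=float)
    return np.asarray(profiles, dtype=float)


def phenotypic_distance(
    profiles, n_conditions_total: int | None = None, min_shared_fraction: float = 0.5
) -> float:
    """Mean pairwise Euclidean distance between replicate phenotype profiles.

    ``profiles`` is a replicates x conditions matrix (DataFrame or array) of
    relative fitness changes; condition order must be shared.  Pairs with
    missing entries are compared on their shared conditions and rescaled by
    sqrt(n_total / n_shared); pairs sharing fewer than half the conditions
    are dropped with a warning.  Fewer than two profiles raises ValueError.
    """
    if isinstance(profiles, pd.DataFrame):
        mat = profiles.to_numpy(dtype=float)
    else:
        rows = list(profiles)
        lens = {np.asarray(r).size for r in rows}
        if len(lens) > 1:
            raise ValueError("mismatched condition sets across profiles")
        mat = np.asarray(rows, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 profiles")
    n_total = n_conditions_total or mat.shape[1]
    if not np.isnan(mat).any():
        return float(pdist(mat, metric="euclidean").mean())
    dists = []
    n_dropped = 0
    for i in range(mat.shape[0]):
        for j in range(i + 1, mat.shape[0]):
            shared = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            k = int(shared.sum())
            if k < min_shared_fraction * n_total:
                n_dropped += 1
                continue
            d = np.linalg.norm(mat[i, shared] - mat[j, shared])
            dists.append(d * np.sqrt(n_total / k))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} pair(s) sharing < {min_shared_fraction:.0%} of "
            "conditions dropped",
            stacklevel=2,
        )
    if not dists:
        return float("nan")
    return float(np.mean(dists))


def jaccard_distance(a, b) -> float:
    """1 - |A n B| / |A u B|; two empty sets are identical (distance 0)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def mutational_distance(clone_sets, feature_space=None) -> float:
    """Mean pairwise Jaccard distance between replicate mutation profiles.

    ``clone_sets`` holds, per replicate, the set of mutated genes and GO
    categories.  ``feature_space`` (everything mutated at least once across
    all clones) restricts the comparison; features outside the space are
    ignored.  Features absent from both members of a pair do not affect the
    Jaccard distance, so enlarging the space with unseen features is a no-op.
    """
    sets = [set(s) for s in clone_sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 profiles")
    if feature_space is not None:
        space = set(feature_space)
        sets = [s & space for s in sets]
    dists = [
        jaccard_distance(sets[i], sets[j])
        for i in range(len(sets))
        for j in range(i + 1, len(sets))
    ]
    return float(np.mean(dists))


def build_distance_report(
    phenotypes_by_genotype: dict | None = None,
    mutation_sets_by_genotype: dict | None = None,
    feature_space=None,
) -> pd.DataFrame:
    """Per-genotype mean pairwise distances (phenotypic and/or mutational).

    Genotypes with fewer than two surviving replicates are excluded with a
    warning.  Returns a DataFrame indexed by genotype with columns
    phenotypic_distance, mutational_distance, n_replicates (where inputs were
    given).
    """
    genotypes = set()
    if phenotypes_by_genotype:
        genotypes |= set(phenotypes_by_genotype)
    if mutation_sets_by_genotype:
        genotypes |= set(mutation_sets_by_genotype)
    if feature_space is None and mutation_sets_by_genotype:
        feature_space = set().union(
            *(set(s) for sets in mutation_sets_by_genotype.values() for s in sets)
        )
    rows = {}
    excluded = []
    for g in sorted(genotypes):
        row = {}
        n_rep = None
        if phenotypes_by_genotype and g in phenotypes_by_genotype:
            prof = phenotypes_by_genotype[g]
            n_rep = len(prof)
            if n_rep >= 2:
                row["phenotypic_distance"] = phenotypic_distance(prof)
        if mutation_sets_by_genotype and g in mutation_sets_by_genotype:
            sets = mutation_sets_by_genotype[g]
            n_rep = len(sets) if n_rep is None else n_rep
            if len(sets) >= 2:
                row["mutational_distance"] = mutational_distance(sets, feature_space)
        if row:
            row["n_replicates"] = n_rep
            rows[g] = row
        else:
            excluded.append(g)
    if excluded:
        warnings.warn(
            f"{len(excluded)} genotype(s) with < 2 replicates excluded",
            stacklevel=2,
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def _ols_fit(x: np.ndarray, y: np.ndarray, n_removed: int = 0) -> LinearFit:
    exog = sm.add_constant(x)
    fit = sm.OLS(y, exog).fit()
    ci = fit.conf_int(alpha=0.05)
    r = float(np.corrcoef(x, y)[0, 1]) if x.size > 1 and np.std(x) > 0 else float("nan")
    return LinearFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(fit.pvalues[1]),
        r=r,
        n=int(fit.nobs),
        n_removed=n_removed,
    )


def distance_vs_degree(
    distances: pd.Series | dict,
    degrees: dict,
    n_bins: int = 3,
    distance_col: str = "phenotypic_distance",
):
    """Relate per-genotype distance to the deleted gene's interaction degree.

    Genotypes are binned into ``n_bins`` quantile bins of log10(degree + 1)
    (tertiles by default); consecutive and extreme bins are compared by Welch
    t-tests, and an OLS fit of distance on log10(degree + 1) is returned.
    Returns (tests DataFrame, LinearFit).
    """
    if isinstance(distances, pd.DataFrame):
        distances = distances[distance_col]
    s = pd.Series(distances, dtype=float).dropna()
    common = [g for g in s.index if g in degrees]
    if len(common) < 4:
        raise ValueError("too few genotypes with both distance and degree")
    d = s.loc[common].to_numpy()
    logdeg = np.log10(np.array([degrees[g] for g in common], dtype=float) + 1.0)
    try:
        bins = pd.qcut(logdeg, n_bins, labels=False, duplicates="drop")
    except ValueError as exc:
        raise ValueError("cannot form degree bins") from exc
    bin_ids = [b for b in np.unique(bins) if np.sum(bins == b) >= 2]
    dropped = set(np.unique(bins)) - set(bin_ids)
    if dropped:
        warnings.warn(f"degenerate degree bin(s) excluded: {sorted(dropped)}", stacklevel=2)
    if len(bin_ids) < 2:
        raise ValueError("need >= 2 degree bins with >= 2 genotypes each")
    pairs = [(bin_ids[i], bin_ids[i + 1]) for i in range(len(bin_ids) - 1)]
    if (bin_ids[0], bin_ids[-1]) not in pairs:
        pairs.append((bin_ids[0], bin_ids[-1]))
    rows = []
    for lo, hi in pairs:
        a, b = d[bins == lo], d[bins == hi]
        t, p = stats.ttest_ind(b, a, equal_var=False)
        rows.append(
            {
                "bin_low": int(lo),
                "bin_high": int(hi),
                "n_low": a.size,
                "n_high": b.size,
                "mean_low": a.mean(),
                "mean_high": b.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows), _ols_fit(logdeg, d)


def rout_outliers(x, y, q: float = 0.01) -> np.ndarray:
    """Indices of points retained after ROUT outlier detection.

    Implements the robust-regression-plus-FDR construction: a linear fit by
    iteratively reweighted least squares with the Tukey biweight, residuals
    standardized by the robust scale estimate (RSDR, the 68.27th percentile
    of absolute residuals with a small-sample correction), and a
    Benjamini-Hochberg-style test at FDR rate ``q`` on the two-sided
    t-probabilities of the standardized residuals.  With fewer than 10 points
    no removal is attempted (warning).  ``q=0`` removes nothing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y length mismatch")
    if n < 10:
        warnings.warn("fewer than 10 points; no outlier removal", stacklevel=2)
        return np.arange(n)
    if q <= 0:
        return np.arange(n)
    k = 2  # slope + intercept
    rlm = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight()).fit()
    resid = y - rlm.predict(sm.add_constant(x))
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - k)
    if rsdr <= 0:
        return np.arange(n)
    t = resid / rsdr
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - k)
    reject = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    return np.nonzero(~reject)[0]


def distance_vs_potential(
    distances: pd.Series | dict,
    potential: dict,
    q: float = 0.01,
) -> LinearFit:
    """Linear fit of per-genotype distance on phenotypic potential.

    ``potential`` is an external per-gene measurement supplied as an input
    table.  ROUT outliers (rate ``q``) are removed before the OLS fit; the
    returned fit carries the slope with its 95% CI and the Pearson r of the
    retained points.
    """
    if isinstance(distances, pd.DataFrame):
        distances = distances["phenotypic_distance"]
    s = pd.Series(distances, dtype=float).dropna()
    common = [g for g in s.index if g in potential]
    if len(common) < 3:
        raise ValueError("too few genotypes with both distance and potential")
    x = np.array([potential[g] for g in common], dtype=float)
    y = s.loc[common].to_numpy()
    keep = rout_outliers(x, y, q=q)
    if keep.size == 0:
        raise ValueError("all points removed as outliers")
    return _ols_fit(x[keep], y[keep], n_removed=x.size - keep.size)


# ---------------------------------------------------------------------------
# File interfaces


def read_phenotypes_tsv(path) -> pd.DataFrame:
    """Clone x condition matrix of % fitness changes (first column clone)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_distance_report_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index_label="genotype")
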