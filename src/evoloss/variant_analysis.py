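"""Mutation-convergence analysis of evolved clones.

Takes already-called per-clone variant tables, applies the recurrence filters
(drop anything present in the ancestor; drop SNVs identical in more than
three independent clones and indels identical in more than one — such calls
are ambiguous), builds binary gene / GO-category mutation profiles, and tests
for convergence: per-gene recurrence against a length-proportional chance
model, competitive (permutation) gene-set enrichment, module-specific
enrichment of mutated processes, and the effect of process mutations on
evolved growth rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MutationProfile",
    "EnrichmentResult",
    "VARIANT_COLUMNS",
    "filter_variants",
    "build_profiles",
    "gene_recurrence_test",
    "competitive_set_test",
    "module_specificity_test",
    "effect_of_mutation_on_growth",
    "read_variants_tsv",
    "read_variants_vcf",
    "read_gene2go_tsv",
    "write_profiles_tsv",
]

#: columns of a variant table (TSV mirror of the minimal VCF)
VARIANT_COLUMNS = ("clone_id", "chrom", "pos", "ref", "alt", "gene", "var_class")

_GENIC = ("SNV", "indel")


@dataclass(frozen=True)
class MutationProfile:
    """Binary mutation incidence of one clone: gene set and GO-category set."""

    clone_id: str
    genes: frozenset
    go_categories: frozenset


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    statistic: float
    p_value: float
    direction: str  # "enriched" | "depleted" | "none"
    group: str = "all"

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def _check_variants(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    bad = set(df["var_class"]) - {"SNV", "indel", "aneuploidy", "ploidy"}
    if bad:
        raise ValueError(f"unknown variant classes: {sorted(bad)}")
    return df


def filter_variants(
    variants: pd.DataFrame,
    ancestor_variants: pd.DataFrame | None = None,
    snv_recurrence_max: int = 3,
    indel_recurrence_max: int = 1,
) -> pd.DataFrame:
    """Apply the ancestor and recurrence filters to a variant table.

    Any variant whose (chrom, pos, alt) matches an ancestor call is dropped.
    SNVs identical in more than ``snv_recurrence_max`` independent clones and
    indels identical in more than ``indel_recurrence_max`` clones are dropped
    from every clone (strict "more than": an SNV seen in exactly three clones
    is kept).  Aneuploidy/ploidy records are untouched.  Idempotent.
    """
    df = _check_variants(variants).copy()
    key = ["chrom", "pos", "alt"]
    if ancestor_variants is not None and len(ancestor_variants):
        anc = set(map(tuple, ancestor_variants[key].itertuples(index=False)))
        in_anc = df[key].apply(tuple, axis=1).isin(anc)
        df = df[~(in_anc & df["var_class"].isin(_GENIC))]
    limits = {"SNV": snv_recurrence_max, "indel": indel_recurrence_max}
    drop = pd.Series(False, index=df.index)
    for cls, limit in limits.items():
        sub = df[df["var_class"] == cls]
        if sub.empty:
            continue
        n_clones = sub.groupby(key)["clone_id"].nunique()
        bad_keys = set(n_clones[n_clones > limit].index)
        if bad_keys:
            drop.loc[sub.index] = sub[key].apply(tuple, axis=1).isin(bad_keys)
    return df[~drop].reset_index(drop=True)


def build_profiles(variants: pd.DataFrame, gene2go: dict) -> list[MutationProfile]:
    """Per-clone deduplicated mutated-gene set and union of GO categories.

    Only genic SNV/indel records contribute; intergenic variants (missing
    gene) and aneuploidy/ploidy records are excluded.  Genes absent from
    ``gene2go`` contribute no GO terms.
    """
    df = _check_variants(variants)
    genic = df[df["var_class"].isin(_GENIC) & df["gene"].notna()]
    profiles = []
    for clone_id in df["clone_id"].unique():
        genes = frozenset(genic.loc[genic["clone_id"] == clone_id, "gene"])
        go = frozenset().union(*(gene2go.get(g, frozenset()) for g in genes)) if genes else frozenset()
        profiles.append(
            MutationProfile(clone_id=str(clone_id), genes=genes, go_categories=frozenset(go))
        )
    return profiles


def _hit_counts(profiles) -> pd.Series:
    """Per-gene number of clones carrying a mutation in the gene."""
    counts: dict[str, int] = {}
    for p in profiles:
        for g in p.genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int)


def gene_recurrence_test(
    profiles,
    gene_lengths: dict,
    n_tests_correction: str = "BH",
    length_weighted: bool = True,
) -> pd.DataFrame:
    """How often each gene is hit versus a chance model.

    Under H0 each of the n observed gene hits lands in gene g independently
    with probability length(g)/sum(lengths) (or uniformly over genes when
    ``length_weighted=False``); the per-gene p-value is the upper-tail
    binomial probability of the observed hit count, with Benjamini-Hochberg
    q-values across genes.
    """
    lengths = pd.Series(gene_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if lengths.sum() <= 0:
        raise ValueError("zero total gene length")
    hits = _hit_counts(profiles).reindex(lengths.index, fill_value=0)
    unknown = set(_hit_counts(profiles).index) - set(lengths.index)
    if unknown:
        warnings.warn(
            f"{len(unknown)} mutated gene(s) without a length; excluded",
            stacklevel=2,
        )
    n = int(hits.sum())
    if n == 0:
        raise ValueError("no gene hits in the profiles")
    if length_weighted:
        prob = lengths / lengths.sum()
    else:
        prob = pd.Series(1.0 / len(lengths), index=lengths.index)
    pvals = stats.binom.sf(hits - 1, n, prob)
    if n_tests_correction == "BH":
        qvals = multipletests(pvals, method="fdr_bh")[1]
    elif n_tests_correction in (None, "none"):
        qvals = pvals
    else:
        raise ValueError(f"unknown correction {n_tests_correction!r}")
    return pd.DataFrame(
        {
            "observed": hits,
            "expected": n * prob,
            "p": pvals,
            "q": qvals,
        },
        index=lengths.index,
    ).sort_values("p")


def _weighted_sample_hits(
    hit_counts: np.ndarray,
    weights: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Total hits in random weighted sets of ``set_size`` genes (Gumbel top-k)."""
    logw = np.log(weights)
    keys = logw[None, :] + rng.gumbel(size=(n_perm, weights.size))
    idx = np.argpartition(-keys, set_size - 1, axis=1)[:, :set_size]
    return hit_counts[idx].sum(axis=1)


def competitive_set_test(
    profiles,
    gene_set,
    gene_lengths: dict | None = None,
    universe=None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Competitive overrepresentation of a gene set among mutated genes.

    The universe is every gene mutated at least once plus all annotated
    unmutated genes (``gene_lengths`` keys, or an explicit ``universe``).
    The statistic is the total number of clone-level hits falling in the set;
    the null draws random sets of the same size from the universe (weighted
    by gene length when lengths are given) and the p-value uses the add-one
    permutation rule.  A reimplementation of the competitive gene-set test
    idea by explicit permutation rather than the parametric original.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    hits = _hit_counts(profiles)
    if universe is None:
        universe = set(hits.index)
        if gene_lengths:
            universe |= set(gene_lengths)
    universe = sorted(universe)
    set_in = sorted(set(gene_set) & set(universe))
    if not set_in:
        warnings.warn("gene set disjoint from universe; p = 1", stacklevel=2)
        return EnrichmentResult(
            set_id=",".join(sorted(map(str, gene_set))[:3]),
            statistic=0.0,
            p_value=1.0,
            direction="none",
        )
    hit_arr = hits.reindex(universe, fill_value=0).to_numpy(float)
    if gene_lengths:
        w = pd.Series(gene_lengths, dtype=float).reindex(universe)
        w = w.fillna(w.median()).to_numpy()
    else:
        w = np.ones(len(universe))
    obs = float(hits.reindex(set_in, fill_value=0).sum())
    rng = np.random.default_rng(seed)
    null = _weighted_sample_hits(hit_arr, w, len(set_in), n_perm, rng)
    p = float((1 + np.sum(null >= obs)) / (1 + n_perm))
    direction = "enriched" if obs > null.mean() else "depleted" if obs < null.mean() else "none"
    return EnrichmentResult(
        set_id=",".join(map(str, set_in[:3])) + ("..." if len(set_in) > 3 else ""),
        statistic=obs,
        p_value=p,
        direction=direction,
    )


def module_specificity_test(
    profiles,
    clone_modules: dict,
    process_sets: dict,
    n_perm: int = 10_000,
    seed: int | None = None,
    min_clones: int = 2,
) -> pd.DataFrame:
    """Is each mutated process specific to one ancestor-module stratum?

    For every (process, ancestor module) pair the statistic is the difference
    in hit frequency (fraction of clones with >= 1 mutation in the process's
    gene set) between clones from that module and all other clones.  One-sided
    p-values come from permuting the clone -> module labels, with the add-one
    rule, and are BH-corrected across the whole matrix.  Modules with fewer
    than ``min_clones`` clones are excluded with a warning.
    """
    profiles = [p for p in profiles if p.clone_id in clone_modules]
    if not profiles:
        raise ValueError("no profiles with a module label")
    labels = np.array([clone_modules[p.clone_id] for p in profiles])
    modules, counts = np.unique(labels, return_counts=True)
    small = modules[counts < min_clones]
    if small.size:
        warnings.warn(
            f"module(s) with < {min_clones} clones excluded: {list(small)}",
            stacklevel=2,
        )
        keep = ~np.isin(labels, small)
        profiles = [p for p, k in zip(profiles, keep) if k]
        labels = labels[keep]
        modules = modules[~np.isin(modules, small)]
    if modules.size < 2:
        raise ValueError("need >= 2 ancestor modules with enough clones")

    proc_names = list(process_sets)
    hit = np.zeros((len(profiles), len(proc_names)), dtype=float)
    for i, p in enumerate(profiles):
        for j, proc in enumerate(proc_names):
            genes = process_sets[proc]
            hit[i, j] = bool(p.genes & set(genes)) or (proc in p.go_categories)

    n = len(profiles)
    group = np.zeros((modules.size, n))
    for mi, m in enumerate(modules):
        group[mi] = labels == m
    n_in = group.sum(axis=1, keepdims=True)
    n_out = n - n_in

    def _stat(h: np.ndarray) -> np.ndarray:
        in_hits = group @ h
        out_hits = h.sum(axis=0, keepdims=True) - in_hits
        return in_hits / n_in - out_hits / n_out

    obs = _stat(hit)  # modules x processes
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += _stat(hit[perm]) >= obs
    pvals = (1 + exceed) / (1 + n_perm)

    rows = []
    for mi, m in enumerate(modules):
        for j, proc in enumerate(proc_names):
            rows.append(
                {
                    "process": proc,
                    "module": m,
                    "statistic": obs[mi, j],
                    "p": pvals[mi, j],
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class GrowthEffectResult:
    mean_with: float
    mean_without: float
    t_statistic: float
    p_value: float
    n_with: int
    n_without: int
    degenerate: bool = False


def effect_of_mutation_on_growth(
    profiles, evolved_rates: dict, process_set
) -> GrowthEffectResult:
    """Welch t-test of evolved growth rates with vs without a process mutation.

    ``process_set`` is a set of genes (a clone counts as mutated when its
    gene set intersects it).  Groups of zero variance are handled by an exact
    difference report instead of an undefined t statistic.
    """
    process_set = set(process_set)
    with_mut, without = [], []
    for p in profiles:
        if p.clone_id not in evolved_rates:
            continue
        (with_mut if p.genes & process_set else without).append(
            evolved_rates[p.clone_id]
        )
    if len(with_mut) < 2 or len(without) < 2:
        raise ValueError("need >= 2 clones in each group")
    a, b = np.asarray(with_mut, float), np.asarray(without, float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        diff = a.mean() - b.mean()
        return GrowthEffectResult(
            mean_with=float(a.mean()),
            mean_without=float(b.mean()),
            t_statistic=float(np.sign(diff) * np.inf) if diff else 0.0,
            p_value=0.0 if diff else 1.0,
            n_with=a.size,
            n_without=b.size,
            degenerate=True,
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GrowthEffectResult(
        mean_with=float(a.mean()),
        mean_without=float(b.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_with=a.size,
        n_without=b.size,
    )


# ---------------------------------------------------------------------------
# File interfaces


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene" in df.columns:
        df["gene"] = df["gene"].replace({"": None, ".": None})
    return _check_variants(df)


def read_variants_vcf(path) -> pd.DataFrame:
    """Read the minimal VCF written by the generator (INFO keys CLONE, GENE,
    CLASS) into the flat variant-table layout."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            rows.append(
                {
                    "clone_id": fields.get("CLONE", ""),
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": ref,
                    "alt": alt,
                    "gene": fields.get("GENE") or None,
                    "var_class": fields.get("CLASS", "SNV"),
                }
            )
    return _check_variants(pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)))


def read_gene2go_tsv(path):
    """Annotation TSV (gene, length_bp, go_terms semicolon-joined) ->
    (gene2go dict, gene_lengths dict)."""
    df = pd.read_csv(path, sep="\t")
    gene2go = {}
    for _, r in df.iterrows():
        terms = r.get("go_terms", "")
        gene2go[r["gene"]] = (
            frozenset(str(terms).split(";")) if isinstance(terms, str) and terms else frozenset()
        )
    lengths = dict(zip(df["gene"], df["length_bp"])) if "length_bp" in df.columns else {}
    return gene2go, lengths


def write_profiles_tsv(profiles, path) -> None:
    rows = [
        {
            "clone": p.clone_id,
            "genes": ";".join(sorted(p.genes)),
            "go_terms": ";".join(sorted(p.go_categories)),
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
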