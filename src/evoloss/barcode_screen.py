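"""Pooled barcode fitness screen: read demultiplexing, TMM normalization,
log2 fold-change fitness, and sensitivity classification.

Each deletion strain carries two unique 20-mer barcodes (UPTAG/DNTAG).  Reads
are assigned to strains by locating the flanking primer sequences, extracting
the intervening tag and matching it against the library with an edit-distance
tolerance (<= 2 edits by default: mismatch, insertion or deletion).  Fitness
under stress is the log2 ratio of TMM-normalized barcode abundance in the
treated versus the untreated condition; strains with log2FC below a threshold
(-3.5 by default) are classified as sensitive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.stats import rankdata


class _Ambiguous:
    """Sentinel for a tag tied between two genes at the minimal distance."""

    def __repr__(self) -> str:  # pragma: no cover
        return "AMBIGUOUS"


AMBIGUOUS = _Ambiguous()

__all__ = [
    "AMBIGUOUS",
    "BarcodeLibrary",
    "FlankSpec",
    "CountTable",
    "extract_barcode",
    "match_barcode",
    "count_reads",
    "tmm_factors",
    "compute_fitness",
    "classify_sensitivity",
    "read_fastq",
    "read_library_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_fitness_tsv",
]


@dataclass(frozen=True)
class FlankSpec:
    """Primer sequences flanking the barcode in a read."""

    upstream: str
    downstream: str


@dataclass(frozen=True)
class BarcodeLibrary:
    """gene -> (uptag, dntag); tags must be unique across the library."""

    tags: dict[str, tuple[str, str]]
    flanks: FlankSpec | None = None

    def __post_init__(self) -> None:
        if not self.tags:
            raise ValueError("empty barcode library")
        all_tags = [t for pair in self.tags.values() for t in pair]
        if len(set(all_tags)) != len(all_tags):
            raise ValueError("barcode tags are not unique")

    def items(self):
        return self.tags.items()


@dataclass
class CountTable:
    """Strain x sample count matrix with per-sample condition labels.

    ``conditions`` maps each sample name to one of initial/control/treated.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]
    tag_counts: pd.DataFrame | None = None  # optional per-tag diagnostics

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        unknown = set(self.conditions.values()) - {"initial", "control", "treated"}
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


# ---------------------------------------------------------------------------
# Read-level assignment


def _locate(query: str, read: str, max_edits: int):
    """Best infix alignment of query in read; (start, end_exclusive) or None."""
    res = edlib.align(query, read, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end + 1


def extract_barcode(read: str, flank_spec: FlankSpec, max_flank_edits: int = 1):
    """Substring between the two flanking primers, or None.

    Each flank is located by best infix alignment allowing up to
    ``max_flank_edits`` edits; absence of either flank (or a zero-length
    insert) yields None, which callers count as "unassigned".
    """
    up = _locate(flank_spec.upstream, read, max_flank_edits)
    if up is None:
        return None
    rest_start = up[1]
    down = _locate(flank_spec.downstream, read[rest_start:], max_flank_edits)
    if down is None:
        return None
    tag = read[rest_start : rest_start + down[0]]
    return tag or None


def match_barcode(tag: str, library: BarcodeLibrary, max_edits: int = 2):
    """Assign a tag to the gene with the closest library barcode.

    Returns the gene whose tag is at minimal edit distance <= ``max_edits``;
    ``AMBIGUOUS`` if two genes tie at that minimum; None if nothing is within
    tolerance.  With a library whose pairwise tag distances exceed
    2*max_edits, ties cannot occur and assignment is unambiguous.
    """
    best_d = max_edits + 1
    best_genes: set[str] = set()
    for gene, pair in library.items():
        for libtag in pair:
            d = edlib.align(tag, libtag, mode="NW", k=max_edits)["editDistance"]
            if d < 0:
                continue
            if d < best_d:
                best_d = d
                best_genes = {gene}
            elif d == best_d:
                best_genes.add(gene)
    if not best_genes:
        return None
    if len(best_genes) > 1:
        return AMBIGUOUS
    return next(iter(best_genes))


def count_reads(
    reads,
    library: BarcodeLibrary,
    flank_spec: FlankSpec,
    max_edits: int = 2,
    max_flank_edits: int = 1,
):
    """Assign reads to genes; returns (per-gene counts Series, stats dict).

    stats holds assigned/ambiguous/unassigned fractions (summing to 1).
    """
    counts: dict[str, int] = {g: 0 for g in library.tags}
    n_total = n_assigned = n_ambiguous = 0
    for read in reads:
        n_total += 1
        tag = extract_barcode(read, flank_spec, max_flank_edits)
        hit = match_barcode(tag, library, max_edits) if tag else None
        if hit is AMBIGUOUS:
            n_ambiguous += 1
        elif hit is not None:
            counts[hit] += 1
            n_assigned += 1
    stats = {
        "n_reads": n_total,
        "assigned": n_assigned / n_total if n_total else 0.0,
        "ambiguous": n_ambiguous / n_total if n_total else 0.0,
        "unassigned": (
            (n_total - n_assigned - n_ambiguous) / n_total if n_total else 0.0
        ),
    }
    return pd.Series(counts, name="count"), stats


# ---------------------------------------------------------------------------
# Normalization and fitness


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    Follows the published TMM definition: the reference sample is the one
    whose upper-quartile relative abundance is closest to the mean upper
    quartile; per-sample factors are weighted trimmed means of gene-wise log2
    ratios to the reference (30% log-ratio trim, 5% abundance trim,
    inverse-asymptotic-variance weights), normalized to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    zero = np.nonzero(libsize == 0)[0]
    if zero.size:
        names = [str(counts.columns[i]) for i in zero]
        raise ValueError(f"sample(s) with all-zero counts: {names}")
    uq = np.array(
        [np.quantile(mat[:, j] / libsize[j], 0.75) for j in range(mat.shape[1])]
    )
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    yr, nr = mat[:, ref], libsize[ref]
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        yk, nk = mat[:, j], libsize[j]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            continue
        m = np.log2((yk[ok] / nk) / (yr[ok] / nr))
        a = 0.5 * np.log2((yk[ok] / nk) * (yr[ok] / nr))
        # asymptotic (binomial) variance of M; weights are its inverse
        v = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        w = 1.0 / v
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_l = np.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * abundance_trim) + 1
        hi_s = n + 1 - lo_s
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if keep.any() and w[keep].sum() > 0:
            factors[j] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _cpm(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    libsize = counts.sum(axis=0)
    eff = libsize * factors.reindex(counts.columns)
    return counts / eff * 1e6


def compute_fitness(
    table: CountTable,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-strain log2FC of treated vs control normalized abundance.

    UPTAG/DNTAG counts are assumed already summed per strain (the per-tag
    table, if present, is diagnostic only).  Abundances are TMM-normalized
    counts per million; ``pseudocount`` is added to the mean CPM of each
    condition before the ratio so zero-count strains stay finite.  Returns a
    DataFrame with log2fc, se, rank (1 = most depleted) and a ``missing``
    flag for strains absent from every sample (excluded from ranking).
    """
    counts = table.counts
    treated = table.samples("treated")
    control = table.samples("control")
    if not treated or not control:
        raise ValueError("need at least one treated and one control sample")
    if factors is None:
        factors = tmm_factors(counts)
    cpm = _cpm(counts, factors)
    mean_t = cpm[treated].mean(axis=1)
    mean_c = cpm[control].mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    log_t = np.log2(cpm[treated] + pseudocount)
    log_c = np.log2(cpm[control] + pseudocount)
    se = np.sqrt(
        log_t.var(axis=1, ddof=1).fillna(0.0) / len(treated)
        + log_c.var(axis=1, ddof=1).fillna(0.0) / len(control)
    )
    missing = counts.sum(axis=1) == 0
    out = pd.DataFrame(
        {"log2fc": log2fc, "se": se, "missing": missing}, index=counts.index
    )
    out["rank"] = out.loc[~missing, "log2fc"].rank(method="first").astype("Int64")
    return out


def classify_sensitivity(fitness: pd.DataFrame, threshold: float = -3.5) -> set[str]:
    """Genes whose log2FC is strictly below the threshold."""
    ok = fitness.loc[~fitness.get("missing", False)]
    return set(ok.index[ok["log2fc"] < threshold])


# ---------------------------------------------------------------------------
# File interfaces


def read_fastq(path):
    """Yield read sequences from a FASTQ file (gzip allowed)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # quality
            yield seq


def read_library_tsv(path, flanks: FlankSpec | None = None) -> BarcodeLibrary:
    df = pd.read_csv(path, sep="\t")
    tags = {r["gene"]: (r["uptag"], r["dntag"]) for _, r in df.iterrows()}
    return BarcodeLibrary(tags=tags, flanks=flanks)


def read_counts_tsv(path) -> CountTable:
    """Counts TSV: first column strain, remaining columns named
    ``<condition>_<replicate>`` (condition in initial/control/treated)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    conditions = {c: c.rsplit("_", 1)[0] for c in df.columns}
    return CountTable(counts=df, conditions=conditions)


def write_counts_tsv(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="strain")


def write_fitness_tsv(fitness: pd.DataFrame, path, threshold: float = -3.5) -> None:
    out = fitness.copy()
    out["sensitive"] = out["log2fc"] < threshold
    out.to_csv(path, sep="\t", index_label="gene")
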