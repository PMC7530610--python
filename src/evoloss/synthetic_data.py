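"""Seeded generator for every input the pipeline consumes.

Emulates the experimental design the pipeline analyses: a panel of ~51
deletion genotypes plus wild type (4 replicate lineages each, 12 for the
wild type) evolved under chronic oxidative stress, with ~80% lineage
survival; per-clone mutation loads of ~5 SNVs and ~1 indel (Poisson), 51%
aneuploidy and 9% whole-genome ploidy increase (Bernoulli); suppressor
mutations whose target process depends on the deleted gene's network module;
evolved growth rates following a linear model in ancestral rate, module and
large-effect suppressors; and 22-condition phenotype profiles whose
between-replicate spread grows with the deleted gene's interaction degree.
It also simulates the pooled barcode screen (negative-binomial counts around
abundances that double per strain at its relative fitness) and OD600 growth
curves.

All randomness flows from one root seed; each lineage draws from a child
stream keyed by a stable hash of (genotype, replicate), so enlarging the
panel never perturbs existing lineages.  Defaults live in
``data/default_config.yaml``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .barcode_screen import BarcodeLibrary, CountTable, FlankSpec
from .growth_curves import GrowthCurve

__all__ = [
    "ConfigurationError",
    "GeneInfo",
    "NetworkSpec",
    "StrainGenotype",
    "PanelSpec",
    "EvolutionConfig",
    "SimulatedExperiment",
    "load_default_config",
    "generate_network",
    "generate_barcode_library",
    "simulate_screen",
    "simulate_reads",
    "simulate_growth_curve",
    "simulate_evolution",
    "simulate_experiment",
    "write_experiment",
]

WT_MODULE = "wild_type"
_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def _child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child stream keyed by a stable hash of ``keys``."""
    digest = hashlib.blake2b(
        "|".join(map(str, keys)).encode(), digest_size=8
    ).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "little")])
    )


def load_default_config() -> dict:
    with resources.files("evoloss.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GeneInfo:
    module: str
    submodule: str
    degree: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ConfigurationError("interaction degree must be >= 0")
        if self.length_bp <= 0:
            raise ConfigurationError("gene length must be > 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Genetic-network layout: modules with submodules, and per-gene info."""

    modules: tuple
    genes: dict

    def __post_init__(self) -> None:
        submods = {m: set(s) for m, s in self.modules}
        for gene, info in self.genes.items():
            if info.module not in submods:
                raise ConfigurationError(f"{gene}: unknown module {info.module!r}")
            if info.submodule not in submods[info.module]:
                raise ConfigurationError(
                    f"{gene}: submodule {info.submodule!r} not in {info.module!r}"
                )

    def module_of(self, gene: str) -> str:
        return self.genes[gene].module


@dataclass(frozen=True)
class StrainGenotype:
    genotype_id: str
    deleted_gene: str | None  # None for the wild type
    module: str
    submodule: str
    degree: int
    ancestral_rate: float

    @property
    def is_wild_type(self) -> bool:
        return self.deleted_gene is None


@dataclass(frozen=True)
class PanelSpec:
    genotypes: tuple
    replicates_per_deletion: int = 4
    replicates_wild_type: int = 12

    def __post_init__(self) -> None:
        for g in self.genotypes:
            if g.is_wild_type and g.module != WT_MODULE:
                raise ConfigurationError("wild type must carry the wild_type module")

    def lineages(self):
        """All (genotype, replicate-index) pairs of the design."""
        out = []
        for g in self.genotypes:
            n = self.replicates_wild_type if g.is_wild_type else self.replicates_per_deletion
            out.extend((g, r) for r in range(n))
        return out


@dataclass(frozen=True)
class EvolutionConfig:
    """Generative parameters of the evolution experiment."""

    survival_prob: float
    snv_mean: float
    indel_mean: float
    aneuploidy_prob: float
    ploidy_increase_prob: float
    n_chromosomes: int
    suppressor_matrix: dict  # module -> {process -> probability}
    process_genes: dict  # process -> tuple of suppressor genes
    large_effect_processes: tuple
    growth_intercept: float
    growth_rate_slope: float
    growth_module_effects: dict
    growth_large_effect_bonus: float
    growth_resid_sd: float
    phenotype_n_conditions: int
    phenotype_baseline_sd: float
    phenotype_degree_scaling: float
    phenotype_mean_loc: float
    phenotype_mean_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("survival_prob", "aneuploidy_prob", "ploidy_increase_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.snv_mean <= 0 or self.indel_mean < 0:
            raise ConfigurationError("mutation means must be positive")
        if self.growth_resid_sd <= 0 or self.phenotype_baseline_sd <= 0:
            raise ConfigurationError("SDs must be > 0")
        for module, row in self.suppressor_matrix.items():
            for proc, p in row.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(
                        f"suppressor probability out of [0,1] at ({module}, {proc})"
                    )
            if sum(row.values()) > self.snv_mean:
                raise ConfigurationError(
                    f"suppressor row for {module!r} exceeds the SNV budget"
                )

    def marginal_module_contrast(self, module: str) -> float:
        """Expected evolved-rate contrast of a module versus wild type at
        equal ancestral rate: module effect plus the large-effect bonus times
        the expected difference in large-effect suppressor hits."""
        def expected_large(m: str) -> float:
            row = self.suppressor_matrix[m]
            return sum(row[p] for p in self.large_effect_processes if p in row)

        return (
            self.growth_module_effects.get(module, 0.0)
            - self.growth_module_effects.get(WT_MODULE, 0.0)
            + self.growth_large_effect_bonus
            * (expected_large(module) - expected_large(WT_MODULE))
        )


@dataclass
class SimulatedExperiment:
    """All observable tables plus the ground truth that generated them.

    ``lineages`` is the ground-truth record (one row per lineage, survivors
    and casualties); non-surviving lineages carry no evolved clone data in
    ``variants``/``phenotypes``/``evolved curves``.
    """

    panel: PanelSpec
    network: NetworkSpec
    config: EvolutionConfig
    lineages: pd.DataFrame
    variants: pd.DataFrame
    phenotypes: pd.DataFrame
    gene2go: dict
    gene_lengths: dict
    gene_layout: pd.DataFrame  # gene -> chrom, start
    process_genes: dict
    curves: dict = field(default_factory=dict)  # lineage -> {"ancestral","evolved"}
    screen: CountTable | None = None


# ---------------------------------------------------------------------------
# Network, panel, annotation


def generate_network(
    n_genes: int,
    module_layout,
    degree_distribution=None,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (500, 4000),
) -> NetworkSpec:
    """Random module-structured gene network.

    ``module_layout`` is a mapping or sequence of (module, submodules);
    genes are dealt round-robin across modules and round-robin across each
    module's submodules.  ``degree_distribution`` may be a callable
    ``(rng, size) -> int array`` or None for the default lognormal, whose
    degrees span well over an order of magnitude.
    """
    if isinstance(module_layout, dict):
        layout = [(m, tuple(s)) for m, s in module_layout.items()]
    else:
        layout = [(m, tuple(s)) for m, s in module_layout]
    if not layout:
        raise ConfigurationError("empty module layout")
    if n_genes < len(layout):
        raise ConfigurationError("need at least one gene per module")
    rng = _child_rng(seed, "network")
    if degree_distribution is None:
        degrees = np.rint(rng.lognormal(mean=1.6, sigma=1.1, size=n_genes)).astype(int)
        degrees = np.maximum(degrees, 0)
    else:
        degrees = np.asarray(degree_distribution(rng, n_genes), dtype=int)
        if (degrees < 0).any():
            raise ConfigurationError("degree distribution yielded negative degrees")
    lengths = rng.integers(gene_length_range[0], gene_length_range[1], size=n_genes)
    genes = {}
    sub_counter = {m: 0 for m, _ in layout}
    for i in range(n_genes):
        module, submods = layout[i % len(layout)]
        sub = submods[sub_counter[module] % len(submods)]
        sub_counter[module] += 1
        genes[f"g{i:03d}"] = GeneInfo(
            module=module,
            submodule=sub,
            degree=int(degrees[i]),
            length_bp=int(lengths[i]),
        )
    return NetworkSpec(modules=tuple(layout), genes=genes)


def build_panel(
    network: NetworkSpec,
    replicates_per_deletion: int = 4,
    replicates_wild_type: int = 12,
    wild_type_rate: float = 0.20,
    deletion_rate_mean: float = 0.12,
    deletion_rate_sd: float = 0.05,
    min_rate: float = 0.01,
    seed: int = 0,
) -> PanelSpec:
    """Panel of one deletion genotype per network gene plus the wild type,
    with ancestral growth rates drawn per genotype."""
    rng = _child_rng(seed, "panel")
    genotypes = [
        StrainGenotype(
            genotype_id=WT_MODULE,
            deleted_gene=None,
            module=WT_MODULE,
            submodule=WT_MODULE,
            degree=0,
            ancestral_rate=wild_type_rate,
        )
    ]
    for gene, info in network.genes.items():
        rate = max(min_rate, rng.normal(deletion_rate_mean, deletion_rate_sd))
        genotypes.append(
            StrainGenotype(
                genotype_id=f"{gene}_del",
                deleted_gene=gene,
                module=info.module,
                submodule=info.submodule,
                degree=info.degree,
                ancestral_rate=float(rate),
            )
        )
    return PanelSpec(
        genotypes=tuple(genotypes),
        replicates_per_deletion=replicates_per_deletion,
        replicates_wild_type=replicates_wild_type,
    )


def build_annotation(
    network: NetworkSpec,
    process_modules: dict,
    genes_per_process: int = 6,
    n_background_genes: int = 400,
    n_chromosomes: int = 16,
    seed: int = 0,
):
    """Gene universe for variant analysis: panel genes, suppressor genes (one
    GO-like category per target process) and passenger background genes.

    Returns (gene2go, gene_lengths, gene_layout DataFrame, process_genes).
    Every gene gets a chromosome and start so simulated variants carry
    VCF-style coordinates.
    """
    rng = _child_rng(seed, "annotation")
    gene2go: dict[str, frozenset] = {}
    gene_lengths: dict[str, int] = {}
    process_genes: dict[str, tuple] = {}
    for gene, info in network.genes.items():
        gene2go[gene] = frozenset({f"GO:{info.module}", f"GO:{info.submodule}"})
        gene_lengths[gene] = info.length_bp
    for proc in process_modules:
        names = tuple(f"sup_{proc}_{i}" for i in range(genes_per_process))
        process_genes[proc] = names
        for name in names:
            gene2go[name] = frozenset({f"GO:{proc}"})
            gene_lengths[name] = int(rng.integers(600, 3000))
    for i in range(n_background_genes):
        name = f"bg{i:04d}"
        gene2go[name] = frozenset({f"GO:background_{i % 25}"})
        gene_lengths[name] = int(rng.integers(500, 4000))
    order = list(gene_lengths)
    chrom = [f"chr{(i % n_chromosomes) + 1}" for i in range(len(order))]
    start = np.zeros(len(order), dtype=int)
    offsets = {c: 1 for c in set(chrom)}
    for i, g in enumerate(order):
        start[i] = offsets[chrom[i]]
        offsets[chrom[i]] += gene_lengths[g] + 200
    layout = pd.DataFrame({"gene": order, "chrom": chrom, "start": start}).set_index(
        "gene"
    )
    return gene2go, gene_lengths, layout, process_genes


# ---------------------------------------------------------------------------
# Barcode library and screen


def generate_barcode_library(
    genes,
    barcode_length: int = 20,
    min_pairwise_edit: int = 5,
    seed: int = 0,
    flanks: FlankSpec | None = None,
    max_attempts_per_tag: int = 500,
) -> BarcodeLibrary:
    """Random UPTAG/DNTAG pairs with guaranteed pairwise separation.

    Tags are sampled and accepted only when their edit distance to every
    already-accepted tag is >= ``min_pairwise_edit`` (verified with edlib),
    which makes <=2-edit matching unambiguous when the separation exceeds
    twice the matching tolerance.  Raises ``ConfigurationError`` when the
    requested separation is impossible or sampling exhausts its retry budget.
    """
    import edlib

    genes = list(genes)
    if min_pairwise_edit > barcode_length:
        raise ConfigurationError(
            "min_pairwise_edit cannot exceed the barcode length"
        )
    rng = _child_rng(seed, "barcodes")
    accepted: list[str] = []
    n_needed = 2 * len(genes)
    while len(accepted) < n_needed:
        for _ in range(max_attempts_per_tag):
            tag = "".join(rng.choice(_BASES, size=barcode_length))
            ok = all(
                edlib.align(tag, other, mode="NW", k=min_pairwise_edit - 1)[
                    "editDistance"
                ]
                < 0
                for other in accepted
            )
            if ok:
                accepted.append(tag)
                break
        else:
            raise ConfigurationError(
                f"could not place {n_needed} barcodes of length {barcode_length} "
                f"at pairwise edit distance >= {min_pairwise_edit}"
            )
    tags = {g: (accepted[2 * i], accepted[2 * i + 1]) for i, g in enumerate(genes)}
    return BarcodeLibrary(tags=tags, flanks=flanks)


def simulate_screen(
    strains,
    fitness_effects: dict,
    n_doublings_treated: float = 18.0,
    n_doublings_control: float = 18.0,
    depth: int = 1_000_000,
    dispersion: float = 0.1,
    seed: int = 0,
    initial_jitter_sd: float = 0.5,
) -> CountTable:
    """Pooled-screen count table: two initial, two control, two treated samples.

    ``fitness_effects`` maps strain -> (control, treated) relative doubling
    rates (1.0 = pool average).  Expected abundance after D doublings is
    proportional to the initial abundance times 2^(rate * D); counts are
    negative binomial around depth * relative abundance with the given
    overdispersion (Poisson when ``dispersion`` is 0).  A strain at half the
    pool's doubling rate over 18 doublings therefore has an expected log2
    fold change of about -9 versus control.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be > 0")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    strains = list(strains)
    rng = _child_rng(seed, "screen")
    init = np.exp(rng.normal(0.0, initial_jitter_sd, size=len(strains)))
    rates = np.array(
        [fitness_effects.get(s, (1.0, 1.0)) for s in strains], dtype=float
    )
    expected = {}
    for name, props in (
        ("initial_1", init),
        ("initial_2", init),
        ("control_1", init * 2.0 ** (rates[:, 0] * n_doublings_control)),
        ("control_2", init * 2.0 ** (rates[:, 0] * n_doublings_control)),
        ("treated_1", init * 2.0 ** (rates[:, 1] * n_doublings_treated)),
        ("treated_2", init * 2.0 ** (rates[:, 1] * n_doublings_treated)),
    ):
        expected[name] = depth * props / props.sum()

    def _draw(mean):
        if dispersion == 0:
            return rng.poisson(mean)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mean))

    counts = pd.DataFrame(
        {name: _draw(mean) for name, mean in expected.items()}, index=strains
    )
    conditions = {name: name.rsplit("_", 1)[0] for name in counts.columns}
    return CountTable(counts=counts, conditions=conditions)


def simulate_reads(
    library: BarcodeLibrary,
    gene_counts: dict,
    flanks: FlankSpec,
    error_rate: float = 0.005,
    seed: int = 0,
):
    """FASTQ-like reads: pad + upstream flank + tag + downstream flank + pad,
    with uniform substitution errors injected at ``error_rate``.

    Yields (read_id, sequence) pairs; UPTAG and DNTAG reads are emitted in
    alternation per gene.
    """
    rng = _child_rng(seed, "reads")
    for gene, n in gene_counts.items():
        up, dn = library.tags[gene]
        for i in range(n):
            tag = up if i % 2 == 0 else dn
            pad5 = "".join(rng.choice(_BASES, size=4))
            pad3 = "".join(rng.choice(_BASES, size=6))
            seq = np.array(list(pad5 + flanks.upstream + tag + flanks.downstream + pad3))
            errs = np.nonzero(rng.random(seq.size) < error_rate)[0]
            for j in errs:
                seq[j] = rng.choice(_BASES[_BASES != seq[j]])
            yield f"{gene}_{i}", "".join(seq)


# ---------------------------------------------------------------------------
# Growth curves


def simulate_growth_curve(
    rate: float,
    lag: float,
    capacity: float,
    od0: float,
    t_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    model: str = "capped_exponential",
    lineage_id: str = "",
    condition_id: str = "",
) -> GrowthCurve:
    """OD600 time series from a lag + exponential growth model.

    The default model holds OD at ``od0`` through the lag, grows
    exponentially at ``rate`` and saturates at ``capacity``; its noiseless
    maximal log-slope equals ``rate`` exactly.  ``model="logistic"`` gives a
    shifted logistic instead (maximal log-slope r*(1 - od0/capacity), i.e.
    slightly below r).  Gaussian observation noise of SD ``noise_sd`` is
    added and readings are clipped at a small positive floor.
    """
    if rate <= 0 or od0 <= 0:
        raise ConfigurationError("rate and od0 must be > 0")
    if capacity < od0:
        raise ConfigurationError("capacity must be >= od0")
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("t_grid must be strictly increasing")
    dt = np.maximum(t - lag, 0.0)
    if model == "capped_exponential":
        od = np.minimum(capacity, od0 * np.exp(rate * dt))
    elif model == "logistic":
        od = capacity / (1.0 + (capacity / od0 - 1.0) * np.exp(-rate * dt))
    else:
        raise ConfigurationError(f"unknown curve model {model!r}")
    if noise_sd > 0:
        if rng is None:
            rng = _child_rng(seed, "curve", lineage_id, condition_id)
        od = od + rng.normal(0.0, noise_sd, size=od.size)
    od = np.maximum(od, 1e-6)
    return GrowthCurve(time=t, od=od, lineage_id=lineage_id, condition_id=condition_id)


# ---------------------------------------------------------------------------
# Evolution


def config_from_dict(cfg: dict, seed: int = 0) -> tuple[EvolutionConfig, dict]:
    """Build an EvolutionConfig (plus the raw dict echo) from a config dict
    shaped like ``data/default_config.yaml``."""
    sup = cfg["suppressors"]
    process_modules = dict(sup["processes"])
    modules = list(cfg["network"]["modules"]) + [WT_MODULE]
    matrix = {
        m: {
            p: (
                sup["within_module_prob"]
                if process_modules[p] == m
                else sup["background_prob"]
            )
            for p in process_modules
        }
        for m in modules
    }
    gm = cfg["growth_model"]
    ph = cfg["phenotype_model"]
    ev = cfg["evolution"]
    config = EvolutionConfig(
        survival_prob=ev["survival_prob"],
        snv_mean=ev["snv_mean"],
        indel_mean=ev["indel_mean"],
        aneuploidy_prob=ev["aneuploidy_prob"],
        ploidy_increase_prob=ev["ploidy_increase_prob"],
        n_chromosomes=ev["n_chromosomes"],
        suppressor_matrix=matrix,
        process_genes={},  # filled by simulate_experiment/build_annotation
        large_effect_processes=tuple(sup["large_effect"]),
        growth_intercept=gm["intercept"],
        growth_rate_slope=gm["rate_slope"],
        growth_module_effects=dict(gm["module_effects"]),
        growth_large_effect_bonus=gm["large_effect_bonus"],
        growth_resid_sd=gm["resid_sd"],
        phenotype_n_conditions=ph["n_conditions"],
        phenotype_baseline_sd=ph["baseline_sd"],
        phenotype_degree_scaling=ph["degree_scaling"],
        phenotype_mean_loc=ph["mean_loc"],
        phenotype_mean_sd=ph["mean_sd"],
        seed=seed,
    )
    return config, process_modules


def _random_snv(rng, layout_row, length: int):
    pos = int(layout_row["start"]) + int(rng.integers(0, length))
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return layout_row["chrom"], pos, str(ref), str(alt)


def simulate_evolution(
    panel: PanelSpec,
    network: NetworkSpec,
    config: EvolutionConfig,
    gene2go: dict | None = None,
    gene_lengths: dict | None = None,
    gene_layout: pd.DataFrame | None = None,
    include_curves: bool = True,
    curve_cfg: dict | None = None,
) -> SimulatedExperiment:
    """Run the evolution experiment for every lineage of the panel.

    Per surviving lineage: suppressor processes are drawn per the ancestor
    module's row of the suppressor matrix (independent Bernoulli per
    process) and each hit places one loss-of-function SNV in a gene of that
    process; passenger SNVs are Poisson with mean ``snv_mean`` minus the
    module's expected suppressor count, so the total per-clone SNV mean
    equals ``snv_mean``; indels are Poisson; aneuploidy and whole-genome
    ploidy increase are Bernoulli; the evolved growth rate follows the
    linear growth model plus Gaussian noise; and the phenotype profile has
    between-replicate SD ``baseline * (1 + kappa * log10(degree + 1))``
    around a genotype-level mean profile.  Dead lineages carry no clone
    data.  Every draw comes from a per-lineage child stream, so the output
    is byte-identical for a fixed seed.
    """
    if gene2go is None or gene_lengths is None or gene_layout is None:
        raise ConfigurationError(
            "simulate_evolution needs the annotation tables; "
            "use simulate_experiment or pass gene2go/gene_lengths/gene_layout"
        )
    if not config.process_genes:
        raise ConfigurationError("config.process_genes is empty; build the annotation first")

    bg_genes = [g for g in gene_lengths if g.startswith("bg")]
    if not bg_genes:
        raise ConfigurationError("annotation has no background genes")
    bg_len = np.array([gene_lengths[g] for g in bg_genes], dtype=float)
    bg_w = bg_len / bg_len.sum()
    curve_cfg = curve_cfg or {}
    t_grid = np.arange(
        0.0, curve_cfg.get("t_max_h", 48.0) + 1e-9, curve_cfg.get("dt_h", 0.25)
    )

    lineage_rows = []
    variant_rows = []
    pheno_rows = {}
    curves: dict[str, dict] = {}
    genotype_means: dict[str, np.ndarray] = {}

    for genotype, rep in panel.lineages():
        lid = f"{genotype.genotype_id}_r{rep}"
        rng = _child_rng(config.seed, "lineage", genotype.genotype_id, rep)
        survived = bool(rng.random() < config.survival_prob)
        row = config.suppressor_matrix[genotype.module]
        record = {
            "lineage_id": lid,
            "genotype_id": genotype.genotype_id,
            "replicate": rep,
            "module": genotype.module,
            "submodule": genotype.submodule,
            "degree": genotype.degree,
            "deleted_gene": genotype.deleted_gene,
            "ancestral_rate": genotype.ancestral_rate,
            "survived": survived,
        }
        if include_curves:
            curves[lid] = {
                "ancestral": simulate_growth_curve(
                    rate=genotype.ancestral_rate,
                    lag=2.0,
                    capacity=curve_cfg.get("capacity", 1.4),
                    od0=curve_cfg.get("od0", 0.05),
                    t_grid=t_grid,
                    noise_sd=curve_cfg.get("noise_sd", 0.003),
                    rng=rng,
                    lineage_id=lid,
                    condition_id="ancestral",
                )
            }
        if not survived:
            record.update(
                evolved_rate=np.nan,
                n_snv=0,
                n_indel=0,
                aneuploidy=False,
                aneuploid_chrom=None,
                ploidy_increase=False,
                processes_hit=(),
                n_large_effect=0,
            )
            lineage_rows.append(record)
            continue

        procs_hit = tuple(p for p in row if rng.random() < row[p])
        for proc in procs_hit:
            gene = str(rng.choice(np.asarray(config.process_genes[proc])))
            chrom, pos, ref, alt = _random_snv(
                rng, gene_layout.loc[gene], gene_lengths[gene]
            )
            variant_rows.append(
                dict(clone_id=lid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     gene=gene, var_class="SNV")
            )
        n_bg = int(rng.poisson(config.snv_mean - sum(row.values())))
        for gene in rng.choice(np.asarray(bg_genes), size=n_bg, p=bg_w):
            gene = str(gene)
            chrom, pos, ref, alt = _random_snv(
                rng, gene_layout.loc[gene], gene_lengths[gene]
            )
            variant_rows.append(
                dict(clone_id=lid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     gene=gene, var_class="SNV")
            )
        n_indel = int(rng.poisson(config.indel_mean))
        for gene in rng.choice(np.asarray(bg_genes), size=n_indel, p=bg_w):
            gene = str(gene)
            layout_row = gene_layout.loc[gene]
            pos = int(layout_row["start"]) + int(rng.integers(0, gene_lengths[gene]))
            base = str(rng.choice(_BASES))
            ins = str(rng.choice(_BASES))
            if rng.random() < 0.5:
                ref, alt = base, base + ins
            else:
                ref, alt = base + ins, base
            variant_rows.append(
                dict(clone_id=lid, chrom=layout_row["chrom"], pos=pos, ref=ref,
                     alt=alt, gene=gene, var_class="indel")
            )
        aneuploid = bool(rng.random() < config.aneuploidy_prob)
        aneuploid_chrom = None
        if aneuploid:
            aneuploid_chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
            variant_rows.append(
                dict(clone_id=lid, chrom=aneuploid_chrom, pos=1, ref="N",
                     alt="<DUP>", gene=None, var_class="aneuploidy")
            )
        ploidy_up = bool(rng.random() < config.ploidy_increase_prob)
        if ploidy_up:
            variant_rows.append(
                dict(clone_id=lid, chrom="genome", pos=1, ref="N", alt="<DUP>",
                     gene=None, var_class="ploidy")
            )

        n_large = sum(1 for p in procs_hit if p in config.large_effect_processes)
        evolved_rate = (
            config.growth_intercept
            + config.growth_rate_slope * genotype.ancestral_rate
            + config.growth_module_effects.get(genotype.module, 0.0)
            + config.growth_large_effect_bonus * n_large
            + rng.normal(0.0, config.growth_resid_sd)
        )
        evolved_rate = float(max(evolved_rate, 0.005))

        gid = genotype.genotype_id
        if gid not in genotype_means:
            grng = _child_rng(config.seed, "phenomean", gid)
            genotype_means[gid] = grng.normal(
                config.phenotype_mean_loc,
                config.phenotype_mean_sd,
                size=config.phenotype_n_conditions,
            )
        sd = config.phenotype_baseline_sd * (
            1.0 + config.phenotype_degree_scaling * np.log10(genotype.degree + 1.0)
        )
        pheno_rows[lid] = genotype_means[gid] + rng.normal(
            0.0, sd, size=config.phenotype_n_conditions
        )

        if include_curves:
            curves[lid]["evolved"] = simulate_growth_curve(
                rate=evolved_rate,
                lag=2.0,
                capacity=curve_cfg.get("capacity", 1.4),
                od0=curve_cfg.get("od0", 0.05),
                t_grid=t_grid,
                noise_sd=curve_cfg.get("noise_sd", 0.003),
                rng=rng,
                lineage_id=lid,
                condition_id="evolved",
            )

        record.update(
            evolved_rate=evolved_rate,
            n_snv=len(procs_hit) + n_bg,
            n_indel=n_indel,
            aneuploidy=aneuploid,
            aneuploid_chrom=aneuploid_chrom,
            ploidy_increase=ploidy_up,
            processes_hit=procs_hit,
            n_large_effect=n_large,
        )
        lineage_rows.append(record)

    lineages = pd.DataFrame(lineage_rows)
    variants = pd.DataFrame(
        variant_rows,
        columns=["clone_id", "chrom", "pos", "ref", "alt", "gene", "var_class"],
    )
    phenotypes = pd.DataFrame.from_dict(
        pheno_rows,
        orient="index",
        columns=[f"cond_{i:02d}" for i in range(config.phenotype_n_conditions)],
    )
    return SimulatedExperiment(
        panel=panel,
        network=network,
        config=config,
        lineages=lineages,
        variants=variants,
        phenotypes=phenotypes,
        gene2go=gene2go,
        gene_lengths=gene_lengths,
        gene_layout=gene_layout,
        process_genes=config.process_genes,
        curves=curves,
    )


def simulate_experiment(
    cfg: dict | None = None,
    seed: int = 0,
    n_deletion_genotypes: int | None = None,
    replicates_per_deletion: int | None = None,
    replicates_wild_type: int | None = None,
    include_curves: bool = True,
    include_screen: bool = False,
) -> SimulatedExperiment:
    """End-to-end generation with the default (or a custom) configuration."""
    cfg = cfg or load_default_config()
    pan = cfg["panel"]
    net_cfg = cfg["network"]
    n_genes = n_deletion_genotypes or pan["n_deletion_genotypes"]
    network = generate_network(
        n_genes=n_genes,
        module_layout=net_cfg["modules"],
        seed=seed,
        gene_length_range=(
            net_cfg["gene_length_bp"]["low"],
            net_cfg["gene_length_bp"]["high"],
        ),
    )
    rates = cfg["ancestral_rates"]
    panel = build_panel(
        network,
        replicates_per_deletion=replicates_per_deletion or pan["replicates_per_deletion"],
        replicates_wild_type=replicates_wild_type or pan["replicates_wild_type"],
        wild_type_rate=rates["wild_type"],
        deletion_rate_mean=rates["deletion_mean"],
        deletion_rate_sd=rates["deletion_sd"],
        min_rate=rates["min_rate"],
        seed=seed,
    )
    config, process_modules = config_from_dict(cfg, seed=seed)
    gene2go, gene_lengths, layout, process_genes = build_annotation(
        network,
        process_modules,
        genes_per_process=cfg["suppressors"]["genes_per_process"],
        n_background_genes=cfg["background_genes"]["n"],
        n_chromosomes=config.n_chromosomes,
        seed=seed,
    )
    config = EvolutionConfig(
        **{
            **{f.name: getattr(config, f.name) for f in config.__dataclass_fields__.values()},
            "process_genes": process_genes,
        }
    )
    exp = simulate_evolution(
        panel,
        network,
        config,
        gene2go=gene2go,
        gene_lengths=gene_lengths,
        gene_layout=layout,
        include_curves=include_curves,
        curve_cfg=cfg.get("curves"),
    )
    if include_screen:
        scr = cfg["screen"]
        wt_rate = rates["wild_type"]
        effects = {
            g.genotype_id: (1.0, min(1.1, g.ancestral_rate / wt_rate))
            for g in panel.genotypes
        }
        exp.screen = simulate_screen(
            [g.genotype_id for g in panel.genotypes],
            effects,
            n_doublings_treated=scr["n_doublings_treated"],
            n_doublings_control=scr["n_doublings_control"],
            depth=scr["depth"],
            dispersion=scr["dispersion"],
            seed=seed,
        )
    return exp


# ---------------------------------------------------------------------------
# Writers


def write_variants_vcf(variants: pd.DataFrame, gene_layout: pd.DataFrame, path) -> None:
    """Minimal VCF: CHROM POS ID REF ALT QUAL FILTER INFO with INFO keys
    CLONE, GENE, CLASS; plus a flat TSV mirror via write_variants_tsv."""
    chroms = sorted(set(gene_layout["chrom"]), key=lambda c: (len(c), c))
    lengths = {
        c: int(
            (gene_layout.loc[gene_layout["chrom"] == c, "start"]).max() + 10_000
        )
        for c in chroms
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLONE,Number=1,Type=String,Description="Clone id">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write(
            '##INFO=<ID=CLASS,Number=1,Type=String,'
            'Description="SNV|indel|aneuploidy|ploidy">\n'
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        fh.write("##contig=<ID=genome,length=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in variants.iterrows():
            info = f"CLONE={r['clone_id']};CLASS={r['var_class']}"
            if pd.notna(r["gene"]) and r["gene"]:
                info += f";GENE={r['gene']}"
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t"
                f".\tPASS\t{info}\n"
            )


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def write_annotation_tsv(
    network: NetworkSpec, gene2go: dict, gene_lengths: dict, path
) -> None:
    rows = []
    for gene in gene_lengths:
        info = network.genes.get(gene)
        rows.append(
            {
                "gene": gene,
                "module": info.module if info else "",
                "submodule": info.submodule if info else "",
                "degree": info.degree if info else 0,
                "length_bp": gene_lengths[gene],
                "go_terms": ";".join(sorted(gene2go.get(gene, ()))),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_curves_tsv(curves: dict, path) -> None:
    frames = []
    for lid, by_cond in curves.items():
        for cond, curve in by_cond.items():
            frames.append(
                pd.DataFrame(
                    {
                        "lineage": lid,
                        "condition": cond,
                        "time_h": curve.time,
                        "od600": curve.od,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_fastq(reads, path) -> None:
    """reads: iterable of (read_id, sequence); quality is constant Phred 37."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'F' * len(seq)}\n")


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Write every observable table of a simulated experiment to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.lineages.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    write_variants_tsv(exp.variants, outdir / "variants.tsv")
    write_variants_vcf(exp.variants, exp.gene_layout, outdir / "variants.vcf")
    exp.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index_label="clone")
    write_annotation_tsv(exp.network, exp.gene2go, exp.gene_lengths, outdir / "annotation.tsv")
    rates = exp.lineages[exp.lineages["survived"]][
        ["lineage_id", "genotype_id", "module", "ancestral_rate", "evolved_rate"]
    ]
    rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
    if exp.curves:
        write_curves_tsv(exp.curves, outdir / "curves.tsv")
    if exp.screen is not None:
        exp.screen.counts.to_csv(outdir / "screen_counts.tsv", sep="\t", index_label="strain")
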