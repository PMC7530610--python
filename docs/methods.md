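# Methods

This note documents the models and procedures implemented in `evoloss`, the
parameter choices that matter, and what the synthetic-data generator does and
does not emulate.

## The experimental design being modelled

A panel of 51 haploid deletion genotypes plus wild type is evolved under
chronic oxidative stress on a respiratory carbon source, four replicate
lineages per deletion and twelve for the wild type (~216 lineages). About
80% of lineages survive to the end of the experiment; one fit clone per
surviving lineage is sequenced and phenotyped across 22 conditions. Evolved
clones carry on average five SNVs and one indel; roughly half are aneuploid
and ~9% have doubled their genome. Suppressor mutations concentrate in
processes functionally linked to the deleted gene's network module, and the
diversity of outcomes among replicate lineages grows with the deleted gene's
genetic-interaction degree. The generator's defaults
(`src/evoloss/data/default_config.yaml`) encode exactly these quantities;
everything not pinned by the design (suppressor probabilities, growth-model
coefficients, noise scales) is an explicit, configurable invention.

## Synthetic data generator

**Randomness.** One root seed; every lineage draws from a child stream keyed
by a stable (BLAKE2) hash of (genotype, replicate), so outputs are
byte-identical across runs and adding lineages never perturbs existing ones.
Genotype-level quantities (ancestral rates, phenotype mean profiles) come
from genotype-keyed streams for the same reason.

**Network and panel.** Genes are dealt round-robin across four modules with
two submodules each; interaction degrees are lognormal (median ~5, spanning
0 to a few hundred) so degree-dependent analyses have leverage; gene lengths
are uniform on 500–4,000 bp. Ancestral growth rates: 0.20 h⁻¹ for wild type,
Normal(0.12, 0.05) truncated at 0.01 for deletion strains.

**Suppressor model.** Each module has one target process, a GO-like category
of six suppressor genes. A surviving lineage hits its ancestor module's
process with probability 0.7 and every other process with probability 0.05,
independently (the matrix rows are free parameters; rows need not sum to 1).
Each hit places one SNV in a random gene of the process. Passenger SNVs are
Poisson with mean `snv_mean − Σ(matrix row)`, placed length-proportionally in
a 400-gene background universe, so the total per-clone SNV count has mean
exactly `snv_mean` (5). Keeping suppressors inside the SNV budget is what
makes the ensemble calibration against the reported per-clone mean honest.
Indels are Poisson(1) in background genes; aneuploidy is Bernoulli(0.51)
with a uniform chromosome; whole-genome ploidy increase is Bernoulli(0.09).

**Growth after evolution.** A linear model:
`rate = 0.04 + 0.35·ancestral + module effect + 0.03·(# large-effect
process hits) + Normal(0, 0.02)`. Module effects (−0.04 … +0.06, wild type
0) plus the bonus for the two large-effect processes give between-module
variance well above the ancestral-rate contribution, reproducing the finding
that network module predicts evolved fitness better than starting fitness.
The two-tier effect-size model (ordinary vs large-effect suppressors) is an
assumption — the real distribution of suppressor effect sizes is unknown.
For parameter-recovery checks, the ground-truth module contrast is the
*marginal* one (module effect + bonus × expected large-effect-hit difference
vs wild type), computed analytically by
`EvolutionConfig.marginal_module_contrast`; OLS on (ancestral rate, module)
is unbiased for that quantity because the bonus enters additively and
independently of ancestral rate.

**Phenotypes.** Per genotype, a 22-condition mean profile is drawn
(Normal(15, 12) % fitness change per condition); each replicate clone adds
independent noise with SD `5·(1 + 0.8·log10(degree + 1))` %. This is the
generative counterpart of the degree–evolvability relation: κ = 0.8 > 0
produces a positive distance–degree slope, κ = 0 a null one.

**Screen.** Two initial, two control-final and two treated-final samples.
Strain abundance after D doublings is `init · 2^(rate·D)` (relative doubling
rates; 18 doublings by default); counts are negative binomial around
`depth × relative abundance` with overdispersion 0.1; read-level simulation
adds uniform substitution errors at 0.005. All invented, configurable.

**Growth curves.** The default curve model is lag + exponential capped at
carrying capacity, because its noiseless maximal log-slope equals the
generating rate exactly — the property the estimator contract is tested
against. A shifted-logistic model is available (`model="logistic"`); its
maximal log-slope is `r·(1 − od0/K)`, slightly below r, which is why the
estimator is only required to be within 2% of r on logistic curves with
od0 ≪ K.

**What the generator does not emulate.** Within-population clonal dynamics
across transfers (only endpoint clones are modelled), raw reads for variant
calling, linkage between mutations, condition-correlated phenotype noise,
genotype-specific survival (survival is i.i.d. Bernoulli), and real
genome annotation. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under these assumptions, not that the
pipeline's conclusions transfer verbatim to any particular real dataset.

## Analysis choices

**Growth-rate estimator.** Sliding-window log-linear regression, window of 8
points (2 h at 15-min sampling), OD floor 0.02 to stay above reader noise;
both configurable. Negative maxima are clamped to 0 and flagged (death
phases are not growth). On noisy curves the max-over-windows construction
has a small upward bias at low OD (many near-tied windows, each with slope
noise ~σ_logOD/√Sxx); raising `min_od` reduces it. Replicate summaries use
the plain mean of the replicate measurements.

**TMM.** Implemented per the published definition — reference sample by
upper-quartile closeness to the mean upper quartile; 30% two-sided log-ratio
trim, 5% abundance trim; inverse-asymptotic-variance weights; factors
normalized to geometric mean 1 — and cross-checked against
`edgeR::calcNormFactors` to 1e-5 in the test suite. A pseudocount of 0.5 on
mean CPM keeps zero-count strains finite. UPTAG/DNTAG counts are summed per
strain (the screen pools both PCRs per sample); ambiguous matches are
discarded, not fractionally assigned. Strain selection uses the log2FC
ranking itself; no parametric differential-abundance test is run.

**Exceedance test.** μ_wt and σ_wt come from wild-type replicate
measurements (sample SD, ddof = 1) or may be supplied directly. "Every data
point" means every replicate measurement of every non-wild-type strain; a
per-strain-mean mode exists as a sensitivity option for designs where
replicates should not count as independent. The add-one p-value rule keeps
p ≥ 1/(n_reps + 1), consistent with reporting "P < 0.001" at 10k reps.
Normality of the null is assumed, not robustified.

**Variant filters.** Strictly "more than": an SNV identical in exactly three
clones is kept, in four is dropped everywhere; indels identical in two or
more clones are dropped. Filtering is idempotent. Aneuploidy/ploidy records
bypass gene-level tests but stay in profile summaries. Coordinates are
1-based VCF-style. Intergenic variants contribute to no GO profile.

**Enrichment.** The competitive gene-set test is an explicit permutation
reimplementation (random same-size sets from the universe, length-weighted,
Gumbel top-k sampling), validated against the hypergeometric oracle within a
factor of 2 on balanced toys. Module specificity permutes clone→module
labels; one-sided add-one p-values are conservative under heavy ties, which
is why calibration tests assert sub-uniformity rather than exact uniformity.
The per-gene recurrence null is length-proportional binomial (a uniform
per-gene mode exists); the "expected by chance" model in the original
figure is not specified, so exact reproduction of those values is not
claimed. Benjamini–Hochberg q-values are reported alongside raw p throughout.

**Linear model.** OLS with module dummies contrasted against wild type, so
module coefficients read as deviations from the evolved wild type;
standardized coefficients center/scale continuous covariates only.
Explained variance per variable is (RSS_reduced − RSS_full)/TSS with a
nested-model F-test; categorical variables drop as blocks. Homoskedastic
errors by default (heteroskedasticity-robust CIs behind a flag would be the
obvious extension). One clone per lineage; replicate lineages are separate
rows. Mann–Whitney U is enumerated exactly (midrank rank-sums over all
subsets) for combined n ≤ 20 — exact with ties — and uses the tie-corrected
normal approximation above that.

**Distances.** Pairs of empty mutation sets get Jaccard distance 0
(identical outcomes; 0/0 is undefined). The mutational feature space is
built from everything mutated at least once across *all* clones, never per
genotype. Phenotype pairs with missing conditions are compared on shared
conditions and rescaled by √(n_total/n_shared); pairs sharing fewer than
half the conditions are dropped with a warning. Degree bins default to
tertiles of log10(degree + 1) with Welch t-tests between consecutive and
extreme bins — the exact binning of the original analysis is unstated, so
this is a documented choice. Genotypes with fewer than two surviving
replicates are excluded.

**ROUT.** Robust linear fit (IRLS, Tukey biweight via statsmodels RLM);
residuals standardized by the RSDR (68.27th percentile of absolute residuals
with an n/(n−k) small-sample correction); two-sided t-probabilities tested
by Benjamini–Hochberg at rate Q (default 1%); flagged points are removed
before the final OLS. Below 10 points nothing is removed. Q = 0 disables
removal entirely.

## Problem sizes used in the automated checks

Ensemble calibration uses 1,287 lineages (~1,030 clones); exceedance
calibration uses 500 null datasets of 50 strains × 4 observations at 2,000
null reps each (type-I) and 200 datasets with 3 strains shifted +3σ
(power); enrichment specificity and linear-model recovery use 50 and 100
regenerated default panels respectively, with 1,000-permutation enrichment
tests. These sizes keep every Monte-Carlo standard error small relative to
the tolerance being asserted while the full suite runs in well under a
minute per criterion.

## Known limitations

- The growth-rate estimator's window maximum is upward-biased on noisy flat
  curves (documented above); it is not an equivalence claim with any
  particular in-house script.
- The permutation competitive test ignores inter-gene correlation, which the
  parametric original models explicitly; on strongly co-mutated gene sets the
  permutation null is the more conservative of the two.
- Survival is genotype-independent in the generator, so it cannot reproduce
  a genotype whose replicates all die.
- ROUT is implemented from its published construction; numerical agreement
  with proprietary implementations is approximate, not exact.
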