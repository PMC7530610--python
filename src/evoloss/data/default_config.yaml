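# Default simulation configuration.
#
# The panel composition, per-clone mutation rates, survival fraction and the
# number of phenotyping conditions follow the study design this pipeline
# emulates (51 deletion genotypes + wild type; 4 replicate lineages per
# deletion, 12 for the wild type; ~80% lineage survival; on average 5 SNVs and
# 1 indel per evolved clone; 51% of clones aneuploid; 9% with a whole-genome
# ploidy increase; 22 phenotyping conditions).  Everything else (suppressor
# probabilities, growth-model coefficients, noise levels) is an invented but
# configurable parameterisation; see docs/methods.md.

panel:
  n_deletion_genotypes: 51
  replicates_per_deletion: 4
  replicates_wild_type: 12

network:
  modules:
    chromatin_organization: [H2AZ_variant, HIR_complex]
    oxidative_stress_response: [superoxide_detox, thioredoxin_system]
    vesicular_transport: [endosome, golgi]
    NAD_homeostasis: [salvage_pathway, sirtuin_regulation]
  degree_lognormal:          # genetic-interaction degree of each panel gene
    mean_log: 1.6
    sigma_log: 1.1
  gene_length_bp:
    low: 500
    high: 4000

evolution:
  survival_prob: 0.80
  snv_mean: 5.0              # per surviving clone, suppressor SNVs included
  indel_mean: 1.0
  aneuploidy_prob: 0.51
  ploidy_increase_prob: 0.09
  n_chromosomes: 16

suppressors:
  # One target process (a GO-like category of suppressor genes) per network
  # module; a lineage whose ancestor lost a gene of that module acquires a
  # loss-of-function SNV in the matching process with within_module_prob, and
  # in any other process with background_prob (independent Bernoulli draws).
  processes:
    nicotinamide_riboside_transport: NAD_homeostasis
    SPS_amino_acid_sensing: vesicular_transport
    ERAD_M: oxidative_stress_response
    histone_exchange: chromatin_organization
  within_module_prob: 0.7
  background_prob: 0.05
  genes_per_process: 6
  large_effect: [nicotinamide_riboside_transport, SPS_amino_acid_sensing]

background_genes:
  n: 400                     # non-suppressor genes that soak up passenger SNVs

growth_model:
  # evolved rate = intercept + rate_slope * ancestral rate + module effect
  #                + large_effect_bonus * (# large-effect processes hit)
  #                + Normal(0, resid_sd)
  intercept: 0.04
  rate_slope: 0.35
  module_effects:
    chromatin_organization: -0.04
    oxidative_stress_response: 0.01
    vesicular_transport: 0.02
    NAD_homeostasis: 0.06
    wild_type: 0.0
  large_effect_bonus: 0.03
  resid_sd: 0.02

ancestral_rates:             # h^-1, growth on the selective medium
  wild_type: 0.20
  deletion_mean: 0.12
  deletion_sd: 0.05
  min_rate: 0.01

phenotype_model:
  n_conditions: 22
  baseline_sd: 5.0           # % fitness change, between-replicate spread
  degree_scaling: 0.8        # kappa: sd = baseline_sd*(1+kappa*log10(degree+1))
  mean_loc: 15.0             # genotype-level mean fitness increase (%)
  mean_sd: 12.0

screen:
  depth: 1000000
  dispersion: 0.1            # negative-binomial overdispersion of counts
  n_doublings_treated: 18
  n_doublings_control: 18
  read_error_rate: 0.005

curves:
  t_max_h: 48.0
  dt_h: 0.25
  od0: 0.05
  capacity: 1.4
  noise_sd: 0.003
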