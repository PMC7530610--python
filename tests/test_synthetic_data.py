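"""Generator determinism, structural guarantees, and trivial-limit behavior."""

import numpy as np
import pandas as pd
import pytest

from evoloss import synthetic_data as sd
from evoloss.barcode_screen import tmm_factors, compute_fitness

LAYOUT3 = {"m1": ["s1"], "m2": ["s2"], "m3": ["s3"]}


class TestGenerateNetwork:
    def test_seeded_determinism(self):
        a = sd.generate_network(12, LAYOUT3, seed=1)
        b = sd.generate_network(12, LAYOUT3, seed=1)
        assert a == b

    def test_round_robin_partition(self):
        net = sd.generate_network(6, LAYOUT3, seed=0)
        per_module = {}
        for info in net.genes.values():
            per_module[info.module] = per_module.get(info.module, 0) + 1
        assert per_module == {"m1": 2, "m2": 2, "m3": 2}

    def test_constant_degree_distribution(self):
        net = sd.generate_network(
            8, LAYOUT3, degree_distribution=lambda rng, n: np.full(n, 7), seed=0
        )
        assert {info.degree for info in net.genes.values()} == {7}

    def test_default_degrees_span_an_order_of_magnitude(self):
        net = sd.generate_network(51, LAYOUT3, seed=2)
        degrees = np.array([i.degree for i in net.genes.values()])
        assert degrees.max() >= 10 * max(degrees.min(), 1)

    def test_config_errors(self):
        with pytest.raises(sd.ConfigurationError, match="empty"):
            sd.generate_network(5, {}, seed=0)
        with pytest.raises(sd.ConfigurationError, match="one gene per module"):
            sd.generate_network(2, LAYOUT3, seed=0)


class TestBarcodeLibrary:
    def test_pairwise_separation_verified_by_oracle(self):
        from test_barcode_screen import edit_distance

        lib = sd.generate_barcode_library(["a", "b", "c"], seed=4)
        tags = [t for pair in lib.tags.values() for t in pair]
        assert len(set(tags)) == 6
        for i in range(len(tags)):
            for j in range(i + 1, len(tags)):
                assert edit_distance(tags[i], tags[j]) >= 5

    def test_seeded_determinism(self):
        a = sd.generate_barcode_library(["x", "y"], seed=9)
        b = sd.generate_barcode_library(["x", "y"], seed=9)
        assert a.tags == b.tags

    def test_impossible_separation_raises(self):
        with pytest.raises(sd.ConfigurationError):
            sd.generate_barcode_library(["a"], barcode_length=20, min_pairwise_edit=21)


class TestSimulateScreen:
    def test_equal_fitness_log2fc_near_zero(self):
        strains = [f"s{i}" for i in range(40)]
        table = sd.simulate_screen(
            strains, {s: (1.0, 1.0) for s in strains}, dispersion=0.0, seed=1,
            initial_jitter_sd=0.0,
        )
        fit = compute_fitness(table, factors=tmm_factors(table.counts))
        assert fit["log2fc"].abs().max() < 0.5

    def test_half_rate_strain_expected_minus_nine(self):
        strains = [f"s{i}" for i in range(50)]
        effects = {s: (1.0, 1.0) for s in strains}
        effects["s0"] = (1.0, 0.5)
        table = sd.simulate_screen(strains, effects, dispersion=0.0, seed=2,
                                   initial_jitter_sd=0.0)
        fit = compute_fitness(table, factors=tmm_factors(table.counts))
        assert fit.loc["s0", "log2fc"] == pytest.approx(-9.0, abs=1.0)

    def test_seeded_determinism_and_design(self):
        strains = ["a", "b"]
        t1 = sd.simulate_screen(strains, {}, seed=3)
        t2 = sd.simulate_screen(strains, {}, seed=3)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        assert sorted(t1.conditions.values()).count("initial") == 2
        assert sorted(t1.conditions.values()).count("control") == 2
        assert sorted(t1.conditions.values()).count("treated") == 2

    def test_invalid_parameters(self):
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_screen(["a"], {}, depth=-1)
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_screen(["a"], {}, dispersion=-0.5)


class TestSimulateGrowthCurve:
    def test_noiseless_max_log_slope_equals_rate(self):
        from evoloss.growth_curves import estimate_growth_rate

        rate = 0.3466
        curve = sd.simulate_growth_curve(
            rate=rate, lag=1.0, capacity=100.0, od0=0.05,
            t_grid=np.arange(0, 24.01, 0.25), noise_sd=0.0,
        )
        assert estimate_growth_rate(curve).rate == pytest.approx(rate, abs=1e-9)

    def test_od0_at_capacity_is_flat(self):
        from evoloss.growth_curves import estimate_growth_rate

        curve = sd.simulate_growth_curve(
            rate=0.3, lag=0.0, capacity=0.5, od0=0.5,
            t_grid=np.arange(0, 12.01, 0.25), noise_sd=0.0,
        )
        assert estimate_growth_rate(curve).rate == 0.0

    def test_seeded_noise_determinism(self):
        kw = dict(rate=0.3, lag=0.0, capacity=1.0, od0=0.05,
                  t_grid=np.arange(0, 10.01, 0.25), noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(
            sd.simulate_growth_curve(**kw).od, sd.simulate_growth_curve(**kw).od
        )

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_growth_curve(
                rate=0.3, lag=0.0, capacity=1.0, od0=0.05,
                t_grid=np.array([0.0, 1.0, 0.5]),
            )


def _experiment_with(overrides: dict, seed=5, **kwargs):
    cfg = sd.load_default_config()
    for dotted, value in overrides.items():
        node = cfg
        *path, leaf = dotted.split(".")
        for key in path:
            node = node[key]
        node[leaf] = value
    return sd.simulate_experiment(cfg, seed=seed, include_curves=False, **kwargs)


class TestSimulateEvolution:
    def test_full_survival(self):
        exp = _experiment_with({"evolution.survival_prob": 1.0})
        assert exp.lineages["survived"].all()

    def test_zero_suppressor_matrix_empty_process_sets(self):
        exp = _experiment_with(
            {
                "suppressors.within_module_prob": 0.0,
                "suppressors.background_prob": 0.0,
            }
        )
        assert exp.lineages["processes_hit"].map(len).sum() == 0
        assert not exp.variants["gene"].fillna("").str.startswith("sup_").any()

    def test_dead_lineages_carry_no_clone_data(self, experiment):
        dead = experiment.lineages.loc[~experiment.lineages["survived"], "lineage_id"]
        assert not experiment.variants["clone_id"].isin(set(dead)).any()
        assert not experiment.phenotypes.index.isin(set(dead)).any()
        assert experiment.lineages.loc[
            ~experiment.lineages["survived"], "evolved_rate"
        ].isna().all()

    def test_byte_identical_repeat_runs(self):
        a = sd.simulate_experiment(seed=21, include_curves=False)
        b = sd.simulate_experiment(seed=21, include_curves=False)
        pd.testing.assert_frame_equal(a.lineages, b.lineages)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_adding_lineages_does_not_perturb_existing_ones(self):
        small = sd.simulate_experiment(seed=8, include_curves=False)
        big = sd.simulate_experiment(
            seed=8, include_curves=False, replicates_per_deletion=6
        )
        merged = small.lineages.merge(
            big.lineages, on="lineage_id", suffixes=("_s", "_b")
        )
        assert len(merged) == len(small.lineages)
        surv = merged[merged["survived_s"]]
        np.testing.assert_allclose(
            surv["evolved_rate_s"].to_numpy(), surv["evolved_rate_b"].to_numpy()
        )

    def test_phenotype_spread_scales_with_degree(self):
        """Between-replicate SD grows as baseline*(1 + kappa*log10(degree+1))."""
        exp = _experiment_with(
            {"evolution.survival_prob": 1.0, "phenotype_model.degree_scaling": 1.5},
            n_deletion_genotypes=60,
            replicates_per_deletion=8,
        )
        lin = exp.lineages
        rows = []
        for gid, grp in lin[lin["module"] != "wild_type"].groupby("genotype_id"):
            profiles = exp.phenotypes.loc[grp["lineage_id"]]
            rows.append((grp["degree"].iloc[0], profiles.std(ddof=1).mean()))
        df = pd.DataFrame(rows, columns=["degree", "sd"])
        lo = df[df["degree"] <= df["degree"].median()]["sd"].mean()
        hi = df[df["degree"] > df["degree"].median()]["sd"].mean()
        assert hi > lo

    def test_kappa_zero_flattens_distance_degree_slope(self):
        from evoloss import evolvability as ev

        exp = _experiment_with(
            {"evolution.survival_prob": 1.0, "phenotype_model.degree_scaling": 0.0},
            n_deletion_genotypes=150,
            replicates_per_deletion=4,
        )
        lin = exp.lineages
        phenos = {
            gid: exp.phenotypes.loc[grp["lineage_id"]]
            for gid, grp in lin[lin["module"] != "wild_type"].groupby("genotype_id")
        }
        rep = ev.build_distance_report(phenotypes_by_genotype=phenos)
        degrees = dict(zip(lin["genotype_id"], lin["degree"]))
        _, fit = ev.distance_vs_degree(rep, degrees)
        assert fit.ci_low <= 0 <= fit.ci_high

    def test_suppressor_budget_validation(self):
        with pytest.raises(sd.ConfigurationError, match="budget"):
            _experiment_with(
                {"evolution.snv_mean": 0.5, "suppressors.within_module_prob": 0.7}
            )


class TestWriters:
    def test_write_experiment_outputs(self, tmp_path):
        exp = sd.simulate_experiment(
            seed=4, n_deletion_genotypes=8, include_curves=True, include_screen=True
        )
        sd.write_experiment(exp, tmp_path)
        for name in (
            "ground_truth.tsv",
            "variants.tsv",
            "variants.vcf",
            "phenotypes.tsv",
            "annotation.tsv",
            "rates.tsv",
            "curves.tsv",
            "screen_counts.tsv",
        ):
            assert (tmp_path / name).exists(), name

    def test_fastq_phred33_format(self, tmp_path):
        path = tmp_path / "r.fq"
        sd.write_fastq([("r1", "ACGT")], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "@r1" and lines[1] == "ACGT" and lines[2] == "+"
        assert all(ord(c) - 33 >= 0 for c in lines[3]) and len(lines[3]) == 4
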