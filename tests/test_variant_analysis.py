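"""Variant filtering, mutation profiles, recurrence and enrichment tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evoloss import variant_analysis as va


def vrow(clone, chrom="chr1", pos=100, ref="A", alt="T", gene="g1", cls="SNV"):
    return dict(
        clone_id=clone, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, var_class=cls
    )


class TestFilterVariants:
    def test_ancestor_variants_removed(self):
        vs = pd.DataFrame([vrow("c1"), vrow("c1", pos=200)])
        anc = pd.DataFrame([vrow("anc")])
        out = va.filter_variants(vs, anc)
        assert list(out["pos"]) == [200]

    def test_snv_recurrence_strictly_more_than_three(self):
        kept = pd.DataFrame([vrow(f"c{i}") for i in range(3)])
        assert len(va.filter_variants(kept)) == 3
        dropped = pd.DataFrame([vrow(f"c{i}") for i in range(4)])
        assert len(va.filter_variants(dropped)) == 0

    def test_indel_recurrence_strictly_more_than_one(self):
        one = pd.DataFrame([vrow("c1", ref="AT", alt="A", cls="indel")])
        assert len(va.filter_variants(one)) == 1
        two = pd.DataFrame(
            [vrow(c, ref="AT", alt="A", cls="indel") for c in ("c1", "c2")]
        )
        assert len(va.filter_variants(two)) == 0

    def test_aneuploidy_untouched_by_recurrence(self):
        vs = pd.DataFrame(
            [vrow(f"c{i}", ref="N", alt="<DUP>", gene=None, cls="aneuploidy") for i in range(6)]
        )
        assert len(va.filter_variants(vs)) == 6

    def test_idempotent(self, rng):
        clones = [f"c{i}" for i in range(8)]
        vs = pd.DataFrame(
            [
                vrow(
                    rng.choice(clones),
                    pos=int(rng.integers(1, 6)) * 100,
                    cls=str(rng.choice(["SNV", "indel"])),
                )
                for _ in range(60)
            ]
        )
        once = va.filter_variants(vs)
        twice = va.filter_variants(once)
        pd.testing.assert_frame_equal(once, twice)


class TestBuildProfiles:
    def test_sets_and_go_union(self):
        vs = pd.DataFrame(
            [
                vrow("c1", gene="g1"),
                vrow("c1", gene="g1", pos=150),  # dedup
                vrow("c1", gene="g2", pos=300),
                vrow("c2", ref="N", alt="<DUP>", gene=None, cls="aneuploidy"),
            ]
        )
        gene2go = {"g1": {"GO:a"}, "g2": {"GO:a", "GO:b"}}
        profiles = {p.clone_id: p for p in va.build_profiles(vs, gene2go)}
        assert profiles["c1"].genes == {"g1", "g2"}
        assert profiles["c1"].go_categories == {"GO:a", "GO:b"}
        assert profiles["c2"].genes == frozenset()
        assert profiles["c2"].go_categories == frozenset()


def binom_upper_tail_oracle(n, p, k):
    """Exact enumeration of the upper-tail binomial probability."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestGeneRecurrence:
    def test_equal_lengths_hotspot(self):
        profiles = [
            va.MutationProfile(f"c{i}", frozenset({"g0"}), frozenset()) for i in range(5)
        ] + [
            va.MutationProfile(f"d{i}", frozenset({f"g{i+1}"}), frozenset())
            for i in range(5)
        ]
        lengths = {f"g{i}": 1000 for i in range(10)}
        out = va.gene_recurrence_test(profiles, lengths)
        oracle = binom_upper_tail_oracle(10, 0.1, 5)
        assert out.loc["g0", "p"] == pytest.approx(oracle, rel=1e-9)
        # independent check of the oracle itself
        assert oracle == pytest.approx(stats.binom.sf(4, 10, 0.1), rel=1e-12)
        assert oracle == pytest.approx(1.635e-3, rel=1e-3)
        assert out.loc["g0", "expected"] == pytest.approx(1.0)

    def test_monopoly_gene_and_zero_hits(self):
        profiles = [va.MutationProfile("c1", frozenset({"big"}), frozenset())]
        out = va.gene_recurrence_test(
            profiles, {"big": 1_000_000, "tiny": 1}, length_weighted=True
        )
        assert out.loc["big", "p"] == pytest.approx(1.0, rel=1e-4)
        assert out.loc["tiny", "p"] == 1.0  # zero observed hits

    def test_invalid_lengths(self):
        profiles = [va.MutationProfile("c1", frozenset({"g"}), frozenset())]
        with pytest.raises(ValueError):
            va.gene_recurrence_test(profiles, {"g": 0})


class TestCompetitiveSetTest:
    def _uniform_profiles(self, rng, n_clones=30, n_genes=40):
        genes = [f"g{i}" for i in range(n_genes)]
        return [
            va.MutationProfile(
                f"c{i}",
                frozenset(rng.choice(genes, size=3, replace=False)),
                frozenset(),
            )
            for i in range(n_clones)
        ], genes

    def test_uniform_hits_not_significant(self, rng):
        hits = 0
        for _ in range(10):
            profiles, genes = self._uniform_profiles(rng)
            res = va.competitive_set_test(
                profiles, set(genes[:8]), n_perm=500, seed=int(rng.integers(2**31))
            )
            hits += res.p_value < 0.05
        assert hits <= 2

    def test_concentrated_hits_hit_floor(self):
        profiles = [
            va.MutationProfile(f"c{i}", frozenset({"s1", "s2"}), frozenset())
            for i in range(20)
        ]
        universe = {f"g{i}" for i in range(300)} | {"s1", "s2"}
        res = va.competitive_set_test(
            profiles, {"s1", "s2"}, universe=universe, n_perm=2000, seed=1
        )
        assert res.p_value == pytest.approx(1 / 2001)

    def test_seeded_reproducible_and_disjoint(self):
        profiles = [va.MutationProfile("c1", frozenset({"g1"}), frozenset())]
        r1 = va.competitive_set_test(profiles, {"g1"}, universe={"g1", "g2"}, n_perm=100, seed=9)
        r2 = va.competitive_set_test(profiles, {"g1"}, universe={"g1", "g2"}, n_perm=100, seed=9)
        assert r1.p_value == r2.p_value
        with pytest.warns(UserWarning, match="disjoint"):
            res = va.competitive_set_test(profiles, {"zz"}, universe={"g1"}, n_perm=10, seed=0)
        assert res.p_value == 1.0


class TestModuleSpecificity:
    def _toy(self):
        # 4 clones of module M all hit the process; 16 others never do
        profiles = [
            va.MutationProfile(f"m{i}", frozenset({"p_gene"}), frozenset())
            for i in range(4)
        ] + [
            va.MutationProfile(f"o{i}", frozenset({"other"}), frozenset())
            for i in range(16)
        ]
        modules = {f"m{i}": "M" for i in range(4)}
        modules.update({f"o{i}": ("A" if i % 2 else "B") for i in range(16)})
        return profiles, modules

    def test_toy_matches_hypergeometric_oracle(self):
        profiles, modules = self._toy()
        out = va.module_specificity_test(
            profiles, modules, {"proc": {"p_gene"}}, n_perm=100_000, seed=4
        )
        p_perm = out.set_index("module").loc["M", "p"]
        # oracle: all 4 hit clones land in the 4 module-M slots
        p_oracle = 1.0 / math.comb(20, 4)
        assert p_oracle == pytest.approx(2.064e-4, rel=1e-3)
        assert p_perm <= 2 * p_oracle and p_perm >= p_oracle / 2

    def test_ubiquitous_process_not_specific(self):
        profiles = [
            va.MutationProfile(f"c{i}", frozenset({"p_gene"}), frozenset())
            for i in range(12)
        ]
        modules = {f"c{i}": ("A" if i < 6 else "B") for i in range(12)}
        out = va.module_specificity_test(
            profiles, modules, {"proc": {"p_gene"}}, n_perm=200, seed=0
        )
        assert (out["p"] > 0.9).all()

    def test_label_shuffle_destroys_signal(self, rng):
        profiles, modules = self._toy()
        clones = list(modules)
        pvals = []
        for _ in range(100):
            labels = rng.permutation([modules[c] for c in clones])
            shuffled = dict(zip(clones, labels))
            out = va.module_specificity_test(
                profiles, shuffled, {"proc": {"p_gene"}}, n_perm=300,
                seed=int(rng.integers(2**31)),
            )
            pvals.append(out.set_index("module").loc["M", "p"])
        assert np.median(pvals) > 0.1

    def test_small_module_excluded_with_warning(self):
        profiles, modules = self._toy()
        modules["m0"] = "lonely"
        profiles = [p for p in profiles if p.clone_id != "m0"] + [
            va.MutationProfile("m0", frozenset({"p_gene"}), frozenset())
        ]
        with pytest.warns(UserWarning, match="lonely"):
            out = va.module_specificity_test(
                profiles, modules, {"proc": {"p_gene"}}, n_perm=100, seed=0
            )
        assert "lonely" not in set(out["module"])

    def test_permutation_p_uniform_under_null(self, rng):
        """Empirical CDF of permutation p-values under label-randomized data."""
        genes = [f"g{i}" for i in range(10)]
        pvals = []
        for _ in range(150):
            profiles = [
                va.MutationProfile(
                    f"c{i}",
                    frozenset(rng.choice(genes, size=2, replace=False)),
                    frozenset(),
                )
                for i in range(20)
            ]
            modules = {f"c{i}": ("A" if rng.random() < 0.5 else "B") for i in range(20)}
            if min(sum(m == "A" for m in modules.values()),
                   sum(m == "B" for m in modules.values())) < 2:
                continue
            out = va.module_specificity_test(
                profiles, modules, {"proc": set(genes[:3])}, n_perm=200,
                seed=int(rng.integers(2**31)),
            )
            pvals.append(out.set_index("module").loc["A", "p"])
        pvals = np.asarray(pvals)
        assert pvals.min() >= 1 / 201
        # valid (conservative) under the null: never anti-conservative beyond
        # Monte-Carlo slack; discreteness of the statistic makes exact
        # uniformity unattainable, so only sub-uniformity is asserted,
        # plus non-degeneracy (small p-values do occur).
        for thr in (0.05, 0.1, 0.25, 0.5):
            assert np.mean(pvals <= thr) <= thr + 0.06
        assert np.mean(pvals <= 0.5) > 0.15


class TestGrowthEffect:
    def test_identical_groups(self):
        profiles = [
            va.MutationProfile(c, frozenset({"p"} if c in "ab" else {"x"}), frozenset())
            for c in "abcd"
        ]
        rates = {c: 0.2 for c in "abcd"}
        res = va.effect_of_mutation_on_growth(profiles, rates, {"p"})
        assert res.t_statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_zero_variance_distinct_means(self):
        profiles = [
            va.MutationProfile(c, frozenset({"p"} if c in "abc" else {"x"}), frozenset())
            for c in "abcdef"
        ]
        rates = dict(zip("abcdef", [0.3, 0.3, 0.3, 0.1, 0.1, 0.1]))
        res = va.effect_of_mutation_on_growth(profiles, rates, {"p"})
        assert res.degenerate and res.p_value == 0.0
        assert res.mean_with - res.mean_without == pytest.approx(0.2)

    def test_power_at_two_pooled_sd(self, rng):
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.normal(0.2 + 2 * 0.03, 0.03, 20)
            b = rng.normal(0.2, 0.03, 20)
            _, p = stats.ttest_ind(a, b, equal_var=False)
            profiles = [
                va.MutationProfile(f"a{i}", frozenset({"p"}), frozenset()) for i in range(20)
            ] + [
                va.MutationProfile(f"b{i}", frozenset({"x"}), frozenset()) for i in range(20)
            ]
            rates = {f"a{i}": a[i] for i in range(20)} | {f"b{i}": b[i] for i in range(20)}
            res = va.effect_of_mutation_on_growth(profiles, rates, {"p"})
            assert res.p_value == pytest.approx(p)
            hits += res.p_value < 0.01
        assert hits >= 0.95 * n_sim

    def test_empty_group_raises(self):
        profiles = [va.MutationProfile("a", frozenset({"p"}), frozenset())] * 3
        with pytest.raises(ValueError):
            va.effect_of_mutation_on_growth(profiles, {"a": 0.1}, {"p"})


class TestIO:
    def test_vcf_round_trip(self, tmp_path, experiment):
        from evoloss import synthetic_data as sd

        path = tmp_path / "v.vcf"
        sd.write_variants_vcf(experiment.variants, experiment.gene_layout, path)
        back = va.read_variants_vcf(path)
        assert len(back) == len(experiment.variants)
        orig = experiment.variants.reset_index(drop=True)
        assert (back["clone_id"] == orig["clone_id"]).all()
        assert (back["var_class"] == orig["var_class"]).all()
        assert (back["pos"] == orig["pos"]).all()

    def test_annotation_round_trip(self, tmp_path, experiment):
        from evoloss import synthetic_data as sd

        path = tmp_path / "ann.tsv"
        sd.write_annotation_tsv(
            experiment.network, experiment.gene2go, experiment.gene_lengths, path
        )
        gene2go, lengths = va.read_gene2go_tsv(path)
        assert lengths == experiment.gene_lengths
        some_gene = next(iter(experiment.network.genes))
        assert gene2go[some_gene] == experiment.gene2go[some_gene]
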