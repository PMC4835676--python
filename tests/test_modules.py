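"""Module construction, epistasis classification, FDR, cis/trans, graph."""

import math
from math import comb

import numpy as np
import pytest

import poem
from poem.grouping import CoAssociationGroup, GroupingSolution
from poem.matrices import P_FLOOR

from conftest import make_genotypes, make_traits


def brute_force_overlap(n1, n2, k, l):
    """Independent oracle: exact hypergeometric tail by binomial summation."""
    return sum(
        comb(n1, i) * comb(l - n1, n2 - i) for i in range(k, min(n1, n2) + 1)
    ) / comb(l, n2)


def group(traits, rep, score=5.0):
    return CoAssociationGroup(tuple(traits), rep, score)


class TestOverlapPvalue:
    def test_forced_total_overlap_is_certain(self):
        assert poem.overlap_pvalue(5, 5, 5, 5) == pytest.approx(1.0)

    def test_zero_overlap_is_certain(self):
        assert poem.overlap_pvalue(4, 6, 0, 30) == 1.0

    def test_point_mass_closed_form(self):
        # All five draws marked: P = 1 / C(100, 5).
        assert poem.overlap_pvalue(5, 5, 5, 100) == pytest.approx(1 / comb(100, 5), rel=1e-9)

    @pytest.mark.parametrize("n1,n2,k,l", [(3, 4, 2, 10), (6, 6, 3, 18), (10, 8, 5, 20)])
    def test_matches_brute_force(self, n1, n2, k, l):
        assert poem.overlap_pvalue(n1, n2, k, l) == pytest.approx(
            brute_force_overlap(n1, n2, k, l), rel=1e-10
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            poem.overlap_pvalue(5, 3, 4, 10)


class TestBuildPoemodules:
    def test_disjoint_families_give_no_modules(self):
        c_P = GroupingSolution([group(["a", "b", "c"], "v0")])
        c_S = GroupingSolution([group(["x", "y", "z"], "v1")])
        assert poem.build_poemodules(c_P, c_S, l=50) == []

    def test_large_overlap_retained(self):
        traits = [f"t{i}" for i in range(10)]
        c_P = GroupingSolution([group(traits, "v0")])
        c_S = GroupingSolution([group(traits, "v1")])
        (mod,) = poem.build_poemodules(c_P, c_S, l=80)
        assert mod.trait_ids == frozenset(traits)
        assert mod.overlap_P < 1e-3
        assert {mod.primary_variant, mod.secondary_variant} == {"v0", "v1"}

    def test_pair_overlap_needs_stringent_cutoff(self):
        # Two shared traits, P ~ 3.2e-4: would pass the >=3-trait cutoff but
        # the pair-size rule demands 1e-6, so the module is rejected.
        c_P = GroupingSolution([group(["a", "b"], "v0")])
        c_S = GroupingSolution([group(["a", "b"], "v1")])
        p = poem.overlap_pvalue(2, 2, 2, 80)
        assert 1e-6 < p < 1e-3
        assert poem.build_poemodules(c_P, c_S, l=80) == []
        assert len(poem.build_poemodules(c_P, c_S, l=80, cutoff_pairs=1e-3)) == 1

    def test_identical_representatives_not_tested(self):
        traits = [f"t{i}" for i in range(10)]
        c_P = GroupingSolution([group(traits, "v0")])
        c_S = GroupingSolution([group(traits, "v0")])
        assert poem.build_poemodules(c_P, c_S, l=80) == []

    def test_mirrored_orientations_unite(self):
        """A symmetric pairwise program split across both role orientations
        is reported once, with the union of the traits."""
        c_P = GroupingSolution(
            [group(["a", "b", "c", "d"], "v0"), group(["e", "f", "g"], "v1")]
        )
        c_S = GroupingSolution(
            [group(["a", "b", "c", "d"], "v1"), group(["e", "f", "g"], "v0")]
        )
        (mod,) = poem.build_poemodules(c_P, c_S, l=80)
        assert mod.trait_ids == frozenset("abcdefg")
        assert mod.variant_pair == {"v0", "v1"}
        ordered = poem.build_poemodules(c_P, c_S, l=80, merge_mirrored=False)
        assert {m.trait_ids for m in ordered} == {frozenset("abcd"), frozenset("efg")}

    def test_stricter_cutoffs_never_add_modules(self):
        traits = [f"t{i}" for i in range(6)]
        c_P = GroupingSolution([group(traits, "v0")])
        c_S = GroupingSolution([group(traits[:4], "v1")])
        loose = poem.build_poemodules(c_P, c_S, l=60, cutoff_larger=1e-2)
        tight = poem.build_poemodules(c_P, c_S, l=60, cutoff_larger=1e-8)
        assert len(tight) <= len(loose)


class TestRemoveNested:
    def _mod(self, traits, p, pair=("v0", "v1")):
        return poem.PoeModule(
            trait_ids=frozenset(traits),
            primary_variant=pair[0],
            secondary_variant=pair[1],
            overlap_P=p,
            primary_group_size=len(traits),
            secondary_group_size=len(traits),
        )

    def test_strict_subset_dropped(self):
        kept = poem.remove_nested(
            [self._mod(["a", "b"], 1e-8), self._mod(["a", "b", "c"], 1e-5, ("v2", "v3"))]
        )
        assert [sorted(m.trait_ids) for m in kept] == [["a", "b", "c"]]

    def test_identical_sets_keep_most_significant(self):
        kept = poem.remove_nested(
            [self._mod(["a", "b"], 1e-7), self._mod(["a", "b"], 1e-9, ("v2", "v3"))]
        )
        (mod,) = kept
        assert mod.overlap_P == 1e-9

    def test_incomparable_modules_all_retained(self):
        mods = [
            self._mod(["a", "b"], 1e-8),
            self._mod(["b", "c"], 1e-8, ("v2", "v3")),
            self._mod(["d", "e"], 1e-8, ("v4", "v5")),
        ]
        assert len(poem.remove_nested(mods)) == 3


class TestEpistasisScore:
    def test_pure_interaction_floors(self, rng):
        G = make_genotypes(rng, 40, 2)
        g1, g2 = G.values[:, 0], G.values[:, 1]
        assert poem.epistasis_score(g1 * g2, g1, g2) == P_FLOOR

    def test_pure_additive_is_null(self, rng):
        G = make_genotypes(rng, 40, 2)
        g1, g2 = G.values[:, 0], G.values[:, 1]
        assert poem.epistasis_score(g1 + g2, g1, g2) == 1.0

    def test_identical_loci_rejected(self, rng):
        G = make_genotypes(rng, 20, 1)
        g = G.values[:, 0]
        with pytest.raises(ValueError, match="differ"):
            poem.epistasis_score(g.copy(), g, g.copy())

    def test_collinear_design_reports_one(self):
        # With g2 = -g1 the interaction column is constant: untestable.
        g1 = np.array([1.0, -1.0] * 6)
        g2 = -g1
        y = np.random.default_rng(0).normal(size=12)
        assert poem.epistasis_score(y, g1, g2) == 1.0

    def test_null_interaction_pvalues_uniform(self):
        """Additive truth at gamma=0.6, sigma2=0.5: interaction P ~ U(0,1)."""
        from scipy import stats

        pvals = []
        for rep in range(400):
            rng = np.random.default_rng(900 + rep)
            g1 = rng.choice((-1.0, 1.0), 50)
            g2 = rng.choice((-1.0, 1.0), 50)
            y = 0.6 * g1 + 0.6 * g2 + rng.normal(0, np.sqrt(0.5), 50)
            pvals.append(poem.epistasis_score(y, g1, g2))
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestClassifyEpistatic:
    def test_empty_module_set(self, rng):
        G = make_genotypes(rng, 20, 2)
        Y = make_traits(rng.normal(size=(20, 1)), G.individual_ids)
        assert poem.classify_epistatic([], Y, G) == []

    def test_planted_interaction_flags_module(self, rng):
        G = make_genotypes(rng, 100, 4)
        g1, g2 = G.values[:, 0], G.values[:, 1]
        y_epi = 1.4 * g1 * g2 + rng.normal(0, 0.7, 100)
        y_add = g1 + g2 + rng.normal(0, 0.7, 100)
        Y = make_traits(np.column_stack([y_epi, y_add]), G.individual_ids)
        mods = [
            poem.PoeModule(frozenset(["t0"]), "v0", "v1", 1e-8, 1, 1),
            poem.PoeModule(frozenset(["t1"]), "v0", "v1", 1e-8, 1, 1),
        ]
        out = poem.classify_epistatic(mods, Y, G)
        flags = {sorted(m.trait_ids)[0]: m.is_epistatic for m in out}
        assert flags == {"t0": True, "t1": False}

    def test_additive_truth_rarely_flags(self):
        """Across many purely additive collections, epistatic calls at
        FDR 0.01 are (essentially) absent."""
        n_flagged = 0
        for s in range(10):
            Y, G, _ = poem.simulate_collection(
                poem.SimulationSpec(gamma=1.0, n_individuals=100), seed=600 + s
            )
            model = poem.run_poem_pipeline(Y, G, poem.PoemParams(k=1))
            n_flagged += sum(bool(m.is_epistatic) for m in model.modules)
        assert n_flagged == 0


class TestCisTrans:
    def _setup(self, rng):
        chrom = ["1", "2", "3", "3"]
        pos = [5_000_000, 50_000_000, 1_000_000, 40_000_000]
        G = make_genotypes(rng, 20, 4, chrom=chrom, pos=pos)
        values = rng.normal(size=(20, 3))
        Y = poem.TraitMatrix(
            values,
            ["tA", "tB", "tC"],
            G.individual_ids,
            gene_chrom=["5", "1", "3"],
            gene_pos_bp=[1_000_000, 9_000_000, 2_000_000],
        )
        return Y, G

    def _mod(self, traits, pair):
        return poem.PoeModule(frozenset(traits), pair[0], pair[1], 1e-9, 3, 3)

    def test_all_trans_module(self, rng):
        Y, G = self._setup(rng)
        mod = poem.classify_cis_trans(self._mod(["tA"], ("v0", "v1")), G, Y)
        assert mod.trait_pair_class == {"tA": "trans-trans"}
        assert mod.cis_trans_label == "trans-acting"

    def test_nearby_locus_is_cis(self, rng):
        Y, G = self._setup(rng)
        # v0 (chr1:5Mb) is 4 Mbp from tB's gene (chr1:9Mb): cis.
        mod = poem.classify_cis_trans(self._mod(["tB"], ("v0", "v1")), G, Y)
        assert mod.trait_pair_class == {"tB": "cis-trans"}
        assert mod.cis_trans_label == "cis-acting"

    def test_boundary_fraction_gets_no_label(self, rng):
        """Trans-trans fraction exactly at the threshold: neither label."""
        Y, G = self._setup(rng)
        mod = poem.classify_cis_trans(
            self._mod(["tA", "tB", "tC"], ("v0", "v1")), G, Y, trans_fraction=2 / 3
        )
        # tA trans-trans, tB cis-trans, tC: v0/v1 on chr 1/2, gene chr3 -> trans-trans.
        assert sorted(mod.trait_pair_class.values()) == [
            "cis-trans", "trans-trans", "trans-trans",
        ]
        assert mod.cis_trans_label == "unannotated"

    def test_cis_window_boundary_is_strict(self, rng):
        Y, G = self._setup(rng)
        # v3 (chr3:40Mb) vs tC gene (chr3:2Mb): 38 Mbp apart -> trans;
        # v2 (chr3:1Mb) is 1 Mbp away -> cis.
        mod = poem.classify_cis_trans(self._mod(["tC"], ("v2", "v3")), G, Y)
        assert mod.trait_pair_class == {"tC": "cis-trans"}


class TestModuleGraph:
    def _mod(self, i, primary, secondary):
        return poem.PoeModule(frozenset([f"m{i}a", f"m{i}b"]), primary, secondary, 1e-9, 2, 2)

    def test_singleton(self):
        _, summary = poem.module_graph([self._mod(0, "v0", "v1")])
        assert [s["architecture"] for s in summary] == ["singleton"]

    def test_multifurcating_shared_secondary(self):
        mods = [self._mod(i, f"p{i}", "s_common") for i in range(5)]
        _, summary = poem.module_graph(mods)
        (comp,) = summary
        assert comp["architecture"] == "multifurcating"
        assert comp["n_modules"] == 5
        assert comp["shared_eqtls"] == [("S", "s_common")]

    def test_composite_sharing_on_both_sides(self):
        mods = [
            self._mod(0, "pX", "s1"),
            self._mod(1, "pX", "s2"),
            self._mod(2, "p3", "s2"),
            self._mod(3, "p4", "s2"),
        ]
        _, summary = poem.module_graph(mods)
        (comp,) = summary
        assert comp["architecture"] == "composite"
        assert comp["n_modules"] == 4

    def test_mixed_components(self):
        mods = [
            self._mod(0, "v0", "v1"),
            self._mod(1, "a", "shared"),
            self._mod(2, "b", "shared"),
        ]
        _, summary = poem.module_graph(mods)
        labels = sorted(s["architecture"] for s in summary)
        assert labels == ["multifurcating", "singleton"]


class TestPoemRun:
    def test_k1_equals_rbsr_for_singleton_groups(self, rng):
        """Distinct per-trait variant pairs keep every group a singleton, and
        the k=1 pair predictions coincide with RBSR's, P-values included."""
        G = make_genotypes(rng, 150, 30)
        cols = []
        for j in range(6):
            a, b = 2 * j, 2 * j + 1
            cols.append(
                2.0 * G.values[:, a] + 1.2 * G.values[:, b] + rng.normal(0, 0.4, 150)
            )
        Y = make_traits(np.column_stack(cols), G.individual_ids)
        model = poem.poem_run(Y, G, k=1)
        assert all(g.size == 1 for g in model.primary_groups.groups)
        poem_pairs = {p.trait_id: p for p in poem.pair_predictions(model)}
        rbsr_pairs = {p.trait_id: p for p in poem.rbsr(Y, G)}
        assert len(poem_pairs) == 6
        for trait_id, pp in poem_pairs.items():
            rp = rbsr_pairs[trait_id]
            assert (pp.primary_variant, pp.secondary_variant) == (
                rp.primary_variant, rp.secondary_variant,
            )
            assert pp.primary_P == pytest.approx(rp.primary_P, rel=1e-9)
            assert pp.secondary_P == pytest.approx(rp.secondary_P, rel=1e-9)

    def test_iteration_trace_counts(self):
        Y, G, _ = poem.simulate_collection(
            poem.SimulationSpec(gamma=1.0, n_individuals=80), seed=77
        )
        model = poem.poem_run(Y, G, k=3)
        stages = [t["stage"] for t in model.iteration_trace]
        assert stages == ["init", "secondary", "primary", "secondary", "primary", "secondary"]
        assert all(t["groups"] >= 0 and t["traits"] >= t["groups"] >= 0 for t in model.iteration_trace)
        for sol in (model.primary_groups, model.secondary_groups):
            assert all(g.score > 2.0 for g in sol.groups)

    def test_planted_pair_becomes_module_representatives(self):
        hits = 0
        for s in range(10):
            Y, G, truth = poem.simulate_collection(
                poem.SimulationSpec(gamma=1.4, n_individuals=150), seed=4000 + s
            )
            model = poem.run_poem_pipeline(Y, G, poem.PoemParams(k=1))
            if any(m.variant_pair == truth.variant_pair for m in model.modules):
                hits += 1
        assert hits >= 9

    def test_invalid_k_rejected(self, rng):
        G = make_genotypes(rng, 10, 2)
        Y = make_traits(rng.normal(size=(10, 1)), G.individual_ids)
        with pytest.raises(ValueError):
            poem.poem_run(Y, G, k=0)


class TestPermutationFdr:
    def test_planted_signal_has_low_fdr(self):
        Y, G, _ = poem.simulate_collection(
            poem.SimulationSpec(gamma=1.4, n_individuals=100), seed=55
        )
        res = poem.permutation_fdr(Y, G, poem.PoemParams(k=1), n_perm=3, seed=1)
        assert res.real_modules >= 1
        assert res.fdr_modules < 0.5

    def test_noise_data_reports_undefined_fdr(self, rng):
        G = make_genotypes(rng, 60, 40)
        Y = make_traits(rng.normal(size=(60, 30)), G.individual_ids)
        res = poem.permutation_fdr(Y, G, poem.PoemParams(k=1), n_perm=2, seed=2)
        assert res.real_modules == 0
        assert math.isnan(res.fdr_modules) and math.isnan(res.fdr_traits)

    def test_single_permutation_is_legal(self):
        Y, G, _ = poem.simulate_collection(
            poem.SimulationSpec(gamma=1.4, n_individuals=80), seed=56
        )
        res = poem.permutation_fdr(Y, G, poem.PoemParams(k=1), n_perm=1, seed=3)
        assert len(res.permuted_modules) == 1
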