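"""Count filtering with species rescue, normalisation, NB-Wald DE tests,
BH, quadrant classification, modules/eigengenes and Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from plastivec import expression, synthdata
from plastivec.expression import (
    bh_adjust,
    contrast_sets,
    de_test,
    detect_modules,
    filter_counts,
    go_enrichment,
    module_eigengene,
    normalize_counts,
    quadrant_classify,
)


def _meta(n_per_species=6):
    samples = [f"s{i}" for i in range(2 * n_per_species)]
    return pd.DataFrame(
        {
            "species": ["A"] * n_per_species + ["B"] * n_per_species,
            "site": ([500] * (n_per_species // 2) + [2000] * (n_per_species // 2)) * 2,
            "genotype": [f"g{i % 3}_{'A' if i < n_per_species else 'B'}" for i in range(2 * n_per_species)],
        },
        index=samples,
    )


class TestFilterCounts:
    def test_high_counts_retained(self):
        meta = _meta(6)
        c = pd.DataFrame(7, index=["g1"], columns=meta.index)
        kept, log = filter_counts(c, meta)
        assert list(kept.index) == ["g1"]
        assert log.loc["g1", "decision"] == "pass"

    def test_rescue_when_low_counts_concentrated_in_one_species(self):
        """12 samples, 8 low counts of which 7 in species A (87.5% > 75%):
        retained by the within-species rescue rule."""
        meta = _meta(6)
        counts = np.full(12, 10)
        counts[:6] = 0  # all 6 species-A samples low
        counts[6] = 0  # one species-B sample low
        counts[7] = 1  # second species-B sample low -> 8 low, 7/8 in A...
        # adjust: 7 of 8 low samples in one species requires 7 A-lows; A has 6
        # samples, so use 6+2 split = 6/8 = 75% (not >75%) vs 7/8 with n=7
        c = pd.DataFrame([counts], index=["g1"], columns=meta.index)
        kept, log = filter_counts(c, meta)
        assert log.loc["g1", "decision"] == "discarded"  # 6/8 = 75% not > 75%

        meta14 = pd.DataFrame(
            {
                "species": ["A"] * 7 + ["B"] * 7,
                "site": [500] * 14,
                "genotype": ["g"] * 14,
            },
            index=[f"s{i}" for i in range(14)],
        )
        counts = np.full(14, 10)
        counts[:7] = 0  # 7 A-samples low
        counts[7] = 0  # 1 B-sample low -> 8 low of 14 (>=50%), 7/8 = 87.5%
        c = pd.DataFrame([counts], index=["g1"], columns=meta14.index)
        kept, log = filter_counts(c, meta14)
        assert log.loc["g1", "decision"] == "rescued"
        assert "g1" in kept.index

    def test_balanced_low_counts_discarded(self):
        """8 of 12 low samples split 4/4 across species: discarded."""
        meta = _meta(6)
        counts = np.full(12, 10)
        counts[[0, 1, 2, 3, 6, 7, 8, 9]] = 2
        c = pd.DataFrame([counts], index=["g1"], columns=meta.index)
        kept, log = filter_counts(c, meta)
        assert log.loc["g1", "decision"] == "discarded"
        assert "g1" not in kept.index

    def test_permutation_invariance(self):
        meta = _meta(6)
        rng = np.random.default_rng(0)
        c = pd.DataFrame(
            rng.integers(0, 20, size=(30, 12)), columns=meta.index,
            index=[f"g{i}" for i in range(30)],
        )
        kept1, log1 = filter_counts(c, meta)
        perm = rng.permutation(12)
        kept2, log2 = filter_counts(c.iloc[:, perm], meta)
        assert list(kept1.index) == list(kept2.index)
        pd.testing.assert_series_equal(log1["decision"], log2["decision"])

    def test_invalid_fractions_rejected(self):
        meta = _meta(6)
        c = pd.DataFrame(5, index=["g1"], columns=meta.index)
        with pytest.raises(ValueError, match="min_fraction"):
            filter_counts(c, meta, min_fraction=0.0)


class TestNormalizeCounts:
    def test_doubled_sample_gets_double_factor(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]},
                         index=["g1", "g2", "g3"])
        sf, _ = normalize_counts(c)
        assert np.isclose(sf["b"] / sf["a"], 2.0)

    def test_identical_samples_equal_factors(self):
        c = pd.DataFrame({"a": [10, 20], "b": [10, 20], "c": [10, 20]},
                         index=["g1", "g2"])
        sf, _ = normalize_counts(c)
        assert np.allclose(sf, sf.iloc[0])

    def test_planted_library_size_recovered(self):
        d = synthdata.SimulationDesign(
            n_genes=800, n_genotypes_expression=3, n_clones_expression=2,
            library_size_sd=0.5, dispersion=0.05, seed=6,
        )
        counts, _ = synthdata.simulate_counts(d)
        # reconstruct the planted factors from the generator's own stream
        sf, _ = normalize_counts(counts)
        lib = counts.sum(axis=0)
        ratio = np.log(sf.to_numpy()) - (np.log(lib) - np.mean(np.log(lib))).to_numpy()
        assert np.std(ratio) < 0.06  # agree with library totals within 5%


class TestBHAdjust:
    def test_hand_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == 0.2

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_stepup_definition_and_dominates_input(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        # brute-force step-up definition
        n = len(p)
        expected = np.empty(n)
        for i in range(n):
            candidates = [
                p[j] * n / (np.sum(p <= p[j]))
                for j in range(n)
                if p[j] >= p[i]
            ]
            expected[i] = min(1.0, min(candidates))
        assert np.allclose(adj, expected, atol=1e-12)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestDeTest:
    def test_planted_interaction_sign_recovered(self):
        """A gene with a strong planted species x site interaction yields
        opposite-signed fold changes in the two species' extreme
        contrasts."""
        g = 300  # mostly-null gene set so size factors stay unbiased
        lfc_int = np.zeros(g)
        lfc_int[:20] = 3.0
        d = synthdata.SimulationDesign(
            n_genes=g, lfc_interaction=lfc_int, dispersion=0.05,
            n_genotypes_expression=6, n_clones_expression=3, seed=10,
        )
        counts, meta = synthdata.simulate_counts(d)
        sp = d.species
        de = de_test(
            counts, meta,
            contrasts={
                "A": ((sp[0], 2000), (sp[0], 500)),
                "B": ((sp[1], 2000), (sp[1], 500)),
            },
        )
        la = de["A"].table["log2fc"][:20]
        lb = de["B"].table["log2fc"][:20]
        # interaction lfc 3 with x_sp = -/+0.5 and z-range 1 => -/+1.5
        assert (np.sign(la) != np.sign(lb)).mean() >= 0.95
        assert np.isclose(la.mean(), -1.5, atol=0.3)
        assert np.isclose(lb.mean(), 1.5, atol=0.3)

    def test_untestable_gene_flagged(self):
        meta = _meta(6)
        rng = np.random.default_rng(2)
        c = pd.DataFrame(
            rng.integers(5, 50, size=(5, 12)), columns=meta.index,
            index=[f"g{i}" for i in range(5)],
        )
        c.iloc[0] = 0
        c.iloc[0, 0] = 3  # keep the sample from being all-zero in no gene
        de = de_test(c, meta, contrasts={"x": (("B", 2000), ("B", 500))})
        assert bool(de["x"].table["untestable"].iloc[0])


class TestContrastSets:
    def test_identical_sets_full_overlap(self):
        s = {"a": {"g1", "g2"}, "b": {"g1", "g2"}}
        out = contrast_sets(s)
        full = out[out.sets == "a+b"]
        assert full["n_intersection"].iloc[0] == 2
        assert full["n_exclusive"].iloc[0] == 2

    def test_disjoint_sets_no_overlap(self):
        s = {"a": {"g1"}, "b": {"g2"}, "c": {"g3"}}
        out = contrast_sets(s)
        assert (out[out.degree > 1]["n_intersection"] == 0).all()

    def test_planted_structure_counted_exactly(self):
        shared = {f"s{i}" for i in range(10)}
        only_a = {f"a{i}" for i in range(5)}
        only_b = {f"b{i}" for i in range(3)}
        out = contrast_sets({"a": shared | only_a, "b": shared | only_b})
        g = out.set_index("sets")
        assert g.loc["a+b", "n_exclusive"] == 10
        assert g.loc["a", "n_exclusive"] == 5
        assert g.loc["b", "n_exclusive"] == 3


class TestQuadrantClassify:
    def _series(self, vals):
        return pd.Series(vals, index=[f"g{i}" for i in range(len(vals))])

    def test_category_rules(self):
        lfc_a = self._series([2.0, 2.0, 2.0, 0.1, -1.0])
        sig_a = self._series([True, True, True, False, False])
        lfc_b = self._series([-2.0, 0.1, 2.0, 2.0, -0.5])
        sig_b = self._series([True, False, True, True, False])
        out = quadrant_classify(lfc_a, sig_a, lfc_b, sig_b, magnitude_delta=0.5)
        assert list(out) == [
            "opposite_direction",
            "A_specific",
            "shared_same_direction",
            "B_specific",
            "unchanged",
        ]

    def test_magnitude_divergent_within_shared(self):
        lfc_a = self._series([3.0])
        lfc_b = self._series([1.0])
        t = self._series([True])
        out = quadrant_classify(lfc_a, t, lfc_b, t, magnitude_delta=1.0)
        assert out.iloc[0] == "magnitude_divergent"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        idx = [f"g{i}" for i in range(n)]
        lfc_a = pd.Series(rng.normal(0, 2, n), index=idx)
        lfc_b = pd.Series(rng.normal(0, 2, n), index=idx)
        sig_a = pd.Series(rng.random(n) < 0.5, index=idx)
        sig_b = pd.Series(rng.random(n) < 0.5, index=idx)
        out = quadrant_classify(lfc_a, sig_a, lfc_b, sig_b)
        assert out.value_counts().sum() == n
        assert out.notna().all()


class TestModules:
    def test_planted_modules_recovered(self):
        """Two latent factors each driving 50 genes are recovered with
        adjusted Rand >= 0.9 against the planted partition."""
        g = 400  # mostly background genes keep size factors clean
        modules = np.zeros(g, dtype=int)
        modules[:50] = 1
        modules[50:100] = 2
        loadings = np.where(modules > 0, 1.2, 0.0)
        d = synthdata.SimulationDesign(
            n_genes=g, module_assignments=modules, module_factor_loadings=loadings,
            module_elevation_weight=0.0,  # independent latent factors
            module_factor_noise_sd=1.0,
            dispersion=0.05, n_genotypes_expression=6, n_clones_expression=2, seed=12,
        )
        counts, meta = synthdata.simulate_counts(d)
        _, norm = normalize_counts(counts)
        assignment, mods = detect_modules(norm, cut_height=0.4, min_module_size=20)
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(modules, assignment.to_numpy())
        assert len(mods) == 2
        assert ari >= 0.9

    def test_independent_noise_gives_no_modules(self):
        meta = _meta(6)
        rng = np.random.default_rng(3)
        norm = pd.DataFrame(
            rng.normal(size=(100, 12)), columns=meta.index,
            index=[f"g{i}" for i in range(100)],
        )
        assignment, mods = detect_modules(norm, cut_height=0.4, min_module_size=20)
        assert len(mods) == 0
        assert (assignment == 0).all()

    def test_eigengene_of_perfectly_correlated_module(self):
        meta = _meta(6)
        profile = np.linspace(-1, 1, 12)
        norm = pd.DataFrame(
            [2 * profile + 5, 3 * profile - 1, profile],
            index=["g1", "g2", "g3"], columns=meta.index,
        )
        res = module_eigengene(["g1", "g2", "g3"], norm, meta)
        assert res.explained_variance > 0.999
        stdprof = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(np.abs(res.eigengene), np.abs(stdprof), atol=1e-8)
        assert res.eigengene @ stdprof > 0  # oriented with mean expression

    def test_elevation_linked_factor_detected_per_species(self):
        """A module factor present in both species correlates with
        elevation within each species."""
        g = 80
        modules = np.zeros(g, dtype=int)
        modules[:40] = 1
        loadings = np.where(modules == 1, 1.0, 0.0)
        d = synthdata.SimulationDesign(
            n_genes=g, module_assignments=modules, module_factor_loadings=loadings,
            dispersion=0.02, n_genotypes_expression=6, n_clones_expression=2, seed=14,
        )
        counts, meta = synthdata.simulate_counts(d)
        _, norm = normalize_counts(counts)
        res = module_eigengene([f"gene{i + 1:05d}" for i in range(40)], norm, meta)
        corr = res.elevation_correlation.set_index("species")
        assert (corr["r"].abs() > 0.9).all()
        assert (corr["p_value"] < 1e-6).all()


class TestGoEnrichment:
    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        tm = pd.DataFrame({"gene": ["g0", "g1"], "term": ["GO:1", "GO:1"]})
        out = go_enrichment({"g5", "g6"}, universe, tm)
        assert np.isclose(out["p_value"].iloc[0], 1.0)

    def test_matches_hypergeometric_tail(self):
        """universe 100, term 10, DE 10, overlap 5: p equals the exact
        hypergeometric tail sum."""
        universe = {f"g{i}" for i in range(100)}
        term_genes = [f"g{i}" for i in range(10)]
        de = {f"g{i}" for i in range(5)} | {f"x{i}" for i in range(0)}
        de |= {f"g{i}" for i in range(50, 55)}  # 5 in term, 5 out
        tm = pd.DataFrame({"gene": term_genes, "term": ["GO:1"] * 10})
        out = go_enrichment(de, universe, tm)
        expected = sum(
            stats.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11)
        )
        assert np.isclose(out["p_value"].iloc[0], expected, rtol=1e-10)

    def test_de_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            go_enrichment({"zz"}, {"g1"}, pd.DataFrame({"gene": [], "term": []}))
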