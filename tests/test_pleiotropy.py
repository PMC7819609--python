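"""Phenome-wide scan, enrichment testing, and the permutation null."""

import itertools
import math

import numpy as np
import pytest

from neurotarget.instruments import make_instrument
from neurotarget.pleiotropy import (
    PhewasMatrix,
    enrichment_test,
    fisher_enrichment,
    molecular_pleiotropy,
    phewas_scan,
    sharing_permutation,
)
from neurotarget.synth import Scenario, simulate_phewas, simulate_region

from conftest import make_record


def hypergeom_two_sided(table):
    """Brute-force enumeration oracle for Fisher's exact two-sided p."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )
    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestFisherEnrichment:
    def test_printed_counts_highly_significant(self):
        # 29/1,549 brain colocalizations vs 35/7,892 other
        res = fisher_enrichment([[29, 1520], [35, 7857]])
        assert res.p < 0.0001
        assert res.p == pytest.approx(hypergeom_two_sided([[29, 1520], [35, 7857]]), rel=1e-6)

    def test_identical_proportions(self):
        assert fisher_enrichment([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_small_table_oracle(self):
        assert fisher_enrichment([[3, 0], [0, 3]]).p == pytest.approx(0.1)

    def test_agrees_with_enumeration_small_margins(self, rng):
        for _ in range(60):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            res = fisher_enrichment(t)
            assert res.p == pytest.approx(hypergeom_two_sided(t.tolist()), abs=1e-10)


class TestPhewasScan:
    def _setup(self, n_traits=3):
        inst_recs = [
            make_record(variant_id="rsA", pos=1_000_000, beta=0.12, se=0.02, gene_id="G1"),
            make_record(variant_id="rsB", pos=2_000_000, beta=-0.10, se=0.02, gene_id="G2"),
        ]
        instruments = [make_instrument(r) for r in inst_recs]
        traits = {}
        categories = {}
        for t in range(n_traits):
            tid = f"trait{t}"
            traits[tid] = [
                make_record(variant_id=v, pos=p, beta=0.001, se=0.01,
                            trait_id=tid, gene_id=None)
                for v, p in [("rsA", 1_000_000), ("rsB", 2_000_000)]
            ]
            categories[tid] = "brain" if t == 0 else "other"
        return instruments, traits, categories

    def test_cell_cardinality(self):
        instruments, traits, categories = self._setup(3)
        matrix = phewas_scan(instruments, traits, categories)
        assert matrix.n_tests == 2 * 3

    def test_no_coloc_without_nominal_p(self):
        instruments, traits, categories = self._setup(1)
        matrix = phewas_scan(instruments, traits, categories)
        # all outcome effects are null -> p > 0.05 -> no coloc attempted
        assert matrix.results["pp4"].isna().all()

    def test_planted_colocalizing_cell_detected(self):
        # one trait shares the causal variant with the gene -> only that cell passes
        sc = Scenario("shared_variant", seed=42)
        eqtl, gwas_shared, _, truth = simulate_region(sc)
        null_sc = Scenario("eqtl_only", seed=43)
        _, gwas_null, _, _ = simulate_region(null_sc)
        anchor = truth.causal_variant_ids[0]
        inst = make_instrument(next(r for r in eqtl if r.variant_id == anchor))
        traits = {
            "planted": [r for r in gwas_shared],
            "null": [r for r in gwas_null],
        }
        categories = {"planted": "brain", "null": "other"}
        matrix = phewas_scan(
            [inst], traits, categories, coloc_regions={"GENE1": eqtl}
        )
        df = matrix.results.set_index("trait_id")
        assert bool(df.loc["planted", "coloc_pass"])
        assert not bool(df.loc["null", "coloc_pass"])


class TestEnrichmentOnMatrix:
    def test_planted_brain_enrichment(self):
        matrix, _ = simulate_phewas(10, 40, brain_fraction=0.25, seed=5)
        df = matrix.results
        # plant colocalization in brain traits only
        brain = df["category"] == "brain"
        df.loc[df.index[brain][:30], "coloc_pass"] = True
        df.loc[df.index[brain][:30], "p"] = 1e-8
        res = enrichment_test(matrix, strict_alpha=6e-6)
        assert res[6e-6].p < 1e-6
        assert res[0.05].p < 1e-6


class TestSharingPermutation:
    def test_matches_exhaustive_enumeration(self):
        # 5-trait pool, subset 2: all 10 subsets enumerable exactly
        matrix, _ = simulate_phewas(20, 6, brain_fraction=1 / 6, seed=9)
        df = matrix.results
        pool = sorted(set(df.loc[df["category"] == "other", "trait_id"]))
        assert len(pool) == 5
        hits = df.groupby("trait_id")["p"].apply(lambda s: int((s < 0.05).sum()))
        cells = df.groupby("trait_id")["p"].size()
        observed = (3, 40)
        obs_prop = observed[0] / observed[1]
        exact = np.mean([
            (hits.loc[list(c)].sum() / cells.loc[list(c)].sum()) >= obs_prop
            for c in itertools.combinations(pool, 2)
        ])
        res = sharing_permutation(matrix, observed, 2, n_iter=4000, seed=3)
        mc_se = math.sqrt(max(exact * (1 - exact), 0.25 / 10) / 4000)
        assert res.empirical_p == pytest.approx(exact, abs=max(4 * mc_se, 0.02))

    def test_extreme_observation_gives_minimum_p(self):
        matrix, _ = simulate_phewas(10, 8, brain_fraction=0.25, seed=2)
        res = sharing_permutation(matrix, (100, 100), 2, n_iter=200, seed=1)
        assert res.empirical_p == pytest.approx(1 / 201)

    def test_seed_determinism(self):
        matrix, _ = simulate_phewas(10, 8, brain_fraction=0.25, seed=2)
        a = sharing_permutation(matrix, (3, 20), 2, n_iter=500, seed=7)
        b = sharing_permutation(matrix, (3, 20), 2, n_iter=500, seed=7)
        assert a.empirical_p == b.empirical_p
        np.testing.assert_array_equal(a.null_props, b.null_props)
        assert a.ci95 == b.ci95

    def test_null_mean_converges(self):
        # mean null proportion ~ per-cell hit rate of the pool (uniform p -> 5%)
        matrix, _ = simulate_phewas(50, 30, brain_fraction=0.1, seed=4)
        res = sharing_permutation(matrix, (1, 100), 5, n_iter=2000, seed=5)
        df = matrix.results
        other = df[df["category"] == "other"]
        pool_rate = (other["p"] < 0.05).mean()
        assert res.null_props.mean() == pytest.approx(pool_rate, abs=0.01)

    def test_zero_total_rejected(self):
        matrix, _ = simulate_phewas(5, 8, seed=1)
        with pytest.raises(ValueError):
            sharing_permutation(matrix, (0, 0), 2, n_iter=10, seed=1)


class TestMolecularPleiotropy:
    def test_single_gene_degree_one(self):
        eqtl = [make_record(variant_id="rsA", beta=0.2, se=0.02, gene_id="G1")]
        gwas = [make_record(variant_id="rsA", beta=0.05, se=0.01,
                            trait_id="disease", gene_id=None)]
        df = molecular_pleiotropy("rsA", eqtl, gwas)
        assert len(df) == 1

    def test_bonferroni_basis_is_extraction_count(self):
        # 1,482 extracted effects -> threshold 3.4e-5 (2 s.f.)
        from neurotarget.mr import bonferroni_threshold

        thr = bonferroni_threshold(0.05, 1482)
        assert float(f"{thr:.1e}") == pytest.approx(3.4e-5)

    def test_three_coregulated_genes_all_colocalize(self):
        # three genes share one causal variant: degree 3, all coloc-pass
        import dataclasses

        sc = Scenario("shared_variant", eqtl_pve=0.04, seed=17)
        eqtl, gwas, _, truth = simulate_region(sc)
        anchor = truth.causal_variant_ids[0]
        all_genes = []
        for g in ("G1", "G2", "G3"):  # perfectly co-regulated transcripts
            all_genes.extend(dataclasses.replace(r, gene_id=g) for r in eqtl)
        df = molecular_pleiotropy(anchor, all_genes, gwas)
        assert len(df) == 3
        assert df["passes_bonferroni"].all()
        assert df["coloc_pass"].all()

    def test_absent_variant_empty(self):
        eqtl = [make_record(variant_id="rsA", gene_id="G1")]
        assert molecular_pleiotropy("rsZ", eqtl, []).empty
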