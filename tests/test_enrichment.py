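"""Fisher enrichment, the size-matched random null, and term flagging."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from exonml import (
    AnnotationCatalog,
    fisher_enrichment,
    flag_terms,
    mirna_pathway_profile,
    random_null,
)
from exonml.enrichment import NullEnsemble


def hypergeom_tail_oracle(k, N, K, n):
    """Brute-force upper-tail hypergeometric probability."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def catalog_from(terms, n_universe, width=3):
    universe = {f"g{i:0{width}d}" for i in range(n_universe)}
    return AnnotationCatalog(
        terms={t: set(g) for t, g in terms.items()},
        universe=universe,
        meta_map={t: ["m1"] for t in terms},
    )


class TestFisherEnrichment:
    def test_matches_exhaustive_oracle_on_small_universes(self):
        # every (N, K, n) configuration with N <= 30, checked at the
        # realized overlap of a deterministic list/term layout
        for N, K, n in product((8, 15, 30), (2, 5, 8), (3, 6, 8)):
            genes = [f"g{i:03d}" for i in range(N)]
            cat = catalog_from({"t": genes[:K]}, N)
            for shift in (0, 2, K):
                gene_list = set(genes[shift : shift + n])
                if not gene_list:
                    continue
                r = fisher_enrichment(gene_list, cat)[0]
                expected = hypergeom_tail_oracle(r.overlap, N, K, len(gene_list))
                assert r.p == pytest.approx(expected, rel=1e-10), (N, K, n, shift)

    def test_disjoint_list_gives_p_one_and_zero_fold(self):
        cat = catalog_from({"t": ["g000", "g001"]}, 20)
        r = fisher_enrichment({"g010", "g011"}, cat)[0]
        assert r.p == 1.0
        assert r.fold_enrichment == 0.0
        assert r.overlap == 0

    def test_list_equal_to_term_is_minimal_p(self):
        cat = catalog_from({"t": ["g000", "g001", "g002"]}, 30)
        full = fisher_enrichment({"g000", "g001", "g002"}, cat)[0]
        partial = fisher_enrichment({"g000", "g001", "g010"}, cat)[0]
        assert full.p < partial.p
        assert full.p == pytest.approx(hypergeom_tail_oracle(3, 30, 3, 3), rel=1e-10)

    def test_fold_enrichment_identity(self):
        cat = catalog_from({"t": [f"g{i:03d}" for i in range(10)]}, 100)
        r = fisher_enrichment({f"g{i:03d}" for i in range(0, 20, 2)}, cat)[0]
        assert r.fold_enrichment == pytest.approx(
            (r.overlap / r.list_size) / (r.term_size / r.universe_size)
        )
        assert r.overlap <= min(r.list_size, r.term_size)

    def test_ease_variant_is_more_conservative(self):
        cat = catalog_from({"t": [f"g{i:03d}" for i in range(10)]}, 100)
        gene_list = {f"g{i:03d}" for i in range(5)}
        plain = fisher_enrichment(gene_list, cat)[0]
        ease = fisher_enrichment(gene_list, cat, ease=True)[0]
        assert ease.p > plain.p
        assert ease.p == pytest.approx(hypergeom_tail_oracle(4, 100, 10, 5), rel=1e-10)

    def test_out_of_universe_genes_dropped_with_warning(self, caplog):
        cat = catalog_from({"t": ["g000"]}, 10)
        with caplog.at_level("WARNING"):
            r = fisher_enrichment({"g000", "not_a_gene"}, cat)[0]
        assert r.list_size == 1
        assert "dropped" in caplog.text

    def test_empty_inputs_rejected(self):
        cat = catalog_from({"t": ["g000"]}, 10)
        with pytest.raises(ValueError):
            fisher_enrichment({"zzz"}, cat)
        with pytest.raises(ValueError):
            fisher_enrichment({"g000"}, AnnotationCatalog(terms={}, universe={"g000"}, meta_map={}))


class TestRandomNull:
    def test_same_seed_gives_identical_ensembles(self):
        cat = catalog_from({"t": [f"g{i:03d}" for i in range(20)]}, 100)
        a = random_null(cat, list_size=10, reps=100, seed=5)
        b = random_null(cat, list_size=10, reps=100, seed=5)
        pd.testing.assert_frame_equal(a.p_values, b.p_values)

    def test_well_populated_term_is_uniform(self):
        # granularity comparable to a genome-scale background: the null
        # p-vector of a well-populated term passes the uniformity check
        cat = catalog_from({"big": [f"g{i:04d}" for i in range(150)]}, 2000, width=4)
        null = random_null(cat, list_size=300, reps=1000, seed=1)
        uni = null.uniformity()
        assert uni.loc["big", "ks_distance"] < 0.1
        assert uni.loc["big", "flag"] == "clean"

    def test_tiny_term_has_discrete_nonuniform_null(self):
        # a 3-gene term in a small universe: its null p-values sit on a
        # handful of atoms and cannot look uniform
        cat = catalog_from({"tiny": ["g000", "g001", "g002"]}, 50)
        null = random_null(cat, list_size=15, reps=1000, seed=2)
        uni = null.uniformity()
        assert uni.loc["tiny", "ks_distance"] >= 0.1
        assert uni.loc["tiny", "flag"] == "enrichment-prone"
        assert null.p_values["tiny"].nunique() <= 4  # overlap in {0..3}

    def test_null_depends_only_on_term_size(self):
        genes = [f"g{i:03d}" for i in range(200)]
        cat = catalog_from({"a": genes[0:25], "b": genes[100:125]}, 200)
        null = random_null(cat, list_size=20, reps=800, seed=3)
        d = ks_2samp(null.p_values["a"], null.p_values["b"]).statistic
        assert d < 0.08

    def test_list_size_bound_and_rep_warning(self, caplog):
        cat = catalog_from({"t": ["g000"]}, 10)
        with pytest.raises(ValueError):
            random_null(cat, list_size=11)
        with caplog.at_level("WARNING"):
            random_null(cat, list_size=5, reps=10, seed=0)
        assert "unstable" in caplog.text


def make_observed(term_id, p):
    from exonml.enrichment import EnrichmentResult

    return EnrichmentResult(
        term_id=term_id, overlap=5, list_size=10, term_size=10,
        universe_size=100, fold_enrichment=5.0, p=p, p_bh=p,
    )


def make_null(term_id, p_vector):
    return NullEnsemble(p_values=pd.DataFrame({term_id: p_vector}), list_size=10)


class TestFlagTerms:
    def test_uniform_null_with_significant_p_is_validated(self):
        rng = np.random.default_rng(0)
        null = make_null("t", rng.uniform(size=1000))
        out = flag_terms([make_observed("t", 0.001)], null)
        assert out.loc["t", "verdict"] == "validated-enriched"

    def test_low_concentrated_null_is_false_discovery_prone(self):
        # 30% of null p-values below 0.05
        vec = np.concatenate([np.full(300, 0.01), np.linspace(0.1, 1, 700)])
        out = flag_terms([make_observed("t", 0.001)], make_null("t", vec))
        assert out.loc["t", "verdict"] == "false-discovery-prone"
        assert out.loc["t", "null_frac_low"] == pytest.approx(0.3)

    def test_nonsignificant_observed_is_not_enriched(self):
        rng = np.random.default_rng(1)
        out = flag_terms([make_observed("t", 0.9)], make_null("t", rng.uniform(size=500)))
        assert out.loc["t", "verdict"] == "not-enriched"

    def test_missing_term_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            flag_terms([make_observed("other", 0.01)], make_null("t", rng.uniform(size=100)))

    def test_shrinking_alpha_never_promotes_to_validated(self):
        rng = np.random.default_rng(3)
        null = make_null("t", rng.uniform(size=1000))
        for p_obs in (0.001, 0.03, 0.2, 0.9):
            verdicts = [
                flag_terms([make_observed("t", p_obs)], null, alpha=a).loc["t", "verdict"]
                for a in (0.05, 0.01, 0.001)
            ]
            for earlier, later in zip(verdicts, verdicts[1:]):
                if earlier == "not-enriched":
                    assert later == "not-enriched"


class TestMirnaPathwayProfile:
    def _catalog(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i:04d}" for i in range(1000)]
        terms = {"planted": set(genes[:120])}
        for i in range(5):
            terms[f"bg{i}"] = set(rng.choice(genes, size=100, replace=False))
        return catalog_from({k: sorted(v) for k, v in terms.items()}, 1000, width=4)

    def test_planted_target_term_is_validated(self):
        cat = self._catalog()
        profiles = mirna_pathway_profile({"mir-x": set(sorted(cat.terms["planted"])[:100])},
                                         cat, reps=400, seed=4)
        assert profiles["mir-x"].loc["planted", "verdict"] == "validated-enriched"

    def test_identical_target_sets_give_identical_profiles(self):
        cat = self._catalog()
        targets = set(list(cat.universe)[:25])
        profiles = mirna_pathway_profile({"mir-a": targets, "mir-b": targets},
                                         cat, reps=200, seed=5)
        pd.testing.assert_frame_equal(profiles["mir-a"], profiles["mir-b"])

    def test_mirna_without_universe_targets_skipped(self, caplog):
        cat = self._catalog()
        with caplog.at_level("WARNING"):
            profiles = mirna_pathway_profile({"mir-empty": {"zzz"}}, cat, reps=100, seed=6)
        assert profiles == {}
        assert "skipped" in caplog.text
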