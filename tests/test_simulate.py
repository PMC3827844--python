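"""Statistical fidelity and determinism of the synthetic fixture generators."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cdmkit import consistency, simulate


class TestStudyGenerator:
    def test_same_seed_reproduces_the_study_bit_for_bit(self):
        kw = dict(n_genes=150, seed=77)
        d1, ann1, t1 = simulate.generate_multiplatform_study(**kw)
        d2, ann2, t2 = simulate.generate_multiplatform_study(**kw)
        assert set(d1) == set(d2)
        for p in d1:
            pd.testing.assert_frame_equal(d1[p].intensities, d2[p].intensities)
        pd.testing.assert_frame_equal(ann1, ann2)
        assert t1.to_dict() == t2.to_dict()

    def test_different_seeds_differ(self):
        d1, _, _ = simulate.generate_multiplatform_study(n_genes=50, seed=1)
        d2, _, _ = simulate.generate_multiplatform_study(n_genes=50, seed=2)
        assert not d1["AFFY1"].intensities.equals(d2["AFFY1"].intensities)

    def test_null_generator_yields_uniform_welch_p_values(self):
        """With no effect, no batch structure and no artifacts, per-subset
        Welch p-values are uniform (KS test on p-values pooled over seeds)."""
        pvals = []
        for seed in range(10):
            datasets, _, _ = simulate.generate_multiplatform_study(
                n_genes=120, seed=seed, planted_fraction=0.0, effect_size=0.0,
                batch_sd=0.0, crosshyb_fraction=0.0, sporadic_fraction=0.0)
            ds = datasets["ILMN1"]
            for label, ctrl, dis in consistency.test_pairs(ds):
                log = np.log2(ds.intensities)
                for probe in log.index:
                    pvals.append(consistency.welch_test(
                        log.loc[probe, ctrl], log.loc[probe, dis]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_downregulated_fraction_matches_truth_parameter(self):
        signs = []
        for seed in range(10):
            _, _, truth = simulate.generate_multiplatform_study(
                n_genes=2000, seed=seed)
            signs.extend(truth.planted_directions.values())
        assert len(signs) == 10 * 40
        down = np.mean(np.asarray(signs) == -1)
        # 400 Bernoulli(0.8) draws: 3 sigma ~ 0.06
        assert down == pytest.approx(0.8, abs=0.06)

    def test_planted_shift_has_the_recorded_sign_and_magnitude(self):
        datasets, ann, truth = simulate.generate_multiplatform_study(
            n_genes=800, seed=3, crosshyb_fraction=0.0, sporadic_fraction=0.0,
            batch_sd=0.0)
        ds = datasets["ILMN1"]
        log = np.log2(ds.intensities)
        gene_of = dict(zip(ann.loc[ann["platform"] == "ILMN1", "probe_id"],
                           ann.loc[ann["platform"] == "ILMN1", "gene_symbol"]))
        dis = ds.condition[ds.condition == "disease"].index
        con = ds.condition[ds.condition == "control"].index
        shift = (log[dis].mean(axis=1) - log[con].mean(axis=1))
        delta = truth.effect_size * truth.params["noise_sd"]
        planted_shift = [shift[p] * truth.planted_directions[gene_of[p]]
                         for p in shift.index
                         if gene_of[p] in truth.planted_directions]
        # each signed shift estimates +delta with se = noise_sd*sqrt(2/30)
        assert np.mean(planted_shift) == pytest.approx(delta, abs=0.1)

    def test_auxiliary_platform_shares_half_the_planted_genes(self):
        _, _, truth = simulate.generate_multiplatform_study(n_genes=1000, seed=9)
        n_planted = len(truth.planted_disease_genes)
        assert len(truth.aux_shared_genes) == round(0.5 * n_planted)
        assert set(truth.aux_shared_genes) <= set(truth.planted_disease_genes)

    def test_single_platform_request_is_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_multiplatform_study(
                n_genes=10, platforms=simulate.DEFAULT_PLATFORMS[:1])


class TestGeneSetGenerator:
    def test_sizes_stay_inside_the_requested_range(self):
        genes = simulate.gene_names(400)
        gsc, _ = simulate.generate_gene_sets(genes, genes[:20],
                                             size_range=(5, 40), seed=0)
        sizes = [len(s) for s in gsc.sets.values()]
        assert min(sizes) >= 5 and max(sizes) <= 40
        assert len(gsc.sets) == 150

    def test_planted_terms_are_built_from_the_disease_pool(self):
        genes = simulate.gene_names(400)
        disease = genes[:30]
        gsc, truth = simulate.generate_gene_sets(
            genes, disease, n_planted_terms=3, planted_member_fraction=0.8, seed=1)
        assert len(truth.planted_enriched_terms) == 3
        for term in truth.planted_enriched_terms:
            members = gsc.sets[term]
            frac = len(members & set(disease)) / len(members)
            assert frac >= 0.8 - 1e-9
        # null terms carry no such guarantee on average
        null_fracs = [len(gsc.sets[t] & set(disease)) / len(gsc.sets[t])
                      for t in gsc.sets if t not in truth.planted_enriched_terms]
        assert np.mean(null_fracs) < 0.25

    def test_zero_planted_terms_gives_uniform_terms_only(self):
        genes = simulate.gene_names(100)
        _, truth = simulate.generate_gene_sets(genes, genes[:5],
                                               n_planted_terms=0, seed=2)
        assert truth.planted_enriched_terms == []

    def test_same_seed_same_collection(self):
        genes = simulate.gene_names(100)
        a, _ = simulate.generate_gene_sets(genes, genes[:5], seed=7)
        b, _ = simulate.generate_gene_sets(genes, genes[:5], seed=7)
        assert a.sets == b.sets


class TestCorpusGenerator:
    def test_fold_one_group_is_indistinguishable_from_background(self):
        universe = simulate.gene_names(500)
        group = set(universe[:50])
        corpus, _ = simulate.generate_corpus(
            universe, n_documents=3000, gene_groups={"g": group},
            association_folds={"g": {"disease": 1.0}}, seed=5)
        tagged = np.array([("disease" in t) for t in corpus["tags"]])
        in_group = np.array([not group.isdisjoint(g) for g in corpus["genes"]])
        r_group = tagged[in_group].mean()
        r_rest = tagged[~in_group].mean()
        # both estimate the base rate 0.08; 3 sigma of the difference ~ 0.05
        assert abs(r_group - r_rest) < 0.05

    def test_planted_fold_raises_the_tag_rate(self):
        universe = simulate.gene_names(500)
        group = set(universe[:50])
        corpus, truth = simulate.generate_corpus(
            universe, n_documents=3000, gene_groups={"g": group},
            association_folds={"g": {"disease": 8.0}}, seed=5)
        tagged = np.array([("disease" in t) for t in corpus["tags"]])
        in_group = np.array([not group.isdisjoint(g) for g in corpus["genes"]])
        assert tagged[in_group].mean() > 4 * tagged[~in_group].mean()
        assert truth.planted_corpus_folds == {"g": {"disease": 8.0}}

    def test_same_seed_same_corpus(self):
        universe = simulate.gene_names(100)
        a, _ = simulate.generate_corpus(universe, n_documents=200, seed=3)
        b, _ = simulate.generate_corpus(universe, n_documents=200, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestNetworkGenerator:
    def test_density_one_plants_a_clique(self):
        g, truth = simulate.generate_network(300, planted_module_size=12,
                                             planted_density=1.0, seed=4)
        module = truth.planted_module_nodes
        for a, b in itertools.combinations(module, 2):
            assert g.has_edge(a, b)

    def test_degree_tail_exponent_near_requested(self):
        """Hill MLE on the degree tail recovers the requested exponent."""
        g, _ = simulate.generate_network(5000, degree_exponent=2.5,
                                         planted_module_size=0, seed=11)
        degrees = np.array([d for _, d in g.degree if d > 0])
        k_min = 10
        tail = degrees[degrees >= k_min]
        assert len(tail) > 100
        gamma_hat = 1.0 + len(tail) / np.sum(np.log(tail / (k_min - 0.5)))
        assert gamma_hat == pytest.approx(2.5, abs=0.3)

    def test_mean_degree_near_requested(self):
        g, _ = simulate.generate_network(3000, mean_degree=6.0,
                                         planted_module_size=0, seed=2)
        mean_deg = 2 * g.number_of_edges() / g.number_of_nodes()
        assert mean_deg == pytest.approx(6.0, rel=0.25)

    def test_same_seed_same_network(self):
        a, _ = simulate.generate_network(200, seed=8)
        b, _ = simulate.generate_network(200, seed=8)
        assert nx.utils.graphs_equal(a, b)

    def test_node_list_input_is_respected(self):
        names = [f"N{i}" for i in range(50)]
        g, _ = simulate.generate_network(names, planted_module_size=5, seed=0)
        assert set(g.nodes) == set(names)
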