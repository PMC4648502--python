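import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from sigpca.core import (
    GopcaConfig,
    SignaturePCA,
    bonferroni_threshold,
    build_signature,
    enrich_ranking,
    global_filter,
    local_filter,
    order_signatures,
    rank_by_loadings,
    run_gopca,
)
from sigpca.decomposition import PcaModel, standardize
from sigpca.enrichment import EnrichmentResult
from sigpca.ontology import GeneSetCollection, Ontology, OntologyTerm

from conftest import planted_dataset


def _pca_model(loadings: dict[str, float]) -> PcaModel:
    genes = list(loadings)
    frame = pd.DataFrame({"PC1": [loadings[g] for g in genes]}, index=genes)
    return PcaModel(loadings=frame, scores=pd.DataFrame(), var_frac=np.array([1.0]), D=1)


class TestRankByLoadings:
    def test_directions(self):
        model = _pca_model({"a": 0.9, "b": -0.9})
        assert rank_by_loadings(model, 1, +1) == ["a", "b"]
        assert rank_by_loadings(model, 1, -1) == ["b", "a"]

    def test_ties_alphabetical(self):
        model = _pca_model({"z": 0.5, "a": 0.5, "m": 0.5})
        assert rank_by_loadings(model, 1, +1) == ["a", "m", "z"]

    def test_reversal_antisymmetry(self):
        model = _pca_model({"a": 0.3, "b": -0.1, "c": 0.7})
        assert rank_by_loadings(model, 1, -1) == rank_by_loadings(model, 1, +1)[::-1]

    def test_out_of_range_pc(self):
        with pytest.raises(ValueError):
            rank_by_loadings(_pca_model({"a": 1.0}), 2, +1)


def _collection(sets: dict[str, set[str]]) -> GeneSetCollection:
    return GeneSetCollection(
        sets={t: frozenset(g) for t, g in sets.items()},
        term_meta={t: (t.lower(), "biological_process") for t in sets},
    )


def _ranked(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


class TestEnrichRanking:
    def test_planted_top_block_significant(self):
        ranked = _ranked(200)
        coll = _collection({"TOP": set(ranked[:10])})
        results = enrich_ranking(ranked, coll, GopcaConfig(), pc_index=1)
        assert [r.term_id for r in results] == ["TOP"]
        r = results[0]
        assert r.n_star == 10 and r.k_star == 10
        assert set(r.driving_genes) == set(ranked[:10])
        assert r.p_mhg <= 1e-6

    def test_random_decoys_not_significant(self):
        rng = np.random.default_rng(0)
        ranked = _ranked(300)
        coll = _collection({
            f"D{i}": set(rng.choice(ranked, size=15, replace=False))
            for i in range(100)
        })
        assert enrich_ranking(ranked, coll, GopcaConfig()) == []

    def test_absent_genes_not_tested(self):
        ranked = _ranked(100)
        coll = _collection({"GHOST": {"nope1", "nope2", "nope3"}})
        assert enrich_ranking(ranked, coll, GopcaConfig()) == []

    def test_K_counts_only_present_genes(self):
        ranked = _ranked(200)
        coll = _collection({"T": set(ranked[:10]) | {"absent1", "absent2"}})
        results = enrich_ranking(ranked, coll, GopcaConfig())
        assert results and results[0].K == 10


class TestLocalFilter:
    def test_duplicate_term_discarded(self):
        ranked = _ranked(200)
        genes = set(ranked[:10])
        coll = _collection({"T1": genes, "T2": genes})
        results = enrich_ranking(ranked, coll, GopcaConfig())
        assert len(results) == 2
        kept = local_filter(results, ranked, coll, GopcaConfig())
        assert len(kept) == 1

    def test_disjoint_terms_both_kept(self):
        ranked = _ranked(400)
        coll = _collection({"T1": set(ranked[:12]), "T2": set(ranked[12:24])})
        results = enrich_ranking(ranked, coll, GopcaConfig())
        kept = local_filter(results, ranked, coll, GopcaConfig())
        assert {r.term_id for r in kept} == {"T1", "T2"}

    def test_single_term_always_kept(self):
        ranked = _ranked(200)
        coll = _collection({"T": set(ranked[:10])})
        results = enrich_ranking(ranked, coll, GopcaConfig())
        assert local_filter(results, ranked, coll, GopcaConfig()) == results

    def test_output_subset_preserving_best(self):
        ranked = _ranked(300)
        coll = _collection({
            "BIG": set(ranked[:30]),
            "SUB": set(ranked[:10]),
        })
        results = enrich_ranking(ranked, coll, GopcaConfig())
        kept = local_filter(results, ranked, coll, GopcaConfig())
        assert set(r.term_id for r in kept) <= set(r.term_id for r in results)
        best = max(results, key=lambda r: r.escore)
        assert best.term_id in {r.term_id for r in kept}


def _result(term_id, pc_index, genes=("g1",), escore=2.0):
    return EnrichmentResult(
        term_id=term_id, term_name=term_id.lower(),
        namespace="biological_process", pc_index=pc_index,
        s_mhg=1e-9, p_mhg=1e-8, n_star=len(genes), k_star=len(genes),
        K=len(genes), N=100, X=1, L=20, escore=escore,
        driving_genes=tuple(genes),
    )


class TestGlobalFilter:
    def test_same_term_on_later_pc_dropped(self):
        kept = global_filter([_result("T", 1), _result("T", 2)], None)
        assert [(r.term_id, r.pc_index) for r in kept] == [("T", 1)]

    def test_related_term_dropped_child_first(self, chain_ontology):
        kept = global_filter([_result("C", 1), _result("A", 3)], chain_ontology)
        assert [r.term_id for r in kept] == ["C"]

    def test_unrelated_terms_kept(self, chain_ontology):
        kept = global_filter([_result("C", 1), _result("X", 2)], chain_ontology)
        assert [r.term_id for r in kept] == ["C", "X"]

    def test_pairwise_unrelated_output(self, diamond_ontology):
        results = [_result(t, i + 1)
                   for i, t in enumerate(["D", "P1", "P2", "R"])]
        kept = global_filter(results, diamond_ontology)
        ids = [r.term_id for r in kept]
        assert ids == ["D"]


class TestBuildSignature:
    def _setup(self, profiles: dict[str, np.ndarray]):
        E = pd.DataFrame(profiles).T
        E.columns = [f"s{j}" for j in range(E.shape[1])]
        return standardize(E)

    def test_perfectly_correlated_all_included(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        E_std = self._setup({f"g{i}": base * (i + 1) + i for i in range(6)})
        r = _result("T", 1, genes=tuple(f"g{i}" for i in range(6)))
        sig = build_signature(r, E_std, GopcaConfig())
        assert set(sig.genes) == set(r.driving_genes)
        assert abs(sig.expression.mean()) < 1e-9

    def test_r_minus_one_disables_filtering(self):
        rng = np.random.default_rng(0)
        E_std = self._setup({f"g{i}": rng.normal(size=8) for i in range(6)})
        r = _result("T", 1, genes=tuple(f"g{i}" for i in range(6)))
        sig = build_signature(r, E_std, GopcaConfig(r_corr=-1.0))
        assert set(sig.genes) == set(r.driving_genes)

    def test_anticorrelated_gene_excluded_and_coherence_rises(self):
        base = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        rng = np.random.default_rng(1)
        profiles = {f"g{i}": base + rng.normal(0, 0.1, 6) for i in range(5)}
        profiles["anti"] = -base + rng.normal(0, 0.1, 6)
        E_std = self._setup(profiles)
        genes = tuple(sorted(profiles))
        r = _result("T", 1, genes=genes)
        r.X = 3
        sig_filtered = build_signature(r, E_std, GopcaConfig(r_corr=0.5))
        sig_all = build_signature(r, E_std, GopcaConfig(r_corr=-1.0))
        assert "anti" not in sig_filtered.genes
        assert "anti" in sig_all.genes

        def median_corr(sig):
            c = np.corrcoef(E_std.loc[list(sig.genes)].to_numpy())
            iu = np.triu_indices(len(sig.genes), k=1)
            return np.median(c[iu])

        assert median_corr(sig_filtered) > median_corr(sig_all)


class TestOrderSignatures:
    def test_single_signature_identity(self, planted_result):
        result, _ = planted_result
        assert order_signatures(result.signatures[:1]) == [0]

    def test_correlated_pair_adjacent(self):
        from sigpca.core import Signature
        base = np.array([1.0, 2.0, -1.0, 0.5, -2.0])
        profiles = [base, -base + 0.01, base * 1.1 + 0.05]
        sigs = []
        for i, prof in enumerate(profiles):
            sigs.append(Signature(
                term_id=f"T{i}", name=f"t{i}", namespace="biological_process",
                pc_index=1, genes=("g",),
                expression=pd.Series(prof, index=list("abcde")),
                enrichment=_result(f"T{i}", 1), K_total=1,
            ))
        order = order_signatures(sigs, "cluster")
        pos = {i: order.index(i) for i in range(3)}
        # profiles 0 and 2 are nearly identical, 1 is anti-correlated
        assert abs(pos[0] - pos[2]) == 1


class TestBonferroni:
    def test_values(self):
        assert bonferroni_threshold(0.05, 20000) == pytest.approx(2.5e-6)
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(1e-6, 1) == 1e-6

    def test_domain(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestRunPipeline:
    def test_planted_recovery(self, planted_result):
        result, truth = planted_result
        precision, recall = truth.precision_recall(result.term_ids())
        assert precision == 1.0 and recall == 1.0
        # active samples are strongly elevated in the matching signature
        for sig in result.signatures:
            active = sorted(truth.active_samples[sig.term_id])
            inactive = [s for s in result.matrix.columns if s not in active]
            expr = sig.expression
            delta = expr[active].mean() - expr[inactive].mean()
            assert abs(delta) > 1.0

    def test_signature_profiles_zero_mean(self, planted_result):
        result, _ = planted_result
        for sig in result.signatures:
            assert abs(sig.expression.mean()) < 1e-9

    def test_signature_genes_annotated_subset_of_driving(
        self, planted, planted_result
    ):
        _, collection, _, _ = planted
        result, _ = planted_result
        for sig in result.signatures:
            driving = set(sig.enrichment.driving_genes)
            assert set(sig.genes) <= driving
            assert len(driving) == sig.enrichment.k_star
            assert set(sig.genes) <= collection.sets[sig.term_id]

    def test_deterministic_rerun(self, planted):
        E, collection, ontology, _ = planted
        cfg = GopcaConfig(seed=42)
        r1 = run_gopca(E, collection, ontology, cfg)
        r2 = run_gopca(E, collection, ontology, cfg)
        assert r1.term_ids() == r2.term_ids()
        pd.testing.assert_frame_equal(r1.matrix, r2.matrix)

    def test_rerun_stability_under_D_inflation(self, planted, planted_result):
        E, collection, ontology, _ = planted
        result, _ = planted_result
        inflated = run_gopca(
            E, collection, ontology,
            GopcaConfig(seed=1, d_override=result.D + 2),
        )
        base = {
            (s.term_id, s.pc_index, s.genes)
            for s in result.signatures
        }
        inflated_early = {
            (s.term_id, s.pc_index, s.genes)
            for s in inflated.signatures if abs(s.pc_index) <= result.D
        }
        assert base == inflated_early

    def test_pure_noise_yields_empty_result(self):
        rng = np.random.default_rng(5)
        E = pd.DataFrame(rng.normal(size=(200, 30)),
                         index=[f"g{i}" for i in range(200)],
                         columns=[f"s{j}" for j in range(30)])
        coll = _collection({"T": {f"g{i}" for i in range(10)}})
        result = run_gopca(E, coll, None, GopcaConfig(seed=5))
        if result.D == 0:
            assert result.n_signatures == 0
            assert result.matrix.shape[0] == 0

    def test_complementary_modules_anticorrelated(self):
        E, coll, onto, truth = planted_dataset(
            seed=9, n_genes=400, n_samples=40, modules=[(40, 0.5, 3.0)] * 2,
            n_decoy_sets=50,
        )
        result = run_gopca(E, coll, onto, GopcaConfig(seed=9))
        assert result.n_signatures >= 2


class TestSignaturePCAEstimator:
    def test_fit_attributes(self, planted):
        E, collection, ontology, truth = planted
        est = SignaturePCA(gene_sets=collection, ontology=ontology, seed=1)
        est.fit(E)
        assert est.n_components_ == 3
        assert len(est.signatures_) == 3
        assert est.signature_matrix_.shape == (3, E.shape[1])
        assert list(est.get_feature_names_out()) == list(est.signature_matrix_.index)

    def test_transform_matches_fit_matrix(self, planted):
        E, collection, ontology, _ = planted
        est = SignaturePCA(gene_sets=collection, ontology=ontology, seed=1)
        est.fit(E)
        projected = est.transform(E)
        assert np.allclose(
            projected.to_numpy(), est.signature_matrix_.T.to_numpy(), atol=1e-9
        )

    def test_clone_and_get_params(self, planted):
        _, collection, ontology, _ = planted
        est = SignaturePCA(gene_sets=collection, ontology=ontology,
                           alpha_b=1e-7, seed=3)
        cloned = clone(est)
        assert cloned.get_params()["alpha_b"] == 1e-7
        assert cloned.get_params()["seed"] == 3

    def test_unfitted_transform_errors(self, planted):
        E, collection, _, _ = planted
        est = SignaturePCA(gene_sets=collection)
        with pytest.raises(ValueError, match="not fitted"):
            est.transform(E)
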