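import numpy as np
import pandas as pd
import pytest

from connpred import (
    ParcelAtlas,
    PredictiveMap,
    back_project,
    fit_dl,
    fit_enet,
    fit_nnmf,
    fit_pca,
    map_correlation,
    n_edges,
    network_block_summary,
    node_contribution,
    predict,
    restore_symmetric,
    standardize,
    top_edges,
    transform,
    vectorize_connectome,
)
from connpred.connectome_data import ConnectomeMatrix, edge_index
from connpred.errors import ConfigError, DomainError, ModelError, ShapeError
from connpred.features import FeatureModel
from connpred.maps import export_map
from connpred.regression import Standardizer, RegressionModel


def _identity_feature_model(p):
    return FeatureModel(
        method="pca", k=p, basis=np.eye(p), forward_map=np.eye(p),
        center=np.zeros(p), F_train=np.zeros((2, p)),
    )


def _plain_model(beta, intercept=0.0, lam=0.1, alpha=1.0):
    beta = np.asarray(beta, dtype=float)
    return RegressionModel(
        beta=beta, intercept=intercept, lam=lam, alpha=alpha,
        nonzero_count=int(np.count_nonzero(beta)),
        standardizer=Standardizer.identity(beta.size), objective=0.0,
    )


def _fit_pipeline(cohort, scores, method="pca", k=4, seed=0):
    y = np.array([scores.scores[s] for s in cohort.subject_ids])
    if method == "pca":
        fm = fit_pca(cohort, k)
    elif method == "dl":
        fm = fit_dl(cohort, k, sparsity=0.05, seed=seed)
    else:
        fm = fit_nnmf(cohort, k, seed=seed)
    Z, _, std = standardize(fm.F_train)
    rm = fit_enet(Z, y, 0.05, 0.5, standardizer=std)
    return fm, rm


class TestBackProject:
    def test_identity_extraction_gives_beta(self):
        p = 10
        fm = _identity_feature_model(p)
        beta = np.arange(1.0, p + 1)
        pmap = back_project(fm, _plain_model(beta), ParcelAtlas.generic(5))
        np.testing.assert_allclose(pmap.edge_weights, beta)
        assert pmap.provenance["transform_source"] == "forward_map"

    def test_zero_beta_gives_zero_map(self):
        p = n_edges(5)
        fm = _identity_feature_model(p)
        pmap = back_project(fm, _plain_model(np.zeros(p)), ParcelAtlas.generic(5))
        assert not pmap.edge_weights.any()

    def test_prediction_equivalence_pca(self, small_cohort):
        cohort, scores, _ = small_cohort
        fm, rm = _fit_pipeline(cohort, scores, "pca")
        pmap = back_project(fm, rm, cohort.atlas)
        X_new = np.random.default_rng(5).standard_normal((6, cohort.n_edges))
        via_edges = X_new @ pmap.edge_weights + pmap.intercept_adjusted
        via_features = predict(rm, transform(fm, X_new))
        np.testing.assert_allclose(via_edges, via_features, atol=1e-8)

    def test_dl_and_nnmf_use_basis(self, small_cohort):
        cohort, scores, _ = small_cohort
        for method in ("dl", "nnmf"):
            fm, rm = _fit_pipeline(cohort, scores, method)
            pmap = back_project(fm, rm, cohort.atlas)
            assert pmap.provenance["transform_source"] == "basis"
            assert pmap.provenance["method"] == method

    def test_unstandardization_applied(self):
        p = 6
        fm = _identity_feature_model(p)
        std = Standardizer(np.zeros(p), np.full(p, 2.0), np.zeros(p, dtype=bool))
        rm = RegressionModel(
            beta=np.ones(p), intercept=0.0, lam=0.1, alpha=1.0, nonzero_count=p,
            standardizer=std, objective=0.0,
        )
        pmap = back_project(fm, rm, ParcelAtlas.generic(4))
        np.testing.assert_allclose(pmap.edge_weights, 0.5)

    def test_k_mismatch(self, small_cohort):
        cohort, scores, _ = small_cohort
        fm, _ = _fit_pipeline(cohort, scores, "pca", k=4)
        with pytest.raises(ShapeError):
            back_project(fm, _plain_model(np.zeros(3)), cohort.atlas)

    def test_missing_maps(self):
        fm = FeatureModel(method="x", k=2, basis=None, forward_map=None,
                          center=np.zeros(3), F_train=np.zeros((2, 2)))
        with pytest.raises(ModelError):
            back_project(fm, _plain_model(np.zeros(2)), ParcelAtlas.generic(3))

    def test_matrix_form_roundtrip(self, rng):
        atlas = ParcelAtlas.generic(8)
        w = rng.standard_normal(n_edges(8))
        pmap = PredictiveMap(edge_weights=w, atlas=atlas)
        m = pmap.matrix_form
        assert np.array_equal(m, m.T)
        v = vectorize_connectome(ConnectomeMatrix(m, atlas))
        np.testing.assert_array_equal(v.values, w)


class TestTopEdges:
    def _map(self, rng, P=8):
        return PredictiveMap(
            edge_weights=rng.standard_normal(n_edges(P)),
            atlas=ParcelAtlas.generic(P),
        )

    def test_default_returns_200_rows(self, rng):
        pmap = PredictiveMap(
            edge_weights=rng.standard_normal(n_edges(64)),
            atlas=ParcelAtlas.generic(64),
        )
        table = top_edges(pmap)
        assert len(table) == 200
        assert list(table["rank"]) == list(range(1, 201))

    def test_sparse_map_heads_table(self):
        P = 30
        w = np.zeros(n_edges(P))
        w[[3, 100, 250]] = [0.5, -2.0, 1.0]
        pmap = PredictiveMap(edge_weights=w, atlas=ParcelAtlas.generic(P))
        table = top_edges(pmap, 200)
        assert (table["weight"].iloc[:3].abs() > 0).all()
        np.testing.assert_allclose(
            table["weight"].iloc[:3].to_numpy(), [-2.0, 1.0, 0.5]
        )
        assert (table["weight"].iloc[3:] == 0).all()

    def test_agrees_with_sort_oracle(self, rng):
        pmap = PredictiveMap(
            edge_weights=rng.standard_normal(2016),
            atlas=ParcelAtlas.generic(64),
        )
        table = top_edges(pmap, 200)
        oracle = np.argsort(-np.abs(pmap.edge_weights), kind="stable")[:200]
        ij = edge_index(64)[oracle]
        np.testing.assert_array_equal(
            table[["parcel_i", "parcel_j"]].to_numpy(), ij
        )

    def test_n_exceeds_p(self, rng):
        with pytest.raises(ConfigError):
            top_edges(self._map(rng), N=n_edges(8) + 1)

    def test_permutation_equivariance(self, rng):
        P = 10
        pmap = self._map(rng, P)
        perm = rng.permutation(P)
        M = pmap.matrix_form
        M_perm = M[np.ix_(perm, perm)]
        pmap_perm = PredictiveMap(
            edge_weights=vectorize_connectome(
                ConnectomeMatrix(M_perm, ParcelAtlas.generic(P))
            ).values,
            atlas=ParcelAtlas.generic(P),
        )
        t1 = top_edges(pmap, 10)
        t2 = top_edges(pmap_perm, 10)
        pairs1 = {
            (min(i, j), max(i, j), round(w, 12))
            for i, j, w in zip(t1["parcel_i"], t1["parcel_j"], t1["weight"])
        }
        pairs2 = {
            (int(min(perm[i], perm[j])), int(max(perm[i], perm[j])), round(w, 12))
            for i, j, w in zip(t2["parcel_i"], t2["parcel_j"], t2["weight"])
        }
        assert pairs1 == pairs2


class TestMapCorrelation:
    def test_self_correlation(self, rng):
        pmap = PredictiveMap(
            edge_weights=rng.standard_normal(n_edges(6)),
            atlas=ParcelAtlas.generic(6),
        )
        assert map_correlation(pmap, pmap) == pytest.approx(1.0)

    def test_negation(self, rng):
        atlas = ParcelAtlas.generic(6)
        w = rng.standard_normal(n_edges(6))
        a = PredictiveMap(edge_weights=w, atlas=atlas)
        b = PredictiveMap(edge_weights=-w, atlas=atlas)
        assert map_correlation(a, b) == pytest.approx(-1.0)

    def test_zero_variance(self):
        atlas = ParcelAtlas.generic(6)
        a = PredictiveMap(edge_weights=np.zeros(n_edges(6)), atlas=atlas)
        with pytest.raises(DomainError):
            map_correlation(a, a)

    def test_pca_vs_ica_maps_highly_correlated(self, small_cohort):
        from connpred import fit_ica

        cohort, scores, _ = small_cohort
        y = np.array([scores.scores[s] for s in cohort.subject_ids])
        maps = {}
        for method, fm in (
            ("pca", fit_pca(cohort, 4)),
            ("ica", fit_ica(cohort, 4, seed=0)),
        ):
            Z, _, std = standardize(fm.F_train)
            rm = fit_enet(Z, y, 0.05, 0.5, standardizer=std)
            maps[method] = back_project(fm, rm, cohort.atlas)
        assert map_correlation(maps["pca"], maps["ica"]) > 0.8


class TestNodeContribution:
    def test_single_edge(self):
        table = pd.DataFrame({"parcel_i": [2], "parcel_j": [5], "weight": [0.7]})
        c = node_contribution(table, n_parcels=8)
        assert c[2] == 1.0 and c[5] == 1.0
        assert c.sum() == 2.0

    def test_star_of_three_equal_edges(self):
        table = pd.DataFrame(
            {"parcel_i": [0, 0, 0], "parcel_j": [1, 2, 3], "weight": [1.0, -1.0, 1.0]}
        )
        c = node_contribution(table, n_parcels=4)
        assert c[0] == 1.0
        np.testing.assert_allclose(c[1:], 1 / 3)

    def test_unnormalized_sum_identity(self, rng):
        P = 12
        pmap = PredictiveMap(
            edge_weights=rng.standard_normal(n_edges(P)),
            atlas=ParcelAtlas.generic(P),
        )
        table = top_edges(pmap, 20)
        c = node_contribution(table, n_parcels=P, normalize=False)
        assert c.sum() == pytest.approx(2 * np.abs(table["weight"]).sum())

    def test_empty_table(self):
        with pytest.raises(ConfigError):
            node_contribution(pd.DataFrame(columns=["parcel_i", "parcel_j", "weight"]))


class TestNetworkBlockSummary:
    def test_uniform_map(self):
        atlas = ParcelAtlas.generic(12, 3)
        pmap = PredictiveMap(edge_weights=np.ones(n_edges(12)), atlas=atlas)
        table = network_block_summary(pmap)
        np.testing.assert_allclose(table.to_numpy(), 1.0)

    def test_within_network_only(self):
        atlas = ParcelAtlas.generic(12, 3)
        nets = np.array([atlas.networks.index(l) for l in atlas.network_labels])
        ij = edge_index(12)
        w = np.where((nets[ij[:, 0]] == 0) & (nets[ij[:, 1]] == 0), 1.0, 0.0)
        table = network_block_summary(PredictiveMap(edge_weights=w, atlas=atlas))
        assert table.iloc[0, 0] == 1.0
        vals = table.to_numpy().copy()
        vals[0, 0] = 0.0
        assert not vals.any()

    def test_brute_force_grouping_oracle(self, rng):
        atlas = ParcelAtlas.generic(10, 3)
        w = rng.standard_normal(n_edges(10))
        table = network_block_summary(PredictiveMap(edge_weights=w, atlas=atlas))
        nets = [atlas.networks.index(l) for l in atlas.network_labels]
        ij = edge_index(10)
        for a in range(3):
            for b in range(3):
                vals = [
                    abs(w[e])
                    for e, (i, j) in enumerate(ij)
                    if {nets[i], nets[j]} == ({a, b} if a != b else {a})
                ]
                assert table.iloc[a, b] == pytest.approx(np.mean(vals))

    def test_symmetric(self, rng):
        atlas = ParcelAtlas.generic(12, 4)
        pmap = PredictiveMap(
            edge_weights=rng.standard_normal(n_edges(12)), atlas=atlas
        )
        t = network_block_summary(pmap).to_numpy()
        np.testing.assert_allclose(t, t.T)


def test_export_map_artifacts(tmp_path, rng):
    atlas = ParcelAtlas.generic(10, 2)
    pmap = PredictiveMap(edge_weights=rng.standard_normal(45), atlas=atlas)
    export_map(pmap, tmp_path, prefix="test", top_n=10)
    for suffix in ("matrix", "top_edges", "network_blocks", "nodes"):
        assert (tmp_path / f"test_{suffix}.csv").exists()
    table = pd.read_csv(tmp_path / "test_top_edges.csv")
    assert table["parcel_i"].min() >= 1  # exported ids are 1-based
    m = np.loadtxt(tmp_path / "test_matrix.csv", delimiter=",")
    np.testing.assert_allclose(m, pmap.matrix_form)
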