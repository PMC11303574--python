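"""Profiles, dispersion-based feature selection, PCA and the repeated
LOOCV scoring loop, including leakage protection."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

import mave_evidence as me
from mave_evidence.config import ModelingConfig
from mave_evidence.modeling import _FeaturePipeline


def _adata(counts, gene_names=None):
    counts = np.asarray(counts)
    gene_names = gene_names or [f"G{i}" for i in range(counts.shape[1])]
    ad = AnnData(
        X=sp.csr_matrix(counts),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene_name")),
    )
    ad.obs_names = [f"cell{i}" for i in range(counts.shape[0])]
    return ad


def _assignments(cells, variants):
    return pd.DataFrame({"cell_barcode": cells, "variant_id": variants})


class TestFilterGenes:
    def test_threshold_is_per_variant(self):
        # gene G1: expressed in exactly 10% of V1's cells, 0% of V2's
        counts = np.zeros((20, 2))
        counts[0, 0] = 3  # one of V1's 10 cells
        counts[:, 1] = 1  # G2 everywhere
        ad = _adata(counts, ["G1", "G2"])
        assignments = _assignments(ad.obs_names, ["V1"] * 10 + ["V2"] * 10)
        assert me.filter_genes(ad, assignments) == ["G1", "G2"]

    def test_below_threshold_everywhere_removed(self):
        # 9% in both variants (1 cell of 11 each... use 100 cells, 9 expressing)
        counts = np.zeros((100, 2))
        counts[:9, 0] = 1  # 9% of V1's 100 cells
        counts[:, 1] = 1
        ad = _adata(counts, ["G1", "G2"])
        assignments = _assignments(ad.obs_names, ["V1"] * 100)
        assert me.filter_genes(ad, assignments) == ["G2"]

    def test_all_zero_gene_removed(self):
        counts = np.ones((10, 2))
        counts[:, 0] = 0
        ad = _adata(counts, ["G1", "G2"])
        assignments = _assignments(ad.obs_names, ["V1"] * 10)
        assert me.filter_genes(ad, assignments) == ["G2"]


class TestBuildProfiles:
    def test_hand_computed_mean_of_normalized_cells(self):
        ad = _adata([[2, 2], [6, 2]])
        assignments = _assignments(["cell0", "cell1"], ["V1", "V1"])
        profiles, n_cells = me.build_profiles(ad, assignments, ["G0", "G1"], min_cells=1)
        assert profiles.loc["V1"].tolist() == pytest.approx([0.625, 0.375])
        assert n_cells["V1"] == 2

    def test_single_cell_profile_is_normalized_vector(self):
        ad = _adata([[1, 3]])
        profiles, _ = me.build_profiles(
            ad, _assignments(["cell0"], ["V1"]), ["G0", "G1"], min_cells=1
        )
        assert profiles.loc["V1"].tolist() == pytest.approx([0.25, 0.75])

    def test_cell_order_invariance(self, small_adata, truth_assignments):
        genes = list(small_adata.var_names[:50])
        a, _ = me.build_profiles(small_adata, truth_assignments, genes, min_cells=1)
        shuffled = truth_assignments.sample(frac=1, random_state=0)
        b, _ = me.build_profiles(small_adata, shuffled, genes, min_cells=1)
        pd.testing.assert_frame_equal(a, b)

    def test_min_cells_excludes_sparse_variants(self):
        ad = _adata(np.ones((6, 2)))
        assignments = _assignments(ad.obs_names, ["V1"] * 5 + ["V2"])
        profiles, _ = me.build_profiles(ad, assignments, ["G0", "G1"], min_cells=5)
        assert list(profiles.index) == ["V1"]


class TestSelectFeatures:
    def test_constant_gene_never_beats_varying_gene(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.full(10, 5.0), rng.gamma(2, 1, size=(10, 3))])
        idx = me.select_features(X, n_top=3)
        assert 0 not in idx

    def test_matches_bruteforce_binned_zscore(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(2.0, 1.0, size=(4, 5))
        got = me.select_features(X, n_top=2, n_bins=2)

        mean = X.mean(axis=0)
        disp = X.var(axis=0, ddof=1) / mean
        order = np.argsort(mean, kind="stable")
        rank = np.empty(5, dtype=int)
        rank[order] = np.arange(5)
        bins = rank * 2 // 5
        z = np.zeros(5)
        for b in (0, 1):
            m = bins == b
            if disp[m].std() > 0:
                z[m] = (disp[m] - disp[m].mean()) / disp[m].std()
        expected = np.lexsort((np.arange(5), -disp, -z))[:2]
        assert list(got) == list(expected)

    def test_requesting_all_genes_returns_all(self):
        X = np.random.default_rng(1).gamma(2, 1, size=(4, 6))
        assert list(me.select_features(X, n_top=10)) == list(range(6))


class TestReduceDimensions:
    def test_rank_one_matrix_one_component(self):
        u = np.arange(1, 9, dtype=float)[:, None]
        v = np.array([[2.0, 1.0, 0.5]])
        scores = me.reduce_dimensions(u @ v, n_pcs=2)
        total_var = (u @ v).var(axis=0).sum()
        assert scores[:, 0].var() / total_var >= 0.999

    def test_sign_convention_makes_output_deterministic(self):
        X = np.random.default_rng(5).normal(size=(12, 6))
        assert np.array_equal(me.reduce_dimensions(X, 3), me.reduce_dimensions(X, 3))

    def test_explained_variance_monotone_in_components(self):
        X = np.random.default_rng(6).normal(size=(15, 8))
        captured = [
            me.reduce_dimensions(X, k).var(axis=0, ddof=1).sum() for k in (1, 2, 4)
        ]
        assert captured[0] <= captured[1] <= captured[2]

    def test_excessive_components_clipped_with_warning(self):
        X = np.random.default_rng(7).normal(size=(5, 3))
        with pytest.warns(UserWarning):
            scores = me.reduce_dimensions(X, 10)
        assert scores.shape == (5, 3)


def _separable_profiles(n_per_class=8, n_genes=30, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.gamma(2, 1, size=n_genes)
    rows, labels = [], {}
    for i in range(2 * n_per_class):
        shift = np.zeros(n_genes)
        pathogenic = i < n_per_class
        shift[:5] = 3.0 if pathogenic else 0.0
        rows.append(base + shift + rng.normal(0, 0.05, n_genes))
        labels[f"V{i}"] = "pathogenic" if pathogenic else "benign"
    profiles = pd.DataFrame(rows, index=list(labels))
    return profiles, pd.Series(labels)


class TestTrainAndScore:
    def test_separable_features_fully_ranked(self, fast_modeling_config):
        profiles, labels = _separable_profiles()
        scores, out = me.train_and_score(profiles, labels, fast_modeling_config)
        s = scores.set_index("variant_id")["score"]
        assert s.between(0, 1).all()
        assert s[labels == "pathogenic"].min() > s[labels == "benign"].max()
        auroc, valid = me.compute_auroc(s, labels)
        assert auroc == 1.0 and valid

    def test_deterministic_given_seed(self, fast_modeling_config):
        profiles, labels = _separable_profiles(seed=2)
        a, _ = me.train_and_score(profiles, labels, fast_modeling_config)
        b, _ = me.train_and_score(profiles, labels, fast_modeling_config)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_labels_fail(self, fast_modeling_config):
        profiles, labels = _separable_profiles()
        with pytest.raises(ValueError):
            me.train_and_score(
                profiles, labels[labels == "benign"], fast_modeling_config
            )

    def test_unlabeled_variants_scored_by_full_model(self, fast_modeling_config):
        profiles, labels = _separable_profiles()
        scores, _ = me.train_and_score(profiles, labels.iloc[:-2], fast_modeling_config)
        prov = scores.set_index("variant_id")["provenance"]
        assert (prov[labels.index[:-2]] == "loocv-mean").all()
        assert (prov[labels.index[-2:]] == "full-model").all()

    def test_held_out_feature_cannot_leak_into_own_score(self):
        """A feature that is informative only in the held-out variant's
        row must not change that variant's LOOCV score: selection and
        PCA are refit without it every fold."""
        config = ModelingConfig(n_features=10, n_pcs=4, loocv_repeats=2, seed=3)
        profiles, labels = _separable_profiles(n_per_class=6, n_genes=25, seed=4)
        target = profiles.index[0]

        # a feature that is zero everywhere except in the held-out row:
        # its training-fold dispersion is 0, so an unleaky pipeline never
        # selects it, and the magnitude of the poison is irrelevant
        def poisoned(value):
            p = profiles.copy()
            col = pd.Series(0.0, index=profiles.index)
            col[target] = value
            p["leak"] = col
            return me.train_and_score(p, labels, config)[0].set_index("variant_id")

        a = poisoned(50.0).loc[target, "score"]
        b = poisoned(5000.0).loc[target, "score"]
        assert a == pytest.approx(b, abs=1e-12)


class TestFeaturePipeline:
    def test_transform_uses_training_fit_only(self):
        rng = np.random.default_rng(8)
        X = rng.gamma(2, 1, size=(10, 20))
        pipe = _FeaturePipeline(n_features=5, n_bins=4, n_pcs=3)
        pipe.fit(X[:8])
        out = pipe.transform(X[8:])
        assert out.shape == (2, 3)
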