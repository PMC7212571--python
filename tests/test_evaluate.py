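"""Transfer, trait tests, label filters, ensembles and elastic nets."""

import numpy as np
import pandas as pd
import pytest

from biobombe import (
    ExpressionMatrix,
    aupr_delta,
    build_alteration_labels,
    build_ensemble_features,
    nonzero_fraction,
    project_external,
    sex_balanced_strata,
    train_elasticnet,
    welch_ttest,
)
from biobombe.compress import ModelRegistry


def _external(values, genes):
    values = np.asarray(values, dtype=float)
    idx = pd.Index([f"e{i}" for i in range(values.shape[0])], name="sample_id")
    return ExpressionMatrix(pd.DataFrame(values, index=idx, columns=genes))


class TestProjectExternal:
    def test_identical_universe_full_overlap(self):
        genes = [f"g{j}" for j in range(10)]
        w = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)),
                         index=genes)
        ext = _external(np.random.default_rng(1).random((4, 10)), genes)
        res = project_external(w, ext)
        assert res.overlap_fraction == 1.0
        assert res.activations.shape == (3, 4)

    def test_restricted_product_equals_zeroed_weights_identity(self):
        rng = np.random.default_rng(2)
        genes = [f"g{j}" for j in range(20)]
        w = pd.DataFrame(rng.normal(size=(20, 2)), index=genes)
        ext = _external(rng.random((5, 12)), genes[:12])
        with pytest.warns(UserWarning):
            restricted = project_external(w, ext, min_overlap=0.7)
        w_zeroed = w.copy()
        w_zeroed.loc[genes[12:]] = 0.0
        padded = _external(
            np.hstack([ext.values, np.zeros((5, 8))]), genes
        )
        full = project_external(w_zeroed, padded)
        np.testing.assert_allclose(restricted.activations.to_numpy(),
                                   full.activations.to_numpy())

    def test_overlap_fraction_reports_gene_intersection(self):
        genes = [f"g{j}" for j in range(8000)]
        w = pd.DataFrame(np.ones((8000, 1)), index=genes)
        ext = _external(np.ones((2, 4645)), genes[:4645])
        res = project_external(w, ext)
        assert round(100 * res.overlap_fraction, 2) == 58.06

    def test_empty_intersection_rejected(self):
        w = pd.DataFrame(np.ones((3, 1)), index=["a", "b", "c"])
        ext = _external(np.ones((2, 2)), ["x", "y"])
        with pytest.raises(ValueError, match="overlap"):
            project_external(w, ext)


class TestWelchTtest:
    def test_identical_groups_give_zero(self):
        scores = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = pd.Series([1, 1, 1, 0, 0, 0])
        res = welch_ttest(scores, labels)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # group1 (1..5), group0 (2..6): var 2.5 each, se = 1, t = -1
        scores = pd.Series([1, 2, 3, 4, 5, 2, 3, 4, 5, 6], dtype=float)
        labels = pd.Series([1] * 5 + [0] * 5)
        res = welch_ttest(scores, labels)
        assert res.t_statistic == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(0.347, abs=0.001)

    def test_swapping_labels_flips_sign_only(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=30))
        labels = pd.Series(rng.integers(0, 2, 30))
        a = welch_ttest(scores, labels)
        b = welch_ttest(scores, 1 - labels)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_group_marked_undefined(self):
        scores = pd.Series([1.0, 2.0, 3.0])
        labels = pd.Series([1, 0, 0])
        assert np.isnan(welch_ttest(scores, labels).t_statistic)


class TestSexBalancedStrata:
    def _meta(self, counts):
        rows = []
        for tissue, (n_m, n_f) in counts.items():
            rows += [{"tissue": tissue, "sex": "male"}] * n_m
            rows += [{"tissue": tissue, "sex": "female"}] * n_f
        return pd.DataFrame(rows)

    def test_balance_window_and_inclusive_boundaries(self):
        meta = self._meta({
            "even": (10, 10),        # ratio 1.0 -> kept
            "skewed": (4, 10),       # ratio 0.4 -> dropped
            "edge": (15, 10),        # ratio 1.5 -> kept (inclusive)
            "lower_edge": (5, 10),   # ratio 0.5 -> kept (inclusive)
        })
        assert sex_balanced_strata(meta) == ["edge", "even", "lower_edge"]

    def test_zero_female_tissue_dropped(self):
        meta = self._meta({"malesonly": (8, 0), "even": (5, 5)})
        assert sex_balanced_strata(meta) == ["even"]


class TestBuildAlterationLabels:
    def _tables(self, statuses, types, burdens=None):
        idx = pd.Index([f"s{i}" for i in range(len(statuses))])
        mutations = pd.DataFrame({"G1": statuses}, index=idx)
        copy_number = pd.DataFrame({"G1": [0] * len(statuses)}, index=idx)
        burden = pd.Series(burdens if burdens is not None else [10] * len(statuses),
                           index=idx, dtype=float)
        cancer = pd.Series(types, index=idx)
        return mutations, copy_number, burden, cancer

    def test_rare_positive_type_excluded(self):
        mut, cn, burden, types = self._tables(
            [1] * 3 + [0] * 97, ["T"] * 100
        )
        res = build_alteration_labels(mut, cn, "G1", "oncogene", burden, types)
        assert res.included_types == []
        assert any("3.0%" in line for line in res.exclusion_log)

    def test_balanced_type_included(self):
        mut, cn, burden, types = self._tables(
            [1] * 20 + [0] * 30, ["T"] * 50
        )
        res = build_alteration_labels(mut, cn, "G1", "oncogene", burden, types)
        assert res.included_types == ["T"]
        assert res.labels.sum() == 20

    def test_copy_number_contributes_by_gene_class(self):
        idx = pd.Index([f"s{i}" for i in range(40)])
        mutations = pd.DataFrame({"G1": [0] * 40}, index=idx)
        copy_number = pd.DataFrame({"G1": [-2] * 20 + [0] * 20}, index=idx)
        burden = pd.Series(10.0, index=idx)
        types = pd.Series(["T"] * 40, index=idx)
        tsg = build_alteration_labels(mutations, copy_number, "G1", "tsg",
                                      burden, types)
        assert tsg.labels.sum() == 20
        onc = build_alteration_labels(mutations, copy_number, "G1", "oncogene",
                                      burden, types)
        assert onc.included_types == []  # deletions do not count for oncogenes

    def test_hypermutator_removed_before_balance(self):
        # log10 of the outlier exceeds mean + 5 sd of the log10 burden vector
        burdens = [10] * 60 + [10 ** 10]
        mut, cn, burden, types = self._tables(
            [1] * 30 + [0] * 31, ["T"] * 61, burdens
        )
        res = build_alteration_labels(mut, cn, "G1", "oncogene", burden, types)
        assert "s60" not in res.labels.index
        assert any("hypermutator" in line for line in res.exclusion_log)

    def test_absent_gene_rejected(self):
        mut, cn, burden, types = self._tables([0, 1], ["T", "T"])
        with pytest.raises(ValueError, match="absent"):
            build_alteration_labels(mut, cn, "G2", "oncogene", burden, types)


class TestEnsembleFeatures:
    @pytest.fixture()
    def registry(self):
        reg = ModelRegistry()
        rng = np.random.default_rng(0)
        idx = pd.Index([f"s{i}" for i in range(6)], name="sample_id")
        for algo in ("pca", "ica", "nmf", "dae", "vae"):
            for k in (3, 4):
                for seed in range(5):
                    key = (algo, k, seed, "real")
                    reg.models[key] = object()
                    acts = pd.DataFrame(
                        rng.normal(size=(6, k)), index=idx,
                        columns=[f"feature_{i}" for i in range(k)],
                    )
                    reg.activations[key] = {"test": acts}
        return reg

    def test_vae_seed_ensemble_width(self, registry):
        feats = build_ensemble_features(registry, "vae_5seed", k=4)
        assert feats.shape == (6, 20)

    def test_one_seed_all_algorithms_width(self, registry):
        feats = build_ensemble_features(registry, "one_seed_all_algorithms",
                                        k=3, seed=0)
        assert feats.shape == (6, 15)

    def test_all_features_width_is_total_latent_dims(self, registry):
        feats = build_ensemble_features(registry, "all_features")
        assert feats.shape == (6, (3 + 4) * 5 * 5)

    def test_column_names_encode_provenance(self, registry):
        feats = build_ensemble_features(registry, "vae_5seed", k=3)
        assert "vae_k3_s0_feature_0" in feats.columns

    def test_missing_models_rejected_with_names(self, registry):
        del registry.models[("vae", 4, 3, "real")]
        with pytest.raises(ValueError, match="vae/k=4/seed=3"):
            build_ensemble_features(registry, "vae_5seed", k=4)


class TestElasticNet:
    @pytest.fixture(scope="class")
    def features(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(200, 20)),
                         index=[f"s{i}" for i in range(200)],
                         columns=[f"f{i}" for i in range(20)])
        return x

    def test_separable_labels_reach_high_auroc(self, features):
        labels = (features["f3"] > features["f3"].median()).astype(int)
        res = train_elasticnet(features, labels, seed=0,
                               alpha_grid=(0.1, 0.2), mixing_grid=(0.2, 0.4))
        assert res.cv_auroc > 0.95

    def test_higher_l1_is_sparser_on_duplicated_features(self, features):
        # duplicate every column: pure-l2 spreads weight, high-l1 prunes
        dup = pd.concat([features, features.add_suffix("_copy")], axis=1)
        labels = (features["f3"] + features["f7"] > 0).astype(int)
        low = train_elasticnet(dup, labels, seed=0, alpha_grid=(2.0,),
                               mixing_grid=(0.05,))
        high = train_elasticnet(dup, labels, seed=0, alpha_grid=(2.0,),
                                mixing_grid=(0.95,))
        assert high.sparsity > low.sparsity

    def test_single_class_rejected(self, features):
        labels = pd.Series(1, index=features.index)
        with pytest.raises(ValueError, match="single class"):
            train_elasticnet(features, labels)


class TestAuprDelta:
    def test_identical_inputs_give_zero(self):
        metrics = {"taskA": 0.7, "taskB": 0.6}
        assert aupr_delta(metrics, metrics) == 0.0

    def test_antisymmetry(self):
        a = {"t1": 0.8, "t2": 0.5}
        b = {"t1": 0.6, "t2": 0.55}
        assert aupr_delta(a, b) == pytest.approx(-aupr_delta(b, a))

    def test_unmatched_keys_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="unmatched"):
            delta = aupr_delta({"t1": 0.8, "only_real": 0.9}, {"t1": 0.6})
        assert delta == pytest.approx(0.2)


def test_nonzero_fraction_counts_exactly():
    coef = np.zeros(1000)
    coef[:37] = 1.5
    assert nonzero_fraction(coef) == pytest.approx(0.037)
    with pytest.raises(ValueError):
        nonzero_fraction(np.array([]))
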