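import numpy as np
import pytest

from normatlas import (
    ABNORMAL,
    NORMAL,
    AtlasConfig,
    FeatureBag,
    FeatureSimConfig,
    MosaicSelection,
    NormalAtlas,
    PatchRecord,
    classify_features,
    fit_atlas,
    prune_selection,
    simulate_feature_dataset,
)


def _gaussian_bags(rng, n_bags=4, per_bag=500, d=8, extractor="toy"):
    bags = []
    for i in range(n_bags):
        patches = [PatchRecord(f"g{i}", 10 * j, 0, 8) for j in range(per_bag)]
        bags.append(
            FeatureBag(f"g{i}", f"pt{i}", NORMAL, patches, rng.normal(size=(per_bag, d)), extractor)
        )
    return bags


class TestFitAtlas:
    def test_ocsvm_nu_bounds_training_outlier_fraction(self, rng):
        bags = _gaussian_bags(rng)  # 2000 clean i.i.d. Gaussian vectors
        atlas = fit_atlas(bags, AtlasConfig(method="ocsvm", nu=0.05, seed=1))
        assert atlas.training_flagged_fraction <= 0.05 + 0.02
        assert atlas.n_training_vectors == 2000

    def test_isolation_forest_flagged_fraction_in_sanity_band(self, rng):
        bags = _gaussian_bags(rng)
        atlas = fit_atlas(bags, AtlasConfig(method="isolation_forest", seed=1))
        assert 0.0 < atlas.training_flagged_fraction < 0.5

    def test_mixed_extractor_ids_rejected(self, rng):
        bags = _gaussian_bags(rng, n_bags=2)
        bags[1].extractor_id = "other"
        with pytest.raises(ValueError, match="extractor"):
            fit_atlas(bags, AtlasConfig())

    def test_too_few_vectors_rejected(self, rng):
        bags = _gaussian_bags(rng, n_bags=1, per_bag=10)
        with pytest.raises(ValueError, match="50"):
            fit_atlas(bags, AtlasConfig())

    def test_non_finite_features_rejected(self, rng):
        bags = _gaussian_bags(rng, n_bags=1, per_bag=100)
        bags[0].vectors[3, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_atlas(bags, AtlasConfig())

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            AtlasConfig(method="kde")


class TestClassifyFeatures:
    def test_pooled_mean_is_normal_and_far_outlier_is_abnormal(self, rng):
        bags = _gaussian_bags(rng)
        pool = np.vstack([b.vectors for b in bags])
        mean, sd = pool.mean(axis=0), pool.std(axis=0)
        for method in ("ocsvm", "isolation_forest"):
            atlas = fit_atlas(bags, AtlasConfig(method=method, seed=2))
            labels = classify_features(atlas, np.stack([mean, mean + 10 * sd]))
            assert labels == [NORMAL, ABNORMAL]

    def test_empty_input_gives_empty_output(self, ocsvm_atlas):
        assert classify_features(ocsvm_atlas, np.empty((0, ocsvm_atlas.feature_dim))) == []

    def test_dimension_mismatch_names_both_dims(self, ocsvm_atlas):
        with pytest.raises(ValueError, match=f"{ocsvm_atlas.feature_dim}"):
            classify_features(ocsvm_atlas, np.zeros((2, ocsvm_atlas.feature_dim + 1)))

    def test_classification_order_is_preserved_and_deterministic(self, ocsvm_atlas, holdout):
        X, _ = holdout
        a = classify_features(ocsvm_atlas, X)
        b = classify_features(ocsvm_atlas, X)
        assert a == b


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def _stub_atlas(d, value, extractor="synthetic"):
    return NormalAtlas(
        config=AtlasConfig(),
        extractor_id=extractor,
        feature_dim=d,
        mean=None,
        scale=None,
        model=_ConstantModel(value),
        n_training_vectors=100,
        training_flagged_fraction=0.0,
    )


class TestPruneSelection:
    def _selection(self, bag):
        return MosaicSelection(
            wsi_id=bag.wsi_id,
            selected=list(bag.patches),
            cluster_of={p.key: 0 for p in bag.patches},
        )

    def test_all_normal_atlas_empties_the_selection(self, labeled_bags):
        bag = labeled_bags[0]
        pruned = prune_selection(self._selection(bag), bag, _stub_atlas(bag.dim, 1))
        assert pruned.selected == []
        assert set(pruned.pruned_flags.values()) == {NORMAL}

    def test_all_abnormal_atlas_keeps_the_selection(self, labeled_bags):
        bag = labeled_bags[0]
        sel = self._selection(bag)
        pruned = prune_selection(sel, bag, _stub_atlas(bag.dim, -1))
        assert [(p.x, p.y) for p in pruned.selected] == [(p.x, p.y) for p in sel.selected]

    def test_planted_half_abnormal_bag_retains_about_half(self, ocsvm_atlas):
        cfg = FeatureSimConfig(seed=23, classes=(("lesion", 4, 0.5),), n_atlas_wsis=20)
        normal_bags, bags = simulate_feature_dataset(cfg)
        from normatlas import fit_atlas as fit

        atlas = fit(normal_bags, AtlasConfig(method="ocsvm", seed=5))
        fractions = []
        for bag in bags:
            pruned = prune_selection(self._selection(bag), bag, atlas)
            fractions.append(len(pruned.selected) / bag.n_patches)
        assert abs(np.mean(fractions) - 0.5) <= 0.10

    def test_pruning_is_idempotent(self, labeled_bags, ocsvm_atlas):
        bag = labeled_bags[-1]
        once = prune_selection(self._selection(bag), bag, ocsvm_atlas)
        twice = prune_selection(once, bag, ocsvm_atlas)
        assert [(p.x, p.y) for p in twice.selected] == [(p.x, p.y) for p in once.selected]

    def test_missing_vector_for_selected_patch_rejected(self, labeled_bags, ocsvm_atlas):
        bag = labeled_bags[0]
        sel = self._selection(bag)
        sel.selected = sel.selected + [PatchRecord(bag.wsi_id, 999_999, 999_999, 1024)]
        with pytest.raises(KeyError):
            prune_selection(sel, bag, ocsvm_atlas)


class TestSerialization:
    def test_round_trip_reproduces_decisions(self, tmp_path, ocsvm_atlas, holdout):
        X, _ = holdout
        path = tmp_path / "atlas.bin"
        ocsvm_atlas.save(path)
        loaded = NormalAtlas.load(path)
        assert classify_features(loaded, X) == classify_features(ocsvm_atlas, X)
        assert loaded.config == ocsvm_atlas.config

    def test_mismatched_dim_on_load_rejected(self, tmp_path, ocsvm_atlas):
        path = tmp_path / "atlas.bin"
        ocsvm_atlas.save(path)
        with pytest.raises(ValueError, match="dim"):
            NormalAtlas.load(path, expect_dim=ocsvm_atlas.feature_dim + 1)
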