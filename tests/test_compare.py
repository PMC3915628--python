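"""Adaptive regional feature extraction and RBF-SVM classification."""

import numpy as np
import pytest

from morphosvm.compare import (
    DiscriminationMap,
    PipelineConfig,
    RegionalElement,
    classify,
    extract_elements,
    grow_region,
    select_features,
    spatial_consistency,
    train_svm,
    voxelwise_discrimination,
    watershed_partition,
)


def _stack_from_columns(columns):
    """(n_subjects, n_voxels) columns -> stack shaped (n, v, 1, 1)."""
    arr = np.asarray(columns, dtype=float)
    return arr.reshape(arr.shape[0], arr.shape[1], 1, 1)


class TestVoxelwiseDiscrimination:
    def test_hand_computed_pearson(self):
        stack = _stack_from_columns([[2.0], [3.0], [1.0], [0.0]])
        dmap = voxelwise_discrimination(stack, [1, 1, 0, 0])
        assert dmap.score.ravel()[0] == pytest.approx(2 / np.sqrt(5), abs=1e-12)

    def test_voxel_tracking_labels_scores_one(self):
        stack = _stack_from_columns([[0.0], [1.0], [0.0], [1.0]])
        dmap = voxelwise_discrimination(stack, [0, 1, 0, 1])
        assert dmap.score.ravel()[0] == pytest.approx(1.0)

    def test_constant_voxel_scores_zero(self):
        stack = _stack_from_columns([[5.0], [5.0], [5.0], [5.0]])
        dmap = voxelwise_discrimination(stack, [1, 1, 0, 0])
        assert dmap.score.ravel()[0] == 0.0

    def test_single_class_rejected(self):
        stack = _stack_from_columns([[1.0], [2.0]])
        with pytest.raises(ValueError, match="two classes"):
            voxelwise_discrimination(stack, [1, 1])

    def test_invariant_under_common_affine_rescale(self, rng):
        stack = rng.normal(size=(10, 5, 4, 3))
        labels = [0, 1] * 5
        d1 = voxelwise_discrimination(stack, labels)
        d2 = voxelwise_discrimination(3.2 * stack + 7.0, labels)
        np.testing.assert_allclose(d1.score, d2.score, atol=1e-10)


def _gaussian_bump(shape, center, sigma=2.0, height=0.9):
    grids = np.indices(shape, dtype=float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return height * np.exp(-d2 / (2 * sigma**2))


class TestWatershedPartition:
    def test_single_bump_single_region(self):
        score = _gaussian_bump((16, 16, 16), (8, 8, 8))
        labels = watershed_partition(DiscriminationMap(score), floor=0.1)
        assert labels.max() == 1

    def test_two_separated_bumps_two_regions_each_with_peak(self):
        shape = (32, 9, 9)
        score = _gaussian_bump(shape, (5, 4, 4)) + _gaussian_bump(shape, (25, 4, 4))
        labels = watershed_partition(DiscriminationMap(np.clip(score, 0, 1)),
                                     floor=0.1)
        assert labels.max() == 2
        assert labels[5, 4, 4] != labels[25, 4, 4]
        assert labels[5, 4, 4] > 0 and labels[25, 4, 4] > 0

    def test_labels_partition_above_floor_voxels(self, rng):
        from scipy.ndimage import gaussian_filter

        score = np.clip(gaussian_filter(rng.normal(size=(12, 12, 12)), 1.5) * 3,
                        -1, 1)
        dmap = DiscriminationMap(score)
        labels = watershed_partition(dmap, floor=0.1)
        mask = np.abs(score) >= 0.1
        assert (labels[mask] > 0).all()
        assert (labels[~mask] == 0).all()

    def test_all_zero_map_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            labels = watershed_partition(
                DiscriminationMap(np.zeros((8, 8, 8))), floor=0.1
            )
        assert labels.max() == 0


class TestSpatialConsistency:
    def test_identical_columns_perfect_agreement(self, rng):
        col = rng.normal(size=12)
        assert spatial_consistency(np.column_stack([col] * 4)) == pytest.approx(1.0)

    def test_two_by_two_exact_agreement(self):
        assert spatial_consistency(np.array([[1.0, 1.0], [2.0, 2.0]])) == (
            pytest.approx(1.0)
        )

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        icc = spatial_consistency(rng.normal(size=(200, 4)))
        assert abs(icc) < 0.2

    def test_zero_variance_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert spatial_consistency(np.ones((5, 3))) == 0.0

    def test_matches_pingouin_icc1(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1)) * 2
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(10), 4),
                "rater": np.tile(np.arange(4), 10),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="target", raters="rater", ratings="score"
        )
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert spatial_consistency(x) == pytest.approx(icc1, abs=1e-9)


class TestGrowRegion:
    def _perfect_seed_stack(self, rng, labels):
        """Voxel 0 tracks the labels perfectly; the rest are pure noise."""
        n = len(labels)
        stack = rng.normal(size=(n, 3, 3, 3))
        stack[:, 0, 0, 0] = np.asarray(labels, dtype=float)
        return stack

    def test_pure_noise_neighbors_stop_at_seed(self, rng):
        labels = np.array([0, 1] * 6)
        stack = self._perfect_seed_stack(rng, labels)
        dmap = voxelwise_discrimination(stack, labels)
        el = grow_region((0, 0, 0), dmap, stack, labels)
        assert el.size == 1 and el.seed_voxel == (0, 0, 0)
        assert el.discriminative_power == pytest.approx(1.0)

    def test_noiseless_planted_cube_recovered(self):
        """On a noiseless phantom the grown element covers the discriminative
        cube intersected with its watershed region."""
        shape = (9, 9, 9)
        labels = np.array([0, 1] * 5)
        stack = np.ones((10,) + shape)
        cube = np.zeros(shape, dtype=bool)
        cube[3:6, 3:6, 3:6] = True
        for i, y in enumerate(labels):
            stack[i][cube] += float(y)
        dmap = voxelwise_discrimination(stack, labels)
        regions = watershed_partition(dmap, floor=0.1)
        seed = (4, 4, 4)
        el = grow_region(seed, dmap, stack, labels,
                         region_mask=regions == regions[seed])
        got = {tuple(v) for v in el.voxels}
        want = {tuple(c) for c in np.argwhere(cube & (regions == regions[seed]))}
        assert want <= got

    def test_power_never_below_seed_power(self, rng):
        labels = np.array([0, 1] * 8)
        stack = rng.normal(size=(16, 6, 6, 6))
        dmap = voxelwise_discrimination(stack, labels)
        seed = np.unravel_index(np.argmax(np.abs(dmap.score)), dmap.score.shape)
        el = grow_region(seed, dmap, stack, labels)
        seed_power = abs(dmap.score[seed])
        assert el.discriminative_power >= seed_power - 1e-9

    def test_result_is_26_connected(self, rng):
        from scipy import ndimage

        labels = np.array([0, 1] * 8)
        stack = rng.normal(size=(16, 6, 6, 6))
        dmap = voxelwise_discrimination(stack, labels)
        el = grow_region((3, 3, 3), dmap, stack, labels)
        grid = np.zeros((6, 6, 6), dtype=bool)
        grid[tuple(el.voxels.T)] = True
        _, n_comp = ndimage.label(grid, structure=np.ones((3, 3, 3)))
        assert n_comp == 1

    def test_seed_outside_grid_rejected(self, rng):
        labels = np.array([0, 1] * 4)
        stack = rng.normal(size=(8, 4, 4, 4))
        dmap = voxelwise_discrimination(stack, labels)
        with pytest.raises(ValueError, match="outside grid"):
            grow_region((9, 0, 0), dmap, stack, labels)


def _element(values, idx=0):
    return RegionalElement(
        voxels=np.array([[idx, 0, 0]]),
        seed_voxel=(idx, 0, 0),
        feature_values=np.asarray(values, dtype=float),
        discriminative_power=0.5,
        consistency=1.0,
    )


class TestSelectFeatures:
    def test_separating_feature_ranked_first(self, rng):
        n = 40
        labels = np.array([0, 1] * (n // 2))
        good = _element(labels + rng.normal(0, 0.05, n), idx=0)
        noise = [_element(rng.normal(size=n), idx=i + 1) for i in range(20)]
        fset = select_features([good] + noise, labels)
        assert fset.elements[0].seed_voxel == (0, 0, 0)
        assert fset.n_selected <= 21

    def test_duplicate_of_best_stays_in_top_two(self, rng):
        n = 40
        labels = np.array([0, 1] * (n // 2))
        vals = labels + rng.normal(0, 0.05, n)
        good = _element(vals, idx=0)
        dup = _element(vals + rng.normal(0, 0.01, n), idx=1)
        noise = [_element(rng.normal(size=n), idx=i + 2) for i in range(10)]
        fset = select_features([good, dup] + noise, labels)
        top2 = {fset.elements[0].seed_voxel[0], fset.elements[1].seed_voxel[0]}
        assert top2 & {0, 1}

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="no candidate"):
            select_features([], np.array([0, 1, 0, 1]))

    def test_deterministic(self, rng):
        n = 20
        labels = np.array([0, 1] * (n // 2))
        cands = [_element(rng.normal(size=n), idx=i) for i in range(8)]
        f1 = select_features(cands, labels)
        f2 = select_features(cands, labels)
        assert [e.seed_voxel for e in f1.elements] == [
            e.seed_voxel for e in f2.elements
        ]
        assert f1.n_selected == f2.n_selected


class TestSvm:
    def test_separable_pair_classified_at_large_c(self):
        X = np.array([[0.0], [1.0], [0.1], [0.9]])
        y = np.array([0, 1, 0, 1])
        model = train_svm(X, y, PipelineConfig(svm_c=1e6))
        scores = model.decision(X)
        assert ((scores > 0).astype(int) == y).all()

    def test_xor_pattern_separated_by_rbf(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([0, 0, 1, 1])
        model = train_svm(X, y, PipelineConfig(svm_c=1e6, svm_gamma=1.0))
        assert ((model.decision(X) > 0).astype(int) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            train_svm(np.zeros((4, 1)), np.array([1, 1, 1, 1]))

    def test_nonfinite_features_rejected(self):
        X = np.array([[0.0], [np.nan], [1.0], [2.0]])
        with pytest.raises(ValueError, match="non-finite"):
            train_svm(X, np.array([0, 0, 1, 1]))

    def test_dimension_mismatch_rejected(self):
        model = train_svm(np.array([[0.0], [1.0], [0.2], [0.8]]),
                          np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="feature count"):
            classify(model, np.array([1.0, 2.0]))

    def test_deep_positive_point_scores_positive(self):
        X = np.concatenate([np.zeros((5, 1)), np.ones((5, 1))])
        y = np.array([0] * 5 + [1] * 5)
        model = train_svm(X, y, PipelineConfig(svm_c=10.0))
        assert classify(model, np.array([1.0])) > 0
        assert classify(model, np.array([0.0])) < 0

    def test_monotone_score_along_class_axis(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(0, 0.1, (10, 1)),
                            rng.normal(1, 0.1, (10, 1))])
        y = np.array([0] * 10 + [1] * 10)
        model = train_svm(X, y)
        sweep = [classify(model, np.array([v])) for v in np.linspace(0, 1, 9)]
        assert all(b >= a - 1e-9 for a, b in zip(sweep, sweep[1:]))


def test_extract_elements_finds_planted_region(tiny_signal_cohort):
    c = tiny_signal_cohort
    ids = [s.id for s in c.subjects]
    stack = np.stack([c.maps[i].gm.data for i in ids])
    labels = np.array([1 if s.group == "BD" else 0 for s in c.subjects])
    elements = extract_elements(stack, labels, PipelineConfig(), "GM")
    assert elements
    best = elements[0]
    # the strongest element sits on the planted sphere at (4,4,4)
    assert np.linalg.norm(np.asarray(best.seed_voxel) - 4) <= 3.0
    assert best.discriminative_power >= 0.8


def test_discrimination_map_and_feature_csv_export(tmp_path, rng):
    import nibabel as nib
    import pandas as pd

    from morphosvm.compare import features_to_csv, save_discrimination_map

    stack = rng.normal(size=(8, 5, 5, 5))
    labels = np.array([0, 1] * 4)
    dmap = voxelwise_discrimination(stack, labels)
    path = tmp_path / "dmap.nii"
    save_discrimination_map(dmap, path)
    back = np.asarray(nib.load(str(path)).dataobj)
    np.testing.assert_allclose(back, dmap.score, atol=1e-6)

    fset = select_features(
        [_element(rng.normal(size=8), idx=i) for i in range(3)], labels
    )
    csv_path = tmp_path / "features.csv"
    features_to_csv(fset, [f"s{i}" for i in range(8)], csv_path)
    df = pd.read_csv(csv_path, index_col="id")
    assert df.shape == (8, 3)
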