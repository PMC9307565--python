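import numpy as np
import pytest

from radharm import (apply_normalisation, discretise, extract_study, glcm,
                     gldm, glrlm, glszm)
from radharm.features import (PANEL_SIZE, _glcm_features, first_order_features,
                              second_order_features)

import _oracles
from conftest import random_roi


def _droi(levels, mask, bin_width=1.0):
    from radharm.features import DiscretisedROI
    return DiscretisedROI(levels=np.asarray(levels), mask=np.asarray(mask),
                          bin_width=bin_width, ng=int(np.max(levels)))


class TestDiscretise:
    def test_fixed_bin_width_formula(self):
        vox = np.array([[[0.0, 60.0]]])
        d = discretise(vox, np.ones_like(vox, bool), 25.0)
        assert d.roi_levels.tolist() == [1, 3]

    def test_constant_roi(self):
        vox = np.full((1, 2, 2), 4.2)
        d = discretise(vox, np.ones_like(vox, bool), 25.0)
        assert d.ng == 1
        assert set(d.roi_levels) == {1}

    def test_unit_range_with_fine_bins(self, rng):
        vox = rng.random((2, 8, 8))[None][0]
        vox.flat[0], vox.flat[1] = 0.0, 1.0
        d = discretise(vox, np.ones_like(vox, bool), 0.05)
        assert d.ng <= 21

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            discretise(np.zeros((1, 2, 2)), np.ones((1, 2, 2), bool), 0.0)


class TestMatrixExamples:
    def test_glcm_horizontal_pairs_example(self):
        levels = np.array([[[1, 1], [2, 2]]])
        d = _droi(levels, np.ones_like(levels, bool))
        tm = glcm(d, directions=[(0, 0, 1)])
        np.testing.assert_array_equal(tm.matrix, [[2.0, 0.0], [0.0, 2.0]])

    def test_glcm_constant_roi_single_diagonal_entry(self):
        levels = np.ones((1, 3, 3), dtype=int)
        d = _droi(levels, np.ones_like(levels, bool))
        tm = glcm(d)
        assert tm.matrix.shape == (1, 1)
        assert tm.matrix[0, 0] > 0

    def test_glrlm_strip_example(self):
        levels = np.array([[[1, 1, 2, 2, 2]]])
        d = _droi(levels, np.ones_like(levels, bool))
        tm = glrlm(d, directions=[(0, 0, 1)])
        expected = np.zeros((2, 3))
        expected[0, 1] = 1  # level 1, run length 2
        expected[1, 2] = 1  # level 2, run length 3
        np.testing.assert_array_equal(tm.matrix, expected)

    def test_glszm_constant_roi_single_zone(self):
        mask = np.zeros((2, 4, 4), bool)
        mask[:, 1:3, 1:3] = True
        levels = np.where(mask, 1, 0)
        tm = glszm(_droi(levels, mask))
        assert tm.matrix.shape == (1, 8)
        assert tm.matrix[0, 7] == 1.0 and tm.matrix.sum() == 1.0


@pytest.mark.parametrize("seed", range(30))
def test_matrices_equal_bruteforce_oracle(seed):
    """All four texture matrices must agree with the independent
    enumeration oracle on random small ROIs."""
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(1, 3)), int(rng.integers(2, 9)),
             int(rng.integers(2, 9)))
    levels, mask = random_roi(rng, shape=shape,
                              n_levels=int(rng.integers(2, 6)))
    d = _droi(levels, mask)
    np.testing.assert_array_equal(glcm(d).matrix,
                                  _oracles.glcm_oracle(levels, mask))
    np.testing.assert_array_equal(glrlm(d).matrix,
                                  _oracles.glrlm_oracle(levels, mask))
    np.testing.assert_array_equal(glszm(d).matrix,
                                  _oracles.glszm_oracle(levels, mask))
    np.testing.assert_array_equal(gldm(d).matrix,
                                  _oracles.gldm_oracle(levels, mask))


class TestMatrixInvariants:
    def test_glcm_symmetric_and_normalises_to_one(self, rng):
        levels, mask = random_roi(rng)
        tm = glcm(_droi(levels, mask))
        np.testing.assert_array_equal(tm.matrix, tm.matrix.T)
        p = tm.matrix / tm.matrix.sum()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_glszm_sizes_account_for_all_voxels(self, rng):
        levels, mask = random_roi(rng)
        tm = glszm(_droi(levels, mask))
        sizes = np.arange(1, tm.matrix.shape[1] + 1)
        assert (tm.matrix * sizes).sum() == mask.sum()

    def test_glrlm_lengths_account_for_all_voxels_per_direction(self, rng):
        levels, mask = random_roi(rng)
        tm = glrlm(_droi(levels, mask))
        lengths = np.arange(1, tm.matrix.shape[1] + 1)
        assert (tm.matrix * lengths).sum() == tm.n_directions * mask.sum()

    def test_gldm_counts_every_voxel_once(self, rng):
        levels, mask = random_roi(rng)
        tm = gldm(_droi(levels, mask))
        assert tm.matrix.sum() == mask.sum()


class TestFirstOrder:
    def test_basic_statistics(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d = discretise(x, np.ones(4, bool), 1.0)
        f = first_order_features(d, x)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Median"] == pytest.approx(2.5)
        assert f["Range"] == pytest.approx(3.0)

    def test_constant_input_degenerate_values(self):
        x = np.full(10, 5.0)
        d = discretise(x, np.ones(10, bool), 1.0)
        f = first_order_features(d, x)
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0

    def test_moments_match_naive_oracle(self, rng):
        x = rng.gamma(2.0, 3.0, 500)
        d = discretise(x, np.ones(x.size, bool), 0.5)
        f = first_order_features(d, x)
        mu = sum(x) / len(x)
        m2 = sum((v - mu) ** 2 for v in x) / len(x)
        m3 = sum((v - mu) ** 3 for v in x) / len(x)
        m4 = sum((v - mu) ** 4 for v in x) / len(x)
        assert f["Mean"] == pytest.approx(mu, abs=1e-10)
        assert f["Variance"] == pytest.approx(m2, abs=1e-10)
        assert f["Skewness"] == pytest.approx(m3 / m2**1.5, abs=1e-10)
        assert f["Kurtosis"] == pytest.approx(m4 / m2**2, abs=1e-10)
        assert f["RootMeanSquared"] == pytest.approx(
            np.sqrt(sum(v * v for v in x) / len(x)), abs=1e-10)


class TestSecondOrder:
    def test_constant_roi_glcm_autocorrelation_is_one(self):
        levels = np.ones((1, 3, 3), dtype=int)
        tm = glcm(_droi(levels, np.ones_like(levels, bool)))
        f = _glcm_features(tm.matrix)
        assert f["Autocorrelation"] == pytest.approx(1.0)

    def test_joint_average_hand_example(self):
        f = _glcm_features(np.array([[0.25, 0.25], [0.25, 0.25]]))
        assert f["JointAverage"] == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_all_features_finite_on_random_rois(self, seed):
        rng = np.random.default_rng(100 + seed)
        levels, mask = random_roi(rng, n_levels=int(rng.integers(1, 7)))
        d = _droi(levels, mask)
        matrices = {"GLCM": glcm(d), "GLRLM": glrlm(d), "GLSZM": glszm(d),
                    "GLDM": gldm(d)}
        feats = second_order_features(matrices, int(mask.sum()))
        for fam, fs in feats.items():
            for name, v in fs.items():
                assert np.isfinite(v), f"{fam}/{name} not finite"


class TestExtractStudy:
    def test_deterministic(self, raw_study):
        a = extract_study(raw_study, 25.0)
        b = extract_study(raw_study, 25.0)
        assert a == b

    def test_panel_size_per_roi(self, raw_study):
        f = extract_study(raw_study, 25.0)
        assert len(f) == 3 * PANEL_SIZE
        for roi in ("LV", "MYO", "RV"):
            assert sum(k.startswith(roi + "|") for k in f) == PANEL_SIZE

    def test_shift_invariance_after_rescaling(self, raw_study):
        """With rescaling upstream, a global intensity shift must not change
        any discretised feature."""
        from dataclasses import replace
        shifted = replace(raw_study, voxels=raw_study.voxels + 137.0)
        a = extract_study(apply_normalisation(raw_study, "R"), 0.05)
        b = extract_study(apply_normalisation(shifted, "R"), 0.05)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_empty_roi_missing_coded(self, raw_study):
        from dataclasses import replace
        mask = raw_study.mask.copy()
        mask[mask == 3] = 0  # drop the RV
        s = replace(raw_study, mask=mask)
        f = extract_study(s, 25.0)
        assert all(np.isnan(v) for k, v in f.items() if k.startswith("RV|"))
        assert all(np.isfinite(v) for k, v in f.items() if k.startswith("LV|"))
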