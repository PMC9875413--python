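"""Texture matrices against hand enumeration and brute-force oracles."""

import numpy as np
import pytest

from exhaustscope.texture import (
    DIRECTIONS_13,
    DegenerateTextureError,
    DiscretizationConfig,
    TextureConfig,
    discretize,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
)

# --------------------------------------------------------------------------
# Brute-force oracles: direct enumeration of pairs and runs


def brute_glcm(labeled, directions, distance=1, symmetric=True):
    """Count co-occurring level pairs by looping over every voxel."""
    n = int(labeled.max())
    counts = np.zeros((n, n))
    shape = labeled.shape
    for d in directions:
        off = tuple(c * distance for c in d)
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    a = labeled[z, y, x]
                    zz, yy, xx = z + off[0], y + off[1], x + off[2]
                    if not (0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]):
                        continue
                    b = labeled[zz, yy, xx]
                    if a > 0 and b > 0:
                        counts[a - 1, b - 1] += 1
                        if symmetric:
                            counts[b - 1, a - 1] += 1
    return counts / counts.sum()


def brute_glrlm(labeled, directions):
    """Enumerate maximal same-level runs along every line of every direction."""
    n = int(labeled.max())
    shape = labeled.shape
    runs = {}
    for d in directions:
        starts = [
            (z, y, x)
            for z in range(shape[0])
            for y in range(shape[1])
            for x in range(shape[2])
            # a line start has no in-grid predecessor along d
            if not (
                0 <= z - d[0] < shape[0]
                and 0 <= y - d[1] < shape[1]
                and 0 <= x - d[2] < shape[2]
            )
        ]
        for start in starts:
            line = []
            p = start
            while all(0 <= c < s for c, s in zip(p, shape)):
                line.append(labeled[p])
                p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            i = 0
            while i < len(line):
                j = i
                while j < len(line) and line[j] == line[i]:
                    j += 1
                if line[i] > 0:
                    runs[(line[i], j - i)] = runs.get((line[i], j - i), 0) + 1
                i = j
    max_len = max((l for (_, l) in runs), default=1)
    R = np.zeros((n, max_len))
    for (g, l), c in runs.items():
        R[g - 1, l - 1] = c
    return R


# --------------------------------------------------------------------------


class TestDiscretize:
    def test_integer_values_align_with_bins(self):
        vals = np.array([[[0.0, 1.0], [2.0, 3.0]]])
        mask = np.ones_like(vals, dtype=bool)
        out = discretize(vals, mask, DiscretizationConfig(4))
        assert np.array_equal(out, np.array([[[1, 2], [3, 4]]]))

    def test_constant_roi_maps_to_level_one(self):
        vals = np.full((2, 2, 2), 7.0)
        out = discretize(vals, np.ones_like(vals, dtype=bool), DiscretizationConfig(16))
        assert np.all(out == 1)

    def test_two_values_two_levels(self):
        vals = np.array([[[0.0, 10.0]]])
        out = discretize(vals, np.ones_like(vals, dtype=bool), DiscretizationConfig(2))
        assert np.array_equal(out, np.array([[[1, 2]]]))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestGlcm:
    def test_hand_enumerated_2x2_example(self):
        """Two horizontal pairs [(1,1), (1,2)], symmetrized: P(1,1)=1/2,
        P(1,2)=P(2,1)=1/4."""
        labeled = np.array([[[1, 1], [1, 2]]])
        cfg = TextureConfig(directions=((0, 0, 1),))
        P = glcm(labeled, cfg)
        assert P == pytest.approx(np.array([[0.5, 0.25], [0.25, 0.0]]))

    def test_homogeneous_roi_all_mass_on_diagonal(self):
        P = glcm(np.ones((3, 3, 3), dtype=int))
        assert P.shape == (1, 1)
        assert P[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization(self, seed):
        rng = np.random.default_rng(seed)
        labeled = rng.integers(0, 5, size=(4, 4, 4))
        P = glcm(labeled)
        assert P.sum() == pytest.approx(1.0)

    def test_degenerate_roi_rejected(self):
        labeled = np.zeros((3, 3, 3), dtype=int)
        labeled[0, 0, 0] = 1  # one voxel: no neighbor pairs
        with pytest.raises((DegenerateTextureError, ValueError)):
            glcm(labeled)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        """Vectorized GLCM equals the voxel-loop enumerator exactly on
        random small ROIs with holes."""
        rng = np.random.default_rng(100 + seed)
        shape = tuple(rng.integers(2, 5, size=3))
        labeled = rng.integers(0, 4, size=shape)
        if (labeled > 0).sum() < 4:
            labeled[0, 0, 0] = labeled[-1, -1, -1] = 1
        P = glcm(labeled, TextureConfig())
        B = brute_glcm(labeled, DIRECTIONS_13)
        assert P == pytest.approx(B, abs=1e-12)


class TestGlcmFeatures:
    def test_hand_example_closed_forms(self):
        P = np.array([[0.5, 0.25], [0.25, 0.0]])
        f = glcm_features(P)
        assert f["Contrast"] == pytest.approx(0.5)
        assert f["Homogeneity2"] == pytest.approx(0.75)
        assert f["InverseVariance"] == pytest.approx(0.5)

    def test_diagonal_matrix_is_the_homogeneous_limit(self):
        P = np.diag([0.5, 0.5])
        f = glcm_features(P)
        assert f["Contrast"] == 0.0
        assert f["Homogeneity2"] == pytest.approx(1.0)
        assert f["InverseVariance"] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_hold_for_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.uniform(size=(6, 6))
        M = M + M.T
        P = M / M.sum()
        f = glcm_features(P)
        assert 0.0 < f["Homogeneity2"] <= 1.0
        assert f["Contrast"] >= 0.0
        assert all(np.isfinite(v) for v in f.values())

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            glcm_features(np.ones((3, 3)))


class TestGlrlm:
    def test_hand_enumerated_line_runs(self):
        """[1,1,1,2] along one direction: a 3-run of level 1 and a 1-run of
        level 2; run percentage 2/4."""
        labeled = np.array([[[1, 1, 1, 2]]])
        cfg = TextureConfig(directions=((0, 0, 1),))
        R = glrlm(labeled, cfg)
        assert R[0, 2] == 1  # level 1, length 3
        assert R[1, 0] == 1  # level 2, length 1
        assert R.sum() == 2
        f = glrlm_features(labeled, cfg)
        assert f["RunPercentage"] == pytest.approx(0.5)

    def test_checkerboard_maximizes_short_run_emphasis(self):
        labeled = np.array([[[1, 2, 1, 2]]])
        cfg = TextureConfig(directions=((0, 0, 1),))
        f = glrlm_features(labeled, cfg)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0)

    def test_homogeneous_line_is_one_run(self):
        labeled = np.ones((1, 1, 8), dtype=int)
        cfg = TextureConfig(directions=((0, 0, 1),))
        R = glrlm(labeled, cfg)
        assert R.sum() == 1
        assert R[0, 7] == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        shape = tuple(rng.integers(2, 5, size=3))
        labeled = rng.integers(0, 4, size=shape)
        if (labeled > 0).sum() < 2:
            labeled[0, 0, 0] = labeled[-1, -1, -1] = 1
        R = glrlm(labeled, TextureConfig())
        B = brute_glrlm(labeled, DIRECTIONS_13)
        # pad to common width before comparing
        w = max(R.shape[1], B.shape[1])
        Rp = np.pad(R, ((0, 0), (0, w - R.shape[1])))
        Bp = np.pad(B, ((0, B.shape[0] - R.shape[0] if B.shape[0] > R.shape[0] else 0), (0, w - B.shape[1])))
        assert Rp == pytest.approx(Bp[: R.shape[0]], abs=0)


class TestTextureConfig:
    def test_redundant_direction_rejected(self):
        with pytest.raises(ValueError, match="redundant"):
            TextureConfig(directions=((0, 0, 1), (0, 0, -1)))

    def test_thirteen_unique_directions(self):
        assert len(DIRECTIONS_13) == 13
        as_set = {d for d in DIRECTIONS_13}
        negs = {tuple(-c for c in d) for d in DIRECTIONS_13}
        assert not (as_set & negs)
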