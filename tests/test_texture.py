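import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytostress.exceptions import ConfigurationError, ContractError, DegenerateInputError
from phytostress.texture import (
    GLCM,
    STANDARD_OFFSETS,
    compute_glcm,
    energy,
    entropy,
    extract_features,
    local_homogeneity,
    quantize,
    segment_leaf,
    to_grayscale,
)


def brute_force_glcm(q, levels, offset, symmetric, mask=None):
    """Independent oracle: enumerate every pixel pair explicitly."""
    h, w = q.shape
    if mask is None:
        mask = np.ones_like(q, dtype=bool)
    dr, dc = offset
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def checkerboard(n=8):
    return np.indices((n, n)).sum(axis=0) % 2


class TestToGrayscale:
    def test_identity_on_gray_input(self):
        rgb = np.full((4, 4, 3), 0.4)
        np.testing.assert_allclose(to_grayscale(rgb), 0.4)

    def test_all_black(self):
        np.testing.assert_array_equal(to_grayscale(np.zeros((3, 3, 3))), 0.0)

    def test_documented_weights(self):
        # hand arithmetic with the BT.601 weights 0.299/0.587/0.114
        rgb = np.zeros((2, 2, 3))
        rgb[0, 0] = (1.0, 0.0, 0.0)
        rgb[0, 1] = (0.0, 1.0, 0.0)
        rgb[1, 0] = (0.0, 0.0, 1.0)
        rgb[1, 1] = (0.5, 0.5, 0.5)
        gray = to_grayscale(rgb)
        np.testing.assert_allclose(gray, [[0.299, 0.587], [0.114, 0.5]])

    def test_wrong_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            to_grayscale(np.zeros((4, 4)))


class TestSegmentLeaf:
    def test_disc_matches_threshold_oracle(self):
        yy, xx = np.mgrid[:64, :64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15 ** 2
        img = np.where(disc, 0.9, 0.1)
        mask = segment_leaf(img)
        # agree with the intensity-threshold oracle within a 2-pixel band
        from skimage.morphology import dilation, disk, erosion
        assert mask[erosion(disc, disk(2))].all()
        assert not mask[~dilation(disc, disk(2))].any()

    def test_uniform_image_falls_back_to_full_frame(self, caplog):
        with caplog.at_level("WARNING"):
            mask = segment_leaf(np.full((32, 32), 0.5))
        assert mask.all()
        assert any("no foreground" in rec.message for rec in caplog.records)

    def test_synthetic_leaf_mask_fraction(self):
        from phytostress.synth import SyntheticLeafImageSpec, generate_leaf_image
        img = generate_leaf_image(SyntheticLeafImageSpec(stress_severity=1.0, seed=4))
        frac = segment_leaf(img).mean()
        assert 0.0 < frac <= 1.0


class TestComputeGlcm:
    def test_constant_image_single_cell(self):
        glcm = compute_glcm(np.full((6, 6), 0.5), levels=4, offset=(0, 1))
        assert glcm.p.sum() == pytest.approx(1.0)
        assert glcm.p.max() == pytest.approx(1.0)

    def test_checkerboard(self):
        glcm = compute_glcm(checkerboard(), levels=2, offset=(0, 1), symmetric=True,
                            value_range=(0, 2))
        assert glcm.p[0, 1] == pytest.approx(0.5)
        assert glcm.p[1, 0] == pytest.approx(0.5)
        assert glcm.p[0, 0] == glcm.p[1, 1] == 0.0

    def test_printed_two_level_fixture(self):
        img = np.array([[0, 0, 1, 1],
                        [0, 0, 1, 1],
                        [0, 1, 1, 0],
                        [1, 1, 0, 0]])
        for symmetric in (False, True):
            glcm = compute_glcm(img, levels=2, offset=(0, 1), symmetric=symmetric,
                                value_range=(0, 2))
            oracle = brute_force_glcm(img, 2, (0, 1), symmetric)
            np.testing.assert_allclose(glcm.p, oracle)

    @pytest.mark.parametrize("offset", STANDARD_OFFSETS)
    def test_oracle_equivalence_random_images(self, offset, rng):
        for _ in range(10):
            h, w = rng.integers(4, 17, size=2)
            levels = int(rng.integers(2, 6))
            img = rng.integers(0, levels, size=(h, w))
            glcm = compute_glcm(img, levels=levels, offset=offset, symmetric=True,
                                value_range=(0, levels))
            np.testing.assert_allclose(glcm.p, brute_force_glcm(img, levels, offset, True))

    def test_oracle_equivalence_with_mask(self, rng):
        img = rng.integers(0, 4, size=(12, 12))
        mask = rng.random((12, 12)) > 0.3
        glcm = compute_glcm(img, levels=4, offset=(1, 1), symmetric=False,
                            mask=mask, value_range=(0, 4))
        np.testing.assert_allclose(glcm.p, brute_force_glcm(img, 4, (1, 1), False, mask))

    def test_symmetric_flag_gives_exact_transpose(self, rng):
        img = rng.integers(0, 5, size=(10, 10))
        glcm = compute_glcm(img, levels=5, offset=(0, 1), symmetric=True,
                            value_range=(0, 5))
        np.testing.assert_array_equal(glcm.p, glcm.p.T)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(2, 8),
           st.sampled_from(STANDARD_OFFSETS))
    def test_normalization_property(self, seed, levels, offset):
        r = np.random.default_rng(seed)
        img = r.random((r.integers(4, 12), r.integers(4, 12)))
        glcm = compute_glcm(img, levels=levels, offset=offset)
        assert abs(glcm.p.sum() - 1.0) <= 1e-12
        assert (glcm.p >= 0).all()

    def test_gray_offset_invariance(self, rng):
        # fixed bin edges spanning the declared range: shifting both leaves
        # the quantized image, hence every feature, unchanged
        img = rng.random((16, 16))
        shift = 3.7
        q0 = quantize(img, 8, (0.0, 1.0))
        q1 = quantize(img + shift, 8, (shift, 1.0 + shift))
        np.testing.assert_array_equal(q0, q1)
        a = extract_features(img, value_range=(0.0, 1.0))
        b = extract_features(img + shift, value_range=(shift, 1.0 + shift))
        assert a == b

    def test_no_valid_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_glcm(np.zeros((4, 4)), levels=2, offset=(0, 1),
                         mask=np.zeros((4, 4), dtype=bool))
        with pytest.raises(DegenerateInputError):
            compute_glcm(np.zeros((2, 2)), levels=2, offset=(0, 5))


def uniform_glcm(cells):
    """GLCM with equal probability on the given (i, j) cells (2 levels)."""
    p = np.zeros((2, 2))
    for i, j in cells:
        p[i, j] = 1.0 / len(cells)
    return GLCM(p, (0, 1), symmetric=False, pair_count=len(cells))


class TestStatistics:
    def test_entropy_closed_forms(self):
        assert entropy(uniform_glcm([(0, 0)])) == pytest.approx(0.0)
        four = uniform_glcm([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert entropy(four) == pytest.approx(math.log(4))
        cb = uniform_glcm([(0, 1), (1, 0)])
        assert entropy(cb) == pytest.approx(math.log(2))

    def test_entropy_log_bases(self):
        four = uniform_glcm([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert entropy(four, 2) == pytest.approx(2.0)
        assert entropy(four, 10) == pytest.approx(math.log10(4))

    def test_energy_closed_forms(self):
        assert energy(uniform_glcm([(0, 0)])) == pytest.approx(1.0)
        assert energy(uniform_glcm([(0, 0), (0, 1), (1, 0), (1, 1)])) == pytest.approx(0.25)
        assert energy(uniform_glcm([(0, 1), (1, 0)])) == pytest.approx(0.5)

    def test_homogeneity_closed_forms(self):
        assert local_homogeneity(uniform_glcm([(0, 0), (1, 1)])) == pytest.approx(1.0)
        assert local_homogeneity(uniform_glcm([(0, 1), (1, 0)])) == pytest.approx(0.5)

    def test_unnormalized_glcm_rejected(self):
        with pytest.raises(ContractError):
            GLCM(np.full((2, 2), 0.3), (0, 1), False, 4)
        with pytest.raises(ContractError):
            GLCM(np.array([[1.5, -0.5], [0.0, 0.0]]), (0, 1), False, 4)

    def test_entropy_energy_duality(self, rng):
        # at fixed support, the uniform distribution maximizes entropy
        # and minimizes energy
        cells = [(0, 0), (0, 1), (1, 0), (1, 1)]
        uni = uniform_glcm(cells)
        for _ in range(20):
            probs = rng.dirichlet(np.ones(4))
            p = np.zeros((2, 2))
            for (i, j), v in zip(cells, probs):
                p[i, j] = v
            g = GLCM(p, (0, 1), False, 4)
            assert entropy(g) <= entropy(uni) + 1e-12
            assert energy(g) >= energy(uni) - 1e-12


class TestExtractFeatures:
    def test_constant_image(self):
        vec = extract_features(np.full((8, 8), 0.3))
        assert (vec.entropy, vec.energy, vec.homogeneity) == pytest.approx((0.0, 1.0, 1.0))

    def test_checkerboard(self):
        vec = extract_features(checkerboard(), levels=2, value_range=(0, 2))
        assert vec.entropy == pytest.approx(math.log(2))
        assert vec.energy == pytest.approx(0.5)
        assert vec.homogeneity == pytest.approx(0.5)

    def test_direction_averaging_runs(self, rng):
        img = rng.random((16, 16))
        vec = extract_features(img, average_directions=True)
        assert vec.entropy > 0
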