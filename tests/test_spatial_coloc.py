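"""Shell geometry, Manders overlap, released fractions, line profiles, and
puncta counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from synquant import spatial_coloc, syngen
from synquant.errors import ShellWidthError, UndefinedFractionError, UndefinedMOCError
from synquant.syngen import GenConfig
from synquant.types import MaskedImagePair


def disk_mask(radius=20, shape=(64, 64)):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    c = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return (rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= radius ** 2


def pair_from(channel_r, mask, channel_g=None, pixel_size=100.0):
    if channel_g is None:
        channel_g = np.zeros_like(channel_r)
    return MaskedImagePair(channel_r=channel_r, channel_g=channel_g,
                           cell_mask=mask, pixel_size=pixel_size)


class TestMembraneShell:
    def test_subpixel_width_rejected(self):
        with pytest.raises(ShellWidthError):
            spatial_coloc.membrane_shell(disk_mask(), shell_width=50.0,
                                         pixel_size=100.0)

    def test_erosion_matches_brute_force_disk_structuring_element(self):
        """Independent oracle: the shell must equal the mask minus binary
        erosion with an explicitly constructed Euclidean disk."""
        mask = disk_mask(radius=20)
        shell, degenerate = spatial_coloc.membrane_shell(mask, 800.0, 100.0)
        assert not degenerate
        r = 8
        offsets = np.mgrid[-r:r + 1, -r:r + 1]
        selem = (offsets[0] ** 2 + offsets[1] ** 2) <= r ** 2
        eroded = ndimage.binary_erosion(mask, structure=selem)
        assert np.array_equal(shell, mask & ~eroded)
        assert np.array_equal(shell | eroded, mask)

    def test_thin_cell_degenerates_to_whole_mask(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:14, 5:28] = True  # 4 px wide strip vs 8 px shell
        with pytest.warns(UserWarning):
            shell, degenerate = spatial_coloc.membrane_shell(mask, 800.0, 100.0)
        assert degenerate and np.array_equal(shell, mask)


class TestMembraneProximalFraction:
    def test_uniform_intensity_equals_pixel_count_ratio(self):
        mask = disk_mask(radius=22)
        img = pair_from(np.where(mask, 3.0, 0.0), mask)
        res = spatial_coloc.membrane_proximal_fraction(img, "R", 800.0)
        assert res.shell_fraction == pytest.approx(
            res.shell_pixel_count / res.mask_pixel_count, abs=1e-12)

    def test_all_intensity_in_shell(self):
        mask = disk_mask(radius=22)
        shell, _ = spatial_coloc.membrane_shell(mask, 800.0, 100.0)
        img = pair_from(np.where(shell, 5.0, 0.0), mask)
        res = spatial_coloc.membrane_proximal_fraction(img)
        assert res.shell_fraction == pytest.approx(1.0)

    def test_zero_intensity_undefined(self):
        mask = disk_mask()
        with pytest.raises(UndefinedFractionError):
            spatial_coloc.membrane_proximal_fraction(pair_from(np.zeros_like(mask, float), mask))

    def test_monotone_in_shell_width_and_saturates(self):
        img, _ = syngen.gen_cell_image(true_shell_fraction=0.4, cfg=GenConfig(seed=9))
        widths = [200.0, 400.0, 800.0, 1600.0, 12800.0]
        fracs = [spatial_coloc.membrane_proximal_fraction(img, "R", w).shell_fraction
                 for w in widths[:-1]]
        with pytest.warns(UserWarning):  # widest shell swallows the whole cell
            fracs.append(spatial_coloc.membrane_proximal_fraction(
                img, "R", widths[-1]).shell_fraction)
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == pytest.approx(1.0)

    def test_generator_closure(self):
        img, gt = syngen.gen_cell_image(true_shell_fraction=0.40,
                                        cfg=GenConfig(seed=21))
        res = spatial_coloc.membrane_proximal_fraction(img, "R", 800.0)
        assert res.shell_fraction == pytest.approx(0.40, abs=0.03)


class TestReleasedFraction:
    def test_identical_images_is_one(self):
        img, _ = syngen.gen_cell_image(cfg=GenConfig(seed=4))
        assert spatial_coloc.released_fraction(img, img) == pytest.approx(1.0)

    def test_half_shell_signal_is_half(self):
        img, _ = syngen.gen_cell_image(cfg=GenConfig(seed=4))
        post_stim = MaskedImagePair(channel_r=0.5 * img.channel_r,
                                    channel_g=img.channel_g,
                                    cell_mask=img.cell_mask,
                                    pixel_size=img.pixel_size)
        assert spatial_coloc.released_fraction(post_stim, img) == pytest.approx(0.5)

    def test_invariant_to_common_scaling(self):
        img, _ = syngen.gen_cell_image(cfg=GenConfig(seed=4))
        a = MaskedImagePair(0.5 * img.channel_r, img.channel_g, img.cell_mask)
        scaled_a = MaskedImagePair(0.5 * 7 * img.channel_r, img.channel_g, img.cell_mask)
        scaled_b = MaskedImagePair(7 * img.channel_r, img.channel_g, img.cell_mask)
        assert spatial_coloc.released_fraction(a, img) == pytest.approx(
            spatial_coloc.released_fraction(scaled_a, scaled_b))


class TestMandersOverlap:
    def test_hand_evaluated_two_pixel_fixture(self):
        mask = np.ones((1, 2), dtype=bool)
        img = pair_from(np.array([[1.0, 2.0]]), mask, np.array([[2.0, 1.0]]))
        assert spatial_coloc.manders_overlap(img) == pytest.approx(0.8, abs=1e-12)

    def test_identical_channels_unity(self):
        mask = disk_mask()
        ch = np.where(mask, np.random.default_rng(0).uniform(0, 10, mask.shape), 0.0)
        assert spatial_coloc.manders_overlap(pair_from(ch, mask, ch.copy())) == \
            pytest.approx(1.0, abs=1e-12)

    def test_zero_channel_undefined(self):
        mask = disk_mask()
        with pytest.raises(UndefinedMOCError):
            spatial_coloc.manders_overlap(pair_from(np.where(mask, 1.0, 0.0), mask))

    @given(data=arrays(float, (4, 4), elements=st.floats(0.01, 100.0)),
           scale=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_scale_invariance_and_bounds(self, data, scale):
        rng = np.random.default_rng(0)
        other = rng.uniform(0.1, 10.0, data.shape)
        mask = np.ones(data.shape, dtype=bool)
        fwd = spatial_coloc.manders_overlap(pair_from(data, mask, other))
        rev = spatial_coloc.manders_overlap(pair_from(other, mask, data))
        scl = spatial_coloc.manders_overlap(pair_from(scale * data, mask, other))
        assert fwd == pytest.approx(rev, abs=1e-12)
        assert fwd == pytest.approx(scl, rel=1e-9)
        assert -1e-12 <= fwd <= 1 + 1e-12


class TestLineProfile:
    def test_constant_image_flat_profile(self):
        mask = np.ones((32, 32), dtype=bool)
        img = pair_from(np.full((32, 32), 7.0), mask)
        prof = spatial_coloc.line_profile(img, (5, 5), (25, 25))
        assert np.allclose(prof["R"], 7.0)

    def test_column_gradient_gives_linear_profile(self):
        mask = np.ones((16, 32), dtype=bool)
        grad = np.tile(np.arange(32, dtype=float), (16, 1))
        img = pair_from(grad, mask)
        prof = spatial_coloc.line_profile(img, (8, 2), (8, 30), n_samples=29)
        assert np.allclose(prof["R"], np.linspace(2, 30, 29))

    def test_distance_axis_in_nm(self):
        mask = np.ones((32, 32), dtype=bool)
        img = pair_from(np.ones((32, 32)), mask, pixel_size=100.0)
        prof = spatial_coloc.line_profile(img, (0, 0), (3, 4))
        assert prof["distance_nm"].iloc[-1] == pytest.approx(500.0)

    def test_zero_length_rejected(self):
        mask = np.ones((8, 8), dtype=bool)
        img = pair_from(np.ones((8, 8)), mask)
        with pytest.raises(ValueError):
            spatial_coloc.line_profile(img, (2, 2), (2, 2))


class TestPunctaCount:
    def test_generator_closure_colabeled_count(self):
        img, gt = syngen.gen_coloc_pair("partial", n_puncta=10, n_shared=7,
                                        cfg=GenConfig(seed=6))
        count = spatial_coloc.count_colocalized_puncta(img, "R", "G",
                                                       puncta_sigma=1.5)
        assert count == gt.n_colabeled == 7

    def test_no_puncta_gives_zero(self):
        mask = disk_mask()
        img = pair_from(np.where(mask, 1.0, 0.0), mask, np.where(mask, 1.0, 0.0))
        assert spatial_coloc.count_colocalized_puncta(img) == 0

    def test_zero_label_channel_gives_zero(self):
        img, _ = syngen.gen_coloc_pair("partial", n_puncta=8, n_shared=0,
                                       cfg=GenConfig(seed=6))
        assert spatial_coloc.count_colocalized_puncta(img) == 0
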