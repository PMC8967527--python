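"""Mish activation, BiFPN same-size contract, circularity and screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulekit import nodules, phantom
from nodulekit.nn.autograd import Tensor
from nodulekit.nodules import (BiFPNUNet, NoduleNetConfig, build_nodule_net,
                               circularity, mish, screen_candidates)


class TestMish:
    def test_zero_fixed_point(self):
        assert mish(0.0) == 0.0

    def test_identity_asymptote(self):
        assert abs(mish(10.0) - 10.0) < 1e-3

    def test_negative_reference_value(self):
        # x·tanh(softplus(x)) at −5, evaluated stably
        assert abs(mish(-5.0) - (-5.0 * np.tanh(np.log1p(np.exp(-5.0))))) < 1e-12
        assert abs(mish(-5.0) - (-0.03357)) < 5e-5

    def test_no_overflow_at_extremes(self):
        assert np.isfinite(mish(1e4)) and np.isfinite(mish(-1e4))
        assert abs(mish(-1e4)) < 1e-9

    def test_global_minimum_against_grid_search(self):
        """Brute-force grid oracle: min ≈ −0.3088 near x ≈ −1.19."""
        xs = np.arange(-5.0, 0.0, 1e-4)
        ys = mish(xs)
        k = int(np.argmin(ys))
        assert abs(ys[k] - (-0.3088)) < 1e-3
        assert abs(xs[k] - (-1.19)) < 0.02
        assert ys.min() >= -0.31

    def test_increasing_for_nonnegative_x(self):
        xs = np.linspace(0, 20, 2000)
        assert (np.diff(mish(xs)) > 0).all()


class TestNoduleNet:
    def test_depth_below_three_rejected(self):
        with pytest.raises(ValueError):
            NoduleNetConfig(levels=2)

    @pytest.mark.parametrize("size", [64, 200])
    def test_five_level_same_size_contract(self, size):
        net = build_nodule_net(levels=5, base_channels=2, pyramid_channels=4,
                               seed=0)
        out = net(Tensor(np.random.default_rng(0).random(
            (1, 1, size, size)).astype(np.float32)))
        assert out.shape == (1, 1, size, size)
        assert (out.data >= 0).all() and (out.data <= 1).all()

    def test_three_level_test_config(self):
        net = build_nodule_net(levels=3, base_channels=2, pyramid_channels=4,
                               seed=0)
        out = net(Tensor(np.zeros((1, 1, 64, 64), np.float32)))
        assert out.shape == (1, 1, 64, 64)

    def test_too_small_input_names_minimum(self):
        net = build_nodule_net(levels=5, base_channels=2, pyramid_channels=4,
                               seed=0)
        with pytest.raises(ValueError, match="16"):
            net(Tensor(np.zeros((1, 1, 8, 8), np.float32)))

    def test_zeroed_head_gives_uniform_half(self):
        net = build_nodule_net(levels=3, base_channels=2, pyramid_channels=4,
                               seed=0)
        net.head.weight.data[:] = 0.0
        net.head.bias.data[:] = 0.0
        out = net(Tensor(np.zeros((1, 1, 32, 32), np.float32)))
        np.testing.assert_allclose(out.data, 0.5, atol=1e-6)

    @settings(deadline=None, max_examples=5, derandomize=True)
    @given(st.integers(2, 14))
    def test_same_size_for_random_multiples(self, k):
        net = build_nodule_net(levels=3, base_channels=2, pyramid_channels=2,
                               seed=1)
        size = 4 * k
        out = net(Tensor(np.zeros((1, 1, size, size), np.float32)))
        assert out.shape[2:] == (size, size)

    def test_fusion_weights_normalised(self):
        net = build_nodule_net(levels=4, base_channels=2, pyramid_channels=4,
                               seed=2)
        for node in net.td_fuse + net.bu_fuse:
            w = node.weights().data
            assert (w >= 0).all()
            assert abs(w.sum() - 1.0) < 1e-3


class TestCircularity:
    def test_disc_close_to_one(self):
        yy, xx = np.mgrid[:50, :50]
        disc = (yy - 25) ** 2 + (xx - 25) ** 2 <= 20**2
        assert circularity(disc) >= 0.85

    def test_line_is_far_from_round(self):
        line = np.zeros((5, 44), bool)
        line[2, 2:42] = True
        assert circularity(line) < 0.3

    def test_square_near_pi_over_four(self):
        sq = np.zeros((50, 50), bool)
        sq[5:45, 5:45] = True
        assert abs(circularity(sq) - np.pi / 4) < 0.1

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            circularity(np.zeros((4, 4), bool))


class TestScreening:
    def test_empty_mask_empty_list(self):
        assert screen_candidates(np.zeros((8, 8, 8), bool), (1, 1, 1)) == []

    def test_phantom_sphere_is_single_candidate(self, clean_sphere_mask):
        cands = screen_candidates(clean_sphere_mask, (1, 1, 1))
        assert len(cands) == 1
        c = cands[0]
        assert c.accepted
        assert abs(c.equivalent_diameter_mm - 8.0) < 1.0
        assert all(v >= 0.55 for v in c.circularity.values())

    def test_axial_cylinder_rejected_by_other_positions(self):
        cyl = phantom.cylinder_mask(
            (64, 64, 64),
            phantom.VesselSpec(axis="z", start=(12, 32, 32), end=(52, 32, 32),
                               radius_mm=2.0),
            (1, 1, 1))
        kept = screen_candidates(cyl, (1, 1, 1))
        assert kept == []
        all_cands = screen_candidates(cyl, (1, 1, 1), keep_rejected=True)
        assert len(all_cands) == 1
        circ = all_cands[0].circularity
        assert circ["axial"] >= 0.55  # round from its own axis only
        assert circ["coronal"] < 0.55 and circ["sagittal"] < 0.55

    def test_diameter_range_filters(self, clean_sphere_mask):
        assert screen_candidates(clean_sphere_mask, (1, 1, 1),
                                 diam_range_mm=(10.0, 12.0)) == []

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.floats(0.1, 0.95), st.floats(0.1, 0.95))
    def test_monotone_in_min_circ(self, lo, hi):
        """Raising the circularity threshold never adds candidates."""
        lo, hi = sorted((lo, hi))
        mask = phantom.sphere_mask((64, 64, 64), (32.0, 32.0, 32.0), 4.0,
                                   (1.0, 1.0, 1.0))
        mask[10:14, 10:14, 10:54] = True  # add an elongated distractor
        kept_lo = {c.component_id for c in screen_candidates(
            mask, (1, 1, 1), min_circ=lo)}
        kept_hi = {c.component_id for c in screen_candidates(
            mask, (1, 1, 1), min_circ=hi)}
        assert kept_hi <= kept_lo


def test_missing_position_net_is_an_error(small_phantom):
    vol, lung, _, _ = small_phantom
    with pytest.raises(ValueError, match="coronal"):
        nodules.segment_nodules(vol, lung, {"axial": None}, NoduleNetConfig())


def test_empty_parenchyma_gives_empty_mask(small_phantom):
    vol, _, _, _ = small_phantom
    nets = {p: build_nodule_net(levels=3, base_channels=2, pyramid_channels=2,
                                seed=0) for p in ("axial", "coronal", "sagittal")}
    # never-trained nets on an all-air masked volume: no candidate voxels
    mask, cands = nodules.segment_nodules(
        vol, np.zeros(vol.shape, bool), nets, NoduleNetConfig(levels=3))
    assert not mask.any() and cands == []
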