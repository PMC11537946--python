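"""Vascular morphometry: analytic oracles, brute-force equivalence, contracts."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octaquant import (
    ProjectionMap,
    VascularNetworkSpec,
    VesselMask,
    binarize,
    compute_bvc,
    compute_bvd,
    compute_bvt,
    compute_vpi,
    extract_features,
    generate_network,
    skeletonize_mask,
)

from conftest import disc_mask, quarter_arc_mask, rect_mask

ARC_TARGET = np.pi / (2 * np.sqrt(2))  # arc/chord ratio of a quarter circle


class TestBinarize:
    def test_zero_image_gives_empty_mask_with_warning(self):
        pmap = ProjectionMap(np.zeros((64, 64), dtype=np.uint8))
        with pytest.warns(UserWarning, match="constant"):
            vm = binarize(pmap)
        assert not vm.mask.any()

    def test_otsu_separates_two_level_image_exactly(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[10:30, 10:30] = 255
        vm = binarize(ProjectionMap(px), method="otsu")
        assert np.array_equal(vm.mask, px == 255)
        assert vm.source == "otsu"
        assert vm.threshold is not None

    def test_otsu_recovers_rasterization_truth(self, default_map):
        pmap, geom = default_map
        truth = geom.rasterize_mask()
        vm = binarize(pmap)
        jaccard = (vm.mask & truth).sum() / (vm.mask | truth).sum()
        assert jaccard >= 0.95

    def test_fixed_and_adaptive_methods(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[20:40, 20:40] = 200
        fixed = binarize(ProjectionMap(px), method="fixed", threshold=100)
        assert fixed.mask.sum() == 400
        adaptive = binarize(ProjectionMap(px), method="adaptive", window=15)
        assert adaptive.mask.dtype == bool

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown binarization"):
            binarize(ProjectionMap(np.zeros((32, 32), np.uint8)), method="magic")


class TestBVD:
    @pytest.mark.parametrize(
        "mask,expected",
        [
            (np.ones((16, 16), bool), 1.0),
            (np.zeros((16, 16), bool), 0.0),
        ],
    )
    def test_extremes(self, mask, expected):
        assert compute_bvd(VesselMask(mask)) == expected

    def test_filled_square_exact_ratio(self):
        m = np.zeros((256, 256), bool)
        m[50:114, 50:114] = True
        assert compute_bvd(VesselMask(m)) == 4096 / 65536

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_pixel_count(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((37, 53)) < rng.uniform(0, 1)
        brute = sum(1 for v in m.ravel() if v) / m.size
        assert compute_bvd(VesselMask(m)) == brute


class TestSkeleton:
    def test_bar_yields_single_branch_with_expected_length(self):
        sk = skeletonize_mask(VesselMask(rect_mask(height=5, width=100)))
        assert sk.n_branches == 1
        assert sk.branches[0].geodesic_len_px == pytest.approx(99, abs=5)

    def test_plus_sign_decomposes_into_four_branches_one_junction(self):
        m = np.zeros((256, 256), bool)
        m[126:131, 50:206] = True
        m[50:206, 126:131] = True
        sk = skeletonize_mask(VesselMask(m))
        assert sk.n_branches == 4
        assert len(sk.junctions) == 1
        assert len(sk.endpoints) == 4

    def test_empty_mask_gives_empty_skeleton(self):
        sk = skeletonize_mask(VesselMask(np.zeros((64, 64), bool)))
        assert sk.n_branches == 0
        assert not sk.skeleton.any()

    def test_branch_geodesic_at_least_euclidean(self, light_network):
        for seed in (0, 1, 2):
            pmap, _ = light_network(seed)
            sk = skeletonize_mask(binarize(pmap))
            for b in sk.branches:
                if not b.is_loop:
                    assert b.geodesic_len_px >= b.euclid_len_px - 1e-9


class TestBVC:
    @pytest.mark.parametrize("width", [5, 9])
    def test_bar_caliber_tracks_width(self, width):
        vm = VesselMask(rect_mask(height=width, width=100))
        bvc = compute_bvc(vm, skeletonize_mask(vm))
        assert bvc == pytest.approx(width, rel=0.10)

    def test_empty_mask_gives_nan_with_warning(self):
        vm = VesselMask(np.zeros((64, 64), bool))
        with pytest.warns(UserWarning, match="BVC"):
            assert np.isnan(compute_bvc(vm, skeletonize_mask(vm)))

    def test_shape_mismatch_rejected(self):
        vm = VesselMask(rect_mask())
        sk = skeletonize_mask(VesselMask(rect_mask(shape=(128, 128), r0=50)))
        with pytest.raises(ValueError, match="shape"):
            compute_bvc(vm, sk)


class TestBVT:
    def test_straight_bar_is_one(self):
        sk = skeletonize_mask(VesselMask(rect_mask()))
        assert compute_bvt(sk) == pytest.approx(1.0, abs=0.005)

    def test_quarter_circle_arc_matches_analytic_ratio(self):
        sk = skeletonize_mask(VesselMask(quarter_arc_mask(radius=80)))
        assert sk.n_branches == 1
        assert compute_bvt(sk) == pytest.approx(ARC_TARGET, abs=0.03)

    def test_two_branch_mean_is_average_of_ratios(self):
        # disjoint straight bar + arc: BVT must equal (1 + rho)/2 with rho
        # measured on the arc-only instance (brute-force mean oracle)
        arc = quarter_arc_mask(radius=60, center=(120.0, 140.0))
        rho = compute_bvt(skeletonize_mask(VesselMask(arc)))
        bar = rect_mask(r0=220, c0=20, height=3, width=80)
        straight = compute_bvt(skeletonize_mask(VesselMask(bar)))
        combined = compute_bvt(skeletonize_mask(VesselMask(arc | bar)))
        assert combined == pytest.approx((rho + straight) / 2, abs=1e-6)

    def test_no_branches_gives_nan_with_warning(self):
        sk = skeletonize_mask(VesselMask(np.zeros((64, 64), bool)))
        with pytest.warns(UserWarning, match="BVT"):
            assert np.isnan(compute_bvt(sk))


class TestVPI:
    def test_rectangle_matches_perimeter_over_area(self):
        vm = VesselMask(rect_mask(r0=50, c0=50, height=64, width=64))
        assert compute_vpi(vm) == pytest.approx(2 * (64 + 64) / (64 * 64), rel=0.05)

    def test_disc_matches_two_over_radius(self):
        assert compute_vpi(VesselMask(disc_mask(radius=50))) == pytest.approx(
            2 / 50, rel=0.05
        )

    def test_duplicating_a_component_leaves_vpi_unchanged(self):
        m = rect_mask(r0=50, c0=50, height=64, width=64)
        m2 = m.copy()
        m2[150:214, 150:214] = True
        assert compute_vpi(VesselMask(m2)) == pytest.approx(
            compute_vpi(VesselMask(m)), rel=1e-12
        )

    def test_empty_mask_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="VPI"):
            assert np.isnan(compute_vpi(VesselMask(np.zeros((64, 64), bool))))


class TestExtractFeatures:
    def test_blank_image_gives_zero_density_and_sentinels(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv = extract_features(ProjectionMap(np.zeros((64, 64), np.uint8)))
        assert fv.bvd == 0.0
        assert np.isnan(fv.bvc) and np.isnan(fv.bvt) and np.isnan(fv.vpi)

    def test_near_straight_network_has_unit_tortuosity(self):
        pmap, _ = generate_network(
            VascularNetworkSpec(n_seeds=3, branch_prob=0.0, tortuosity_amp=0.0, rng_seed=5)
        )
        fv = extract_features(pmap)
        assert 1.0 <= fv.bvt <= 1.05

    def test_deterministic_given_config(self, light_network):
        pmap, _ = light_network(9)
        a = extract_features(pmap)
        b = extract_features(pmap)
        assert a.as_dict() == b.as_dict()

    def test_report_scale_factors_apply(self, light_network):
        from octaquant import MorphometryConfig

        pmap, _ = light_network(9)
        plain = extract_features(pmap)
        scaled = extract_features(pmap, MorphometryConfig(scale={"bvd": 100.0}))
        assert scaled.bvd == pytest.approx(100.0 * plain.bvd)
        assert scaled.bvt == pytest.approx(plain.bvt)
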