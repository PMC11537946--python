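"""Synthetic vasculature generator: determinism, degradation, cohorts."""

import numpy as np
import pandas as pd
import pytest

from octaquant import (
    CohortSpec,
    DegradationSpec,
    GroupSpec,
    VascularNetworkSpec,
    VesselMask,
    degrade,
    extract_features,
    generate_network,
    make_cohort,
    read_image,
    ssim,
)
from octaquant.morphometry import skeletonize_mask

from conftest import LIGHT


class TestGenerateNetwork:
    def test_bit_identical_for_same_seed(self):
        spec = VascularNetworkSpec(rng_seed=42, image_size=128)
        a, _ = generate_network(spec)
        b, _ = generate_network(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seed_differs(self):
        a, _ = generate_network(VascularNetworkSpec(rng_seed=1, image_size=128))
        b, _ = generate_network(VascularNetworkSpec(rng_seed=2, image_size=128))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_no_seeds_gives_blank_image_and_empty_geometry(self):
        pmap, geom = generate_network(VascularNetworkSpec(n_seeds=0, rng_seed=0))
        assert pmap.pixels.max() == 0
        assert geom.n_branches == 0

    def test_degenerate_growth_single_straight_vessel(self):
        _, geom = generate_network(
            VascularNetworkSpec(n_seeds=1, branch_prob=0.0, tortuosity_amp=0.0, rng_seed=3)
        )
        assert geom.n_branches == 1
        b = geom.branches[0]
        # a straight walk: arc length equals chord length
        assert b.arc_length_px == pytest.approx(b.chord_length_px, rel=1e-9)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_seeds", -1),
            ("branch_prob", 1.5),
            ("tortuosity_amp", -0.1),
            ("caliber_root_px", 0.0),
            ("caliber_decay", 1.2),
            ("min_branch_len_px", 0.0),
            ("fov_label", "9mm"),
            ("image_size", 8),
        ],
    )
    def test_invalid_spec_names_offending_field(self, field, value):
        spec = VascularNetworkSpec(**{field: value})
        with pytest.raises(ValueError, match=field):
            generate_network(spec)

    def test_geometry_matches_raster_branch_count_on_sparse_networks(self):
        # skeletonizing the exact rasterization should recover the generated
        # branch count within one artifact per junction
        sparse = dict(
            image_size=192, n_seeds=1, branch_prob=0.02, tortuosity_amp=0.1,
            caliber_root_px=2.0, min_branch_len_px=20,
        )
        for seed in range(10):
            _, geom = generate_network(VascularNetworkSpec(**sparse, rng_seed=seed))
            skel = skeletonize_mask(VesselMask(geom.rasterize_mask(), source="truth"))
            n_skel = sum(1 for b in skel.branches if not b.is_loop)
            slack = len(skel.junctions) + 1
            assert abs(n_skel - geom.n_branches) <= slack, f"seed {seed}"


class TestDegrade:
    def test_identity_degradation_is_bitwise_exact(self, light_network):
        gt, _ = light_network(7)
        tr = degrade(gt, DegradationSpec())
        assert np.array_equal(tr.pixels, gt.pixels)
        assert tr.arm == "TR"

    def test_total_dropout_of_small_branches_blanks_the_image(self):
        # all branches share the root caliber, below the dropout cutoff
        spec = VascularNetworkSpec(
            image_size=128, n_seeds=3, branch_prob=0.0, caliber_root_px=1.0, rng_seed=5
        )
        gt, geom = generate_network(spec)
        tr = degrade(
            gt,
            DegradationSpec(dropout_frac=1.0, small_caliber_cutoff_px=1.5, rng_seed=0),
            geometry=geom,
        )
        assert tr.pixels.max() == 0

    def test_blur_strictly_reduces_ssim(self, light_network):
        gt, _ = light_network(11)
        tr = degrade(gt, DegradationSpec(blur_sigma_px=2.0, rng_seed=0))
        assert ssim(gt, tr) < 1.0

    def test_geometry_required_for_structural_degradation(self, light_network):
        gt, _ = light_network(11)
        with pytest.raises(ValueError, match="geometry"):
            degrade(gt, DegradationSpec(dropout_frac=0.5, rng_seed=0))

    def test_invalid_degradation_parameters(self):
        with pytest.raises(ValueError, match="dropout_frac"):
            DegradationSpec(dropout_frac=1.5).validate()
        with pytest.raises(ValueError, match="contrast_gain"):
            DegradationSpec(contrast_gain=0.0).validate()


class TestMakeCohort:
    def _spec(self, seed=0, **kwargs):
        return CohortSpec(
            groups={"NORMAL": GroupSpec(n=10), "DR": GroupSpec(n=5)},
            master_seed=seed,
            image_size=96,
            network=dict(n_seeds=3, branch_prob=0.02),
            **kwargs,
        )

    def test_manifest_counts_and_files(self, tmp_path):
        manifest = make_cohort(self._spec(), tmp_path / "c")
        assert manifest["subject_id"].nunique() == 15
        assert len(manifest) == 30  # one GT + one TR row per subject
        assert all((tmp_path / "c" / f).exists() for f in
                   [p.split("/")[-1] for p in manifest["path"]])
        assert sum(1 for p in (tmp_path / "c").glob("*.png")) == 30

    def test_same_master_seed_reproduces_identical_files(self, tmp_path):
        make_cohort(self._spec(seed=3), tmp_path / "a")
        make_cohort(self._spec(seed=3), tmp_path / "b")
        a_csv = (tmp_path / "a" / "manifest.csv").read_text()
        b_csv = (tmp_path / "b" / "manifest.csv").read_text()
        assert a_csv.replace(str(tmp_path / "a"), "X") == b_csv.replace(str(tmp_path / "b"), "X")
        for pa in sorted((tmp_path / "a").glob("*.png")):
            pb = tmp_path / "b" / pa.name
            assert pa.read_bytes() == pb.read_bytes()

    def test_path_collision_raises(self, tmp_path):
        make_cohort(self._spec(), tmp_path / "c")
        with pytest.raises(FileExistsError):
            make_cohort(self._spec(), tmp_path / "c")

    def test_empty_group_rejected(self, tmp_path):
        spec = CohortSpec(groups={"NORMAL": GroupSpec(n=0)}, image_size=96)
        with pytest.raises(ValueError, match="n >= 1"):
            make_cohort(spec, tmp_path / "c")

    def test_group_level_tortuosity_shows_in_measured_bvt(self, tmp_path):
        spec = CohortSpec(
            groups={
                "NORMAL": GroupSpec(n=6, network={"tortuosity_amp": 0.05}),
                "DR": GroupSpec(n=6, network={"tortuosity_amp": 0.45}),
            },
            master_seed=1,
            image_size=128,
            network=dict(n_seeds=4, branch_prob=0.02),
        )
        manifest = make_cohort(spec, tmp_path / "c")
        gt_rows = manifest[manifest["arm"] == "GT"]
        bvt = {
            g: np.mean(
                [extract_features(read_image(p)).bvt
                 for p in gt_rows[gt_rows["group"] == g]["path"]]
            )
            for g in ("NORMAL", "DR")
        }
        assert bvt["DR"] > bvt["NORMAL"]
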