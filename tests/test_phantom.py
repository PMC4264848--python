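"""Ground-truth correctness of the synthetic phantom generator: woodpile
geometry, per-section occupancy bookkeeping, bias/noise rendering and the
determinism contract."""

import numpy as np
import pytest

from scaffoldmri import (
    AcquisitionModel,
    ScaffoldGeometry,
    TissueModel,
    bias_field,
    generate_phantom,
    generate_scaffold_mask,
    generate_tissue_mask,
    render_stack,
)
from scaffoldmri.phantom import (
    _scaffold_z0,
    _slice_centers,
    scaffold_roi,
    section_ranges,
    split_into_sections,
    tube_roi,
)


def _layer_axis_slice(geometry, acq, orientation_index):
    """Index of the slice closest to the axis plane of a layer laid at the
    given orientation (0 -> fibers along x)."""
    z0 = _scaffold_z0(geometry, acq)
    centers = _slice_centers(acq)
    pattern = geometry.lay_down_pattern
    for k in range(round(geometry.cylinder_height / geometry.layer_thickness)):
        if (pattern[k % len(pattern)] % 180.0 == 0.0) != (orientation_index == 0):
            continue
        z_axis = z0 + (k + 0.5) * geometry.layer_thickness
        i = int(np.argmin(np.abs(centers - z_axis)))
        if abs(centers[i] - z_axis) < 0.25 * geometry.fiber_diameter and 5 < i < acq.n_slices - 5:
            return i, z_axis
    raise AssertionError("no layer axis plane close to a slice center")


class TestScaffoldMask:
    def test_fiber_period_matches_spacing_by_autocorrelation(self):
        geometry, acq = ScaffoldGeometry(), AcquisitionModel()
        mask = generate_scaffold_mask(geometry, acq)
        i, _ = _layer_axis_slice(geometry, acq, orientation_index=0)
        # fibers along x -> periodic profile along y
        profile = mask[i].sum(axis=1).astype(float)
        profile -= profile.mean()
        ac = np.correlate(profile, profile, mode="full")[len(profile) - 1 :]
        lags = np.arange(len(ac))
        peak = lags[3:20][np.argmax(ac[3:20])]
        expected = round(geometry.fiber_spacing / acq.pixel_size)  # ~12.8 px -> 13
        assert peak == expected

    def test_layer_area_fraction_matches_closed_form(self):
        """Voxel count per slice vs the analytic union of two orthogonal
        aligned stripe arrays (widths from the circular fiber section)."""
        geometry, acq = ScaffoldGeometry(), AcquisitionModel()
        mask = generate_scaffold_mask(geometry, acq)
        z0 = _scaffold_z0(geometry, acq)
        centers = _slice_centers(acq)
        radius, spacing = geometry.fiber_diameter / 2.0, geometry.fiber_spacing
        n_layers = round(geometry.cylinder_height / geometry.layer_thickness)
        roi2d = scaffold_roi(geometry, acq).mask(mask.shape[1:])
        n_cyl = roi2d.sum()
        total_observed = total_expected = 0.0
        for i in range(1, acq.n_slices - 1):
            widths = {0: 0.0, 1: 0.0}
            for k in range(n_layers):
                dz = centers[i] - (z0 + (k + 0.5) * geometry.layer_thickness)
                if abs(dz) < radius:
                    w = 2.0 * np.sqrt(radius**2 - dz**2)
                    widths[k % 2] = max(widths[k % 2], w)
            fx, fy = widths[0] / spacing, widths[1] / spacing
            expected = fx + fy - fx * fy
            observed = mask[i][roi2d].sum() / n_cyl
            # per-slice bound: row quantization can move ~1 px per stripe,
            # ~9 stripes x ~100-px chords on a ~8200-px disk ~ 0.05
            assert observed == pytest.approx(expected, abs=0.05)
            total_observed += observed
            total_expected += expected
        assert total_observed == pytest.approx(total_expected, rel=0.10)

    def test_zero_fiber_diameter_gives_empty_mask(self):
        geometry = ScaffoldGeometry(fiber_diameter=0.0)
        assert not generate_scaffold_mask(geometry, AcquisitionModel()).any()

    def test_cylinder_larger_than_fov_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            generate_scaffold_mask(
                ScaffoldGeometry(cylinder_diameter=12.0), AcquisitionModel()
            )

    def test_reference_slices_are_empty(self, default_phantom):
        assert not default_phantom.scaffold_mask[0].any()
        assert not default_phantom.scaffold_mask[-1].any()
        assert not default_phantom.tissue_mask[0].any()
        assert not default_phantom.tissue_mask[-1].any()


class TestTissueMask:
    def test_zero_target_gives_empty_mask(self, small_geometry, small_acquisition):
        scaffold = generate_scaffold_mask(small_geometry, small_acquisition)
        empty = TissueModel(
            target_occupancy_by_section={"top": 0.0, "middle": 0.0, "bottom": 0.0}
        )
        mask = generate_tissue_mask(scaffold, empty, small_acquisition, small_geometry, seed=1)
        assert not mask.any()

    @pytest.mark.parametrize("morphology", ["sheet", "string", "blob"])
    def test_occupancy_hits_target_and_avoids_scaffold(
        self, morphology, small_geometry, small_acquisition
    ):
        scaffold = generate_scaffold_mask(small_geometry, small_acquisition)
        model = TissueModel(
            target_occupancy_by_section={"bottom": 0.02},
            morphology=morphology,
            component_scale=0.4,
        )
        mask = generate_tissue_mask(scaffold, model, small_acquisition, small_geometry, seed=3)
        assert not (mask & scaffold).any()
        roi2d = scaffold_roi(small_geometry, small_acquisition).mask(scaffold.shape[1:])
        lo, hi = section_ranges(scaffold)["bottom"]
        pore = roi2d[None] & ~scaffold
        occ = (mask[lo : hi + 1] & pore[lo : hi + 1]).sum() / pore[lo : hi + 1].sum()
        assert 0.018 <= occ <= 0.022  # within 10% relative of the 2% target
        assert not mask[: lo].any() and not mask[hi + 1 :].any()

    def test_same_seed_reproduces_identical_mask(self, small_geometry, small_acquisition):
        scaffold = generate_scaffold_mask(small_geometry, small_acquisition)
        model = TissueModel(target_occupancy_by_section={"middle": 0.03})
        a = generate_tissue_mask(scaffold, model, small_acquisition, small_geometry, seed=5)
        b = generate_tissue_mask(scaffold, model, small_acquisition, small_geometry, seed=5)
        assert np.array_equal(a, b)
        c = generate_tissue_mask(scaffold, model, small_acquisition, small_geometry, seed=6)
        assert not np.array_equal(a, c)

    def test_unreachable_occupancy_reports_achievable_maximum(
        self, small_geometry, small_acquisition
    ):
        scaffold = generate_scaffold_mask(small_geometry, small_acquisition)
        # a sheet is bounded to a band at the section face; it can never
        # fill the whole section
        model = TissueModel(
            target_occupancy_by_section={"bottom": 1.0},
            morphology="sheet",
            component_scale=0.2,
        )
        with pytest.raises(RuntimeError, match="achievable maximum"):
            generate_tissue_mask(scaffold, model, small_acquisition, small_geometry, seed=1)


class TestRendering:
    def test_noise_and_bias_free_liquid_is_exactly_the_liquid_level(self, clean_phantom):
        ph = clean_phantom
        tube = tube_roi(ph.acquisition).mask(ph.stack.shape[1:])
        liquid = tube[None] & ~ph.scaffold_mask & ~ph.tissue_mask
        vals = ph.stack.data[liquid]
        assert np.all(vals == ph.acquisition.levels["liquid"])

    def test_bias_extremes_set_liquid_intensity_ratio(self):
        acq = AcquisitionModel(bias_amplitude=0.3, noise_sigma=0.0, bit_depth=16)
        ph = generate_phantom(acquisition=acq)
        tube = tube_roi(acq).mask(ph.stack.shape[1:])
        liquid = tube[None] & ~ph.scaffold_mask & ~ph.tissue_mask
        vals = ph.stack.data[liquid].astype(float)
        expected = (1 + 0.3) / (1 - 0.3)
        assert vals.max() / vals.min() == pytest.approx(expected, rel=0.02)
        # and the field itself attains the +/- amplitude extremes over the tube
        field = bias_field(acq)
        assert field[:, tube].max() == pytest.approx(1.3, abs=1e-9)
        assert field[:, tube].min() == pytest.approx(0.7, abs=1e-9)

    def test_agent_mode_reduces_scaffold_liquid_contrast(self):
        native = AcquisitionModel(seed=3)
        agent = AcquisitionModel(seed=3, contrast_mode="agent")
        ln, la = native.levels, agent.levels
        assert abs(la["scaffold"] - la["liquid"]) < abs(ln["scaffold"] - ln["liquid"])
        assert la["tissue"] - la["liquid"] > ln["tissue"] - ln["liquid"]

    def test_rendering_is_deterministic_and_seed_changes_noise_only(self, small_phantom):
        ph = small_phantom
        again = render_stack(ph.scaffold_mask, ph.tissue_mask, ph.acquisition)
        assert np.array_equal(again.data, ph.stack.data)
        other_seed = AcquisitionModel(
            **{**_acq_kwargs(ph.acquisition), "seed": ph.acquisition.seed + 1}
        )
        other = render_stack(ph.scaffold_mask, ph.tissue_mask, other_seed)
        assert not np.array_equal(other.data, ph.stack.data)

    def test_overlapping_masks_rejected(self, small_phantom):
        bad = small_phantom.scaffold_mask.copy()
        assert bad.any()
        with pytest.raises(ValueError, match="disjoint"):
            render_stack(bad, bad, small_phantom.acquisition)

    def test_rician_noise_renders_nonnegative(self, small_geometry):
        acq = AcquisitionModel(
            matrix_size=64, n_slices=20, slice_thickness=0.1, tube_diameter=6.0,
            noise_model="rician", seed=2,
        )
        ph = generate_phantom(geometry=small_geometry, acquisition=acq)
        assert ph.stack.data.min() >= 0


def _acq_kwargs(acq: AcquisitionModel) -> dict:
    import dataclasses

    return dataclasses.asdict(acq)


class TestSections:
    def test_split_into_thirds_with_remainder_forward(self):
        assert split_into_sections(1, 43) == {
            "top": (1, 15),
            "middle": (16, 29),
            "bottom": (30, 43),
        }
        assert split_into_sections(0, 2) == {
            "top": (0, 0),
            "middle": (1, 1),
            "bottom": (2, 2),
        }

    def test_achieved_occupancy_recorded_per_section(self, default_phantom):
        targets = default_phantom.tissue.target_occupancy_by_section
        for name, target in targets.items():
            assert default_phantom.achieved_occupancy[name] == pytest.approx(
                target, rel=0.10
            )
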