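"""Synthetic phantom generator: geometry, optics, determinism."""

import dataclasses

import numpy as np
import pytest

from conftest import small_spec
from htpore.phantom import (
    FieldTooCrowdedError,
    PhantomSpec,
    generate_phantom,
    render_defocus,
)
from htpore.stack_io import RIStack


class TestSpecValidation:
    def test_ri_ordering_enforced(self):
        with pytest.raises(ValueError, match="RI ordering"):
            small_spec(ri_nucleus=1.37)  # above cytoplasm

    def test_zero_area_pore_rejected(self):
        with pytest.raises(ValueError, match="zero-area pore"):
            small_spec(pore_radius_um_range=(0.05, 0.1))

    def test_focal_slice_bounds(self):
        with pytest.raises(ValueError, match="focal_slice"):
            small_spec(focal_slice=12, n_slices=12)

    def test_crowded_field_raises(self):
        with pytest.raises(FieldTooCrowdedError):
            generate_phantom(small_spec(n_cells=30))

    def test_json_round_trip(self, tmp_path):
        spec = small_spec(seed=9)
        spec.to_json(tmp_path / "s.json")
        assert PhantomSpec.from_json(tmp_path / "s.json") == spec


class TestEmptyScenes:
    def test_no_cells_means_background_plus_noise(self):
        spec = small_spec(n_cells=0, noise_sd=0.001)
        out = generate_phantom(spec)
        assert out.truth_volume().max() == 0
        assert out.instance_truth.empty
        np.testing.assert_allclose(
            out.stack.voxels, spec.ri_background, atol=6 * spec.noise_sd
        )

    def test_no_pores_requested_none_generated(self):
        out = generate_phantom(small_spec(pores_per_cell_mean=0.0))
        assert (out.instance_truth["type"] != "pore").all()
        assert out.truth_volume().max() <= 3
        assert not (out.truth_volume() == 1).any()


class TestPoreGeometry:
    def test_single_pore_area_matches_rasterization_oracle(self):
        pores = None
        for seed in range(21, 30):  # Poisson(1) may draw zero pores
            spec = small_spec(
                noise_sd=0.0,
                blur_sigma_xy_px=0.0,
                blur_sigma_z_slices=0.0,
                pores_per_cell_mean=1.0,
                pore_radius_um_range=(1.0, 1.0),
                vesicles_per_cell_mean=0.0,
                seed=seed,
            )
            out = generate_phantom(spec)
            pores = out.instance_truth[out.instance_truth["type"] == "pore"]
            if len(pores):
                break
        assert pores is not None and len(pores) >= 1
        # oracle: count integer pixels inside the circle equation
        r_px = 1.0 / spec.pixel_size_xy_um
        yy, xx = np.mgrid[-8:9, -8:9]
        oracle_px = int(np.count_nonzero(yy**2 + xx**2 <= r_px**2))
        analytic_um2 = np.pi * 1.0**2
        for _, row in pores.iterrows():
            area_px = row["area_um2"] / spec.pixel_size_xy_um**2
            assert area_px == pytest.approx(oracle_px, rel=1e-9)
            assert abs(area_px - analytic_um2 / 0.04) / (analytic_um2 / 0.04) < 0.1

    def test_pores_span_their_cell_thickness(self, small_phantom):
        """Every pore is transcellular: present on all slices of its cell."""
        out = small_phantom
        vols = out.instance_labels
        pores = out.instance_truth[out.instance_truth["type"] == "pore"]
        truth = out.truth_volume()
        for pid in pores["instance_id"]:
            zs = np.unique(np.nonzero((vols == pid).any(axis=(1, 2)))[0])
            # pore voxels occupy a contiguous z-range (the parent cell's)
            assert len(zs) >= 5
            assert np.array_equal(zs, np.arange(zs[0], zs[-1] + 1))

    def test_every_pore_annotated_at_focal_slice(self, small_phantom):
        out = small_phantom
        z = out.spec_echo.focal_slice
        pores = out.instance_truth[out.instance_truth["type"] == "pore"]
        for pid in pores["instance_id"]:
            inst = out.instance_labels[z] == pid
            assert inst.any()
            assert (out.truth[z].labels[inst] == 1).all()

    def test_nucleolus_inside_nucleus(self, small_phantom):
        truth = small_phantom.truth_volume()
        # nucleolus pixels sit within the nucleus footprint: on the focal
        # slice they are surrounded by nucleus-class pixels
        z = small_phantom.spec_echo.focal_slice
        from scipy import ndimage as ndi

        nucleolus = truth[z] == 3
        nucleus_or_nucleolus = (truth[z] == 2) | nucleolus
        grown = ndi.binary_dilation(nucleolus)
        assert (nucleus_or_nucleolus[grown]).all()


class TestOptics:
    def test_ri_contrast_pore_equals_background_when_clean(self):
        out = generate_phantom(
            small_spec(noise_sd=0.0, blur_sigma_xy_px=0.0, blur_sigma_z_slices=0.0)
        )
        z = out.spec_echo.focal_slice
        img = out.stack.voxels[z]
        truth = out.truth[z].labels
        cells = img != out.spec_echo.ri_background
        pore_vals = img[truth == 1]
        bg_vals = img[(truth == 0) & ~cells]
        # pore interiors take exactly the background RI, pixel for pixel, so
        # the population mean contrast is exactly zero
        ri_bg = np.float32(out.spec_echo.ri_background)
        assert pore_vals.size and bg_vals.size
        assert (pore_vals == ri_bg).all()
        assert (bg_vals == ri_bg).all()

    def test_ri_contrast_with_noise_within_sampling_error(self):
        spec = small_spec(noise_sd=0.004, blur_sigma_xy_px=0.0,
                          blur_sigma_z_slices=0.0, seed=33)
        out = generate_phantom(spec)
        z = spec.focal_slice
        img = out.stack.voxels[z]
        truth = out.truth[z].labels
        pore = truth == 1
        bg = truth == 0
        # remove cytoplasm pixels from the background-class sample
        clean = generate_phantom(dataclasses.replace(spec, noise_sd=0.0))
        bg &= clean.stack.voxels[z] == spec.ri_background
        n = min(pore.sum(), bg.sum())
        diff = abs(img[pore].mean() - img[bg].mean())
        assert diff < 3 * spec.noise_sd / np.sqrt(n)

    def test_defocus_blur_grows_away_from_focus(self):
        spec = small_spec(noise_sd=0.0, seed=3)
        out = generate_phantom(spec)
        from htpore.focus import focus_metric

        metric = focus_metric(out.stack)
        z0 = spec.focal_slice
        # sharpness decays monotonically within the cell's z-extent
        occupied = np.nonzero((out.truth_volume() > 0).any(axis=(1, 2)))[0]
        upper = [z for z in occupied if z >= z0]
        vals = metric[upper]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestRenderDefocus:
    def _stack(self, vox):
        return RIStack(np.asarray(vox, np.float32), 0.2, 1.0)

    def test_zero_blur_is_identity(self):
        rng = np.random.default_rng(0)
        stack = self._stack(rng.normal(1.35, 0.01, (4, 12, 12)))
        out = render_defocus(stack, 0.0, 0.0, 1)
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_focal_slice_unchanged_when_base_sigma_zero(self):
        rng = np.random.default_rng(1)
        stack = self._stack(rng.normal(1.35, 0.01, (5, 12, 12)))
        out = render_defocus(stack, 0.0, 1.5, 2)
        np.testing.assert_array_equal(out.voxels[2], stack.voxels[2])
        assert not np.array_equal(out.voxels[0], stack.voxels[0])

    def test_impulse_response_matches_gaussian_kernel(self):
        img = np.zeros((1, 41, 41), dtype=np.float64)
        img[0, 20, 20] = 1.0
        out = render_defocus(self._stack(img), 2.0, 0.0, 0)
        x = np.arange(-8, 9)  # scipy truncates at 4 sigma
        k1 = np.exp(-(x**2) / 8.0)
        k1 /= k1.sum()
        oracle = np.outer(k1, k1)
        got = out.voxels[0, 12:29, 12:29]
        assert np.abs(got - oracle).max() < 1e-6

    def test_slice_means_preserved(self):
        rng = np.random.default_rng(2)
        stack = self._stack(rng.normal(1.35, 0.01, (6, 30, 30)))
        out = render_defocus(stack, 1.0, 0.8, 3)
        for z in range(6):
            assert out.voxels[z].mean() == pytest.approx(
                stack.voxels[z].mean(), abs=1e-6
            )


class TestDeterminismAndStatistics:
    def test_identical_spec_bit_identical_output(self):
        spec = small_spec(seed=77)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        np.testing.assert_array_equal(a.stack.voxels, b.stack.voxels)
        assert a.instance_truth.equals(b.instance_truth)
        np.testing.assert_array_equal(a.truth_volume(), b.truth_volume())

    def test_different_seeds_differ(self):
        a = generate_phantom(small_spec(seed=1))
        b = generate_phantom(small_spec(seed=2))
        assert not np.array_equal(a.stack.voxels, b.stack.voxels)

    def test_pores_per_cell_mean_recovered_over_many_cells(self):
        """Requested Poisson rate is recovered within sampling error."""
        lam = 4.0
        counts = []
        for seed in range(60):
            out = generate_phantom(
                small_spec(
                    pores_per_cell_mean=lam,
                    n_slices=8,
                    focal_slice=3,
                    noise_sd=0.0,
                    blur_sigma_xy_px=0.0,
                    blur_sigma_z_slices=0.0,
                    vesicles_per_cell_mean=0.0,
                    seed=1000 + seed,
                )
            )
            counts.extend(out.pores_per_cell().tolist())
        counts = np.asarray(counts, float)
        assert len(counts) >= 50
        se = np.sqrt(lam / len(counts))
        assert abs(counts.mean() - lam) < 3 * se
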