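"""Generator contracts: axes, component spectra, scenes, cubes, class sets."""

import numpy as np
import pytest

import ramancellmap as rm
from ramancellmap.errors import InvalidArgumentError, PlacementError
from ramancellmap.synthdata import NoiseModel


class TestMakeAxis:
    def test_emulated_instrument_grid(self):
        axis = rm.make_axis(466, 1667, 1022)
        assert axis.n_channels == 1022
        assert axis.wavenumbers[0] == 466
        assert axis.wavenumbers[-1] == 1667
        spacing = np.diff(axis.wavenumbers)
        assert np.allclose(spacing, (1667 - 466) / 1021)

    def test_two_point_grid(self):
        axis = rm.make_axis(0, 1, 2)
        assert np.array_equal(axis.wavenumbers, [0.0, 1.0])

    @pytest.mark.parametrize("args", [(466, 1667, 1), (466, 1667, 0), (1667, 466, 10), (5, 5, 10)])
    def test_invalid_arguments(self, args):
        with pytest.raises(InvalidArgumentError):
            rm.make_axis(*args)


class TestComponentSpectra:
    def test_single_band_peaks_at_nearest_channel(self, axis_small):
        band = rm.BandDef("b", 749.0, 10.0, "nucleic-acid", 1.0)
        (comp,) = rm.make_component_spectra(axis_small, [band])
        assert np.argmax(comp.profile) == axis_small.index_of(749.0)

    def test_well_separated_amplitude_ratio(self):
        # unit-spaced axis puts both centers exactly on the grid
        axis = rm.make_axis(400, 1600, 1201)
        bands = [
            rm.BandDef("lo", 600.0, 10.0, "c", 1.0),
            rm.BandDef("hi", 1400.0, 10.0, "c", 2.0),
        ]
        (comp,) = rm.make_component_spectra(axis, bands)
        h_lo = comp.profile[axis.index_of(600.0)]
        h_hi = comp.profile[axis.index_of(1400.0)]
        assert h_hi / h_lo == pytest.approx(2.0, rel=0.01)

    def test_nucleic_acid_has_its_signature_bands(self, axis_default):
        comps = {c.component: c for c in rm.melanoma_components(axis_default)}
        nucleic = comps["nucleic-acid"]
        assert nucleic.profile[axis_default.index_of(749.0)] > 0.5
        assert nucleic.profile[axis_default.index_of(1580.0)] > 0.3

    def test_center_outside_span_rejected(self, axis_small):
        with pytest.raises(InvalidArgumentError):
            rm.make_component_spectra(axis_small, [rm.BandDef("x", 3000.0)])

    def test_profiles_nonnegative(self, axis_default):
        for comp in rm.melanoma_components(axis_default):
            assert np.all(comp.profile >= 0)


class TestMakeScene:
    def test_two_disjoint_cells_on_study_grid(self):
        scene = rm.make_scene(31, 43, 2, seed=1)
        assert scene.masks.shape == (31, 43)
        assert set(np.unique(scene.masks)) == {0, 1, 2}
        assert not (scene.cell_mask(1) & scene.cell_mask(2)).any()

    def test_empty_scene(self):
        scene = rm.make_scene(5, 5, 0, seed=7)
        assert scene.n_cells == 0
        assert not scene.cell_mask().any()
        assert np.all(scene.concentration_maps["pbs-buffer"] > 0)

    def test_seeded_determinism(self):
        a = rm.make_scene(31, 43, 2, seed=11)
        b = rm.make_scene(31, 43, 2, seed=11)
        assert np.array_equal(a.masks, b.masks)
        for name in a.concentration_maps:
            assert np.array_equal(a.concentration_maps[name], b.concentration_maps[name])

    def test_morphologies_alternate(self):
        scene = rm.make_scene(40, 60, 2, seed=2)
        assert scene.morphologies[1] == "elongated"
        assert scene.morphologies[2] == "round"

    def test_cell_components_zero_outside_masks(self):
        scene = rm.make_scene(31, 43, 2, seed=5)
        outside = ~scene.cell_mask()
        for name in ("nucleic-acid", "protein", "lipid"):
            assert np.all(scene.concentration_maps[name][outside] == 0)

    def test_placement_failure_is_diagnosed(self):
        with pytest.raises(PlacementError):
            rm.make_scene(4, 4, 6, seed=1, max_attempts=20)


class TestRenderCube:
    def test_zero_noise_identity(self, axis_small):
        scene = rm.make_scene(20, 20, 1, seed=1)
        comps = rm.melanoma_components(axis_small)
        null = NoiseModel(baseline_scale=0, noise_sd=0, spike_rate=0, seed=0)
        observed, truth = rm.render_cube(scene, comps, null)
        assert np.array_equal(observed.intensities, truth.intensities)

    def test_noise_sd_matches_law_of_large_numbers(self, axis_small):
        # >= 1e5 residual samples; no baseline/spikes so residual is pure noise
        scene = rm.make_scene(20, 20, 0, seed=2)
        comps = rm.melanoma_components(axis_small)
        noise = NoiseModel(baseline_scale=0, noise_sd=0.35, spike_rate=0, seed=2)
        observed, truth = rm.render_cube(scene, comps, noise)
        resid = observed.intensities - truth.intensities
        assert resid.size >= 1e5
        assert np.std(resid) == pytest.approx(0.35, rel=0.05)

    def test_linearity_in_concentration(self, axis_small):
        scene = rm.make_scene(10, 10, 1, seed=3)
        comps = rm.melanoma_components(axis_small)
        null = NoiseModel(baseline_scale=0, noise_sd=0, spike_rate=0, seed=0)
        _, truth1 = rm.render_cube(scene, comps, null)
        scene.concentration_maps["protein"] = 2 * scene.concentration_maps["protein"]
        _, truth2 = rm.render_cube(scene, comps, null)
        prot = next(c for c in comps if c.component == "protein")
        delta = truth2.intensities - truth1.intensities
        cmap = scene.concentration_maps["protein"] / 2
        expected = cmap[:, :, None] * prot.profile[None, None, :]
        assert np.allclose(delta, expected)

    def test_masked_bands_phenomenology(self, axis_default):
        """Raw spectra hide the 749/1003/1451 peaks from naive argmax detection."""
        spectra = rm.make_labeled_classes(
            50, 50, rm.MELANOMA_EFFECT, rm.melanoma_noise(seed=1), seed=1,
            axis=axis_default,
        )
        for center in (749.0, 1003.0, 1451.0):
            mask = axis_default.window_mask(center - 25, center + 25)
            idx = np.nonzero(mask)[0]
            hits = 0
            true_ch = axis_default.index_of(center)
            for row in spectra.matrix:
                if abs(idx[np.argmax(row[mask])] - true_ch) <= 1:
                    hits += 1
            assert hits / spectra.n_spectra < 0.9

    def test_determinism(self, axis_small):
        scene = rm.make_scene(8, 8, 1, seed=4)
        comps = rm.melanoma_components(axis_small)
        noise = rm.melanoma_noise(seed=9)
        obs1, _ = rm.render_cube(scene, comps, noise)
        obs2, _ = rm.render_cube(scene, comps, noise)
        assert np.array_equal(obs1.intensities, obs2.intensities)


class TestMakeLabeledClasses:
    def test_null_effect_class_means_agree(self, axis_small):
        quiet = NoiseModel(baseline_scale=0, noise_sd=0, spike_rate=0, seed=0)
        s = rm.make_labeled_classes(400, 400, rm.NULL_EFFECT, quiet, seed=5,
                                    axis=axis_small, abundance_cv=0.1)
        mean_a = s.subset(rm.CLASS_A).mean(axis=0)
        mean_b = s.subset(rm.CLASS_B).mean(axis=0)
        scale = np.abs(mean_b).max()
        # Monte-Carlo error of lognormal(cv=0.1) means at n=400
        assert np.abs(mean_a - mean_b).max() < 3 * 0.1 / np.sqrt(400) * scale * 3

    def test_single_band_effect_exact_ratio(self, axis_small):
        """Noiseless, variability-free generation makes the ratio exact."""
        band = (rm.BandDef("phe", 1003.0, 10.0, "protein", 1.0),)
        null = NoiseModel(baseline_scale=0, noise_sd=0, spike_rate=0, seed=0)
        s = rm.make_labeled_classes(
            500, 500, rm.EffectVector({1003.0: 0.5}), null, seed=1,
            axis=axis_small, band_table=band, abundance_cv=0.0, pbs_cv=0.0,
        )
        ch = axis_small.index_of(1003.0)
        ratio = s.subset(rm.CLASS_A)[:, ch].mean() / s.subset(rm.CLASS_B)[:, ch].mean()
        assert ratio == pytest.approx(0.5, abs=1e-12)

    def test_melanoma_pattern_lower_bands_equal_1580(self, axis_small):
        null = NoiseModel(baseline_scale=0, noise_sd=0, spike_rate=0, seed=0)
        s = rm.make_labeled_classes(600, 600, rm.MELANOMA_EFFECT, null, seed=2,
                                    axis=axis_small)
        mean_a = s.subset(rm.CLASS_A).mean(axis=0)
        mean_b = s.subset(rm.CLASS_B).mean(axis=0)
        for center in (749.0, 1003.0, 1126.0, 1340.0, 1451.0):
            ch = axis_small.index_of(center)
            assert mean_a[ch] < 0.85 * mean_b[ch]
        ch = axis_small.index_of(1580.0)
        assert mean_a[ch] == pytest.approx(mean_b[ch], rel=0.05)

    def test_seeded_determinism(self, axis_small):
        kw = dict(effect=rm.MELANOMA_EFFECT, noise=rm.melanoma_noise(3), seed=3,
                  axis=axis_small)
        a = rm.make_labeled_classes(10, 10, **kw)
        b = rm.make_labeled_classes(10, 10, **kw)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.labels, b.labels)

    def test_background_rows_are_buffer_only(self, axis_small):
        null = NoiseModel(baseline_scale=0, noise_sd=0, spike_rate=0, seed=0)
        s = rm.make_labeled_classes(5, 5, rm.NULL_EFFECT, null, seed=1,
                                    axis=axis_small, n_background=4)
        bg = s.subset(rm.BACKGROUND_LABEL)
        assert bg.shape[0] == 4
        assert bg[:, axis_small.index_of(1003.0)].max() < 0.05
        assert bg[:, axis_small.index_of(916.0)].min() > 0.5

    def test_effect_ratio_validation(self):
        with pytest.raises(InvalidArgumentError):
            rm.EffectVector({749.0: 0.0})
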