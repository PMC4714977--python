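"""Profile math: oracle equivalence, invariances, septum calls, averaging."""

import numpy as np
import pytest

from polarprof import synthgen as sg
from polarprof.axialprofile import (
    SeptumParams,
    average_profiles,
    axial_profile,
    detect_septa,
    estimate_background,
    kymograph,
    orient_and_align,
    random_pole_profiles,
)
from conftest import EXACT_RP, PX, brute_force_bins, render_single, segment_whole


def profile_for(scene, mesh, n_bins=50):
    bg = (scene.render_params.bg_reporter, scene.render_params.bg_membrane)
    return axial_profile(
        mesh, scene.channels["reporter"], scene.channels["membrane"],
        n_bins=n_bins, background=bg,
    )


class TestAxialProfile:
    def test_flat_ratio_for_uniform_membrane_reporter(self):
        """Reporter == membrane pattern -> normalized ratio exactly 1."""
        cell = sg.build_cell(3.25, 0.9, class_label="uniform_membrane",
                             centroid_px=(48.0, 48.0), angle_rad=0.3)
        scene = render_single(cell, rp=EXACT_RP)
        _, meshes = segment_whole(scene)
        prof = profile_for(scene, meshes[0])
        assert prof.usable
        np.testing.assert_allclose(prof.ratio[prof.valid], 1.0, atol=1e-9)
        assert np.nanmean(prof.ratio[prof.valid]) == pytest.approx(1.0, abs=1e-9)

    def test_binned_sums_match_brute_force(self, divided_cell_scene):
        """Vectorized binning == explicit per-pixel projection loop."""
        scene = divided_cell_scene
        _, meshes = segment_whole(scene)
        prof = profile_for(scene, meshes[0])
        oracle_rep = brute_force_bins(
            meshes[0], scene.channels["reporter"], prof.n_bins, 0.2
        )
        oracle_mem = brute_force_bins(
            meshes[0], scene.channels["membrane"], prof.n_bins, 0.2
        )
        np.testing.assert_allclose(prof.reporter, oracle_rep, rtol=0, atol=1e-9)
        np.testing.assert_allclose(prof.membrane, oracle_mem, rtol=0, atol=1e-9)

    def test_gain_invariance(self, divided_cell_scene):
        """reporter x c, membrane x d leaves the unit-mean profile unchanged."""
        scene = divided_cell_scene
        _, meshes = segment_whole(scene)
        mesh = meshes[0]
        rep = scene.channels["reporter"] - 0.2
        mem = scene.channels["membrane"] - 0.2
        base = axial_profile(mesh, rep, mem)
        scaled = axial_profile(mesh, 3.7 * rep, 0.4 * mem)
        np.testing.assert_allclose(
            scaled.ratio[scaled.valid], base.ratio[base.valid], atol=1e-9
        )

    def test_membrane_starved_profile_flagged(self):
        cell = sg.build_cell(3.25, 0.9, centroid_px=(48.0, 48.0))
        scene = render_single(cell, rp=EXACT_RP)
        _, meshes = segment_whole(scene)
        mesh = meshes[0]
        mem = np.zeros_like(scene.channels["membrane"])  # no membrane signal
        prof = axial_profile(mesh, scene.channels["reporter"], mem)
        assert not prof.usable

    def test_rejects_too_few_bins_and_negative_background(self, divided_cell_scene):
        scene = divided_cell_scene
        _, meshes = segment_whole(scene)
        with pytest.raises(ValueError):
            profile_for(scene, meshes[0], n_bins=5)
        with pytest.raises(ValueError):
            axial_profile(meshes[0], scene.channels["reporter"],
                          scene.channels["membrane"], background=(-1.0, 0.0))


class TestDetectSepta:
    def test_no_septum_empty_list(self):
        cell = sg.build_cell(3.25, 0.9, centroid_px=(48.0, 48.0))
        scene = render_single(cell)
        _, meshes = segment_whole(scene)
        assert detect_septa(profile_for(scene, meshes[0])) == []

    @pytest.mark.parametrize("planted,polar", [(0.2, True), (0.5, False)])
    def test_single_septum_localized(self, planted, polar):
        cell = sg.build_cell(3.25, 0.9, [planted], centroid_px=(48.0, 48.0),
                             angle_rad=0.6)
        scene = render_single(cell)
        _, meshes = segment_whole(scene)
        prof = profile_for(scene, meshes[0])
        calls = detect_septa(prof)
        assert len(calls) == 1
        err = min(abs(calls[0].position_snorm - planted),       # mesh axis
                  abs(1.0 - calls[0].position_snorm - planted))  # direction is arbitrary
        assert err <= 1.0 / prof.n_bins + 1e-9
        assert calls[0].polar is polar

    def test_two_polar_septa(self):
        """Disporic geometry: septa at 0.2 and 0.8, both called polar."""
        cell = sg.build_cell(4.0, 0.9, [0.2, 0.8], centroid_px=(48.0, 48.0))
        scene = render_single(cell)
        _, meshes = segment_whole(scene)
        prof = profile_for(scene, meshes[0])
        calls = detect_septa(prof)
        assert len(calls) == 2
        assert all(c.polar for c in calls)
        assert abs(calls[0].position_snorm - 0.2) <= 1.0 / prof.n_bins + 1e-9
        assert abs(calls[1].position_snorm - 0.8) <= 1.0 / prof.n_bins + 1e-9


class TestOrientAndAlign:
    def _profile(self, septum, angle=0.0):
        polar = septum is not None and min(septum, 1 - septum) <= 0.3
        cell = sg.build_cell(
            3.25, 0.9, [septum] if septum else [],
            class_label="compartment_restricted" if polar else "uniform_membrane",
            enrichment={"forespore": 1.0, "mother": 0.05} if polar else None,
            centroid_px=(48.0, 48.0), angle_rad=angle,
        )
        scene = render_single(cell)
        _, meshes = segment_whole(scene)
        prof = profile_for(scene, meshes[0])
        return prof, detect_septa(prof)

    def test_distal_septum_flipped_to_origin(self):
        prof, septa = self._profile(0.8)
        op = orient_and_align(prof, septa)
        assert op.division_state == "polar_divided"
        assert op.flipped
        assert op.septum_snorm == pytest.approx(0.2, abs=1.0 / prof.n_bins + 1e-9)
        assert op.forespore_interval[0] == 0.0

    def test_orientation_idempotent(self):
        prof, septa = self._profile(0.8)
        op = orient_and_align(prof, septa)
        assert orient_and_align(op) is op

    def test_predivisional_contract(self):
        prof, septa = self._profile(None)
        op = orient_and_align(prof, septa)
        assert op.division_state == "predivisional"
        assert not op.oriented
        with pytest.raises(ValueError, match="predivisional"):
            _ = op.forespore_interval

    def test_midcell_state(self):
        prof, septa = self._profile(0.5)
        op = orient_and_align(prof, septa)
        assert op.division_state == "midcell_divided"


class TestAverageProfiles:
    def test_copies_of_one_profile(self):
        prof, septa = TestOrientAndAlign()._profile(0.2)
        op = orient_and_align(prof, septa)
        pop = average_profiles([op] * 5, min_n=1)
        single = average_profiles([op], min_n=1)
        ok = ~np.isnan(pop.mean)
        np.testing.assert_allclose(pop.mean[ok], single.mean[ok], atol=1e-12)
        np.testing.assert_allclose(pop.sem[ok], 0.0, atol=1e-12)

    def test_two_profile_mean_is_arithmetic_mean(self):
        p1, s1 = TestOrientAndAlign()._profile(0.2)
        p2, s2 = TestOrientAndAlign()._profile(0.8, angle=0.5)
        ops = [orient_and_align(p1, s1), orient_and_align(p2, s2)]
        pop = average_profiles(ops, min_n=2)
        # independent two-term oracle
        grid = pop.grid_um
        vals = []
        for op in ops:
            p = op.profile
            x = p.centers_snorm * p.length_um
            ok = p.valid & np.isfinite(p.ratio)
            v = np.interp(grid, x[ok], p.ratio[ok])
            v[grid > p.length_um] = np.nan
            vals.append(v)
        oracle = np.nanmean(np.vstack(vals), axis=0)
        both = pop.n == 2
        np.testing.assert_allclose(pop.mean[both], oracle[both], atol=1e-9)

    def test_grid_beyond_all_cells_masked(self):
        prof, septa = TestOrientAndAlign()._profile(0.2)
        op = orient_and_align(prof, septa)
        pop = average_profiles([op], window_um=6.0, min_n=1)
        beyond = pop.grid_um > prof.length_um
        assert beyond.any()
        assert np.isnan(pop.mean[beyond]).all()
        assert (pop.n[beyond] == 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([])


class TestRandomPoleProfiles:
    def _population_profiles(self, class_label, n=24, seed=31):
        spec = sg.PopulationSpec(
            n_cells=n, class_mixture={class_label: 1.0},
            septum_rule="none", seed=seed,
        )
        scene, _ = sg.simulate_population(spec)
        _, meshes = segment_whole(scene)
        return [profile_for(scene, m) for m in meshes]

    def test_uniform_membrane_population_flat(self):
        profs = self._population_profiles("uniform_membrane")
        pop, _ = random_pole_profiles(profs, n_poles=20, seed=5, min_n=5)
        ok = ~np.isnan(pop.mean)
        assert np.all(np.abs(pop.mean[ok] - 1.0) <= 3 * np.maximum(pop.sem[ok], 0.02))

    def test_polar_cap_population_recovers_enrichment(self):
        """Cap-decorated cells: near-pole mean exceeds distal mean."""
        profs = self._population_profiles("polar_cap")
        pop, _ = random_pole_profiles(profs, n_poles=20, seed=5, min_n=3)
        near = pop.mean[(pop.grid_um <= 0.3)]
        far = pop.mean[(pop.grid_um >= 2.0) & (pop.grid_um <= 3.0)]
        assert np.nanmean(near) > np.nanmean(far)

    def test_seeded_sampling_deterministic(self):
        profs = self._population_profiles("uniform_membrane", n=10)
        _, picks1 = random_pole_profiles(profs, n_poles=8, seed=2)
        _, picks2 = random_pole_profiles(profs, n_poles=8, seed=2)
        assert picks1 == picks2

    def test_too_many_poles_rejected(self):
        profs = self._population_profiles("uniform_membrane", n=4)
        with pytest.raises(ValueError):
            random_pole_profiles(profs, n_poles=9, seed=0)


class TestKymograph:
    def test_static_scene_rows_identical(self):
        frame = sg.render_ring_frames([5.0], (48, 48))[0]
        stack = np.stack([frame] * 4)
        kymo = kymograph(stack, ((4.0, 24.0), (44.0, 24.0)))
        for row in kymo[1:]:
            np.testing.assert_allclose(row, kymo[0], atol=1e-12)

    def test_constricting_ring_width_non_increasing(self):
        """Shrinking ring: above-background segment narrows monotonically."""
        radii = np.linspace(10.0, 2.0, 6)
        frames = sg.render_ring_frames(radii, (48, 48))
        kymo = kymograph(frames, ((4.0, 24.0), (44.0, 24.0)))
        widths = [(row > 0.5 * frames.max()).sum() for row in kymo]
        assert all(b <= a for a, b in zip(widths, widths[1:]))

    def test_contracts(self):
        frame = np.zeros((16, 16))
        with pytest.raises(ValueError):
            kymograph(frame[None], ((0, 0), (15, 15)))  # single frame
        with pytest.raises(ValueError):
            kymograph(np.stack([frame] * 3), ((0, 0), (40, 40)))  # off image


class TestMirrorInvariance:
    def test_population_profile_unchanged_by_image_flip(self, mixed_population):
        """Left-right mirroring the micrograph leaves the oriented population
        profile unchanged (orientation comes from the septum, not the grid)."""
        scene, _ = mixed_population

        def population(channels):
            from polarprof.pipeline import analyze_scene

            res = analyze_scene(channels, scene.pixel_size_um, min_n=1)
            return res["population_profile"]

        pop = population(scene.channels)
        flipped = {k: np.fliplr(v).copy() for k, v in scene.channels.items()}
        pop_f = population(flipped)
        ok = ~np.isnan(pop.mean)
        np.testing.assert_allclose(pop.mean[ok], pop_f.mean[ok], atol=1e-9)
        np.testing.assert_array_equal(pop.n, pop_f.n)


def test_background_estimate_recovers_offset(divided_cell_scene):
    scene = divided_cell_scene
    bg = estimate_background(scene.channels["membrane"], scene.truth_mask())
    # small upward bias from the PSF halo just outside the mask is expected
    assert bg == pytest.approx(0.2, abs=5e-3)
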