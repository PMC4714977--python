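"""Compartmentalization categories and the mean+2SD enrichment rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polarprof import synthgen as sg
from polarprof.axialprofile import AxialProfile, OrientedProfile, detect_septa, orient_and_align
from polarprof.compartment_stats import (
    ActivityThresholds,
    CompartmentCall,
    activity_threshold_from_controls,
    call_sigmaF_activity,
    compartment_fractions,
    enrichment_calls,
    summarize_population,
)
from conftest import EXACT_RP, render_single, segment_whole


def synthetic_profile(reporter_bins, septum=0.2, n_bins=50, length_um=3.25):
    """Hand-built oriented profile with prescribed per-bin reporter sums."""
    rep = np.asarray(reporter_bins, dtype=float)
    mem = np.ones(n_bins)
    prof = AxialProfile(
        cell_id=1, n_bins=n_bins, reporter=rep, membrane=mem,
        ratio=rep / max(rep.mean(), 1e-12), valid=np.ones(n_bins, dtype=bool),
        length_um=length_um,
    )
    return OrientedProfile(prof, "polar_divided", septum_snorm=septum)


class TestCompartmentFractions:
    def test_all_reporter_in_forespore(self):
        rep = np.zeros(50)
        rep[:10] = 5.0  # bins below septum 0.2
        call = compartment_fractions(synthetic_profile(rep))
        assert call.f_fs == pytest.approx(1.0)
        assert call.rho == np.inf

    def test_uniform_reporter_fraction_equals_septum(self):
        """Uniform reporter, septum at 0.2 -> f_fs = 0.2 and rho = 1."""
        call = compartment_fractions(synthetic_profile(np.ones(50)))
        assert call.f_fs == pytest.approx(0.2)
        assert call.rho == pytest.approx(1.0)

    def test_fraction_matches_ground_truth_mask_pixel_sums(self):
        """Rendered cell: binned f_fs equals the per-pixel oracle over the
        planted compartment masks (no blur, no noise, septum on a bin edge
        of the 51 effective bins)."""
        septum = 10.0 / 51.0
        cell = sg.build_cell(
            3.4, 0.9, [septum], class_label="compartment_restricted",
            enrichment={"forespore": 1.0, "mother": 0.3},
            centroid_px=(48.0, 48.0), angle_rad=0.5,
        )
        scene = render_single(cell, rp=EXACT_RP)
        _, meshes = segment_whole(scene)
        mesh = meshes[0]
        from polarprof.axialprofile import axial_profile

        prof = axial_profile(mesh, scene.channels["reporter"],
                             scene.channels["membrane"], n_bins=51)
        assert prof.n_bins == 51
        op = OrientedProfile(prof, "polar_divided", septum_snorm=septum)
        call = compartment_fractions(op)
        # oracle: direct pixel sums split by the same axial projection
        rep = scene.channels["reporter"]
        vals = rep[mesh.pixels[:, 0], mesh.pixels[:, 1]]
        snorm = mesh.axial_fraction(mesh.pixels)
        oracle = vals[snorm < septum].sum() / vals.sum()
        assert call.f_fs == pytest.approx(oracle, abs=1e-12)
        # and the generator's own per-compartment integrals agree closely
        truth_frac = scene.ground_truth["cells"][0]["forespore_fraction"]
        assert call.f_fs == pytest.approx(truth_frac, abs=0.02)

    def test_zero_signal_is_inactive(self):
        call = compartment_fractions(synthetic_profile(np.zeros(50)))
        assert np.isnan(call.f_fs)
        assert call_sigmaF_activity(call) == "inactive"


class TestCallSigmaF:
    def test_mother_empty_is_forespore_specific(self):
        rep = np.zeros(50)
        rep[:10] = 1.0
        call = compartment_fractions(synthetic_profile(rep))
        assert call_sigmaF_activity(call) == "forespore_specific"

    def test_below_activity_floor_is_inactive(self):
        call = compartment_fractions(synthetic_profile(np.ones(50)))
        th = ActivityThresholds(activity_min=100.0)
        assert call_sigmaF_activity(call, th) == "inactive"

    def test_balanced_cell_is_both(self):
        """Equal densities in the two compartments: rho = 1 in (0.5, 2)."""
        call = compartment_fractions(synthetic_profile(np.ones(50)))
        assert call_sigmaF_activity(call) == "both"

    def test_mother_dominated_cell(self):
        rep = np.ones(50)
        rep[:10] = 0.1
        call = compartment_fractions(synthetic_profile(rep))
        assert call_sigmaF_activity(call) == "mother_cell"

    def test_predivisional_categories(self):
        prof = synthetic_profile(np.ones(50)).profile
        op = OrientedProfile(prof, "predivisional", oriented=False)
        call = compartment_fractions(op)
        assert call_sigmaF_activity(call) == "predivisional_active"
        quiet = OrientedProfile(
            synthetic_profile(np.zeros(50)).profile, "predivisional", oriented=False
        )
        assert call_sigmaF_activity(compartment_fractions(quiet)) == "predivisional_inactive"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ActivityThresholds(rho_hi=0.4, rho_lo=0.5)


class TestEnrichmentRule:
    def test_equal_intensities_no_flags(self):
        res = enrichment_calls(np.full(10, 3.0))
        assert res.sigma == 0.0
        assert res.n_flagged == 0

    def test_worked_example_population_sd(self):
        """[1,1,1,10]: mu=3.25, population sigma~3.897, threshold~11.05."""
        res = enrichment_calls(np.array([1.0, 1.0, 1.0, 10.0]))
        assert res.mu == pytest.approx(3.25)
        assert res.sigma == pytest.approx(np.sqrt(((np.array([1, 1, 1, 10]) - 3.25) ** 2).mean()))
        assert res.sigma == pytest.approx(3.897, abs=1e-3)
        assert res.threshold == pytest.approx(11.044, abs=1e-3)
        assert res.n_flagged == 0

    def test_planted_bright_minicells_recovered(self):
        """1000 dim cells + 20 planted 10x bright: precision/recall >= 0.9."""
        rng = np.random.default_rng(42)
        dim = rng.normal(1.0, 0.05, 1000).clip(0)
        bright = rng.normal(10.0, 0.5, 20).clip(0)
        intensities = np.concatenate([dim, bright])
        planted = np.zeros(1020, dtype=bool)
        planted[1000:] = True
        res = enrichment_calls(intensities)
        tp = (res.flags & planted).sum()
        assert tp / max(res.n_flagged, 1) >= 0.9   # precision
        assert tp / planted.sum() >= 0.9           # recall

    def test_flags_match_definition_exactly(self):
        rng = np.random.default_rng(0)
        I = rng.gamma(2.0, 1.0, 500)
        res = enrichment_calls(I)
        np.testing.assert_array_equal(res.flags, I > I.mean() + 2 * I.std(ddof=0))

    def test_contracts(self):
        with pytest.raises(ValueError):
            enrichment_calls(np.array([1.0]))
        with pytest.raises(ValueError):
            enrichment_calls(np.array([1.0, -2.0]))
        with pytest.raises(ValueError):
            enrichment_calls(np.ones(4), np.ones(3))

    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=60))
    def test_flag_count_consistent(self, vals):
        I = np.asarray(vals)
        res = enrichment_calls(I)
        assert res.n_flagged == int((I > res.threshold).sum())


class TestSummarize:
    def _call(self, cat, length=3.0):
        c = CompartmentCall(0, 0.5, 1.0, 10.0, "polar_divided", 0.2, length)
        c.category = cat
        return c

    def test_single_category_is_100_percent(self):
        s = summarize_population([self._call("forespore_specific")] * 4)
        assert s["categories"].loc["forespore_specific", "percent"] == 100.0
        assert s["miscompartmentalized_pct"] == 0.0

    def test_percentages_sum_to_100(self):
        calls = [self._call(c) for c in
                 ("forespore_specific", "both", "both", "mother_cell", "inactive")]
        s = summarize_population(calls)
        assert s["categories"]["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        assert s["miscompartmentalized_pct"] == pytest.approx(75.0)

    def test_confusion_and_accuracy(self):
        calls = [self._call("forespore_specific"), self._call("both"),
                 self._call("both")]
        s = summarize_population(calls, truth_categories=[
            "forespore_specific", "both", "forespore_specific"])
        assert s["category_accuracy"] == pytest.approx(2 / 3)
        assert s["confusion"].loc["forespore_specific", "both"] == 1

    def test_enriched_minicells_shift_length_distribution(self):
        """Enrichment planted only in short cells -> flagged median length
        below unflagged median (the minicell signature)."""
        rng = np.random.default_rng(7)
        lengths = np.concatenate([rng.uniform(2.5, 5.0, 300), rng.uniform(0.7, 1.2, 8)])
        intens = np.concatenate([rng.normal(1, 0.05, 300), rng.normal(10, 0.5, 8)]).clip(0)
        enr = enrichment_calls(intens, lengths)
        calls = [self._call("predivisional_active", l) for l in lengths]
        s = summarize_population(calls, enrichment=enr)
        assert s["n_flagged"] == 8
        assert s["median_length_flagged_um"] < s["median_length_unflagged_um"]


def test_activity_threshold_from_inactive_controls():
    rng = np.random.default_rng(3)
    controls = rng.normal(5.0, 1.0, 2000).clip(0)
    thr = activity_threshold_from_controls(controls, q=99.0)
    assert thr == pytest.approx(np.percentile(controls, 99.0))
    assert (controls > thr).mean() <= 0.011
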