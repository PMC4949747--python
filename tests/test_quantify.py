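"""Peak detection/integration, confirmation, IS quantification, validation stats."""

import math

import numpy as np
import pytest

import napesrm as n
import napesrm.quantify as Q
from napesrm import studies
from napesrm.quantify import SNR_CAP, InternalStandardError
from napesrm.simulate import SamplePlan, SrmTrace

from conftest import IS_NAME


def make_trace(tid="x|F1", n_pts=601, dt_s=0.5, peaks=(), noise_sd=0.0,
               baseline=0.0, seed=0):
    """Trace on a uniform grid with optional (center_min, area_cs, sigma_s) peaks."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_pts) * dt_s / 60.0
    y = np.full(n_pts, float(baseline))
    for center, area, sigma in peaks:
        y += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((t - center) * 60.0 / sigma) ** 2
        )
    if noise_sd > 0:
        y += rng.normal(0, noise_sd, n_pts)
    return SrmTrace(tid, t, np.clip(y, 0, None))


class TestEstimateNoise:
    def test_constant_trace_gives_zero(self):
        tr = make_trace(peaks=[(2.5, 100.0, 4.0)], baseline=10.0)
        assert Q.estimate_noise(tr, exclusion=(2.0, 3.0)) == 0.0

    def test_gaussian_noise_recovered(self):
        tr = make_trace(n_pts=2000, noise_sd=5.0, baseline=50.0, seed=1)
        assert Q.estimate_noise(tr) == pytest.approx(5.0, rel=0.10)

    def test_exclusion_covering_everything_errors(self):
        tr = make_trace()
        with pytest.raises(ValueError):
            Q.estimate_noise(tr, exclusion=(-1.0, 100.0))


class TestDetectPeaks:
    def test_single_peak_apex_accuracy(self):
        tr = make_trace(peaks=[(2.5, 1000.0, 4.0)], noise_sd=2.0, baseline=20.0, seed=2)
        peaks = Q.detect_peaks(tr, (1.0, 4.0))
        assert len(peaks) == 1
        assert abs(peaks[0].rt_apex - 2.5) < 0.5 / 60.0  # one sampling interval

    def test_noise_only_false_positive_rate(self):
        # 300 independent noise-only windows at the 3-SD threshold: the
        # >=3-sample width requirement keeps the false-positive rate per
        # window well under 1 %.
        hits = 0
        for seed in range(300):
            tr = make_trace(n_pts=361, noise_sd=5.0, baseline=20.0, seed=seed)
            hits += bool(Q.detect_peaks(tr, (0.0, 3.0)))
        assert hits / 300 < 0.01

    def test_two_separated_peaks(self):
        sigma = 4.0
        sep = 5 * sigma / 60.0
        tr = make_trace(
            peaks=[(2.0, 1000.0, sigma), (2.0 + sep, 800.0, sigma)],
            noise_sd=2.0,
            baseline=20.0,
            seed=3,
        )
        peaks = Q.detect_peaks(tr, (1.0, 4.0))
        assert len(peaks) == 2

    def test_noiseless_snr_capped(self):
        tr = make_trace(peaks=[(2.5, 1000.0, 4.0)], baseline=10.0)
        peaks = Q.detect_peaks(tr, (1.0, 4.0))
        assert peaks[0].snr == SNR_CAP


class TestIntegrate:
    def test_unit_area_gaussian(self):
        tr = make_trace(peaks=[(2.5, 1.0, 4.0)])
        assert Q.integrate(tr, (1.0, 4.0)) == pytest.approx(1.0, abs=1e-3)

    def test_zero_trace(self):
        tr = make_trace()
        assert Q.integrate(tr, (1.0, 4.0)) == 0.0

    def test_zero_width_bounds(self):
        tr = make_trace(peaks=[(2.5, 100.0, 4.0)])
        assert Q.integrate(tr, (2.5, 2.5)) == 0.0

    def test_inverted_bounds_rejected(self):
        tr = make_trace()
        with pytest.raises(ValueError):
            Q.integrate(tr, (3.0, 1.0))

    def test_constant_baseline_removed(self):
        tr = make_trace(peaks=[(2.5, 500.0, 4.0)], baseline=40.0)
        assert Q.integrate(tr, (1.5, 3.5)) == pytest.approx(500.0, rel=2e-3)


class TestConfirm:
    def _peak(self, rt, area, tid="x"):
        return Q.Peak(tid, rt, area, height=area / 10, snr=100.0, bounds=(rt - 0.2, rt + 0.2))

    def test_clean_pass(self):
        c = Q.confirm_species(
            [self._peak(10.0, 1000.0)], [self._peak(10.01, 350.0)], expected_ratio=0.35
        )
        assert c.detected and not c.flags

    def test_ratio_failure_flagged(self):
        c = Q.confirm_species(
            [self._peak(10.0, 1000.0)], [self._peak(10.01, 700.0)], expected_ratio=0.35
        )
        assert not c.detected and c.flags == {"ion_ratio_fail"}

    def test_rt_mismatch_flagged(self):
        c = Q.confirm_species(
            [self._peak(10.0, 1000.0)], [self._peak(10.2, 350.0)], expected_ratio=0.35
        )
        assert "rt_mismatch" in c.flags

    def test_missing_qualifier(self):
        c = Q.confirm_species([self._peak(10.0, 1000.0)], [], expected_ratio=0.35)
        assert not c.detected and c.flags == {"missing_qualifier"}

    def test_missing_quantifier(self):
        c = Q.confirm_species([], [self._peak(10.0, 350.0)], expected_ratio=0.35)
        assert not c.detected and c.flags == {"missing_quantifier"}


@pytest.fixture(scope="module")
def iso_rt_method(rt_model):
    """Method whose analyte shares the IS's (C+n, D+dn) totals, so both peaks
    sit at the same predicted RT on identical grids."""
    species = [n.parse_name("PE 37:1-N-18:1"), n.parse_name(IS_NAME)]
    return n.build_method(species, rt_model)


class TestQuantifySample:
    def test_equal_areas_give_exactly_500(self, iso_rt_method):
        plan = SamplePlan(
            species_amounts={"PE 37:1-N-18:1": 50.0},
            response_factors=2000.0,
            noise_sd=0.0,
            rt_jitter_sd_s=0.0,
        )
        traces = n.simulate_sample(plan, iso_rt_method)
        results = n.quantify_sample(traces, iso_rt_method, IS_NAME, 50.0, 0.1)
        r = next(x for x in results if x.species_name == "PE 37:1-N-18:1")
        assert r.concentration_pmol_per_g == 500.0

    def test_two_percent_of_is_gives_lloq_level(self, iso_rt_method):
        plan = SamplePlan(
            species_amounts={"PE 37:1-N-18:1": 1.0},
            response_factors=2000.0,
            noise_sd=0.0,
            rt_jitter_sd_s=0.0,
        )
        traces = n.simulate_sample(plan, iso_rt_method)
        results = n.quantify_sample(traces, iso_rt_method, IS_NAME, 50.0, 0.1)
        r = next(x for x in results if x.species_name == "PE 37:1-N-18:1")
        assert r.concentration_pmol_per_g == pytest.approx(10.0, rel=1e-6)

    def test_noiseless_end_to_end_recovery(self, validation_method):
        amounts = {a: amt for a, amt in zip(studies.HEPTADECANOYL_ANALYTES,
                                            (2.0, 7.5, 20.0, 55.0, 130.0))}
        plan = SamplePlan(
            species_amounts=amounts,
            response_factors=2000.0,
            noise_sd=0.0,
            rt_jitter_sd_s=0.0,
        )
        traces = n.simulate_sample(plan, validation_method)
        results = n.quantify_sample(traces, validation_method, IS_NAME, 50.0, 0.1)
        for r in results:
            if r.species_name in amounts:
                truth = amounts[r.species_name] / 0.1
                assert r.detected
                assert r.concentration_pmol_per_g == pytest.approx(truth, rel=5e-3)

    def test_missing_is_hard_error(self, iso_rt_method):
        plan = SamplePlan(
            species_amounts={"PE 37:1-N-18:1": 50.0},
            is_amount_pmol=0.0,
            noise_sd=0.0,
            rt_jitter_sd_s=0.0,
        )
        traces = n.simulate_sample(plan, iso_rt_method)
        with pytest.raises(InternalStandardError):
            n.quantify_sample(traces, iso_rt_method, IS_NAME, 50.0, 0.1)

    def test_is_normalization_invariance(self, validation_method):
        amounts = {"PE 36:2-N-17:0": 12.0, "PE 38:4-N-17:0": 90.0}
        plan = SamplePlan(species_amounts=amounts, seed=6)
        traces = n.simulate_sample(plan, validation_method)
        scaled = {
            tid: SrmTrace(tid, tr.times, tr.intensities * 3.7)
            for tid, tr in traces.items()
        }
        base = n.quantify_sample(traces, validation_method, IS_NAME, 50.0, 0.1)
        scl = n.quantify_sample(scaled, validation_method, IS_NAME, 50.0, 0.1)
        for r0, r1 in zip(base, scl):
            assert r0.detected == r1.detected
            if r0.concentration_pmol_per_g is not None:
                assert r1.concentration_pmol_per_g == pytest.approx(
                    r0.concentration_pmol_per_g, rel=1e-6
                )

    def test_interference_on_qualifier_fails_ion_ratio(self, validation_method):
        plan = SamplePlan(
            species_amounts={"PE 36:2-N-17:0": 40.0, "PE 34:1-N-17:0": 40.0}, seed=9
        )
        traces = n.simulate_sample(plan, validation_method)
        tl = validation_method.qualifier("PE 36:2-N-17:0")
        bumped = n.inject_interference(
            traces, validation_method, tl.transition_id,
            rt_offset_min=0.05, area=40.0 * 2000.0,
        )
        results = n.quantify_sample(bumped, validation_method, IS_NAME, 50.0, 0.1)
        hit = next(r for r in results if r.species_name == "PE 36:2-N-17:0")
        clean = next(r for r in results if r.species_name == "PE 34:1-N-17:0")
        assert not hit.detected and "ion_ratio_fail" in hit.flags
        assert clean.detected and not clean.flags


class TestIsobarSelectivity:
    def test_coeluting_isomers_quantified_independently(self, rt_model, fig2_trio):
        species = fig2_trio + [n.parse_name(IS_NAME)]
        method = n.build_method(species, rt_model)
        amounts = {sp.name: amt for sp, amt in zip(fig2_trio, (20.0, 40.0, 10.0))}
        plan = SamplePlan(
            species_amounts=amounts,
            response_factors=2000.0,
            noise_sd=0.0,
            rt_jitter_sd_s=0.0,
        )
        traces = n.simulate_sample(plan, method)
        results = n.quantify_sample(traces, method, IS_NAME, 50.0, 0.1)
        for r in results:
            if r.species_name in amounts:
                assert r.concentration_pmol_per_g == pytest.approx(
                    amounts[r.species_name] / 0.1, rel=5e-3
                )
        # A precursor-only analysis sums the co-eluting isomers and cannot
        # recover any individual amount.
        tq = method.quantifier(fig2_trio[0].name)
        summed = SrmTrace(
            "summed",
            traces[tq.transition_id].times,
            sum(
                traces[method.quantifier(sp.name).transition_id].intensities
                for sp in fig2_trio
            ),
        )
        total_area = Q.integrate(summed, (tq.rt_start, tq.rt_end))
        for sp in fig2_trio:
            own_area = Q.integrate(
                traces[method.quantifier(sp.name).transition_id],
                (tq.rt_start, tq.rt_end),
            )
            assert total_area > 1.2 * own_area


class TestLinearity:
    def test_exact_line_recovered(self):
        # Slope/intercept of a representative heptadecanoyl analyte's
        # calibration line; noiseless sampling must recover it exactly.
        levels = studies.CALIBRATION_LEVELS
        ratios = [0.7351 * x + 2.2269 for x in levels]
        fit = n.fit_linearity(levels, ratios)
        assert fit.slope == pytest.approx(0.7351, abs=1e-10)
        assert fit.intercept == pytest.approx(2.2269, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(10)
        x = np.array(studies.CALIBRATION_LEVELS * 3)
        y = 0.002 * x + 0.1 + rng.normal(0, 0.05, x.size)
        fit = n.fit_linearity(x, y)
        xm, ym = x.mean(), y.mean()
        slope = ((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm))
        intercept = ym - slope * xm
        ss_res = ((y - slope * x - intercept) ** 2).sum()
        ss_tot = ((y - ym) ** 2).sum()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_constant_response_degenerate(self):
        fit = n.fit_linearity([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0 and fit.r2 == 0.0

    def test_weighted_refused(self):
        with pytest.raises(ValueError):
            n.fit_linearity([1, 2, 3], [1, 2, 3], weighted=True)

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            n.fit_linearity([1, 1, 2], [1, 1, 2])


class TestAccuracy:
    def test_point_on_line_is_zero(self):
        fit = n.LinearityFit(0.7351, 2.2269, 0.999, 9)
        acc = n.accuracy(fit, [(400.0, 0.7351 * 400.0 + 2.2269)])
        assert acc[400.0] == pytest.approx(0.0, abs=1e-9)

    def test_definition_arithmetic(self):
        # A back-calculated value 1.166x nominal is 16.6 % inaccuracy.
        fit = n.LinearityFit(1.0, 0.0, 1.0, 9)
        acc = n.accuracy(fit, [(50.0, 58.3)])
        assert acc[50.0] == pytest.approx(16.6, abs=1e-9)

    def test_negative_backcalc_warns(self):
        fit = n.LinearityFit(1.0, 10.0, 1.0, 9)
        with pytest.warns(UserWarning):
            acc = n.accuracy(fit, [(5.0, 2.0)])
        assert acc[5.0] > 100.0

    def test_zero_slope_rejected(self):
        fit = n.LinearityFit(0.0, 1.0, 0.0, 9)
        with pytest.raises(ValueError):
            n.accuracy(fit, [(50.0, 1.0)])


class TestPrecision:
    def test_identical_replicates(self):
        assert n.precision([7.0, 7.0, 7.0]) == 0.0

    def test_hand_arithmetic(self):
        assert n.precision([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_chi_square_envelope(self):
        # 15 replicates at 10 % multiplicative CV: the sample RSD estimate
        # lies within the [5, 15] % chi-square envelope.
        rng = np.random.default_rng(12)
        reps = 100.0 * rng.lognormal(0, 0.0997513, size=15)  # sigma for CV 10 %
        assert 5.0 < n.precision(reps) < 15.0

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            n.precision([1.0])


class TestLloq:
    def test_lowest_level_qualifies(self):
        res = n.lloq({10.0: [12.0, 13.0, 11.5], 25.0: [30.0, 31.0, 29.0]})
        assert res.lloq_pmol_per_g == 10.0

    def test_second_level_when_first_fails(self):
        res = n.lloq({10.0: [5.0, 12.0, 11.0], 25.0: [20.0, 22.0, 21.0]})
        assert res.lloq_pmol_per_g == 25.0

    def test_capped_snr_from_zero_noise(self):
        res = n.lloq({10.0: [SNR_CAP] * 3, 25.0: [SNR_CAP] * 3})
        assert res.lloq_pmol_per_g == 10.0

    def test_no_level_qualifies(self):
        res = n.lloq({10.0: [2.0], 25.0: [4.0]})
        assert res.lloq_pmol_per_g is None and res.above_highest_tested

    def test_undetected_replicate_disqualifies(self):
        res = n.lloq({10.0: [None, 15.0], 25.0: [20.0, 21.0]})
        assert res.lloq_pmol_per_g == 25.0
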