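"""Unit and property tests for the LRET lifetime-analysis machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrbiophys as mb
from mrbiophys.lret import (
    DecayTrace,
    ESMGridSpec,
    EquilibrationTrace,
    distribution_to_distances,
    efficiency_to_distance,
    esm_deconvolve,
    fit_equilibration,
    fit_multiexponential,
    lifetime_to_efficiency,
    populations_from_fit,
)
from mrbiophys.noise import NoiseSpec
from mrbiophys.simulate import simulate_equilibration, simulate_lret_decay


# ---------------------------------------------------------------------------
# efficiency / distance conversions
# ---------------------------------------------------------------------------

class TestConversions:
    def test_known_values(self):
        assert lifetime_to_efficiency(400.0, 1200.0) == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert efficiency_to_distance(2.0 / 3.0, 44.9) == pytest.approx(40.0, abs=0.02)
        # E = 0.5 at R = R0 by symmetry of the Forster equation
        assert efficiency_to_distance(0.5, 44.9) == pytest.approx(44.9, abs=1e-9)

    def test_limits(self):
        assert lifetime_to_efficiency(1e-9, 1200.0) == pytest.approx(1.0, abs=1e-10)
        with pytest.warns(UserWarning, match="clamped"):
            e = lifetime_to_efficiency(1200.0, 1200.0)
        assert 0 < e < 1e-9
        assert efficiency_to_distance(1.0 - 1e-12, 44.9) < 0.5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lifetime_to_efficiency(-5.0, 1200.0)
        for bad in (0.0, 1.0, 1.2, -0.1):
            with pytest.raises(ValueError):
                efficiency_to_distance(bad, 44.9)

    @given(
        r=st.floats(min_value=20.0, max_value=80.0),
        r0=st.floats(min_value=30.0, max_value=60.0),
    )
    def test_distance_efficiency_round_trip(self, r, r0):
        e = mb.distance_to_efficiency(r, r0)
        assert efficiency_to_distance(e, r0) == pytest.approx(r, rel=1e-10)


# ---------------------------------------------------------------------------
# multi-exponential fitting
# ---------------------------------------------------------------------------

class TestMultiExponentialFit:
    def test_single_exponential_recovery(self):
        t = np.linspace(0, 3000, 600)
        trace = DecayTrace(t, np.exp(-t / 500.0))
        fit = fit_multiexponential(trace, n_components=1)
        assert fit.lifetimes_us[0] == pytest.approx(500.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(1.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-8)

    def test_three_exponential_recovery_within_one_percent(self):
        t = np.linspace(0, 6000, 1500)
        amps, taus = np.array([0.5, 1.0, 1.0]), np.array([60.0, 400.0, 800.0])
        y = np.exp(-t[:, None] / taus[None, :]) @ amps
        fit = fit_multiexponential(DecayTrace(t, y), n_components=3)
        np.testing.assert_allclose(fit.lifetimes_us, taus, rtol=0.01)
        np.testing.assert_allclose(fit.amplitudes, amps, rtol=0.01)
        assert fit.residual_norm < 1e-6

    def test_offset_recovered(self):
        t = np.linspace(0, 3000, 400)
        trace = DecayTrace(t, 0.8 * np.exp(-t / 600.0) + 0.05)
        fit = fit_multiexponential(trace, n_components=1, fit_offset=True)
        assert fit.offset == pytest.approx(0.05, abs=1e-6)

    def test_components_sorted_ascending(self, biexp_trace):
        trace, _, taus = biexp_trace
        fit = fit_multiexponential(trace, n_components=2, fit_offset=False)
        assert np.all(np.diff(fit.lifetimes_us) > 0)
        np.testing.assert_allclose(fit.lifetimes_us, taus, rtol=1e-6)

    def test_degenerate_inputs_rejected(self):
        t = np.linspace(0, 100, 50)
        with pytest.raises(ValueError, match="constant"):
            fit_multiexponential(DecayTrace(t, np.ones_like(t)), n_components=1)
        with pytest.raises(ValueError):
            fit_multiexponential(DecayTrace(t, np.exp(-t / 10)), n_components=5)

    def test_round_trip_to_table_distances(self, wildtype_apo_truth, noiseless):
        trace = simulate_lret_decay(wildtype_apo_truth, noise=noiseless)
        fit = fit_multiexponential(trace, n_components=2)
        pops = populations_from_fit(fit, 1200.0, 44.9)
        closed, partial = pops.states
        assert closed.distance_A == pytest.approx(40.0, abs=0.01)
        assert partial.distance_A == pytest.approx(54.2, abs=0.01)


# ---------------------------------------------------------------------------
# exponential series method
# ---------------------------------------------------------------------------

class TestESM:
    def test_default_grid_matches_specification(self):
        bins = ESMGridSpec().bins()
        assert bins.size == 200
        assert bins[0] == pytest.approx(100.0)
        assert bins[-1] == pytest.approx(1500.0)
        assert np.allclose(np.diff(np.log(bins)), np.diff(np.log(bins))[0])

    def test_single_exponential_concentrates_near_truth(self):
        t = np.linspace(0, 6000, 1000)
        dist = esm_deconvolve(DecayTrace(t, np.exp(-t / 500.0)))
        bins = dist.lifetime_bins_us
        idx = np.argmin(np.abs(bins - 500.0))
        near = dist.weights[max(idx - 1, 0):idx + 2].sum()
        assert near >= 0.95 * dist.total_weight

    def test_two_component_bimodal_modes_within_one_step(self):
        t = np.linspace(0, 6000, 1200)
        y = 0.5 * np.exp(-t / 400.0) + 0.5 * np.exp(-t / 1000.0)
        dist = esm_deconvolve(DecayTrace(t, y))
        bins = dist.lifetime_bins_us
        step = np.log(bins[1] / bins[0])
        for target in (400.0, 1000.0):
            window = np.abs(np.log(bins / target)) <= 1.5 * step
            assert dist.weights[window].sum() > 0.2 * dist.total_weight

    def test_forward_consistency(self, wildtype_apo_truth, noiseless):
        trace = simulate_lret_decay(wildtype_apo_truth, noise=noiseless)
        dist = esm_deconvolve(trace)
        recon = dist.reconstruct(trace.time_us)
        rel_rms = np.sqrt(np.mean((recon - trace.intensity) ** 2)) / np.max(trace.intensity)
        assert rel_rms <= 1e-3

    def test_out_of_grid_decay_warns(self):
        t = np.linspace(0, 100, 300)
        with pytest.warns(UserWarning, match="outside the ESM grid"):
            esm_deconvolve(DecayTrace(t, np.exp(-t / 5.0)))


class TestDistanceDistribution:
    def test_single_bin_at_half_donor_lifetime_maps_to_r0(self):
        grid = ESMGridSpec(3, 400, 900)
        from mrbiophys.lret import ESMDistribution

        bins = grid.bins()
        weights = np.zeros_like(bins)
        weights[np.argmin(np.abs(bins - 600.0))] = 1.0
        d = distribution_to_distances(ESMDistribution(bins, weights, grid), tau_d_us=1200.0, r0_A=44.9)
        peak = d.distances_A[np.argmax(d.weights)]
        assert peak == pytest.approx(44.9, rel=0.01)

    def test_weight_conservation_and_monotonicity(self):
        from mrbiophys.lret import ESMDistribution

        grid = ESMGridSpec()
        bins = grid.bins()
        weights = np.linspace(1.0, 2.0, bins.size)
        with pytest.warns(UserWarning, match="dropping"):
            d = distribution_to_distances(ESMDistribution(bins, weights, grid), tau_d_us=1200.0)
        kept = bins < 1200.0
        assert d.total_weight == pytest.approx(weights[kept].sum())
        assert np.all(np.diff(d.distances_A) > 0)  # larger tau -> larger R

    def test_all_bins_above_donor_lifetime_raises(self):
        from mrbiophys.lret import ESMDistribution

        grid = ESMGridSpec(5, 1300, 1500)
        bins = grid.bins()
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                distribution_to_distances(ESMDistribution(bins, np.ones_like(bins), grid), tau_d_us=1200.0)


# ---------------------------------------------------------------------------
# population correction
# ---------------------------------------------------------------------------

def _manual_fit(amps, taus):
    from mrbiophys.lret import MultiExpFitResults

    amps, taus = np.asarray(amps, float), np.asarray(taus, float)
    return MultiExpFitResults(
        amplitudes=amps, lifetimes_us=taus, offset=0.0,
        amplitude_err=np.zeros_like(amps), lifetime_err=np.zeros_like(taus), offset_err=0.0,
        residual_norm=0.0, n_obs=100, fit_offset=False, success=True,
    )


class TestPopulations:
    def test_corrected_weights_worked_example(self):
        # A=(1,1), tau=(400,800), tau_D=1200 -> weights 1/800 : 1/400 -> 33.3%/66.7%
        pops = populations_from_fit(_manual_fit([1.0, 1.0], [400.0, 800.0]), 1200.0, 44.9)
        closed, partial = pops.states
        assert closed.population_pct == pytest.approx(100.0 / 3.0, abs=0.01)
        assert partial.population_pct == pytest.approx(200.0 / 3.0, abs=0.01)
        assert closed.label == "closed" and partial.label == "partially_open"
        assert closed.lifetime_us == 400.0

    def test_equal_corrected_weights_split_evenly(self):
        # amplitudes chosen so A_i/|tau_i - tau_D| are equal
        pops = populations_from_fit(_manual_fit([800.0, 400.0], [400.0, 800.0]), 1200.0)
        assert pops.states[0].population_pct == pytest.approx(50.0, abs=1e-9)

    def test_populations_always_sum_to_100(self):
        pops = populations_from_fit(_manual_fit([0.3, 1.7, 0.4], [150.0, 420.0, 800.0]), 1200.0,
                                    mode="threshold")
        assert sum(s.population_pct for s in pops.states) == pytest.approx(100.0)

    def test_footnote_mode_drops_first_of_three_components(self):
        # first component slower than the 100 us cutoff, but still dropped
        fit = _manual_fit([0.5, 1.0, 1.0], [150.0, 400.0, 800.0])
        pops = populations_from_fit(fit, 1200.0, mode="footnote_a")
        assert len(pops.states) == 2
        assert {s.lifetime_us for s in pops.states} == {400.0, 800.0}
        pops_thresh = populations_from_fit(fit, 1200.0, mode="threshold")
        assert len(pops_thresh.states) == 3

    def test_components_beyond_donor_lifetime_excluded(self):
        with pytest.warns(UserWarning, match="tau >= tau_D"):
            pops = populations_from_fit(
                _manual_fit([1.0, 1.0, 1.0], [400.0, 800.0, 1300.0]), 1200.0, mode="threshold"
            )
        assert len(pops.states) == 2

    def test_too_few_retained_components_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            populations_from_fit(_manual_fit([1.0, 1.0], [40.0, 800.0]), 1200.0, mode="threshold")


# ---------------------------------------------------------------------------
# equilibration kinetics
# ---------------------------------------------------------------------------

class TestEquilibration:
    def test_noiseless_exact_recovery(self, noiseless):
        trace = simulate_equilibration(0.02, 0.2, 1.0, np.linspace(0, 300, 60), noiseless)
        fit = fit_equilibration(trace)
        assert fit.kex == pytest.approx(0.02, rel=1e-8)
        assert fit.f0 == pytest.approx(0.2, abs=1e-9)
        assert fit.fmax == pytest.approx(1.0, abs=1e-9)
        # closed form at t = 1/kex
        assert fit.predict(np.array([50.0]))[0] == pytest.approx(
            0.2 + (1 - np.exp(-1.0)) * 0.8, rel=1e-9
        )

    def test_decreasing_trace_warns(self):
        t = np.linspace(0, 100, 30)
        with pytest.warns(UserWarning, match="sign convention"):
            fit_equilibration(EquilibrationTrace(t, 1.0 - 0.5 * (1 - np.exp(-0.05 * t))))

    def test_short_span_warns(self, noiseless):
        trace = simulate_equilibration(0.001, 0.2, 1.0, np.linspace(0, 100, 30), noiseless)
        with pytest.warns(UserWarning, match="poorly constrained"):
            fit_equilibration(trace)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_equilibration(EquilibrationTrace(np.array([0.0, 1, 2, 3.0]), np.array([0, 1, 1, 1.0])))

    def test_eightfold_rate_ratio_recovered_under_noise(self):
        # mirrors the mutant-vs-wild-type equilibration-rate comparison
        ok = 0
        for seed in range(20):
            wt = simulate_equilibration(0.02, 0.2, 1.0, np.linspace(0, 300, 120),
                                        NoiseSpec("gaussian_proportional", 0.01), seed)
            mut = simulate_equilibration(0.16, 0.2, 1.0, np.linspace(0, 37.5, 120),
                                         NoiseSpec("gaussian_proportional", 0.01), seed + 500)
            ratio = fit_equilibration(mut).kex / fit_equilibration(wt).kex
            ok += abs(ratio - 8.0) / 8.0 <= 0.05
        assert ok >= 19
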