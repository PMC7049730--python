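"""Forward-model and determinism tests for the synthetic-data generators."""

import numpy as np
import pytest

import mrbiophys as mb
from mrbiophys.noise import NoiseSpec
from mrbiophys.simulate import (
    DEFAULT_TQ_DELAYS_MS,
    ConformerTruth,
    perturb_peaklist,
    simulate_atpase,
    simulate_equilibration,
    simulate_fp_titration,
    simulate_lret_decay,
    simulate_tq_buildup,
)


# ---------------------------------------------------------------------------
# noise models
# ---------------------------------------------------------------------------

class TestNoiseSpec:
    def test_none_is_exact(self):
        y = np.linspace(1.0, 0.1, 20)
        out = NoiseSpec("none").apply(y, np.random.default_rng(0))
        np.testing.assert_array_equal(out, y)

    @pytest.mark.parametrize("kind", ["gaussian_constant", "gaussian_proportional", "poisson"])
    def test_seeded_noise_is_deterministic(self, kind):
        y = np.full(50, 100.0)
        spec = NoiseSpec(kind, 0.05)
        a = spec.apply(y, np.random.default_rng(42))
        b = spec.apply(y, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, y)

    def test_proportional_noise_scales_with_signal(self):
        rng = np.random.default_rng(0)
        big = NoiseSpec("gaussian_proportional", 0.01).apply(np.full(4000, 1000.0), rng)
        assert np.std(big - 1000.0) == pytest.approx(10.0, rel=0.1)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec("bogus")
        with pytest.raises(ValueError):
            NoiseSpec("gaussian_constant", -1.0)
        with pytest.raises(ValueError):
            NoiseSpec("poisson").apply(np.array([-1.0]), np.random.default_rng(0))


# ---------------------------------------------------------------------------
# LRET decay generator
# ---------------------------------------------------------------------------

class TestSimulateLretDecay:
    def test_single_state_at_r0_gives_half_donor_lifetime(self, noiseless):
        # E = 0.5 exactly when R equals the Forster radius
        truth = ConformerTruth(((44.9, 1.0),), donor_lifetime_us=1200.0)
        trace = simulate_lret_decay(truth, noise=noiseless)
        expected = np.exp(-trace.time_us / 600.0)
        np.testing.assert_allclose(trace.intensity, expected, rtol=1e-12)

    def test_noiseless_matches_forward_model_everywhere(self, wildtype_apo_truth, noiseless):
        trace = simulate_lret_decay(wildtype_apo_truth, noise=noiseless)
        taus = wildtype_apo_truth.lifetimes_us()
        fracs = np.array([f for _, f in wildtype_apo_truth.states])
        amps = fracs * np.abs(taus - 1200.0)
        amps /= amps.sum()
        expected = np.exp(-trace.time_us[:, None] / taus[None, :]) @ amps
        np.testing.assert_allclose(trace.intensity, expected, rtol=1e-12)
        assert trace.intensity[0] == pytest.approx(1.0, rel=1e-12)

    def test_same_seed_bit_identical(self, wildtype_apo_truth):
        a = simulate_lret_decay(wildtype_apo_truth, seed=7)
        b = simulate_lret_decay(wildtype_apo_truth, seed=7)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_amplitude_construction_inverts_population_correction(self, wildtype_apo_truth, noiseless):
        trace = simulate_lret_decay(wildtype_apo_truth, noise=noiseless)
        fit = mb.fit_multiexponential(trace, n_components=2)
        pops = mb.populations_from_fit(fit, 1200.0, 44.9)
        closed, partial = pops.states
        assert closed.population_pct == pytest.approx(15.0, abs=1e-4)
        assert partial.population_pct == pytest.approx(85.0, abs=1e-4)

    def test_instrument_component_adds_fast_exponential(self, wildtype_apo_truth, noiseless):
        trace = simulate_lret_decay(
            wildtype_apo_truth, noise=noiseless, instrument_amplitude=0.2, instrument_tau_us=30.0
        )
        assert trace.intensity[0] == pytest.approx(1.0, rel=1e-12)
        plain = simulate_lret_decay(wildtype_apo_truth, noise=noiseless)
        # fast component decays away: tails agree up to the 0.8 rescale
        tail = trace.time_us > 500
        np.testing.assert_allclose(trace.intensity[tail], 0.8 * plain.intensity[tail], rtol=1e-6)

    def test_invalid_truths_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ConformerTruth(((40.0, 0.5), (50.0, 0.4)))
        with pytest.raises(ValueError, match="positive"):
            ConformerTruth(((-4.0, 1.0),))
        with pytest.raises(ValueError, match="degenerate"):
            # distance so large that E underflows to exactly zero
            simulate_lret_decay(ConformerTruth(((1e60, 1.0),)), noise=NoiseSpec("none"))
        with pytest.raises(ValueError, match="increasing"):
            simulate_lret_decay(ConformerTruth(((40.0, 1.0),)), time_grid_us=np.array([0.0, 2.0, 1.0]))


# ---------------------------------------------------------------------------
# equilibration, ATPase, FP, TQ generators
# ---------------------------------------------------------------------------

class TestScalarGenerators:
    def test_equilibration_limits_and_value(self, noiseless):
        t = np.array([0.0, 50.0, 1e6])
        trace = simulate_equilibration(0.02, 0.2, 1.0, t, noiseless)
        assert trace.intensity[0] == pytest.approx(0.2)
        assert trace.intensity[1] == pytest.approx(0.2 + 0.8 * (1 - np.exp(-1.0)), rel=1e-12)
        assert trace.intensity[2] == pytest.approx(1.0)

    def test_equilibration_input_validation(self, noiseless):
        with pytest.raises(ValueError):
            simulate_equilibration(-1.0, 0.0, 1.0, np.array([0.0, 1.0]), noiseless)
        with pytest.raises(ValueError):
            simulate_equilibration(0.1, 0.0, 1.0, np.array([]), noiseless)
        with pytest.raises(ValueError):
            simulate_equilibration(0.1, 0.0, 1.0, np.array([-1.0, 2.0]), noiseless)

    def test_hill_velocities(self, noiseless):
        data = simulate_atpase(10.0, 20.0, 2.0, np.array([0.0, 20.0, 60.0, 100.0, 300.0]),
                               replicates=1, noise=noiseless)
        assert data.velocity[0] == 0.0
        assert data.velocity[1] == pytest.approx(5.0)  # v(KM) = Vmax/2 for any n
        assert data.velocity[2] == pytest.approx(9.0)  # 10*3600/(400+3600)
        with pytest.raises(ValueError):
            simulate_atpase(10.0, 20.0, 2.0, np.array([-5.0]), noise=noiseless)

    def test_fp_titration_limits(self, noiseless):
        grid = np.array([0.0, 10.0, 1e6])
        data = simulate_fp_titration(0.0, 0.005, 50.0, 250.0, grid, noiseless)
        assert data.polarization[0] == pytest.approx(50.0)
        assert data.polarization[1] == pytest.approx(250.0)  # KD=0, P >> probe: full binding
        assert data.polarization[2] == pytest.approx(250.0)

    def test_tq_buildup_model_values(self, noiseless):
        curve = simulate_tq_buildup(50.0, 0.0, noise=noiseless)
        np.testing.assert_allclose(
            curve.ratios, 0.75 * np.tanh(50.0 * DEFAULT_TQ_DELAYS_MS / 1000.0), rtol=1e-12
        )
        curve2 = simulate_tq_buildup(50.0, 100.0, np.array([10.0]), noise=noiseless)
        assert curve2.ratios[0] == pytest.approx(0.9725, abs=2e-4)
        # small-T expansion: ratio ~ 0.75 * eta * T
        tiny = simulate_tq_buildup(50.0, 100.0, np.array([1e-4]), noise=noiseless)
        assert tiny.ratios[0] == pytest.approx(0.75 * 50.0 * 1e-7, rel=1e-3)

    def test_tq_intensity_noise_mode(self):
        curve = simulate_tq_buildup(80.0, 50.0, noise=NoiseSpec("gaussian_constant", 0.001),
                                    seed=3, noise_on="intensities")
        assert curve.sigma == 0.001
        assert curve.ratio_sigma is not None and np.all(curve.ratio_sigma > 0)


# ---------------------------------------------------------------------------
# peak-list perturbation
# ---------------------------------------------------------------------------

def _base_peaklist():
    return [
        mb.MethylPeak(839, "Ile", "Ile_d1", 13.5, 0.75),
        mb.MethylPeak(828, "Leu", "Leu_d", 24.1, 0.92, stereo_tag=1),
        mb.MethylPeak(828, "Leu", "Leu_d", 23.8, 0.88, stereo_tag=2),
        mb.MethylPeak(808, "Met", "Met_e", 17.0, 1.95),
    ]


class TestPerturbPeaklist:
    def test_empty_map_is_identity(self):
        base = _base_peaklist()
        assert perturb_peaklist(base, {}) == base

    def test_stated_shift_produces_root2_csp(self):
        base = _base_peaklist()
        mut = perturb_peaklist(base, {"I839d1": (1.65, 0.29)})
        pairs, _, _ = mb.pair_peaklists(base, mut)
        records = {r.methyl_id: r for r in (mb.compute_csp(p) for p in pairs)}
        assert records["I839d1"].csp_ppm == pytest.approx(np.sqrt(2.0), rel=1e-12)
        assert records["L828d1"].csp_ppm == 0.0

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            perturb_peaklist(_base_peaklist(), {"Q1x": (0.1, 0.1)})

    def test_jitter_deterministic_under_seed(self):
        base = _base_peaklist()
        jitter = NoiseSpec("gaussian_constant", 0.01)
        a = perturb_peaklist(base, {}, jitter=jitter, seed=5)
        b = perturb_peaklist(base, {}, jitter=jitter, seed=5)
        assert a == b
        assert a != base
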