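"""Synthetic-data generators for every experimental input of the pipeline.

Each generator is the exact forward model of the corresponding analysis
stage, with a known ground truth, an explicit :class:`~mrbiophys.noise.NoiseSpec`,
and a seed, so every downstream fit can be validated by parameter recovery.
Equal seeds and specifications produce bit-identical outputs.

The LRET decay generator deserves a note: for a mixture of conformers the
acceptor decay is ``I(t) = sum_i A_i exp(-t / tau_i)`` with
``tau_i = tau_D * (1 - E_i)``, and the amplitude of each component scales
with both the molecule fraction and the per-molecule intensity contribution
of that component. Amplitudes are therefore constructed as
``A_i proportional to fraction_i * |tau_i - tau_D|`` — the exact inverse of
the population correction ``A_i / |tau_i - tau_D|`` applied by the analysis
— so a noiseless round trip returns the input fractions to solver
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinetics import BindingTitration, RateDataset, hill_velocity, quadratic_binding_polarization
from .lret import DecayTrace, EquilibrationTrace, distance_to_efficiency
from .nmr import MethylPeak, TQBuildupCurve, tq_ratio_model
from .noise import NoiseSpec

__all__ = [
    "ConformerTruth",
    "simulate_lret_decay",
    "simulate_equilibration",
    "simulate_atpase",
    "simulate_fp_titration",
    "simulate_tq_buildup",
    "perturb_peaklist",
    "default_decay_time_grid",
    "DEFAULT_ATP_GRID_UM",
    "DEFAULT_PROTEIN_GRID_UM",
    "DEFAULT_TQ_DELAYS_MS",
]

#: Default donor (Tb3+) lifetime, microseconds. Within the 100-1500 us
#: window analysed for the sensitized-acceptor lifetimes.
DEFAULT_TAU_D_US = 1200.0

#: Default decay noise: 1% proportional Gaussian.
DEFAULT_DECAY_NOISE = NoiseSpec("gaussian_proportional", 0.01)

#: Nine-point ATP titration spanning 0-300 uM.
DEFAULT_ATP_GRID_UM = np.array([0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 150.0, 200.0, 300.0])

#: Ten-point protein titration spanning 0-25 uM.
DEFAULT_PROTEIN_GRID_UM = np.array([0.0, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 17.5, 25.0])

#: Triple-quantum relaxation delays, milliseconds.
DEFAULT_TQ_DELAYS_MS = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 25.0, 30.0])


def default_decay_time_grid(n_points: int = 1500, t_max_us: float = 6000.0) -> np.ndarray:
    """Uniform acquisition grid from 0 to ``t_max_us`` microseconds.

    The defaults emulate a lifetime photometer digitizing 4 us channels
    over a 6 ms window, i.e. about five donor lifetimes, so the slowest
    sensitized component is sampled to near-complete decay.
    """
    return np.linspace(0.0, t_max_us, n_points)


@dataclass(frozen=True)
class ConformerTruth:
    """Ground-truth conformer mixture for an LRET decay.

    ``states`` is a list of (distance in Angstrom, molecule fraction) pairs;
    fractions must sum to 1.
    """

    states: tuple
    donor_lifetime_us: float = DEFAULT_TAU_D_US
    forster_radius_A: float = 44.9

    def __post_init__(self) -> None:
        states = tuple((float(r), float(f)) for r, f in self.states)
        object.__setattr__(self, "states", states)
        if not states:
            raise ValueError("at least one conformer state is required")
        if any(r <= 0 for r, _ in states):
            raise ValueError("all distances must be positive")
        if any(not 0 < f <= 1 for _, f in states):
            raise ValueError("fractions must lie in (0, 1]")
        total = sum(f for _, f in states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total!r})")
        if self.donor_lifetime_us <= 0 or self.forster_radius_A <= 0:
            raise ValueError("donor lifetime and Forster radius must be positive")

    def efficiencies(self) -> np.ndarray:
        radii = np.array([r for r, _ in self.states])
        return distance_to_efficiency(radii, self.forster_radius_A)

    def lifetimes_us(self) -> np.ndarray:
        return self.donor_lifetime_us * (1.0 - self.efficiencies())

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "donor_lifetime_us": self.donor_lifetime_us,
            "forster_radius_A": self.forster_radius_A,
        }


def simulate_lret_decay(
    truth: ConformerTruth,
    time_grid_us: np.ndarray | None = None,
    noise: NoiseSpec = DEFAULT_DECAY_NOISE,
    seed: int = 0,
    scale: float = 1.0,
    instrument_amplitude: float = 0.0,
    instrument_tau_us: float = 30.0,
) -> DecayTrace:
    """Donor-sensitized acceptor decay for a known conformer mixture.

    Noiseless model: ``I(t) = sum_i A_i exp(-t / tau_i)`` with
    ``tau_i = tau_D (1 - E_i)`` and amplitudes proportional to
    ``fraction_i * |tau_i - tau_D|``, normalised so ``I(0) = scale``.

    ``instrument_amplitude`` > 0 adds a fast extra exponential (default
    lifetime 30 us) emulating the instrument-response component that real
    traces show below ~100 us; it takes that fraction of the t = 0
    intensity.
    """
    t = default_decay_time_grid() if time_grid_us is None else np.asarray(time_grid_us, dtype=float)
    if np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("time grid must be strictly increasing and nonnegative")
    eff = truth.efficiencies()
    if np.any(eff == 0):
        raise ValueError(
            "a state with zero transfer efficiency (tau = tau_D) is degenerate with "
            "the donor decay and cannot be simulated as an acceptor component"
        )
    if not 0 <= instrument_amplitude < 1:
        raise ValueError("instrument_amplitude must lie in [0, 1)")
    taus = truth.lifetimes_us()
    fractions = np.array([f for _, f in truth.states])
    amps = fractions * np.abs(taus - truth.donor_lifetime_us)
    amps = scale * (1.0 - instrument_amplitude) * amps / amps.sum()
    if instrument_amplitude > 0:
        taus = np.concatenate([[instrument_tau_us], taus])
        amps = np.concatenate([[scale * instrument_amplitude], amps])
    intensity = np.exp(-t[:, None] / taus[None, :]) @ amps
    rng = np.random.default_rng(seed)
    metadata = {
        "generator": "simulate_lret_decay",
        "seed": seed,
        "noise": noise.to_dict(),
        "truth": truth.to_dict(),
        "scale": scale,
        "instrument_amplitude": instrument_amplitude,
    }
    return DecayTrace(time_us=t, intensity=noise.apply(intensity, rng), channel="acceptor", metadata=metadata)


def simulate_equilibration(
    kex: float,
    f0: float,
    fmax: float,
    time_grid_s: np.ndarray,
    noise: NoiseSpec = NoiseSpec("gaussian_proportional", 0.01),
    seed: int = 0,
) -> EquilibrationTrace:
    """Saturating-exponential LRET time course after ATP addition."""
    if kex <= 0:
        raise ValueError("kex must be positive")
    if fmax < f0:
        raise ValueError("Fmax must be >= F0")
    t = np.asarray(time_grid_s, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t < 0):
        raise ValueError("negative times are not allowed")
    signal = (fmax - f0) * (1.0 - np.exp(-kex * t)) + f0
    rng = np.random.default_rng(seed)
    metadata = {
        "generator": "simulate_equilibration", "seed": seed, "noise": noise.to_dict(),
        "kex": kex, "f0": f0, "fmax": fmax,
    }
    return EquilibrationTrace(time_s=t, intensity=noise.apply(signal, rng), metadata=metadata)


def simulate_atpase(
    vmax: float,
    km_uM: float,
    n: float,
    atp_grid_uM: np.ndarray | None = None,
    replicates: int = 3,
    noise: NoiseSpec = NoiseSpec("gaussian_proportional", 0.05),
    seed: int = 0,
) -> RateDataset:
    """Hill-shaped initial-velocity dataset with replicate noise."""
    if vmax <= 0 or km_uM <= 0 or n <= 0:
        raise ValueError("Vmax, KM and n must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    atp = DEFAULT_ATP_GRID_UM if atp_grid_uM is None else np.asarray(atp_grid_uM, dtype=float)
    if np.any(atp < 0):
        raise ValueError("ATP concentrations must be nonnegative")
    v_true = hill_velocity(atp, vmax, km_uM, n)
    rng = np.random.default_rng(seed)
    atp_all, v_all, rep_all = [], [], []
    for rep in range(replicates):
        atp_all.append(atp)
        v_all.append(noise.apply(v_true, rng))
        rep_all.append(np.full(atp.size, rep))
    return RateDataset(
        atp_uM=np.concatenate(atp_all),
        velocity=np.concatenate(v_all),
        replicate=np.concatenate(rep_all),
        condition={
            "generator": "simulate_atpase", "seed": seed, "noise": noise.to_dict(),
            "vmax": vmax, "km_uM": km_uM, "n": n, "replicates": replicates,
        },
    )


def simulate_fp_titration(
    kd_uM: float,
    probe_uM: float,
    f0: float,
    fmax: float,
    protein_grid_uM: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec("gaussian_constant", 0.0),
    seed: int = 0,
) -> BindingTitration:
    """Fluorescence-polarization titration from the quadratic binding model."""
    if probe_uM <= 0:
        raise ValueError("probe concentration must be positive")
    if kd_uM < 0:
        raise ValueError("KD must be nonnegative")
    grid = DEFAULT_PROTEIN_GRID_UM if protein_grid_uM is None else np.asarray(protein_grid_uM, dtype=float)
    signal = quadratic_binding_polarization(grid, kd_uM, probe_uM, f0, fmax)
    rng = np.random.default_rng(seed)
    return BindingTitration(
        protein_uM=grid, polarization=noise.apply(signal, rng), probe_uM=probe_uM
    )


def simulate_tq_buildup(
    eta: float,
    delta: float,
    T_grid_ms: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec("gaussian_constant", 0.0),
    seed: int = 0,
    noise_on: str = "ratio",
    methyl_id: str | None = None,
) -> TQBuildupCurve:
    """Triple-quantum build-up curve from the tanh ratio model.

    ``noise_on="ratio"`` (default) perturbs the forbidden/allowed ratio with
    unit allowed intensities; ``noise_on="intensities"`` perturbs the two
    intensities separately, with the allowed channel decaying as a single
    exponential (rate 25 s^-1) so the ratio noise grows with T as in real
    spectra.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if noise_on not in ("ratio", "intensities"):
        raise ValueError("noise_on must be 'ratio' or 'intensities'")
    T_ms = DEFAULT_TQ_DELAYS_MS if T_grid_ms is None else np.asarray(T_grid_ms, dtype=float)
    if np.any(T_ms <= 0):
        raise ValueError("relaxation delays must be positive")
    ratio = tq_ratio_model(T_ms / 1000.0, eta, delta)
    rng = np.random.default_rng(seed)
    if noise_on == "ratio":
        i_allow = np.ones_like(T_ms)
        i_forbid = noise.apply(ratio, rng)
    else:
        i_allow_clean = np.exp(-25.0 * T_ms / 1000.0)
        i_forbid = noise.apply(ratio * i_allow_clean, rng)
        i_allow = noise.apply(i_allow_clean, rng)
    sigma = noise.sigma if noise.kind == "gaussian_constant" and noise.sigma > 0 else None
    return TQBuildupCurve(T_ms=T_ms, I_forbid=i_forbid, I_allow=i_allow, sigma=sigma, methyl_id=methyl_id)


def perturb_peaklist(
    base: list[MethylPeak],
    perturbations: dict[str, tuple[float, float]],
    jitter: NoiseSpec = NoiseSpec("none"),
    seed: int = 0,
) -> list[MethylPeak]:
    """Apply (delta-13C, delta-1H) shifts to named peaks, plus optional jitter.

    ``perturbations`` maps assignment ids (e.g. ``"L828d1"``) to ppm shifts;
    unknown ids raise. Jitter (per the NoiseSpec) is added independently to
    both shift axes of every peak. Assignments are preserved.
    """
    by_assignment = {p.assignment: p for p in base}
    unknown = set(perturbations) - set(by_assignment)
    if unknown:
        raise KeyError(f"unknown methyl ids in perturbation map: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = []
    for peak in base:
        d_c, d_h = perturbations.get(peak.assignment, (0.0, 0.0))
        new_c, new_h = peak.delta_C + d_c, peak.delta_H + d_h
        if jitter.kind != "none":
            new_c = float(jitter.apply(np.array([new_c]), rng)[0])
            new_h = float(jitter.apply(np.array([new_h]), rng)[0])
        out.append(replace(peak, delta_C=new_c, delta_H=new_h))
    return out
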