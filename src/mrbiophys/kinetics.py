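"""Steady-state ATPase kinetics, fluorescence-polarization ATP binding, and
size-exclusion dimer quantification.

ATP hydrolysis rates come from a colorimetric phosphate assay: absorbances
are converted to velocities (uM PO4 per uM MR complex per hour) through a
per-condition phosphate standard curve, then fitted to the Hill equation

    v = Vmax * [ATP]**n / (KM**n + [ATP]**n)

whose cooperativity exponent ``n`` reports on coupling between the two ATP
sites of the Rad50 dimer. Equilibrium ATP binding is measured by
fluorescence polarization of a Bodipy FL ATP probe and fitted with the
two-state quadratic (ligand-depletion) binding function, which remains
valid when the probe concentration is comparable to KD. Dimerisation is
quantified from size-exclusion chromatograms as the dimer peak area over
the summed dimer + monomer areas (box summation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from ._fitting import format_summary

__all__ = [
    "StandardCurve",
    "RateDataset",
    "BindingTitration",
    "SECChromatogram",
    "HillModel",
    "HillFitResults",
    "QuadraticBindingModel",
    "QuadraticFitResults",
    "KineticComparison",
    "fit_standard_curve",
    "absorbance_to_rate",
    "fit_hill",
    "fit_quadratic_binding",
    "derived_constants",
    "sec_dimer_fraction",
    "hill_velocity",
    "quadratic_binding_polarization",
]

HILL_N_BOUNDS = (0.3, 4.0)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def hill_velocity(atp_uM, vmax: float, km_uM: float, n: float):
    """Hill equation ``v = Vmax [ATP]^n / (KM^n + [ATP]^n)``."""
    atp = np.asarray(atp_uM, dtype=float)
    with np.errstate(invalid="ignore"):
        v = vmax * atp ** n / (km_uM ** n + atp ** n)
    return np.where(atp == 0, 0.0, v)


def quadratic_binding_polarization(protein_uM, kd_uM: float, probe_uM: float, f0: float, fmax: float):
    """Two-state quadratic (ligand-depletion) binding function.

    ``F = F0 + (Fmax - F0) * ((KD + L + P) - sqrt((KD + L + P)^2 - 4 L P)) / (2 L)``
    with ``L`` the fluorescent-probe (ATP) concentration and ``P`` the
    titrated protein concentration; exact for a 1:1 complex without the
    free-ligand approximation.
    """
    p = np.asarray(protein_uM, dtype=float)
    s = kd_uM + probe_uM + p
    disc = np.clip(s * s - 4.0 * probe_uM * p, 0.0, None)
    bound = (s - np.sqrt(disc)) / (2.0 * probe_uM)
    return f0 + (fmax - f0) * bound


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """Linear phosphate standard: absorbance = slope * [PO4] + intercept."""

    slope: float
    intercept: float
    r_squared: float
    slope_err: float
    intercept_err: float
    n_obs: int

    def absorbance_to_phosphate(self, absorbance) -> np.ndarray | float:
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope

    def summary(self) -> str:
        rows = [
            ("slope", self.slope, self.slope_err, "abs / uM PO4"),
            ("intercept", self.intercept, self.intercept_err, "abs"),
        ]
        return format_summary("Phosphate standard curve", rows,
                              [f"R^2 = {self.r_squared:.6f}, n_obs = {self.n_obs}"])


@dataclass
class RateDataset:
    """Initial velocities versus [ATP], possibly replicated.

    ``velocity`` is in uM PO4 per uM MR complex per hour. ``condition``
    carries flags such as construct and +/-DNA.
    """

    atp_uM: np.ndarray
    velocity: np.ndarray
    replicate: np.ndarray | None = None
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atp_uM = np.asarray(self.atp_uM, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.atp_uM.shape != self.velocity.shape:
            raise ValueError("atp and velocity must have equal lengths")
        if np.any(self.atp_uM < 0):
            raise ValueError("ATP concentrations must be nonnegative")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.atp_uM.shape:
                raise ValueError("replicate ids must align with the data")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **condition) -> "RateDataset":
        rep = frame["replicate"].to_numpy() if "replicate" in frame else None
        return cls(frame["atp_uM"].to_numpy(), frame["velocity"].to_numpy(), rep, condition)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"atp_uM": self.atp_uM, "velocity": self.velocity}
        if self.replicate is not None:
            data["replicate"] = self.replicate
        return pd.DataFrame(data)


@dataclass
class BindingTitration:
    """Fluorescence polarization of a fixed probe titrated with protein."""

    protein_uM: np.ndarray
    polarization: np.ndarray
    probe_uM: float = 0.005

    def __post_init__(self) -> None:
        self.protein_uM = np.asarray(self.protein_uM, dtype=float)
        self.polarization = np.asarray(self.polarization, dtype=float)
        if self.protein_uM.shape != self.polarization.shape:
            raise ValueError("protein grid and polarization must align")
        if np.any(self.protein_uM < 0):
            raise ValueError("protein concentrations must be nonnegative")
        if self.probe_uM <= 0:
            raise ValueError("probe concentration must be positive")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, probe_uM: float = 0.005) -> "BindingTitration":
        return cls(frame["protein_uM"].to_numpy(), frame["polarization"].to_numpy(), probe_uM)


@dataclass
class SECChromatogram:
    """Size-exclusion trace with dimer and monomer elution windows (mL)."""

    volume_mL: np.ndarray
    signal: np.ndarray
    dimer_window: tuple[float, float]
    monomer_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.volume_mL = np.asarray(self.volume_mL, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.volume_mL.shape != self.signal.shape:
            raise ValueError("volume and signal must align")
        for name, (lo, hi) in (("dimer", self.dimer_window), ("monomer", self.monomer_window)):
            if not lo < hi:
                raise ValueError(f"{name} window must satisfy lo < hi")
            if lo < self.volume_mL.min() or hi > self.volume_mL.max():
                raise ValueError(f"{name} window lies outside the recorded volume range")
        d, m = sorted([self.dimer_window, self.monomer_window])
        if d[1] > m[0]:
            raise ValueError("dimer and monomer windows must be disjoint")


# ---------------------------------------------------------------------------
# standard-curve conversion
# ---------------------------------------------------------------------------

def fit_standard_curve(standards: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares line through (phosphate uM, absorbance) pairs."""
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    phosphate = np.asarray([s[0] for s in standards], dtype=float)
    absorbance = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(phosphate) == 0:
        raise ValueError("standards must span a range of phosphate concentrations")
    res = stats.linregress(phosphate, absorbance)
    if res.slope <= 0:
        raise ValueError("standard curve slope is non-positive: assay failure")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_err=float(res.stderr),
        intercept_err=float(res.intercept_stderr),
        n_obs=phosphate.size,
    )


def absorbance_to_rate(
    absorbance: float,
    curve: StandardCurve,
    mr_conc_uM: float,
    time_h: float,
    blank: float = 0.0,
) -> float:
    """Convert a raw assay absorbance to uM PO4 per uM MR per hour.

    ``v = ((abs - blank - intercept) / slope) / (mr_conc * time)``; small
    negative values (blank noise) are floored at zero with a warning.
    """
    if mr_conc_uM <= 0 or time_h <= 0:
        raise ValueError("enzyme concentration and time must be positive")
    phosphate = (absorbance - blank - curve.intercept) / curve.slope
    v = phosphate / (mr_conc_uM * time_h)
    if v < 0:
        warnings.warn("absorbance below blank: velocity floored at 0", stacklevel=2)
        return 0.0
    return float(v)


# ---------------------------------------------------------------------------
# Hill kinetics
# ---------------------------------------------------------------------------

class HillModel:
    """Hill-equation fit of initial velocities versus [ATP].

    Replicated points are fitted pooled (every individual observation enters
    the least squares) rather than as per-level means; ``n`` is bounded in
    [0.3, 4] to exclude degenerate fits. Multi-start over cooperativity and
    KM guesses guards against local minima.
    """

    def __init__(self, data: RateDataset) -> None:
        if np.unique(data.atp_uM).size < 5:
            raise ValueError("need at least 5 distinct ATP concentrations")
        self.data = data

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **condition) -> "HillModel":
        return cls(RateDataset.from_dataframe(frame, **condition))

    def fit(self) -> "HillFitResults":
        atp, v = self.data.atp_uM, self.data.velocity
        vmax0 = max(float(v.max()), 1e-12)
        positive = atp[atp > 0]
        km_guesses = np.geomspace(positive.min(), positive.max(), 4)
        best = None
        for n0 in (0.8, 1.0, 1.5, 2.0, 3.0):
            for km0 in km_guesses:
                try:
                    popt, pcov = curve_fit(
                        hill_velocity, atp, v,
                        p0=[vmax0, km0, n0],
                        bounds=([1e-12, 1e-9, HILL_N_BOUNDS[0]], [np.inf, np.inf, HILL_N_BOUNDS[1]]),
                        maxfev=20000,
                    )
                except RuntimeError:
                    continue
                sse = float(np.sum((hill_velocity(atp, *popt) - v) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, popt, pcov)
        if best is None:
            raise RuntimeError("Hill fit failed to converge from any start")
        sse, popt, pcov = best
        if not (positive.min() <= popt[1] <= positive.max()):
            warnings.warn("fitted KM lies outside the measured ATP range (extrapolation)", stacklevel=2)
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        return HillFitResults(
            vmax=float(popt[0]), km_uM=float(popt[1]), n=float(popt[2]),
            vmax_err=float(perr[0]), km_err=float(perr[1]), n_err=float(perr[2]),
            residual_norm=float(np.sqrt(sse)), n_obs=atp.size,
            condition=dict(self.data.condition),
        )


@dataclass
class HillFitResults:
    """Hill-equation parameters with derived catalytic constants.

    ``kcat`` converts Vmax (uM PO4 uM MR^-1 h^-1) to min^-1 per MR complex;
    pass ``per_site=True`` to normalise per Rad50 ATP site (two per complex).
    """

    vmax: float
    km_uM: float
    n: float
    vmax_err: float
    km_err: float
    n_err: float
    residual_norm: float
    n_obs: int
    condition: dict = field(default_factory=dict)

    def kcat_per_min(self, per_site: bool = False) -> float:
        kcat = self.vmax / 60.0
        return kcat / 2.0 if per_site else kcat

    @property
    def catalytic_efficiency(self) -> float:
        """kcat / KM in min^-1 uM^-1 (per complex)."""
        return self.kcat_per_min() / self.km_uM

    def predict(self, atp_uM) -> np.ndarray:
        return hill_velocity(atp_uM, self.vmax, self.km_uM, self.n)

    def summary(self) -> str:
        rows = [
            ("Vmax", self.vmax, self.vmax_err, "uM PO4 / uM MR / h"),
            ("KM", self.km_uM, self.km_err, "uM"),
            ("n (Hill)", self.n, self.n_err, ""),
            ("kcat", self.kcat_per_min(), None, "1/min"),
            ("kcat/KM", self.catalytic_efficiency, None, "1/(min uM)"),
        ]
        return format_summary("Hill kinetics fit", rows,
                              [f"n_obs = {self.n_obs}, residual norm = {self.residual_norm:.4g}"])

    def to_dict(self) -> dict:
        return {
            "vmax": self.vmax, "vmax_err": self.vmax_err,
            "km_uM": self.km_uM, "km_err": self.km_err,
            "n": self.n, "n_err": self.n_err,
            "kcat_per_min": self.kcat_per_min(),
            "catalytic_efficiency": self.catalytic_efficiency,
            "residual_norm": self.residual_norm, "n_obs": self.n_obs,
            "condition": self.condition,
        }


def fit_hill(data: RateDataset) -> HillFitResults:
    """Fit the Hill equation to an initial-velocity dataset."""
    return HillModel(data).fit()


@dataclass
class KineticComparison:
    """Fold changes between two Hill fits (e.g. +DNA vs -DNA, mutant vs wt)."""

    vmax_ratio: float
    vmax_ratio_err: float
    efficiency_a: float
    efficiency_b: float
    efficiency_ratio: float
    efficiency_ratio_err: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def derived_constants(fit_a: HillFitResults, fit_b: HillFitResults) -> KineticComparison:
    """Catalytic efficiencies and a/b fold changes with propagated errors.

    Relative uncertainties combine in quadrature (first-order propagation,
    parameters treated as independent).
    """
    vr = fit_a.vmax / fit_b.vmax
    vr_rel = np.hypot(fit_a.vmax_err / fit_a.vmax, fit_b.vmax_err / fit_b.vmax)
    ea, eb = fit_a.catalytic_efficiency, fit_b.catalytic_efficiency
    er = ea / eb
    er_rel = np.sqrt(
        (fit_a.vmax_err / fit_a.vmax) ** 2 + (fit_a.km_err / fit_a.km_uM) ** 2
        + (fit_b.vmax_err / fit_b.vmax) ** 2 + (fit_b.km_err / fit_b.km_uM) ** 2
    )
    return KineticComparison(
        vmax_ratio=float(vr), vmax_ratio_err=float(vr * vr_rel),
        efficiency_a=float(ea), efficiency_b=float(eb),
        efficiency_ratio=float(er), efficiency_ratio_err=float(er * er_rel),
    )


# ---------------------------------------------------------------------------
# quadratic (ligand-depletion) binding
# ---------------------------------------------------------------------------

class QuadraticBindingModel:
    """Fluorescence-polarization binding fit with explicit ligand depletion."""

    def __init__(self, data: BindingTitration) -> None:
        if np.unique(data.protein_uM).size < 6:
            raise ValueError("need at least 6 distinct protein concentrations")
        self.data = data

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, probe_uM: float = 0.005) -> "QuadraticBindingModel":
        return cls(BindingTitration.from_dataframe(frame, probe_uM))

    def fit(self) -> "QuadraticFitResults":
        p, y = self.data.protein_uM, self.data.polarization
        probe = self.data.probe_uM
        f0_0 = float(y[np.argmin(p)])
        fmax_0 = float(y[np.argmax(p)])
        half = f0_0 + 0.5 * (fmax_0 - f0_0)
        above = p[y >= half] if fmax_0 >= f0_0 else p[y <= half]
        kd0 = float(above.min()) if above.size and above.min() > 0 else float(max(p.max() / 10, probe))

        def model(pp, kd, f0, fmax):
            return quadratic_binding_polarization(pp, kd, probe, f0, fmax)

        popt, pcov = curve_fit(
            model, p, y, p0=[kd0, f0_0, fmax_0],
            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        kd = float(popt[0])
        if kd > 2 * p.max():
            warnings.warn("fitted KD far exceeds the titration range: lower bound only", stacklevel=2)
        resid = model(p, *popt) - y
        return QuadraticFitResults(
            kd_uM=kd, f0=float(popt[1]), fmax=float(popt[2]),
            kd_err=float(perr[0]), f0_err=float(perr[1]), fmax_err=float(perr[2]),
            probe_uM=probe, residual_norm=float(np.linalg.norm(resid)), n_obs=p.size,
        )


@dataclass
class QuadraticFitResults:
    kd_uM: float
    f0: float
    fmax: float
    kd_err: float
    f0_err: float
    fmax_err: float
    probe_uM: float
    residual_norm: float
    n_obs: int

    def predict(self, protein_uM) -> np.ndarray:
        return quadratic_binding_polarization(protein_uM, self.kd_uM, self.probe_uM, self.f0, self.fmax)

    def summary(self) -> str:
        rows = [
            ("KD", self.kd_uM, self.kd_err, "uM"),
            ("F0", self.f0, self.f0_err, "a.u."),
            ("Fmax", self.fmax, self.fmax_err, "a.u."),
        ]
        return format_summary("Quadratic binding fit", rows,
                              [f"probe = {self.probe_uM} uM, n_obs = {self.n_obs}"])

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd_uM, "kd_err": self.kd_err,
            "f0": self.f0, "f0_err": self.f0_err,
            "fmax": self.fmax, "fmax_err": self.fmax_err,
            "probe_uM": self.probe_uM,
            "residual_norm": self.residual_norm, "n_obs": self.n_obs,
        }


def fit_quadratic_binding(data: BindingTitration) -> QuadraticFitResults:
    """Fit the two-state quadratic binding function to an FP titration."""
    return QuadraticBindingModel(data).fit()


# ---------------------------------------------------------------------------
# SEC dimer fraction
# ---------------------------------------------------------------------------

def _window_area(chrom: SECChromatogram, window: tuple[float, float], baseline: str | None) -> float:
    v, s = chrom.volume_mL, chrom.signal
    mask = (v >= window[0]) & (v <= window[1])
    if not np.any(mask):
        return 0.0
    seg = s[mask].astype(float)
    if baseline == "linear":
        x = v[mask]
        base = seg[0] + (seg[-1] - seg[0]) * (x - x[0]) / max(x[-1] - x[0], 1e-300)
        seg = seg - base
    area = float(np.sum(np.clip(seg, 0.0, None)))
    return area


def sec_dimer_fraction(chrom: SECChromatogram, baseline: str | None = "linear") -> float:
    """Dimer fraction = dimer peak area / (dimer + monomer peak areas).

    Areas are box sums of the signal inside each elution window, after an
    optional straight-line baseline drawn between the window edges
    (``baseline="linear"``, the default; pass ``None`` for raw sums).
    """
    if baseline not in (None, "linear"):
        raise ValueError("baseline must be None or 'linear'")
    dimer = _window_area(chrom, chrom.dimer_window, baseline)
    monomer = _window_area(chrom, chrom.monomer_window, baseline)
    total = dimer + monomer
    if total == 0:
        raise ValueError("zero total peak area: cannot form a dimer fraction")
    return dimer / total
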