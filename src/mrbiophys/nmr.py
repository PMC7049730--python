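"""Comparative methyl-NMR analysis: chemical-shift perturbations and
triple-quantum side-chain dynamics.

Chemical-shift perturbations (CSPs) between wild-type and mutant ILVM
methyl peak lists are weighted Euclidean distances in the (13C, 1H) shift
plane, each axis scaled by the BMRB standard deviation of that methyl
class, so perturbations of different methyl types are comparable.

Side-chain ps--ns dynamics are read out from 1H triple-quantum "forbidden"
build-up experiments: the ratio of forbidden to allowed intensities grows
with the relaxation delay T as

    |I_forbid / I_allow| = C * eta * tanh(sqrt(eta^2 + delta^2) * T)
                           / (sqrt(eta^2 + delta^2) - delta * tanh(sqrt(eta^2 + delta^2) * T))

with C = 0.75, eta the intra-methyl 1H-1H dipolar cross-correlated
relaxation rate and delta the relaxation contribution of external protons.
Differences Delta-eta = eta_mut - eta_wt map changes in motional amplitude
onto the structure (assuming unchanged global tumbling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._fitting import format_summary

__all__ = [
    "MethylPeak",
    "CSPWeights",
    "DEFAULT_CSP_WEIGHTS",
    "CSPRecord",
    "TQBuildupCurve",
    "TQBuildupModel",
    "EtaFitResults",
    "DeltaEtaRecord",
    "tq_ratio_model",
    "pair_peaklists",
    "compute_csp",
    "select_csp_outliers",
    "fit_eta",
    "compute_delta_eta",
    "peaklist_to_dataframe",
    "peaklist_from_dataframe",
]

TQ_RATIO_C = 0.75
CSP_OUTLIER_THRESHOLD_PPB = 20.0
DELTA_ETA_THRESHOLD = 16.0  # s^-1

METHYL_CLASSES = ("Ile_d1", "Leu_d", "Val_g", "Met_e")
_CLASS_FOR_RESIDUE = {"Ile": "Ile_d1", "Leu": "Leu_d", "Val": "Val_g", "Met": "Met_e"}
_ONE_LETTER = {"Ile": "I", "Leu": "L", "Val": "V", "Met": "M"}
_CLASS_SUFFIX = {"Ile_d1": "d1", "Leu_d": "d", "Val_g": "g", "Met_e": "e"}


# ---------------------------------------------------------------------------
# peaks and peak lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylPeak:
    """One assigned methyl cross-peak in a 13C,1H correlation spectrum."""

    residue_number: int
    residue_type: str  # Ile | Leu | Val | Met
    methyl_class: str  # Ile_d1 | Leu_d | Val_g | Met_e
    delta_C: float  # ppm
    delta_H: float  # ppm
    stereo_tag: int | None = None  # 1 | 2 for prochiral Leu/Val methyls

    def __post_init__(self) -> None:
        if self.residue_type not in _CLASS_FOR_RESIDUE:
            raise ValueError(f"unknown residue type {self.residue_type!r}")
        if _CLASS_FOR_RESIDUE[self.residue_type] != self.methyl_class:
            raise ValueError(
                f"methyl class {self.methyl_class!r} inconsistent with residue {self.residue_type!r}"
            )
        if not (np.isfinite(self.delta_C) and np.isfinite(self.delta_H)):
            raise ValueError("chemical shifts must be finite")
        if self.stereo_tag not in (None, 1, 2):
            raise ValueError("stereo tag must be None, 1 or 2")

    @property
    def key(self) -> tuple:
        return (self.residue_number, self.methyl_class, self.stereo_tag)

    @property
    def assignment(self) -> str:
        """Compact id, e.g. ``I839d1``, ``L828d1`` (stereo 1), ``M808e``."""
        suffix = _CLASS_SUFFIX[self.methyl_class]
        tag = str(self.stereo_tag) if self.stereo_tag is not None and self.methyl_class != "Ile_d1" else ""
        return f"{_ONE_LETTER[self.residue_type]}{self.residue_number}{suffix}{tag}"


PeakList = list  # list[MethylPeak]


def peaklist_to_dataframe(peaks: list[MethylPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "assignment": [p.assignment for p in peaks],
            "residue_number": [p.residue_number for p in peaks],
            "residue_type": [p.residue_type for p in peaks],
            "methyl_class": [p.methyl_class for p in peaks],
            "stereo": [p.stereo_tag if p.stereo_tag is not None else "" for p in peaks],
            "delta_C_ppm": [p.delta_C for p in peaks],
            "delta_H_ppm": [p.delta_H for p in peaks],
        }
    )


def peaklist_from_dataframe(frame: pd.DataFrame) -> list[MethylPeak]:
    peaks = []
    for _, row in frame.iterrows():
        stereo = row.get("stereo", "")
        stereo_tag = None if stereo in ("", None) or pd.isna(stereo) else int(stereo)
        peaks.append(
            MethylPeak(
                residue_number=int(row["residue_number"]),
                residue_type=str(row["residue_type"]),
                methyl_class=str(row["methyl_class"]),
                delta_C=float(row["delta_C_ppm"]),
                delta_H=float(row["delta_H_ppm"]),
                stereo_tag=stereo_tag,
            )
        )
    return peaks


def pair_peaklists(
    wt: list[MethylPeak], mut: list[MethylPeak]
) -> tuple[list[tuple[MethylPeak, MethylPeak]], list[MethylPeak], list[MethylPeak]]:
    """Pair peaks by (residue number, methyl class, stereo tag).

    Returns (pairs, unpaired wild-type peaks, unpaired mutant peaks);
    unpaired peaks are reported, never silently dropped. Duplicate keys
    within one list are an error.
    """
    def index(peaks: list[MethylPeak], name: str) -> dict:
        table: dict = {}
        for p in peaks:
            if p.key in table:
                raise ValueError(f"duplicate assignment {p.assignment} in {name} peak list")
            table[p.key] = p
        return table

    wt_idx, mut_idx = index(wt, "wild-type"), index(mut, "mutant")
    pairs = [(wt_idx[k], mut_idx[k]) for k in wt_idx if k in mut_idx]
    unpaired_wt = [p for p in wt if p.key not in mut_idx]
    unpaired_mut = [p for p in mut if p.key not in wt_idx]
    return pairs, unpaired_wt, unpaired_mut


# ---------------------------------------------------------------------------
# chemical shift perturbations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSPWeights:
    """Per-class shift normalisation (BMRB standard deviations, ppm)."""

    w_C: dict = field(default_factory=lambda: {"Ile_d1": 1.65, "Leu_d": 1.6, "Val_g": 1.4, "Met_e": 1.54})
    w_H: dict = field(default_factory=lambda: {"Ile_d1": 0.29, "Leu_d": 0.28, "Val_g": 0.27, "Met_e": 0.41})

    def __post_init__(self) -> None:
        for table in (self.w_C, self.w_H):
            if any(v <= 0 for v in table.values()):
                raise ValueError("CSP weights must be positive")


DEFAULT_CSP_WEIGHTS = CSPWeights()


@dataclass
class CSPRecord:
    """Weighted chemical-shift perturbation of one methyl group."""

    methyl_id: str
    residue_number: int
    csp_ppm: float  # weighted ppm
    is_outlier: bool | None = None
    rule: str | None = None

    @property
    def csp_ppb(self) -> float:
        return 1000.0 * self.csp_ppm


def compute_csp(
    pair: tuple[MethylPeak, MethylPeak], weights: CSPWeights = DEFAULT_CSP_WEIGHTS
) -> CSPRecord:
    """Weighted Euclidean shift distance between a wild-type/mutant pair.

    ``CSP = sqrt(((dC_wt - dC_mut)/w_C)^2 + ((dH_wt - dH_mut)/w_H)^2)`` in
    weighted ppm (multiply by 1000 for ppb).
    """
    wt, mut = pair
    if wt.key != mut.key:
        raise ValueError("peaks are not a matched pair")
    cls = wt.methyl_class
    if cls not in weights.w_C or cls not in weights.w_H:
        raise KeyError(f"no CSP weights for methyl class {cls!r}")
    csp = float(
        np.hypot(
            (wt.delta_C - mut.delta_C) / weights.w_C[cls],
            (wt.delta_H - mut.delta_H) / weights.w_H[cls],
        )
    )
    return CSPRecord(methyl_id=wt.assignment, residue_number=wt.residue_number, csp_ppm=csp)


def select_csp_outliers(
    records: list[CSPRecord],
    rule: str = "fixed_threshold",
    threshold_ppb: float = CSP_OUTLIER_THRESHOLD_PPB,
) -> list[CSPRecord]:
    """Flag structurally perturbed methyls.

    ``fixed_threshold`` (default) flags CSP >= 20 ppb (inclusive);
    ``above_mean`` flags CSP strictly greater than the mean CSP of the set.
    Returns new records with ``is_outlier`` and the rule recorded.
    """
    if not records:
        raise ValueError("no CSP records to classify")
    if rule == "fixed_threshold":
        cut = threshold_ppb / 1000.0
        return [replace(r, is_outlier=r.csp_ppm >= cut, rule=rule) for r in records]
    if rule == "above_mean":
        mean = float(np.mean([r.csp_ppm for r in records]))
        return [replace(r, is_outlier=r.csp_ppm > mean, rule=rule) for r in records]
    raise ValueError("rule must be 'fixed_threshold' or 'above_mean'")


# ---------------------------------------------------------------------------
# triple-quantum build-up
# ---------------------------------------------------------------------------

def tq_ratio_model(T_s, eta: float, delta: float, C: float = TQ_RATIO_C):
    """Forbidden/allowed intensity ratio versus relaxation delay (seconds)."""
    t = np.asarray(T_s, dtype=float)
    root = np.sqrt(eta * eta + delta * delta)
    th = np.tanh(root * t)
    denom = root - delta * th
    if np.any(denom <= 0):
        raise ValueError("non-physical parameter set: model denominator is non-positive")
    return C * eta * th / denom


@dataclass
class TQBuildupCurve:
    """Forbidden and allowed intensities versus relaxation delay."""

    T_ms: np.ndarray
    I_forbid: np.ndarray
    I_allow: np.ndarray
    sigma: float | np.ndarray | None = None  # per-point spectral noise (a.u.)
    methyl_id: str | None = None

    def __post_init__(self) -> None:
        self.T_ms = np.asarray(self.T_ms, dtype=float)
        self.I_forbid = np.asarray(self.I_forbid, dtype=float)
        self.I_allow = np.asarray(self.I_allow, dtype=float)
        if not (self.T_ms.shape == self.I_forbid.shape == self.I_allow.shape):
            raise ValueError("delays and intensities must have equal lengths")
        if np.any(self.T_ms <= 0):
            raise ValueError("relaxation delays must be positive")
        if np.any(self.I_allow == 0):
            raise ValueError("allowed intensities must be nonzero")

    @property
    def T_s(self) -> np.ndarray:
        return self.T_ms / 1000.0

    @property
    def ratios(self) -> np.ndarray:
        return np.abs(self.I_forbid / self.I_allow)

    @property
    def ratio_sigma(self) -> np.ndarray | None:
        """Ratio noise propagated from the spectral noise floor.

        ``sigma_ratio = |ratio| * sqrt((sigma/I_forbid)^2 + (sigma/I_allow)^2)``.
        """
        if self.sigma is None:
            return None
        sigma = np.broadcast_to(np.asarray(self.sigma, dtype=float), self.T_ms.shape)
        return self.ratios * np.sqrt(
            (sigma / self.I_forbid) ** 2 + (sigma / self.I_allow) ** 2
        )


class TQBuildupModel:
    """Weighted fit of the tanh build-up model for (eta, delta).

    eta is constrained positive; delta is initialised nonnegative but its
    sign is not constrained (the model depends on delta both through
    sqrt(eta^2 + delta^2) and linearly in the denominator). Points are
    weighted by the propagated ratio noise when the curve carries a
    spectral noise floor.
    """

    def __init__(self, curve: TQBuildupCurve, C: float = TQ_RATIO_C) -> None:
        if curve.T_ms.size < 5:
            raise ValueError("need at least 5 relaxation delays")
        self.curve = curve
        self.C = C

    def fit(self) -> "EtaFitResults":
        t, y = self.curve.T_s, self.curve.ratios
        sigma = self.curve.ratio_sigma
        # initial eta from the small-T slope: ratio ~ C * eta * T
        eta0 = max(float(y[0] / (self.C * t[0])), 1.0)
        best = None
        for e0 in (eta0, eta0 / 3, eta0 * 3):
            for d0 in (0.0, e0, 3 * e0):
                try:
                    popt, pcov = curve_fit(
                        lambda tt, eta, delta: tq_ratio_model(tt, eta, delta, self.C),
                        t, y, p0=[e0, d0],
                        sigma=sigma, absolute_sigma=sigma is not None,
                        bounds=([1e-9, -np.inf], [np.inf, np.inf]),
                        maxfev=20000,
                    )
                except (RuntimeError, ValueError):
                    continue
                resid = tq_ratio_model(t, *popt, self.C) - y
                if sigma is not None:
                    resid = resid / sigma
                sse = float(np.sum(resid**2))
                if best is None or sse < best[0]:
                    best = (sse, popt, pcov)
        if best is None:
            raise RuntimeError("triple-quantum build-up fit failed to converge")
        sse, popt, pcov = best
        if popt[0] <= 0:
            raise RuntimeError("fitted eta is non-positive")
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        return EtaFitResults(
            eta=float(popt[0]), delta=float(popt[1]),
            eta_err=float(perr[0]), delta_err=float(perr[1]),
            residual_norm=float(np.sqrt(sse)), n_obs=t.size,
            methyl_id=self.curve.methyl_id,
        )


@dataclass
class EtaFitResults:
    """Intra-methyl 1H-1H dipolar cross-correlated relaxation rate fit."""

    eta: float  # s^-1
    delta: float  # s^-1
    eta_err: float
    delta_err: float
    residual_norm: float
    n_obs: int
    methyl_id: str | None = None

    def predict(self, T_s) -> np.ndarray:
        return tq_ratio_model(T_s, self.eta, self.delta)

    def summary(self) -> str:
        rows = [
            ("eta", self.eta, self.eta_err, "1/s"),
            ("delta", self.delta, self.delta_err, "1/s"),
        ]
        title = "TQ build-up fit" + (f" ({self.methyl_id})" if self.methyl_id else "")
        return format_summary(title, rows, [f"n_obs = {self.n_obs}"])

    def to_dict(self) -> dict:
        return {
            "methyl_id": self.methyl_id,
            "eta": self.eta, "eta_err": self.eta_err,
            "delta": self.delta, "delta_err": self.delta_err,
            "residual_norm": self.residual_norm, "n_obs": self.n_obs,
        }


def fit_eta(curve: TQBuildupCurve, C: float = TQ_RATIO_C) -> EtaFitResults:
    """Fit (eta, delta) to a forbidden/allowed build-up curve."""
    return TQBuildupModel(curve, C).fit()


@dataclass
class DeltaEtaRecord:
    """Change in side-chain dynamics for one methyl: eta_mut - eta_wt."""

    methyl_id: str
    delta_eta: float  # s^-1
    is_significant: bool
    rule: str


def compute_delta_eta(
    wt_fits: dict[str, EtaFitResults],
    mut_fits: dict[str, EtaFitResults],
    rule: str = "fixed_threshold",
    threshold: float = DELTA_ETA_THRESHOLD,
) -> tuple[list[DeltaEtaRecord], list[str]]:
    """Per-methyl Delta-eta = eta_mut - eta_wt with significance flags.

    ``fixed_threshold`` (default) flags |Delta-eta| > 16 s^-1;
    ``above_mean`` flags |Delta-eta| above the mean |Delta-eta| of the set.
    Returns (records, unpaired methyl ids); unpaired ids are reported, not
    dropped.
    """
    shared = [k for k in wt_fits if k in mut_fits]
    unpaired = sorted(set(wt_fits) ^ set(mut_fits))
    deltas = {k: mut_fits[k].eta - wt_fits[k].eta for k in shared}
    if rule == "fixed_threshold":
        cut = threshold
    elif rule == "above_mean":
        cut = float(np.mean([abs(d) for d in deltas.values()])) if deltas else 0.0
    else:
        raise ValueError("rule must be 'fixed_threshold' or 'above_mean'")
    records = [
        DeltaEtaRecord(methyl_id=k, delta_eta=float(d), is_significant=abs(d) > cut, rule=rule)
        for k, d in deltas.items()
    ]
    if unpaired:
        warnings.warn(f"{len(unpaired)} methyls present in only one condition", stacklevel=2)
    return records, unpaired
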