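"""CSV input/output with commented provenance headers.

All tabular files produced by this package start with ``# key = value``
provenance lines (seed, generating parameters, noise model) followed by an
ordinary CSV header and data rows, so every file documents how it was made.

Fixed column schemas per data type: decay ``time_us,intensity``;
equilibration ``time_s,intensity``; rates ``atp_uM,velocity,replicate``;
titration ``protein_uM,polarization``; TQ build-up ``T_ms,I_forbid,I_allow``;
chromatogram ``volume_mL,signal``; peak list
``assignment,residue_number,residue_type,methyl_class,stereo,delta_C_ppm,delta_H_ppm``.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "save_decay",
    "load_decay",
    "save_equilibration",
    "load_equilibration",
    "save_rates",
    "load_rates",
    "save_titration",
    "load_titration",
    "save_tq_buildup",
    "load_tq_buildup",
    "save_peaklist",
    "load_peaklist",
]


def _format_value(value: Any) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_table(path: str | Path, frame: pd.DataFrame, provenance: dict[str, Any] | None = None) -> Path:
    """Write *frame* as CSV preceded by ``# key = value`` provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        for key, value in (provenance or {}).items():
            handle.write(f"# {key} = {_format_value(value)}\n")
        # %.17g guarantees doubles survive the text round trip bit-exactly
        frame.to_csv(handle, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a CSV written by :func:`write_table`.

    Returns the data frame and the provenance mapping (values as strings;
    callers convert types as needed). Files without provenance lines are
    plain CSV and return an empty mapping.
    """
    provenance: dict[str, str] = {}
    lines = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    provenance[key.strip()] = value.strip()
                continue
            lines.append(line)
    frame = pd.read_csv(_io.StringIO("".join(lines)), float_precision="round_trip")
    return frame, provenance


# ---------------------------------------------------------------------------
# per-data-type schemas
# ---------------------------------------------------------------------------

def _flatten_metadata(metadata: dict) -> dict:
    flat = {}
    for key, value in metadata.items():
        flat[key] = json.dumps(value) if isinstance(value, (dict, list, tuple)) else value
    return flat


def save_decay(path: str | Path, trace) -> Path:
    frame = pd.DataFrame({"time_us": trace.time_us, "intensity": trace.intensity})
    meta = {"channel": trace.channel, **_flatten_metadata(trace.metadata)}
    return write_table(path, frame, meta)


def load_decay(path: str | Path):
    from .lret import DecayTrace

    frame, meta = read_table(path)
    channel = meta.pop("channel", "acceptor")
    return DecayTrace(frame["time_us"].to_numpy(), frame["intensity"].to_numpy(),
                      channel=channel, metadata=meta)


def save_equilibration(path: str | Path, trace) -> Path:
    frame = pd.DataFrame({"time_s": trace.time_s, "intensity": trace.intensity})
    return write_table(path, frame, _flatten_metadata(trace.metadata))


def load_equilibration(path: str | Path):
    from .lret import EquilibrationTrace

    frame, meta = read_table(path)
    return EquilibrationTrace(frame["time_s"].to_numpy(), frame["intensity"].to_numpy(), metadata=meta)


def save_rates(path: str | Path, data) -> Path:
    return write_table(path, data.to_dataframe(), _flatten_metadata(data.condition))


def load_rates(path: str | Path):
    from .kinetics import RateDataset

    frame, meta = read_table(path)
    return RateDataset.from_dataframe(frame, **meta)


def save_titration(path: str | Path, data) -> Path:
    frame = pd.DataFrame({"protein_uM": data.protein_uM, "polarization": data.polarization})
    return write_table(path, frame, {"probe_uM": data.probe_uM})


def load_titration(path: str | Path):
    from .kinetics import BindingTitration

    frame, meta = read_table(path)
    return BindingTitration(frame["protein_uM"].to_numpy(), frame["polarization"].to_numpy(),
                            probe_uM=float(meta.get("probe_uM", 0.005)))


def save_tq_buildup(path: str | Path, curve) -> Path:
    frame = pd.DataFrame({"T_ms": curve.T_ms, "I_forbid": curve.I_forbid, "I_allow": curve.I_allow})
    meta: dict[str, Any] = {}
    if curve.methyl_id:
        meta["methyl_id"] = curve.methyl_id
    if curve.sigma is not None:
        meta["sigma"] = float(np.mean(np.atleast_1d(curve.sigma)))
    return write_table(path, frame, meta)


def load_tq_buildup(path: str | Path):
    from .nmr import TQBuildupCurve

    frame, meta = read_table(path)
    sigma = float(meta["sigma"]) if "sigma" in meta else None
    return TQBuildupCurve(frame["T_ms"].to_numpy(), frame["I_forbid"].to_numpy(),
                          frame["I_allow"].to_numpy(), sigma=sigma,
                          methyl_id=meta.get("methyl_id"))


def save_peaklist(path: str | Path, peaks, provenance: dict | None = None) -> Path:
    from .nmr import peaklist_to_dataframe

    return write_table(path, peaklist_to_dataframe(peaks), provenance)


def load_peaklist(path: str | Path):
    from .nmr import peaklist_from_dataframe

    frame, _ = read_table(path)
    return peaklist_from_dataframe(frame)
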