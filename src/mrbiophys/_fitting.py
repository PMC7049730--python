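"""Shared nonlinear least-squares helpers (covariance, summaries)."""

from __future__ import annotations

import numpy as np

__all__ = ["covariance_from_jacobian", "format_summary"]


def covariance_from_jacobian(jac: np.ndarray, cost: float, n_obs: int, n_params: int) -> np.ndarray:
    """Parameter covariance from a least-squares Jacobian.

    Uses the standard linearisation ``cov = s^2 (J^T J)^-1`` with the
    residual variance ``s^2 = 2 * cost / (n_obs - n_params)`` (``cost`` is
    SciPy's ``0.5 * sum(r^2)``). Singular ``J^T J`` falls back to the
    pseudo-inverse; for a saturated fit (no residual degrees of freedom)
    the covariance is reported as zero.
    """
    jtj = jac.T @ jac
    dof = n_obs - n_params
    s2 = 2.0 * cost / dof if dof > 0 else 0.0
    try:
        inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(jtj)
    return s2 * inv


def format_summary(title: str, rows: list[tuple[str, float, float | None, str]], extra: list[str] | None = None) -> str:
    """Plain-text parameter table: name, estimate, std. error, units."""
    lines = [title, "=" * len(title)]
    width = max(len(name) for name, *_ in rows) if rows else 8
    lines.append(f"{'param':<{width}}  {'estimate':>12}  {'std err':>12}  units")
    for name, value, err, units in rows:
        err_s = f"{err:12.6g}" if err is not None and np.isfinite(err) else f"{'--':>12}"
        lines.append(f"{name:<{width}}  {value:12.6g}  {err_s}  {units}")
    if extra:
        lines.extend(extra)
    return "\n".join(lines)
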