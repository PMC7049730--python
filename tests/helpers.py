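"""Independent brute-force oracles used to cross-check the nonlinear fitters.

These deliberately share no code with the implementations they validate:
lifetimes are found by exhaustive search over a fixed grid with amplitudes
solved linearly, and (eta, delta) by exhaustive 2-D grid evaluation of the
tanh ratio model written out longhand.
"""

import numpy as np


def biexp_grid_oracle(time, intensity, tau_grid, fit_offset=False):
    """Exhaustive two-lifetime search; amplitudes by linear least squares.

    Returns the (tau_fast, tau_slow) pair from ``tau_grid`` minimising the
    sum of squared residuals.
    """
    best = None
    ones = np.ones_like(time)
    basis = {tau: np.exp(-time / tau) for tau in tau_grid}
    for i, tau_i in enumerate(tau_grid):
        for tau_j in tau_grid[i + 1:]:
            cols = [basis[tau_i], basis[tau_j]]
            if fit_offset:
                cols.append(ones)
            design = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(design, intensity, rcond=None)
            sse = float(np.sum((design @ coef - intensity) ** 2))
            if best is None or sse < best[0]:
                best = (sse, tau_i, tau_j)
    return best[1], best[2]


def eta_grid_oracle(T_s, ratios, eta_grid, delta_grid, C=0.75):
    """Exhaustive (eta, delta) search of the triple-quantum ratio model."""
    eta = np.asarray(eta_grid)[:, None, None]
    delta = np.asarray(delta_grid)[None, :, None]
    t = np.asarray(T_s)[None, None, :]
    root = np.sqrt(eta**2 + delta**2)
    th = np.tanh(root * t)
    pred = C * eta * th / (root - delta * th)
    sse = np.sum((pred - np.asarray(ratios)[None, None, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(np.asarray(eta_grid)[i]), float(np.asarray(delta_grid)[j])
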