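"""Power transformations shared by the linear-modelling stages."""

from __future__ import annotations

import numpy as np

# lambda grid for Box-Cox maximum likelihood: [-2, 2] in steps of 0.1
BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


def boxcox_transform(x: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox transform (x^lam - 1)/lam, log at lam == 0; x must be > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    if abs(lam) < 1e-12:
        return np.log(x)
    return (x**lam - 1.0) / lam


def _boxcox_loglik(x: np.ndarray, lam: float) -> float:
    n = x.size
    y = boxcox_transform(x, lam)
    var = y.var()  # MLE variance (ddof=0)
    if var <= 0:
        return -np.inf
    return -0.5 * n * np.log(var) + (lam - 1.0) * np.log(x).sum()


def boxcox_mle(x: np.ndarray, grid: np.ndarray = BOXCOX_GRID) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with lambda chosen by profile likelihood over a fixed grid.

    Data that are not strictly positive are first shifted by a constant
    (min + machine-scale epsilon is subtracted so the smallest value maps to
    a small positive number); the shift applied is returned so it can be
    reported alongside the fitted lambda.

    Returns (transformed values, lambda, shift).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations for Box-Cox")
    shift = 0.0
    if np.any(x <= 0):
        span = np.ptp(x)
        shift = -x.min() + (0.01 * span if span > 0 else 1.0)
        x = x + shift
    lls = np.array([_boxcox_loglik(x, lam) for lam in grid])
    lam = float(grid[int(np.argmax(lls))])
    return boxcox_transform(x, lam), lam, shift
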