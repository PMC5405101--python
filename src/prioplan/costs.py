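"""Target and organ-at-risk cost functions.

Two nonlinear convex costs drive the wishlist: the logarithmic tumor
control probability (LTCP) surrogate for target coverage and the
generalized equivalent uniform dose (gEUD) power mean for serial organs.

LTCP over a target with prescription ``D_p`` and sensitivity ``alpha``::

    LTCP(d) = (1/N) * sum_i exp(-alpha * (d_i - D_p))

It equals 1 at a uniform prescription dose, blows up exponentially on
underdosage and decays toward 0 on overdosage; it is strictly decreasing
and convex in every voxel dose, which keeps the per-stage problems convex.
Because feasible iterates far below prescription make the raw sum
overflow, the optimizer works with ``log LTCP`` (a logsumexp, also convex)
and converts back; both forms are exposed here.

gEUD with volume-effect exponent ``k >= 1``::

    EUD_k(d) = ( (1/N) * sum_i d_i^k )^(1/k)

the power mean: ``k = 1`` is the mean dose, ``k -> inf`` the maximum, and
it is nondecreasing in ``k``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = ["ltcp", "log_ltcp", "log_ltcp_grad_dose", "eud", "eud_grad_dose"]


def _check_doses(doses: np.ndarray) -> np.ndarray:
    d = np.asarray(doses, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("cost function evaluated on an empty volume")
    return d


def ltcp(doses: np.ndarray, d_p: float, alpha: float) -> float:
    """LTCP of a dose vector: ``mean(exp(-alpha * (d - D_p)))``.

    Parameters
    ----------
    doses : array of Gy over the target voxels (nonempty).
    d_p : prescribed dose in Gy.
    alpha : sensitivity in 1/Gy, > 0.
    """
    return float(np.exp(log_ltcp(doses, d_p, alpha)))


def log_ltcp(doses: np.ndarray, d_p: float, alpha: float) -> float:
    """Natural log of LTCP, computed overflow-free via logsumexp."""
    d = _check_doses(doses)
    if alpha <= 0:
        raise ValueError(f"LTCP sensitivity alpha must be > 0, got {alpha}")
    return float(logsumexp(-alpha * (d - d_p)) - np.log(d.size))


def log_ltcp_grad_dose(doses: np.ndarray, d_p: float, alpha: float) -> np.ndarray:
    """Gradient of ``log_ltcp`` with respect to each voxel dose.

    Equals ``-alpha * softmax(-alpha * (d - D_p))``; the softmax keeps the
    weights normalized regardless of the magnitude of the exponents.
    """
    d = _check_doses(doses)
    if alpha <= 0:
        raise ValueError(f"LTCP sensitivity alpha must be > 0, got {alpha}")
    return -alpha * softmax(-alpha * (d - d_p))


def eud(doses: np.ndarray, k: float) -> float:
    """Generalized equivalent uniform dose: the ``k``-power mean in Gy."""
    d = _check_doses(doses)
    if k < 1:
        raise ValueError(f"EUD exponent k must be >= 1, got {k}")
    if np.any(d < 0):
        raise ValueError("EUD requires nonnegative doses")
    if k == 1:
        return float(d.mean())
    # log-domain power mean, stable for large k
    dmax = d.max()
    if dmax == 0:
        return 0.0
    return float(dmax * np.exp(np.log(np.mean((d / dmax) ** k)) / k))


def eud_grad_dose(doses: np.ndarray, k: float, eps: float = 1e-9) -> np.ndarray:
    """Gradient of gEUD with respect to each voxel dose.

    ``d EUD / d d_i = (1/N) * (d_i / EUD)^(k-1)``; an ``eps`` floor on the
    EUD keeps the expression finite at the all-zero dose.
    """
    d = _check_doses(doses)
    if k < 1:
        raise ValueError(f"EUD exponent k must be >= 1, got {k}")
    if k == 1:
        return np.full(d.size, 1.0 / d.size)
    g = max(eud(d, k), eps)
    return (np.maximum(d, 0.0) / g) ** (k - 1) / d.size
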