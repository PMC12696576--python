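"""Gaussian-copula machinery for correlated ordinal sampling.

Correlated Likert responses are produced by discretizing an
equicorrelated multivariate normal at per-item cutpoints chosen so each
item keeps its fitted category probabilities exactly.  Discretization
attenuates rank correlation, so the latent Gaussian correlation is
*calibrated*: the post-discretization mean pairwise Spearman correlation
is computed in closed form (bivariate-normal rectangle probabilities via
Gauss-Legendre quadrature and the mid-distribution representation of
Spearman's rho with ties) and inverted by bisection to hit the target.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import ndtr, ndtri

_GL_NODES = 96
_gl_x, _gl_w = np.polynomial.legendre.leggauss(_GL_NODES)
_LOWER = -8.5  # effective -infinity on the standard normal scale


def bvn_cdf(a, b, rho: float):
    """P(Z1 <= a, Z2 <= b) for standard bivariate normal with correlation rho.

    Vectorized over broadcastable ``a``, ``b``; computed as
    ``int_{-inf}^{a} phi(t) Phi((b - rho t)/sqrt(1-rho^2)) dt`` with
    fixed Gauss-Legendre nodes (abs. error ~1e-10 for |rho| <= 0.999).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    if rho >= 1.0:
        return ndtr(np.minimum(a, b))
    if rho <= -1.0:
        return np.maximum(ndtr(a) + ndtr(b) - 1.0, 0.0)
    s = np.sqrt(1.0 - rho * rho)
    half = (a - _LOWER) / 2.0
    # t has shape nodes x a.shape
    t = half * (_gl_x.reshape((-1,) + (1,) * a.ndim) + 1.0) + _LOWER
    integrand = np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi) * ndtr((b - rho * t) / s)
    return half * np.tensordot(_gl_w, integrand, axes=(0, 0))


def cutpoints(probs) -> np.ndarray:
    """Latent-scale cutpoints reproducing the category probabilities.

    Returns the 3 interior cutpoints ``ndtri(cumsum(p)[:3])``, clipped
    away from +/-inf for degenerate categories.
    """
    p = np.asarray(probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    cum = np.clip(np.cumsum(p)[:3], 1e-12, 1 - 1e-12)
    z = ndtri(cum)
    if not np.all(np.diff(np.concatenate([[-np.inf], cum])) >= 0):
        raise ValueError("cumulative probabilities must be nondecreasing")
    return z


def _mid_scores(probs: np.ndarray) -> tuple[np.ndarray, float]:
    """Mid-distribution scores and their SD for a discrete marginal.

    The large-sample Spearman correlation with average ranks equals the
    Pearson correlation of the mid-CDF transforms F(x-) + p(x)/2.
    """
    cdf = np.cumsum(probs)
    mid = cdf - probs / 2.0
    mean = float(np.dot(probs, mid))
    var = float(np.dot(probs, (mid - mean) ** 2))
    return mid, np.sqrt(var)


def induced_spearman(rho: float, probs_i, probs_j) -> float:
    """Population Spearman of two copula-discretized items at latent rho."""
    pi = np.asarray(probs_i, dtype=float)
    pj = np.asarray(probs_j, dtype=float)
    mid_i, sd_i = _mid_scores(pi)
    mid_j, sd_j = _mid_scores(pj)
    if sd_i == 0 or sd_j == 0:
        return float("nan")  # degenerate (constant) item
    zi = np.concatenate([[_LOWER], cutpoints(pi), [-_LOWER]])
    zj = np.concatenate([[_LOWER], cutpoints(pj), [-_LOWER]])
    G = bvn_cdf(zi[:, None], zj[None, :], rho)  # 5 x 5 grid of joint CDF values
    cells = G[1:, 1:] - G[:-1, 1:] - G[1:, :-1] + G[:-1, :-1]
    cells = np.clip(cells, 0.0, None)
    e_ij = float(mid_i @ cells @ mid_j)
    mean_i = float(np.dot(pi, mid_i))
    mean_j = float(np.dot(pj, mid_j))
    return (e_ij - mean_i * mean_j) / (sd_i * sd_j)


def mean_induced_spearman(rho: float, probs_list) -> float:
    """Mean pairwise induced Spearman over all item pairs of a subscale.

    Pairs involving a degenerate (single-category) item are excluded.
    """
    probs_list = [np.asarray(p, dtype=float) for p in probs_list]
    vals = []
    for i in range(len(probs_list)):
        for j in range(i + 1, len(probs_list)):
            v = induced_spearman(rho, probs_list[i], probs_list[j])
            if np.isfinite(v):
                vals.append(v)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def calibrate_latent_rho(
    target_rho: float,
    probs_list,
    tol: float = 0.01,
    max_iter: int = 40,
    rho_max: float = 0.9995,
) -> float:
    """Invert the attenuation: latent equicorrelation hitting a target Spearman.

    Monotone bisection on rho in [0, rho_max].  Targets at or beyond the
    attainable maximum are clamped (with a warning).  Raises on
    non-convergence, reporting the bracket.
    """
    if not 0.0 <= target_rho < 1.0:
        raise ValueError("target correlation must lie in [0, 1)")
    if target_rho <= tol:
        return 0.0
    attainable = mean_induced_spearman(rho_max, probs_list)
    if not np.isfinite(attainable):
        warnings.warn("all item pairs degenerate; latent correlation set to 0")
        return 0.0
    if target_rho >= attainable - tol:
        warnings.warn(
            f"target {target_rho:.3f} at/above attainable maximum "
            f"{attainable:.3f}; clamping latent correlation to {rho_max}"
        )
        return rho_max
    lo, hi = 0.0, rho_max
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = mean_induced_spearman(mid, probs_list)
        if abs(val - target_rho) <= tol * 0.5:
            return mid
        if val < target_rho:
            lo = mid
        else:
            hi = mid
    val_lo = mean_induced_spearman(lo, probs_list)
    val_hi = mean_induced_spearman(hi, probs_list)
    if abs(val_lo - target_rho) <= tol or abs(val_hi - target_rho) <= tol:
        return lo if abs(val_lo - target_rho) <= abs(val_hi - target_rho) else hi
    raise RuntimeError(
        f"calibration did not converge after {max_iter} steps; "
        f"bracket [{lo:.6f}, {hi:.6f}] -> induced [{val_lo:.4f}, {val_hi:.4f}], "
        f"target {target_rho:.4f}"
    )


def sample_discretized(
    rho: float, probs_list, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n rows of correlated ordinal responses via the Gaussian copula.

    Latents follow an equicorrelated standard MVN (one shared factor,
    valid for rho in [0, 1]); each coordinate is mapped through the
    normal CDF and inverted against its item's categorical CDF, so the
    marginals are exact by construction.
    """
    k = len(probs_list)
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"equicorrelation {rho} outside [0, 1]")
    shared = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, k))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
    u = ndtr(z)
    out = np.empty((n, k), dtype=np.int64)
    for j, probs in enumerate(probs_list):
        cum = np.cumsum(np.asarray(probs, dtype=float))
        cum[-1] = 1.0 + 1e-12
        out[:, j] = np.searchsorted(cum, u[:, j], side="left")
    return out
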