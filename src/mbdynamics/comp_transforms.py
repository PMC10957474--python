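"""Log-ratio geometry for compositional microbiome data.

Relative abundances live on the simplex: each sample is a vector of
non-negative parts summing to one, so only ratios between parts carry
information.  The additive log-ratio (alr) transform maps a D-part
composition to D-1 unconstrained coordinates ``log(x_i / x_ref)``; the
centered log-ratio (clr) uses the sample geometric mean as reference and
yields D coordinates summing to zero.  Model coefficients estimated in any
alr system can be re-expressed in clr coordinates, which makes downstream
summaries invariant to the (arbitrary) choice of alr reference.

All functions accept a single composition (1-D array) or a matrix whose
*columns* are compositions (features x samples), matching the orientation
used throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "zero_replace",
    "closure",
    "clr",
    "alr",
    "alr_inv",
    "alr_to_clr_coeffs",
    "clr_to_alr_coeffs",
]


def closure(x: np.ndarray) -> np.ndarray:
    """Rescale parts so each composition sums to 1."""
    x = np.asarray(x, dtype=float)
    s = x.sum(axis=0)
    if np.any(s <= 0):
        raise ValueError("cannot close a composition with non-positive total")
    return x / s


def zero_replace(c: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Multiplicative zero replacement.

    Zeros become ``epsilon`` and the non-zero parts of the same composition
    are rescaled by ``(1 - n_zero * epsilon) / sum(nonzero)`` so the result
    is strictly positive and sums to one.  Compositions without zeros are
    simply closed (ratios unchanged).

    Parameters
    ----------
    c : array
        Non-negative composition(s); columns are samples if 2-D.
    epsilon : float
        Replacement value per zero part, as a proportion of the sample.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("composition parts must be non-negative")
    squeeze = c.ndim == 1
    m = c[:, None] if squeeze else c.copy()
    totals = m.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("all-zero composition cannot be zero-replaced")
    zeros = m == 0
    n_zero = zeros.sum(axis=0)
    if np.any(n_zero * epsilon >= 1):
        raise ValueError("epsilon * n_zero >= 1; epsilon too large for this composition")
    nz_sum = np.where(zeros, 0.0, m).sum(axis=0)
    scale = (1.0 - n_zero * epsilon) / nz_sum
    out = m * scale
    out[zeros] = epsilon
    return out[:, 0] if squeeze else out


def _require_positive(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("log-ratio transforms require strictly positive parts")
    return c


def clr(c: np.ndarray) -> np.ndarray:
    """Centered log-ratio: log(x_i / g(x)) with g the per-sample geometric mean."""
    c = _require_positive(c)
    logc = np.log(c)
    return logc - logc.mean(axis=0)


def alr(c: np.ndarray, ref: int = -1) -> np.ndarray:
    """Additive log-ratio with reference part ``ref`` (dropped from the output)."""
    c = _require_positive(c)
    D = c.shape[0]
    ref = ref % D
    logc = np.log(c)
    return np.delete(logc - logc[ref], ref, axis=0)


def alr_inv(coords: np.ndarray, ref: int = -1) -> np.ndarray:
    """Inverse alr (softmax): insert the reference at slot ``ref`` and close.

    A zero coordinate vector maps to the uniform composition.
    """
    coords = np.asarray(coords, dtype=float)
    squeeze = coords.ndim == 1
    m = coords[:, None] if squeeze else coords
    D = m.shape[0] + 1
    ref = ref % D
    full = np.insert(m, ref, 0.0, axis=0)
    # subtract the max per sample for overflow-safe softmax
    full = full - full.max(axis=0)
    e = np.exp(full)
    out = e / e.sum(axis=0)
    return out[:, 0] if squeeze else out


def alr_to_clr_coeffs(M: np.ndarray, ref: int = -1) -> np.ndarray:
    """Map a (D-1) x Q alr-coordinate coefficient matrix to clr coordinates.

    Inserts a zero row at the reference slot and centers every column
    (left-multiplication by I - J/D), so each output column sums to zero.
    Works on a single coefficient vector as well.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("coefficient matrix must be finite")
    squeeze = M.ndim == 1
    m = M[:, None] if squeeze else M
    D = m.shape[0] + 1
    ref = ref % D
    full = np.insert(m, ref, 0.0, axis=0)
    full = full - full.mean(axis=0)
    return full[:, 0] if squeeze else full


def clr_to_alr_coeffs(M: np.ndarray, ref: int = -1) -> np.ndarray:
    """Inverse of :func:`alr_to_clr_coeffs`: subtract the reference row, drop it."""
    M = np.asarray(M, dtype=float)
    squeeze = M.ndim == 1
    m = M[:, None] if squeeze else M
    D = m.shape[0]
    ref = ref % D
    out = np.delete(m - m[ref], ref, axis=0)
    return out[:, 0] if squeeze else out
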