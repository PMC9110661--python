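"""Circular statistics and small set-overlap helpers.

Phases live on the circle, so ordinary means and correlations are replaced by
their circular analogues: the circular mean is the argument of the resultant
vector, concentration is its length, and association between two phase sets
uses the Fisher-Lee circular correlation coefficient.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "circ_mean",
    "resultant_length",
    "circ_corr",
    "circ_rmse",
    "jaccard",
]


def wrap_angle(a):
    """Wrap angles to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=np.float64)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def _resultant(angles, weights=None) -> complex:
    z = np.exp(1j * np.asarray(angles, dtype=np.float64))
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        s = w.sum()
        if s <= 0:
            raise ValueError("weights must have positive sum")
        return complex((z * w).sum() / s)
    return complex(z.mean())


def circ_mean(angles, weights=None) -> float:
    """Circular mean direction in (-pi, pi]."""
    r = _resultant(angles, weights)
    if abs(r) == 0:
        raise ValueError("circular mean undefined: zero resultant")
    return float(np.angle(r))


def resultant_length(angles, weights=None) -> float:
    """Mean resultant length in [0, 1]; 1 = perfectly concentrated phases."""
    return abs(_resultant(angles, weights))


def circ_corr(a, b) -> float:
    """Fisher-Lee T-linear circular correlation between paired angle samples.

    Uses the pairwise form
    ``rho = sum_{i,j} sin(a_i - a_j) sin(b_i - b_j) / sqrt(...)`` (computed in
    O(n) via trigonometric resultants), which stays well-defined for
    multimodal phase samples — e.g. the antipodal arterial/venous mixture —
    where the mean-deviation form degenerates.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("angle arrays must have the same shape")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    # sum_{i,j} sin(ai-aj) sin(bi-bj) = (|sum e^{i(a-b)}|^2 - |sum e^{i(a+b)}|^2) / 2
    num = (np.abs(np.exp(1j * (a - b)).sum()) ** 2 - np.abs(np.exp(1j * (a + b)).sum()) ** 2)
    den_a = n**2 - np.abs(np.exp(2j * a).sum()) ** 2
    den_b = n**2 - np.abs(np.exp(2j * b).sum()) ** 2
    if den_a <= 0 or den_b <= 0:
        raise ValueError("circular correlation undefined: a sample has no angular spread")
    return float(num / np.sqrt(den_a * den_b))


def circ_rmse(a, b) -> float:
    """Root-mean-square wrapped angular difference (radians)."""
    d = wrap_angle(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))
    return float(np.sqrt(np.mean(np.square(d))))


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a & b| / |a | b| of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Jaccard undefined for two empty masks")
    return float(np.logical_and(a, b).sum() / union)
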