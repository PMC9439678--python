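"""Circular statistics on angles in degrees.

Implements the small set of directional tests the association analyses
need: circular variance, the Rayleigh uniformity test, a sign/binomial
test of the circular median, and a two-sample concentration comparison
(Fisher-style dispersion ratio for concentrated samples, permutation on
the circular-variance difference otherwise).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "resultant_length",
    "circ_mean",
    "circ_variance",
    "rayleigh_test",
    "circ_median_test",
    "concentration_difference_test",
]


def _rad(angles) -> np.ndarray:
    return np.deg2rad(np.asarray(angles, dtype=float))


def resultant_length(angles) -> float:
    """Mean resultant vector length, in [0, 1]."""
    a = _rad(angles)
    if a.size == 0:
        raise ValueError("empty sample")
    return float(np.abs(np.mean(np.exp(1j * a))))


def circ_mean(angles) -> float:
    """Mean direction in degrees, in [0, 360)."""
    a = _rad(angles)
    return float(np.rad2deg(np.angle(np.mean(np.exp(1j * a)))) % 360.0)


def circ_variance(angles) -> float:
    """1 - mean resultant length; 0 = perfectly concentrated."""
    return 1.0 - resultant_length(angles)


def rayleigh_test(angles) -> float:
    """Rayleigh test of uniformity; returns the p-value.

    Uses the standard finite-sample approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n * rbar.
    """
    a = _rad(angles)
    n = a.size
    if n < 4:
        raise ValueError("Rayleigh test needs n >= 4")
    R = n * float(np.abs(np.mean(np.exp(1j * a))))
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - R**2)) - (1.0 + 2.0 * n))
    return float(min(max(p, 0.0), 1.0))


def circ_median_test(angles, mu0: float) -> float:
    """Sign test of H0: the circular median equals ``mu0``.

    Counts sample angles on each open semicircle about mu0; angles
    exactly on the boundary (mu0 or mu0 + 180) are excluded.  The
    counts are compared with a two-sided binomial test at 1/2.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 5:
        raise ValueError("circular median test needs n >= 5")
    d = (a - mu0 + 180.0) % 360.0 - 180.0
    pos = int(np.sum((d > 0) & (d < 180.0)))
    neg = int(np.sum((d < 0) & (d > -180.0)))
    n = pos + neg
    if n == 0:
        return 1.0
    return float(stats.binomtest(pos, n, 0.5, alternative="two-sided").pvalue)


def _dispersion(angles_rad: np.ndarray) -> float:
    mu = np.angle(np.mean(np.exp(1j * angles_rad)))
    return float(np.sum(1.0 - np.cos(angles_rad - mu)))


def concentration_difference_test(
    angles_a,
    angles_b,
    method: str = "auto",
    n_perm: int = 2000,
    seed: Optional[int] = 0,
) -> float:
    """Two-sample test of equal concentration.

    For concentrated samples (both mean resultant lengths >= 0.7) the
    ratio of mean angular dispersions 1 - cos(theta - mean direction)
    is referred to an F distribution with (n1-1, n2-1) degrees of
    freedom, two-sided.  Otherwise the absolute circular-variance
    difference is compared against ``n_perm`` random relabellings.
    ``method`` forces ``"fisher"`` or ``"permutation"``.
    """
    a = _rad(angles_a)
    b = _rad(angles_b)
    if a.size < 10 or b.size < 10:
        raise ValueError("concentration comparison needs n >= 10 per sample")
    if method == "auto":
        ra = float(np.abs(np.mean(np.exp(1j * a))))
        rb = float(np.abs(np.mean(np.exp(1j * b))))
        method = "fisher" if min(ra, rb) >= 0.7 else "permutation"
    if method == "fisher" and min(_dispersion(a), _dispersion(b)) == 0.0:
        # at least one sample is perfectly concentrated; the dispersion
        # ratio is degenerate, so fall back to the permutation test
        method = "permutation"
    if method == "fisher":
        f = (_dispersion(a) / (a.size - 1)) / (_dispersion(b) / (b.size - 1))
        cdf = stats.f.cdf(f, a.size - 1, b.size - 1)
        return float(2.0 * min(cdf, 1.0 - cdf))
    if method != "permutation":
        raise ValueError("method must be 'auto', 'fisher' or 'permutation'")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = a.size
    obs = abs(np.abs(np.mean(np.exp(1j * a))) - np.abs(np.mean(np.exp(1j * b))))
    z = np.exp(1j * pooled)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.size)
        stat = abs(np.abs(np.mean(z[perm[:na]])) - np.abs(np.mean(z[perm[na:]])))
        if stat >= obs - 1e-15:
            count += 1
    return float((1 + count) / (1 + n_perm))
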