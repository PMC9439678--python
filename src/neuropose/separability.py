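"""Separable orientation x distance models and distance tolerance.

A 3D pose tuning curve R(theta, D) (33 orientations x 4 distances) is
fit with the multiplicatively separable model

    R(theta, D) = DC + g * H(theta) * F(D),

where H is the orientation profile (unit L2 norm), F the distance
profile (max = 1) and g a gain.  The model is fit by alternating least
squares: given DC the rank-1 factors come from the best rank-1 (SVD)
approximation of the residual; given the factors DC is the mean
residual.  An additively separable variant R = DC + H + F has the
closed-form two-way-means solution.

The tolerance index is the mean across distances of the Pearson
correlation between the observed 33-point orientation tuning curve and
the fitted curve at that distance; values near one indicate that
tuning-curve shape is invariant to distance (3D pose tuning), values
near zero that it is strongly distance-dependent (lower-level feature
selectivity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .tuning import TuningSurface, normal_to_tilt_slant, tilt_slant_to_normal

__all__ = [
    "SeparableFit",
    "fit_separable",
    "tolerance_index",
    "PrincipalOrientation",
    "principal_orientation",
    "angular_deviation",
]


@dataclass
class SeparableFit:
    dc: float
    gain: float
    H: np.ndarray
    F: np.ndarray
    model: str
    sse: float
    per_distance_r: np.ndarray
    n_iter: int = 0
    degenerate: bool = False

    def predict(self) -> np.ndarray:
        if self.model == "multiplicative":
            return self.dc + self.gain * np.outer(self.H, self.F)
        return self.dc + self.H[:, None] + self.F[None, :]


def _as_matrix(surface) -> np.ndarray:
    if isinstance(surface, TuningSurface):
        R = surface.mean_rate
    else:
        R = np.asarray(surface, dtype=float)
    if np.isnan(R).any():
        raise ValueError("response matrix has missing cells")
    return R


def fit_separable(surface, model: str = "multiplicative",
                  tol: float = 1e-10, max_iter: int = 1000) -> SeparableFit:
    """Fit the separable model to a complete response matrix
    (orientations x distances)."""
    R = _as_matrix(surface)
    if model == "additive":
        dc = float(R.mean())
        H = R.mean(axis=1) - dc
        F = R.mean(axis=0) - dc
        pred = dc + H[:, None] + F[None, :]
        sse = float(np.sum((R - pred) ** 2))
        return SeparableFit(dc, np.nan, H, F, "additive", sse,
                            _per_distance_r(R, pred), n_iter=0)
    if model != "multiplicative":
        raise ValueError("model must be 'multiplicative' or 'additive'")

    if np.ptp(R) == 0:
        # zero-variance matrix: H undefined
        H = np.full(R.shape[0], np.nan)
        F = np.full(R.shape[1], np.nan)
        return SeparableFit(float(R.mean()), 0.0, H, F, "multiplicative",
                            0.0, np.full(R.shape[1], np.nan), degenerate=True)

    dc = float(R.mean())
    prev_sse = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        A = R - dc
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        u, sv, v = U[:, 0], s[0], Vt[0]
        # orient so that the distance profile's peak is positive
        f_raw = sv * v
        eps = 1.0 if f_raw.max() >= -f_raw.min() else -1.0
        H = eps * u
        f_raw = eps * f_raw
        g = float(f_raw.max())
        if g <= 0:
            g = float(np.abs(f_raw).max())
        F = f_raw / g
        pred = dc + g * np.outer(H, F)
        dc = float(np.mean(R - g * np.outer(H, F)))
        sse = float(np.sum((R - dc - g * np.outer(H, F)) ** 2))
        if prev_sse - sse < tol:
            break
        prev_sse = sse
    pred = dc + g * np.outer(H, F)
    sse = float(np.sum((R - pred) ** 2))
    return SeparableFit(dc, g, H, F, "multiplicative", sse,
                        _per_distance_r(R, pred), n_iter=n_iter)


def _per_distance_r(R: np.ndarray, pred: np.ndarray) -> np.ndarray:
    out = np.full(R.shape[1], np.nan)
    for j in range(R.shape[1]):
        if np.std(R[:, j]) > 0 and np.std(pred[:, j]) > 0:
            out[j] = stats.pearsonr(R[:, j], pred[:, j])[0]
    return out


def tolerance_index(surface, fit: Optional[SeparableFit] = None) -> float:
    """Mean per-distance correlation between observed and fitted
    orientation tuning curves.  Zero-variance columns (observed or
    fitted) are excluded; if every column is excluded the index is
    undefined (NaN).  Reported unclipped — anti-correlated columns can
    drive it negative."""
    R = _as_matrix(surface)
    if fit is None:
        fit = fit_separable(R, "multiplicative")
    if fit.model != "multiplicative":
        raise ValueError("tolerance requires the multiplicative fit")
    rs = _per_distance_r(R, fit.predict())
    valid = np.isfinite(rs)
    if not valid.any():
        return float("nan")
    return float(rs[valid].mean())


@dataclass
class PrincipalOrientation:
    tilt: float
    slant: float
    eigenvalue_fraction: float
    n_distances_used: int


def principal_orientation(preferred: Sequence[Tuple[float, float]]) -> PrincipalOrientation:
    """Principal orientation of a set of (tilt, slant) preferences.

    The surface normals of the preferences form the scatter matrix
    sum(n n^T); its top eigenvector (sign-fixed to z >= 0) is the axis
    about which the preferences cluster."""
    if len(preferred) == 0:
        raise ValueError("need at least one preferred orientation")
    N = np.array([tilt_slant_to_normal(t, s) for t, s in preferred])
    S = N.T @ N
    w, V = np.linalg.eigh(S)
    v = V[:, -1]
    if v[2] < 0 or (v[2] == 0 and (v[0] < 0 or (v[0] == 0 and v[1] < 0))):
        v = -v
    tilt, slant = normal_to_tilt_slant(v)
    frac = float(w[-1] / w.sum())
    return PrincipalOrientation(tilt, slant, frac, len(preferred))


def angular_deviation(a: Tuple[float, float], b: Tuple[float, float]) -> float:
    """Angle in degrees between the surface normals of two
    (tilt, slant) orientations, in [0, 180]."""
    na = tilt_slant_to_normal(*a)
    nb = tilt_slant_to_normal(*b)
    return float(np.rad2deg(np.arccos(np.clip(na @ nb, -1.0, 1.0))))
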