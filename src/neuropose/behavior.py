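"""Behavioral tilt-error distributions and von Mises sensitivity.

For each non-zero slant and distance, the tilt errors
DeltaTilt = reported - presented (pooled across tilt, wrapped to
(-180, 180]) fall on the eight multiples of 45 deg of the 8AFC task.
Each binned error distribution is fit with a discretised von Mises
density

    VM(x) = exp(kappa cos(x - mu)) / (2 pi I0(kappa)),

evaluated at the bin centres and renormalised over the eight bins.  The
concentration kappa is the behavioral sensitivity (capped at 18, where
the discretised density is numerically saturated) and mu the accuracy.
Because choices are discrete, the discretised model — not raw-angle
maximum likelihood — is the matching likelihood family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BIN_CENTERS",
    "ErrorDistribution",
    "error_distribution",
    "fit_vonmises_error",
    "SensitivityMap",
    "sensitivity_map",
    "behavior_neural_correlation",
]

BIN_CENTERS = np.array([-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0])
KAPPA_BOUND_DEFAULT = 18.0


@dataclass
class ErrorDistribution:
    bin_centers: np.ndarray
    probabilities: np.ndarray
    n_trials: int
    slant: float
    distance: float


def wrap_angle(a):
    """Wrap degrees to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def error_distribution(trials: pd.DataFrame, slant: float,
                       distance: float) -> ErrorDistribution:
    """Binned DeltaTilt distribution for one slant-distance condition,
    pooled across presented tilt."""
    if slant <= 0:
        raise ValueError("tilt errors are undefined at slant 0")
    t = trials[(trials["slant"] == slant) & (trials["distance_cm"] == distance)]
    t = t.dropna(subset=["tilt", "reported_tilt"])
    if len(t) == 0:
        raise ValueError(f"no trials at slant {slant}, distance {distance}")
    err = wrap_angle(t["reported_tilt"].to_numpy() - t["tilt"].to_numpy())
    counts = np.array([np.sum(err == c) for c in BIN_CENTERS], dtype=float)
    if counts.sum() != len(t):
        # guard against off-grid reports (binning must conserve trials)
        idx = np.argmin(np.abs(wrap_angle(err[:, None] - BIN_CENTERS)), axis=1)
        counts = np.bincount(idx, minlength=len(BIN_CENTERS)).astype(float)
    return ErrorDistribution(BIN_CENTERS.copy(), counts / counts.sum(),
                             int(len(t)), slant, distance)


def _discretised_vm(mu: float, kappa: float) -> np.ndarray:
    x = np.deg2rad(BIN_CENTERS)
    logp = kappa * np.cos(x - np.deg2rad(mu))
    logp -= logp.max()  # stable up to the bin renormalisation
    p = np.exp(logp)
    return p / p.sum()


def fit_vonmises_error(dist: ErrorDistribution,
                       kappa_bound: float = KAPPA_BOUND_DEFAULT) -> Tuple[float, float]:
    """Least-squares fit of the discretised von Mises to the binned
    probabilities.  Returns (mu, kappa) with kappa in [0, kappa_bound];
    degenerate (delta-like) inputs saturate the bound."""
    y = dist.probabilities

    def resid(p):
        return _discretised_vm(p[0], p[1]) - y

    best, best_cost = None, np.inf
    for mu0 in BIN_CENTERS:
        for k0 in (0.5, 3.0, 10.0):
            sol = optimize.least_squares(
                resid, np.array([mu0, k0]),
                bounds=(np.array([-360.0, 0.0]), np.array([360.0, kappa_bound])),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500)
            if sol.cost < best_cost - 1e-15:
                best, best_cost = sol, sol.cost
    mu, kappa = best.x
    # boundary refinement: if the bound fits at least as well, report it
    if np.sum(resid([mu, kappa_bound]) ** 2) <= 2.0 * best_cost + 1e-12:
        kappa = kappa_bound
    mu = float(wrap_angle(mu))
    return mu, float(kappa)


@dataclass
class SensitivityMap:
    """kappa and mu per (slant, distance); rows index slants, columns
    distances, in ascending order."""
    slants: np.ndarray
    distances: np.ndarray
    kappa: np.ndarray
    mu: np.ndarray


def sensitivity_map(trials: pd.DataFrame,
                    kappa_bound: float = KAPPA_BOUND_DEFAULT,
                    session_col: Optional[str] = None) -> SensitivityMap:
    """Fit the von Mises sensitivity for every non-zero slant x distance
    combination.  With ``session_col``, fits are per session and kappa /
    mu are averaged across sessions with equal weight (mu circularly).
    """
    slants = np.array(sorted(s for s in trials["slant"].dropna().unique() if s > 0))
    distances = np.array(sorted(trials["distance_cm"].dropna().unique()))
    kappa = np.full((len(slants), len(distances)), np.nan)
    mu = np.full_like(kappa, np.nan)
    for i, s in enumerate(slants):
        for j, d in enumerate(distances):
            if session_col is None:
                m, k = fit_vonmises_error(error_distribution(trials, s, d), kappa_bound)
                kappa[i, j], mu[i, j] = k, m
            else:
                ks, ms = [], []
                for _, sess in trials.groupby(session_col):
                    m, k = fit_vonmises_error(error_distribution(sess, s, d), kappa_bound)
                    ks.append(k)
                    ms.append(m)
                kappa[i, j] = float(np.mean(ks))
                ang = np.deg2rad(ms)
                mu[i, j] = float(np.rad2deg(np.angle(np.mean(np.exp(1j * ang)))))
    return SensitivityMap(slants, distances, kappa, mu)


def behavior_neural_correlation(kappa_map: np.ndarray,
                                tdi_map: np.ndarray) -> Tuple[float, float]:
    """Spearman rank correlation between behavioral sensitivities and
    mean TDI values over the paired slant-distance cells."""
    a = np.asarray(kappa_map, dtype=float).ravel()
    b = np.asarray(tdi_map, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have matching shapes")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("maps must be complete")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant map")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
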