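"""Orientation-tuning models: Bingham surfaces and von Mises curves.

3D surface orientation is a point on the unit hemisphere, parameterised
by tilt (azimuth of the near side, 0-360 deg) and slant (rotation in
depth from frontoparallel, 0-90 deg) with surface normal

    n(T, S) = (sin S cos T, sin S sin T, cos S).

A neuron's orientation tuning at one distance is modelled with the
(unnormalised) Bingham function

    rate(n) = offset + gain * exp(l1 (n.u1)^2 + l2 (n.u2)^2),

where {mu, u1, u2} is an orthonormal frame, mu the preferred direction,
(u1, u2) rotated about mu by the anisotropy axis angle Phi, and
l1 <= l2 <= 0 concentration parameters.  The exponent vanishes at
n = +/-mu, so the maximum rate offset + gain is attained at the
preferred orientation.  By the ordering convention the signed l1 is the
isotropy parameter (more negative = more elongated tuning) and |l2| the
bandwidth parameter (larger = narrower tuning).

Choice and saccade-direction tuning over the eight target directions is
modelled with a peak-normalised von Mises curve

    rate(theta) = offset + gain * exp(kappa cos(theta - mu)) / exp(kappa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .design import StimulusCondition, TaskDesign, enumerate_conditions

__all__ = [
    "tilt_slant_to_normal",
    "normal_to_tilt_slant",
    "BinghamFit",
    "bingham_frame",
    "bingham_predict",
    "fit_bingham",
    "TuningSurface",
    "tuning_surface",
    "orientation_anova",
    "orientation_significance",
    "VonMisesFit",
    "fit_vonmises_tuning",
]


def tilt_slant_to_normal(tilt: Optional[float], slant: float) -> np.ndarray:
    """Unit surface normal for a (tilt, slant) orientation, degrees."""
    if not (0.0 <= slant <= 90.0):
        raise ValueError(f"slant must be in [0, 90], got {slant}")
    if slant == 0.0:
        return np.array([0.0, 0.0, 1.0])
    if tilt is None:
        raise ValueError("tilt required for non-zero slant")
    t = np.deg2rad(tilt)
    s = np.deg2rad(slant)
    return np.array([np.sin(s) * np.cos(t), np.sin(s) * np.sin(t), np.cos(s)])


def normal_to_tilt_slant(n: np.ndarray) -> Tuple[float, float]:
    """Inverse of :func:`tilt_slant_to_normal`; expects z >= 0."""
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)
    slant = float(np.rad2deg(np.arccos(np.clip(n[2], -1.0, 1.0))))
    tilt = float(np.rad2deg(np.arctan2(n[1], n[0])) % 360.0)
    return tilt, slant


def bingham_frame(mu_tilt: float, mu_slant: float, phi: float) -> np.ndarray:
    """Orthonormal frame (mu, u1, u2) with (u1,u2) rotated about mu by phi.

    The reference u1 (phi = 0) is the slant tangent d(mu)/d(slant), so
    phi measures anisotropy relative to the tilt/slant coordinate axes.
    """
    t = np.deg2rad(mu_tilt)
    s = np.deg2rad(mu_slant)
    mu = np.array([np.sin(s) * np.cos(t), np.sin(s) * np.sin(t), np.cos(s)])
    u1 = np.array([np.cos(s) * np.cos(t), np.cos(s) * np.sin(t), -np.sin(s)])
    u2 = np.cross(mu, u1)
    p = np.deg2rad(phi)
    u1r = np.cos(p) * u1 + np.sin(p) * u2
    u2r = -np.sin(p) * u1 + np.cos(p) * u2
    return np.vstack([mu, u1r, u2r])


@dataclass
class BinghamFit:
    """Fitted Bingham tuning surface at one distance.

    ``lambda1`` is signed (<= 0, isotropy); ``lambda2_mag`` is the
    magnitude of the second concentration parameter (bandwidth).  The
    internal ordering convention is l1 <= -lambda2_mag <= 0.
    """

    mu_tilt: float
    mu_slant: float
    lambda1: float
    lambda2_mag: float
    phi: float
    gain: float
    offset: float
    goodness_r: float
    sse: float = np.nan
    flat: bool = False
    phi_unidentifiable: bool = False

    def predict(self, conditions) -> np.ndarray:
        return bingham_predict(self, conditions)


def _condition_orientations(conditions) -> np.ndarray:
    normals = []
    for c in conditions:
        if isinstance(c, StimulusCondition):
            normals.append(tilt_slant_to_normal(c.tilt, c.slant))
        else:
            tilt, slant = c
            normals.append(tilt_slant_to_normal(tilt, slant))
    return np.asarray(normals)


def bingham_predict(fit: BinghamFit, conditions) -> np.ndarray:
    """Model rates at the given conditions ((tilt, slant) pairs or
    :class:`StimulusCondition` objects; distance is ignored)."""
    normals = _condition_orientations(conditions)
    frame = bingham_frame(fit.mu_tilt, fit.mu_slant, fit.phi)
    l1, l2 = fit.lambda1, -abs(fit.lambda2_mag)
    c1 = normals @ frame[1]
    c2 = normals @ frame[2]
    return fit.offset + fit.gain * np.exp(l1 * c1**2 + l2 * c2**2)


def _bingham_rates(params: np.ndarray, normals: np.ndarray) -> np.ndarray:
    mu_t, mu_s, l1, l2, phi, gain, offset = params
    frame = bingham_frame(mu_t, mu_s, phi)
    c1 = normals @ frame[1]
    c2 = normals @ frame[2]
    return offset + gain * np.exp(l1 * c1**2 + l2 * c2**2)


def fit_bingham(
    conditions,
    rates: Sequence[float],
    max_iter: int = 500,
    tol: float = 1e-8,
    flat_gain_fraction: float = 0.01,
    n_starts: Optional[int] = None,
) -> BinghamFit:
    """Bounded nonlinear least-squares Bingham fit to one distance's
    orientation tuning curve.

    Multi-start from every stimulus orientation (``n_starts`` caps the
    number of starts, taken in descending order of observed rate); the
    solution with the lowest SSE wins, ties broken by the lowest start
    index.  A fit whose gain is below ``flat_gain_fraction`` of the
    offset (or of the mean rate when the offset is ~0) is flagged
    ``flat``; a fit with l1 ~= l2 has an unidentifiable anisotropy axis
    and is flagged.
    """
    rates = np.asarray(rates, dtype=float)
    normals = _condition_orientations(conditions)
    if len(rates) != len(normals):
        raise ValueError("conditions and rates must have equal length")

    rmax, rmin = float(rates.max()), float(rates.min())
    gain0 = max(rmax - rmin, 1e-6)
    lb = np.array([-360.0, 0.0, -50.0, -50.0, -1.0, 0.0, -np.inf])
    ub = np.array([720.0, 90.0, 0.0, 0.0, 181.0, np.inf, np.inf])

    starts = []
    for c, r in zip(conditions, rates):
        if isinstance(c, StimulusCondition):
            tilt, slant = (c.tilt if c.tilt is not None else 0.0), c.slant
        else:
            tilt, slant = c
            tilt = 0.0 if tilt is None else tilt
        starts.append((tilt, slant, r))
    # highest-rate orientations first so early starts are informative
    order = np.argsort([-s[2] for s in starts], kind="stable")
    if n_starts is not None:
        order = order[:n_starts]

    best = None
    best_cost = np.inf
    for rank, idx in enumerate(order):
        tilt0, slant0, _ = starts[idx]
        x0 = np.array([tilt0, slant0, -2.0, -1.0, 90.0, gain0, rmin])
        try:
            sol = optimize.least_squares(
                lambda p: _bingham_rates(p, normals) - rates,
                x0, bounds=(lb, ub), xtol=tol, ftol=tol, gtol=tol,
                max_nfev=max_iter,
            )
        except Exception:
            continue
        if sol.cost < best_cost - 1e-12:
            best_cost = sol.cost
            best = sol
    if best is None:
        raise RuntimeError("Bingham fit failed to converge from any start")

    mu_t, mu_s, l1, l2, phi, gain, offset = best.x
    # ordering convention: |l1| >= |l2|; swapping axes rotates phi by 90
    if abs(l2) > abs(l1):
        l1, l2 = l2, l1
        phi += 90.0
    mu_t = mu_t % 360.0
    phi = phi % 180.0
    pred = _bingham_rates(np.array([mu_t, mu_s, l1, l2, phi, gain, offset]), normals)
    sse = float(np.sum((pred - rates) ** 2))
    if np.std(pred) > 0 and np.std(rates) > 0:
        goodness = float(stats.pearsonr(pred, rates)[0])
    else:
        goodness = np.nan
    ref = abs(offset) if abs(offset) > 1e-9 else max(abs(rates.mean()), 1e-9)
    flat = gain < flat_gain_fraction * ref
    iso = abs(l1 - l2) < 1e-3 * max(abs(l1), 1.0)
    return BinghamFit(
        mu_tilt=float(mu_t), mu_slant=float(mu_s), lambda1=float(l1),
        lambda2_mag=float(abs(l2)), phi=float(phi), gain=float(gain),
        offset=float(offset), goodness_r=goodness, sse=sse,
        flat=bool(flat), phi_unidentifiable=bool(iso),
    )


# ----------------------------------------------------------------------
# Tuning surfaces (orientation x distance response matrices)
# ----------------------------------------------------------------------

@dataclass
class TuningSurface:
    """Per-condition mean rates over the response window.

    ``mean_rate``, ``trial_counts`` and ``within_condition_sse`` are
    (n_orientations x n_distances) arrays; ``orientations`` lists the
    (tilt, slant) pairs indexing the rows (frontoparallel first).
    """

    mean_rate: np.ndarray
    trial_counts: np.ndarray
    within_condition_sse: np.ndarray
    orientations: list
    distances: list
    baseline: float = np.nan

    @property
    def n_orientations(self) -> int:
        return self.mean_rate.shape[0]

    def column(self, distance: float) -> np.ndarray:
        j = self.distances.index(distance)
        return self.mean_rate[:, j]


def _orientation_key(tilt, slant):
    return (np.nan if tilt is None or (isinstance(tilt, float) and np.isnan(tilt)) else float(tilt),
            float(slant))


def tuning_surface(data, window: Optional[Tuple[float, float]] = None) -> TuningSurface:
    """Per-condition means, counts and within-condition SSE from the
    tilt-task trials of a dataset.

    Rates are spike counts over the response window scaled to spikes/s.
    If ``window`` is given and spike times are available, counts are
    recomputed in that window; otherwise the stored counts (taken over
    ``data.response_window``) are used.
    """
    trials = data.tilt_trials()
    if len(trials) == 0:
        raise ValueError("dataset has no tilt-task trials")
    if window is not None and data.spike_times is not None:
        w0, w1 = window
        counts = np.array([
            np.count_nonzero((data.spike_times[i] >= w0) & (data.spike_times[i] < w1))
            for i in trials.index
        ], dtype=float)
        rates = counts * 1000.0 / (w1 - w0)
    else:
        w0, w1 = data.response_window
        rates = trials["spike_count"].to_numpy(dtype=float) * 1000.0 / (w1 - w0)

    design = data.design
    per_distance = [c for c in enumerate_conditions(design)
                    if c.distance == design.distances[0]]
    orientations = [(c.tilt, c.slant) for c in per_distance]
    distances = list(design.distances)
    shape = (len(orientations), len(distances))
    mean = np.full(shape, np.nan)
    counts_mat = np.zeros(shape)
    sse = np.full(shape, np.nan)

    tilt_col = trials["tilt"].to_numpy(dtype=float)
    slant_col = trials["slant"].to_numpy(dtype=float)
    dist_col = trials["distance_cm"].to_numpy(dtype=float)
    for i, (t, s) in enumerate(orientations):
        if s == 0.0:
            omask = slant_col == 0.0
        else:
            omask = (slant_col == s) & (tilt_col == t)
        for j, d in enumerate(distances):
            m = omask & (dist_col == d)
            r = rates[m]
            counts_mat[i, j] = r.size
            if r.size:
                mean[i, j] = r.mean()
                sse[i, j] = float(np.sum((r - r.mean()) ** 2))
    return TuningSurface(mean, counts_mat, sse, orientations, distances)


def orientation_anova(data, distance: float,
                      window: Optional[Tuple[float, float]] = None) -> float:
    """One-way ANOVA p-value across the orientation conditions at one
    distance, on trial firing rates."""
    trials = data.tilt_trials()
    trials = trials[trials["distance_cm"] == distance]
    if len(trials) == 0:
        raise ValueError(f"no trials at distance {distance}")
    w0, w1 = data.response_window if window is None else window
    if window is not None and data.spike_times is not None:
        rates = np.array([
            np.count_nonzero((data.spike_times[i] >= w0) & (data.spike_times[i] < w1))
            for i in trials.index
        ], dtype=float) * 1000.0 / (w1 - w0)
    else:
        rates = trials["spike_count"].to_numpy(dtype=float) * 1000.0 / (w1 - w0)
    keys = [
        _orientation_key(t, s)
        for t, s in zip(trials["tilt"].to_numpy(), trials["slant"].to_numpy())
    ]
    groups = {}
    for k, r in zip(keys, rates):
        groups.setdefault(k, []).append(r)
    samples = [np.asarray(v) for v in groups.values()]
    if any(len(v) < 2 for v in samples):
        raise ValueError("need >= 2 trials per orientation condition")
    if np.ptp(np.concatenate(samples)) == 0:
        return 1.0  # identical rates everywhere: F = 0
    f, p = stats.f_oneway(*samples)
    return float(p) if np.isfinite(p) else 1.0


def orientation_significance(data, alpha: float = 0.05) -> dict:
    """Per-distance orientation ANOVA with Holm correction across the
    four distances.  Returns ``{distance: (p_raw, significant)}``."""
    from statsmodels.stats.multitest import multipletests

    distances = list(data.design.distances)
    pvals = np.array([orientation_anova(data, d) for d in distances])
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return {d: (float(p), bool(r)) for d, p, r in zip(distances, pvals, reject)}


# ----------------------------------------------------------------------
# von Mises direction/choice tuning
# ----------------------------------------------------------------------

@dataclass
class VonMisesFit:
    mu: float
    kappa: float
    gain: float
    offset: float
    goodness_r: float
    flat: bool = False

    def predict(self, directions_deg) -> np.ndarray:
        th = np.deg2rad(np.asarray(directions_deg, dtype=float))
        m = np.deg2rad(self.mu)
        return self.offset + self.gain * np.exp(
            self.kappa * (np.cos(th - m) - 1.0))


def fit_vonmises_tuning(
    directions_deg: Sequence[float],
    means: Sequence[float],
    sems: Optional[Sequence[float]] = None,
    kappa_max: float = 500.0,
) -> VonMisesFit:
    """Least-squares fit of ``offset + gain * exp(kappa(cos(th-mu)-1))``
    to direction-binned mean responses (peak-normalised von Mises).

    Multi-start over mu at every direction bin and a small kappa grid.
    A near-zero-modulation result is flagged ``flat``.
    """
    d = np.asarray(directions_deg, dtype=float)
    y = np.asarray(means, dtype=float)
    if d.shape != y.shape:
        raise ValueError("directions and means must match")
    th = np.deg2rad(d)

    def resid(p):
        mu, kappa, gain, offset = p
        pred = offset + gain * np.exp(kappa * (np.cos(th - np.deg2rad(mu)) - 1.0))
        return pred - y

    gain0 = max(np.ptp(y), 1e-9)
    lb = np.array([-360.0, 0.0, 0.0, -np.inf])
    ub = np.array([720.0, kappa_max, np.inf, np.inf])
    best, best_cost = None, np.inf
    for mu0 in d:
        for k0 in (0.5, 2.0, 8.0):
            sol = optimize.least_squares(
                resid, np.array([mu0, k0, gain0, y.min()]),
                bounds=(lb, ub), xtol=1e-10, ftol=1e-10, max_nfev=500)
            if sol.cost < best_cost - 1e-12:
                best, best_cost = sol, sol.cost
    mu, kappa, gain, offset = best.x
    pred = offset + gain * np.exp(kappa * (np.cos(th - np.deg2rad(mu)) - 1.0))
    if np.std(pred) > 1e-12 and np.std(y) > 1e-12:
        r = float(stats.pearsonr(pred, y)[0])
    else:
        r = np.nan
    flat = kappa < 0.1 or gain < 1e-6 * max(abs(y).max(), 1.0)
    return VonMisesFit(mu=float(mu % 360.0), kappa=float(kappa), gain=float(gain),
                       offset=float(offset), goodness_r=r, flat=bool(flat))
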