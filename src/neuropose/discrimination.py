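"""Neuronal discrimination indices.

The discrimination index of a tuning curve with per-condition trial
responses is

    DI = (Rmax - Rmin) / (Rmax - Rmin + 2 sqrt(SSE / (N - M))),

where Rmax and Rmin are the largest and smallest condition means, SSE
the within-condition sum of squared errors pooled over conditions, N
the total trial count and M the number of conditions.  DI lies in
[0, 1]: near one for strong modulation relative to trial noise, near
zero for weak.  It is invariant to a common additive offset and a
common positive scaling of all responses, which makes the choice
variant insensitive to the per-distance z-scoring used upstream.

Four instantiations share this formula:

* SODI — orientations at one distance (M = 33), raw rates;
* TDI  — tilts at one slant-distance combination (M = 8), raw rates;
* CDI  — choices on frontoparallel trials (M = 8), per-distance
  z-scored responses pooled over distance;
* SDI  — saccade directions (M = 8), saccade-window rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

__all__ = ["DIResult", "discrimination_index", "sodi", "tdi", "cdi", "sdi"]


@dataclass
class DIResult:
    di: float
    r_max: float
    r_min: float
    sse: float
    n_trials: int
    n_conditions: int


def discrimination_index(grouped_responses: Sequence[Sequence[float]]) -> DIResult:
    """DI from per-condition trial response lists."""
    groups = [np.asarray(g, dtype=float) for g in grouped_responses]
    if any(g.size == 0 for g in groups):
        raise ValueError("every condition needs at least one trial")
    M = len(groups)
    N = sum(g.size for g in groups)
    if N <= M:
        raise ValueError("need more trials than conditions (N > M)")
    means = np.array([g.mean() for g in groups])
    sse = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    r_max, r_min = float(means.max()), float(means.min())
    spread = r_max - r_min
    noise = 2.0 * np.sqrt(sse / (N - M))
    di = spread / (spread + noise) if spread + noise > 0 else 0.0
    return DIResult(float(di), r_max, r_min, sse, int(N), M)


def _group_by(values: np.ndarray, keys: np.ndarray) -> list:
    out: Dict = {}
    for k, v in zip(keys, values):
        out.setdefault(k, []).append(v)
    return [np.asarray(v) for _, v in sorted(out.items())]


def sodi(data, distance: float) -> DIResult:
    """Surface-orientation DI across the 33 orientation conditions at
    one distance (raw response-window rates)."""
    trials = data.tilt_trials()
    trials = trials[trials["distance_cm"] == distance]
    rates = data.rates(trials)
    tilt = trials["tilt"].to_numpy(dtype=float)
    slant = trials["slant"].to_numpy(dtype=float)
    keys = np.where(slant == 0.0, -1.0, slant * 1000.0 + tilt)
    return discrimination_index(_group_by(rates, keys))


def tdi(data, slant: float, distance: float) -> DIResult:
    """Tilt DI across the 8 tilts at one slant-distance combination."""
    if slant <= 0:
        raise ValueError("TDI requires a non-zero slant")
    trials = data.tilt_trials()
    trials = trials[(trials["distance_cm"] == distance) & (trials["slant"] == slant)]
    rates = data.rates(trials)
    return discrimination_index(_group_by(rates, trials["tilt"].to_numpy(dtype=float)))


def cdi(data, zscore: bool = True) -> DIResult:
    """Choice DI on frontoparallel trials grouped by the reported tilt.

    Responses are z-scored separately per distance then pooled (the
    choice-pipeline convention); the index itself is z-score invariant.
    """
    trials = data.frontoparallel_trials()
    rates = data.rates(trials)
    if zscore:
        dist = trials["distance_cm"].to_numpy(dtype=float)
        z = np.empty_like(rates)
        for d in np.unique(dist):
            m = dist == d
            mu, sd = rates[m].mean(), rates[m].std(ddof=0)
            z[m] = (rates[m] - mu) / sd if sd > 0 else 0.0
        rates = z
    return discrimination_index(
        _group_by(rates, trials["reported_tilt"].to_numpy(dtype=float)))


def sdi(data, window=None) -> DIResult:
    """Saccade-direction DI on saccade-window rates grouped by target
    direction.  ``window`` (ms, saccade-aligned) recounts from spike
    times; otherwise the stored saccade-window counts are used."""
    trials = data.saccade_trials()
    w0, w1 = data.saccade_window if window is None else window
    if window is not None and data.spike_times is not None:
        rates = np.array([
            np.count_nonzero((data.spike_times[i] >= w0) & (data.spike_times[i] < w1))
            for i in trials.index
        ], dtype=float) * 1000.0 / (w1 - w0)
    else:
        rates = trials["spike_count"].to_numpy(dtype=float) * 1000.0 / (w1 - w0)
    return discrimination_index(
        _group_by(rates, trials["saccade_dir"].to_numpy(dtype=float)))
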