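"""Spike-density functions, onset detection and population time courses.

Spike trains (1 ms bins) are convolved with a causal double-exponential
kernel k(t) ~ (1 - exp(-t/tau_g)) exp(-t/tau_d), unit area, to form
spike-density functions (SDFs).  Onsets — visual latency, the
divergence of choice- or saccade-conditioned time courses, and
per-quartile starts of pre-saccadic activity — are all detected the
same way: a per-1 ms-bin ANOVA with significance sustained for at least
30 consecutive bins; the onset is the first bin of the run.

The population choice analysis z-scores baseline-subtracted
frontoparallel responses separately per distance, groups trials by the
reported tilt, relabels each tuned neuron's per-choice SDFs relative to
its preferred choice, averages across neurons, and refits the analysis
window iteratively until the detected onset stops changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats

from .behavior import wrap_angle

__all__ = [
    "double_exponential_kernel",
    "sdf",
    "sdf_matrix",
    "sustained_run",
    "visual_latency",
    "divergence_onset",
    "choice_anova",
    "direction_anova",
    "PopulationTimecourse",
    "population_choice_timecourses",
    "saccade_onset_from_eye",
    "QuartileAnalysis",
    "latency_quartile_analysis",
    "integrate_and_match",
]

REL_CHOICES = np.array([0.0, 45.0, 90.0, 135.0, 180.0, -135.0, -90.0, -45.0])
SUSTAIN_MS = 30


def double_exponential_kernel(tau_growth: float = 1.0,
                              tau_decay: float = 20.0) -> np.ndarray:
    """Causal unit-area kernel (1 ms sampling)."""
    if tau_growth <= 0 or tau_decay <= 0:
        raise ValueError("kernel taus must be positive")
    length = int(np.ceil(10 * tau_decay + 5 * tau_growth))
    t = np.arange(length, dtype=float)
    k = (1.0 - np.exp(-t / tau_growth)) * np.exp(-t / tau_decay)
    return k / k.sum()


@dataclass
class SDF:
    time: np.ndarray   # ms, 1 ms resolution
    rate: np.ndarray   # spikes/s
    alignment: str = "stimulus_onset"


def _bin_spikes(spike_times: np.ndarray, t_start: float, t_stop: float) -> np.ndarray:
    n = int(round(t_stop - t_start))
    edges = t_start + np.arange(n + 1, dtype=float)
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), bins=edges)
    return counts.astype(float)


def sdf(spike_times, t_start: float, t_stop: float,
        tau_growth: float = 1.0, tau_decay: float = 20.0,
        alignment: str = "stimulus_onset") -> SDF:
    """SDF of one trial over [t_start, t_stop) at 1 ms resolution."""
    k = double_exponential_kernel(tau_growth, tau_decay)
    counts = _bin_spikes(spike_times, t_start, t_stop)
    rate = np.convolve(counts, k)[: counts.size] * 1000.0
    return SDF(t_start + np.arange(counts.size, dtype=float), rate, alignment)


def sdf_matrix(spike_times_list: Sequence[np.ndarray], t_start: float,
               t_stop: float, tau_growth: float = 1.0,
               tau_decay: float = 20.0) -> Tuple[np.ndarray, np.ndarray]:
    """Trial x time SDF matrix; returns (time_grid, matrix)."""
    k = double_exponential_kernel(tau_growth, tau_decay)
    n = int(round(t_stop - t_start))
    counts = np.empty((len(spike_times_list), n))
    for i, st in enumerate(spike_times_list):
        counts[i] = _bin_spikes(st, t_start, t_stop)
    rates = signal.fftconvolve(counts, k[None, :], axes=1)[:, :n] * 1000.0
    rates[rates < 0] = 0.0  # fft round-off
    return t_start + np.arange(n, dtype=float), rates


def sustained_run(significant: np.ndarray, min_len: int = SUSTAIN_MS) -> Optional[int]:
    """Index of the first run of >= min_len consecutive True values."""
    sig = np.asarray(significant, dtype=bool).astype(int)
    if sig.size < min_len:
        return None
    run = np.convolve(sig, np.ones(min_len, dtype=int), mode="valid")
    hits = np.nonzero(run == min_len)[0]
    return int(hits[0]) if hits.size else None


def _binwise_anova_p(*groups: np.ndarray) -> np.ndarray:
    """Per-column one-way ANOVA p-values across trial x time groups."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*groups, axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    return p


def visual_latency(data, baseline_ms: float = 150.0, alpha: float = 0.05,
                   tau_growth: float = 1.0, tau_decay: float = 20.0) -> Optional[float]:
    """Visual response latency of one neuron (ms after stimulus onset).

    First 1 ms bin at which the across-trial SDF values differ from the
    across-trial baseline rates (last ``baseline_ms`` of fixation) at
    p < alpha, sustained for at least 30 ms; ``None`` if never.
    """
    trials = data.tilt_trials()
    if data.spike_times is None:
        raise ValueError("visual latency needs spike times")
    sts = [data.spike_times[i] for i in trials.index if data.spike_times[i] is not None]
    if len(sts) < 4:
        raise ValueError("too few trials with spike times")
    dur = data.design.stimulus_duration
    # start the SDF inside the fixation epoch so the kernel has settled
    # by stimulus onset (avoids a spurious warm-up dip at t = 0)
    warmup = baseline_ms
    grid, mat = sdf_matrix(sts, -warmup, dur, tau_growth, tau_decay)
    keep = grid >= 0.0
    mat = mat[:, keep]
    base = np.array([
        np.count_nonzero((st >= -baseline_ms) & (st < 0.0)) for st in sts
    ]) * 1000.0 / baseline_ms
    p = _binwise_anova_p(mat, np.tile(base[:, None], (1, mat.shape[1])))
    onset = sustained_run(p < alpha)
    return float(onset) if onset is not None else None


def divergence_onset(groups: Sequence[np.ndarray], time_grid: np.ndarray,
                     alpha: float = 0.05) -> Optional[float]:
    """Onset (ms) of a sustained difference between condition groups.

    ``groups`` are trial-x-time (or neuron-x-time) value matrices on a
    common grid; a per-bin one-way ANOVA across groups must stay below
    alpha for at least 30 consecutive bins.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.shape[0] < 2 for g in groups):
        raise ValueError("need >= 2 rows per group")
    p = _binwise_anova_p(*[np.asarray(g, dtype=float) for g in groups])
    onset = sustained_run(p < alpha)
    return float(time_grid[onset]) if onset is not None else None


# ----------------------------------------------------------------------
# Choice / direction screening ANOVAs
# ----------------------------------------------------------------------

def _fp_window_responses(data, window: Tuple[float, float],
                         baseline_ms: float = 150.0):
    """Per-FP-trial baseline-subtracted rates z-scored per distance.

    Returns (trial index, z, choices, distances, baseline rates,
    per-distance (mean, sd) of the baseline-subtracted rates).
    """
    trials = data.frontoparallel_trials()
    idx = trials.index.to_numpy()
    w0, w1 = window
    if data.spike_times is not None and all(
            data.spike_times[i] is not None for i in idx):
        rate = np.array([
            np.count_nonzero((data.spike_times[i] >= w0) & (data.spike_times[i] < w1))
            for i in idx]) * 1000.0 / (w1 - w0)
        base = np.array([
            np.count_nonzero((data.spike_times[i] >= -baseline_ms)
                             & (data.spike_times[i] < 0.0))
            for i in idx]) * 1000.0 / baseline_ms
    else:
        ww0, ww1 = data.response_window
        rate = trials["spike_count"].to_numpy(dtype=float) * 1000.0 / (ww1 - ww0)
        base = np.zeros(len(trials))
    adj = rate - base
    dist = trials["distance_cm"].to_numpy(dtype=float)
    z = np.empty_like(adj)
    norms = {}
    for d in np.unique(dist):
        m = dist == d
        mu, sd = adj[m].mean(), adj[m].std(ddof=0)
        sd = sd if sd > 0 else 1.0
        z[m] = (adj[m] - mu) / sd
        norms[d] = (mu, sd)
    choices = trials["reported_tilt"].to_numpy(dtype=float)
    return idx, z, choices, dist, base, norms


def choice_anova(data, window: Tuple[float, float]) -> float:
    """ANOVA p-value for choice tuning of per-distance z-scored
    frontoparallel responses in the given stimulus-aligned window."""
    _, z, choices, _, _, _ = _fp_window_responses(data, window)
    groups = [z[choices == c] for c in np.unique(choices)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("too few choices represented")
    f, p = stats.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


def direction_anova(data, window: Optional[Tuple[float, float]] = None) -> float:
    """ANOVA p-value for saccade-direction tuning of saccade-window
    rates."""
    trials = data.saccade_trials()
    w0, w1 = data.saccade_window if window is None else window
    if window is not None and data.spike_times is not None:
        rates = np.array([
            np.count_nonzero((data.spike_times[i] >= w0) & (data.spike_times[i] < w1))
            for i in trials.index]) * 1000.0 / (w1 - w0)
    else:
        rates = trials["spike_count"].to_numpy(dtype=float) * 1000.0 / (w1 - w0)
    dirs = trials["saccade_dir"].to_numpy(dtype=float)
    groups = [rates[dirs == d] for d in np.unique(dirs)]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 trials per direction")
    if np.ptp(rates) == 0:
        return 1.0
    f, p = stats.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


# ----------------------------------------------------------------------
# Population choice time courses with iterative onset
# ----------------------------------------------------------------------

@dataclass
class PopulationTimecourse:
    time: np.ndarray
    curves: np.ndarray            # 8 x T, ordered as rel_choices
    rel_choices: np.ndarray
    onset: Optional[float]
    n_neurons: int
    units: str = "z"
    n_iterations: int = 0


def population_choice_timecourses(
    neurons: Sequence,
    alpha: float = 0.05,
    initial_onset: float = 46.0,
    max_iter: int = 20,
    baseline_ms: float = 150.0,
    tau_growth: float = 1.0,
    tau_decay: float = 20.0,
) -> PopulationTimecourse:
    """Population choice time courses with iterative onset detection.

    The analysis window starts at ``initial_onset`` (the area's median
    visual latency) and is refit to [detected onset, stimulus end]
    until the onset no longer changes (previously seen onsets terminate
    an oscillation).
    """
    if not neurons:
        raise ValueError("no neurons given")
    dur = neurons[0].design.stimulus_duration
    onset = initial_onset
    history = [onset]
    result = None
    for it in range(1, max_iter + 1):
        result = _choice_timecourses_once(
            neurons, (onset, dur), alpha, baseline_ms, tau_growth, tau_decay)
        result.n_iterations = it
        new = result.onset
        if new is None or new == onset:
            return result
        if new in history:   # oscillation: return the repeated value
            result.onset = new
            return result
        history.append(new)
        onset = new
    return result


def _choice_timecourses_once(neurons, window, alpha, baseline_ms,
                             tau_growth, tau_decay) -> PopulationTimecourse:
    dur = neurons[0].design.stimulus_duration
    per_neuron = []  # (8 x T) z-scored mean SDFs, rel-choice ordered
    for data in neurons:
        idx, z, choices, dist, base, norms = _fp_window_responses(
            data, window, baseline_ms)
        groups = [z[choices == c] for c in np.unique(choices)]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            continue
        f, p = stats.f_oneway(*groups)
        if not np.isfinite(p) or p >= alpha:
            continue
        uniq = np.unique(choices)
        pref = uniq[np.argmax([z[choices == c].mean() for c in uniq])]
        sts = [data.spike_times[i] for i in idx]
        time, mat = sdf_matrix(sts, 0.0, dur, tau_growth, tau_decay)
        zmat = np.empty_like(mat)
        for k in range(mat.shape[0]):
            mu, sd = norms[dist[k]]
            zmat[k] = (mat[k] - base[k] - mu) / sd
        rel = wrap_angle(choices - pref)
        curves = np.full((len(REL_CHOICES), mat.shape[1]), np.nan)
        for r, rc in enumerate(REL_CHOICES):
            m = rel == rc
            if m.any():
                curves[r] = zmat[m].mean(axis=0)
        if np.isnan(curves).any():
            continue
        per_neuron.append(curves)
    time = np.arange(dur, dtype=float)
    if not per_neuron:
        return PopulationTimecourse(time, np.full((8, int(dur)), np.nan),
                                    REL_CHOICES.copy(), None, 0)
    stack = np.stack(per_neuron)          # n x 8 x T
    curves = stack.mean(axis=0)
    groups = [stack[:, r, :] for r in range(len(REL_CHOICES))]
    onset = divergence_onset(groups, time, alpha) if stack.shape[0] >= 2 else None
    return PopulationTimecourse(time, curves, REL_CHOICES.copy(), onset,
                                stack.shape[0])


# ----------------------------------------------------------------------
# Saccade analyses
# ----------------------------------------------------------------------

def saccade_onset_from_eye(velocity_trace: np.ndarray,
                           threshold: float = 150.0) -> float:
    """First sample (ms) at which eye velocity reaches the threshold."""
    v = np.asarray(velocity_trace, dtype=float)
    hits = np.nonzero(v >= threshold)[0]
    if hits.size == 0:
        raise ValueError("velocity never crossed the saccade threshold")
    return float(hits[0])


@dataclass
class QuartileAnalysis:
    time: np.ndarray
    quartile_curves: np.ndarray          # 4 x T
    quartile_mean_latencies: np.ndarray
    starts: List[Optional[float]]
    coalescence_time: float
    growth_rates: np.ndarray             # units/s
    gr_latency_correlation: float
    degenerate: bool = False


def latency_quartile_analysis(
    latencies: np.ndarray,
    trial_curves: np.ndarray,
    time_grid: np.ndarray,
    baseline_window: Tuple[float, float] = (-450.0, -300.0),
    alpha: float = 0.05,
    alignment_time: float = 0.0,
) -> QuartileAnalysis:
    """Latency-quartile analysis of saccade-aligned activity.

    Trials (rows of ``trial_curves``, preferred-direction only) are
    partitioned into four near-equal groups by latency rank.  Each
    quartile's start is the onset of a sustained divergence of its
    trial values from the trial baseline rates; the coalescence time
    minimises the summed squared deviation of the four mean curves from
    their mean (searched from the latest start to the alignment event,
    earliest minimiser on ties); growth rates are least-squares slopes
    from each quartile's start to coalescence.
    """
    latencies = np.asarray(latencies, dtype=float)
    trial_curves = np.asarray(trial_curves, dtype=float)
    n = latencies.size
    if n < 8:
        raise ValueError("need at least 8 trials for quartiles")
    order = np.argsort(latencies, kind="stable")
    parts = np.array_split(order, 4)
    degenerate = np.ptp(latencies) == 0
    q_lat = np.array([latencies[p].mean() for p in parts])
    curves = np.vstack([trial_curves[p].mean(axis=0) for p in parts])

    bmask = (time_grid >= baseline_window[0]) & (time_grid < baseline_window[1])
    starts: List[Optional[float]] = []
    for p in parts:
        sub = trial_curves[p]
        base = sub[:, bmask].mean(axis=1)
        pvals = _binwise_anova_p(sub, np.tile(base[:, None], (1, sub.shape[1])))
        # only consider bins after the baseline window
        pvals[time_grid < baseline_window[1]] = 1.0
        onset = sustained_run(pvals < alpha)
        starts.append(float(time_grid[onset]) if onset is not None else None)

    known = [s for s in starts if s is not None]
    search_from = max(known) if known else float(time_grid[0])
    smask = (time_grid >= search_from) & (time_grid <= alignment_time)
    if not smask.any():
        smask = time_grid <= alignment_time
    dev = np.sum((curves - curves.mean(axis=0)) ** 2, axis=0)
    cand = np.nonzero(smask)[0]
    coalescence = float(time_grid[cand[np.argmin(dev[cand])]])

    growth = np.full(4, np.nan)
    for q in range(4):
        s = starts[q]
        if s is None or s >= coalescence:
            continue
        m = (time_grid >= s) & (time_grid <= coalescence)
        t = time_grid[m]
        y = curves[q][m]
        slope = np.polyfit(t, y, 1)[0] if t.size >= 2 else np.nan
        growth[q] = slope * 1000.0   # per-ms slope -> per-s

    ok = np.isfinite(growth)
    if ok.sum() >= 3 and np.ptp(growth[ok]) > 0 and np.ptp(q_lat[ok]) > 0:
        r = float(stats.pearsonr(growth[ok], q_lat[ok])[0])
    else:
        r = np.nan
    return QuartileAnalysis(time_grid, curves, q_lat, starts, coalescence,
                            growth, r, degenerate=bool(degenerate))


def integrate_and_match(
    source_curves: np.ndarray,
    source_onset: float,
    target_curves: np.ndarray,
    target_window_end: float,
    time_grid: np.ndarray,
    integrate: bool = True,
) -> List[dict]:
    """Temporal integration of source curves matched to target curves.

    Each source curve is baseline-subtracted (mean before onset),
    cumulatively integrated (1 ms steps) from ``source_onset``, then an
    offset and gain are chosen in closed form to minimise the squared
    error against the target over [source_onset, target_window_end].
    With ``integrate=False`` the raw source curve is matched instead
    (the control comparison).
    """
    source_curves = np.atleast_2d(np.asarray(source_curves, dtype=float))
    target_curves = np.atleast_2d(np.asarray(target_curves, dtype=float))
    if source_curves.shape != target_curves.shape:
        raise ValueError("source and target must share a time grid and shape")
    wmask = (time_grid >= source_onset) & (time_grid <= target_window_end)
    if not wmask.any():
        raise ValueError("empty matching window")
    pre = time_grid < source_onset
    out = []
    for src, tgt in zip(source_curves, target_curves):
        base = src[pre].mean() if pre.any() else 0.0
        adj = src - base
        adj[pre] = 0.0
        feat = np.cumsum(adj) if integrate else adj
        X = np.column_stack([np.ones(wmask.sum()), feat[wmask]])
        coef, *_ = np.linalg.lstsq(X, tgt[wmask], rcond=None)
        matched = np.full_like(src, np.nan)
        matched[wmask] = X @ coef
        sse = float(np.sum((tgt[wmask] - X @ coef) ** 2))
        out.append({"offset": float(coef[0]), "gain": float(coef[1]),
                    "matched": matched, "sse": sse})
    return out
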