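"""Synthetic neurons, populations, behavior and saccade trials.

Every analysis stage in the package can be exercised on data from this
module, with known ground truth.  The generator emulates the two-task
experiment: an 8AFC tilt-discrimination task over a tilt x slant x
distance pose grid, and a visually guided saccade task with eight
target directions.

Trial variability is Poisson at 1 ms resolution, optionally multiplied
by a per-trial lognormal shared gain (mean one) common to all neurons
of a simulated tetrode — the minimal model producing the positive
noise correlations analysed downstream.  Orientation tuning follows the
Bingham surface model; cross-distance preference jitter controls the
ground-truth distance tolerance of a neuron.  Behavioral tilt reports
are the presented tilt plus a von Mises error snapped to the nearest of
the eight choice targets.  Saccade latencies follow a shifted gamma
distribution (positive, right-skewed).

Within-trial dynamics (the tuning analyses constrain only mean rates):
the visual response is a rate step from baseline to the condition rate
at ``visual_latency``; choice-related activity is a step (or ramp) that
begins at the choice-modulation onset; pre-saccadic activity ramps
linearly from its onset to a coalescence time before the saccade.
These shapes are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .datasets import NeuronDataset, TRIAL_COLUMNS
from .design import StimulusCondition, TaskDesign, block_trial_conditions, enumerate_conditions
from .tuning import bingham_frame, tilt_slant_to_normal

__all__ = [
    "GroundTruthNeuron",
    "make_ground_truth",
    "simulate_neuron",
    "simulate_population",
    "simulate_behavior",
    "simulate_saccade_trials",
    "percent_correct",
    "shared_gain_sd_for_noise_r",
]


# ----------------------------------------------------------------------
# Ground truth
# ----------------------------------------------------------------------

@dataclass
class GroundTruthNeuron:
    """Generator-side counterpart of the fitted tuning models.

    ``preferred_tilt`` / ``preferred_slant`` hold one preference per
    distance (cross-distance jitter already applied); ``gain_per_distance``
    sets the response amplitude at each distance (the distance "gain
    profile" of a pose-tuned neuron).  ``lambda1 <= -lambda2_mag <= 0``
    are the Bingham concentration parameters, shared across distance.
    """

    preferred_tilt: Sequence[float]
    preferred_slant: Sequence[float]
    lambda1: float = -2.0
    lambda2_mag: float = 1.0
    phi: float = 90.0
    gain_per_distance: Sequence[float] = (30.0, 40.0, 25.0, 15.0)
    baseline: float = 10.0
    cross_distance_jitter: float = 0.0
    visual_latency: float = 46.0
    choice_modulation: Optional[dict] = None
    saccade_modulation: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.baseline < 0 or any(g < 0 for g in self.gain_per_distance):
            raise ValueError("rates must be non-negative")
        if self.cross_distance_jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.lambda1 > 0 or self.lambda2_mag < 0:
            raise ValueError("need lambda1 <= 0 and lambda2_mag >= 0")
        if self.choice_modulation is not None:
            onset = self.choice_modulation.get("onset_ms", 190.0)
            if onset < 0:
                raise ValueError("choice-modulation onset must lie in the stimulus epoch")

    def rate(self, condition: StimulusCondition, design: TaskDesign) -> float:
        """Mean visual firing rate (spikes/s) for one pose."""
        j = list(design.distances).index(condition.distance)
        n = tilt_slant_to_normal(condition.tilt, condition.slant)
        frame = bingham_frame(self.preferred_tilt[j], self.preferred_slant[j], self.phi)
        c1 = float(n @ frame[1])
        c2 = float(n @ frame[2])
        r = self.baseline + self.gain_per_distance[j] * math.exp(
            self.lambda1 * c1**2 - self.lambda2_mag * c2**2)
        if r < 0:
            raise ValueError("inconsistent truth parameters give negative rate")
        return r

    def choice_rate_bonus(self, choice_deg: float) -> float:
        """Extra rate (spikes/s) after choice-modulation onset."""
        if self.choice_modulation is None:
            return 0.0
        m = self.choice_modulation
        kappa = m.get("kappa", 4.7)
        delta = np.deg2rad(choice_deg - m["preferred_choice"])
        return m["depth"] * math.exp(kappa * (math.cos(delta) - 1.0))

    def saccade_rate_peak(self, direction_deg: float) -> float:
        """Peak pre-saccadic rate increment (spikes/s) for a direction."""
        if self.saccade_modulation is None:
            return 0.0
        m = self.saccade_modulation
        kappa = m.get("kappa", 6.3)
        delta = np.deg2rad(direction_deg - m["preferred_direction"])
        return m["depth"] * math.exp(kappa * (math.cos(delta) - 1.0))


def _jitter_normal(n: np.ndarray, tangent: np.ndarray, angle_deg: float) -> np.ndarray:
    """Walk ``angle_deg`` along the great circle through ``n`` in the
    ``tangent`` direction, reflecting into the z >= 0 hemisphere (the
    Bingham surface is antipodally symmetric, so the reflection leaves
    the tuning curve unchanged)."""
    if angle_deg == 0:
        return n
    a = np.deg2rad(angle_deg)
    out = math.cos(a) * n + math.sin(a) * tangent
    if out[2] < 0:
        out = -out
    return out


def make_ground_truth(
    design: TaskDesign,
    rng: np.random.Generator,
    cross_distance_jitter: float = 0.0,
    baseline: float = 10.0,
    peak_gain: float = 40.0,
    lambda1: float = -2.0,
    lambda2_mag: float = 1.0,
    phi: float = 90.0,
    choice_modulation: Optional[dict] = None,
    saccade_modulation: Optional[dict] = None,
    visual_latency: float = 46.0,
) -> GroundTruthNeuron:
    """Draw a random neuron: uniform preferred tilt, slant in [15, 60],
    distance gain profile peaking at the fixation distance, and
    per-distance preferences scattered around the base preference.

    The scatter model walks along one random great-circle direction per
    neuron, each distance by an excursion uniform in
    [0, cross_distance_jitter] degrees, so the pairwise preference
    scatter (and hence the true distance tolerance) is controlled
    monotonically by the jitter knob."""
    base_tilt = float(rng.uniform(0.0, 360.0))
    base_slant = float(rng.uniform(15.0, 60.0))
    n0 = tilt_slant_to_normal(base_tilt, base_slant)
    tangent = rng.normal(size=3)
    tangent -= (tangent @ n0) * n0
    tangent /= np.linalg.norm(tangent)
    tilts, slants = [], []
    for _ in design.distances:
        a = float(rng.uniform(0.0, cross_distance_jitter)) \
            if cross_distance_jitter > 0 else 0.0
        n = _jitter_normal(n0, tangent, a)
        slant = float(np.rad2deg(np.arccos(np.clip(n[2], -1, 1))))
        tilt = float(np.rad2deg(np.arctan2(n[1], n[0])) % 360.0)
        tilts.append(tilt)
        slants.append(slant)
    # inverted-U gain profile centred on the fixation distance
    d = np.asarray(design.distances, dtype=float)
    rel = np.abs(d - design.fixation_distance)
    gains = peak_gain * (1.0 - 0.6 * rel / max(rel.max(), 1.0))
    return GroundTruthNeuron(
        preferred_tilt=tilts, preferred_slant=slants,
        lambda1=lambda1, lambda2_mag=lambda2_mag, phi=phi,
        gain_per_distance=list(gains), baseline=baseline,
        cross_distance_jitter=cross_distance_jitter,
        visual_latency=visual_latency,
        choice_modulation=choice_modulation,
        saccade_modulation=saccade_modulation,
    )


# ----------------------------------------------------------------------
# Spike generation helpers
# ----------------------------------------------------------------------

def _spikes_from_profile(rate_matrix: np.ndarray, t0: float,
                         rng: np.random.Generator) -> list:
    """Inhomogeneous Poisson draws from per-trial 1 ms rate profiles
    (spikes/s); returns one sorted time array per trial, times relative
    to the profile start ``t0`` + bin centre."""
    counts = rng.poisson(rate_matrix / 1000.0)
    out = []
    for row in counts:
        idx = np.nonzero(row)[0]
        if idx.size == 0:
            out.append(np.empty(0))
            continue
        times = np.repeat(idx.astype(float) + 0.5 + t0, row[idx])
        out.append(times)
    return out


# ----------------------------------------------------------------------
# Single neuron / population simulation
# ----------------------------------------------------------------------

def _tilt_trial_scaffold(design: TaskDesign, n_blocks: int,
                         rng: np.random.Generator,
                         fp_choice_probs: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Session-level tilt-task trial list shared by simultaneously
    recorded neurons: conditions, blocks, and frontoparallel choices."""
    rows = []
    dirs = design.choice_directions
    if fp_choice_probs is None:
        fp_choice_probs = np.full(len(dirs), 1.0 / len(dirs))
    for b in range(n_blocks):
        for cond in block_trial_conditions(design):
            if cond.frontoparallel:
                choice = float(rng.choice(dirs, p=fp_choice_probs))
                rows.append((b, np.nan, 0.0, cond.distance, choice))
            else:
                rows.append((b, cond.tilt, cond.slant, cond.distance, np.nan))
    return pd.DataFrame(rows, columns=["block", "tilt", "slant", "distance_cm",
                                       "reported_tilt"])


def simulate_neuron(
    truth: GroundTruthNeuron,
    design: TaskDesign,
    n_blocks: int,
    seed: Optional[int] = None,
    spike_times: str = "all",
    rng: Optional[np.random.Generator] = None,
    scaffold: Optional[pd.DataFrame] = None,
    shared_gains: Optional[np.ndarray] = None,
    saccade_scaffold: Optional[pd.DataFrame] = None,
    neuron_id: str = "sim0",
    choice_shape: str = "step",
) -> NeuronDataset:
    """Simulate all trials of one neuron across both tasks.

    ``spike_times`` selects which trials get full 1 ms spike trains:
    ``"all"``, ``"frontoparallel"`` (tilt-task FP + saccade trials), or
    ``"none"`` (Poisson counts only; fastest).  With a fixed ``seed``
    the output is bit-identical across calls.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if scaffold is None:
        scaffold = _tilt_trial_scaffold(design, n_blocks, rng)
    n_tilt = len(scaffold)
    if shared_gains is None:
        shared_gains = np.ones(n_tilt)

    lat = truth.visual_latency
    dur = design.stimulus_duration
    fix = design.fixation_duration
    window = (lat, dur)
    win_len_s = (dur - lat) / 1000.0

    # mean visual rate per trial
    cond_rate = np.empty(n_tilt)
    for i, row in enumerate(scaffold.itertuples(index=False)):
        tilt = None if np.isnan(row.tilt) else float(row.tilt)
        cond = StimulusCondition(tilt, float(row.slant), float(row.distance_cm))
        cond_rate[i] = truth.rate(cond, design)

    fp_mask = scaffold["slant"].to_numpy() == 0.0
    choice_bonus = np.zeros(n_tilt)
    if truth.choice_modulation is not None:
        for i in np.nonzero(fp_mask)[0]:
            choice_bonus[i] = truth.choice_rate_bonus(
                float(scaffold["reported_tilt"].iloc[i]))

    want_times = np.zeros(n_tilt, dtype=bool)
    if spike_times == "all":
        want_times[:] = True
    elif spike_times == "frontoparallel":
        want_times = fp_mask.copy()
    elif spike_times != "none":
        raise ValueError("spike_times must be 'all', 'frontoparallel' or 'none'")

    onset = (truth.choice_modulation or {}).get("onset_ms", 190.0)
    t_grid = np.arange(-fix, dur)  # 1 ms bins, left edges
    times_list: List[Optional[np.ndarray]] = [None] * n_tilt
    counts = np.empty(n_tilt)

    idx_times = np.nonzero(want_times)[0]
    if idx_times.size:
        profiles = np.empty((idx_times.size, t_grid.size))
        for k, i in enumerate(idx_times):
            prof = np.full(t_grid.size, truth.baseline)
            vis = t_grid >= lat
            prof[vis] = cond_rate[i]
            if choice_bonus[i] != 0.0:
                if choice_shape == "step":
                    prof[t_grid >= onset] += choice_bonus[i]
                else:  # linear ramp from onset to stimulus end
                    ramp = np.clip((t_grid - onset) / max(dur - onset, 1.0), 0, 1)
                    prof += choice_bonus[i] * ramp
            profiles[k] = prof * shared_gains[i]
        spikes = _spikes_from_profile(profiles, -fix, rng)
        for k, i in enumerate(idx_times):
            times_list[i] = spikes[k]
            counts[i] = np.count_nonzero(
                (spikes[k] >= window[0]) & (spikes[k] < window[1]))

    idx_fast = np.nonzero(~want_times)[0]
    if idx_fast.size:
        # choice bonus applies over [onset, dur]; fold its window share
        # into the mean count over the response window
        frac = max(dur - max(onset, lat), 0.0) / (dur - lat)
        mean = (cond_rate[idx_fast] + choice_bonus[idx_fast] * frac) \
            * win_len_s * shared_gains[idx_fast]
        counts[idx_fast] = rng.poisson(mean)

    tilt_df = pd.DataFrame({
        "neuron_id": neuron_id,
        "task": "tilt",
        "block": scaffold["block"].to_numpy(),
        "tilt": scaffold["tilt"].to_numpy(),
        "slant": scaffold["slant"].to_numpy(),
        "distance_cm": scaffold["distance_cm"].to_numpy(),
        "spike_count": counts.astype(int),
        "reported_tilt": scaffold["reported_tilt"].to_numpy(),
        "saccade_dir": np.nan,
        "saccade_latency_ms": np.nan,
    })

    # ------------------------------------------------------------------
    # saccade task
    # ------------------------------------------------------------------
    sacc_window = (-150.0, 0.0)
    sacc_frames = []
    if design.saccade_repeats > 0:
        if saccade_scaffold is None:
            saccade_scaffold = _saccade_trial_scaffold(design, n_blocks, rng)
        ns = len(saccade_scaffold)
        sacc_times: List[Optional[np.ndarray]] = [None] * ns
        sg = np.arange(-600.0, 100.0)  # relative to saccade initiation
        want = spike_times in ("all", "frontoparallel")
        peak = np.array([
            truth.saccade_rate_peak(d)
            for d in saccade_scaffold["saccade_dir"].to_numpy()
        ])
        lead = (truth.saccade_modulation or {}).get("lead_ms", 108.0)
        coalesce = (truth.saccade_modulation or {}).get("coalesce_ms", -59.0)
        if want:
            profiles = np.empty((ns, sg.size))
            for i in range(ns):
                prof = np.full(sg.size, truth.baseline)
                if peak[i] > 0:
                    ramp = np.clip((sg + lead) / max(lead + coalesce, 1.0), 0, 1)
                    prof = prof + peak[i] * ramp
                profiles[i] = prof
            spikes = _spikes_from_profile(profiles, -600.0, rng)
            sc = np.empty(ns)
            for i in range(ns):
                sacc_times[i] = spikes[i]
                sc[i] = np.count_nonzero((spikes[i] >= sacc_window[0])
                                         & (spikes[i] < sacc_window[1]))
        else:
            # mean count over the saccade window from the same profile
            w = (sg >= sacc_window[0]) & (sg < sacc_window[1])
            sc = np.empty(ns)
            for i in range(ns):
                prof = np.full(sg.size, truth.baseline)
                if peak[i] > 0:
                    ramp = np.clip((sg + lead) / max(lead + coalesce, 1.0), 0, 1)
                    prof = prof + peak[i] * ramp
                sc[i] = rng.poisson(prof[w].sum() / 1000.0)
        sacc_df = pd.DataFrame({
            "neuron_id": neuron_id,
            "task": "saccade",
            "block": saccade_scaffold["block"].to_numpy(),
            "tilt": np.nan,
            "slant": np.nan,
            "distance_cm": np.nan,
            "spike_count": sc.astype(int),
            "reported_tilt": np.nan,
            "saccade_dir": saccade_scaffold["saccade_dir"].to_numpy(),
            "saccade_latency_ms": saccade_scaffold["saccade_latency_ms"].to_numpy(),
        })
        sacc_frames.append((sacc_df, sacc_times))

    frames = [tilt_df] + [f for f, _ in sacc_frames]
    trials = pd.concat(frames, ignore_index=True)
    all_times = times_list + (sacc_frames[0][1] if sacc_frames else [])
    has_any_times = any(t is not None for t in all_times)
    return NeuronDataset(
        neuron_id=neuron_id, design=design, trials=trials,
        spike_times=all_times if has_any_times else None,
        response_window=window, saccade_window=sacc_window,
        truth=asdict(truth),
    )


def _saccade_trial_scaffold(design: TaskDesign, n_blocks: int,
                            rng: np.random.Generator,
                            latency: Optional[dict] = None) -> pd.DataFrame:
    latency = latency or {"shift": 100.0, "shape": 2.0, "scale": 30.0}
    rows = []
    for b in range(n_blocks):
        for _ in range(design.saccade_repeats):
            for d in design.choice_directions:
                lat = latency["shift"] + rng.gamma(latency["shape"], latency["scale"])
                rows.append((b, float(d), float(np.round(lat))))
    return pd.DataFrame(rows, columns=["block", "saccade_dir", "saccade_latency_ms"])


def simulate_population(
    truths: Sequence[GroundTruthNeuron],
    design: TaskDesign,
    n_blocks: int,
    shared_gain_sd: float = 0.0,
    seed: Optional[int] = None,
    spike_times: str = "none",
) -> List[NeuronDataset]:
    """Simulate simultaneously recorded neurons sharing trials, choices
    and a per-trial multiplicative lognormal gain (mean one, SD
    ``shared_gain_sd``), which induces positive noise correlations.
    ``shared_gain_sd = 0`` gives independent neurons."""
    if shared_gain_sd < 0:
        raise ValueError("shared_gain_sd must be >= 0")
    rng = np.random.default_rng(seed)
    scaffold = _tilt_trial_scaffold(design, n_blocks, rng)
    saccade_scaffold = _saccade_trial_scaffold(design, n_blocks, rng) \
        if design.saccade_repeats > 0 else None
    n = len(scaffold)
    if shared_gain_sd > 0:
        sigma = math.sqrt(math.log(1.0 + shared_gain_sd**2))
        gains = rng.lognormal(-sigma**2 / 2.0, sigma, size=n)
    else:
        gains = np.ones(n)
    out = []
    for i, truth in enumerate(truths):
        out.append(simulate_neuron(
            truth, design, n_blocks, rng=rng, scaffold=scaffold,
            shared_gains=gains, saccade_scaffold=saccade_scaffold,
            spike_times=spike_times, neuron_id=f"sim{i}",
        ))
    return out


def shared_gain_sd_for_noise_r(
    truths: Sequence[GroundTruthNeuron],
    design: TaskDesign,
    target_r: float,
) -> float:
    """Shared-gain SD whose predicted mean pairwise noise correlation
    equals ``target_r``.

    Under Poisson counts with a mean-one multiplicative gain of variance
    v, two neurons with per-condition mean counts (m1, m2) have
    per-condition correlation m1 m2 v / sqrt((m1 + m1^2 v)(m2 + m2^2 v));
    the pooled estimate averages this over conditions and pairs.
    """
    if not (0.0 < target_r < 1.0):
        raise ValueError("target_r must be in (0, 1)")
    lat = truths[0].visual_latency
    win_s = (design.stimulus_duration - lat) / 1000.0
    conds = enumerate_conditions(design)
    means = np.array([[t.rate(c, design) * win_s for c in conds] for t in truths])

    def mean_corr(v: float) -> float:
        total, count = 0.0, 0
        for a in range(len(truths)):
            for b in range(a + 1, len(truths)):
                m1, m2 = means[a], means[b]
                r = (m1 * m2 * v) / np.sqrt((m1 + m1**2 * v) * (m2 + m2**2 * v))
                total += r.mean()
                count += 1
        return total / count

    v = optimize.brentq(lambda v: mean_corr(v) - target_r, 1e-8, 10.0)
    return float(np.sqrt(v))


# ----------------------------------------------------------------------
# Behavior
# ----------------------------------------------------------------------

KappaMap = Union[float, Dict[Tuple[float, float], float], Callable[[float, float], float]]


def _kappa_for(kappa_map: KappaMap, slant: float, distance: float) -> float:
    if callable(kappa_map):
        return float(kappa_map(slant, distance))
    if isinstance(kappa_map, dict):
        return float(kappa_map[(slant, distance)])
    return float(kappa_map)


def simulate_behavior(
    kappa_map: KappaMap,
    design: TaskDesign,
    n_trials: int,
    seed: Optional[int] = None,
    include_frontoparallel: bool = False,
    fp_choice_probs: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Simulate tilt-discrimination reports.

    The reported tilt is the presented tilt plus a von Mises error with
    the condition's concentration, snapped to the nearest of the eight
    choice directions.  Frontoparallel trials (if included) get choices
    from ``fp_choice_probs`` (default uniform).  Returns a trial table
    with columns tilt, slant, distance_cm, reported_tilt.
    """
    rng = np.random.default_rng(seed)
    conds = [c for c in enumerate_conditions(design)
             if include_frontoparallel or not c.frontoparallel]
    dirs = np.asarray(design.choice_directions)
    step = 360.0 / len(dirs)
    if fp_choice_probs is None:
        fp_choice_probs = np.full(len(dirs), 1.0 / len(dirs))
    picks = rng.integers(0, len(conds), size=n_trials)
    tilt = np.empty(n_trials)
    slant = np.empty(n_trials)
    dist = np.empty(n_trials)
    reported = np.empty(n_trials)
    for i, k in enumerate(picks):
        c = conds[k]
        slant[i] = c.slant
        dist[i] = c.distance
        if c.frontoparallel:
            tilt[i] = np.nan
            reported[i] = rng.choice(dirs, p=fp_choice_probs)
        else:
            tilt[i] = c.tilt
            kappa = _kappa_for(kappa_map, c.slant, c.distance)
            err = float(np.rad2deg(rng.vonmises(0.0, kappa)))
            reported[i] = (np.round((c.tilt + err) / step) * step) % 360.0
    return pd.DataFrame({"tilt": tilt, "slant": slant, "distance_cm": dist,
                         "reported_tilt": reported})


def percent_correct(trials: pd.DataFrame) -> float:
    """Percent of non-frontoparallel trials whose reported tilt equals
    the presented tilt."""
    t = trials[trials["slant"] > 0]
    if len(t) == 0:
        raise ValueError("no non-frontoparallel trials")
    return 100.0 * float(np.mean(t["reported_tilt"] == t["tilt"]))


# ----------------------------------------------------------------------
# Saccade trials
# ----------------------------------------------------------------------

def simulate_saccade_trials(
    latency_distribution: Optional[dict] = None,
    tuning: Optional[dict] = None,
    activity_model: Optional[dict] = None,
    n_trials: int = 256,
    seed: Optional[int] = None,
    design: Optional[TaskDesign] = None,
    with_eye_traces: bool = True,
    directions: Optional[Sequence[float]] = None,
) -> NeuronDataset:
    """Simulate one neuron's visually guided saccade trials.

    ``latency_distribution``: shifted gamma ``{shift, shape, scale}``
    (ms); ``tuning``: ``{preferred_direction, kappa, baseline, depth}``
    (spikes/s); ``activity_model``: onset-vs-latency rule
    ``{onset_frac, coalesce_ms}`` — pre-saccadic activity starts at
    ``-onset_frac * latency`` relative to the saccade and ramps linearly
    to its peak at ``coalesce_ms``, so longer-latency trials start
    earlier and grow more slowly (the inverse growth-rate/latency rule).
    Eye-velocity traces cross 150 deg/s exactly at the latency.
    ``directions`` restricts the target set (default: all eight).
    """
    rng = np.random.default_rng(seed)
    design = design or TaskDesign()
    latency_distribution = latency_distribution or \
        {"shift": 100.0, "shape": 2.0, "scale": 30.0}
    if latency_distribution["shift"] <= 0:
        raise ValueError("latency support must be positive")
    tuning = tuning or {"preferred_direction": 0.0, "kappa": 6.3,
                        "baseline": 10.0, "depth": 40.0}
    activity_model = activity_model or {"onset_frac": 0.8, "coalesce_ms": -59.0}

    dirs = tuple(directions) if directions is not None else design.choice_directions
    n_dirs = len(dirs)
    direction = np.array([dirs[i % n_dirs] for i in range(n_trials)])
    lat = latency_distribution["shift"] + rng.gamma(
        latency_distribution["shape"], latency_distribution["scale"], size=n_trials)
    lat = np.round(lat)

    kappa = tuning.get("kappa", 6.3)
    pref = tuning["preferred_direction"]
    base = tuning["baseline"]
    depth = tuning["depth"]
    peak = depth * np.exp(kappa * (np.cos(np.deg2rad(direction - pref)) - 1.0))

    sg = np.arange(-600.0, 100.0)
    coalesce = activity_model.get("coalesce_ms", -59.0)
    onset_frac = activity_model.get("onset_frac", 0.8)
    profiles = np.empty((n_trials, sg.size))
    for i in range(n_trials):
        start = -onset_frac * lat[i]
        denom = max(coalesce - start, 1.0)
        ramp = np.clip((sg - start) / denom, 0.0, 1.0)
        profiles[i] = base + peak[i] * ramp
    spikes = _spikes_from_profile(profiles, -600.0, rng)

    window = (-150.0, 0.0)
    counts = np.array([
        np.count_nonzero((s >= window[0]) & (s < window[1])) for s in spikes])

    eye = None
    if with_eye_traces:
        eye = []
        for L in lat:
            T = int(L) + 100
            v = np.zeros(T)
            t = np.arange(T, dtype=float)
            rise = t >= L
            v[rise] = 150.0 + 10.0 * (t[rise] - L)
            eye.append(np.minimum(v, 400.0))

    trials = pd.DataFrame({
        "neuron_id": "sacc0",
        "task": "saccade",
        "block": np.arange(n_trials) // (n_dirs * max(design.saccade_repeats, 1)),
        "tilt": np.nan,
        "slant": np.nan,
        "distance_cm": np.nan,
        "spike_count": counts.astype(int),
        "reported_tilt": np.nan,
        "saccade_dir": direction,
        "saccade_latency_ms": lat,
    })
    ds = NeuronDataset(
        neuron_id="sacc0", design=design, trials=trials,
        spike_times=list(spikes), response_window=(46.0, design.stimulus_duration),
        saccade_window=window,
        truth={"latency_distribution": latency_distribution, "tuning": tuning,
               "activity_model": activity_model},
    )
    ds.eye_velocity = eye  # per-trial deg/s traces sampled at 1 kHz
    return ds
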