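"""Pairwise correlations and sensorimotor-association statistics.

Noise correlations quantify trial-by-trial shared variability between
simultaneously recorded neurons after removing stimulus-driven response
differences: per-pose outliers (> 3 SD from the condition mean) are
removed, the remaining counts are z-scored separately per pose, and a
single Pearson correlation is pooled across all trials.  Signal
correlations compare the two mean tuning vectors across the 132 poses.

The association analyses relate each neuron's principal surface tilt,
choice preference and saccade-direction preference.  Wrapped circular
preference differences are summarised per choice-flag split by their
circular variance, a Rayleigh uniformity test and a circular-median
test against 0 deg; the moderation regression asks whether the effect
of distance tolerance on the |tilt - saccade preference| difference
depends on the presence of choice-related activity (the
tolerance x choice interaction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import wrap_angle
from .circstats import (circ_median_test, circ_variance,
                        concentration_difference_test, rayleigh_test)

__all__ = [
    "PairCorrelation",
    "noise_correlation",
    "type2_regression",
    "AssociationRecord",
    "preference_difference_analysis",
    "moderation_regression",
]


@dataclass
class PairCorrelation:
    noise_r: float
    signal_r: float
    n_trials_used: int
    n_outliers_removed: int


def _condition_counts(data) -> Dict[tuple, np.ndarray]:
    trials = data.tilt_trials()
    tilt = trials["tilt"].to_numpy(dtype=float)
    slant = trials["slant"].to_numpy(dtype=float)
    dist = trials["distance_cm"].to_numpy(dtype=float)
    counts = trials["spike_count"].to_numpy(dtype=float)
    keys = list(zip(np.where(np.isnan(tilt), -1.0, tilt), slant, dist))
    out: Dict[tuple, list] = {}
    for k, c in zip(keys, counts):
        out.setdefault(k, []).append(c)
    return {k: np.asarray(v) for k, v in out.items()}


def noise_correlation(data_a, data_b, outlier_sd: float = 3.0) -> PairCorrelation:
    """Noise and signal correlation for a simultaneously recorded pair.

    Both datasets must share the same trial schedule (same scaffold).
    """
    ca = _condition_counts(data_a)
    cb = _condition_counts(data_b)
    if set(ca) != set(cb):
        raise ValueError("pair must share the same conditions")
    za, zb = [], []
    mean_a, mean_b = [], []
    n_outliers = 0
    usable_conditions = 0
    for k in ca:
        x, y = ca[k], cb[k]
        if x.size != y.size:
            raise ValueError("pair must share trials per condition")
        keep = np.ones(x.size, dtype=bool)
        for v in (x, y):
            sd = v.std(ddof=0)
            if sd > 0:
                keep &= np.abs(v - v.mean()) <= outlier_sd * sd
        n_outliers += int(np.sum(~keep))
        x, y = x[keep], y[keep]
        if x.size >= 2:
            usable_conditions += 1
            sx = x.std(ddof=0)
            sy = y.std(ddof=0)
            za.append((x - x.mean()) / sx if sx > 0 else np.zeros_like(x))
            zb.append((y - y.mean()) / sy if sy > 0 else np.zeros_like(y))
        mean_a.append(x.mean() if x.size else np.nan)
        mean_b.append(y.mean() if y.size else np.nan)
    if usable_conditions < 2:
        raise ValueError("need >= 2 conditions with >= 2 trials")
    za = np.concatenate(za)
    zb = np.concatenate(zb)
    if np.std(za) > 0 and np.std(zb) > 0:
        noise_r = float(stats.pearsonr(za, zb)[0])
    else:
        noise_r = 1.0 if np.allclose(za, zb) else np.nan
    ma = np.asarray(mean_a)
    mb = np.asarray(mean_b)
    ok = np.isfinite(ma) & np.isfinite(mb)
    signal_r = float(stats.pearsonr(ma[ok], mb[ok])[0]) \
        if np.std(ma[ok]) > 0 and np.std(mb[ok]) > 0 else np.nan
    return PairCorrelation(noise_r, signal_r, int(za.size), n_outliers)


def type2_regression(x, y) -> Tuple[float, float]:
    """Standardised major-axis (type II) regression.

    slope = sign(r) * SD(y) / SD(x), intercept through the means.
    Symmetric: swapping x and y inverts the slope exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 pairs")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("constant input")
    r = stats.pearsonr(x, y)[0]
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return float(slope), intercept


# ----------------------------------------------------------------------
# Sensorimotor associations
# ----------------------------------------------------------------------

@dataclass
class AssociationRecord:
    neuron_id: str
    principal_tilt: float
    tolerance: float
    choice_pref: Optional[float] = None
    saccade_pref: Optional[float] = None
    has_choice: bool = False
    has_saccade: bool = False


_PAIR_FIELDS = {
    "tilt-choice": ("principal_tilt", "choice_pref"),
    "tilt-saccade": ("principal_tilt", "saccade_pref"),
    "choice-saccade": ("choice_pref", "saccade_pref"),
}


def _pair_differences(records: Sequence[AssociationRecord], pair: str) -> np.ndarray:
    fa, fb = _PAIR_FIELDS[pair]
    diffs = []
    for r in records:
        a, b = getattr(r, fa), getattr(r, fb)
        if a is None or b is None:
            continue
        diffs.append(wrap_angle(a - b))
    return np.asarray(diffs, dtype=float)


def preference_difference_analysis(
    records: Sequence[AssociationRecord],
    pair: str = "tilt-saccade",
    split_by_choice_flag: bool = True,
) -> dict:
    """Wrapped preference-difference distributions with circular tests.

    Returns per-split (choice-flagged vs not, or 'all') the differences,
    circular variance, Rayleigh uniformity p, and circular-median-vs-0
    p, plus the two-sample concentration-difference p between splits.
    """
    if split_by_choice_flag:
        splits = {
            "with_choice": [r for r in records if r.has_choice],
            "without_choice": [r for r in records if not r.has_choice],
        }
    else:
        splits = {"all": list(records)}
    out: dict = {"pair": pair, "splits": {}}
    for name, recs in splits.items():
        d = _pair_differences(recs, pair)
        if d.size < 10:
            raise ValueError(f"need >= 10 records in split '{name}', got {d.size}")
        out["splits"][name] = {
            "differences": d,
            "n": int(d.size),
            "cv": circ_variance(d),
            "rayleigh_p": rayleigh_test(d),
            "median_vs_zero_p": circ_median_test(d, 0.0),
        }
    if split_by_choice_flag:
        out["concentration_difference_p"] = concentration_difference_test(
            out["splits"]["with_choice"]["differences"],
            out["splits"]["without_choice"]["differences"])
    return out


def moderation_regression(records: Sequence[AssociationRecord],
                          pair: str = "tilt-saccade") -> dict:
    """OLS of |wrapped preference difference| on tolerance, the choice
    flag, and their interaction.

    Returns coefficients and p-values for intercept, tolerance slope,
    choice-flag effect and the tolerance x choice interaction, plus the
    per-group tolerance slopes (slope and slope + interaction).
    """
    import statsmodels.api as sm

    rows = []
    fa, fb = _PAIR_FIELDS[pair]
    for r in records:
        a, b = getattr(r, fa), getattr(r, fb)
        if a is None or b is None or not np.isfinite(r.tolerance):
            continue
        rows.append((abs(wrap_angle(a - b)), r.tolerance, float(r.has_choice)))
    df = pd.DataFrame(rows, columns=["absdiff", "tolerance", "choice"])
    if df["choice"].nunique() < 2:
        raise ValueError("both choice-flag groups must be non-empty")
    if df["tolerance"].nunique() < 2:
        raise ValueError("tolerance must vary")
    X = sm.add_constant(np.column_stack([
        df["tolerance"], df["choice"], df["tolerance"] * df["choice"]]))
    fit = sm.OLS(df["absdiff"], X).fit()
    names = ["intercept", "tolerance", "choice", "interaction"]
    coef = dict(zip(names, np.asarray(fit.params, dtype=float)))
    pvals = dict(zip(names, np.asarray(fit.pvalues, dtype=float)))
    ci = np.asarray(fit.conf_int(), dtype=float)
    return {
        "coef": coef,
        "p": pvals,
        "conf_int": {n: (float(ci[i, 0]), float(ci[i, 1]))
                     for i, n in enumerate(names)},
        "slope_without_choice": float(coef["tolerance"]),
        "slope_with_choice": float(coef["tolerance"] + coef["interaction"]),
        "n": int(len(df)),
    }
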