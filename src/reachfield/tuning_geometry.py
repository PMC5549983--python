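"""Preferred directions, wrapped angular differences, and circular statistics.

The preferred direction (PD) of a neuron in an epoch is the sampled reach
direction with the maximal mean firing rate, pooling amplitudes.  The
direction of strongest amplitude modulation is the one with the smallest
direction-wise amplitude-t-test p-value; their wrapped difference is the
neuron's delta-PD for that epoch, kept in (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .response_field import midrange_normalize
from .selectivity import directionwise_amplitude_tests
from .synthetic_data import EPOCHS, rate_column
from .task_geometry import wrap_angle_deg


def preferred_direction(trials: pd.DataFrame, epoch: str) -> tuple[float, dict]:
    """Direction (deg) with maximal mean rate in ``epoch``, pooling amplitudes.

    Ties are broken toward the smallest angle and flagged.  Returns
    ``(direction_deg, flags)``.
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    col = rate_column(epoch)
    means = trials.groupby("direction_deg")[col].mean()
    best = means.max()
    winners = sorted(means.index[means == best])
    return float(winners[0]), {"tie": len(winners) > 1}


def delta_pd(
    trials: pd.DataFrame,
    epoch: str,
    alpha: float = 0.05,
    mode: str = "best",
) -> tuple[float | None, dict]:
    """Wrapped angular difference between the direction of strongest amplitude
    modulation and the preferred direction, for one neuron and epoch.

    Only neurons with at least one direction significant at ``alpha`` in the
    direction-wise amplitude t-tests are included; others are filtered (the
    returned value is None with ``included=False``).  ``mode="best"`` uses
    the minimal-p direction; ``mode="circular_average"`` uses the circular
    mean of all significant directions.
    """
    if mode not in ("best", "circular_average"):
        raise ValueError(f"unknown mode {mode!r}")
    tests = directionwise_amplitude_tests(trials, epoch, alpha=alpha)
    significant = [d for d, p in tests["p_by_direction"].items() if p < alpha]
    if not significant:
        return None, {"included": False, "reason": "no direction with significant modulation"}
    if mode == "best":
        mod_direction = tests["best_direction"]
    else:
        mod_direction, _ = circular_mean_se(np.array(significant))
    pd_deg, pd_flags = preferred_direction(trials, epoch)
    return float(wrap_angle_deg(mod_direction - pd_deg)), {
        "included": True,
        "preferred_direction": pd_deg,
        "modulation_direction": float(mod_direction),
        "pd_tie": pd_flags["tie"],
    }


def rayleigh_test(angles_deg: Sequence[float] | np.ndarray) -> dict:
    """Rayleigh test of circular uniformity.

    Returns the mean resultant length ``R_bar`` and the p-value from the
    standard approximation (Zar 1999, eq. 27.4, as used in circular-statistics
    toolboxes):

        p = exp( sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n) ),   R = n * R_bar.

    Requires n >= 4 for the approximation to hold.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    n = len(a)
    if n < 4:
        raise ValueError(f"Rayleigh test needs n >= 4, got {n}")
    C, S = np.cos(a).sum(), np.sin(a).sum()
    R = math.hypot(C, S)
    r_bar = R / n
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - R * R)) - (1.0 + 2.0 * n))
    return {"r_bar": float(r_bar), "p": float(min(p, 1.0)), "n": n, "z": float(n * r_bar**2)}


def circular_mean_se(angles_deg: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Circular mean and standard error of a sample of angles, in degrees.

    Mean is ``atan2(sum sin, sum cos)``.  The SE uses the circular dispersion
    of Fisher (1993, eq. 2.28/4.21): ``delta = (1 - rho2) / (2 * R_bar^2)``
    with ``rho2`` the mean resultant length of the doubled angles, and
    ``SE = sqrt(delta / n)`` (radians, converted to degrees).  Undefined when
    the resultant vanishes.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    n = len(a)
    if n < 2:
        raise ValueError("need n >= 2 angles")
    C, S = np.cos(a).mean(), np.sin(a).mean()
    r_bar = math.hypot(C, S)
    if r_bar < 1e-12:
        raise ValueError("resultant length is 0; circular mean undefined")
    mean_deg = math.degrees(math.atan2(S, C)) % 360.0
    rho2 = math.hypot(np.cos(2 * a).mean(), np.sin(2 * a).mean())
    dispersion = (1.0 - rho2) / (2.0 * r_bar**2)
    se_deg = math.degrees(math.sqrt(max(dispersion, 0.0) / n))
    return mean_deg, se_deg


@dataclass
class DirectionStats:
    """Per-neuron preferred-direction geometry across epochs."""

    neuron_id: int
    preferred_direction: dict[str, float]
    delta_pd: dict[str, float | None]
    modulation_direction: dict[str, float | None]


def direction_stats(trials: pd.DataFrame, alpha: float = 0.05, mode: str = "best") -> DirectionStats:
    """Compute PD and delta-PD for every epoch of one neuron's trials."""
    neuron_id = int(trials["neuron_id"].iloc[0])
    pds, dpds, mods = {}, {}, {}
    for epoch in EPOCHS:
        pds[epoch], _ = preferred_direction(trials, epoch)
        dpd, flags = delta_pd(trials, epoch, alpha=alpha, mode=mode)
        dpds[epoch] = dpd
        mods[epoch] = flags.get("modulation_direction")
    return DirectionStats(
        neuron_id=neuron_id, preferred_direction=pds, delta_pd=dpds, modulation_direction=mods
    )


def population_delta_pd_summary(
    trials: pd.DataFrame, alpha: float = 0.05, mode: str = "best"
) -> dict:
    """Pool delta-PD over neurons and epochs; Rayleigh test + circular mean.

    Mirrors the population analysis of amplitude-modulation bias toward the
    preferred direction: per epoch and pooled, the distribution of delta-PD
    over included neurons is tested for circular uniformity and summarized by
    its circular mean +- SE.
    """
    per_epoch: dict[str, list[float]] = {e: [] for e in EPOCHS}
    for _, grp in trials.groupby("neuron_id"):
        for epoch in EPOCHS:
            dpd, flags = delta_pd(grp, epoch, alpha=alpha, mode=mode)
            if flags["included"]:
                per_epoch[epoch].append(dpd)
    pooled = [v for vals in per_epoch.values() for v in vals]
    out: dict = {"per_epoch": {}, "n_pooled": len(pooled)}
    for epoch, vals in per_epoch.items():
        entry: dict = {"n": len(vals), "values": vals}
        if len(vals) >= 4:
            entry.update(rayleigh_test(vals))
            mean, se = circular_mean_se(vals)
            entry["circular_mean"] = wrap_angle_deg(mean)
            entry["circular_se"] = se
        out["per_epoch"][epoch] = entry
    if len(pooled) >= 4:
        out["pooled"] = rayleigh_test(pooled)
        mean, se = circular_mean_se(pooled)
        out["pooled"]["circular_mean"] = wrap_angle_deg(mean)
        out["pooled"]["circular_se"] = se
    return out


# ---------------------------------------------------------------------------
# Amplitude-response curves along the preferred / anti-preferred direction

def _safe_pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _ray_rates(trials: pd.DataFrame, col: str, direction: float) -> pd.Series:
    """Mean rate per amplitude along the sampled ray closest to ``direction``
    within each amplitude ring (rings may be angularly staggered)."""
    out = {}
    for amp, grp in trials.groupby("amplitude_cm"):
        dirs = grp["direction_deg"].unique()
        closest = dirs[np.argmin(np.abs(wrap_angle_deg(dirs - direction)))]
        out[float(amp)] = grp.loc[grp["direction_deg"] == closest, col].mean()
    return pd.Series(out).sort_index()


def amplitude_response_curve(trials: pd.DataFrame, epochs: Sequence[str] = EPOCHS) -> dict:
    """Normalized rate vs amplitude along the PD and anti-PD rays.

    Requires >= 3 amplitude levels.  Per epoch, the mean rates at each
    amplitude along the preferred direction and along the sampled direction
    closest to PD + 180 deg are mid-range normalized together (shared scale).
    Pearson r and p between amplitude and normalized rate are pooled over
    epochs, separately for the PD and anti-PD rays.
    """
    amps = np.sort(trials["amplitude_cm"].unique())
    if len(amps) < 3:
        raise ValueError(f"amplitude-response curves require >= 3 amplitudes, got {len(amps)}")
    curves: dict[str, dict] = {}
    pooled_amp, pooled_pd, pooled_anti = [], [], []
    for epoch in epochs:
        col = rate_column(epoch)
        pd_deg, _ = preferred_direction(trials, epoch)
        pd_rates = _ray_rates(trials, col, pd_deg)
        anti_rates = _ray_rates(trials, col, pd_deg + 180.0)
        stacked = np.concatenate([pd_rates.to_numpy(), anti_rates.to_numpy()])
        norm, degenerate = midrange_normalize(stacked)
        k = len(pd_rates)
        curves[epoch] = {
            "preferred_direction": pd_deg,
            "amplitudes": pd_rates.index.to_numpy(),
            "pd_curve": norm[:k],
            "anti_pd_curve": norm[k:],
            "degenerate": degenerate,
        }
        pooled_amp.extend(pd_rates.index)
        pooled_pd.extend(norm[:k])
        pooled_anti.extend(norm[k:])
    r_pd, p_pd = _safe_pearson(pooled_amp, pooled_pd)
    r_anti, p_anti = _safe_pearson(pooled_amp, pooled_anti)
    return {
        "per_epoch": curves,
        "pd_correlation": {"r": r_pd, "p": p_pd},
        "anti_pd_correlation": {"r": r_anti, "p": p_anti},
    }


def population_amplitude_response(trials: pd.DataFrame, epochs: Sequence[str] = EPOCHS) -> dict:
    """Pool normalized amplitude-response curves over neurons.

    Pearson correlations between amplitude and normalized rate are computed
    over all (neuron, epoch, amplitude) points, separately for the PD and
    anti-PD rays.
    """
    pooled_amp, pooled_pd, pooled_anti = [], [], []
    per_neuron = {}
    for nid, grp in trials.groupby("neuron_id"):
        curve = amplitude_response_curve(grp, epochs)
        per_neuron[int(nid)] = curve
        for epoch in epochs:
            c = curve["per_epoch"][epoch]
            pooled_amp.extend(c["amplitudes"])
            pooled_pd.extend(c["pd_curve"])
            pooled_anti.extend(c["anti_pd_curve"])
    r_pd, p_pd = _safe_pearson(pooled_amp, pooled_pd)
    r_anti, p_anti = _safe_pearson(pooled_amp, pooled_anti)
    return {
        "per_neuron": per_neuron,
        "pd_correlation": {"r": r_pd, "p": p_pd},
        "anti_pd_correlation": {"r": r_anti, "p": p_anti},
        "n_points": len(pooled_amp),
    }
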