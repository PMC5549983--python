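"""Task-relatedness filtering and direction/amplitude selectivity statistics.

The screen follows a fixed battery: a paired t-test of each trial epoch
against baseline (Bonferroni 0.05/4) plus a 1 Hz rate floor decides
task-relatedness; a two-way fixed-effects ANOVA with interaction (direction x
amplitude factors) supplies per-epoch F and p values; amplitude selectivity
flags apply literal Bonferroni thresholds (0.05/8 over both amplitude effects
x four epochs, 0.05/4 over both effects x the two memory epochs); and
direction-wise unpaired t-tests localize amplitude effects for two-amplitude
layouts.  Degenerate (zero-variance) statistics report p = 1 with a flag so
population screens never abort.

Sums of squares are type II, which coincides with type I/III on balanced
designs and is robust to mild imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import EPOCHS, rate_column

ALPHA = 0.05
#: Epochs counted as movement planning for the 0.05/4 Bonferroni rule.
PLANNING_EPOCHS = ("EM", "LM")


def epoch_windows() -> dict[str, tuple[str, int, int]]:
    """Analysis windows: epoch -> (anchor event, start ms, end ms).

    All windows are 500 ms.  The baseline window is the final 500 ms of
    fixation immediately before cue onset.
    """
    return {
        "baseline": ("cue onset", -500, 0),
        "C": ("cue onset", 0, 500),
        "EM": ("cue offset", 200, 700),
        "LM": ("go signal", -700, -200),
        "RT/MT": ("go signal", 0, 500),
    }


# ---------------------------------------------------------------------------
# Task-relatedness

@dataclass
class TaskRelatedness:
    neuron_id: int
    task_related: bool
    p_values: dict[str, float]
    epoch_means: dict[str, float]
    rate_floor_ok: bool
    degenerate: bool = False


def is_task_related(
    trials: pd.DataFrame,
    alpha: float = ALPHA,
    paired: bool = True,
    rate_floor_hz: float = 1.0,
) -> TaskRelatedness:
    """Task-relatedness screen for one neuron's trials.

    True iff (a) a two-sided t-test of epoch rate against baseline rate is
    significant at ``alpha/4`` in at least one trial epoch and (b) the mean
    rate exceeds ``rate_floor_hz`` in at least one trial epoch.  The t-test
    is paired across trials by default (epoch vs baseline of the same trial);
    ``paired=False`` switches to the unpaired variant.
    """
    if trials["neuron_id"].nunique() != 1:
        raise ValueError("is_task_related expects trials of a single neuron")
    if len(trials) < 2:
        raise ValueError("need >= 2 trials")
    neuron_id = int(trials["neuron_id"].iloc[0])
    baseline = trials[rate_column("baseline")].to_numpy(dtype=float)
    threshold = alpha / len(EPOCHS)
    p_values: dict[str, float] = {}
    epoch_means: dict[str, float] = {}
    degenerate = False
    for epoch in EPOCHS:
        rates = trials[rate_column(epoch)].to_numpy(dtype=float)
        epoch_means[epoch] = float(rates.mean())
        if paired:
            diff = rates - baseline
            if np.all(diff == diff[0]):
                # zero-variance difference: no test statistic; a constant
                # nonzero shift is treated as unambiguous evidence
                p_values[epoch] = 0.0 if diff[0] != 0 else 1.0
                degenerate = True
                continue
            p = stats.ttest_rel(rates, baseline).pvalue
        else:
            if rates.std() == 0 and baseline.std() == 0:
                p_values[epoch] = 1.0
                degenerate = True
                continue
            p = stats.ttest_ind(rates, baseline).pvalue
        p_values[epoch] = float(p) if np.isfinite(p) else 1.0
    rate_floor_ok = any(m > rate_floor_hz for m in epoch_means.values())
    significant = any(p < threshold for p in p_values.values())
    return TaskRelatedness(
        neuron_id=neuron_id,
        task_related=bool(significant and rate_floor_ok),
        p_values=p_values,
        epoch_means=epoch_means,
        rate_floor_ok=rate_floor_ok,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA with interaction

def _design_columns(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded columns for one categorical factor."""
    levels = np.unique(labels)
    return (labels[:, None] == levels[1:][None, :]).astype(float)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def anova2_interaction(
    rates: Sequence[float] | np.ndarray,
    direction_labels: Sequence | np.ndarray,
    amplitude_labels: Sequence | np.ndarray,
) -> dict[str, dict[str, float]]:
    """Two-way fixed-effects ANOVA with interaction (type II sums of squares).

    Returns ``{"direction": {"F", "p", "df"}, "amplitude": {...},
    "interaction": {...}}``.  Every (direction, amplitude) cell must be
    occupied, with >= 2 trials in at least one cell so the error term exists;
    zero residual variance yields F = inf and p = 0 for effects with nonzero
    sums of squares, p = 1 otherwise.
    """
    y = np.asarray(rates, dtype=float)
    a = np.asarray(direction_labels)
    b = np.asarray(amplitude_labels)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("rates and labels must have equal length")
    a_levels, a_codes = np.unique(a, return_inverse=True)
    b_levels, b_codes = np.unique(b, return_inverse=True)
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("need >= 2 levels per factor")
    counts = np.zeros((len(a_levels), len(b_levels)), dtype=int)
    np.add.at(counts, (a_codes, b_codes), 1)
    if np.any(counts == 0):
        i, j = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"empty design cell: direction={a_levels[i]!r}, amplitude={b_levels[j]!r}"
        )
    n = len(y)
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = n - len(a_levels) * len(b_levels)
    if df_err < 1:
        raise ValueError("no residual degrees of freedom; need >= 2 trials in some cell")

    ones = np.ones((n, 1))
    A = _design_columns(a)
    B = _design_columns(b)
    AB = (A[:, :, None] * B[:, None, :]).reshape(n, -1)
    X_full = np.hstack([ones, A, B, AB])
    rss_full = _rss(X_full, y)
    rss_ab = _rss(np.hstack([ones, A, B]), y)  # A + B (no interaction)
    rss_a = _rss(np.hstack([ones, A]), y)
    rss_b = _rss(np.hstack([ones, B]), y)
    # clamp least-squares rounding noise so exactly-fitting designs yield
    # F = inf / p = 0 instead of noise-over-noise ratios
    tss = float(((y - y.mean()) ** 2).sum())
    tiny = 1e-12 * max(tss, 1.0)
    rss_full = 0.0 if rss_full < tiny else rss_full

    # Type II: each main effect adjusted for the other, interaction last.
    ss = {
        "direction": rss_b - rss_ab,
        "amplitude": rss_a - rss_ab,
        "interaction": rss_ab - rss_full,
    }
    dfs = {"direction": df_a, "amplitude": df_b, "interaction": df_ab}
    mse = rss_full / df_err
    out = {}
    for effect, ss_eff in ss.items():
        ss_eff = 0.0 if ss_eff < tiny else ss_eff
        if mse > 0:
            F = (ss_eff / dfs[effect]) / mse
            p = float(stats.f.sf(F, dfs[effect], df_err))
        elif ss_eff > 0:
            F, p = float("inf"), 0.0
        else:
            F, p = 0.0, 1.0
        out[effect] = {"F": float(F), "p": p, "df": dfs[effect]}
    out["df_error"] = df_err
    return out


# ---------------------------------------------------------------------------
# Selectivity results and flags

@dataclass
class SelectivityResult:
    """Per-neuron selectivity battery: per-epoch ANOVA results, direction-wise
    amplitude t-tests, task-relatedness, and Bonferroni flags."""

    neuron_id: int
    task_related: bool
    anova: dict[str, dict]  # epoch -> anova2_interaction output
    directionwise_p: dict[str, dict[float, float]] = field(default_factory=dict)
    amplitude_selective_any_epoch: bool = False
    amplitude_selective_planning: bool = False
    direction_selective_any_epoch: bool = False
    task_relatedness: TaskRelatedness | None = None


def amplitude_selectivity_flags(
    anova_by_epoch: dict[str, dict], alpha: float = ALPHA
) -> dict[str, bool]:
    """Bonferroni amplitude-selectivity flags from per-epoch ANOVA results.

    ``any_epoch``: any of {main amplitude, interaction} x all four epochs
    significant at ``alpha/8``.  ``planning``: same effects over the memory
    epochs only, at ``alpha/4``.  Also returns a direction flag (main
    direction effect over four epochs at ``alpha/8``, companion statistic).
    """
    missing = set(EPOCHS) - set(anova_by_epoch)
    if missing:
        raise ValueError(f"ANOVA results missing epochs: {sorted(missing)}")
    amp_ps_all = [
        anova_by_epoch[e][eff]["p"] for e in EPOCHS for eff in ("amplitude", "interaction")
    ]
    amp_ps_planning = [
        anova_by_epoch[e][eff]["p"]
        for e in PLANNING_EPOCHS
        for eff in ("amplitude", "interaction")
    ]
    dir_ps_all = [anova_by_epoch[e]["direction"]["p"] for e in EPOCHS]
    return {
        "any_epoch": bool(min(amp_ps_all) < alpha / 8),
        "planning": bool(min(amp_ps_planning) < alpha / 4),
        "direction_any_epoch": bool(min(dir_ps_all) < alpha / len(dir_ps_all)),
    }


def directionwise_amplitude_tests(
    trials: pd.DataFrame, epoch: str, alpha: float = ALPHA
) -> dict:
    """Per-direction unpaired t-tests of small vs large amplitude rates.

    Valid only for two-amplitude layouts; returns per-direction two-sided
    p-values, the count of directions significant at ``alpha``, and the
    direction with the smallest p-value.  Zero-variance ties give p = 1 with
    a degeneracy flag.
    """
    col = rate_column(epoch)
    amps = np.sort(trials["amplitude_cm"].unique())
    if len(amps) != 2:
        raise ValueError(
            f"directionwise amplitude tests require exactly 2 amplitude levels, got "
            f"{len(amps)}; use the amplitude-response-curve analysis for denser layouts"
        )
    p_by_direction: dict[float, float] = {}
    degenerate: dict[float, bool] = {}
    for direction, grp in trials.groupby("direction_deg"):
        small = grp.loc[grp["amplitude_cm"] == amps[0], col].to_numpy(dtype=float)
        large = grp.loc[grp["amplitude_cm"] == amps[1], col].to_numpy(dtype=float)
        if len(small) < 2 or len(large) < 2:
            raise ValueError(f"need >= 2 trials per (direction, amplitude) at {direction} deg")
        if small.std() == 0 and large.std() == 0:
            # no within-cell variance: p = 1 when means tie (no evidence),
            # 0 when they differ (unambiguous separation)
            p = 1.0 if small.mean() == large.mean() else 0.0
            degenerate[float(direction)] = True
        else:
            p = float(stats.ttest_ind(small, large).pvalue)
            if not np.isfinite(p):
                p = 1.0
                degenerate[float(direction)] = True
        p_by_direction[float(direction)] = p
    n_significant = sum(p < alpha for p in p_by_direction.values())
    best_direction = min(p_by_direction, key=lambda d: (p_by_direction[d], d))
    return {
        "p_by_direction": p_by_direction,
        "n_significant": n_significant,
        "best_direction": best_direction,
        "degenerate_directions": degenerate,
    }


def derive_direction_factor(trials: pd.DataFrame) -> np.ndarray:
    """Ray labels for the ANOVA direction factor.

    Radial layouts may stagger each amplitude ring by a small angular offset,
    so raw direction values do not repeat across amplitudes.  The direction
    factor is therefore the ray identity: within each amplitude ring,
    directions sorted ascending are labeled 0..k-1.  For unstaggered layouts
    this reproduces the raw direction grouping exactly; for nonnegative
    per-ring offsets smaller than the ray spacing it aligns corresponding
    rays across rings.
    """
    labels = np.empty(len(trials), dtype=int)
    dirs = trials["direction_deg"].to_numpy(dtype=float)
    amps = trials["amplitude_cm"].to_numpy(dtype=float)
    for amp in np.unique(amps):
        sel = amps == amp
        ring_dirs = np.unique(dirs[sel])
        rank = {d: i for i, d in enumerate(ring_dirs)}
        labels[sel] = [rank[d] for d in dirs[sel]]
    return labels


def population_proportion_test(k_selective: int, n_neurons: int, p0: float = 0.05) -> float:
    """Exact one-tailed binomial p-value: P(X >= k) for X ~ Bin(n, p0)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= k_selective <= n_neurons:
        raise ValueError("need 0 <= k_selective <= n_neurons")
    return float(stats.binom.sf(k_selective - 1, n_neurons, p0))


# ---------------------------------------------------------------------------
# Population screen

def screen_neuron(trials: pd.DataFrame, alpha: float = ALPHA) -> SelectivityResult:
    """Run the full selectivity battery on one neuron's trials."""
    relatedness = is_task_related(trials, alpha=alpha)
    direction_factor = derive_direction_factor(trials)
    anova_by_epoch = {}
    for epoch in EPOCHS:
        anova_by_epoch[epoch] = anova2_interaction(
            trials[rate_column(epoch)].to_numpy(dtype=float),
            direction_factor,
            trials["amplitude_cm"].to_numpy(),
        )
    flags = amplitude_selectivity_flags(anova_by_epoch, alpha=alpha)
    directionwise = {}
    if trials["amplitude_cm"].nunique() == 2:
        for epoch in EPOCHS:
            directionwise[epoch] = directionwise_amplitude_tests(trials, epoch, alpha=alpha)
    return SelectivityResult(
        neuron_id=relatedness.neuron_id,
        task_related=relatedness.task_related,
        anova=anova_by_epoch,
        directionwise_p={
            e: d["p_by_direction"] for e, d in directionwise.items()
        },
        amplitude_selective_any_epoch=flags["any_epoch"],
        amplitude_selective_planning=flags["planning"],
        direction_selective_any_epoch=flags["direction_any_epoch"],
        task_relatedness=relatedness,
    )


def screen_population(trials: pd.DataFrame, alpha: float = ALPHA) -> list[SelectivityResult]:
    return [screen_neuron(grp, alpha=alpha) for _, grp in trials.groupby("neuron_id")]


def selectivity_table(results: Sequence[SelectivityResult]) -> pd.DataFrame:
    """Flatten screen results into one row per neuron."""
    rows = []
    for r in results:
        row = {
            "neuron_id": r.neuron_id,
            "task_related": r.task_related,
            "amplitude_selective_any_epoch": r.amplitude_selective_any_epoch,
            "amplitude_selective_planning": r.amplitude_selective_planning,
            "direction_selective_any_epoch": r.direction_selective_any_epoch,
        }
        for e in EPOCHS:
            tag = e.replace("/", "").lower()
            for eff in ("direction", "amplitude", "interaction"):
                row[f"F_{eff}_{tag}"] = r.anova[e][eff]["F"]
                row[f"p_{eff}_{tag}"] = r.anova[e][eff]["p"]
            if r.task_relatedness is not None:
                row[f"p_vs_baseline_{tag}"] = r.task_relatedness.p_values[e]
        rows.append(row)
    return pd.DataFrame(rows)


def population_summary(results: Sequence[SelectivityResult], p0: float = 0.05) -> dict:
    """Population-level proportions and the exact binomial test against p0,
    restricted to task-related neurons."""
    task_related = [r for r in results if r.task_related]
    n = len(task_related)
    k_any = sum(r.amplitude_selective_any_epoch for r in task_related)
    k_planning = sum(r.amplitude_selective_planning for r in task_related)
    k_dir = sum(r.direction_selective_any_epoch for r in task_related)
    return {
        "n_neurons": len(results),
        "n_task_related": n,
        "k_amplitude_any_epoch": k_any,
        "k_amplitude_planning": k_planning,
        "k_direction_any_epoch": k_dir,
        "proportion_amplitude_any_epoch": k_any / n if n else float("nan"),
        "proportion_amplitude_planning": k_planning / n if n else float("nan"),
        "proportion_direction_any_epoch": k_dir / n if n else float("nan"),
        "binomial_p_amplitude_any_epoch": (
            population_proportion_test(k_any, n, p0) if n else float("nan")
        ),
        "binomial_p_amplitude_planning": (
            population_proportion_test(k_planning, n, p0) if n else float("nan")
        ),
    }


def shuffle_null_proportion(
    trials: pd.DataFrame, n_shuffles: int = 100, seed: int = 0, alpha: float = ALPHA
) -> dict:
    """Chance level of the any-epoch amplitude flag under label shuffling.

    Permutes target labels across trials within each neuron, reruns the
    amplitude-selectivity criterion, and returns the mean flagged proportion
    over ``n_shuffles`` shuffles (plus the per-shuffle values).  Deterministic
    given the seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    label_cols = ["target_index", "direction_deg", "amplitude_cm"]
    proportions = np.empty(n_shuffles)
    for s in range(n_shuffles):
        flagged = 0
        n_neurons = 0
        for _, grp in trials.groupby("neuron_id"):
            perm = rng.permutation(len(grp))
            shuffled = grp.copy()
            shuffled[label_cols] = grp[label_cols].to_numpy()[perm]
            direction_factor = derive_direction_factor(shuffled)
            anova_by_epoch = {
                epoch: anova2_interaction(
                    shuffled[rate_column(epoch)].to_numpy(dtype=float),
                    direction_factor,
                    shuffled["amplitude_cm"].to_numpy(),
                )
                for epoch in EPOCHS
            }
            flags = amplitude_selectivity_flags(anova_by_epoch, alpha=alpha)
            flagged += flags["any_epoch"]
            n_neurons += 1
        proportions[s] = flagged / n_neurons
    return {
        "mean_proportion": float(proportions.mean()),
        "proportions": proportions,
        "n_shuffles": n_shuffles,
    }
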