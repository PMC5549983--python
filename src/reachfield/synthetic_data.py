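"""Synthetic sessions of per-trial epoch firing rates with known ground truth.

Each neuron has a tuning model (one of the five parametric encoding models or
an untuned constant), a baseline rate, and per-epoch response gains.  The
mean rate for a target is ``baseline + gain(epoch) * f_norm(target)`` where
``f_norm`` is the model response mid-range normalized over the
configuration's active targets, so the gain is the peak modulation in Hz and
rates are guaranteed nonnegative.  The baseline epoch carries the baseline
rate only, for every neuron.

Noise is Poisson on 500 ms spike counts: ``count ~ Poisson(rate * 0.5)`` and
the recorded rate is ``count / 0.5``, hence all generated rates are integer
multiples of 2 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .task_geometry import ReachTarget, TargetConfiguration

#: Trial epochs analyzed against baseline, in canonical order.
EPOCHS = ("C", "EM", "LM", "RT/MT")
ALL_EPOCHS = ("baseline",) + EPOCHS

#: Analysis window length in seconds (all epochs are 500 ms bins).
EPOCH_SECONDS = 0.5

UNTUNED = "untuned"

_RATE_COLS = {
    "baseline": "rate_baseline_hz",
    "C": "rate_c_hz",
    "EM": "rate_em_hz",
    "LM": "rate_lm_hz",
    "RT/MT": "rate_rtmt_hz",
}

#: Canonical trial-table column order; the same schema ingests real data.
TRIAL_TABLE_COLUMNS = [
    "neuron_id",
    "trial_id",
    "target_index",
    "direction_deg",
    "amplitude_cm",
    "rate_baseline_hz",
    "rate_c_hz",
    "rate_em_hz",
    "rate_lm_hz",
    "rate_rtmt_hz",
    "memory_period_s",
]


def rate_column(epoch: str) -> str:
    """Trial-table column holding the firing rate of ``epoch``."""
    try:
        return _RATE_COLS[epoch]
    except KeyError:
        raise ValueError(f"unknown epoch {epoch!r}; expected one of {ALL_EPOCHS}") from None


@dataclass
class GroundTruthNeuron:
    """A simulated neuron with a known tuning model.

    ``model_id`` is ``"untuned"`` or an encoding-model id 1-5;
    ``true_params`` must lie within that model's box constraints.
    ``epoch_gains`` maps each trial epoch to its peak modulation in Hz.
    """

    neuron_id: int
    model_id: int | str
    true_params: np.ndarray
    baseline_rate: float
    epoch_gains: dict[str, float]
    task_related: bool = True

    def __post_init__(self) -> None:
        self.true_params = np.asarray(self.true_params, dtype=float)
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        missing = set(EPOCHS) - set(self.epoch_gains)
        if missing:
            raise ValueError(f"epoch_gains missing epochs: {sorted(missing)}")
        if any(g < 0 for g in self.epoch_gains.values()):
            raise ValueError("epoch_gains must be >= 0")
        if self.model_id != UNTUNED:
            from .encoding_models import MODEL_SPECS

            MODEL_SPECS[int(self.model_id)].check_params(self.true_params)


def tuning_profile(neuron: GroundTruthNeuron, config: TargetConfiguration) -> np.ndarray:
    """``f_norm`` over the configuration's active targets: the neuron's model
    response mid-range normalized to [0, 1] (all zeros if untuned)."""
    n = len(config.active_targets)
    if neuron.model_id == UNTUNED:
        return np.zeros(n)
    from .encoding_models import ModelPoints, evaluate_model
    from .response_field import midrange_normalize

    raw = evaluate_model(int(neuron.model_id), neuron.true_params, ModelPoints.from_config(config))
    norm, _ = midrange_normalize(raw)
    return norm


def rate_function(
    neuron: GroundTruthNeuron,
    target: ReachTarget,
    epoch: str,
    config: TargetConfiguration,
) -> float:
    """Mean firing rate (Hz) of ``neuron`` for ``target`` in ``epoch``."""
    if epoch not in ALL_EPOCHS:
        raise ValueError(f"unknown epoch {epoch!r}")
    if epoch == "baseline":
        return float(neuron.baseline_rate)
    profile = tuning_profile(neuron, config)
    active_idx = [t.index for t in config.active_targets]
    try:
        i = active_idx.index(target.index)
    except ValueError:
        raise ValueError(f"target {target.index} is not active in this configuration") from None
    return float(neuron.baseline_rate + neuron.epoch_gains[epoch] * profile[i])


# ---------------------------------------------------------------------------
# Population sampling

def _default_param_sampler(model_id: int | str, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth parameter draws inside each model's constraints."""
    if model_id == UNTUNED:
        return np.array([])
    model_id = int(model_id)
    theta0 = rng.uniform(-np.pi, np.pi)
    if model_id == 1:
        return np.array([theta0])
    if model_id == 2:
        return np.array([theta0, rng.uniform(0.5, 5.0)])
    if model_id == 3:
        return np.array([theta0, rng.uniform(0.5, 4.0)])
    if model_id == 4:
        return np.array([theta0, rng.uniform(0.5, 4.0), rng.uniform(0.5, 5.0)])
    if model_id == 5:
        return np.array(
            [
                rng.uniform(-5.0, 5.0),
                rng.uniform(-5.0, 5.0),
                rng.uniform(1.5, 4.0),
                rng.uniform(1.5, 4.0),
                rng.uniform(-0.5, 0.5),
            ]
        )
    raise ValueError(f"unknown model id {model_id}")


def make_population(
    n_neurons: int,
    mixture_weights: Mapping[int | str, float],
    param_priors: Mapping[int | str, Callable[[np.random.Generator], np.ndarray]] | None = None,
    seed: int = 0,
    baseline_range: tuple[float, float] = (2.0, 8.0),
    gain_range: tuple[float, float] = (15.0, 35.0),
    equal_gains: bool = True,
) -> list[GroundTruthNeuron]:
    """Reproducibly draw a mixed population of ground-truth neurons.

    ``mixture_weights`` maps model ids (ints 1-5 and/or ``"untuned"``) to
    probabilities summing to 1.  Baselines and epoch gains are uniform draws;
    with ``equal_gains`` the gain is shared across epochs (untuned neurons
    always get zero gain).  ``param_priors`` overrides the default per-model
    parameter samplers.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    ids = list(mixture_weights.keys())
    weights = np.array([mixture_weights[i] for i in ids], dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError(f"mixture weights must be nonnegative and sum to 1, got {weights}")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    neurons = []
    for nid in range(n_neurons):
        model_id = ids[rng.choice(len(ids), p=weights)]
        if param_priors and model_id in param_priors:
            params = np.asarray(param_priors[model_id](rng), dtype=float)
        else:
            params = _default_param_sampler(model_id, rng)
        baseline = rng.uniform(*baseline_range)
        if model_id == UNTUNED:
            gains = {e: 0.0 for e in EPOCHS}
        elif equal_gains:
            g = rng.uniform(*gain_range)
            gains = {e: g for e in EPOCHS}
        else:
            gains = {e: rng.uniform(*gain_range) for e in EPOCHS}
        neurons.append(
            GroundTruthNeuron(
                neuron_id=nid,
                model_id=model_id,
                true_params=params,
                baseline_rate=baseline,
                epoch_gains=gains,
                task_related=model_id != UNTUNED,
            )
        )
    return neurons


# ---------------------------------------------------------------------------
# Session simulation

def simulate_session(
    config: TargetConfiguration,
    population: Sequence[GroundTruthNeuron],
    n_trials_per_target: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a session: Poisson 500 ms spike counts per neuron, trial,
    target, and epoch.

    Each neuron draws from its own seed stream derived from ``(seed,
    neuron_id)``, so extending the population leaves existing neurons'
    trials untouched.  The memory-period duration (uniform on [1.1, 1.7] s)
    is recorded as metadata only.  Identical inputs yield identical tables.
    """
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    if not config.active_targets:
        raise ValueError("configuration has no active targets")
    if n_trials_per_target < 2:
        raise ValueError("n_trials_per_target must be >= 2")
    targets = config.active_targets
    n_targets = len(targets)
    n_trials = n_targets * n_trials_per_target
    tgt_index = np.repeat([t.index for t in targets], n_trials_per_target)
    tgt_dir = np.repeat([t.direction for t in targets], n_trials_per_target)
    tgt_amp = np.repeat([t.amplitude for t in targets], n_trials_per_target)

    frames = []
    for neuron in population:
        rng = np.random.default_rng(np.random.SeedSequence([seed, neuron.neuron_id]))
        profile = tuning_profile(neuron, config)
        data = {
            "neuron_id": np.full(n_trials, neuron.neuron_id, dtype=int),
            "trial_id": np.arange(n_trials, dtype=int),
            "target_index": tgt_index,
            "direction_deg": tgt_dir,
            "amplitude_cm": tgt_amp,
        }
        for epoch in ALL_EPOCHS:
            if epoch == "baseline":
                rates = np.full(n_targets, neuron.baseline_rate)
            else:
                rates = neuron.baseline_rate + neuron.epoch_gains[epoch] * profile
            mean_counts = np.repeat(rates, n_trials_per_target) * EPOCH_SECONDS
            counts = rng.poisson(mean_counts)
            data[rate_column(epoch)] = counts / EPOCH_SECONDS
        data["memory_period_s"] = rng.uniform(1.1, 1.7, size=n_trials)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)[TRIAL_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# Tables

def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = [c for c in TRIAL_TABLE_COLUMNS if c != "memory_period_s"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} missing columns: {sorted(missing)}")
    return df


def ground_truth_table(population: Sequence[GroundTruthNeuron]) -> pd.DataFrame:
    """Tabulate a population for serialization (params padded to 5 columns)."""
    rows = []
    for n in population:
        row = {
            "neuron_id": n.neuron_id,
            "model_id": n.model_id,
            "baseline_rate_hz": n.baseline_rate,
            "task_related": n.task_related,
        }
        for e in EPOCHS:
            row[f"gain_{rate_column(e).removeprefix('rate_').removesuffix('_hz')}_hz"] = (
                n.epoch_gains[e]
            )
        for i in range(5):
            row[f"p{i + 1}"] = n.true_params[i] if i < len(n.true_params) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_ground_truth(population: Sequence[GroundTruthNeuron], path) -> None:
    ground_truth_table(population).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ground_truth(path) -> list[GroundTruthNeuron]:
    df = pd.read_csv(path, sep="\t")
    neurons = []
    gain_cols = {e: f"gain_{rate_column(e).removeprefix('rate_').removesuffix('_hz')}_hz" for e in EPOCHS}
    for _, row in df.iterrows():
        model_id = row["model_id"]
        model_id = UNTUNED if model_id == UNTUNED else int(model_id)
        params = np.array([row[f"p{i + 1}"] for i in range(5)], dtype=float)
        params = params[~np.isnan(params)]
        neurons.append(
            GroundTruthNeuron(
                neuron_id=int(row["neuron_id"]),
                model_id=model_id,
                true_params=params,
                baseline_rate=float(row["baseline_rate_hz"]),
                epoch_gains={e: float(row[gain_cols[e]]) for e in EPOCHS},
                task_related=bool(row["task_related"]),
            )
        )
    return neurons
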