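"""Parametric encoding models of spatial response patterns.

Five models map a reach-target location ``x = (x, y) = (theta, r)`` to a
scalar response:

1. ``cos(theta - theta0)`` — cosine directional tuning.
2. ``cos(theta - theta0) * k*r`` — cosine tuning with linear amplitude gain.
3. ``exp(sigma*cos(theta - theta0)) / (2*pi*I0(sigma))`` — Von Mises tuning.
4. Von Mises tuning with linear amplitude gain ``k*r``.
5. ``exp(-1/2 (x - mu)^T Sigma^-1 (x - mu))`` — 2D Gaussian position tuning,
   with ``Sigma = [[sx*sx, rho*sx*sy], [rho*sx*sy, sy*sy]]``.

NOTE on model 5: the source formulation omits the negative sign (and the
conventional 1/2) in the exponent; as written it would diverge away from the
center instead of describing a response field peaking at ``mu``.  The decaying
form ``exp(-q/2)`` is implemented here.

Model patterns are mid-range normalized over the evaluation grid before any
comparison with data, so Pearson-correlation scoring is scale/offset-free.
Fitting is box-constrained least squares from multiple starts; model/data
comparison uses the split-half cross-validated consistency protocol with the
split-half Pearson correlation of the data itself as the noise ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import least_squares

from .response_field import FieldInterpolator, GridSpec, ResponsePattern, midrange_normalize
from .task_geometry import TargetConfiguration

MODEL_IDS = (1, 2, 3, 4, 5)

#: Optimizer stand-in for the unbounded concentration: at sigma = 1e3 the
#: normalized pattern is numerically a delta on any sampled grid.
SIGMA_CAP = 1.0e3

#: Lower bound replacing the printed [-5, 50] Gaussian width range: the width
#: enters the covariance only as sx*sx / sy*sy, so sign is irrelevant and the
#: domain is folded to positive values.
WIDTH_EPS = 1.0e-3


@dataclass(frozen=True)
class ModelSpec:
    """Parameter names and box constraints for one encoding model."""

    model_id: int
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    description: str

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def check_params(self, params: Sequence[float]) -> np.ndarray:
        p = np.asarray(params, dtype=float)
        if p.shape != (self.n_params,):
            raise ValueError(
                f"model {self.model_id} expects {self.n_params} params, got shape {p.shape}"
            )
        lo, hi = np.array(self.lower), np.array(self.upper)
        if np.any(p < lo - 1e-12) or np.any(p > hi + 1e-12):
            raise ValueError(f"params {p} outside bounds for model {self.model_id}")
        return p


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, ("theta0",), (-math.pi,), (math.pi,), "cosine directional tuning"),
    2: ModelSpec(
        2,
        ("theta0", "k"),
        (-math.pi, -100.0),
        (math.pi, 100.0),
        "cosine directional tuning with linear amplitude gain",
    ),
    3: ModelSpec(
        3,
        ("theta0", "sigma"),
        (-math.pi, 0.01),
        (math.pi, SIGMA_CAP),
        "Von Mises directional tuning",
    ),
    4: ModelSpec(
        4,
        ("theta0", "sigma", "k"),
        (-math.pi, 0.01, -100.0),
        (math.pi, SIGMA_CAP, 100.0),
        "Von Mises directional tuning with linear amplitude gain",
    ),
    5: ModelSpec(
        5,
        ("mu_x", "mu_y", "sigma_x", "sigma_y", "rho"),
        (-20.0, -20.0, WIDTH_EPS, WIDTH_EPS, -0.99),
        (20.0, 20.0, 50.0, 50.0, 0.99),
        "Gaussian position tuning",
    ),
}


class ModelPoints:
    """Evaluation points with precomputed polar coordinates."""

    def __init__(self, xy: np.ndarray):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if xy.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if not np.all(np.isfinite(xy)):
            raise ValueError("points must be finite")
        self.x = xy[:, 0]
        self.y = xy[:, 1]
        self.theta = np.arctan2(self.y, self.x)
        self.r = np.hypot(self.x, self.y)

    @classmethod
    def from_grid(cls, grid: GridSpec) -> "ModelPoints":
        return cls(grid.flat_points())

    @classmethod
    def from_config(cls, config: TargetConfiguration) -> "ModelPoints":
        return cls(config.active_xy())

    def __len__(self) -> int:
        return len(self.x)


def _von_mises(theta: np.ndarray, theta0: float, sigma: float) -> np.ndarray:
    # exp(sigma*cos(dphi)) / (2*pi*I0(sigma)), computed via the scaled Bessel
    # function ive to stay finite at large concentration.
    return np.exp(sigma * (np.cos(theta - theta0) - 1.0)) / (
        2.0 * math.pi * special.ive(0, sigma)
    )


def evaluate_model(
    model_id: int, params: Sequence[float], points: ModelPoints | np.ndarray
) -> np.ndarray:
    """Raw (un-normalized) model response at each point."""
    if not isinstance(points, ModelPoints):
        points = ModelPoints(points)
    spec = MODEL_SPECS[model_id]
    p = spec.check_params(params)
    if model_id == 1:
        return np.cos(points.theta - p[0])
    if model_id == 2:
        return np.cos(points.theta - p[0]) * p[1] * points.r
    if model_id == 3:
        return _von_mises(points.theta, p[0], p[1])
    if model_id == 4:
        return _von_mises(points.theta, p[0], p[1]) * p[2] * points.r
    if model_id == 5:
        mu_x, mu_y, sx, sy, rho = p
        det = (sx * sx) * (sy * sy) * (1.0 - rho * rho)
        if det <= 0:
            raise ValueError("covariance not positive-definite")
        dx = points.x - mu_x
        dy = points.y - mu_y
        # quadratic form via the analytic 2x2 inverse
        q = (dx * dx / (sx * sx) - 2.0 * rho * dx * dy / (sx * sy) + dy * dy / (sy * sy)) / (
            1.0 - rho * rho
        )
        return np.exp(-0.5 * q)
    raise ValueError(f"unknown model id {model_id}")


def model_jacobian(
    model_id: int, params: Sequence[float], points: ModelPoints
) -> np.ndarray:
    """Analytic Jacobian of the raw model response, shape (n_points, n_params)."""
    spec = MODEL_SPECS[model_id]
    p = spec.check_params(params)
    if model_id in (1, 2):
        theta0 = p[0]
        phi = points.theta - theta0
        if model_id == 1:
            return np.sin(phi)[:, None]
        k = p[1]
        return np.column_stack([np.sin(phi) * k * points.r, np.cos(phi) * points.r])
    if model_id in (3, 4):
        theta0, sigma = p[0], p[1]
        phi = points.theta - theta0
        g = _von_mises(points.theta, theta0, sigma)
        # d/dsigma log I0 = I1/I0, via scaled Bessel functions
        bessel_ratio = special.ive(1, sigma) / special.ive(0, sigma)
        dg_dtheta0 = g * sigma * np.sin(phi)
        dg_dsigma = g * (np.cos(phi) - bessel_ratio)
        if model_id == 3:
            return np.column_stack([dg_dtheta0, dg_dsigma])
        k = p[2]
        kr = k * points.r
        return np.column_stack([dg_dtheta0 * kr, dg_dsigma * kr, g * points.r])
    if model_id == 5:
        mu_x, mu_y, sx, sy, rho = p
        one_m = 1.0 - rho * rho
        u = points.x - mu_x
        v = points.y - mu_y
        q = (u * u / (sx * sx) - 2.0 * rho * u * v / (sx * sy) + v * v / (sy * sy)) / one_m
        f = np.exp(-0.5 * q)
        dq_dmux = -(2.0 * u / (sx * sx) - 2.0 * rho * v / (sx * sy)) / one_m
        dq_dmuy = -(2.0 * v / (sy * sy) - 2.0 * rho * u / (sx * sy)) / one_m
        dq_dsx = (-2.0 * u * u / sx**3 + 2.0 * rho * u * v / (sx * sx * sy)) / one_m
        dq_dsy = (-2.0 * v * v / sy**3 + 2.0 * rho * u * v / (sx * sy * sy)) / one_m
        dq_drho = (-2.0 * u * v / (sx * sy)) / one_m + 2.0 * rho * q / one_m
        scale = -0.5 * f
        return np.column_stack(
            [scale * dq_dmux, scale * dq_dmuy, scale * dq_dsx, scale * dq_dsy, scale * dq_drho]
        )
    raise ValueError(f"unknown model id {model_id}")


def evaluate_model_normalized(
    model_id: int, params: Sequence[float], points: ModelPoints | np.ndarray
) -> np.ndarray:
    """Model response mid-range normalized over the evaluation points."""
    norm, _ = midrange_normalize(evaluate_model(model_id, params, points))
    return norm


@dataclass
class FitResult:
    """Best constrained least-squares fit of one model to one pattern."""

    model_id: int
    params: np.ndarray
    objective: float
    fitted: np.ndarray  # normalized model pattern at the evaluation points
    success: bool
    n_restarts: int
    failure: bool = False
    message: str = ""

    def params_dict(self) -> dict[str, float]:
        names = MODEL_SPECS[self.model_id].param_names
        return {n: float(v) for n, v in zip(names, self.params)}


def _data_driven_start(model_id: int, target: np.ndarray, points: ModelPoints) -> np.ndarray:
    """Initial guess anchored at the pattern's argmax."""
    i = int(np.argmax(target))
    theta_peak = float(points.theta[i])
    if model_id == 1:
        return np.array([theta_peak])
    if model_id == 2:
        return np.array([theta_peak, 1.0])
    if model_id == 3:
        return np.array([theta_peak, 2.0])
    if model_id == 4:
        return np.array([theta_peak, 2.0, 1.0])
    x_peak, y_peak = float(points.x[i]), float(points.y[i])
    return np.array([x_peak, y_peak, 3.0, 3.0, 0.0])


def _random_starts(model_id: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform draws inside a sane sub-box of the constraints.

    Concentration and gain are drawn from moderate ranges ([0.01, 20] and
    [-10, 10]); the optimizer itself still explores the full bounds.
    """
    spec = MODEL_SPECS[model_id]
    lo = np.array(spec.lower)
    hi = np.array(spec.upper)
    for j, name in enumerate(spec.param_names):
        if name == "sigma":
            hi[j] = 20.0
        elif name == "k":
            lo[j], hi[j] = -10.0, 10.0
        elif name in ("sigma_x", "sigma_y"):
            lo[j], hi[j] = 0.5, 10.0
    return rng.uniform(lo, hi, size=(n, spec.n_params))


def fit_model(
    model_id: int,
    target: np.ndarray | ResponsePattern,
    points: ModelPoints | None = None,
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = 0,
    tol: float = 1e-8,
) -> FitResult:
    """Fit one model to a normalized target pattern by multi-start
    box-constrained least squares.

    ``target`` is a mid-range-normalized pattern (flat vector or
    :class:`ResponsePattern`); ``points`` are the matching evaluation
    coordinates (derived from the pattern's grid when omitted).  One start is
    data-driven (anchored at the pattern argmax) plus ``n_restarts`` random
    starts; the best objective across starts wins.  Deterministic given the
    seed.  A constant target yields a failure-flagged result, never a crash.
    """
    if isinstance(target, ResponsePattern):
        if points is None:
            points = ModelPoints.from_grid(target.grid)
        target_vec = target.flat()
    else:
        target_vec = np.asarray(target, dtype=float).ravel()
        if points is None:
            raise ValueError("points required when target is a plain vector")
    if len(target_vec) != len(points):
        raise ValueError("target length does not match evaluation points")
    spec = MODEL_SPECS[model_id]
    if np.all(target_vec == target_vec[0]):
        return FitResult(
            model_id=model_id,
            params=np.array(spec.lower, dtype=float),
            objective=float(np.sum((target_vec - target_vec) ** 2)),
            fitted=np.zeros_like(target_vec),
            success=False,
            n_restarts=0,
            failure=True,
            message="degenerate (constant) target pattern",
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def residuals(p: np.ndarray) -> np.ndarray:
        raw = evaluate_model(model_id, p, points)
        lo, hi = raw.min(), raw.max()
        if hi == lo:
            return np.full_like(target_vec, 10.0)  # flat model: push away
        return (raw - lo) / (hi - lo) - target_vec

    def jacobian(p: np.ndarray) -> np.ndarray:
        # d/dp of the mid-range-normalized response, treating the argmin /
        # argmax bins as locally fixed (the normalization is piecewise smooth)
        raw = evaluate_model(model_id, p, points)
        i_min, i_max = int(np.argmin(raw)), int(np.argmax(raw))
        lo, hi = raw[i_min], raw[i_max]
        J = model_jacobian(model_id, p, points)
        if hi == lo:
            return np.zeros_like(J)
        norm = (raw - lo) / (hi - lo)
        return (J - J[i_min] - norm[:, None] * (J[i_max] - J[i_min])) / (hi - lo)

    starts = [_data_driven_start(model_id, target_vec, points)]
    if n_restarts > 0:
        starts.extend(_random_starts(model_id, n_restarts, rng))
    lo = np.array(spec.lower)
    hi = np.array(spec.upper)
    best = None
    any_success = False
    for s in starts:
        s = np.clip(s, lo, hi)
        try:
            sol = least_squares(
                residuals,
                s,
                jac=jacobian,
                bounds=(lo, hi),
                method="trf",
                ftol=tol,
                xtol=tol,
                gtol=tol,
            )
        except Exception:  # pragma: no cover - optimizer blow-up on one start
            continue
        obj = float(np.sum(sol.fun**2))
        any_success = any_success or bool(sol.success)
        if best is None or obj < best[0]:
            best = (obj, sol.x)
    if best is None:
        return FitResult(
            model_id=model_id,
            params=np.array(spec.lower, dtype=float),
            objective=float("inf"),
            fitted=np.zeros_like(target_vec),
            success=False,
            n_restarts=len(starts) - 1,
            failure=True,
            message="all restarts failed",
        )
    obj, params = best
    fitted = evaluate_model_normalized(model_id, params, points)
    return FitResult(
        model_id=model_id,
        params=params,
        objective=obj,
        fitted=fitted,
        success=any_success,
        n_restarts=len(starts) - 1,
    )


@dataclass
class ConsistencyResult:
    """Split-half internal consistency and per-model cross-validated
    consistency for one neuron-epoch, averaged over resamples."""

    neuron_id: int
    epoch: str
    internal_consistency: float
    internal_se: float
    model_consistency: dict[int, float]
    model_se: dict[int, float]
    n_resamples: int
    n_discarded: int = 0
    unusable: bool = False
    raw_internal: np.ndarray | None = None
    raw_model: dict[int, np.ndarray] | None = None
    fitted_params: dict[int, list[np.ndarray]] = field(default_factory=dict)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def split_half_consistency(
    trials: pd.DataFrame,
    epoch: str,
    config: TargetConfiguration,
    interpolator: FieldInterpolator | None = None,
    models: Sequence[int] = MODEL_IDS,
    n_repeats: int = 50,
    n_restarts: int = 10,
    seed: int = 0,
    mask_only: bool = False,
    min_target_fraction: float = 0.8,
    max_discard_fraction: float = 0.5,
    keep_raw: bool = False,
) -> ConsistencyResult:
    """Cross-validated model consistency against a split-half noise ceiling.

    Per repeat: trials are split into stratified halves within each target
    (an odd trial goes to a random half); each half's per-target means are
    interpolated and mid-range normalized into patterns ``N1``/``N2``;
    internal consistency is ``Pearson(N1, N2)``; each model is fitted to each
    half (patterns ``M1``/``M2``) and its consistency is the mean of
    ``Pearson(N1, M2)`` and ``Pearson(N2, M1)``.  Results are averaged over
    ``n_repeats`` resamples; the spread is reported as the SE over repeats.

    Targets with fewer than 2 trials are excluded; the neuron-epoch is marked
    unusable if fewer than ``min_target_fraction`` of targets survive or if
    more than ``max_discard_fraction`` of repeats are degenerate (constant
    half-pattern after several redraws).
    """
    from .synthetic_data import rate_column  # local import to avoid a cycle

    col = rate_column(epoch)
    if trials["neuron_id"].nunique() != 1:
        raise ValueError("split_half_consistency expects trials of a single neuron")
    neuron_id = int(trials["neuron_id"].iloc[0])
    interp = interpolator or FieldInterpolator(config)
    active = config.active_targets
    index_order = [t.index for t in active]
    pos = {t_idx: i for i, t_idx in enumerate(index_order)}

    rates_by_target: dict[int, np.ndarray] = {}
    excluded = []
    for t_idx, grp in trials.groupby("target_index"):
        if t_idx not in pos:
            continue
        vals = grp[col].to_numpy(dtype=float)
        if len(vals) < 2:
            excluded.append(t_idx)
        else:
            rates_by_target[t_idx] = vals
    missing = [t for t in index_order if t not in rates_by_target]
    n_missing = len(missing)
    if n_missing > (1.0 - min_target_fraction) * len(index_order):
        return ConsistencyResult(
            neuron_id=neuron_id,
            epoch=epoch,
            internal_consistency=float("nan"),
            internal_se=float("nan"),
            model_consistency={m: float("nan") for m in models},
            model_se={m: float("nan") for m in models},
            n_resamples=0,
            unusable=True,
        )
    usable_targets = [t for t in index_order if t in rates_by_target]
    usable_pos = [pos[t] for t in usable_targets]
    sub_points = ModelPoints(config.active_xy()[usable_pos])
    # Interpolate only over usable targets when some are missing.
    if n_missing:
        sub_config = TargetConfiguration(
            task_id=config.task_id,
            targets=[config.target_by_index(t) for t in usable_targets],
            n_directions=config.n_directions,
            n_amplitudes=config.n_amplitudes,
            screen_distance=config.screen_distance,
        )
        interp = FieldInterpolator(sub_config, interp.grid)
    grid_points = ModelPoints.from_grid(interp.grid)

    rng = np.random.default_rng(np.random.SeedSequence([seed, neuron_id & 0x7FFFFFFF]))
    internal = np.empty(n_repeats)
    model_vals = {m: np.empty(n_repeats) for m in models}
    params_log: dict[int, list[np.ndarray]] = {m: [] for m in models}
    n_discarded = 0
    max_attempts = n_repeats * 4

    def one_split() -> tuple[np.ndarray, np.ndarray] | None:
        means1 = np.empty(len(usable_targets))
        means2 = np.empty(len(usable_targets))
        for i, t_idx in enumerate(usable_targets):
            vals = rates_by_target[t_idx]
            perm = rng.permutation(len(vals))
            half = len(vals) // 2
            if len(vals) % 2 == 1 and rng.random() < 0.5:
                half += 1
            means1[i] = vals[perm[:half]].mean()
            means2[i] = vals[perm[half:]].mean()
        p1 = midrange_normalize(interp(means1))
        p2 = midrange_normalize(interp(means2))
        if p1.degenerate or p2.degenerate:
            return None
        return p1.flat(mask_only=mask_only), p2.flat(mask_only=mask_only)

    rep = 0
    attempts = 0
    fit_points = grid_points if not mask_only else ModelPoints(
        interp.grid.flat_points()[interp.hull_mask.ravel()]
    )
    while rep < n_repeats and attempts < max_attempts:
        attempts += 1
        halves = one_split()
        if halves is None:
            n_discarded += 1
            continue
        n1, n2 = halves
        internal[rep] = _pearson(n1, n2)
        for m in models:
            fit_seed = np.random.default_rng(
                np.random.SeedSequence([seed, neuron_id & 0x7FFFFFFF, rep, m])
            )
            f1 = fit_model(m, n1, fit_points, n_restarts=n_restarts, seed=fit_seed)
            f2 = fit_model(m, n2, fit_points, n_restarts=n_restarts, seed=fit_seed)
            if f1.failure or f2.failure:
                model_vals[m][rep] = float("nan")
            else:
                model_vals[m][rep] = 0.5 * (_pearson(n1, f2.fitted) + _pearson(n2, f1.fitted))
            params_log[m].append(f1.params)
        rep += 1
    unusable = rep < n_repeats and n_discarded > max_discard_fraction * attempts
    internal = internal[:rep]
    for m in models:
        model_vals[m] = model_vals[m][:rep]

    def mean_se(v: np.ndarray) -> tuple[float, float]:
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return float("nan"), float("nan")
        if len(v) == 1:
            return float(v.mean()), 0.0
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))

    int_mean, int_se = mean_se(internal)
    return ConsistencyResult(
        neuron_id=neuron_id,
        epoch=epoch,
        internal_consistency=int_mean,
        internal_se=int_se,
        model_consistency={m: mean_se(model_vals[m])[0] for m in models},
        model_se={m: mean_se(model_vals[m])[1] for m in models},
        n_resamples=rep,
        n_discarded=n_discarded,
        unusable=unusable or rep == 0,
        raw_internal=internal if keep_raw else None,
        raw_model={m: model_vals[m] for m in models} if keep_raw else None,
        fitted_params=params_log,
    )


def consistency_table(results: Sequence[ConsistencyResult]) -> pd.DataFrame:
    """Tabulate per neuron-epoch consistencies for output and comparison."""
    rows = []
    for r in results:
        row = {
            "neuron_id": r.neuron_id,
            "epoch": r.epoch,
            "internal_consistency": r.internal_consistency,
            "internal_se": r.internal_se,
            "n_resamples": r.n_resamples,
            "n_discarded": r.n_discarded,
            "unusable": r.unusable,
        }
        for m in sorted(r.model_consistency):
            row[f"model{m}_consistency"] = r.model_consistency[m]
            row[f"model{m}_se"] = r.model_se[m]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(
    results: Sequence[ConsistencyResult] | pd.DataFrame,
    models: Sequence[int] = MODEL_IDS,
) -> dict:
    """Pairwise two-tailed Wilcoxon signed-rank tests on per-neuron model
    consistencies.

    Returns the p-value matrix, the per-model mean consistencies, and a
    winner summary (the model with the highest mean consistency plus the
    models it significantly beats at p < 0.05).  All-zero differences for a
    pair give p = 1 by convention.
    """
    table = results if isinstance(results, pd.DataFrame) else consistency_table(results)
    table = table[~table["unusable"].astype(bool)] if "unusable" in table else table
    cols = {m: table[f"model{m}_consistency"].to_numpy(dtype=float) for m in models}
    n = len(table)
    if n < 6:
        raise ValueError(f"need >= 6 neuron-epoch samples for the signed-rank test, got {n}")
    k = len(models)
    pmat = np.ones((k, k))
    for i, mi in enumerate(models):
        for j, mj in enumerate(models):
            if j <= i:
                continue
            diff = cols[mi] - cols[mj]
            diff = diff[np.isfinite(diff)]
            if len(diff) == 0 or np.all(diff == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
            pmat[i, j] = pmat[j, i] = p
    means = {m: float(np.nanmean(cols[m])) for m in models}
    best = max(means, key=means.get)
    bi = list(models).index(best)
    beats = [
        m
        for j, m in enumerate(models)
        if m != best and pmat[bi, j] < 0.05 and means[best] > means[m]
    ]
    return {
        "models": list(models),
        "p_matrix": pmat,
        "mean_consistency": means,
        "best_model": best,
        "significantly_beats": beats,
    }
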