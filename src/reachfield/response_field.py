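"""Interpolated 2D spatial response patterns and their characterization.

Per-target mean firing rates are linearly interpolated onto a Cartesian grid
(default 11x11 bins spanning 14 cm x 14 cm, centered at the origin).  Bins
outside the convex hull of the targets are filled with the nearest target's
value and flagged in the validity mask.  Downstream statistics use all bins
by default, with a mask-only mode available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial import QhullError, cKDTree, Delaunay

from .task_geometry import TargetConfiguration, cm_to_visual_degrees


@dataclass(frozen=True)
class GridSpec:
    """A square analysis grid: ``n_bins`` x ``n_bins`` bins spanning
    ``extent_cm`` x ``extent_cm`` centered at the origin.

    Bin centers sit at cell centers, so the bin side is ``extent_cm / n_bins``
    and the outermost centers lie half a bin inside the window edge.
    """

    n_bins: int = 11
    extent_cm: float = 14.0

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.extent_cm <= 0:
            raise ValueError("need n_bins >= 2 and extent_cm > 0")

    @property
    def bin_side(self) -> float:
        return self.extent_cm / self.n_bins

    @property
    def bin_area(self) -> float:
        return self.bin_side**2

    @property
    def centers(self) -> np.ndarray:
        half = self.extent_cm / 2.0
        return -half + (np.arange(self.n_bins) + 0.5) * self.bin_side

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) bin-center meshgrid, row index = y, column index = x."""
        c = self.centers
        return np.meshgrid(c, c, indexing="xy")

    def flat_points(self) -> np.ndarray:
        """(n_bins**2, 2) array of bin-center coordinates."""
        x, y = self.mesh()
        return np.column_stack([x.ravel(), y.ravel()])


@dataclass
class ResponsePattern:
    """A scalar field over a :class:`GridSpec` with a hull-validity mask.

    ``values[i, j]`` is the response at y-center ``grid.centers[i]`` and
    x-center ``grid.centers[j]``.  ``mask`` is True inside the interpolation
    hull.  ``normalized`` records whether mid-range normalization has been
    applied; ``degenerate`` flags an all-constant field; ``smoothed`` flags a
    display-only blurred pattern that quantification functions reject.
    """

    values: np.ndarray
    grid: GridSpec
    mask: np.ndarray
    normalized: bool = False
    degenerate: bool = False
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = (self.grid.n_bins, self.grid.n_bins)
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(f"values/mask must have shape {expected}")

    def flat(self, mask_only: bool = False) -> np.ndarray:
        """Bin values as a 1-D vector, optionally restricted to in-hull bins."""
        v = self.values.ravel()
        return v[self.mask.ravel()] if mask_only else v

    def write(self, path_matrix, path_sidecar=None) -> None:
        """Serialize as a delimited-text matrix plus an optional JSON sidecar."""
        np.savetxt(path_matrix, self.values, delimiter="\t", fmt="%.10g")
        if path_sidecar is not None:
            meta = {
                "n_bins": self.grid.n_bins,
                "extent_cm": self.grid.extent_cm,
                "bin_centers_cm": self.grid.centers.tolist(),
                "mask": self.mask.astype(int).tolist(),
                "normalized": self.normalized,
                "degenerate": self.degenerate,
                "smoothed": self.smoothed,
            }
            with open(path_sidecar, "w") as fh:
                json.dump(meta, fh, indent=1)


class FieldInterpolator:
    """Reusable piecewise-linear interpolator over a fixed target layout.

    The Delaunay triangulation and the nearest-target lookup are built once
    per (configuration, grid) pair; per-call work is only the barycentric
    evaluation, which makes split-half resampling loops cheap.
    """

    def __init__(self, config: TargetConfiguration, grid: GridSpec | None = None):
        self.config = config
        self.grid = grid or GridSpec()
        self.points = config.active_xy()
        if len(self.points) < 3:
            raise ValueError("need at least 3 targets to interpolate")
        try:
            self._tri = Delaunay(self.points)
        except QhullError as err:  # collinear or otherwise degenerate layout
            raise ValueError(f"degenerate target layout (collinear?): {err}") from None
        if self._tri.simplices.size == 0:
            raise ValueError("degenerate target layout: empty triangulation")
        self._kdtree = cKDTree(self.points)
        gp = self.grid.flat_points()
        # Precompute, per grid bin: containing simplex + barycentric weights
        # (in-hull), or nearest target index (out-of-hull).
        simplex = self._tri.find_simplex(gp)
        self._in_hull = simplex >= 0
        self._vertex_idx = np.zeros((len(gp), 3), dtype=int)
        self._weights = np.zeros((len(gp), 3))
        inh = np.where(self._in_hull)[0]
        if inh.size:
            s = simplex[inh]
            transform = self._tri.transform[s]
            delta = gp[inh] - transform[:, 2]
            bary = np.einsum("nij,nj->ni", transform[:, :2], delta)
            self._weights[inh, :2] = bary
            self._weights[inh, 2] = 1.0 - bary.sum(axis=1)
            self._vertex_idx[inh] = self._tri.simplices[s]
        out = np.where(~self._in_hull)[0]
        if out.size:
            _, nearest = self._kdtree.query(gp[out])
            self._vertex_idx[out, 0] = nearest
            self._weights[out, 0] = 1.0

    @property
    def hull_mask(self) -> np.ndarray:
        n = self.grid.n_bins
        return self._in_hull.reshape(n, n)

    def grid_values(self, target_rates: np.ndarray) -> np.ndarray:
        """Evaluate the interpolant at every bin center; (n_bins, n_bins)."""
        target_rates = np.asarray(target_rates, dtype=float)
        if target_rates.shape != (len(self.points),):
            raise ValueError(
                f"expected {len(self.points)} per-target rates, got {target_rates.shape}"
            )
        flat = (self._weights * target_rates[self._vertex_idx]).sum(axis=1)
        n = self.grid.n_bins
        return flat.reshape(n, n)

    def __call__(self, target_rates: np.ndarray) -> ResponsePattern:
        return ResponsePattern(
            values=self.grid_values(target_rates), grid=self.grid, mask=self.hull_mask
        )

    def at_points(self, target_rates: np.ndarray, xy: np.ndarray) -> np.ndarray:
        """Evaluate at arbitrary (n, 2) points (nearest-target outside hull)."""
        target_rates = np.asarray(target_rates, dtype=float)
        interp = LinearNDInterpolator(self._tri, target_rates)
        vals = interp(np.atleast_2d(xy))
        nan = np.isnan(vals)
        if np.any(nan):
            _, nearest = self._kdtree.query(np.atleast_2d(xy)[nan])
            vals[nan] = target_rates[nearest]
        return vals


def interpolate_pattern(
    target_rates: Sequence[float] | np.ndarray,
    config: TargetConfiguration,
    grid: GridSpec | None = None,
) -> ResponsePattern:
    """One-shot interpolation of per-active-target mean rates onto the grid.

    ``target_rates`` must align with ``config.active_targets``.  For repeated
    calls on the same layout, build a :class:`FieldInterpolator` once instead.
    """
    return FieldInterpolator(config, grid)(np.asarray(target_rates, dtype=float))


def midrange_normalize(values: np.ndarray | ResponsePattern):
    """Affine rescale onto [0, 1]: ``v <- (v - min) / (max - min)``.

    A constant input maps to all zeros and is flagged degenerate.  For an
    array input, returns ``(normalized_array, degenerate_flag)``; for a
    :class:`ResponsePattern`, returns a new pattern with flags set.
    Idempotent on non-degenerate inputs.
    """
    if isinstance(values, ResponsePattern):
        norm, degenerate = midrange_normalize(values.values)
        return replace(
            values, values=norm, normalized=True, degenerate=degenerate or values.degenerate
        )
    arr = np.asarray(values, dtype=float)
    lo, hi = arr.min(), arr.max()
    # relative tolerance so interpolation round-off on a constant field
    # (range ~1e-15 * value) still counts as degenerate
    if hi - lo <= 1e-12 * max(abs(hi), abs(lo)):
        return np.zeros_like(arr), True
    return (arr - lo) / (hi - lo), False


def _require_quantifiable(pattern: ResponsePattern, allow_smoothed: bool) -> None:
    if pattern.smoothed and not allow_smoothed:
        raise ValueError(
            "pattern was smoothed for display; quantification on smoothed "
            "patterns is disabled (pass allow_smoothed=True to override)"
        )


def peak_eccentricity(
    pattern: ResponsePattern,
    screen_distance: float | None = None,
    convention: str = "atan",
    mask_only: bool = False,
    allow_smoothed: bool = False,
) -> tuple[float, dict]:
    """Visual-angle eccentricity of the argmax bin center.

    Ties are broken by smallest eccentricity, then smallest angle; a tie is
    recorded in the returned flags.  Degenerate patterns yield NaN with a
    flag rather than raising.  Returns ``(degrees, flags)``.
    """
    _require_quantifiable(pattern, allow_smoothed)
    if screen_distance is None:
        screen_distance = 45.0
    flags = {"tie": False, "degenerate": False}
    considered = pattern.mask if mask_only else np.ones_like(pattern.mask, dtype=bool)
    v_considered = pattern.values[considered]
    if pattern.degenerate or v_considered.max() == v_considered.min():
        flags["degenerate"] = True
        return float("nan"), flags
    vals = np.where(considered, pattern.values, -np.inf)
    vmax = vals.max()
    iy, ix = np.nonzero(vals == vmax)
    centers = pattern.grid.centers
    xs, ys = centers[ix], centers[iy]
    ecc_cm = np.hypot(xs, ys)
    if len(ecc_cm) > 1:
        flags["tie"] = True
        angles = np.mod(np.degrees(np.arctan2(ys, xs)), 360.0)
        order = np.lexsort((angles, ecc_cm))
        best = order[0]
    else:
        best = 0
    return cm_to_visual_degrees(float(ecc_cm[best]), screen_distance, convention), flags


def field_width(
    pattern: ResponsePattern,
    screen_distance: float | None = None,
    convention: str = "atan",
    mask_only: bool = False,
    allow_smoothed: bool = False,
) -> tuple[float, dict]:
    """Visual-angle width: sqrt of the area holding the top quartile of bins.

    The threshold is the 75th percentile of considered bin values (linear
    interpolation between order statistics); bins with value >= threshold
    count toward the area.  Affine-invariant, so raw and normalized patterns
    give the same width.  Returns ``(degrees, flags)``.
    """
    _require_quantifiable(pattern, allow_smoothed)
    if screen_distance is None:
        screen_distance = 45.0
    flags = {"degenerate": bool(pattern.degenerate)}
    vals = pattern.flat(mask_only=mask_only)
    if np.all(vals == vals[0]):
        flags["degenerate"] = True
    threshold = np.percentile(vals, 75, method="linear")
    n_top = int(np.sum(vals >= threshold))
    area_cm2 = n_top * pattern.grid.bin_area
    return cm_to_visual_degrees(float(np.sqrt(area_cm2)), screen_distance, convention), flags


def smooth_for_display(pattern: ResponsePattern, kernel_width: float = 0.5) -> ResponsePattern:
    """Gaussian blur (sigma in bins, reflective padding) for figures only.

    The result is flagged ``smoothed``; :func:`peak_eccentricity` and
    :func:`field_width` refuse it unless explicitly overridden.  Reflective
    padding keeps the total mass unchanged.
    """
    blurred = gaussian_filter(pattern.values, sigma=kernel_width, mode="reflect")
    return replace(pattern, values=blurred, smoothed=True)
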