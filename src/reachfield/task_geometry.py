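"""Reach-target configurations and coordinate conventions.

Angles are degrees at every public interface, measured counterclockwise from
screen-rightward (+x); internal model math converts to radians.  Coordinates
are screen-centered (fixation at the origin) in centimeters, consistent with
center-out reaches from a central touch point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TASK1 = "task1"
TASK2 = "task2"

#: Default eye-to-screen distance in cm.
DEFAULT_SCREEN_DISTANCE_CM = 45.0

#: Mapping of the four cardinal reach directions to their angle in degrees.
CARDINAL_DIRECTIONS = {"RIGHT": 0.0, "UP": 90.0, "LEFT": 180.0, "DOWN": 270.0}


@dataclass(frozen=True)
class ReachTarget:
    """A single reach target in polar and Cartesian screen coordinates.

    Parameters
    ----------
    index : int
        Integer id, unique within a configuration.
    direction : float
        Angle in degrees, counterclockwise from +x, wrapped into [0, 360).
    amplitude : float
        Radial distance from screen center in cm; strictly positive.
    """

    index: int
    direction: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        object.__setattr__(self, "direction", float(self.direction) % 360.0)
        object.__setattr__(self, "amplitude", float(self.amplitude))

    @property
    def x(self) -> float:
        """Cartesian x in cm."""
        return self.amplitude * math.cos(math.radians(self.direction))

    @property
    def y(self) -> float:
        """Cartesian y in cm."""
        return self.amplitude * math.sin(math.radians(self.direction))

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class TargetConfiguration:
    """A reach-target layout with task metadata.

    ``omitted_targets`` holds indices of targets excluded from analysis
    (e.g. dropped for insufficient trials); :attr:`active_targets` filters
    them out.
    """

    task_id: str
    targets: list[ReachTarget]
    n_directions: int
    n_amplitudes: int
    screen_distance: float = DEFAULT_SCREEN_DISTANCE_CM
    omitted_targets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.screen_distance <= 0:
            raise ValueError("screen_distance must be > 0")
        indices = [t.index for t in self.targets]
        if len(set(indices)) != len(indices):
            raise ValueError("target indices must be unique")
        unknown = set(self.omitted_targets) - set(indices)
        if unknown:
            raise ValueError(f"omitted_targets reference unknown indices: {sorted(unknown)}")

    @property
    def active_targets(self) -> list[ReachTarget]:
        omitted = set(self.omitted_targets)
        return [t for t in self.targets if t.index not in omitted]

    @property
    def directions(self) -> np.ndarray:
        """Sorted unique directions (deg) over active targets."""
        return np.unique(np.array([t.direction for t in self.active_targets]))

    @property
    def amplitudes(self) -> np.ndarray:
        """Sorted unique amplitudes (cm) over active targets."""
        return np.unique(np.array([t.amplitude for t in self.active_targets]))

    def target_by_index(self, index: int) -> ReachTarget:
        for t in self.targets:
            if t.index == index:
                return t
        raise KeyError(f"no target with index {index}")

    def active_xy(self) -> np.ndarray:
        """(n, 2) array of active-target Cartesian coordinates in cm."""
        return np.array([[t.x, t.y] for t in self.active_targets])

    def to_frame(self) -> pd.DataFrame:
        """Tabulate all targets (active and omitted) with an ``omitted`` flag."""
        omitted = set(self.omitted_targets)
        return pd.DataFrame(
            {
                "index": [t.index for t in self.targets],
                "direction_deg": [t.direction for t in self.targets],
                "amplitude_cm": [t.amplitude for t in self.targets],
                "x_cm": [t.x for t in self.targets],
                "y_cm": [t.y for t in self.targets],
                "omitted": [t.index in omitted for t in self.targets],
            }
        )

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def make_task1(
    amp_small: float = 2.5,
    amp_large: float = 7.0,
    screen_distance: float = DEFAULT_SCREEN_DISTANCE_CM,
) -> TargetConfiguration:
    """Four equally distributed directions x two amplitudes (8 targets).

    Directions are the cardinals {0, 90, 180, 270} deg, i.e. RIGHT, UP,
    LEFT, DOWN.  Target indices enumerate direction-major, small amplitude
    before large.
    """
    if amp_small <= 0 or amp_large <= 0:
        raise ValueError("amplitudes must be positive")
    if amp_small >= amp_large:
        raise ValueError(f"need amp_small < amp_large, got {amp_small} >= {amp_large}")
    targets = []
    idx = 0
    for direction in (0.0, 90.0, 180.0, 270.0):
        for amp in (amp_small, amp_large):
            targets.append(ReachTarget(index=idx, direction=direction, amplitude=amp))
            idx += 1
    return TargetConfiguration(
        task_id=TASK1,
        targets=targets,
        n_directions=4,
        n_amplitudes=2,
        screen_distance=screen_distance,
    )


def make_task2(
    amps: Sequence[float] = (2.5, 4.75, 7.0),
    radial_offset: float = 7.5,
    omit: Iterable[int] = (),
    screen_distance: float = DEFAULT_SCREEN_DISTANCE_CM,
) -> TargetConfiguration:
    """16 equally spaced directions x three amplitude rings (48 targets).

    Each ring ``i`` (0-based, ordered by increasing amplitude) is rotated by
    ``radial_offset * i`` degrees relative to a perfectly radial layout, so
    the three rings are staggered.  ``omit`` marks target indices as omitted
    without removing them from the table.  Default amplitudes span the
    standard 14 cm x 14 cm interpolation window.
    """
    amps = tuple(float(a) for a in amps)
    if len(amps) != 3:
        raise ValueError(f"exactly 3 amplitudes required, got {len(amps)}")
    if amps[0] <= 0 or not (amps[0] < amps[1] < amps[2]):
        raise ValueError(f"amplitudes must be positive and strictly increasing: {amps}")
    spacing = 360.0 / 16
    if abs(radial_offset) >= spacing:
        raise ValueError(
            f"|radial_offset| must be < ring spacing {spacing} deg, got {radial_offset}"
        )
    targets = []
    idx = 0
    for ring, amp in enumerate(amps):
        for k in range(16):
            direction = (k * spacing + radial_offset * ring) % 360.0
            targets.append(ReachTarget(index=idx, direction=direction, amplitude=amp))
            idx += 1
    return TargetConfiguration(
        task_id=TASK2,
        targets=targets,
        n_directions=16,
        n_amplitudes=3,
        screen_distance=screen_distance,
        omitted_targets=sorted(omit),
    )


def cm_to_visual_degrees(
    d: float | np.ndarray,
    screen_distance: float = DEFAULT_SCREEN_DISTANCE_CM,
    convention: str = "atan",
) -> float | np.ndarray:
    """Convert an on-screen distance in cm to degrees of visual angle.

    ``convention="atan"`` (default) uses the exact ``atan(d / D)``;
    ``convention="linear"`` uses the small-angle form ``d / D`` in radians.
    The two agree to <1% for ``d / D < 0.15``.
    """
    if screen_distance <= 0:
        raise ValueError("screen_distance must be > 0")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance must be non-negative")
    if convention == "atan":
        out = np.degrees(np.arctan(d_arr / screen_distance))
    elif convention == "linear":
        out = np.degrees(d_arr / screen_distance)
    else:
        raise ValueError(f"unknown convention {convention!r}; use 'atan' or 'linear'")
    return float(out) if np.isscalar(d) else out


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angular difference in degrees into (-180, 180]."""
    wrapped = -(np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0)
    return float(wrapped) if np.isscalar(angle) else wrapped
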