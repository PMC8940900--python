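"""Core data containers shared across the pipeline stages.

The pipeline operates on four kinds of records: 2-D video-tracking
trajectories inside a named arena, two-channel fiber-photometry
recordings (490 nm calcium-dependent + 405 nm isosbestic control),
families of patch-clamp step sweeps, and per-mouse summary rows.
Everything here is a plain dataclass; the stage modules own the
algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rect",
    "ArenaSpec",
    "Trajectory",
    "PhotometryRecording",
    "SweepSet",
    "MouseRecord",
]


@dataclass(frozen=True)
class Rect:
    """Closed axis-aligned rectangle in cm. Boundary points count as inside."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, x, y):
        """Vectorized closed-rectangle membership."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


@dataclass(frozen=True)
class ArenaSpec:
    """A behavioral arena: overall extents plus named zones.

    A zone is a union of closed rectangles (sufficient for the plus maze,
    open field, social-interaction and three-chamber arenas).  Zone
    insertion order is the deterministic tie-break when a sample sits on a
    shared boundary: assignment scans take the first matching zone.
    """

    name: str
    extents: Rect
    zones: dict[str, tuple[Rect, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for zname, rects in self.zones.items():
            for r in rects:
                if not (
                    r.x0 >= self.extents.x0
                    and r.x1 <= self.extents.x1
                    and r.y0 >= self.extents.y0
                    and r.y1 <= self.extents.y1
                ):
                    raise ValueError(
                        f"zone {zname!r} rectangle {r} exceeds arena extents"
                    )

    def zone_names(self) -> list[str]:
        return list(self.zones)

    def in_zone(self, zone: str, x, y):
        """Boolean membership of points in the named zone."""
        if zone not in self.zones:
            raise KeyError(f"unknown zone {zone!r} in arena {self.name!r}")
        rects = self.zones[zone]
        x = np.asarray(x)
        y = np.asarray(y)
        out = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        for r in rects:
            out |= r.contains(x, y)
        return out


@dataclass
class Trajectory:
    """Uniformly sampled 2-D track of the animal's center point."""

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    arena: ArenaSpec

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if t.size == 0:
            raise ValueError("empty trajectory")
        if t.size != len(self.x_cm) or t.size != len(self.y_cm):
            raise ValueError("time and position arrays differ in length")
        dt = np.diff(t)
        if t.size > 1:
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 1e-6 * dt.mean():
                raise ValueError("sampling interval not constant within 1 ppm")

    @property
    def dt_s(self) -> float:
        if len(self.time_s) < 2:
            return float("nan")
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        # duration counts every sample at one sampling interval
        return len(self.time_s) * self.dt_s

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class PhotometryRecording:
    """Decimated two-channel photometry record.

    ``f490`` is the calcium-dependent channel, ``f405`` the isosbestic
    control; both in arbitrary fluorescence units on a common time base
    (default 381 Hz).  ``sync_events`` are behavior-synchronization
    timestamps (stand-ins for acquisition TTLs), as (time_s, label).
    """

    time_s: np.ndarray
    f490: np.ndarray
    f405: np.ndarray
    rate_hz: float = 381.0
    sync_events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.time_s)
        if len(self.f490) != n or len(self.f405) != n:
            raise ValueError("channel lengths differ")
        if n > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return len(self.time_s) / self.rate_hz

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class SweepSet:
    """A family of step-protocol sweeps from one neuron.

    ``protocol`` is one of ``cell_attached``, ``excitability``,
    ``ih_vclamp``, ``sag_cclamp``.  ``commands`` are the per-sweep step
    commands (pA for current clamp, mV for voltage clamp), strictly
    increasing; ``traces`` is (n_sweeps, n_samples) in mV (current clamp)
    or pA (voltage clamp).  ``step_on_s``/``step_off_s`` delimit the
    command step within each sweep.
    """

    protocol: str
    commands: np.ndarray
    traces: np.ndarray
    rate_hz: float
    step_on_s: float
    step_off_s: float

    def __post_init__(self) -> None:
        cmds = np.asarray(self.commands, dtype=float)
        if cmds.ndim != 1 or len(cmds) != self.traces.shape[0]:
            raise ValueError("one command per sweep required")
        if len(cmds) > 1 and np.any(np.diff(cmds) <= 0):
            raise ValueError("command values must be strictly increasing")
        if self.step_off_s <= self.step_on_s:
            raise ValueError("step window is empty")

    @property
    def n_sweeps(self) -> int:
        return int(self.traces.shape[0])

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.traces.shape[1]) / self.rate_hz


@dataclass
class MouseRecord:
    """Per-mouse behavioral and circuit summary; the unit of correlation."""

    mouse_id: str
    stressed: bool
    si_time_target_s: float | None = None
    si_time_notarget_s: float | None = None
    si_ratio: float | None = None
    group: str | None = None  # CTL / A / AD
    epm_open_time_s: float | None = None
    epm_open_pct: float | None = None
    epm_open_entries: int | None = None
    oft_center_pct: float | None = None
    oft_center_entries: int | None = None
    fust_preference: float | None = None
    sucrose_preference: float | None = None
    firing_hz: float | None = None
    events_per_min: float | None = None
    auc_per_s: dict[str, float] = field(default_factory=dict)
    summary_z: dict[str, float] = field(default_factory=dict)
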