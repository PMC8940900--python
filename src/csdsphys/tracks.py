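"""Zone-biased random-walk trajectory generator.

The walk emulates a video-tracked center point at a fixed frame rate.
A schedule of zone dwells — allocated in proportion to the requested
occupancy fractions by largest-remainder apportionment, in shuffled
order — drives the walk: within a dwell it diffuses inside one rectangle
of the zone with reflecting walls, and between dwells it moves toward a
point of the next zone at a bounded speed (via the arena center for
plus-shaped mazes, where arms only connect through the hub).  Realized
occupancy therefore tracks the targets at trial length, with the only
systematic error coming from transit time between zones.

Entry/exit micro-structure is not modeled; the walk exists to exercise
the behavioral scoring stage, not to mimic rodent locomotion.
"""

from __future__ import annotations

import math

import numpy as np

from .core import ArenaSpec, Rect, Trajectory

__all__ = ["gen_trajectory"]

REST_ZONE = "_rest"  # pseudo-zone: arena area outside every named zone


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by reflection."""
    rng = hi - lo
    if rng <= 0:
        return lo
    v = (v - lo) % (2.0 * rng)
    if v > rng:
        v = 2.0 * rng - v
    return v + lo


def _in_named_zone(arena: ArenaSpec, x: float, y: float) -> bool:
    for rects in arena.zones.values():
        for r in rects:
            if r.x0 <= x <= r.x1 and r.y0 <= y <= r.y1:
                return True
    return False


def _zones_cover_extents(arena: ArenaSpec) -> bool:
    """Heuristic: do the named zones tile the full extents rectangle?

    Checked on the extents' corners and midpoints; a plus maze fails
    (corner regions are off-apparatus) while square fields pass.
    """
    e = arena.extents
    xs = (e.x0, 0.5 * (e.x0 + e.x1), e.x1)
    ys = (e.y0, 0.5 * (e.y0 + e.y1), e.y1)
    return all(_in_named_zone(arena, x, y) for x in xs for y in ys)


def gen_trajectory(
    arena: ArenaSpec,
    occupancy_targets: dict[str, float],
    duration_s: float,
    video_hz: float = 30.0,
    seed: int | np.random.SeedSequence = 0,
    step_sd_cm: float = 1.2,
    transit_speed_cm_s: float = 25.0,
    dwell_mean_s: float = 4.0,
) -> Trajectory:
    """Simulate a tracked trajectory hitting the given zone occupancies.

    ``occupancy_targets`` maps zone names to target fractions summing to
    at most 1; the remainder is spent in the unzoned area of the arena.
    The number of samples is ``round(duration_s * video_hz)``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if video_hz <= 0:
        raise ValueError("video rate must be positive")
    for z in occupancy_targets:
        if z not in arena.zones:
            raise KeyError(f"unknown zone {z!r} in arena {arena.name!r}")
    fracs = np.array([max(0.0, f) for f in occupancy_targets.values()], dtype=float)
    total = fracs.sum()
    if total > 1.0 + 1e-9:
        raise ValueError(f"occupancy targets sum to {total:.3f} > 1")

    zone_names = list(occupancy_targets)
    rest = 1.0 - total
    if rest > 1e-9:
        zone_names.append(REST_ZONE)
        fracs = np.append(fracs, rest)
    fracs = fracs / fracs.sum()

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * video_hz))
    dt = 1.0 / video_hz
    step_max = 4.0 * step_sd_cm  # continuity bound on per-frame displacement
    transit_step = transit_speed_cm_s * dt
    via_center = not _zones_cover_extents(arena) and len(arena.zones) > 1
    hub = arena.extents.center

    # pre-draw all diffusion noise; the walk loop runs on python floats
    noise = rng.normal(0.0, step_sd_cm, size=(n, 2))
    np.clip(noise, -step_max, step_max, out=noise)

    def pick_rect(zone: str) -> Rect | None:
        if zone == REST_ZONE:
            return None
        rects = arena.zones[zone]
        if len(rects) == 1:
            return rects[0]
        areas = np.array([r.area for r in rects])
        return rects[rng.choice(len(rects), p=areas / areas.sum())]

    def rest_point() -> tuple[float, float]:
        """A point of the arena outside every named zone (rejection sample)."""
        e = arena.extents
        for _ in range(200):
            px = rng.uniform(e.x0, e.x1)
            py = rng.uniform(e.y0, e.y1)
            if not _in_named_zone(arena, px, py):
                return px, py
        return e.center  # zones (nearly) tile the arena; degenerate rest

    def quota_block() -> list[int]:
        """Shuffled zone indices allocated in proportion to the targets.

        Largest-remainder apportionment keeps realized occupancy tight
        around the targets at trial length instead of fluctuating like an
        i.i.d. draw.
        """
        n_seg = max(len(zone_names), int(round(duration_s / dwell_mean_s)))
        ideal = fracs * n_seg
        counts = np.floor(ideal).astype(int)
        short = n_seg - counts.sum()
        if short > 0:
            order = np.argsort(-(ideal - counts))
            counts[order[:short]] += 1
        block = np.repeat(np.arange(len(zone_names)), counts)
        return list(rng.permutation(block))

    schedule: list[int] = []

    def next_dwell() -> tuple[str, int, Rect | None]:
        if not schedule:
            schedule.extend(quota_block())
        z = zone_names[schedule.pop()]
        dur = max(1, int(round(dwell_mean_s * rng.uniform(0.8, 1.2) * video_hz)))
        return z, dur, pick_rect(z)

    def arrived(zone: str, rect: Rect | None, px: float, py: float) -> bool:
        if zone == REST_ZONE:
            return not _in_named_zone(arena, px, py)
        return rect.x0 <= px <= rect.x1 and rect.y0 <= py <= rect.y1

    zone, remaining, rect = next_dwell()
    if rect is not None:
        cx, cy = rect.center
        x = cx + rng.uniform(-0.4, 0.4) * (rect.x1 - rect.x0)
        y = cy + rng.uniform(-0.4, 0.4) * (rect.y1 - rect.y0)
    else:
        x, y = rest_point()

    xs = np.empty(n)
    ys = np.empty(n)
    single_zone = len(zone_names) == 1
    in_transit = False
    waypoints: list[tuple[float, float]] = []

    def start_transit() -> list[tuple[float, float]]:
        goal = rect.center if rect is not None else rest_point()
        return ([hub, goal] if via_center else [goal])

    for i in range(n):
        if in_transit:
            tx, ty = waypoints[0]
            dx = tx - x
            dy = ty - y
            d = math.hypot(dx, dy)
            if d <= transit_step:
                x, y = tx, ty
                waypoints.pop(0)
            else:
                s = transit_step / d
                x += dx * s + 0.2 * noise[i, 0]
                y += dy * s + 0.2 * noise[i, 1]
            x = _reflect(x, arena.extents.x0, arena.extents.x1)
            y = _reflect(y, arena.extents.y0, arena.extents.y1)
            if not waypoints or (len(waypoints) == 1 and arrived(zone, rect, x, y)):
                in_transit = False
        else:
            lo_x, hi_x = (arena.extents.x0, arena.extents.x1) if rect is None else (rect.x0, rect.x1)
            lo_y, hi_y = (arena.extents.y0, arena.extents.y1) if rect is None else (rect.y0, rect.y1)
            nx = _reflect(x + noise[i, 0], lo_x, hi_x)
            ny = _reflect(y + noise[i, 1], lo_y, hi_y)
            if zone == REST_ZONE and _in_named_zone(arena, nx, ny):
                pass  # rejected step: stay put to remain in unzoned area
            else:
                x, y = nx, ny
        xs[i] = x
        ys[i] = y
        if not single_zone and not in_transit:
            # the dwell clock only runs once the destination is reached
            remaining -= 1
            if remaining <= 0:
                zone, remaining, rect = next_dwell()
                if not arrived(zone, rect, x, y):
                    in_transit = True
                    waypoints = start_transit()

    t = np.arange(n) / video_hz
    return Trajectory(time_s=t, x_cm=xs, y_cm=ys, arena=arena)
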