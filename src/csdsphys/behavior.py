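"""Behavioral scoring: zone occupancy, preference indices, phenotyping.

Zone membership uses the tracked center point with closed-rectangle
zones; when zones share a boundary, a sample is assigned to the first
matching zone in the arena's insertion order, so a partition of the
arena yields exactly additive occupancy times.  Entries use a
minimum-dwell hysteresis (default 0.2 s) to suppress boundary jitter,
and initial placement inside a zone counts as one entry.

Phenotype classification follows the social-interaction (SI) ratio rule:
stressed mice with SI ratio >= 100 are resilient ("A", anxiety-only),
stressed mice below 100 are susceptible ("AD", anxiety + depressive-
like), and unstressed mice are controls ("CTL").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory

__all__ = [
    "ZoneOccupancy",
    "assign_zones",
    "zone_occupancy",
    "zone_entry_times",
    "si_ratio",
    "classify_mouse",
    "sucrose_preference",
    "fust_preference",
    "UndefinedRatioError",
]

UNZONED = "_unzoned"


class UndefinedRatioError(ZeroDivisionError):
    """Denominator of a behavioral ratio is zero; flag the mouse instead."""


@dataclass
class ZoneOccupancy:
    time_in_zone_s: dict[str, float] = field(default_factory=dict)
    entries: dict[str, int] = field(default_factory=dict)
    distance_cm: float = 0.0
    mean_velocity_cm_s: float = 0.0
    duration_s: float = 0.0


def assign_zones(traj: Trajectory) -> np.ndarray:
    """One zone label per sample; first matching zone wins, else ``_unzoned``."""
    labels = np.full(len(traj), UNZONED, dtype=object)
    unassigned = np.ones(len(traj), dtype=bool)
    for zname in traj.arena.zones:
        hit = unassigned & traj.arena.in_zone(zname, traj.x_cm, traj.y_cm)
        labels[hit] = zname
        unassigned &= ~hit
    return labels


def _entries_from_mask(inside: np.ndarray, min_dwell_n: int) -> int:
    """Count outside->inside transitions persisting at least ``min_dwell_n``."""
    count = 0
    i = 0
    n = len(inside)
    prev_in = False
    while i < n:
        if inside[i] and not prev_in:
            run = i
            while run < n and inside[run]:
                run += 1
            if run - i >= min_dwell_n:
                count += 1
            prev_in = True
            i = run
        else:
            prev_in = bool(inside[i])
            i += 1
    return count


def zone_occupancy(traj: Trajectory, min_dwell_s: float = 0.2) -> ZoneOccupancy:
    """Time, entries, distance and velocity for every zone of the arena.

    Time in zone = (samples assigned to the zone) x sampling interval;
    an entry is an outside-to-inside transition whose inside run lasts at
    least ``min_dwell_s``.  Distance is the summed Euclidean step length.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    dt = traj.dt_s
    labels = assign_zones(traj)
    # at least one sample of dwell even at coarse frame rates
    min_dwell_n = max(1, int(round(min_dwell_s / dt))) if np.isfinite(dt) else 1

    occ = ZoneOccupancy(duration_s=traj.duration_s)
    for zname in traj.arena.zones:
        inside = labels == zname
        occ.time_in_zone_s[zname] = float(inside.sum() * dt)
        occ.entries[zname] = _entries_from_mask(inside, min_dwell_n)

    steps = np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))
    occ.distance_cm = float(steps.sum())
    occ.mean_velocity_cm_s = float(occ.distance_cm / traj.duration_s) if traj.duration_s > 0 else 0.0
    return occ


def zone_entry_times(traj: Trajectory, zone: str, min_dwell_s: float = 0.2) -> np.ndarray:
    """Times of qualifying entries into one zone (union membership).

    Used to time-lock photometry epochs to behavior onsets; membership
    here is the zone's own rectangles (not the partition assignment), so
    an entry is counted whenever the center point crosses into the zone.
    """
    inside = np.asarray(traj.arena.in_zone(zone, traj.x_cm, traj.y_cm))
    dt = traj.dt_s
    min_dwell_n = max(1, int(round(min_dwell_s / dt))) if np.isfinite(dt) else 1
    times = []
    i = 0
    n = len(inside)
    prev_in = False
    while i < n:
        if inside[i] and not prev_in:
            run = i
            while run < n and inside[run]:
                run += 1
            if run - i >= min_dwell_n:
                times.append(traj.time_s[i])
            prev_in = True
            i = run
        else:
            prev_in = bool(inside[i])
            i += 1
    return np.asarray(times)


def si_ratio(time_target_s: float, time_notarget_s: float) -> float:
    """Social-interaction ratio, percent: 100 x target-phase / no-target-phase."""
    if time_target_s < 0 or time_notarget_s < 0:
        raise ValueError("zone times must be non-negative")
    if time_notarget_s == 0:
        raise UndefinedRatioError("no-target zone time is zero; SI ratio undefined")
    return 100.0 * time_target_s / time_notarget_s


def classify_mouse(si_ratio_pct: float, stressed: bool) -> str:
    """CTL if unstressed; A (resilient) if SI ratio >= 100; AD (susceptible) below."""
    if not np.isfinite(si_ratio_pct) or si_ratio_pct < 0:
        raise ValueError("SI ratio must be finite and non-negative")
    if not stressed:
        return "CTL"
    return "A" if si_ratio_pct >= 100.0 else "AD"


def sucrose_preference(sucrose_consumed_g: float, water_consumed_g: float) -> float:
    """Percent of total fluid intake taken from the sucrose bottle."""
    total = sucrose_consumed_g + water_consumed_g
    if sucrose_consumed_g < 0 or water_consumed_g < 0:
        raise ValueError("consumption must be non-negative")
    if total <= 0:
        raise UndefinedRatioError("no fluid consumed; sucrose preference undefined")
    return 100.0 * sucrose_consumed_g / total


def fust_preference(time_urine_zone_s: float, time_water_zone_s: float) -> float:
    """Female-urine sniffing preference: urine-zone time / water-zone time."""
    if time_urine_zone_s < 0 or time_water_zone_s < 0:
        raise ValueError("zone times must be non-negative")
    if time_water_zone_s == 0:
        raise UndefinedRatioError("water-zone time is zero; preference undefined")
    return time_urine_zone_s / time_water_zone_s
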