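"""Builders for the four behavioral arenas.

Geometry follows the apparatus dimensions used throughout the study:

* elevated plus maze (EPM): four arms of 70 x 5 cm around a 5 x 5 cm
  center platform; zones ``open`` (two arms), ``closed`` (two arms),
  ``center``;
* open field (OFT): 44 x 44 cm with a 10 x 10 cm ``center`` zone and a
  ``periphery`` frame;
* social-interaction arena (SI): a 44 x 44 cm open field with a wire-mesh
  cage on one wall and an ``interaction`` zone abutting it (the mesh-cage
  zone size is not standardized; the default is configurable);
* three-chamber arena: three 44 x 17 cm chambers side by side, with 3 x 5 cm
  sniffing zones (``urine_zone`` / ``water_zone``) at the center of the two
  side chambers.
"""

from __future__ import annotations

from .core import ArenaSpec, Rect

__all__ = ["epm_arena", "oft_arena", "si_arena", "three_chamber_arena", "make_arena"]

EPM_ARM_LENGTH_CM = 70.0
EPM_ARM_WIDTH_CM = 5.0
OFT_SIDE_CM = 44.0
OFT_CENTER_CM = 10.0
CHAMBER_W_CM = 44.0
CHAMBER_D_CM = 17.0


def epm_arena(arm_length: float = EPM_ARM_LENGTH_CM, arm_width: float = EPM_ARM_WIDTH_CM) -> ArenaSpec:
    """Plus maze centered at the origin; open arms along x, closed along y."""
    h = arm_width / 2.0
    span = h + arm_length
    extents = Rect(-span, -span, span, span)
    zones = {
        "open": (Rect(h, -h, span, h), Rect(-span, -h, -h, h)),
        "closed": (Rect(-h, h, h, span), Rect(-h, -span, h, -h)),
        "center": (Rect(-h, -h, h, h),),
    }
    return ArenaSpec("EPM", extents, zones)


def oft_arena(side: float = OFT_SIDE_CM, center: float = OFT_CENTER_CM) -> ArenaSpec:
    """Square open field with a centered center zone and a periphery frame."""
    c0 = (side - center) / 2.0
    c1 = c0 + center
    extents = Rect(0.0, 0.0, side, side)
    zones = {
        "center": (Rect(c0, c0, c1, c1),),
        "periphery": (
            Rect(0.0, 0.0, side, c0),
            Rect(0.0, c1, side, side),
            Rect(0.0, c0, c0, c1),
            Rect(c1, c0, side, c1),
        ),
    }
    return ArenaSpec("OFT", extents, zones)


def si_arena(
    side: float = OFT_SIDE_CM,
    interaction_w: float = 26.0,
    interaction_d: float = 16.0,
    corner: float = 9.0,
) -> ArenaSpec:
    """Open field with a mesh cage on the far (y = side) wall.

    The ``interaction`` zone is a rectangle centered on that wall; the two
    ``corners`` opposite the cage are the avoidance zones.  Neither zone
    size is standardized across labs, so both are parameters.
    """
    x0 = (side - interaction_w) / 2.0
    extents = Rect(0.0, 0.0, side, side)
    zones = {
        "interaction": (Rect(x0, side - interaction_d, x0 + interaction_w, side),),
        "corners": (Rect(0.0, 0.0, corner, corner), Rect(side - corner, 0.0, side, corner)),
    }
    return ArenaSpec("SI", extents, zones)


def three_chamber_arena(
    chamber_w: float = CHAMBER_W_CM,
    chamber_d: float = CHAMBER_D_CM,
    sniff_w: float = 3.0,
    sniff_d: float = 5.0,
) -> ArenaSpec:
    """Three chambers stacked along y; sniffing zones centered in the side chambers."""
    extents = Rect(0.0, 0.0, chamber_w, 3 * chamber_d)
    cx = chamber_w / 2.0

    def sniff(cy: float) -> Rect:
        return Rect(cx - sniff_w / 2.0, cy - sniff_d / 2.0, cx + sniff_w / 2.0, cy + sniff_d / 2.0)

    zones = {
        "urine_zone": (sniff(chamber_d / 2.0),),
        "water_zone": (sniff(2.5 * chamber_d),),
        "left": (Rect(0.0, 0.0, chamber_w, chamber_d),),
        "middle": (Rect(0.0, chamber_d, chamber_w, 2 * chamber_d),),
        "right": (Rect(0.0, 2 * chamber_d, chamber_w, 3 * chamber_d),),
    }
    return ArenaSpec("ThreeChamber", extents, zones)


_BUILDERS = {
    "EPM": epm_arena,
    "OFT": oft_arena,
    "SI": si_arena,
    "ThreeChamber": three_chamber_arena,
}


def make_arena(name: str, **kwargs) -> ArenaSpec:
    try:
        return _BUILDERS[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown arena {name!r}; choose from {sorted(_BUILDERS)}") from None
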