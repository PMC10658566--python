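"""Microneedle and patch geometry.

Two needle shapes are supported, matching the two microneedle (MN)
classes used in Franz-cell permeation studies: PEGDA hydrogel needles
shaped as a conical frustum, and plastic (solid) needles shaped as a
regular square pyramid used to pre-treat the skin.

Surface areas count the faces in contact with skin: the lateral faces
plus, for the frustum, the top cap.  The base face attached to the
patch backing is excluded for both shapes.

Lengths are in micrometres (µm); reported areas are in mm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "FrustumNeedle",
    "PyramidNeedle",
    "PatchLayout",
    "Needle",
    "frustum_surface_area",
    "pyramid_surface_area",
    "needle_surface_area",
    "patch_surface_area",
    "rasterize_half_needle",
]

_UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class FrustumNeedle:
    """Conical-frustum needle (hydrogel MN).

    Parameters
    ----------
    r_top : float
        Radius of the top circle (needle tip, deepest in skin), µm.
    r_base : float
        Radius of the bottom circle (attached to the patch backing,
        at the skin surface), µm.
    slant : float
        Slant height of the frustum, µm.
    length : float
        Axial needle length, µm.
    """

    r_top: float
    r_base: float
    slant: float
    length: float

    def __post_init__(self) -> None:
        for name in ("r_top", "r_base", "slant", "length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.slant < self.length:
            raise ValueError("slant height cannot be shorter than axial length")
        # Pythagorean consistency when all four dimensions are meaningful
        expected = math.hypot(self.r_base - self.r_top, self.length)
        if expected > 0 and not math.isclose(self.slant, expected, rel_tol=1e-6):
            raise ValueError(
                f"inconsistent frustum: slant={self.slant} but "
                f"sqrt((R-r)^2 + L^2)={expected}"
            )

    def half_width_at(self, depth: float) -> float:
        """Half cross-section width (radius) at a given depth below the
        skin surface, µm.  Linear taper from r_base at depth 0 to r_top
        at depth ``length``; zero beyond the tip."""
        if depth < 0 or depth >= self.length:
            if self.length == 0:
                return 0.0
            return 0.0 if depth >= self.length else self.r_base
        frac = depth / self.length
        return self.r_base + (self.r_top - self.r_base) * frac


@dataclass(frozen=True)
class PyramidNeedle:
    """Regular square-pyramid needle (plastic / solid MN).

    Parameters
    ----------
    base_edge : float
        Edge length of the bottom square (at the patch backing), µm.
    height : float
        Apex-to-base height, µm.
    """

    base_edge: float
    height: float

    def __post_init__(self) -> None:
        if self.base_edge < 0:
            raise ValueError("base_edge must be non-negative")
        if self.height < 0:
            raise ValueError("height must be non-negative")

    @property
    def length(self) -> float:
        return self.height

    def half_width_at(self, depth: float) -> float:
        """Half cross-section width at a given depth below the skin
        surface, µm.  The base sits at the surface, the apex at depth
        ``height``."""
        if self.height == 0 or depth < 0 or depth >= self.height:
            return 0.0
        return (self.base_edge / 2.0) * (1.0 - depth / self.height)


Needle = Union[FrustumNeedle, PyramidNeedle]


@dataclass(frozen=True)
class PatchLayout:
    """A microneedle patch: one needle design replicated n times."""

    needle: Needle
    n_needles: int
    needle_type_label: str = "hydrogel"

    def __post_init__(self) -> None:
        if self.n_needles < 0 or int(self.n_needles) != self.n_needles:
            raise ValueError("n_needles must be a non-negative integer")
        if self.needle_type_label not in ("hydrogel", "plastic"):
            raise ValueError("needle_type_label must be 'hydrogel' or 'plastic'")


def frustum_surface_area(needle: FrustumNeedle) -> float:
    """Skin-contact surface area of a frustum needle, mm².

    S = π r² + π (R + r) l : top cap plus lateral frustum surface.
    The base circle (patch side) is excluded.
    """
    r, big_r, slant = needle.r_top, needle.r_base, needle.slant
    area_um2 = math.pi * r * r + math.pi * (big_r + r) * slant
    return area_um2 / _UM2_PER_MM2


def pyramid_surface_area(needle: PyramidNeedle) -> float:
    """Skin-contact surface area of a square-pyramid needle, mm².

    S = 4 · (a/2) · sqrt((a/2)² + h²) : the four triangular lateral
    faces.  The base square (patch side) is excluded.
    """
    a, h = needle.base_edge, needle.height
    half = a / 2.0
    area_um2 = 4.0 * half * math.hypot(half, h)
    return area_um2 / _UM2_PER_MM2


def needle_surface_area(needle: Needle) -> float:
    """Dispatch to the formula matching the needle shape, mm²."""
    if isinstance(needle, FrustumNeedle):
        return frustum_surface_area(needle)
    if isinstance(needle, PyramidNeedle):
        return pyramid_surface_area(needle)
    raise TypeError(f"unsupported needle type: {type(needle).__name__}")


def patch_surface_area(layout: PatchLayout) -> float:
    """Total needle surface area of a patch: S_total = S · n, mm²."""
    return needle_surface_area(layout.needle) * layout.n_needles


def rasterize_half_needle(
    needle: Needle, dx: float, dy: float, skin_thickness: float
) -> np.ndarray:
    """Rasterize the needle's half cross-section onto the unit-cell grid.

    The simulation domain is the half unit cell with the needle symmetry
    axis at the left column and the skin surface at the top row.  A grid
    cell belongs to the needle when its left edge lies strictly inside
    the analytic half-width profile evaluated at the cell-row centre,
    i.e. each row holds ``ceil(w/dx)`` needle cells — the smallest cell
    set covering the profile.

    Returns a boolean mask of shape (nrows, max_cols) where nrows spans
    the skin thickness; columns extend to the widest needle row.  For a
    needle with positive dimensions at least one cell is marked.
    """
    if dx <= 0 or dy <= 0:
        raise ValueError("dx and dy must be positive")
    length = needle.length
    if length > skin_thickness:
        raise ValueError(
            f"needle length {length} µm exceeds skin thickness {skin_thickness} µm"
        )
    nrows = max(int(round(skin_thickness / dy)), 1)
    widths = np.zeros(nrows, dtype=int)
    for i in range(nrows):
        depth = (i + 0.5) * dy
        w = needle.half_width_at(depth)
        if w > 0:
            widths[i] = int(math.ceil(w / dx))
    positive_dims = (
        length > 0
        and needle.half_width_at(0.0) > 0
    )
    if positive_dims and widths.max() == 0:
        widths[0] = 1  # sub-cell needle: keep one seed cell at the surface
    # enforce monotone non-increasing width with depth (guards rounding)
    widths = np.minimum.accumulate(widths)
    ncols = max(int(widths.max()), 0)
    mask = np.zeros((nrows, ncols), dtype=bool)
    for i, w in enumerate(widths):
        mask[i, :w] = True
    return mask
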