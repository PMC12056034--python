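"""Geometry of the two-part conjunction object.

A conjunction object is a half-disc (radius ``r``) sitting flush on one long
edge of a ``2r`` x ``r`` rectangle.  The canonical frame has its origin at the
midpoint of the shared edge, +y pointing into the half-disc and -y into the
rectangle; x runs along the shared edge.  Screen orientation 0 equals the
canonical pose; orientations 90/180/270 are clockwise screen rotations
(screen coordinates are y-down, origin top-left).
"""

from __future__ import annotations

import numpy as np

#: Default half-disc radius in pixels (the rectangle is 2r wide and r tall).
DEFAULT_RADIUS = 23.0

CARDINAL_ORIENTATIONS = (0, 90, 180, 270)


def disc_area(r: float = DEFAULT_RADIUS) -> float:
    return float(np.pi * r * r / 2.0)


def rect_area(r: float = DEFAULT_RADIUS) -> float:
    return float(2.0 * r * r)


def disc_centroid(r: float = DEFAULT_RADIUS) -> np.ndarray:
    """Centroid of the half-disc in canonical coordinates: (0, 4r/(3*pi))."""
    return np.array([0.0, 4.0 * r / (3.0 * np.pi)])


def rect_centroid(r: float = DEFAULT_RADIUS) -> np.ndarray:
    """Centroid of the rectangle in canonical coordinates: (0, -r/2)."""
    return np.array([0.0, -r / 2.0])


def part_centroid(part: str, r: float = DEFAULT_RADIUS) -> np.ndarray:
    if part == "disc":
        return disc_centroid(r)
    if part == "rect":
        return rect_centroid(r)
    raise ValueError(f"unknown part {part!r}; expected 'disc' or 'rect'")


def center_of_mass(r: float = DEFAULT_RADIUS) -> np.ndarray:
    """Area-weighted centroid of the whole object (canonical frame).

    Lies slightly on the rectangle side of the shared edge (y < 0) because
    the rectangle's area, 2r^2, exceeds the half-disc's, pi*r^2/2.
    """
    a_d, a_r = disc_area(r), rect_area(r)
    y = (a_d * disc_centroid(r)[1] + a_r * rect_centroid(r)[1]) / (a_d + a_r)
    return np.array([0.0, y])


def center_of_mass_numeric(r: float = DEFAULT_RADIUS, n: int = 4001) -> np.ndarray:
    """Center of mass by numeric integration over the shape's indicator.

    Independent oracle for :func:`center_of_mass`: integrates x and y over a
    fine raster covering the object (midpoint rule).
    """
    x = np.linspace(-r, r, n)
    y = np.linspace(-r, r, n)
    xx, yy = np.meshgrid(x, y)
    inside = ((yy >= 0) & (xx**2 + yy**2 <= r**2)) | ((yy < 0) & (np.abs(xx) <= r))
    w = inside.astype(float)
    total = w.sum()
    return np.array([(xx * w).sum() / total, (yy * w).sum() / total])


def rotation_matrix(orientation_deg: float) -> np.ndarray:
    """Clockwise screen rotation in y-down screen coordinates."""
    th = np.deg2rad(orientation_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def canonical_to_screen(xy, center_px, orientation_deg: float) -> np.ndarray:
    """Map canonical coordinates to screen: rotate clockwise, then translate."""
    xy = np.asarray(xy, dtype=float)
    rot = rotation_matrix(orientation_deg)
    return xy @ rot.T + np.asarray(center_px, dtype=float)


def screen_to_canonical(xy, center_px, orientation_deg: float) -> np.ndarray:
    """Inverse of :func:`canonical_to_screen`."""
    xy = np.asarray(xy, dtype=float) - np.asarray(center_px, dtype=float)
    rot = rotation_matrix(-orientation_deg)
    return xy @ rot.T


def part_boundary_distance(part: str, lam: float, r: float = DEFAULT_RADIUS) -> float:
    """Distance of the tap anchor from the part boundary (the shared edge).

    The anchor is the convex combination (1-lam)*part_centroid + lam*COM; the
    boundary is the line y = 0, so the distance is just |anchor_y|.
    """
    anchor = (1.0 - lam) * part_centroid(part, r) + lam * center_of_mass(r)
    return float(abs(anchor[1]))
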