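"""Planar polyline geometry shared by the simulation and analysis stages.

All functions operate on ``(n, 2)`` float arrays of ``(x, y)`` vertices.
Units are whatever the caller uses (px or nm); nothing here rescales.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_polyline",
    "arc_length",
    "resample_polyline",
    "min_distance_to_polyline",
    "point_to_segment_distance",
    "chord_deviation",
]


def as_polyline(points) -> np.ndarray:
    """Validate and return a polyline as an ``(n, 2)`` float array.

    Raises ``ValueError`` for fewer than 2 points or consecutive
    duplicate vertices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"polyline must be (n, 2), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    seg = np.diff(pts, axis=0)
    if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
        raise ValueError("polyline has consecutive duplicate vertices")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polyline has non-finite vertices")
    return pts


def _segment_lengths(pts: np.ndarray) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    return np.hypot(seg[:, 0], seg[:, 1])


def arc_length(points) -> float:
    """Total length of the polyline."""
    return float(_segment_lengths(as_polyline(points)).sum())


def resample_polyline(points, spacing: float):
    """Stations along the polyline at uniform arc-length ``spacing``.

    Returns ``(stations, tangents)``: points at arc lengths
    ``0, spacing, 2*spacing, ...`` up to the total length (inclusive of 0,
    giving ``floor(L / spacing) + 1`` stations), and unit tangents from
    central differences of the stations (one-sided at the ends).
    """
    pts = as_polyline(points)
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    seglen = _segment_lengths(pts)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    n_stations = int(np.floor(total / spacing + 1e-9)) + 1
    s = np.arange(n_stations) * spacing
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    stations = np.column_stack([x, y])

    if n_stations == 1:
        # degenerate sampling; tangent of first segment
        t = pts[1] - pts[0]
        tangents = (t / np.hypot(*t))[None, :]
        return stations, tangents

    tangents = np.empty_like(stations)
    tangents[1:-1] = stations[2:] - stations[:-2]
    tangents[0] = stations[1] - stations[0]
    tangents[-1] = stations[-1] - stations[-2]
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    # duplicate stations can appear if spacing >> vertex spacing; fall back
    # to the global chord direction for those
    bad = norms == 0.0
    if np.any(bad):
        chord = pts[-1] - pts[0]
        tangents[bad] = chord
        norms = np.hypot(tangents[:, 0], tangents[:, 1])
    tangents /= norms[:, None]
    return stations, tangents


def point_at_arclength(points, s: float):
    """Point and unit tangent at arc length ``s`` along the polyline.

    ``s`` is clamped to ``[0, L]``.  Returns ``(point, tangent)``.
    """
    pts = as_polyline(points)
    seglen = _segment_lengths(pts)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seglen) - 1)
    t = (s - cum[i]) / seglen[i]
    p = pts[i] + t * (pts[i + 1] - pts[i])
    tan = (pts[i + 1] - pts[i]) / seglen[i]
    return p, tan


def point_to_segment_distance(point, a, b) -> float:
    """Exact distance from ``point`` to segment ``a``–``b`` (projection
    clamped to the segment)."""
    p = np.asarray(point, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise ValueError("degenerate segment")
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t * ab
    return float(np.hypot(*(p - proj)))


def min_distance_to_polyline(point, polyline) -> float:
    """Minimum distance from a point to a polyline.

    Degenerate (zero-length) segments are skipped; an all-degenerate
    polyline raises ``ValueError``.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be (n>=2, 2)")
    p = np.asarray(point, dtype=float)
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    ok = denom > 0.0
    if not np.any(ok):
        raise ValueError("polyline has only degenerate segments")
    a, ab, denom = a[ok], ab[ok], denom[ok]
    t = np.clip(np.einsum("j,ij->i", p, ab) - np.einsum("ij,ij->i", a, ab), None, None) / denom
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.hypot(*(p - proj).T)
    return float(d.min())


def min_distances_to_polyline(points, polyline) -> np.ndarray:
    """Vectorized :func:`min_distance_to_polyline` for many points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return np.array([min_distance_to_polyline(p, polyline) for p in pts])


def chord_deviation(points) -> float:
    """Max perpendicular distance of vertices from the end-to-end chord,
    divided by the chord length.  Raises on zero chord."""
    pts = as_polyline(points)
    chord = pts[-1] - pts[0]
    L = float(np.hypot(*chord))
    if L == 0.0:
        raise ValueError("zero chord length: trace ends coincide")
    u = chord / L
    rel = pts - pts[0]
    perp = rel[:, 0] * u[1] - rel[:, 1] * u[0]
    return float(np.max(np.abs(perp)) / L)
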