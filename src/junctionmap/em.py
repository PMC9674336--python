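"""Immunogold particle statistics relative to the TJ and apical membrane.

Coordinates are 2D projections in nm.  The antibody-linkage window
(3–37 nm: gold radius up to primary+secondary antibody extent) and the
38-nm membrane-association threshold are both reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .geometry import min_distance_to_polyline
from .types import GoldParticleSet

LINKAGE_LOWER = 3.0  # nm, gold particle radius
LINKAGE_UPPER = 37.0  # nm, primary + gold-labeled secondary antibody span
MEMBRANE_THRESHOLD = 38.0  # nm, membrane-association statistic

MICROVILLI = "microvilli"
MEMBRANE_VICINITY = "membrane_vicinity"
CYTOPLASM = "cytoplasm"


def tj_offsets(particle, tj_reference, apical_axis):
    """Signed apico-basal and lateral offsets plus Euclidean distance of
    a particle from the TJ reference.

    ``ab_offset`` is the projection on ``apical_axis`` (apical positive);
    ``lateral_offset`` is the projection on the axis rotated -90 deg
    (right of the apical axis positive).
    """
    p = np.asarray(particle, dtype=float)
    r = np.asarray(tj_reference, dtype=float)
    u = np.asarray(apical_axis, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r)) and np.all(np.isfinite(u))):
        raise ValueError("inputs must be finite")
    v = p - r
    ab = float(v @ u)
    lateral = float(v @ np.array([u[1], -u[0]]))
    return ab, lateral, float(np.hypot(*v))


def _check_simple(polygon: np.ndarray) -> Polygon:
    poly = Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_valid:
        raise ValueError("self-intersecting (non-simple) polygon")
    return poly


def point_in_polygon(point, polygon) -> bool:
    """Boundary-inclusive even-odd containment test."""
    poly = _check_simple(polygon)
    return bool(poly.covers(Point(float(point[0]), float(point[1]))))


def classify_compartment(
    particle,
    microvilli: Sequence[np.ndarray],
    membrane,
    vicinity_threshold: float = MEMBRANE_THRESHOLD,
) -> str:
    """``microvilli`` if inside any polygon (boundary counts as inside),
    else ``membrane_vicinity`` if within ``vicinity_threshold`` of the
    membrane, else ``cytoplasm``."""
    for poly in microvilli:
        if point_in_polygon(particle, poly):
            return MICROVILLI
    if min_distance_to_polyline(particle, membrane) <= vicinity_threshold:
        return MEMBRANE_VICINITY
    return CYTOPLASM


def linkage_fraction(
    membrane_distances: Sequence[float],
    lower: float = LINKAGE_LOWER,
    upper: float = MEMBRANE_THRESHOLD,
) -> dict:
    """Counts of particles compatible with membrane association.

    ``n_below_upper`` counts distances < ``upper`` (the headline
    fraction); ``n_in_window`` counts ``lower <= d <= upper - 1``, the
    amber antibody-linkage window whose upper edge sits 1 nm below the
    association threshold.
    """
    d = np.asarray(membrane_distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if not (0 <= lower < upper):
        raise ValueError("need 0 <= lower < upper")
    n_total = int(d.size)
    n_below = int(np.count_nonzero(d < upper))
    n_window = int(np.count_nonzero((d >= lower) & (d <= upper - 1.0)))
    return {
        "n_below_upper": n_below,
        "n_total": n_total,
        "fraction": n_below / n_total,
        "n_in_window": n_window,
    }


@dataclass
class DistanceReport:
    per_particle: pd.DataFrame
    summary: dict


def analyze_particles(
    particles: GoldParticleSet,
    vicinity_threshold: float = MEMBRANE_THRESHOLD,
    linkage_lower: float = LINKAGE_LOWER,
    linkage_upper: float = LINKAGE_UPPER,
) -> DistanceReport:
    """Per-particle TJ offsets, membrane distances, and compartment labels,
    with summary counts and the linkage-compatibility fractions."""
    rows = []
    for pid, p in zip(particles.ids, particles.particles):
        ab, lat, dist = tj_offsets(p, particles.tj_reference, particles.apical_axis)
        mdist = min_distance_to_polyline(p, particles.membrane)
        label = classify_compartment(
            p, particles.microvilli, particles.membrane, vicinity_threshold
        )
        rows.append(
            {
                "id": pid,
                "x_nm": p[0],
                "y_nm": p[1],
                "ab_offset_nm": ab,
                "lateral_offset_nm": lat,
                "tj_distance_nm": dist,
                "membrane_distance_nm": mdist,
                "compartment": label,
            }
        )
    df = pd.DataFrame(rows)
    counts = df["compartment"].value_counts().to_dict()
    frac = linkage_fraction(
        df["membrane_distance_nm"].to_numpy(), linkage_lower, vicinity_threshold
    )
    summary = {
        "n_total": int(len(df)),
        "compartment_counts": {
            k: int(counts.get(k, 0)) for k in (MICROVILLI, MEMBRANE_VICINITY, CYTOPLASM)
        },
        "compartment_fractions": {
            k: counts.get(k, 0) / len(df)
            for k in (MICROVILLI, MEMBRANE_VICINITY, CYTOPLASM)
        },
        "membrane_association": frac,
        "linkage_window": {
            "lower_nm": linkage_lower,
            "upper_nm": linkage_upper,
            "n_in_window": int(
                np.count_nonzero(
                    (df["membrane_distance_nm"] >= linkage_lower)
                    & (df["membrane_distance_nm"] <= linkage_upper)
                )
            ),
        },
    }
    return DistanceReport(per_particle=df, summary=summary)
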