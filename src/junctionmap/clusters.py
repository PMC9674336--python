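"""Protein cluster detection and microvilli-region contingency counts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
DEFAULT_REGION_LABELS = ("within_microvillus", "base", "between")


@dataclass
class ClusterSet:
    """Detected clusters: centroids in nm plus peak intensity and an
    equivalent diameter from the watershed support area.  Clusters at the
    resolution limit are allowed (no minimum size)."""

    centroids: np.ndarray  # (n, 2) nm, (x, y)
    peak_intensity: np.ndarray
    equivalent_diameter: np.ndarray  # nm

    def __len__(self):
        return len(self.centroids)


@dataclass
class RegionMap:
    """Tagged, non-overlapping polygons partitioning the junction area."""

    polygons: List[np.ndarray]  # (k, 2) nm vertex arrays
    tags: List[str]
    source: str = ""

    def __post_init__(self):
        if len(self.polygons) != len(self.tags):
            raise ValueError("one tag per polygon required")
        shp = [Polygon(np.asarray(p, float)) for p in self.polygons]
        for p in shp:
            if not p.is_valid:
                raise ValueError("self-intersecting region polygon")
        for i in range(len(shp)):
            for j in range(i + 1, len(shp)):
                inter = shp[i].intersection(shp[j])
                if inter.area > 1e-9:
                    raise ValueError(f"regions {i} and {j} overlap")


def detect_clusters(
    image: np.ndarray,
    pixel_size: float,
    smoothing_sigma: float = 34.0,  # nm; PSF sigma for an 80-nm FWHM
    min_prominence: float = 0.2,
) -> ClusterSet:
    """Local maxima of the Gaussian-smoothed image with relative
    prominence, segmented by watershed; centroid = intensity-weighted
    centroid of each maximum's support.

    ``min_prominence`` is a fraction of (max - background) where the
    background is the image median, making detection invariant to
    intensity scaling.  A constant image yields an empty set with a
    warning.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        log.warning("constant image: no clusters detectable")
        empty = np.empty((0, 2))
        return ClusterSet(empty, np.empty(0), np.empty(0))
    sigma_px = smoothing_sigma / pixel_size
    smooth = gaussian(img, sigma=sigma_px, preserve_range=True)
    background = float(np.median(smooth))
    threshold = background + min_prominence * (smooth.max() - background)
    coords = peak_local_max(
        smooth, min_distance=max(1, int(round(sigma_px))), threshold_abs=threshold
    )
    if coords.size == 0:
        return ClusterSet(np.empty((0, 2)), np.empty(0), np.empty(0))

    markers = np.zeros(img.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    mask = smooth > background + 0.5 * min_prominence * (smooth.max() - background)
    labels = watershed(-smooth, markers=markers, mask=mask)

    centroids, peaks, diameters = [], [], []
    for i, (r, c) in enumerate(coords, start=1):
        support = labels == i
        if not np.any(support):
            support = np.zeros_like(mask)
            support[r, c] = True
        w = np.where(support, smooth - background, 0.0)
        w = np.clip(w, 0.0, None)
        total = w.sum()
        if total <= 0:
            cy, cx = float(r), float(c)
        else:
            yy, xx = np.nonzero(support)
            cy = float((yy * w[yy, xx]).sum() / total)
            cx = float((xx * w[yy, xx]).sum() / total)
        area_px = int(support.sum())
        centroids.append((cx * pixel_size, cy * pixel_size))
        peaks.append(float(img[r, c]))
        diameters.append(2.0 * np.sqrt(area_px / np.pi) * pixel_size)
    return ClusterSet(
        centroids=np.array(centroids),
        peak_intensity=np.array(peaks),
        equivalent_diameter=np.array(diameters),
    )


def region_contingency(
    clusters_per_protein: Dict[str, ClusterSet],
    regions: RegionMap,
) -> pd.DataFrame:
    """Contingency table of cluster counts per protein (rows) and region
    (columns, plus ``unassigned``).

    Each centroid is assigned to the containing region
    (boundary-inclusive even-odd rule) or counted unassigned.  Row sums
    equal the cluster counts per protein.
    """
    for name, cs in clusters_per_protein.items():
        if len(cs) == 0:
            raise ValueError(f"empty cluster set for {name!r}")
    shp = [Polygon(np.asarray(p, float)) for p in regions.polygons]
    tags = list(dict.fromkeys(regions.tags))  # preserve order, unique
    columns = tags + [UNASSIGNED]
    table = pd.DataFrame(0, index=list(clusters_per_protein), columns=columns)
    for name, cs in clusters_per_protein.items():
        for x, y in cs.centroids:
            pt = Point(float(x), float(y))
            assigned = UNASSIGNED
            for poly, tag in zip(shp, regions.tags):
                if poly.covers(pt):
                    assigned = tag
                    break
            table.loc[name, assigned] += 1
    return table
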