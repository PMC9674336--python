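"""Junction-referenced protein density profiles.

Workflow: sample intensity lines perpendicular to a traced junction
(planar) or along the apical axis (apico-basal) with bilinear
interpolation, locate the TJ-marker reference on each line, align lines
on that reference, normalize per junction, then pool junctions into a
mean +- SD density curve.  The 2D product map multiplies the planar and
apico-basal pooled curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .geometry import arc_length, resample_polyline
from .types import APICO_BASAL, DensityProfile, ImagePair, JunctionTrace, PLANAR

log = logging.getLogger(__name__)

UNIT_INTEGRAL = "unit_integral"
UNIT_MAX = "unit_max"


@dataclass
class ProfileStack:
    """Per-line sampled intensities for both channels of one junction.

    ``positions`` are signed nm relative to each line's origin (the
    station on the trace); rows of ``ref``/``target`` are lines.
    """

    positions: np.ndarray  # (m,) nm, uniform step
    ref: np.ndarray  # (n_lines, m)
    target: np.ndarray  # (n_lines, m)
    step: float  # nm
    n_dropped: int = 0

    def __post_init__(self):
        if self.ref.shape != self.target.shape:
            raise ValueError("channel stacks must have identical shapes")
        if self.ref.ndim != 2 or self.ref.shape[1] != len(self.positions):
            raise ValueError("stack shape does not match positions")
        d = np.diff(self.positions)
        if len(d) and not np.allclose(d, d[0]):
            raise ValueError("positions must have uniform step")


@dataclass
class JunctionProfile:
    """One junction's aligned, normalized two-channel profile on the
    common grid (NaN outside the junction's support)."""

    positions: np.ndarray  # nm, 0 = TJ reference
    ref: np.ndarray
    target: np.ndarray
    n_lines: int
    junction_id: str = ""


def bilinear_sample(image: np.ndarray, point) -> float:
    """Bilinear interpolation at a sub-pixel point (x, y).

    Pixel-center convention: integer coordinates address pixel centers,
    0-based, x = column.  The point must lie in the image interior (all
    four neighbors exist).
    """
    x, y = float(point[0]), float(point[1])
    rows, cols = image.shape
    if not (0.0 <= x <= cols - 1 and 0.0 <= y <= rows - 1):
        raise ValueError(f"point ({x}, {y}) outside image interior")
    x0 = min(int(np.floor(x)), cols - 2)
    y0 = min(int(np.floor(y)), rows - 2)
    fx, fy = x - x0, y - y0
    img = np.asarray(image, dtype=float)
    return float(
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


def _bilinear_many(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorized bilinear sampling; caller guarantees interior points."""
    rows, cols = image.shape
    img = np.asarray(image, dtype=float)
    x0 = np.clip(np.floor(xs).astype(int), 0, cols - 2)
    y0 = np.clip(np.floor(ys).astype(int), 0, rows - 2)
    fx, fy = xs - x0, ys - y0
    return (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


def sample_perpendicular_profiles(
    pair: ImagePair,
    trace: JunctionTrace,
    half_length: float = 1000.0,
    step: Optional[float] = None,
    line_spacing: Optional[float] = None,
) -> ProfileStack:
    """Sample intensity lines across the junction, one per arc-length step.

    Line direction is the local perpendicular to the trace (planar) or
    the trace's ``apical_direction`` (apico-basal); for apico-basal
    lines, samples are ordered apical -> basal along the line, so
    position increases toward basal.  Lines with any sample outside the
    image interior are dropped (counted in ``n_dropped``).
    """
    px = pair.pixel_size
    step = px if step is None else step
    spacing = step if line_spacing is None else line_spacing
    if step <= 0:
        raise ValueError("step must be > 0")
    if half_length < step:
        raise ValueError("half_length must be >= step")

    stations, tangents = resample_polyline(trace.points, spacing / px)
    if pair.orientation == APICO_BASAL:
        if trace.apical_direction is None:
            raise ValueError("apico-basal sampling requires apical_direction")
        # order apical -> basal: start at the apical side of the station
        directions = np.tile(-trace.apical_direction, (len(stations), 1))
    else:
        directions = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    offsets_nm = np.arange(-half_length, half_length + step / 2, step)
    offsets_px = offsets_nm / px

    rows, cols = pair.shape
    ref_lines, tgt_lines = [], []
    n_dropped = 0
    for p, d in zip(stations, directions):
        xs = p[0] + offsets_px * d[0]
        ys = p[1] + offsets_px * d[1]
        if xs.min() < 0 or xs.max() > cols - 1 or ys.min() < 0 or ys.max() > rows - 1:
            n_dropped += 1
            continue
        ref_lines.append(_bilinear_many(pair.channel_ref, xs, ys))
        tgt_lines.append(_bilinear_many(pair.channel_target, xs, ys))
    if n_dropped:
        log.info("dropped %d/%d lines leaving the image interior", n_dropped, len(stations))
    if not ref_lines:
        raise ValueError("all sampling lines left the image interior")
    return ProfileStack(
        positions=offsets_nm,
        ref=np.array(ref_lines),
        target=np.array(tgt_lines),
        step=step,
        n_dropped=n_dropped,
    )


def planar_reference(positions: np.ndarray, profile: np.ndarray) -> float:
    """Reference = position of the TJ-marker maximum, refined to
    sub-sample precision with a three-point parabola.

    Ties are broken toward the line midpoint.  A constant profile has no
    reference and raises ``ValueError``.
    """
    profile = np.asarray(profile, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if np.all(profile == profile[0]):
        raise ValueError("no reference: constant profile")
    maxima = np.flatnonzero(profile == profile.max())
    mid = (len(profile) - 1) / 2.0
    i = int(maxima[np.argmin(np.abs(maxima - mid))])
    if i == 0 or i == len(profile) - 1:
        return float(positions[i])
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(positions[i])
    delta = 0.5 * (y0 - y2) / denom
    step = positions[1] - positions[0]
    return float(positions[i] + delta * step)


def apicobasal_reference(
    positions: np.ndarray,
    profile: np.ndarray,
    fraction: float = 1.0 / 3.0,
):
    """Reference = most apical point where the TJ marker reaches
    ``fraction`` of its maximum, with linear interpolation between the
    bracketing samples.

    The profile must be ordered apical -> basal.  Junction extents along
    the apico-basal axis vary severalfold, so the threshold crossing
    gives a reproducible apical edge where the raw maximum would not.
    Returns ``(position, flagged)``; flagged is True when the first
    sample already reaches the threshold (reference clipped to the
    apical end).
    """
    profile = np.asarray(profile, dtype=float)
    positions = np.asarray(positions, dtype=float)
    m = profile.max()
    if m <= 0:
        raise ValueError("max intensity must be > 0")
    thr = fraction * m
    if profile[0] >= thr:
        return float(positions[0]), True
    above = np.flatnonzero(profile >= thr)
    i = int(above[0])
    frac = (thr - profile[i - 1]) / (profile[i] - profile[i - 1])
    return float(positions[i - 1] + frac * (positions[i] - positions[i - 1])), False


def align_and_normalize(
    stack: ProfileStack,
    refs: Sequence[float],
    mode: str = UNIT_INTEGRAL,
    junction_id: str = "",
) -> JunctionProfile:
    """Re-index each line so its reference is 0, average lines within the
    junction on the common grid, and scale per ``mode``.

    The common grid is the stack's position grid (anchored at 0); shifted
    lines are re-gridded by linear interpolation, NaN outside their
    support, and averaged with ``nanmean``.  Both channels are scaled by
    the same rule applied per channel: ``unit_integral`` (sum * step = 1)
    or ``unit_max`` (peak = 1) — either makes the result invariant to
    per-junction intensity scaling.
    """
    refs = np.asarray(refs, dtype=float)
    if stack.ref.shape[0] == 0:
        raise ValueError("empty profile stack")
    if len(refs) != stack.ref.shape[0]:
        raise ValueError("one reference per line required")
    if not np.all(np.isfinite(refs)):
        raise ValueError("references must be finite")
    if mode not in (UNIT_INTEGRAL, UNIT_MAX):
        raise ValueError(f"unknown normalization mode {mode!r}")

    grid = stack.positions
    aligned_ref = np.full((len(refs), len(grid)), np.nan)
    aligned_tgt = np.full_like(aligned_ref, np.nan)
    for k, r in enumerate(refs):
        shifted = stack.positions - r
        aligned_ref[k] = np.interp(grid, shifted, stack.ref[k], left=np.nan, right=np.nan)
        aligned_tgt[k] = np.interp(grid, shifted, stack.target[k], left=np.nan, right=np.nan)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_ref = np.nanmean(aligned_ref, axis=0)
        mean_tgt = np.nanmean(aligned_tgt, axis=0)

    def _scale(v):
        valid = np.isfinite(v)
        if mode == UNIT_INTEGRAL:
            s = np.nansum(v[valid]) * stack.step
        else:
            s = np.nanmax(v[valid])
        if s <= 0:
            raise ValueError("cannot normalize non-positive profile")
        return v / s

    return JunctionProfile(
        positions=grid,
        ref=_scale(mean_ref),
        target=_scale(mean_tgt),
        n_lines=len(refs),
        junction_id=junction_id,
    )


def pool_density(junction_profiles: List[JunctionProfile], channel: str = "target") -> DensityProfile:
    """Mean and SD across junctions per position (sample SD, n-1
    denominator; SD = 0 when a position has a single junction)."""
    if not junction_profiles:
        raise ValueError("need at least one junction profile")
    grid = junction_profiles[0].positions
    for jp in junction_profiles[1:]:
        if jp.positions.shape != grid.shape or not np.allclose(jp.positions, grid):
            raise ValueError("junction profiles are on mismatched grids")
    import warnings

    data = np.array([getattr(jp, channel) for jp in junction_profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_per = np.sum(np.isfinite(data), axis=0)
        mean = np.nanmean(data, axis=0)
        sd = np.zeros_like(mean)
        multi = n_per > 1
        if np.any(multi):
            sd[multi] = np.nanstd(data[:, multi], axis=0, ddof=1)
    keep = n_per > 0
    return DensityProfile(
        positions=grid[keep],
        mean=mean[keep],
        sd=sd[keep],
        n_junctions=len(junction_profiles),
    )


def profile_junction(
    pair: ImagePair,
    trace: JunctionTrace,
    half_length: float = 1000.0,
    step: Optional[float] = None,
    mode: str = UNIT_INTEGRAL,
    fraction: float = 1.0 / 3.0,
) -> JunctionProfile:
    """Sample, reference, align and normalize one junction end to end."""
    stack = sample_perpendicular_profiles(pair, trace, half_length, step)
    refs = []
    for line in stack.ref:
        if pair.orientation == APICO_BASAL:
            r, _ = apicobasal_reference(stack.positions, line, fraction)
        else:
            r = planar_reference(stack.positions, line)
        refs.append(r)
    return align_and_normalize(stack, refs, mode, junction_id=trace.image_id)


def density_map_2d(planar: DensityProfile, apico_basal: DensityProfile) -> np.ndarray:
    """Outer-product localization map: ``map[i, j] =
    apico_basal.mean[i] * planar.mean[j]``, axes in nm with (0, 0) at the
    TJ reference."""
    if len(planar.mean) == 0 or len(apico_basal.mean) == 0:
        raise ValueError("profiles must be non-empty")
    return np.outer(apico_basal.mean, planar.mean)
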