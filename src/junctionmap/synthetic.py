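"""Ground-truthed synthetic junction scenes and gold-particle sets.

The forward model: every structure (TJ line cross-section, protein
cluster) is an isotropic Gaussian parameterized by FWHM, and the
microscope blur is a second Gaussian (PSF).  Convolution of two
Gaussians is again a Gaussian, so noiseless channels are rendered
analytically with the combined width — exact, fast, and
mass-conserving.  Poisson noise, when enabled, is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .geometry import arc_length, as_polyline, point_at_arclength
from .types import FWHM_TO_SIGMA, GoldParticleSet, ImagePair, JunctionTrace, PLANAR

_RETRY_CAP = 1000  # rejection-sampling cap for non-overlap placement


@dataclass
class SceneParams:
    """Parameters of one synthetic two-channel junction scene.

    Lengths are nm unless stated; ``junction_path`` is in px
    (pixel-center convention, x = column).
    """

    image_shape: Tuple[int, int] = (256, 256)  # (rows, cols)
    pixel_size: float = 20.0  # nm/px; 4 px per 80-nm PSF FWHM by default
    junction_path: Optional[np.ndarray] = None  # px; default: horizontal midline
    tj_amplitude: float = 1000.0
    tj_line_width: float = 100.0  # nm FWHM of the line cross-section
    n_clusters: int = 20
    cluster_fwhm: Tuple[float, float] = (80.0, 200.0)  # nm, drawn uniformly
    cluster_amplitude: float = 800.0
    offset_perp_mean: float = 0.0  # nm, signed
    offset_perp_sd: float = 0.0  # nm
    overlap_fraction: float = 1.0
    psf_fwhm: float = 80.0  # nm
    background: float = 10.0
    poisson_noise: bool = False
    noise_gain: float = 1.0
    seed: int = 0
    orientation: str = PLANAR

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        lo, hi = self.cluster_fwhm
        if not (40.0 <= lo <= hi <= 400.0):
            raise ValueError("cluster_fwhm range must lie within [40, 400] nm")
        if self.psf_fwhm <= 0 or self.tj_line_width <= 0:
            raise ValueError("widths must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.junction_path is None:
            rows, cols = self.image_shape
            mid = (rows - 1) / 2.0
            margin = self.border_margin_px
            self.junction_path = np.array(
                [[margin, mid], [cols - 1 - margin, mid]], dtype=float
            )
        else:
            self.junction_path = as_polyline(self.junction_path)

    @property
    def psf_sigma_nm(self) -> float:
        return self.psf_fwhm * FWHM_TO_SIGMA

    @property
    def border_margin_px(self) -> float:
        """Clusters are kept >= 3 PSF sigmas from the image edge so the
        rendering conservation property holds."""
        return 3.0 * self.psf_sigma_nm / self.pixel_size


@dataclass
class GroundTruth:
    """What the simulator actually drew, for downstream recovery checks."""

    centers_a: np.ndarray  # (n, 2) nm
    centers_b: np.ndarray  # (n, 2) nm
    shared_center_ids: np.ndarray = field(default_factory=lambda: np.array([], int))
    true_offsets: np.ndarray = field(default_factory=lambda: np.array([]))
    overlap_fraction: float = 0.0


def _blob_image(shape, centers_px, sigmas_px, masses):
    """Sum of 2D Gaussians with given total masses (intensity * px^2),
    evaluated in a +-6 sigma window each."""
    img = np.zeros(shape, dtype=float)
    rows, cols = shape
    for (cx, cy), s, m in zip(centers_px, sigmas_px, masses):
        w = int(np.ceil(6.0 * s)) + 1
        r0, r1 = max(0, int(np.floor(cy)) - w), min(rows, int(np.ceil(cy)) + w + 1)
        c0, c1 = max(0, int(np.floor(cx)) - w), min(cols, int(np.ceil(cx)) + w + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1, dtype=float)[:, None]
        xx = np.arange(c0, c1, dtype=float)[None, :]
        g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * s * s))
        img[r0:r1, c0:c1] += (m / (2.0 * np.pi * s * s)) * g
    return img


def render_channel(
    centers: np.ndarray,
    params: SceneParams,
    *,
    cluster_fwhms: Optional[np.ndarray] = None,
    amplitudes: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one channel: background + Gaussian blobs convolved with the
    Gaussian PSF; Poisson noise applied last if enabled.

    ``centers`` are (x, y) in nm.  Each blob is an isotropic Gaussian with
    per-cluster FWHM and peak amplitude (pre-blur); the PSF convolution is
    applied analytically.  Centers outside the image bounds are rejected.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    rows, cols = params.image_shape
    px = params.pixel_size
    if centers.size:
        x_px = centers[:, 0] / px
        y_px = centers[:, 1] / px
        bad = (x_px < 0) | (x_px > cols - 1) | (y_px < 0) | (y_px > rows - 1)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"cluster center {i} at {tuple(centers[i])} nm is outside the "
                f"image bounds"
            )
    n = len(centers)
    if cluster_fwhms is None:
        cluster_fwhms = np.full(n, np.mean(params.cluster_fwhm))
    if amplitudes is None:
        amplitudes = np.full(n, params.cluster_amplitude)
    sigma_c = np.asarray(cluster_fwhms, float) * FWHM_TO_SIGMA  # nm
    sigma_psf = params.psf_sigma_nm
    sigma_eff_px = np.sqrt(sigma_c**2 + sigma_psf**2) / px
    # mass of a 2D Gaussian of peak A and sigma s (in px^2)
    masses = np.asarray(amplitudes, float) * 2.0 * np.pi * (sigma_c / px) ** 2
    img = params.background + (
        _blob_image((rows, cols), centers / px, sigma_eff_px, masses)
        if n
        else np.zeros((rows, cols))
    )
    if params.poisson_noise:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        g = params.noise_gain
        img = rng.poisson(np.clip(img * g, 0, None)).astype(float) / g
    np.clip(img, 0.0, None, out=img)
    return img


def render_tj_line(params: SceneParams) -> np.ndarray:
    """Reference channel: a line of Gaussian cross-section along the
    junction path, PSF-blurred analytically (noise handled by caller)."""
    rows, cols = params.image_shape
    px = params.pixel_size
    path_nm = params.junction_path * px
    sigma_line = params.tj_line_width * FWHM_TO_SIGMA
    sigma_eff = np.hypot(sigma_line, params.psf_sigma_nm)  # nm
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel() * px, yy.ravel() * px])
    a = path_nm[:-1]
    b = path_nm[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    dmin = np.full(len(pts), np.inf)
    for ai, abi, di in zip(a, ab, denom):
        t = np.clip(((pts - ai) @ abi) / di, 0.0, 1.0)
        proj = ai + t[:, None] * abi
        d = np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1])
        np.minimum(dmin, d, out=dmin)
    amp = params.tj_amplitude * params.tj_line_width * FWHM_TO_SIGMA / sigma_eff
    img = amp * np.exp(-(dmin**2) / (2.0 * sigma_eff**2))
    return img.reshape(rows, cols)


def _draw_cluster_centers(params: SceneParams, rng: np.random.Generator):
    """Cluster centers along the junction at signed perpendicular offsets
    ~ Normal(offset_perp_mean, offset_perp_sd).  Returns (centers nm,
    offsets nm).  Perpendicular = tangent rotated +90 deg ((-ty, tx))."""
    px = params.pixel_size
    path_nm = params.junction_path * px
    L = arc_length(path_nm)
    margin_nm = params.border_margin_px * px
    rows, cols = params.image_shape
    lo = np.array([margin_nm, margin_nm])
    hi = np.array([(cols - 1) * px - margin_nm, (rows - 1) * px - margin_nm])

    centers = np.empty((params.n_clusters, 2))
    offsets = np.empty(params.n_clusters)
    for i in range(params.n_clusters):
        for _ in range(_RETRY_CAP):
            s = rng.uniform(0.0, L)
            d = rng.normal(params.offset_perp_mean, params.offset_perp_sd)
            p, t = point_at_arclength(path_nm, s)
            perp = np.array([-t[1], t[0]])
            c = p + d * perp
            if np.all(c >= lo) and np.all(c <= hi):
                centers[i] = c
                offsets[i] = d
                break
        else:
            raise RuntimeError(
                "could not place cluster inside border margin after "
                f"{_RETRY_CAP} tries"
            )
    return centers, offsets


def simulate_junction_scene(params: SceneParams):
    """Simulate a TJ-marker channel plus an offset-cluster protein channel.

    Returns ``(ImagePair, JunctionTrace, GroundTruth)``.  Deterministic
    for a fixed seed and parameter set.
    """
    if len(params.junction_path) < 2:
        raise ValueError("junction_path needs at least 2 points")
    rng = np.random.default_rng(params.seed)
    centers, offsets = _draw_cluster_centers(params, rng)
    fwhms = rng.uniform(*params.cluster_fwhm, size=params.n_clusters)

    ch_ref = render_tj_line(params) + params.background
    ch_tgt = render_channel(
        centers, params, cluster_fwhms=fwhms, rng=rng
    )
    if params.poisson_noise:
        g = params.noise_gain
        ch_ref = rng.poisson(np.clip(ch_ref * g, 0, None)).astype(float) / g

    pair = ImagePair(
        channel_ref=ch_ref,
        channel_target=ch_tgt,
        pixel_size=params.pixel_size,
        orientation=params.orientation,
        id=f"sim-{params.seed}",
    )
    trace = JunctionTrace(points=params.junction_path.copy(), image_id=pair.id)
    truth = GroundTruth(
        centers_a=centers,
        centers_b=centers.copy(),
        true_offsets=offsets,
        overlap_fraction=1.0,
    )
    return pair, trace, truth


def simulate_pair_with_overlap(
    params: SceneParams,
    f: float,
    *,
    min_separation_factor: float = 3.0,
):
    """Two protein channels sharing ``round(f * n)`` cluster centers.

    Non-shared channel-B centers are drawn at least
    ``min_separation_factor * psf_fwhm`` away from every channel-A center.
    Returns ``(ImagePair, JunctionTrace, GroundTruth)``; the pair's
    channel_ref holds channel A and channel_target holds channel B.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("overlap fraction must be in [0, 1]")
    rng = np.random.default_rng(params.seed)
    n = params.n_clusters
    centers_a, offsets_a = _draw_cluster_centers(params, rng)
    fwhms = rng.uniform(*params.cluster_fwhm, size=n)

    n_shared = int(round(f * n))
    shared_ids = np.arange(n_shared)
    sep = min_separation_factor * params.psf_fwhm
    centers_b = np.empty_like(centers_a)
    centers_b[:n_shared] = centers_a[:n_shared]
    for i in range(n_shared, n):
        for _ in range(_RETRY_CAP):
            c, _ = _draw_cluster_centers(
                SceneParams(**{**params.__dict__, "n_clusters": 1, "seed": 0}),
                rng,
            )
            d = np.hypot(*(centers_a - c[0]).T)
            if np.all(d >= sep):
                centers_b[i] = c[0]
                break
        else:
            raise RuntimeError(
                f"could not place non-overlapping cluster after {_RETRY_CAP} "
                "tries (scene too crowded)"
            )

    ch_a = render_channel(centers_a, params, cluster_fwhms=fwhms, rng=rng)
    ch_b = render_channel(centers_b, params, cluster_fwhms=fwhms, rng=rng)
    pair = ImagePair(
        channel_ref=ch_a,
        channel_target=ch_b,
        pixel_size=params.pixel_size,
        orientation=params.orientation,
        id=f"simpair-{params.seed}",
    )
    trace = JunctionTrace(points=params.junction_path.copy(), image_id=pair.id)
    truth = GroundTruth(
        centers_a=centers_a,
        centers_b=centers_b,
        shared_center_ids=shared_ids,
        true_offsets=offsets_a,
        overlap_fraction=f,
    )
    return pair, trace, truth


def simulate_gold_particles(
    n: int,
    membrane,
    displacement_sd: float,
    outlier_fraction: float,
    seed: int,
    *,
    far_zone: Optional[Tuple[float, float]] = None,
    tj_reference=None,
    apical_axis=(0.0, 1.0),
) -> GoldParticleSet:
    """Gold-particle coordinates at known distances from a membrane polyline.

    ``(1 - outlier_fraction) * n`` particles sit at half-normal distances
    (scale ``displacement_sd``) from the membrane on its +normal side; the
    rest are uniform within a far zone well beyond the labeling linkage.
    True distances are recorded for recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= outlier_fraction <= 1.0):
        raise ValueError("outlier_fraction must be in [0, 1]")
    if displacement_sd < 0:
        raise ValueError("displacement_sd must be >= 0")
    membrane = as_polyline(membrane)
    rng = np.random.default_rng(seed)

    if far_zone is None:
        lo = max(5.0 * displacement_sd, 100.0)
        far_zone = (lo, lo + 200.0)
    far_lo, far_hi = far_zone
    if far_lo <= 0 or far_hi <= far_lo:
        raise ValueError("far_zone must satisfy 0 < lo < hi")

    n_out = int(round(outlier_fraction * n))
    n_near = n - n_out
    L = arc_length(membrane)

    def _at(s, d):
        p, t = point_at_arclength(membrane, s)
        normal = np.array([-t[1], t[0]])
        return p + d * normal

    pts = np.empty((n, 2))
    true_d = np.empty(n)
    s_near = rng.uniform(0.05 * L, 0.95 * L, size=n_near)
    d_near = np.abs(rng.normal(0.0, displacement_sd, size=n_near)) if displacement_sd > 0 else np.zeros(n_near)
    for i in range(n_near):
        pts[i] = _at(s_near[i], d_near[i])
        true_d[i] = d_near[i]
    s_out = rng.uniform(0.05 * L, 0.95 * L, size=n_out)
    d_out = rng.uniform(far_lo, far_hi, size=n_out)
    for j in range(n_out):
        pts[n_near + j] = _at(s_out[j], d_out[j])
        true_d[n_near + j] = d_out[j]

    if tj_reference is None:
        tj_reference = membrane[0]
    axis = np.asarray(apical_axis, dtype=float)
    axis = axis / float(np.hypot(*axis))
    return GoldParticleSet(
        particles=pts,
        tj_reference=tj_reference,
        apical_axis=axis,
        membrane=membrane,
        true_distances=true_d,
        far_zone_min=far_lo,
    )
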