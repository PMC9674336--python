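"""Domain types shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import as_polyline, chord_deviation

PLANAR = "planar"
APICO_BASAL = "apico_basal"

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ImagePair:
    """Two-channel raster: a reference channel (TJ marker) and a target
    channel (polarity protein), with shared geometry metadata."""

    channel_ref: np.ndarray
    channel_target: np.ndarray
    pixel_size: float  # nm / px
    orientation: str = PLANAR
    id: str = ""

    def __post_init__(self):
        self.channel_ref = np.asarray(self.channel_ref, dtype=float)
        self.channel_target = np.asarray(self.channel_target, dtype=float)
        if self.channel_ref.shape != self.channel_target.shape:
            raise ValueError(
                f"channel shapes differ: {self.channel_ref.shape} vs "
                f"{self.channel_target.shape}"
            )
        if self.channel_ref.ndim != 2:
            raise ValueError("channels must be 2D rasters")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.orientation not in (PLANAR, APICO_BASAL):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def shape(self):
        return self.channel_ref.shape


@dataclass
class JunctionTrace:
    """Ordered sub-pixel polyline marking one junction on an image.

    ``points`` are (x, y) in pixel units, pixel-center convention
    (integer coordinates address pixel centers, 0-based, x = column).
    ``apical_direction`` is required for apico-basal profile sampling.
    """

    points: np.ndarray
    image_id: str = ""
    apical_direction: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = as_polyline(self.points)
        if self.apical_direction is not None:
            v = np.asarray(self.apical_direction, dtype=float)
            n = float(np.hypot(*v))
            if n == 0:
                raise ValueError("apical_direction must be non-zero")
            self.apical_direction = v / n

    @property
    def straightness(self) -> float:
        """Max chord deviation over chord length (0 for a straight trace)."""
        return chord_deviation(self.points)


@dataclass
class DensityProfile:
    """Pooled 1D protein density vs. signed distance from the TJ reference."""

    positions: np.ndarray  # nm, 0 = TJ reference, strictly increasing
    mean: np.ndarray
    sd: np.ndarray
    n_junctions: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.positions.shape == self.mean.shape == self.sd.shape):
            raise ValueError("positions/mean/sd must have identical shapes")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class GoldParticleSet:
    """Immunogold particle centers with TJ and membrane references (nm)."""

    particles: np.ndarray  # (n, 2) nm
    tj_reference: np.ndarray  # (2,) nm
    apical_axis: np.ndarray  # unit vector
    membrane: np.ndarray  # polyline (m, 2) nm
    microvilli: list = field(default_factory=list)  # list of (k, 2) polygons
    ids: Optional[np.ndarray] = None
    true_distances: Optional[np.ndarray] = None  # set by the simulator
    far_zone_min: Optional[float] = None

    def __post_init__(self):
        self.particles = np.asarray(self.particles, dtype=float).reshape(-1, 2)
        self.tj_reference = np.asarray(self.tj_reference, dtype=float)
        self.apical_axis = np.asarray(self.apical_axis, dtype=float)
        if abs(float(np.hypot(*self.apical_axis)) - 1.0) > 1e-9:
            raise ValueError("apical_axis must be a unit vector (1e-9)")
        self.membrane = as_polyline(self.membrane)
        if self.ids is None:
            self.ids = np.arange(len(self.particles))
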