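"""Correlation-based protein–protein proximity index (PPI) on junction bands.

Straight junctions are resampled into 400-nm-wide two-channel bands
centered on the TJ reference, concatenated along the junction axis, and
auto-/cross-correlated with 1D lags along that axis.  The index is the
ratio of fitted correlation peak amplitudes: P1 = C12/A2, P2 = C12/A1.
A value of 0 means no proximity, 1 perfect proximity; intermediate
values estimate the fraction of one protein population in close
proximity to the other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .geometry import chord_deviation, resample_polyline
from .profiles import _bilinear_many, planar_reference
from .types import ImagePair, JunctionTrace

log = logging.getLogger(__name__)

DEFAULT_BAND_WIDTH = 400.0  # nm
DEFAULT_STRAIGHTNESS = 0.05


@dataclass
class JunctionBand:
    """Straightened two-channel strip: rows = across-junction (center row
    on the TJ reference), cols = along-junction."""

    ref: np.ndarray
    target: np.ndarray
    width: float  # nm
    pixel_size: float  # nm/px
    junction_id: str = ""

    def __post_init__(self):
        if self.ref.shape != self.target.shape:
            raise ValueError("band channels must have identical shapes")
        if self.ref.shape[0] % 2 == 0:
            raise ValueError("band row count must be odd (center = reference)")

    @property
    def n_cols(self) -> int:
        return self.ref.shape[1]


@dataclass
class CorrelationCurve:
    lags: np.ndarray  # px along the junction axis
    values: np.ndarray  # normalized correlation coefficient per lag

    def __post_init__(self):
        if self.lags.shape != self.values.shape:
            raise ValueError("lags/values shape mismatch")


@dataclass
class ProximityResult:
    A1: float
    A2: float
    C12: float
    P1: float
    P2: float
    n_junctions: int = 0
    total_band_length: float = 0.0  # nm

    def as_dict(self) -> dict:
        return {
            "A1": self.A1,
            "A2": self.A2,
            "C12": self.C12,
            "P1": self.P1,
            "P2": self.P2,
            "n_junctions": self.n_junctions,
            "total_band_length_nm": self.total_band_length,
        }


def junction_straightness(trace: JunctionTrace) -> float:
    """Straightness score: max perpendicular deviation of vertices from
    the end-to-end chord, over the chord length (0 = perfectly straight)."""
    return chord_deviation(trace.points)


def extract_band(
    pair: ImagePair,
    trace: JunctionTrace,
    width: float = DEFAULT_BAND_WIDTH,
    *,
    center_on_reference: bool = True,
    straightness_threshold: Optional[float] = DEFAULT_STRAIGHTNESS,
) -> JunctionBand:
    """Resample a 400-nm band centered on the junction into a straight strip.

    Columns sit at arc-length steps of one pixel along the trace; rows at
    pixel steps across it.  With ``center_on_reference`` each column is
    centered on the per-column TJ reference (sub-pixel peak of the
    reference channel); otherwise on the trace itself (used for
    simulated pairs that carry no TJ marker channel).  Out-of-bounds
    columns are dropped and logged; a fully out-of-bounds band raises.
    """
    px = pair.pixel_size
    if straightness_threshold is not None:
        s = junction_straightness(trace)
        if s > straightness_threshold:
            raise ValueError(
                f"junction not straight enough: score {s:.4f} > "
                f"{straightness_threshold}"
            )
    half_rows = int(np.floor(width / (2.0 * px)))
    row_offsets_px = np.arange(-half_rows, half_rows + 1, dtype=float)

    stations, tangents = resample_polyline(trace.points, 1.0)  # 1 px steps
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    rows, cols = pair.shape

    # search window for the per-column reference: band half-width plus a
    # half-band margin so an off-center TJ peak can still be found
    search_px = np.arange(-1.5 * half_rows, 1.5 * half_rows + 0.5)

    ref_cols, tgt_cols = [], []
    n_dropped = 0
    for p, nvec in zip(stations, normals):
        center = 0.0
        if center_on_reference:
            xs = p[0] + search_px * nvec[0]
            ys = p[1] + search_px * nvec[1]
            if xs.min() < 0 or xs.max() > cols - 1 or ys.min() < 0 or ys.max() > rows - 1:
                n_dropped += 1
                continue
            line = _bilinear_many(pair.channel_ref, xs, ys)
            try:
                center = planar_reference(search_px, line)
            except ValueError:
                n_dropped += 1
                continue
        offs = center + row_offsets_px
        xs = p[0] + offs * nvec[0]
        ys = p[1] + offs * nvec[1]
        if xs.min() < 0 or xs.max() > cols - 1 or ys.min() < 0 or ys.max() > rows - 1:
            n_dropped += 1
            continue
        ref_cols.append(_bilinear_many(pair.channel_ref, xs, ys))
        tgt_cols.append(_bilinear_many(pair.channel_target, xs, ys))

    if n_dropped:
        log.info("extract_band: dropped %d/%d columns", n_dropped, len(stations))
    if not ref_cols:
        raise ValueError("band entirely outside the image interior")
    return JunctionBand(
        ref=np.array(ref_cols).T,
        target=np.array(tgt_cols).T,
        width=width,
        pixel_size=px,
        junction_id=trace.image_id,
    )


def concatenate_bands(bands: Sequence[JunctionBand]):
    """Place bands side by side along the junction axis.

    Returns ``(ref, target, band_ids)`` where ``band_ids[j]`` marks the
    source band of column ``j`` so correlation lags never pair columns
    across a seam.
    """
    if not bands:
        raise ValueError("no bands to concatenate")
    n_rows = bands[0].ref.shape[0]
    px = bands[0].pixel_size
    for b in bands[1:]:
        if b.ref.shape[0] != n_rows or b.pixel_size != px:
            raise ValueError("bands have heterogeneous shapes or pixel sizes")
    ref = np.hstack([b.ref for b in bands])
    tgt = np.hstack([b.target for b in bands])
    band_ids = np.concatenate(
        [np.full(b.n_cols, i, dtype=int) for i, b in enumerate(bands)]
    )
    return ref, tgt, band_ids


def correlation_function(
    chan_a: np.ndarray,
    chan_b: np.ndarray,
    band_ids: Optional[np.ndarray] = None,
    max_lag: int = 50,
) -> CorrelationCurve:
    """Normalized correlation vs. 1D lag along the junction axis.

    For lag d, the Pearson correlation between A(:, x) and B(:, x+d)
    over all pixel pairs whose two columns belong to the same source
    band (non-circular; means and SDs are computed per lag over the
    overlapping support).  Raises on a channel with zero variance.
    """
    a = np.asarray(chan_a, dtype=float)
    b = np.asarray(chan_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    n_cols = a.shape[1]
    if band_ids is None:
        band_ids = np.zeros(n_cols, dtype=int)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance: constant channel")

    lags = np.arange(-max_lag, max_lag + 1)
    values = np.empty(len(lags))
    cols = np.arange(n_cols)
    for k, d in enumerate(lags):
        if d >= 0:
            xa = cols[: n_cols - d] if d else cols
            xb = xa + d
        else:
            xb = cols[: n_cols + d]
            xa = xb - d
        same = band_ids[xa] == band_ids[xb]
        xa, xb = xa[same], xb[same]
        if xa.size == 0:
            values[k] = np.nan
            continue
        va = a[:, xa].ravel()
        vb = b[:, xb].ravel()
        sa = va.std()
        sb = vb.std()
        if sa == 0 or sb == 0:
            values[k] = np.nan
            continue
        values[k] = float(np.mean((va - va.mean()) * (vb - vb.mean())) / (sa * sb))
    return CorrelationCurve(lags=lags, values=values)


def peak_amplitude(
    curve: CorrelationCurve,
    psf_fwhm_px: float = 4.0,
    *,
    exclude_zero_lag: bool = False,
) -> float:
    """Central peak height above baseline from a least-squares fit of
    Gaussian + constant over |lag| <= 5 PSF FWHM.

    Falls back to (value at lag 0 minus the median beyond 3 PSF FWHM)
    when the fit fails.  Negative amplitudes are floored at 0 with a
    warning.  ``exclude_zero_lag`` removes the lag-0 sample from the fit
    (useful when uncorrelated shot noise adds a single-pixel spike).
    """
    lags = np.asarray(curve.lags, dtype=float)
    vals = np.asarray(curve.values, dtype=float)
    ok = np.isfinite(vals)
    lags, vals = lags[ok], vals[ok]
    if lags.size == 0 or not np.all(np.isfinite(vals)):
        raise ValueError("correlation curve has no finite values")

    fit_win = 5.0 * psf_fwhm_px
    sel = np.abs(lags) <= fit_win
    if exclude_zero_lag:
        sel &= lags != 0
    x, y = lags[sel], vals[sel]

    amp = None
    if x.size >= 4 and np.ptp(y) > 0:
        def model(l, c, a, s):
            return c + a * np.exp(-(l**2) / (2.0 * s**2))

        base0 = float(np.median(y[np.abs(x) >= 3.0 * psf_fwhm_px])) if np.any(
            np.abs(x) >= 3.0 * psf_fwhm_px
        ) else float(y.min())
        peak0 = float(y[np.argmin(np.abs(x))]) - base0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model,
                    x,
                    y,
                    p0=[base0, peak0, psf_fwhm_px],
                    maxfev=5000,
                )
            amp = float(popt[1])
        except (RuntimeError, ValueError):
            amp = None

    if amp is None:
        far = np.abs(lags) > 3.0 * psf_fwhm_px
        baseline = float(np.median(vals[far])) if np.any(far) else 0.0
        center = float(vals[np.argmin(np.abs(lags))])
        amp = center - baseline

    if amp < 0:
        log.warning("negative correlation peak amplitude %.4g floored at 0", amp)
        amp = 0.0
    return amp


def proximity_indices(
    A1: float,
    A2: float,
    C12: float,
    n_junctions: int = 0,
    total_band_length: float = 0.0,
) -> ProximityResult:
    """P1 = C12/A2 (fraction of protein 1 near protein 2) and
    P2 = C12/A1; raw values, no clamping."""
    if A1 <= 0 or A2 <= 0:
        raise ValueError("autocorrelation amplitudes must be > 0")
    if C12 < 0:
        raise ValueError("cross-correlation amplitude must be >= 0")
    return ProximityResult(
        A1=A1,
        A2=A2,
        C12=C12,
        P1=C12 / A2,
        P2=C12 / A1,
        n_junctions=n_junctions,
        total_band_length=total_band_length,
    )


def venn_fractions(result: ProximityResult):
    """Per-protein (colocalizing, non-colocalizing) fractions for the
    Venn representation; indices clamped to [0, 1] here only."""
    p1 = min(max(result.P1, 0.0), 1.0)
    p2 = min(max(result.P2, 0.0), 1.0)
    return {
        "protein1": (p1, 1.0 - p1),
        "protein2": (p2, 1.0 - p2),
    }


def compute_ppi(
    bands: Sequence[JunctionBand],
    max_lag: int = 50,
    psf_fwhm_px: float = 4.0,
    *,
    exclude_zero_lag: bool = False,
) -> ProximityResult:
    """Concatenate bands, correlate, extract peak amplitudes, and form
    the proximity indices."""
    ref, tgt, band_ids = concatenate_bands(bands)
    ac1 = correlation_function(ref, ref, band_ids, max_lag)
    ac2 = correlation_function(tgt, tgt, band_ids, max_lag)
    cc = correlation_function(ref, tgt, band_ids, max_lag)
    A1 = peak_amplitude(ac1, psf_fwhm_px, exclude_zero_lag=exclude_zero_lag)
    A2 = peak_amplitude(ac2, psf_fwhm_px, exclude_zero_lag=exclude_zero_lag)
    C12 = peak_amplitude(cc, psf_fwhm_px, exclude_zero_lag=exclude_zero_lag)
    total_len = sum(b.n_cols * b.pixel_size for b in bands)
    return proximity_indices(A1, A2, C12, len(bands), total_len)
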