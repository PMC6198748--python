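"""AFM morphometry of collagen fibrils.

Height rasters (nm, 8 nm pixels in the original acquisitions) of fibrils
adsorbed on glass are reduced to: the cross-sectional area used as the
stress denominator (average of aligned cross-profiles over a short segment,
integrated), the D-band axial periodicity (~65-67 nm in native collagen),
kink positions along the post-rupture centerline (plastic damage sites), and
the mean height loss after rupture.

The fibril is assumed to run roughly along the raster's x (column) axis; the
centerline is traced by ridge following (height-weighted centroid per
column within the fibril mask, then smoothed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HeightMap:
    """AFM topography raster with its pixel size and fibril mask."""

    heights_nm: np.ndarray
    pixel_size_nm: float = 8.0
    fibril_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heights_nm = np.asarray(self.heights_nm, dtype=float)
        if self.heights_nm.ndim != 2:
            raise ValueError("heights must be a 2-D raster")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        if not np.all(np.isfinite(self.heights_nm)):
            raise ValueError("heights must be finite")
        if self.fibril_mask is None:
            self.fibril_mask = default_mask(self.heights_nm)
        self.fibril_mask = np.asarray(self.fibril_mask, dtype=bool)


@dataclass
class KinkAnnotation:
    """Kink (plastic damage site) positions along the fibril arc length."""

    positions_nm: np.ndarray
    count: int
    mean_spacing_nm: float = field(default=np.nan)
    undamaged_segments_nm: list[tuple[float, float]] = field(default_factory=list)


def default_mask(heights: np.ndarray, k_sigma: float = 5.0) -> np.ndarray:
    """Fibril footprint: pixels well above the substrate level.

    The fibril occupies a minority of pixels, so the raster median sits at
    the substrate level and the median absolute deviation gives a robust
    surface-noise scale; the mask is everything ``k_sigma`` noise scales
    above the substrate.
    """
    med = np.median(heights)
    sd = 1.4826 * np.median(np.abs(heights - med))
    if sd == 0:
        return heights > med
    return heights > med + k_sigma * sd


def subtract_background_plane(hmap: HeightMap) -> HeightMap:
    """Least-squares plane fit to off-mask (substrate) pixels, subtracted."""
    h = hmap.heights_nm
    off = ~hmap.fibril_mask
    if off.sum() < 3:
        raise ValueError("not enough substrate pixels for a plane fit")
    yy, xx = np.nonzero(off)
    A = np.column_stack([xx, yy, np.ones_like(xx)])
    coef, *_ = np.linalg.lstsq(A, h[off], rcond=None)
    gy, gx = np.mgrid[0:h.shape[0], 0:h.shape[1]]
    plane = coef[0] * gx + coef[1] * gy + coef[2]
    return HeightMap(heights_nm=h - plane, pixel_size_nm=hmap.pixel_size_nm,
                     fibril_mask=hmap.fibril_mask)


def trace_centerline(hmap: HeightMap, smooth_px: int = 5
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-following centerline: (x_nm, y_nm) per occupied column.

    Per column, the height-weighted centroid of masked pixels; the y path is
    then smoothed by a small moving average to suppress pixel noise.
    """
    h, mask = hmap.heights_nm, hmap.fibril_mask
    cols = np.nonzero(mask.any(axis=0))[0]
    if cols.size < 2:
        raise ValueError("no fibril found to trace")
    # only the contiguous span (avoids stray mask speckle at the borders)
    cols = np.arange(cols[0], cols[-1] + 1)
    ys = np.empty(cols.size)
    rows = np.arange(h.shape[0], dtype=float)
    for i, c in enumerate(cols):
        m = mask[:, c]
        if not m.any():
            ys[i] = np.nan
            continue
        w = np.clip(h[m, c], 0, None)
        ys[i] = float((rows[m] * w).sum() / w.sum()) if w.sum() > 0 \
            else float(rows[m].mean())
    good = np.isfinite(ys)
    ys = np.interp(np.arange(cols.size), np.nonzero(good)[0], ys[good])
    if smooth_px > 1:
        k = np.ones(smooth_px) / smooth_px
        pad = smooth_px // 2
        ypad = np.pad(ys, pad, mode="edge")
        ys = np.convolve(ypad, k, mode="valid")
    return cols * hmap.pixel_size_nm, ys * hmap.pixel_size_nm


def centerline_arclength(x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
    seg = np.hypot(np.diff(x_nm), np.diff(y_nm))
    return np.concatenate([[0.0], np.cumsum(seg)])


def average_profile(hmap: HeightMap, segment_length_nm: float = 500.0,
                    center_nm: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean of centerline-aligned cross-profiles over a short axial segment.

    The background plane is subtracted first; each column's profile is
    shifted so the centerline sits at a common position, and the shifted
    profiles are averaged.  Returns (offset_nm, height_nm).
    """
    flat = subtract_background_plane(hmap)
    x_nm, y_nm = trace_centerline(flat)
    px = flat.pixel_size_nm
    if center_nm is None:
        center_nm = 0.5 * (x_nm[0] + x_nm[-1])
    half = segment_length_nm / 2.0
    sel = (x_nm >= center_nm - half) & (x_nm <= center_nm + half)
    if sel.sum() < 2:
        raise ValueError("segment lies outside the traced fibril "
                         "or spans fewer than 2 scanlines")
    h = flat.heights_nm
    ny = h.shape[0]
    rows = np.arange(ny, dtype=float)
    y_ref = float(np.mean(y_nm[sel])) / px
    profiles = []
    for c, yc in zip((x_nm[sel] / px).astype(int), y_nm[sel] / px):
        shift = yc - y_ref
        profiles.append(np.interp(rows, rows - shift, h[:, c],
                                  left=0.0, right=0.0))
    mean_profile = np.mean(profiles, axis=0)
    offsets = (rows - y_ref) * px
    return offsets, mean_profile


def cross_sectional_area(offset_nm: np.ndarray, height_nm: np.ndarray
                         ) -> float:
    """Trapezoidal integral of height above zero, in um^2."""
    h = np.clip(np.asarray(height_nm, dtype=float), 0.0, None)
    area_nm2 = float(np.trapezoid(h, np.asarray(offset_nm, dtype=float)))
    if area_nm2 == 0:
        import warnings
        warnings.warn("all-zero profile: cross-sectional area is 0")
    return area_nm2 * 1e-6


def centerline_height_signal(hmap: HeightMap) -> tuple[np.ndarray, np.ndarray]:
    """Height along the traced centerline, resampled uniformly in arc length.

    Returns (arclength_nm, height_nm) at the raster's pixel spacing.
    """
    flat = subtract_background_plane(hmap)
    x_nm, y_nm = trace_centerline(flat)
    px = flat.pixel_size_nm
    # height at the (sub-pixel) centerline via per-column interpolation
    rows = np.arange(flat.heights_nm.shape[0], dtype=float)
    hvals = np.array([
        np.interp(y / px, rows, flat.heights_nm[:, int(round(x / px))])
        for x, y in zip(x_nm, y_nm)
    ])
    s = centerline_arclength(x_nm, y_nm)
    s_uniform = np.arange(0.0, s[-1], px)
    return s_uniform, np.interp(s_uniform, s, hvals)


def dband_period(hmap: HeightMap, period_band_nm: tuple[float, float] = (30.0, 150.0),
                 peak_snr: float = 5.0, pad_factor: int = 8,
                 min_concentration: float = 0.2) -> float:
    """Dominant axial period (nm) of the centerline height signal.

    Detrended, Hann-windowed, zero-padded spectrum; the strongest peak
    within the plausible banding range, refined by parabolic interpolation.
    Raises if no peak stands above the in-band noise floor, or if the peak
    does not concentrate at least ``min_concentration`` of the in-band power
    within its natural linewidth (a coherent sinusoid does; noise spreads
    its power across the band).
    """
    s, h = centerline_height_signal(hmap)
    if s.size < 16:
        raise ValueError("centerline too short for period estimation")
    ds = s[1] - s[0]
    y = h - np.polyval(np.polyfit(s, h, 1), s)   # remove mean and tilt
    y = y * np.hanning(y.size)
    nfft = int(2 ** np.ceil(np.log2(y.size * pad_factor)))
    power = np.abs(np.fft.rfft(y, nfft)) ** 2
    freq = np.fft.rfftfreq(nfft, d=ds)
    band = (freq > 1.0 / period_band_nm[1]) & (freq < 1.0 / period_band_nm[0])
    if not band.any():
        raise ValueError("no periodicity detected: empty search band")
    idx = np.nonzero(band)[0]
    k = idx[np.argmax(power[idx])]
    floor = np.median(power[idx])
    if floor <= 0 or power[k] < peak_snr * floor:
        raise ValueError("no periodicity detected: spectral peak does not "
                         "stand above the noise floor")
    # Hann main lobe spans ~4 natural bins -> 4 * (nfft / y.size) padded bins
    half_lobe = 2 * max(1, int(round(nfft / y.size)))
    lo = np.searchsorted(idx, k - half_lobe)
    hi = np.searchsorted(idx, k + half_lobe, side="right")
    concentration = power[idx[lo:hi]].sum() / power[idx].sum()
    if concentration < min_concentration:
        raise ValueError("no periodicity detected: in-band power is not "
                         "concentrated at the spectral peak")
    if 0 < k < power.size - 1:
        y0, y1, y2 = np.log(power[k - 1:k + 2] + 1e-300)
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    f_peak = (k + delta) / nfft / ds
    return float(1.0 / f_peak)


def detect_kinks(hmap: HeightMap, angle_threshold_deg: float = 20.0,
                 window_nm: float = 200.0) -> KinkAnnotation:
    """Kinks: sharp bends of the traced centerline.

    The local tangent direction is estimated over +/- one window; positions
    where it changes by more than the threshold are kinks, non-maximum
    suppressed within one window.  Undamaged segments are the intervals
    between consecutive kinks longer than one window.
    """
    x_nm, y_nm = trace_centerline(hmap)
    s = centerline_arclength(x_nm, y_nm)
    if s[-1] < 2 * window_nm:
        raise ValueError("centerline shorter than two windows")
    w_pts = max(2, int(round(window_nm / (s[-1] / (s.size - 1)))))
    n = s.size
    change = np.zeros(n)
    for i in range(w_pts, n - w_pts):
        a_before = np.arctan2(y_nm[i] - y_nm[i - w_pts],
                              x_nm[i] - x_nm[i - w_pts])
        a_after = np.arctan2(y_nm[i + w_pts] - y_nm[i],
                             x_nm[i + w_pts] - x_nm[i])
        d = np.rad2deg(a_after - a_before)
        change[i] = abs((d + 180.0) % 360.0 - 180.0)

    thresh = angle_threshold_deg
    positions = []
    i = 0
    while i < n:
        if change[i] > thresh:
            # local maximum within one window
            j0 = i
            j1 = i
            while j1 + 1 < n and (s[j1 + 1] - s[j0]) <= window_nm and \
                    change[j1 + 1] > thresh:
                j1 += 1
            k = j0 + int(np.argmax(change[j0:j1 + 1]))
            positions.append(s[k])
            i = j1 + 1
            # skip ahead one window to suppress the same bend
            while i < n and s[i] - s[k] < window_nm:
                i += 1
        else:
            i += 1
    positions = np.asarray(positions, dtype=float)
    count = positions.size
    spacing = float(np.diff(positions).mean()) if count >= 2 else np.nan
    undamaged = []
    for a, b in zip(positions[:-1], positions[1:]):
        if b - a > window_nm:
            undamaged.append((float(a), float(b)))
    return KinkAnnotation(positions_nm=positions, count=int(count),
                          mean_spacing_nm=spacing,
                          undamaged_segments_nm=undamaged)


def height_loss(before: HeightMap, after: HeightMap
                ) -> tuple[float, float, float]:
    """(mean height before, loss, normalized loss %) along the centerlines."""
    _, h_before = centerline_height_signal(before)
    _, h_after = centerline_height_signal(after)
    mean_before = float(h_before.mean())
    if mean_before <= 0:
        raise ValueError("non-positive mean fibril height before rupture")
    loss = mean_before - float(h_after.mean())
    return mean_before, loss, 100.0 * loss / mean_before
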