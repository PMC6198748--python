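"""Polarization-resolved SHG anisotropy analysis.

A pol-stack is a series of forward-scattered second-harmonic images of one
field acquired while the linear excitation polarization angle alpha is
rotated 0-240 degrees in 10-degree steps (25 images).  Under cylindrical
(C6v) and Kleinman symmetry the fibril response to polarization alpha, for a
fibril at angle phi, is

    I_2w  ∝  [rho cos^2(phi - alpha) + sin^2(phi - alpha)]^2
             + sin^2(2 (phi - alpha))

where rho = chi2_xxx / chi2_xyy is the anisotropy parameter: the ratio of
the two independent components of the second-order susceptibility tensor.
The law is pi-periodic in alpha, so the first 18 images (0-170 deg) span
exactly one period; they are the only ones used, both for the maximum
intensity map and for the Fourier analysis.  Expanding in harmonics of
theta = phi - alpha,

    I_2w ∝ a0 + a2 cos(2 theta) + a4 cos(4 theta)

with, for a trace of unit proportionality constant,

    a0 = (rho+1)^2/4 + (rho-1)^2/8 + 1/2
    a2 = (rho^2 - 1)/2
    a4 = (rho-1)^2/8 - 1/2

so that a0 + a2 + a4 = rho^2 and a0 - a2 + a4 = 1, and hence

    rho = sqrt((a0 + a2 + a4) / (a0 - a2 + a4)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Polarization angles of a full acquisition, degrees.
STANDARD_ANGLES = tuple(range(0, 250, 10))
#: Number of images spanning one 180-degree period at 10-degree steps.
PERIOD_IMAGES = 18


@dataclass
class PolStack:
    """Stack of SHG intensity images with its polarization-angle axis."""

    images: np.ndarray          # (n_angles, ny, nx) counts
    angles_deg: np.ndarray      # (n_angles,) strictly increasing
    pixel_size_nm: float = 200.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_angles, ny, nx) stack")
        if len(self.angles_deg) != self.images.shape[0]:
            raise ValueError("one image per angle required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.images < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class AnisotropyResult:
    """Per-pixel Fourier coefficients and anisotropy map for one pol-stack."""

    rho_map: np.ndarray          # NaN where undefined
    a0_map: np.ndarray
    a2_map: np.ndarray
    a4_map: np.ndarray
    phi_map: np.ndarray          # fibril angle estimate, deg mod 180
    mask: np.ndarray
    phi_estimate: float = field(default=np.nan)   # mask-median fibril angle
    peak_rho: float = field(default=np.nan)
    fwhm_rho: float = field(default=np.nan)

    @property
    def defined(self) -> np.ndarray:
        return self.mask & np.isfinite(self.rho_map)


def forward_model(rho, phi_deg, alpha_deg):
    """Relative SHG intensity for anisotropy rho, fibril angle phi,
    polarization angle alpha (degrees).  Broadcasts over inputs."""
    theta = np.deg2rad(np.asarray(phi_deg, dtype=float)
                       - np.asarray(alpha_deg, dtype=float))
    rho = np.asarray(rho, dtype=float)
    bracket = rho * np.cos(theta) ** 2 + np.sin(theta) ** 2
    return bracket**2 + np.sin(2.0 * theta) ** 2


def expansion_coeffs(rho: float) -> tuple[float, float, float]:
    """Closed-form (a0, a2, a4) of the intensity law at unit amplitude."""
    a0 = (rho + 1) ** 2 / 4 + (rho - 1) ** 2 / 8 + 0.5
    a2 = (rho**2 - 1) / 2
    a4 = (rho - 1) ** 2 / 8 - 0.5
    return a0, a2, a4


def max_intensity_map(stack: PolStack) -> np.ndarray:
    """Polarization-corrected maximum intensity map.

    Pixelwise maximum over exactly the first 18 images (0-170 deg, one full
    period of the intensity law); later images are redundant and ignored.
    """
    if stack.images.shape[0] < PERIOD_IMAGES:
        raise ValueError(
            f"pol-stack must contain at least {PERIOD_IMAGES} images "
            f"covering 0-170 deg, got {stack.images.shape[0]}")
    return stack.images[:PERIOD_IMAGES].max(axis=0)


def _consistency_residual(a0: float, a2: float, a4: float) -> float:
    # Amplitude is locked by a0 - a2 + a4 = A; the sin^2(2 theta) term then
    # pins a4 = A ((rho-1)^2/8 - 1/2).  Non-physical candidates violate this.
    denom = a0 - a2 + a4
    num = a0 + a2 + a4
    if denom <= 0 or num < 0:
        return np.inf
    rho = np.sqrt(num / denom)
    a4_pred = denom * ((rho - 1) ** 2 / 8 - 0.5)
    return abs(a4 - a4_pred)


def fourier_coeffs(trace: np.ndarray,
                   angles_deg: np.ndarray | None = None
                   ) -> tuple[float, float, float, float]:
    """Harmonic decomposition of one 18-point polarization trace.

    Returns ``(a0, a2, a4, phi_deg)`` where phi is the fibril-angle estimate
    modulo 180 degrees.  The trace must sample one full 180-degree period
    uniformly (the standard 0-170 deg in 10-degree steps).

    The DFT of the trace yields amplitude and phase of the 2-theta and
    4-theta harmonics; the fibril angle phi is the common phase.  phi and
    phi + 90 deg fit the harmonics equally well (with the sign of a2
    flipped, i.e. rho mapped to 1/rho), but only one choice is consistent
    with the full intensity law, whose sin^2(2 theta) term fixes the ratio
    of a4 to the overall amplitude.  The consistent candidate is returned.
    """
    y = np.asarray(trace, dtype=float)
    n = y.size
    if angles_deg is not None:
        ang = np.asarray(angles_deg, dtype=float)
        if ang.size != n:
            raise ValueError("angles and trace lengths differ")
        step = np.diff(ang)
        if not np.allclose(step, step[0]):
            raise ValueError("angles must be uniformly spaced")
        if not np.isclose(step[0] * n, 180.0):
            raise ValueError("trace must span one 180-degree period")
    if n < 5:
        raise ValueError("at least 5 samples required")

    f = np.fft.rfft(y)
    a0 = f[0].real / n
    # I(alpha_k) = a0 + p cos(2 alpha_k) + q sin(2 alpha_k)
    #                 + u cos(4 alpha_k) + v sin(4 alpha_k)
    # with p = a2 cos(2 phi), q = a2 sin(2 phi), u = a4 cos(4 phi),
    # v = a4 sin(4 phi): harmonics 1 and 2 of the 180-deg period.
    p = 2.0 * f[1].real / n
    q = -2.0 * f[1].imag / n
    u = 2.0 * f[2].real / n
    v = -2.0 * f[2].imag / n

    if np.hypot(p, q) > 1e-12 * max(abs(a0), 1.0):
        phi0 = 0.5 * np.arctan2(q, p)
    elif np.hypot(u, v) > 1e-12 * max(abs(a0), 1.0):
        # rho = 1: no 2-theta harmonic; take phi from the 4-theta phase
        # assuming a4 < 0 (true for the intensity law whenever |rho-1| < 2).
        phi0 = (np.arctan2(v, u) - np.pi) / 4.0
    else:
        return a0, 0.0, 0.0, 0.0

    best = None
    for phi in (phi0, phi0 + np.pi / 2):
        a2 = p * np.cos(2 * phi) + q * np.sin(2 * phi)
        a4 = u * np.cos(4 * phi) + v * np.sin(4 * phi)
        r = _consistency_residual(a0, a2, a4)
        if best is None or r < best[0]:
            best = (r, a2, a4, phi)
    _, a2, a4, phi = best
    phi_deg = float(np.rad2deg(phi) % 180.0)
    return float(a0), float(a2), float(a4), phi_deg


def anisotropy_from_coeffs(a0: float, a2: float, a4: float) -> float:
    """rho = sqrt((a0 + a2 + a4) / (a0 - a2 + a4)).

    Exact inversion of the intensity law: for a unit-amplitude trace
    a0 + a2 + a4 = rho^2 and a0 - a2 + a4 = 1.  Returns NaN when either
    combination is non-positive (undefined pixel).
    """
    num = a0 + a2 + a4
    den = a0 - a2 + a4
    if num <= 0 or den <= 0:
        return np.nan
    return float(np.sqrt(num / den))


def rho_map(stack: PolStack, mask: np.ndarray) -> AnisotropyResult:
    """Per-pixel anisotropy over a fibril mask.

    Runs the harmonic decomposition on the first 18 images at every masked
    pixel; off-mask and non-invertible pixels are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.images.shape[1:]:
        raise ValueError("mask shape does not match images")
    if not mask.any():
        raise ValueError("empty fibril mask")
    if stack.images.shape[0] < PERIOD_IMAGES:
        raise ValueError(f"pol-stack must contain at least {PERIOD_IMAGES} images")
    sub = stack.images[:PERIOD_IMAGES]
    ny, nx = mask.shape
    shape = (ny, nx)
    rho = np.full(shape, np.nan)
    a0m = np.full(shape, np.nan)
    a2m = np.full(shape, np.nan)
    a4m = np.full(shape, np.nan)
    phim = np.full(shape, np.nan)
    ys, xs = np.nonzero(mask)
    for yy, xx in zip(ys, xs):
        a0, a2, a4, phi = fourier_coeffs(sub[:, yy, xx])
        a0m[yy, xx], a2m[yy, xx], a4m[yy, xx] = a0, a2, a4
        phim[yy, xx] = phi
        rho[yy, xx] = anisotropy_from_coeffs(a0, a2, a4)
    result = AnisotropyResult(rho_map=rho, a0_map=a0m, a2_map=a2m,
                              a4_map=a4m, phi_map=phim, mask=mask)
    good = result.defined
    if good.any():
        result.phi_estimate = float(np.median(phim[good]))
    return result


def rho_distribution(result: AnisotropyResult, bin_width: float = 0.05,
                     min_pixels: int = 50) -> tuple[float, float]:
    """Peak and FWHM of the distribution of defined per-pixel rho values.

    Histogram at the given bin width; the peak is the modal bin center
    refined by parabolic interpolation over three bins, the FWHM by linear
    interpolation of the half-maximum crossings.
    """
    vals = result.rho_map[result.defined]
    if vals.size < min_pixels:
        raise ValueError(f"need at least {min_pixels} defined pixels, "
                         f"got {vals.size}")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.argmax(counts))
    peak = centers[k]
    if 0 < k < len(counts) - 1:
        y0, y1, y2 = counts[k - 1:k + 2].astype(float)
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            peak = centers[k] + 0.5 * (y0 - y2) / denom * bin_width

    half = counts[k] / 2.0
    # left crossing
    left = centers[0]
    for i in range(k, 0, -1):
        if counts[i - 1] < half <= counts[i]:
            frac = (half - counts[i - 1]) / (counts[i] - counts[i - 1])
            left = centers[i - 1] + frac * bin_width
            break
    right = centers[-1]
    for i in range(k, len(counts) - 1):
        if counts[i] >= half > counts[i + 1]:
            frac = (counts[i] - half) / (counts[i] - counts[i + 1])
            right = centers[i] + frac * bin_width
            break
    fwhm = max(right - left, 0.0)
    if fwhm == 0.0:
        fwhm = bin_width  # all mass in one bin
    return float(peak), float(fwhm)


def intensity_ratio(ruptured_map: np.ndarray, control_map: np.ndarray,
                    ruptured_mask: np.ndarray,
                    control_mask: np.ndarray) -> float:
    """Mean max-intensity over the ruptured mask / mean over the control."""
    rm = np.asarray(ruptured_mask, dtype=bool)
    cm = np.asarray(control_mask, dtype=bool)
    if not rm.any() or not cm.any():
        raise ValueError("both masks must be non-empty")
    control_mean = float(np.asarray(control_map)[cm].mean())
    if control_mean == 0:
        raise ValueError("control region has zero mean intensity")
    return float(np.asarray(ruptured_map)[rm].mean()) / control_mean


def fibril_mask_from_max(max_map: np.ndarray, k_sigma: float = 5.0
                         ) -> np.ndarray:
    """Threshold mask: pixels well above the background intensity.

    The fibril is a minority of pixels, so the map median sits at the
    background level; the median absolute deviation gives a robust noise
    scale.  Pixels more than ``k_sigma`` noise scales above the background
    form the mask.  With zero background noise, any positive pixel counts.
    """
    m = np.asarray(max_map, dtype=float)
    med = np.median(m)
    sd = 1.4826 * np.median(np.abs(m - med))
    if sd == 0:
        return m > med
    return m > med + k_sigma * sd


def write_polstack(stack: PolStack, path: str | Path) -> None:
    """Multi-page TIFF plus a sidecar angle table (<path>.angles.csv)."""
    path = Path(path)
    tifffile.imwrite(path, stack.images.astype(np.float32))
    pd.DataFrame({"angle_deg": stack.angles_deg}).to_csv(
        path.with_suffix(path.suffix + ".angles.csv"), index=False)


def read_polstack(path: str | Path, pixel_size_nm: float = 200.0) -> PolStack:
    path = Path(path)
    images = tifffile.imread(path).astype(float)
    angle_file = path.with_suffix(path.suffix + ".angles.csv")
    if angle_file.exists():
        angles = pd.read_csv(angle_file)["angle_deg"].to_numpy()
    else:
        angles = np.array(STANDARD_ANGLES[:images.shape[0]], dtype=float)
    return PolStack(images=images, angles_deg=angles,
                    pixel_size_nm=pixel_size_nm)
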