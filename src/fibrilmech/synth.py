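"""Synthetic raw-data generator with known ground truth.

Every input modality of the workflow is generated here from a
:class:`FibrilGroundTruth`, so each analysis stage can be verified by
parameter recovery:

* pol-stacks obeying the SHG intensity law, with optional Poisson shot noise;
* AFM height maps: a half-cylinder fibril with sinusoidal D-band modulation,
  optional kinks, and Gaussian surface noise;
* bowstring pull experiments: a constant-velocity deflection ramp (video
  rate) and a lateral force trace (force rate) of frictional background plus
  projected fibril tension, with an abrupt rupture;
* two-channel CHP fluorescence images.

All draws flow from a single explicit seed per generator call; identical
seeds and parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .afm import HeightMap
from .cantilever import CantileverSpec
from .fluorescence import FluorImage
from .mechanics import PullExperiment
from .shg import STANDARD_ANGLES, PolStack, forward_model


@dataclass
class FibrilGroundTruth:
    """Ground-truth parameters of one synthetic fibril.

    Defaults follow the study conditions: ~100 nm dry radius, 50 um
    prepared segment, 67 nm D-band, anisotropy ~1.5, rupture around 20%
    strain with an effectively linear high-strain response.
    """

    dry_radius_nm: float = 100.0
    segment_length_um: float = 50.0
    dband_period_nm: float = 67.0
    rho_true: float = 1.5
    fibril_angle_phi_deg: float = 30.0
    rupture_strain_pct: float = 20.0
    modulus_mpa: float = 500.0
    stress_law: Callable[[np.ndarray], np.ndarray] | None = None
    kink_positions_nm: tuple[float, ...] = ()
    kink_angle_deg: float = 30.0
    slack_deflection_um: float = 0.0
    dband_depth_nm: float = 4.0        # peak-to-peak height modulation

    def __post_init__(self) -> None:
        if self.dry_radius_nm <= 0:
            raise ValueError("dry radius must be positive")
        if not 0 < self.rupture_strain_pct < 100:
            raise ValueError("rupture strain must lie in (0, 100)%")
        if self.rho_true <= 0:
            raise ValueError("anisotropy must be positive")
        kp = np.asarray(self.kink_positions_nm, dtype=float)
        if kp.size and (np.any(np.diff(kp) <= 0) or kp.min() < 0 or
                        kp.max() > self.segment_length_um * 1000.0):
            raise ValueError("kink positions must be strictly increasing "
                             "within the segment")

    @property
    def dry_area_um2(self) -> float:
        """Half-cylinder cross-sectional area pi r^2 / 2, um^2."""
        return float(np.pi * self.dry_radius_nm**2 / 2.0) * 1e-6

    def stress_at(self, strain_pct):
        """Stress (MPa) at a given strain (%), per the fibril's law."""
        if self.stress_law is not None:
            return self.stress_law(strain_pct)
        return self.modulus_mpa * np.asarray(strain_pct, dtype=float) / 100.0


def make_polstack(rho_field: np.ndarray, phi_deg: float,
                  angles_deg=STANDARD_ANGLES, amplitude: float = 1000.0,
                  noise: bool = True, background: float = 0.0,
                  seed: int = 0, pixel_size_nm: float = 200.0) -> PolStack:
    """Pol-stack from a per-pixel anisotropy raster.

    ``rho_field`` is positive on the fibril footprint and zero elsewhere;
    fibril pixels follow amplitude x the intensity law, background pixels
    carry only the (optional) background level.  Poisson shot noise is
    applied to the expected counts when ``noise`` is set.
    """
    rho = np.asarray(rho_field, dtype=float)
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if np.any(rho < 0):
        raise ValueError("anisotropy field must be non-negative")
    if not np.all(np.isfinite(rho)):
        raise ValueError("anisotropy field must be finite")
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("at least one polarization angle required")
    on = rho > 0
    images = np.empty((angles.size,) + rho.shape)
    for i, alpha in enumerate(angles):
        img = np.full(rho.shape, float(background))
        img[on] += amplitude * forward_model(rho[on], phi_deg, alpha)
        images[i] = img
    if noise:
        rng = np.random.default_rng(seed)
        images = rng.poisson(images).astype(float)
    return PolStack(images=images, angles_deg=angles,
                    pixel_size_nm=pixel_size_nm)


def _centerline_polyline(truth: FibrilGroundTruth, step_nm: float,
                         initial_angle_deg: float = 0.0
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled centerline (x, y, s) in nm, bending at each kink position."""
    total = truth.segment_length_um * 1000.0
    s = np.arange(0.0, total + step_nm, step_nm)
    kinks = np.asarray(truth.kink_positions_nm, dtype=float)
    # alternate the bend direction so the path stays compact
    angle = np.full_like(s, initial_angle_deg)
    a = initial_angle_deg
    sign = 1.0
    for i, kp in enumerate(kinks):
        sign = -sign if i else 1.0
        a_new = a + sign * truth.kink_angle_deg
        angle[s >= kp] = a_new
        a = a_new
    theta = np.deg2rad(angle)
    dx = np.cos(theta) * step_nm
    dy = np.sin(theta) * step_nm
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0.0], np.cumsum(dy[:-1])])
    return x, y, s


def make_afm_map(truth: FibrilGroundTruth, pixel_nm: float = 8.0,
                 noise_sd_nm: float = 0.5, seed: int = 0,
                 margin_nm: float = 400.0,
                 initial_angle_deg: float = 0.0,
                 shape: tuple[int, int] | None = None) -> HeightMap:
    """Synthetic AFM height map of one (possibly kinked) fibril.

    The fibril is a half-cylinder of the ground-truth dry radius along a
    centerline that bends at each kink position; its height is modulated
    axially by a sinusoid of the D-band period (``dband_depth_nm``
    peak-to-peak), with additive Gaussian surface noise everywhere.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel size must be positive")
    from scipy.spatial import cKDTree

    r = truth.dry_radius_nm
    cx, cy, cs = _centerline_polyline(truth, step_nm=pixel_nm / 2.0,
                                      initial_angle_deg=initial_angle_deg)
    x0, x1 = cx.min() - margin_nm, cx.max() + margin_nm
    y0, y1 = cy.min() - margin_nm, cy.max() + margin_nm
    if shape is None:
        nx = int(np.ceil((x1 - x0) / pixel_nm))
        ny = int(np.ceil((y1 - y0) / pixel_nm))
    else:
        ny, nx = shape
        if (x1 - x0) > nx * pixel_nm or (y1 - y0) > ny * pixel_nm:
            raise ValueError(
                f"fibril footprint ({(x1 - x0):.0f} x {(y1 - y0):.0f} nm) "
                f"exceeds the requested raster "
                f"({nx * pixel_nm:.0f} x {ny * pixel_nm:.0f} nm)")
    gx = x0 + (np.arange(nx) + 0.5) * pixel_nm
    gy = y0 + (np.arange(ny) + 0.5) * pixel_nm
    gxx, gyy = np.meshgrid(gx, gy)

    # nearest centerline sample per pixel; pruned beyond the fibril radius
    tree = cKDTree(np.column_stack([cx, cy]))
    dist, idx = tree.query(np.column_stack([gxx.ravel(), gyy.ravel()]),
                           distance_upper_bound=r, workers=-1)
    dist = dist.reshape(ny, nx)
    on = np.isfinite(dist) & (dist < r)
    s_near = np.zeros((ny, nx))
    s_near[on] = cs[idx.reshape(ny, nx)[on]]

    heights = np.zeros((ny, nx))
    heights[on] = np.sqrt(r**2 - dist[on] ** 2)
    if truth.dband_depth_nm > 0:
        mod = 0.5 * truth.dband_depth_nm * np.sin(
            2.0 * np.pi * s_near[on] / truth.dband_period_nm)
        # taper the modulation with the profile so the footprint edge stays clean
        heights[on] += mod * (heights[on] / r)
    if noise_sd_nm > 0:
        rng = np.random.default_rng(seed)
        heights += rng.normal(0.0, noise_sd_nm, size=heights.shape)
    return HeightMap(heights_nm=heights, pixel_size_nm=pixel_nm,
                     fibril_mask=on)


def make_pull_experiment(truth: FibrilGroundTruth,
                         cantilever: CantileverSpec | None = None,
                         friction_level_un: float = 1.0,
                         friction_sd_un: float = 0.05,
                         force_rate_hz: float = 500.0,
                         video_rate_fps: float = 20.0,
                         pull_speed_um_s: float = 1.0,
                         post_rupture_s: float = 2.0,
                         seed: int = 0) -> PullExperiment:
    """Bowstring pull-to-rupture experiment with known ground truth.

    The midpoint deflection ramps at the pull speed and is sampled at the
    video rate; the lateral force (force rate) is frictional background plus
    the bowstring-projected fibril tension once the deflection exceeds the
    slack.  At the ground-truth rupture strain the fibril term vanishes
    within one force sample; a trailing window of pure friction follows.
    """
    if force_rate_hz <= 0 or video_rate_fps <= 0 or pull_speed_um_s <= 0:
        raise ValueError("rates and pull speed must be positive")
    L0 = truth.segment_length_um
    slack = truth.slack_deflection_um
    rest = 2.0 * np.hypot(L0 / 2.0, slack)     # taut length at slack onset

    def strain_pct(d):
        arc = 2.0 * np.hypot(L0 / 2.0, np.asarray(d, dtype=float))
        return np.clip((arc - rest) / rest, 0.0, None) * 100.0

    target_arc = rest * (1.0 + truth.rupture_strain_pct / 100.0)
    d_rupture = np.sqrt((target_arc / 2.0) ** 2 - (L0 / 2.0) ** 2)
    t_rupture = d_rupture / pull_speed_um_s
    total_s = t_rupture + post_rupture_s
    if total_s * force_rate_hz > 5e7:
        raise ValueError("rupture strain is never reached within a "
                         "practicable ramp; the requested pull speed and "
                         "rupture strain imply more than 5e7 force samples")

    video_t = np.arange(0.0, total_s, 1.0 / video_rate_fps)
    deflection = pull_speed_um_s * video_t
    force_t = np.arange(0.0, total_s, 1.0 / force_rate_hz)
    if force_t[-1] <= t_rupture:
        raise ValueError("rupture strain is never reached within the ramp; "
                         "extend the ramp or lower the rupture strain")

    d_f = pull_speed_um_s * force_t
    eps = strain_pct(d_f)
    sigma = np.asarray(truth.stress_at(eps), dtype=float)
    tension_un = sigma * truth.dry_area_um2          # MPa * um^2 = uN
    arm = np.hypot(L0 / 2.0, d_f)
    with np.errstate(invalid="ignore"):
        lateral = np.where(d_f > 0, 2.0 * tension_un * d_f / arm, 0.0)
    intact = (force_t <= t_rupture) & (d_f > slack)
    fibril_force = np.where(intact, lateral, 0.0)

    rng = np.random.default_rng(seed)
    friction = np.full(force_t.shape, friction_level_un)
    if friction_sd_un > 0:
        friction = friction + rng.normal(0.0, friction_sd_un,
                                         size=force_t.shape)
    force = friction + fibril_force

    rupture_frame = int(np.searchsorted(video_t, t_rupture, side="right") - 1)
    return PullExperiment(
        force_time_s=force_t, force_un=force,
        video_time_s=video_t, deflection_um=deflection,
        segment_length_um=L0, dry_area_um2=truth.dry_area_um2,
        rupture_frame_index=rupture_frame,
    )


def make_fluorescence_image(mask: np.ndarray, fibril_level: float = 500.0,
                            background_level: float = 100.0,
                            noise_sd: float = 10.0, seed: int = 0,
                            laser_power_mw: float = 12.0) -> FluorImage:
    """Two-channel fluorescence image from a fibril footprint mask.

    Fluorescence = background + (fibril - background) on the mask, plus
    Gaussian noise (clipped at zero counts); brightfield is a deterministic
    dark silhouette of the fibril.
    """
    if fibril_level < 0 or background_level < 0:
        raise ValueError("levels must be non-negative")
    m = np.asarray(mask, dtype=bool)
    fl = background_level + (fibril_level - background_level) * m.astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fl = fl + rng.normal(0.0, noise_sd, size=m.shape)
    fl = np.clip(fl, 0.0, None)
    brightfield = 1000.0 - 400.0 * m.astype(float)
    return FluorImage(brightfield=brightfield, fluorescence=fl,
                      laser_power_mw=laser_power_mw)


def rectangle_mask(shape: tuple[int, int], row0: int, row1: int,
                   col0: int, col1: int) -> np.ndarray:
    """Convenience footprint: a straight fibril band in a raster."""
    m = np.zeros(shape, dtype=bool)
    m[row0:row1, col0:col1] = True
    return m
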