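"""Bowstring tensile-test analysis: from raw traces to mechanical parameters.

A fibril segment of prepared length L0 is glued at both ends and pulled
laterally at its midpoint by an AFM tip at constant velocity.  The lateral
force on the tip is recorded at 500 Hz; the midpoint deflection d comes from
a 20 fps video of the test.  The two records are synchronized at the rupture
instant, which is sharp in both: the load falls precipitously within one
force sample, and the fibril is present in one video frame and absent in the
next.

Bowstring geometry (two straight arms of half-span L0/2 deflected by d):

    strain   eps = (2 sqrt((L0/2)^2 + d^2) - L0) / L0
    tension  T   = F * sqrt((L0/2)^2 + d^2) / (2 d)

with F the lateral force after subtraction of the constant frictional
background (tip on glass) measured from the post-rupture window.  Stress is
tension over the dried cross-sectional area (uN / um^2 = MPa).  Points
before full tension (bending-dominated regime) and after rupture are
discarded, leaving the curves with their characteristic gap between 0% and
typically ~5% strain.

Four parameters summarize each curve: rupture strain and stress (last point
before the drop), toughness (integral of stress over fractional strain from
0%, the missing low-strain portion linearly extrapolated), and the
high-strain elastic modulus (least-squares slope over the final 10% strain
before rupture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PullExperiment:
    """Paired force and video-deflection records of one bowstring test."""

    force_time_s: np.ndarray
    force_un: np.ndarray            # lateral force, uN
    video_time_s: np.ndarray
    deflection_um: np.ndarray       # midpoint deflection, um
    segment_length_um: float        # prepared segment length L0
    dry_area_um2: float             # dried cross-sectional area
    rupture_frame_index: int = -1   # last frame with the fibril present
    rupture_force_index: int = -1   # detected; last sample before the drop
    full_tension_index: int = -1    # optional manual override (force index)

    def __post_init__(self) -> None:
        for name in ("force_time_s", "force_un", "video_time_s",
                     "deflection_um"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.segment_length_um <= 0 or self.dry_area_um2 <= 0:
            raise ValueError("segment length and dry area must be positive")
        if np.any(np.diff(self.force_time_s) <= 0) or \
           np.any(np.diff(self.video_time_s) <= 0):
            raise ValueError("time axes must be strictly increasing")


@dataclass
class StressStrainCurve:
    """Ordered (strain %, stress MPa) pairs, post-rupture points removed."""

    strain_pct: np.ndarray
    stress_mpa: np.ndarray

    def __post_init__(self) -> None:
        self.strain_pct = np.asarray(self.strain_pct, dtype=float)
        self.stress_mpa = np.asarray(self.stress_mpa, dtype=float)
        if self.strain_pct.size != self.stress_mpa.size:
            raise ValueError("strain and stress lengths differ")
        if np.any(np.diff(self.strain_pct) <= 0):
            raise ValueError("strain must be strictly increasing")
        if not np.all(np.isfinite(self.stress_mpa)):
            raise ValueError("stresses must be finite")


@dataclass
class MechanicalSummary:
    """The four per-curve mechanical parameters plus the modulus fit error."""

    rupture_strain_pct: float
    rupture_stress_mpa: float
    toughness_mj_m3: float
    high_strain_modulus_mpa: float
    modulus_error_mpa: float = field(default=np.nan)


def detect_rupture(force_un: np.ndarray, threshold_sigma: float = 5.0,
                   post_window: int = 200) -> int:
    """Index of the last sample before the largest single-step load drop.

    The drop must exceed ``threshold_sigma`` times the standard deviation of
    the post-drop window (the frictional noise level); otherwise no rupture
    is declared.
    """
    f = np.asarray(force_un, dtype=float)
    if f.size < 3:
        raise ValueError("force trace too short")
    steps = np.diff(f)
    k = int(np.argmin(steps))
    drop = -steps[k]
    if drop <= 0:
        raise ValueError("no rupture detected: no falling step in the trace")
    post = f[k + 1:k + 1 + post_window]
    noise = float(post.std()) if post.size > 1 else 0.0
    if drop < threshold_sigma * noise:
        raise ValueError(
            f"no rupture detected: largest drop {drop:.3g} uN is below "
            f"{threshold_sigma} x post-drop noise {noise:.3g} uN")
    return k


def subtract_background(force_un: np.ndarray, rupture_index: int,
                        min_window: int = 10) -> np.ndarray:
    """Subtract the mean frictional force of the post-rupture window."""
    f = np.asarray(force_un, dtype=float)
    post = f[rupture_index + 1:]
    if post.size < min_window:
        raise ValueError(
            f"post-rupture window has {post.size} samples; "
            f"at least {min_window} required to estimate the background")
    return f - post.mean()


def smooth_adjacent(force_un: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered adjacent averaging; edge windows shrink symmetrically."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    f = np.asarray(force_un, dtype=float)
    n = f.size
    h = window // 2
    out = np.empty_like(f)
    csum = np.concatenate([[0.0], np.cumsum(f)])
    for i in range(n):
        hw = min(h, i, n - 1 - i)
        if hw == 0:
            out[i] = f[i]
        else:
            out[i] = (csum[i + hw + 1] - csum[i - hw]) / (2 * hw + 1)
    return out


def synchronize(force_time_s: np.ndarray, force_un: np.ndarray,
                video_time_s: np.ndarray, deflection_um: np.ndarray,
                rupture_force_index: int, rupture_frame_index: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Align the two records at the rupture instant.

    The video time axis is shifted so the last frame with the fibril present
    coincides with the last force sample before the drop; deflection is then
    linearly interpolated onto the force timestamps.  Force samples outside
    the video span are dropped.  Returns (time, deflection, force,
    rupture_index_in_aligned).
    """
    ft = np.asarray(force_time_s, dtype=float)
    f = np.asarray(force_un, dtype=float)
    vt = np.asarray(video_time_s, dtype=float)
    d = np.asarray(deflection_um, dtype=float)
    if not (0 <= rupture_force_index < ft.size):
        raise ValueError("rupture force index out of range")
    if not (0 <= rupture_frame_index < vt.size):
        raise ValueError("rupture frame index out of range")
    shift = ft[rupture_force_index] - vt[rupture_frame_index]
    vt = vt + shift
    keep = (ft >= vt[0]) & (ft <= vt[-1])
    if not keep.any() or not keep[rupture_force_index]:
        raise ValueError("rupture instant falls outside the record overlap")
    ti = ft[keep]
    di = np.interp(ti, vt, d)
    fi = f[keep]
    new_rupture = int(np.nonzero(keep)[0].searchsorted(rupture_force_index))
    return ti, di, fi, new_rupture


def bowstring_strain(deflection_um, length_um: float):
    """Strain (%) of the bowstring at midpoint deflection d."""
    d = np.asarray(deflection_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("deflection must be non-negative")
    if length_um <= 0:
        raise ValueError("segment length must be positive")
    arm = np.hypot(length_um / 2.0, d)
    out = (2.0 * arm - length_um) / length_um * 100.0
    return float(out) if np.isscalar(deflection_um) else out


def bowstring_tension(force_un, deflection_um, length_um: float):
    """Fibril tension (uN) from lateral force via the arm angle.

    Diverges as d -> 0; only evaluated past the full-tension onset.
    """
    d = np.asarray(deflection_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("deflection must be positive for tension conversion")
    arm = np.hypot(length_um / 2.0, d)
    out = np.asarray(force_un, dtype=float) * arm / (2.0 * d)
    return float(out) if np.isscalar(force_un) else out


def estimate_full_tension(deflection_um: np.ndarray, force_un: np.ndarray,
                          n_candidates: int = 200) -> int:
    """First sample at which the fibril is taut.

    The force-deflection record is fit with a two-segment piecewise-linear
    model; the breakpoint with minimal squared error estimates the slack
    deflection, and the onset is the first sample beyond it.  (In the
    original workflow this instant was identified from the video.)
    """
    d = np.asarray(deflection_um, dtype=float)
    f = np.asarray(force_un, dtype=float)
    n = d.size
    if n < 8:
        raise ValueError("record too short for piecewise fit")

    def seg_sse(x, y):
        if x.size < 2:
            return 0.0
        A = np.vstack([x, np.ones_like(x)]).T
        resid = np.linalg.lstsq(A, y, rcond=None)[1]
        return float(resid[0]) if resid.size else 0.0

    cands = np.unique(np.linspace(2, n - 3, min(n_candidates, n - 4)).astype(int))
    best_k, best_sse = cands[0], np.inf
    for k in cands:
        sse = seg_sse(d[:k], f[:k]) + seg_sse(d[k:], f[k:])
        if sse < best_sse:
            best_k, best_sse = k, sse
    return int(best_k)


def build_stress_strain(deflection_um: np.ndarray, force_un: np.ndarray,
                        full_tension_index: int, rupture_index: int,
                        length_um: float, dry_area_um2: float
                        ) -> StressStrainCurve:
    """Stress-strain curve from the aligned, background-free record.

    Keeps samples from full tension to rupture inclusive; stress is the
    bowstring tension over the dried cross-section (dry-area basis).
    """
    if dry_area_um2 <= 0:
        raise ValueError("dry area must be positive")
    if not 0 <= full_tension_index <= rupture_index:
        raise ValueError("full-tension onset must precede rupture")
    d = np.asarray(deflection_um, dtype=float)[full_tension_index:rupture_index + 1]
    f = np.asarray(force_un, dtype=float)[full_tension_index:rupture_index + 1]
    ok = d > 0
    d, f = d[ok], f[ok]
    if d.size == 0:
        raise ValueError("no samples retained between full tension and rupture")
    strain = bowstring_strain(d, length_um)
    stress = bowstring_tension(f, d, length_um) / dry_area_um2
    # video-interpolated deflection is monotone up to interpolation ties
    keep = np.concatenate([[True], np.diff(strain) > 0])
    return StressStrainCurve(strain_pct=strain[keep], stress_mpa=stress[keep])


def _lsq_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, slope standard error)."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate abscissa in line fit")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    if n > 2:
        resid = y - (slope * x + intercept)
        se = float(np.sqrt((resid ** 2).sum() / (n - 2) / sxx))
    else:
        se = 0.0
    return slope, intercept, se


def summarize(curve: StressStrainCurve, modulus_window_pct: float = 10.0,
              extrapolation_window_pct: float = 2.0) -> MechanicalSummary:
    """The four mechanical parameters of one stress-strain curve.

    Rupture strain/stress are the last curve point.  Toughness integrates
    stress over fractional strain (MPa = MJ/m^3) by the trapezoid rule, plus
    the area of a linear extrapolation from the first retained point down to
    0% strain (slope fit over the first 2% strain of data; if the
    extrapolated stress crosses zero the area is clamped at the crossing).
    The high-strain modulus is the least-squares slope over the last 10%
    strain before rupture, with its standard error.
    """
    eps = curve.strain_pct / 100.0
    sig = curve.stress_mpa
    if eps.size < 2:
        raise ValueError("curve too short to summarize")
    rupture_strain = float(curve.strain_pct[-1])
    rupture_stress = float(sig[-1])

    # toughness: trapezoid over the retained curve
    tough = float(np.trapezoid(sig, eps))
    # plus the linearly extrapolated low-strain area
    win = eps <= eps[0] + extrapolation_window_pct / 100.0
    if win.sum() < 2:
        win[:2] = True
    m, _, _ = _lsq_line(eps[win], sig[win])
    sig0 = sig[0] - m * eps[0]
    if sig0 >= 0:
        tough += 0.5 * (sig0 + sig[0]) * eps[0]
    else:
        eps_zero = eps[0] - sig[0] / m
        tough += 0.5 * sig[0] * (eps[0] - eps_zero)

    # high-strain modulus over the last `modulus_window_pct` strain
    lo = rupture_strain - modulus_window_pct
    sel = curve.strain_pct >= lo
    if sel.sum() < 2:
        raise ValueError("fewer than 2 points in the high-strain window")
    if curve.strain_pct[sel][0] > curve.strain_pct[0] and \
            rupture_strain - curve.strain_pct[0] < modulus_window_pct:
        warnings.warn("curve spans less than the modulus window; "
                      "fit truncated to available range")
    slope, _, se = _lsq_line(eps[sel], sig[sel])

    return MechanicalSummary(
        rupture_strain_pct=rupture_strain,
        rupture_stress_mpa=rupture_stress,
        toughness_mj_m3=tough,
        high_strain_modulus_mpa=float(slope),
        modulus_error_mpa=float(se),
    )


def bending_force_estimate(e_bend_gpa: float, radius_nm: float,
                           length_um: float, deflection_um: float,
                           boundary: str = "clamped") -> float:
    """Upper-bound bending force (nN) of a centrally loaded fibril beam.

    Clamped-clamped (ends glued): F = 192 E I d / L^3; simply supported:
    F = 48 E I d / L^3; with the area moment I = pi r^4 / 4.
    """
    if e_bend_gpa <= 0 or radius_nm <= 0 or length_um <= 0:
        raise ValueError("modulus, radius and length must be positive")
    if deflection_um < 0:
        raise ValueError("deflection must be non-negative")
    coeff = {"clamped": 192.0, "simply_supported": 48.0}.get(boundary)
    if coeff is None:
        raise ValueError(f"unknown boundary condition: {boundary!r}")
    e = e_bend_gpa * 1e9
    r = radius_nm * 1e-9
    length = length_um * 1e-6
    d = deflection_um * 1e-6
    inertia = np.pi * r**4 / 4.0
    return coeff * e * inertia * d / length**3 * 1e9


def hydrated_stress_rescale(dry_stress_mpa, radius_swell_factor: float = 2.0):
    """Rescale dry-area stress to a hydrated-area basis.

    Fibril radius roughly doubles on rehydration, so the cross-sectional
    area grows ~4-fold and hydrated-basis stress is dry stress / factor^2.
    """
    if radius_swell_factor <= 0:
        raise ValueError("swell factor must be positive")
    return dry_stress_mpa / radius_swell_factor**2


def analyze_pull(exp: PullExperiment, smoothing_window: int = 5,
                 threshold_sigma: float = 5.0
                 ) -> tuple[StressStrainCurve, MechanicalSummary]:
    """Full pipeline: raw pull experiment to curve and summary.

    Detect rupture in the force trace, subtract the post-rupture frictional
    background, smooth the pre-rupture segment by adjacent averaging,
    synchronize with the video deflection at the rupture instant, convert to
    stress-strain past the full-tension onset, and summarize.
    """
    k = detect_rupture(exp.force_un, threshold_sigma=threshold_sigma)
    exp.rupture_force_index = k
    f = subtract_background(exp.force_un, k)
    f[:k + 1] = smooth_adjacent(f[:k + 1], smoothing_window)
    if exp.rupture_frame_index < 0:
        raise ValueError("rupture frame index (from the video) is required")
    t, d, fa, ka = synchronize(exp.force_time_s, f, exp.video_time_s,
                               exp.deflection_um, k, exp.rupture_frame_index)
    if exp.full_tension_index >= 0:
        ft_idx = exp.full_tension_index
    else:
        ft_idx = estimate_full_tension(d[:ka + 1], fa[:ka + 1])
    curve = build_stress_strain(d, fa, ft_idx, ka, exp.segment_length_um,
                                exp.dry_area_um2)
    return curve, summarize(curve)
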