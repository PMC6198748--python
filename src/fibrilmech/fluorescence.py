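"""Denatured-collagen positivity calls from CHP fluorescence images.

Collagen hybridizing peptide (CHP) binds unfolded collagen chains; a
ruptured fibril that is fluorescent above the background level indicates
molecular-level denaturation.  The call is qualitative: the fibril is
positive when its mean fluorescence exceeds the background mean by more than
``k_sigma`` background standard deviations.  Laser power is carried as
metadata only; images are analyzed raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FluorImage:
    """Two-channel confocal image: brightfield plus fluorescence."""

    brightfield: np.ndarray
    fluorescence: np.ndarray
    laser_power_mw: float = np.nan

    def __post_init__(self) -> None:
        self.brightfield = np.asarray(self.brightfield, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.brightfield.shape != self.fluorescence.shape:
            raise ValueError("channels must have the same shape")
        if np.any(self.fluorescence < 0):
            raise ValueError("fluorescence counts must be non-negative")


def mask_from_brightfield(brightfield: np.ndarray, pad_px: int = 2
                          ) -> tuple[np.ndarray, np.ndarray]:
    """(fibril_mask, background_mask) from the brightfield silhouette.

    The fibril appears dark against the substrate; pixels below the midpoint
    of the channel's range form the fibril mask, dilated by ``pad_px`` to
    build a guard band excluded from the background mask.
    """
    bf = np.asarray(brightfield, dtype=float)
    thr = 0.5 * (bf.min() + bf.max())
    fibril = bf < thr
    guard = fibril.copy()
    for _ in range(pad_px):
        g = guard.copy()
        g[1:] |= guard[:-1]
        g[:-1] |= guard[1:]
        g[:, 1:] |= guard[:, :-1]
        g[:, :-1] |= guard[:, 1:]
        guard = g
    return fibril, ~guard


def classify_fibril(image: FluorImage, fibril_mask: np.ndarray,
                    background_mask: np.ndarray, k_sigma: float = 3.0
                    ) -> tuple[bool, float]:
    """Is the fibril fluorescent above background?  Returns (call, margin).

    Positive iff mean fluorescence over the fibril exceeds the background
    mean + k_sigma * background sd; the margin is the exceedance in units of
    the background sd.
    """
    fm = np.asarray(fibril_mask, dtype=bool)
    bm = np.asarray(background_mask, dtype=bool)
    if not fm.any() or not bm.any():
        raise ValueError("both masks must be non-empty")
    if (fm & bm).any():
        raise ValueError("fibril and background masks must be disjoint")
    fl = image.fluorescence
    bg_mean = float(fl[bm].mean())
    bg_sd = float(fl[bm].std())
    fib_mean = float(fl[fm].mean())
    if bg_sd == 0:
        if fib_mean > bg_mean:
            return True, np.inf
        return False, 0.0
    threshold = bg_mean + k_sigma * bg_sd
    margin = (fib_mean - threshold) / bg_sd
    return fib_mean > threshold, margin
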