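"""Cantilever lateral-force calibration.

Board-shaped AFM cantilevers used for lateral (bowstring) pulling are
calibrated vertically on-instrument: the vertical spring constant K_z (N/m)
from a thermal-noise fit and the vertical deflection sensitivity S_z (nm/V)
on a hard substrate.  The lateral quantities follow from beam mechanics:

    K_L = 2 L^2 K_z / (3 (1 + nu) H^2)        [N/m]
    S_L = 3 H S_z / (2 L)                      [nm/V]

where L is the cantilever length, H the tip height (including half the board
thickness) and nu the Poisson ratio of the cantilever material (0.27 for
silicon <111>).  Lateral force in newtons is then K_L * S_L * signal with
S_L converted to m/V.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Poisson ratio of silicon <111>, the cantilever material.
SILICON_111_POISSON = 0.27


def lateral_spring_constant(length_um: float, tip_height_um: float,
                            kz_n_per_m: float,
                            nu: float = SILICON_111_POISSON) -> float:
    """Lateral spring constant K_L = 2 L^2 K_z / (3 (1+nu) H^2) in N/m.

    ``length_um`` and ``tip_height_um`` only enter as a ratio, so any
    consistent length unit gives the same result.
    """
    if length_um <= 0 or tip_height_um <= 0 or kz_n_per_m <= 0:
        raise ValueError("cantilever geometry and K_z must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    return 2.0 * length_um**2 * kz_n_per_m / (3.0 * (1.0 + nu) * tip_height_um**2)


def lateral_sensitivity(tip_height_um: float, sz_nm_per_v: float,
                        length_um: float) -> float:
    """Lateral deflection sensitivity S_L = 3 H S_z / (2 L) in nm/V."""
    if tip_height_um <= 0 or length_um <= 0 or sz_nm_per_v <= 0:
        raise ValueError("H, L and S_z must be positive")
    return 3.0 * tip_height_um * sz_nm_per_v / (2.0 * length_um)


@dataclass
class CantileverSpec:
    """Geometry, vertical calibration and derived lateral calibration.

    Lengths in micrometers, spring constants in N/m, sensitivities in nm/V.
    The derived fields ``lateral_spring_kl`` and ``lateral_sensitivity_sl``
    are filled in from the calibration formulas at construction.
    """

    number: int = 1
    manufacturer: str = ""
    model: str = ""
    type: str = ""
    material: str = "Si"
    length_um: float = 225.0
    tip_height_um: float = 17.5
    vertical_spring_kz: float = 40.0
    vertical_sensitivity_sz: float = 100.0
    poisson_nu: float = SILICON_111_POISSON
    lateral_spring_kl: float = field(default=0.0)
    lateral_sensitivity_sl: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.lateral_spring_kl = lateral_spring_constant(
            self.length_um, self.tip_height_um, self.vertical_spring_kz,
            self.poisson_nu)
        self.lateral_sensitivity_sl = lateral_sensitivity(
            self.tip_height_um, self.vertical_sensitivity_sz, self.length_um)


def lateral_force(signal_v, spec: CantileverSpec):
    """Convert a photodiode lateral signal (V) to force in micronewtons.

    force[N] = K_L [N/m] * S_L [m/V] * signal [V]; reported in uN.
    Accepts scalars or arrays; linear in the signal.
    """
    if spec.lateral_spring_kl <= 0 or spec.lateral_sensitivity_sl <= 0:
        raise ValueError("cantilever spec is missing derived lateral calibration")
    sl_m_per_v = spec.lateral_sensitivity_sl * 1e-9
    force_n = spec.lateral_spring_kl * sl_m_per_v * np.asarray(signal_v, dtype=float)
    out = force_n * 1e6
    return float(out) if np.isscalar(signal_v) else out


def signal_from_force(force_un, spec: CantileverSpec):
    """Inverse of :func:`lateral_force`: micronewtons back to volts."""
    sl_m_per_v = spec.lateral_sensitivity_sl * 1e-9
    sig = np.asarray(force_un, dtype=float) * 1e-6 / (spec.lateral_spring_kl * sl_m_per_v)
    return float(sig) if np.isscalar(force_un) else sig


# Cantilever sheet: columns A-I of the deposition worksheet, mirrored as CSV.
SHEET_COLUMNS = [
    "cantilever_number", "manufacturer", "model", "type", "material",
    "length_um", "tip_height_um", "vertical_spring_n_per_m",
    "lateral_spring_n_per_m",
]


def write_cantilever_sheet(specs: list[CantileverSpec], path: str | Path) -> None:
    rows = [
        {
            "cantilever_number": s.number,
            "manufacturer": s.manufacturer,
            "model": s.model,
            "type": s.type,
            "material": s.material,
            "length_um": s.length_um,
            "tip_height_um": s.tip_height_um,
            "vertical_spring_n_per_m": s.vertical_spring_kz,
            "lateral_spring_n_per_m": s.lateral_spring_kl,
        }
        for s in specs
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, index=False)


def read_cantilever_sheet(path: str | Path) -> list[CantileverSpec]:
    df = pd.read_csv(path)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cantilever sheet missing columns: {missing}")
    specs = []
    for _, row in df.iterrows():
        specs.append(CantileverSpec(
            number=int(row["cantilever_number"]),
            manufacturer=str(row["manufacturer"]),
            model=str(row["model"]),
            type=str(row["type"]),
            material=str(row["material"]),
            length_um=float(row["length_um"]),
            tip_height_um=float(row["tip_height_um"]),
            vertical_spring_kz=float(row["vertical_spring_n_per_m"]),
        ))
    return specs
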