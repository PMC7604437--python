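"""Stereological conversion of areal (2D) to volumetric (3D) cell density.

Cell densities read off a stained section of thickness t count cell
*profiles* per area; a spherical cell of diameter D is visible whenever its
cap within the section exceeds the segmentation's minimum detectable
profile area A_crit.  The classical correction is

    N_V = N_A / (t + D − 2h),   h = D/2 − √((D/2)² − A_crit/π),

where h is the minimum detectable spherical-cap height; 2h accounts for the
undetected sliver at each face.  Default presets: section thickness
t = 4.75 μm, T-cell diameter 6.05 μm, B-cell diameter 7.25 μm (midpoints of
the reported ranges), A_crit = 10 μm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StereologyParams", "cap_height", "areal_to_volume_density", "T_CELL_PRESET", "B_CELL_PRESET"]

UM_PER_MM = 1000.0


def cap_height(diameter_um: float, a_crit_um2: float) -> float:
    """Minimum detectable spherical-cap height h (μm)."""
    r = diameter_um / 2.0
    max_area = np.pi * r**2
    if a_crit_um2 < 0 or a_crit_um2 > max_area + 1e-12:
        raise ValueError(
            f"A_crit must lie in [0, pi*(D/2)^2] = [0, {max_area:.4g}] um^2"
        )
    return float(r - np.sqrt(max(r**2 - a_crit_um2 / np.pi, 0.0)))


@dataclass
class StereologyParams:
    """Section thickness t, cell diameter D and detection limit A_crit (μm)."""

    t_um: float = 4.75
    d_um: float = 6.05
    a_crit_um2: float = 10.0

    def __post_init__(self) -> None:
        if self.t_um <= 0 or self.d_um <= 0:
            raise ValueError("t and D must be positive")
        self.h_um = cap_height(self.d_um, self.a_crit_um2)

    @property
    def denominator_um(self) -> float:
        return self.t_um + self.d_um - 2.0 * self.h_um


T_CELL_PRESET = StereologyParams(t_um=4.75, d_um=6.05, a_crit_um2=10.0)
B_CELL_PRESET = StereologyParams(t_um=4.75, d_um=7.25, a_crit_um2=10.0)


def areal_to_volume_density(n_a_mm2, params: StereologyParams) -> np.ndarray | float:
    """Convert an areal density N_A (mm⁻²) to volumetric N_V (mm⁻³)."""
    denom_mm = params.denominator_um / UM_PER_MM
    if denom_mm <= 0:
        raise ValueError("non-positive conversion denominator t + D - 2h")
    out = np.asarray(n_a_mm2, float) / denom_mm
    return float(out) if np.isscalar(n_a_mm2) else out
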