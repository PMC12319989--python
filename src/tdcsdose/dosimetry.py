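"""Scalp-level dose arithmetic for the HD montage.

Four electrode pairs share the total current (1.0 mA per pair for the 4 mA
arm, 1.5 mA for 6 mA, 0.25 mA for the 1 mA sham ramp); each gel contact has
about 4.5 cm² of area, and skin current density is compared against the
0.5 mA/cm² tolerability bound from the iontophoresis literature.  Brain
field estimates require FEM modeling and are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

TOLERABILITY_LIMIT_MA_PER_CM2 = 0.5


class DoseError(ValueError):
    pass


@dataclass
class MontageSpec:
    n_electrode_pairs: int = 4
    current_per_pair_ma: float = 1.0
    gel_contact_area_cm2: float = 4.5
    ramp_s: float = 30.0
    duration_min: float = 12.0

    def __post_init__(self):
        if self.current_per_pair_ma < 0:
            raise DoseError("currents must be >= 0")
        if self.gel_contact_area_cm2 <= 0:
            raise DoseError("contact area must be > 0")


@dataclass
class DensityResult:
    density_ma_per_cm2: float
    limit_ma_per_cm2: float
    flag: str  # below-limit | at-limit | above-limit


def skin_current_density(current_ma: float, area_cm2: float,
                         limit: float = TOLERABILITY_LIMIT_MA_PER_CM2,
                         rel_tol: float = 1e-9) -> DensityResult:
    """Per-electrode skin current density (mA/cm²) with a tolerability flag."""
    if area_cm2 <= 0:
        raise DoseError("contact area must be > 0")
    if current_ma < 0:
        raise DoseError("current must be >= 0")
    density = current_ma / area_cm2
    if abs(density - limit) <= rel_tol * limit:
        flag = "at-limit"
    elif density < limit:
        flag = "below-limit"
    else:
        flag = "above-limit"
    return DensityResult(density, limit, flag)


def total_current(montage: MontageSpec) -> float:
    """Total injected current in mA across all electrode pairs."""
    return montage.n_electrode_pairs * montage.current_per_pair_ma
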