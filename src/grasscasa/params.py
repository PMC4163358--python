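"""Model parameters for the CASA light-use-efficiency chain.

Every numeric constant of the NPP equation chain lives here so that a run
is fully described by one :class:`ModelParams` value: the PAR fraction of
total solar radiation, the grass maximum light-use efficiency, the two
temperature-stress scalars, the vapor-pressure-deficit moisture stress,
the precipitable-water/dew-point regression, and the biomass-to-carbon
conversion used in validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

#: Default root:shoot (belowground/aboveground biomass) ratios per grassland type.
DEFAULT_ROOT_SHOOT: dict[str, float] = {
    "mountain meadow": 6.23,
    "alpine meadow": 7.92,
    "alpine shrub meadow": 7.92,
}

#: Default elevation band breaks (m) for zonal summaries.
DEFAULT_ELEVATION_BREAKS: tuple[float, ...] = (1000.0, 2000.0, 3000.0, 4000.0, 5000.0)


@dataclass(frozen=True)
class ModelParams:
    """Constants of the NPP model and validation conversion.

    Attributes
    ----------
    par_fraction : float
        Fraction of total solar radiation in the photosynthetically active
        band (0.4-0.7 um) usable by vegetation; dimensionless.
    eps_max : float
        Maximum light-use efficiency for grass, g MJ^-1.
    te2_scale, te2_k_warm, te2_k_cold, te2_offset : float
        Constants of the second temperature stress scalar: a double-logistic
        in (Topt - T) with scale 1.1814, warm-side rate 0.2 degC^-1,
        cold-side rate 0.3 degC^-1 and offset 10 degC.
    we_a, we_b, we_c : float
        Moisture stress We = we_a * exp(-we_b * D) - we_c with D the vapor
        pressure deficit in kPa.
    we_floor : float
        Lower clamp for We; the bare expression goes negative for
        D > ~5.1 kPa, which would make productivity negative.
    svp_coeff, svp_a, svp_t0, svp_b : float
        Saturation-vapor-pressure form 0.611 * exp(17.27 (T - 273)/(T - 36))
        with T in Kelvin; svp_t0 doubles as the Celsius->Kelvin offset used
        throughout (printed as 273, not 273.15).
    dew_intercept, dew_slope : float
        Regression ln(U) = 1.8084 + 0.0735 * Td linking total precipitable
        water U (mm) to dew point Td (degC).
    carbon_fraction : float
        Grams of carbon per gram of dry biomass.
    root_shoot : mapping
        Grassland type -> belowground/aboveground biomass ratio.
    """

    par_fraction: float = 0.5
    eps_max: float = 0.604

    te2_scale: float = 1.1814
    te2_k_warm: float = 0.2
    te2_k_cold: float = 0.3
    te2_offset: float = 10.0

    we_a: float = 1.2
    we_b: float = 0.35
    we_c: float = 0.2
    we_floor: float = 0.0

    svp_coeff: float = 0.611
    svp_a: float = 17.27
    svp_t0: float = 273.0
    svp_b: float = 36.0

    dew_intercept: float = 1.8084
    dew_slope: float = 0.0735

    carbon_fraction: float = 0.45
    root_shoot: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROOT_SHOOT)
    )

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name not in ("root_shoot", "we_floor")
        }
        for name, value in numeric.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0 < self.par_fraction <= 1:
            raise ValueError("par_fraction must lie in (0, 1]")
        if self.we_floor < 0:
            raise ValueError("we_floor must be >= 0")
        for gtype, ratio in self.root_shoot.items():
            if ratio < 0:
                raise ValueError(f"root:shoot ratio for {gtype!r} must be >= 0")

    def with_overrides(self, overrides: Mapping[str, object]) -> "ModelParams":
        """Return a copy with ``overrides`` applied; unknown keys rejected."""
        known = {f.name for f in fields(self)}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise KeyError(
                f"unknown model parameter(s) {unknown}; valid keys: {sorted(known)}"
            )
        return replace(self, **dict(overrides))
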