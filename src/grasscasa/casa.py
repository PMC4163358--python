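"""CASA light-use-efficiency NPP model on monthly raster stacks.

The production-efficiency chain is

    NPP(x, t) = APAR(x, t) * LUE(x, t)
    APAR      = SOL * FPAR * 0.5
    LUE       = Te1(Topt) * Te2(Topt, T) * We(D) * eps_max

with Topt the mean air temperature in each cell's greenest month, Te1/Te2
temperature stress scalars, and We a moisture stress scalar driven by the
vapor pressure deficit D computed from land-surface temperature and a dew
point regressed from total precipitable water.

All operations propagate nodata: a cell masked in any input is masked in
the output, and masks are unioned along the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import Grid, GridStack, ensure_aligned
from .params import ModelParams

logger = logging.getLogger(__name__)

# exp() saturates rather than overflows beyond this argument
_EXP_CAP = 700.0


def _exp(arg: np.ndarray) -> np.ndarray:
    """exp with the argument clipped so large exponents saturate, never fault."""
    return np.exp(np.clip(arg, -_EXP_CAP, _EXP_CAP))


def compute_apar(sol: GridStack, fpar: GridStack, params: ModelParams) -> GridStack:
    """Absorbed photosynthetically active radiation, MJ m^-2 per month.

    APAR = SOL * FPAR * par_fraction, where par_fraction (default 0.5) is
    the photosynthetically usable share of total solar surface radiation.
    """
    ensure_aligned(sol, fpar, names=["sol", "fpar"])
    mask = sol.mask | fpar.mask
    values = sol.values * fpar.values * params.par_fraction
    return GridStack(values, sol.georef, mask, units="MJ m-2")


def compute_topt(temperature: GridStack, fpar: GridStack) -> Grid:
    """Optimal temperature: monthly mean air temperature of the greenest month.

    Greenness is proxied by FPAR; per cell the month of maximal FPAR is
    found (earliest month wins ties) and that month's air temperature is
    returned.  Cells with FPAR masked in all 12 months are masked.
    """
    ensure_aligned(temperature, fpar, names=["temperature", "fpar"])
    fv = fpar.values.copy()
    fv[fpar.mask] = -np.inf
    all_masked = fpar.mask.all(axis=0)
    # argmax returns the first maximal month, which is the tie rule
    best = np.argmax(fv, axis=0)
    rows, cols = np.indices(best.shape)
    topt = temperature.values[best, rows, cols]
    mask = all_masked | temperature.mask[best, rows, cols]
    return Grid(topt, temperature.georef, mask, units="degC")


def temperature_stress_1(topt: Grid) -> Grid:
    """First temperature stress scalar, a quadratic in Topt.

    Te1 = 0.8 + 0.02*Topt - 0.0005*Topt^2: 1.0 at the 20 degC optimum,
    0.8 at 0 and 40 degC.  No clamp is applied; extreme Topt driving Te1
    negative is logged as a warning instead.
    """
    t = topt.values
    te1 = 0.8 + 0.02 * t - 0.0005 * t * t
    n_neg = int(np.count_nonzero((te1 < 0) & ~topt.mask))
    if n_neg:
        logger.warning("temperature_stress_1: %d cells with Te1 < 0 (extreme Topt)", n_neg)
    return Grid(te1, topt.georef, topt.mask.copy(), units="")


def temperature_stress_2(
    topt: Grid, temperature: GridStack, params: ModelParams
) -> GridStack:
    """Second temperature stress scalar, a double logistic around Topt.

    Te2 = 1.1814 / (1 + exp(0.2*(Topt - 10 - T))) / (1 + exp(0.3*(-Topt - 10 + T)))

    penalising months much colder (warm-side factor) or much hotter
    (cold-side factor) than each cell's optimum.  Exponentials saturate for
    extreme arguments instead of overflowing.
    """
    ensure_aligned(topt, temperature, names=["topt", "temperature"])
    to = topt.values[None, :, :]
    t = temperature.values
    p = params
    warm = 1.0 + _exp(p.te2_k_warm * (to - p.te2_offset - t))
    cold = 1.0 + _exp(p.te2_k_cold * (-to - p.te2_offset + t))
    te2 = p.te2_scale / (warm * cold)
    mask = temperature.mask | topt.mask[None, :, :]
    return GridStack(te2, temperature.georef, mask, units="")


def dew_point_from_precipitable_water(u: GridStack, params: ModelParams) -> GridStack:
    """Dew point (degC) from total precipitable water U (mm).

    Inverts the regression ln(U) = 1.8084 + 0.0735 * Td.  Non-positive U
    cannot be log-transformed; such cells are masked with a warning.
    """
    bad = (u.values <= 0) & ~u.mask
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        logger.warning(
            "dew_point_from_precipitable_water: %d cells with U <= 0 masked", n_bad
        )
    mask = u.mask | bad
    with np.errstate(divide="ignore", invalid="ignore"):
        td = (np.log(np.where(u.values > 0, u.values, 1.0)) - params.dew_intercept) / params.dew_slope
    return GridStack(td, u.georef, mask, units="degC")


def vapor_pressure_deficit(ts: GridStack, td: GridStack, params: ModelParams) -> GridStack:
    """Vapor pressure deficit D (kPa) from surface and dew-point temperature (K).

    D = 0.611 * [exp(17.27 (Ts-273)/(Ts-36)) - exp(17.27 (Td-273)/(Td-36))],
    set to 0 wherever Ts < Td.  Temperatures at or below the 36 K
    singularity of the saturation formula are masked with a warning.
    """
    ensure_aligned(ts, td, names=["ts", "td"])
    p = params
    degenerate = ((ts.values <= p.svp_b) & ~ts.mask) | ((td.values <= p.svp_b) & ~td.mask)
    n_deg = int(np.count_nonzero(degenerate))
    if n_deg:
        logger.warning(
            "vapor_pressure_deficit: %d cells with temperature <= %g K masked",
            n_deg,
            p.svp_b,
        )
    mask = ts.mask | td.mask | degenerate

    def svp(t: np.ndarray) -> np.ndarray:
        denom = np.where(t > p.svp_b, t - p.svp_b, 1.0)
        return p.svp_coeff * _exp(p.svp_a * (t - p.svp_t0) / denom)

    d = svp(ts.values) - svp(td.values)
    d = np.where(ts.values - td.values < 0, 0.0, d)
    return GridStack(d, ts.georef, mask, units="kPa")


def water_stress(d: GridStack, params: ModelParams) -> GridStack:
    """Moisture stress scalar We from vapor pressure deficit D (kPa).

    We = 1.2*exp(-0.35*D) - 0.2, clamped below at ``we_floor`` (default 0)
    so productivity stays non-negative at extreme D.  Monotone
    non-increasing in D; We(0) = 1 exactly.
    """
    if np.any((d.values < 0) & ~d.mask):
        raise ValueError("vapor pressure deficit must be non-negative")
    p = params
    raw = p.we_a * _exp(-p.we_b * d.values) - p.we_c
    n_clamped = int(np.count_nonzero((raw < p.we_floor) & ~d.mask))
    if n_clamped:
        logger.warning("water_stress: clamped %d cells at We = %g", n_clamped, p.we_floor)
    we = np.maximum(raw, p.we_floor)
    return GridStack(we, d.georef, d.mask.copy(), units="")


def compute_lue(
    te1: Grid, te2: GridStack, we: GridStack, params: ModelParams
) -> GridStack:
    """Light use efficiency: LUE = Te1 * Te2 * We * eps_max, g MJ^-1."""
    ensure_aligned(te1, te2, we, names=["te1", "te2", "we"])
    values = te1.values[None, :, :] * te2.values * we.values * params.eps_max
    mask = te1.mask[None, :, :] | te2.mask | we.mask
    return GridStack(values, te2.georef, mask, units="g MJ-1")


def compute_npp(apar: GridStack, lue: GridStack) -> GridStack:
    """Monthly NPP = APAR * LUE, gC m^-2 per month."""
    ensure_aligned(apar, lue, names=["apar", "lue"])
    values = apar.values * lue.values
    mask = apar.mask | lue.mask
    return GridStack(values, apar.georef, mask, units="gC m-2")


def annual_sum(stack: GridStack) -> Grid:
    """Annual layer: per-cell sum of the 12 monthly layers over unmasked months.

    A cell is masked only if it is masked in all 12 months.
    """
    vals = np.where(stack.mask, 0.0, stack.values).sum(axis=0)
    mask = stack.mask.all(axis=0)
    return Grid(vals, stack.georef, mask, units=stack.units)


@dataclass
class CasaInputs:
    """Aligned monthly input bundle for one model year.

    sol : total solar surface radiation, MJ m-2 per month
    fpar : fraction of absorbed PAR, [0, 1]
    temperature : monthly mean air temperature, degC
    lst : land surface temperature, K
    precipitable_water : total precipitable water, mm
    """

    sol: GridStack
    fpar: GridStack
    temperature: GridStack
    lst: GridStack
    precipitable_water: GridStack

    def validate(self) -> None:
        layers = {
            "sol": self.sol,
            "fpar": self.fpar,
            "temperature": self.temperature,
            "lst": self.lst,
            "precipitable_water": self.precipitable_water,
        }
        for name, layer in layers.items():
            if layer is None:
                raise ValueError(f"missing input layer: {name}")
        ensure_aligned(*layers.values(), names=list(layers))
        f = self.fpar
        valid = ~f.mask
        if np.any((f.values[valid] < 0) | (f.values[valid] > 1)):
            raise ValueError("fpar values must lie in [0, 1]")


@dataclass
class CasaOutputs:
    """All intermediates and results of one model run, for inspection."""

    apar: GridStack
    topt: Grid
    te1: Grid
    te2: GridStack
    d_vpd: GridStack
    we: GridStack
    lue: GridStack
    npp: GridStack
    npp_annual: Grid


def run_casa(inputs: CasaInputs, params: ModelParams | None = None) -> CasaOutputs:
    """Run the full equation chain on an aligned monthly input bundle.

    Chains Topt -> Te1/Te2 -> dew point -> VPD -> We -> LUE, computes APAR,
    multiplies into monthly NPP and accumulates the annual layer.  The dew
    point from the precipitable-water regression is in degC and is shifted
    by +273 K before entering the saturation-vapor-pressure formula.
    """
    params = params or ModelParams()
    inputs.validate()

    topt = compute_topt(inputs.temperature, inputs.fpar)
    te1 = temperature_stress_1(topt)
    te2 = temperature_stress_2(topt, inputs.temperature, params)

    td_c = dew_point_from_precipitable_water(inputs.precipitable_water, params)
    td_k = GridStack(td_c.values + params.svp_t0, td_c.georef, td_c.mask, units="K")
    d = vapor_pressure_deficit(inputs.lst, td_k, params)
    we = water_stress(d, params)

    lue = compute_lue(te1, te2, we, params)
    apar = compute_apar(inputs.sol, inputs.fpar, params)
    npp = compute_npp(apar, lue)

    return CasaOutputs(
        apar=apar,
        topt=topt,
        te1=te1,
        te2=te2,
        d_vpd=d,
        we=we,
        lue=lue,
        npp=npp,
        npp_annual=annual_sum(npp),
    )
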