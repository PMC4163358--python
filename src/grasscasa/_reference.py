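"""Deliberately naive scalar-loop reference implementation of the NPP chain.

Used by the synthetic-scene generator to compute ground truth, and by the
test suite as an independent oracle for the vectorised model.  Everything
here works on plain nested Python loops over ``math`` scalars and must stay
independent of :mod:`grasscasa.casa`.

``None`` plays the role of a masked cell.
"""

from __future__ import annotations

import math

from .params import ModelParams


def te1_scalar(topt: float) -> float:
    return 0.8 + 0.02 * topt - 0.0005 * topt * topt


def te2_scalar(topt: float, t: float, p: ModelParams) -> float:
    warm = 1.0 + math.exp(min(p.te2_k_warm * (topt - p.te2_offset - t), 700.0))
    cold = 1.0 + math.exp(min(p.te2_k_cold * (-topt - p.te2_offset + t), 700.0))
    return p.te2_scale / (warm * cold)


def dew_point_scalar(u: float, p: ModelParams) -> float | None:
    if u <= 0:
        return None
    return (math.log(u) - p.dew_intercept) / p.dew_slope


def precipitable_water_scalar(td_c: float, p: ModelParams) -> float:
    """Forward regression: U (mm) from dew point (degC)."""
    return math.exp(p.dew_intercept + p.dew_slope * td_c)


def svp_scalar(t_k: float, p: ModelParams) -> float:
    return p.svp_coeff * math.exp(min(p.svp_a * (t_k - p.svp_t0) / (t_k - p.svp_b), 700.0))


def vpd_scalar(ts_k: float, td_k: float, p: ModelParams) -> float | None:
    if ts_k <= p.svp_b or td_k <= p.svp_b:
        return None
    if ts_k - td_k < 0:
        return 0.0
    return svp_scalar(ts_k, p) - svp_scalar(td_k, p)


def we_scalar(d: float, p: ModelParams) -> float:
    return max(p.we_a * math.exp(-p.we_b * d) - p.we_c, p.we_floor)


def topt_scalar(fpar_series: list, temp_series: list) -> float | None:
    """Air temperature in the month of maximum FPAR; earliest month on ties."""
    best_m, best_f = None, None
    for m, f in enumerate(fpar_series):
        if f is None:
            continue
        if best_f is None or f > best_f:
            best_m, best_f = m, f
    if best_m is None:
        return None
    return temp_series[best_m]


def npp_chain_scalar(
    sol, fpar, temp, lst_k, pw, p: ModelParams
) -> dict:
    """Evaluate the whole chain for one cell.

    ``sol``, ``fpar``, ``temp``, ``lst_k``, ``pw`` are 12-element lists
    (``None`` = masked).  Returns per-cell dict of 12-element lists for
    apar, te2, d, we, lue, npp plus scalars topt, te1 and npp_annual.
    """
    topt = topt_scalar(fpar, temp)
    te1 = None if topt is None else te1_scalar(topt)
    out = {
        "topt": topt,
        "te1": te1,
        "apar": [],
        "te2": [],
        "d": [],
        "we": [],
        "lue": [],
        "npp": [],
    }
    annual = None
    for m in range(12):
        if sol[m] is None or fpar[m] is None:
            apar = None
        else:
            apar = sol[m] * fpar[m] * p.par_fraction
        te2 = None if (topt is None or temp[m] is None) else te2_scalar(topt, temp[m], p)
        td_c = None if pw[m] is None else dew_point_scalar(pw[m], p)
        if td_c is None or lst_k[m] is None:
            d = None
        else:
            d = vpd_scalar(lst_k[m], td_c + p.svp_t0, p)
        we = None if d is None else we_scalar(d, p)
        if None in (te1, te2, we):
            lue = None
        else:
            lue = te1 * te2 * we * p.eps_max
        npp = None if (apar is None or lue is None) else apar * lue
        if npp is not None:
            annual = npp if annual is None else annual + npp
        for key, val in (
            ("apar", apar), ("te2", te2), ("d", d), ("we", we), ("lue", lue), ("npp", npp)
        ):
            out[key].append(val)
    out["npp_annual"] = annual
    return out
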