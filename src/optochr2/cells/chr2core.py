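"""Numba-compiled ChR2 photocycle core shared by the host-cell models.

The model parameters are packed into a flat float64 vector so the
compiled right-hand sides stay signature-stable.  The python-level
reference implementation lives in :mod:`optochr2.kinetics`; a unit test
pins the two paths to each other.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..params import ChR2Params

# packed parameter vector layout
(IG, IGAMMA, IRECT_A, IRECT_B, IRECT_VS, IEPS1K, IEPS2K, IFLUX, ITAU,
 ITHETA, IE12D, IC112, IE21D, IC121, ILOGC2, IGD2, IGD1B, IGD1A, IGD1V0,
 IGD1VS, IGRP, IGRS) = range(22)

NPVEC = 22


def pack_chr2_params(params: ChR2Params) -> np.ndarray:
    """Flatten a ChR2Params into the vector consumed by the njit cores."""
    if params.e_rev != 0.0:
        raise ValueError("host-cell coupling uses the closed-form "
                         "rectification product, which requires e_rev = 0")
    pv = np.empty(NPVEC)
    pv[IG] = params.g_chr2
    pv[IGAMMA] = params.gamma
    pv[IRECT_A] = params.rect_a
    pv[IRECT_B] = params.rect_b
    pv[IRECT_VS] = params.rect_vs
    pv[IEPS1K] = params.eps1 * params.k1_scale
    pv[IEPS2K] = params.eps2 * params.k2_scale
    pv[IFLUX] = params.flux_coeff * params.lambda_max / params.w_loss
    pv[ITAU] = params.tau_chr2
    pv[ITHETA] = params.theta_scale
    pv[IE12D] = params.e12_dark
    pv[IC112] = params.log_c1_12
    pv[IE21D] = params.e21_dark
    pv[IC121] = params.log_c1_21
    pv[ILOGC2] = params.log_c2
    pv[IGD2] = params.gd2
    pv[IGD1B] = params.gd1_base
    pv[IGD1A] = params.gd1_amp
    pv[IGD1V0] = params.gd1_v0
    pv[IGD1VS] = params.gd1_vs
    pv[IGRP] = params.gr_pref
    pv[IGRS] = params.gr_slope
    return pv


@njit(cache=True)
def chr2_current_nb(o1, o2, v, pv):
    rect = pv[IRECT_A] - pv[IRECT_B] * math.exp(-v / pv[IRECT_VS])
    return pv[IG] * rect * (o1 + pv[IGAMMA] * o2)


@njit(cache=True)
def chr2_derivs_nb(o1, o2, c2, p, v, irr, pv):
    """Returns (do1, do2, dc2, dp)."""
    c1 = 1.0 - o1 - o2 - c2
    F = pv[IFLUX] * irr
    log_term = math.log(1.0 + irr / pv[ILOGC2])
    k1 = pv[IEPS1K] * F * p
    k2 = pv[IEPS2K] * F * p
    e12 = pv[IE12D] + pv[IC112] * log_term
    e21 = pv[IE21D] + pv[IC121] * log_term
    gd1 = pv[IGD1B] + pv[IGD1A] * math.tanh((v + pv[IGD1V0]) / pv[IGD1VS])
    gr = pv[IGRP] * math.exp(-pv[IGRS] * v)
    do1 = k1 * c1 - (gd1 + e12) * o1 + e21 * o2
    do2 = k2 * c2 + e12 * o1 - (pv[IGD2] + e21) * o2
    dc2 = pv[IGD2] * o2 - (k2 + gr) * c2
    s_inf = 0.5 * (1.0 + math.tanh(120.0 * (pv[ITHETA] * irr - 0.1)))
    dp = (s_inf - p) / pv[ITAU]
    return do1, do2, dc2, dp
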