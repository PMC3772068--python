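"""Human atrial myocyte model (Courtemanche, Ramirez & Nattel 1998) with
the ChR2 photocurrent inserted as an additional sarcolemmal current.

State vector: 21 cell variables followed by the 4 ChR2 variables.
All membrane currents are expressed as densities (pA/pF); intracellular
fluxes follow the original absolute formulation with Cm = 100 pF.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .chr2core import chr2_current_nb, chr2_derivs_nb

R_GAS = 8.3143
TEMP = 310.0
FARADAY = 96.4867
RTF = R_GAS * TEMP / FARADAY     # ~26.713 mV
CM = 100.0                       # pF

KO = 5.4
NAO = 140.0
CAO = 1.8

GNA = 7.8
GK1 = 0.09
GTO = 0.1652
GKR = 0.029411765
GKS = 0.12941176
GCAL = 0.12375
GBCA = 0.001131
GBNA = 0.0006744375
INAK_MAX = 0.59933874
KMNAI = 10.0
KMKO = 1.5
INACA_MAX = 1600.0
KMNA = 87.5
KMCA = 1.38
KSAT = 0.1
GAM_NCX = 0.35
IPCA_MAX = 0.275
KQ10 = 3.0

VI = 13668.0
VUP = 1109.52
VREL_VOL = 96.48
KREL = 30.0
KUP = 0.00092
IUP_MAX = 0.005
CA_UP_MAX = 15.0
TAU_TR = 180.0
TRPN_MAX = 0.07
KM_TRPN = 0.0005
CMDN_MAX = 0.05
KM_CMDN = 0.00238
CSQN_MAX = 10.0
KM_CSQN = 0.8

N_CELL = 21
N_STATE = N_CELL + 4
(IV, IM, IH, IJ, IOA, IOI, IUA, IUI, IXR, IXS, ID, IF, IFCA, IU, IVG, IW,
 INAI, IKI, ICAI, ICAUP, ICAREL) = range(N_CELL)

STATE_NAMES = ("V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d",
               "f", "fCa", "u", "v_rel", "w", "Nai", "Ki", "Cai", "Ca_up",
               "Ca_rel", "o1", "o2", "c2", "p")

Y0 = np.array([
    -81.18, 2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1, 4.966e-3,
    9.986e-1, 3.296e-5, 1.869e-2, 1.367e-4, 9.996e-1, 7.755e-1, 0.0, 1.0,
    9.992e-1, 1.117e1, 1.39e2, 1.013e-4, 1.488, 1.488,
    0.0, 0.0, 0.0, 0.0,
])


@njit(cache=True)
def ik1_crn_nb(v, ek):
    return GK1 * (v - ek) / (1.0 + math.exp(0.07 * (v + 80.0)))


@njit(cache=True)
def _rhs(y, irr, pv, ik1_scale, stim):
    dy = np.zeros(N_STATE)
    v = y[IV]
    nai = y[INAI]
    ki = y[IKI]
    cai = max(y[ICAI], 1e-10)
    caup = y[ICAUP]
    carel = max(y[ICAREL], 1e-10)

    ena = RTF * math.log(NAO / nai)
    ek = RTF * math.log(KO / ki)
    eca = 0.5 * RTF * math.log(CAO / cai)

    ina = GNA * y[IM] ** 3 * y[IH] * y[IJ] * (v - ena)
    ik1 = ik1_scale * ik1_crn_nb(v, ek)
    ito = GTO * y[IOA] ** 3 * y[IOI] * (v - ek)
    gkur = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
    ikur = gkur * y[IUA] ** 3 * y[IUI] * (v - ek)
    ikr = GKR * y[IXR] * (v - ek) / (1.0 + math.exp((v + 15.0) / 22.4))
    iks = GKS * y[IXS] * y[IXS] * (v - ek)
    ical = GCAL * y[ID] * y[IF] * y[IFCA] * (v - 65.0)

    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                  + 0.0365 * sigma * math.exp(-v / RTF))
    inak = (INAK_MAX * fnak * KO / (KO + KMKO)
            / (1.0 + (KMNAI / nai) ** 1.5))
    e1 = math.exp(GAM_NCX * v / RTF)
    e2 = math.exp((GAM_NCX - 1.0) * v / RTF)
    inaca = INACA_MAX * (e1 * nai ** 3 * CAO - e2 * NAO ** 3 * cai) / (
        (KMNA ** 3 + NAO ** 3) * (KMCA + CAO) * (1.0 + KSAT * e2))
    ibna = GBNA * (v - ena)
    ibca = GBCA * (v - eca)
    ipca = IPCA_MAX * cai / (0.0005 + cai)

    ichr2 = chr2_current_nb(y[N_CELL], y[N_CELL + 1], v, pv)

    i_ion = (ina + ik1 + ito + ikur + ikr + iks + ical + inak + inaca
             + ibna + ibca + ipca)
    dy[IV] = -(i_ion + ichr2 + stim)

    # fast sodium gates
    if abs(v + 47.13) < 1e-7:
        am = 3.2
    else:
        am = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
    bm = 0.08 * math.exp(-v / 11.0)
    dy[IM] = (am / (am + bm) - y[IM]) * (am + bm)

    if v < -40.0:
        ah = 0.135 * math.exp(-(v + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = ((-1.2714e5 * math.exp(0.2444 * v)
               - 3.474e-5 * math.exp(-0.04391 * v)) * (v + 37.78)
              / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.1212 * math.exp(-0.01052 * v) / (
            1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    dy[IH] = (ah / (ah + bh) - y[IH]) * (ah + bh)
    dy[IJ] = (aj / (aj + bj) - y[IJ]) * (aj + bj)

    # transient outward gates
    aoa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    boa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    oainf = 1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54))
    dy[IOA] = (oainf - y[IOA]) * (aoa + boa) * KQ10

    aoi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
    boi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    oiinf = 1.0 / (1.0 + math.exp((v + 43.1) / 5.3))
    dy[IOI] = (oiinf - y[IOI]) * (aoi + boi) * KQ10

    # ultrarapid gates
    uainf = 1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6))
    dy[IUA] = (uainf - y[IUA]) * (aoa + boa) * KQ10
    aui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
    bui = math.exp((v - 158.0) / 16.0)
    uiinf = 1.0 / (1.0 + math.exp((v - 99.45) / 27.48))
    dy[IUI] = (uiinf - y[IUI]) * (aui + bui) * KQ10

    # delayed rectifier gates
    if abs(v + 14.1) < 1e-7:
        axr = 0.0015
    else:
        axr = 0.0003 * (v + 14.1) / (1.0 - math.exp(-(v + 14.1) / 5.0))
    if abs(v - 3.3328) < 1e-7:
        bxr = 3.7836118e-4
    else:
        bxr = 7.3898e-5 * (v - 3.3328) / (math.exp((v - 3.3328) / 5.1237) - 1.0)
    xrinf = 1.0 / (1.0 + math.exp(-(v + 14.1) / 6.5))
    dy[IXR] = (xrinf - y[IXR]) * (axr + bxr)

    if abs(v - 19.9) < 1e-7:
        axs = 0.00068
        bxs = 0.000315
    else:
        axs = 4e-5 * (v - 19.9) / (1.0 - math.exp(-(v - 19.9) / 17.0))
        bxs = 3.5e-5 * (v - 19.9) / (math.exp((v - 19.9) / 9.0) - 1.0)
    xsinf = 1.0 / math.sqrt(1.0 + math.exp(-(v - 19.9) / 12.7))
    dy[IXS] = (xsinf - y[IXS]) * 2.0 * (axs + bxs)

    # L-type calcium gates
    if abs(v + 10.0) < 1e-7:
        taud = 4.579 / (1.0 + math.exp(-(v + 10.0) / 6.24))
    else:
        taud = (1.0 - math.exp(-(v + 10.0) / 6.24)) / (
            0.035 * (v + 10.0) * (1.0 + math.exp(-(v + 10.0) / 6.24)))
    dinf = 1.0 / (1.0 + math.exp(-(v + 10.0) / 8.0))
    dy[ID] = (dinf - y[ID]) / taud

    finf = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
    tauf = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)
    dy[IF] = (finf - y[IF]) / tauf

    fcainf = 1.0 / (1.0 + cai / 0.00035)
    dy[IFCA] = (fcainf - y[IFCA]) / 2.0

    # SR release gating
    irel = KREL * y[IU] ** 2 * y[IVG] * y[IW] * (carel - cai)
    fn = (1e-12 * VREL_VOL * irel
          - (5e-13 / FARADAY) * (0.5 * ical - 0.2 * inaca) * CM)
    uinf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    dy[IU] = (uinf - y[IU]) / 8.0
    vinf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 1.367e-15))
    tauv = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    dy[IVG] = (vinf - y[IVG]) / tauv
    winf = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))
    if abs(v - 7.9) < 1e-7:
        tauw = 6.0 * 0.2 / 1.3
    else:
        tauw = (6.0 * (1.0 - math.exp(-(v - 7.9) / 5.0))
                / ((1.0 + 0.3 * math.exp(-(v - 7.9) / 5.0)) * (v - 7.9)))
    dy[IW] = (winf - y[IW]) / tauw

    # intracellular concentrations
    iup = IUP_MAX / (1.0 + KUP / cai)
    iupleak = IUP_MAX * caup / CA_UP_MAX
    itr = (caup - carel) / TAU_TR

    dy[INAI] = -(3.0 * inak + 3.0 * inaca + ibna + ina) * CM / (FARADAY * VI)
    dy[IKI] = (2.0 * inak - (ik1 + ito + ikur + ikr + iks + stim)) * CM / (
        FARADAY * VI)
    b1 = ((2.0 * inaca - ipca - ical - ibca) * CM / (2.0 * FARADAY * VI)
          + (VUP * (iupleak - iup) + irel * VREL_VOL) / VI)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2)
    dy[ICAI] = b1 / b2
    dy[ICAUP] = iup - iupleak - itr * VREL_VOL / VUP
    dy[ICAREL] = (itr - irel) / (
        1.0 + CSQN_MAX * KM_CSQN / (carel + KM_CSQN) ** 2)

    do1, do2, dc2, dp = chr2_derivs_nb(y[N_CELL], y[N_CELL + 1],
                                       y[N_CELL + 2], y[N_CELL + 3], v, irr, pv)
    dy[N_CELL] = do1
    dy[N_CELL + 1] = do2
    dy[N_CELL + 2] = dc2
    dy[N_CELL + 3] = dp
    return dy


@njit(cache=True)
def _currents(y, pv, ik1_scale):
    v = y[IV]
    ek = RTF * math.log(KO / y[IKI])
    ik1 = ik1_scale * ik1_crn_nb(v, ek)
    ichr2 = chr2_current_nb(y[N_CELL], y[N_CELL + 1], v, pv)
    return ik1, ichr2


class Courtemanche1998:
    """Atrial host cell."""

    name = "atrial"
    n_cell_states = N_CELL
    n_states = N_STATE
    state_names = STATE_NAMES
    v_index = IV

    def __init__(self, ik1_scale: float = 1.0):
        self.ik1_scale = ik1_scale
        self.y0 = Y0.copy()

    def rhs(self, t, y, irr, pv):
        return _rhs(y, irr, pv, self.ik1_scale, 0.0)

    def currents(self, y, pv) -> dict:
        ik1, ichr2 = _currents(np.asarray(y), pv, self.ik1_scale)
        return {"IK1": ik1, "IChR2": ichr2}
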