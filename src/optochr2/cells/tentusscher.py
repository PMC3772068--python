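"""Human ventricular myocyte model (ten Tusscher & Panfilov 2006) with the
ChR2 photocurrent inserted as an additional sarcolemmal current density.

The epicardial parameterisation is the default (endo and mid-myocardial
variants differ in Gto/GKs and the s-gate kinetics and are selectable).
State vector: 19 cell variables followed by the 4 ChR2 variables
(o1, o2, c2, p).  All currents are densities in pA/pF; time in ms.

The inward-rectifier IK1 can be swapped for a Purkinje-style
instantaneous rectifier (Sampson-type formulation, see ``ik1_purkinje``),
which is the numerical experiment behind the reduced optical threshold of
ventricular cells with Purkinje IK1.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .chr2core import chr2_current_nb, chr2_derivs_nb

# physical constants
R_GAS = 8314.472
TEMP = 310.0
FARADAY = 96485.3415
RTF = R_GAS * TEMP / FARADAY        # ~26.714 mV

# extracellular concentrations (mM)
KO = 5.4
NAO = 140.0
CAO = 2.0

# maximal conductances (nS/pF) and exchanger/pump parameters
GNA = 14.838
GK1 = 5.405
GKR = 0.153
GCAL = 3.98e-5
GPCA = 0.1238
KPCA = 0.0005
GPK = 0.0146
GBNA = 0.00029
GBCA = 0.000592
PNAK = 2.724
KMK = 1.0
KMNA = 40.0
KNACA = 1000.0
GAM_NCX = 0.35
KMCA = 1.38
KMNAI = 87.5
KSAT = 0.1
ALPHA_NCX = 2.5
PKNA = 0.03

# calcium handling
VMAXUP = 0.006375
KUP = 0.00025
VREL = 0.102
VLEAK = 0.00036
VXFER = 0.0038
K1P = 0.15
K2P = 0.045
K3 = 0.060
K4 = 0.005
EC_SR = 1.5
MAXSR = 2.5
MINSR = 1.0
BUFC = 0.2
KBUFC = 0.001
BUFSR = 10.0
KBUFSR = 0.3
BUFSS = 0.4
KBUFSS = 0.00025
VC = 0.016404
VSR = 0.001094
VSS = 0.00005468
CMEM = 0.185

# Purkinje-style IK1 (Sampson-type instantaneous rectifier)
KMK1_PURK = 13.0
#: Purkinje IK1 conductance (mS/uF).  The supplement-level value is set so
#: the formulation reproduces the ~0.32 pA/pF peak IK1 reported for the
#: human Purkinje cell during an optically triggered action potential.
GK1_PURK = 0.266

# state layout
N_CELL = 19
N_STATE = N_CELL + 4
(IV, IM, IH, IJ, IXR1, IXR2, IXS, IR, IS, ID, IF, IF2, IFCASS, IRQ,
 ICAI, ICASR, ICASS, INAI, IKI) = range(N_CELL)

STATE_NAMES = ("V", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f",
               "f2", "fCass", "Rq", "Cai", "CaSR", "CaSS", "Nai", "Ki",
               "o1", "o2", "c2", "p")

# published epicardial initial conditions (resting, dark)
Y0_EPI = np.array([
    -85.23, 0.00172, 0.7444, 0.7045, 0.00621, 0.4712, 0.0095, 2.42e-8,
    0.999998, 3.373e-5, 0.7888, 0.9755, 0.9953, 0.9073, 0.000126, 3.64,
    0.00036, 8.604, 136.89,
    0.0, 0.0, 0.0, 0.0,
])

# variant-dependent conductances: (Gto, GKs)
VARIANTS = {"epi": (0.294, 0.392), "endo": (0.073, 0.392), "mid": (0.294, 0.098)}


@njit(cache=True)
def ik1_native_nb(v, ek):
    a = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    b = (3.0 * math.exp(0.0002 * (v - ek + 100.0))
         + math.exp(0.1 * (v - ek - 10.0))) / (1.0 + math.exp(-0.5 * (v - ek)))
    xk1 = a / (a + b)
    return GK1 * math.sqrt(KO / 5.4) * xk1 * (v - ek)


@njit(cache=True)
def ik1_purkinje_nb(v, ek, gk1p):
    return gk1p * (KO / (KO + KMK1_PURK)) * (v - ek) / (
        2.0 + math.exp(1.5 * (v - ek) / RTF))


@njit(cache=True)
def _rhs(y, irr, pv, gto, gks, epi_s, ik1_mode, gk1p, stim):
    dy = np.zeros(N_STATE)
    v = y[IV]
    cai = max(y[ICAI], 1e-10)
    casr = max(y[ICASR], 1e-10)
    cass = max(y[ICASS], 1e-10)
    nai = y[INAI]
    ki = y[IKI]

    ena = RTF * math.log(NAO / nai)
    ek = RTF * math.log(KO / ki)
    eks = RTF * math.log((KO + PKNA * NAO) / (ki + PKNA * nai))
    eca = 0.5 * RTF * math.log(CAO / cai)

    ina = GNA * y[IM] ** 3 * y[IH] * y[IJ] * (v - ena)
    if ik1_mode == 0:
        ik1 = ik1_native_nb(v, ek)
    else:
        ik1 = ik1_purkinje_nb(v, ek, gk1p)
    ikr = GKR * math.sqrt(KO / 5.4) * y[IXR1] * y[IXR2] * (v - ek)
    iks = gks * y[IXS] * y[IXS] * (v - eks)
    ito = gto * y[IR] * y[IS] * (v - ek)

    zv = 2.0 * (v - 15.0) / RTF
    if abs(zv) < 1e-7:
        zv = 1e-7
    ez = math.exp(zv)
    ical = (GCAL * y[ID] * y[IF] * y[IF2] * y[IFCASS] * 2.0 * zv * FARADAY
            * (0.25 * cass * ez - CAO) / (ez - 1.0))

    inak = PNAK * KO * nai / ((KO + KMK) * (nai + KMNA) *
                              (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                               + 0.0353 * math.exp(-v / RTF)))
    e1 = math.exp(GAM_NCX * v / RTF)
    e2 = math.exp((GAM_NCX - 1.0) * v / RTF)
    inaca = KNACA * (e1 * nai ** 3 * CAO - e2 * NAO ** 3 * cai * ALPHA_NCX) / (
        (KMNAI ** 3 + NAO ** 3) * (KMCA + CAO) * (1.0 + KSAT * e2))
    ipca = GPCA * cai / (cai + KPCA)
    ipk = GPK * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    ibna = GBNA * (v - ena)
    ibca = GBCA * (v - eca)

    ichr2 = chr2_current_nb(y[N_CELL], y[N_CELL + 1], v, pv)

    i_ion = (ik1 + ito + ikr + iks + ical + inak + ina + ibna + inaca
             + ibca + ipk + ipca)
    dy[IV] = -(i_ion + ichr2 + stim)

    # gating variables
    minf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (
        1.0 + math.exp((v - 50.0) / 200.0))
    dy[IM] = (minf - y[IM]) / (am * bm)

    hinf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    dy[IH] = (hinf - y[IH]) * (ah + bh)

    if v < -40.0:
        aj = ((-2.5428e4 * math.exp(0.2444 * v)
               - 6.948e-6 * math.exp(-0.04391 * v)) * (v + 37.78)
              / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * v) / (
            1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    dy[IJ] = (hinf - y[IJ]) * (aj + bj)

    xr1inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    dy[IXR1] = (xr1inf - y[IXR1]) / (axr1 * bxr1)

    xr2inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    dy[IXR2] = (xr2inf - y[IXR2]) / (axr2 * bxr2)

    xsinf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    dy[IXS] = (xsinf - y[IXS]) / (axs * bxs + 80.0)

    rinf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    taur = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    dy[IR] = (rinf - y[IR]) / taur

    if epi_s == 1:
        sinf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
        taus = 85.0 * math.exp(-(v + 45.0) ** 2 / 320.0) + 5.0 / (
            1.0 + math.exp((v - 20.0) / 5.0)) + 3.0
    else:
        sinf = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
        taus = 1000.0 * math.exp(-(v + 67.0) ** 2 / 1000.0) + 8.0
    dy[IS] = (sinf - y[IS]) / taus

    dinf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    dy[ID] = (dinf - y[ID]) / (ad * bd + gd)

    finf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tauf = (1102.5 * math.exp(-(v + 27.0) ** 2 / 225.0)
            + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
            + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0)
    dy[IF] = (finf - y[IF]) / tauf

    f2inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    tauf2 = (562.0 * math.exp(-(v + 27.0) ** 2 / 240.0)
             + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
             + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0)))
    dy[IF2] = (f2inf - y[IF2]) / tauf2

    fcassinf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    dy[IFCASS] = (fcassinf - y[IFCASS]) / taufcass

    # SR release and calcium dynamics
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC_SR / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    dy[IRQ] = -k2 * cass * y[IRQ] + K4 * (1.0 - y[IRQ])
    o_rel = k1 * cass ** 2 * y[IRQ] / (K3 + k1 * cass ** 2)
    irel = VREL * o_rel * (casr - cass)
    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)

    bufc = 1.0 / (1.0 + BUFC * KBUFC / (cai + KBUFC) ** 2)
    dy[ICAI] = bufc * ((ileak - iup) * VSR / VC + ixfer
                       - (ibca + ipca - 2.0 * inaca) * CMEM / (2.0 * VC * FARADAY))
    bufsr = 1.0 / (1.0 + BUFSR * KBUFSR / (casr + KBUFSR) ** 2)
    dy[ICASR] = bufsr * (iup - irel - ileak)
    bufss = 1.0 / (1.0 + BUFSS * KBUFSS / (cass + KBUFSS) ** 2)
    dy[ICASS] = bufss * (-ical * CMEM / (2.0 * VSS * FARADAY)
                         + irel * VSR / VSS - ixfer * VC / VSS)

    dy[INAI] = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * CMEM / (VC * FARADAY)
    dy[IKI] = -(ik1 + ito + ikr + iks + ipk - 2.0 * inak + stim) * CMEM / (
        VC * FARADAY)

    do1, do2, dc2, dp = chr2_derivs_nb(y[N_CELL], y[N_CELL + 1],
                                       y[N_CELL + 2], y[N_CELL + 3], v, irr, pv)
    dy[N_CELL] = do1
    dy[N_CELL + 1] = do2
    dy[N_CELL + 2] = dc2
    dy[N_CELL + 3] = dp
    return dy


@njit(cache=True)
def _currents(y, pv, ik1_mode, gk1p):
    """Readouts: (IK1, IChR2) in pA/pF."""
    v = y[IV]
    ek = RTF * math.log(KO / y[IKI])
    if ik1_mode == 0:
        ik1 = ik1_native_nb(v, ek)
    else:
        ik1 = ik1_purkinje_nb(v, ek, gk1p)
    ichr2 = chr2_current_nb(y[N_CELL], y[N_CELL + 1], v, pv)
    return ik1, ichr2


class TenTusscher2006:
    """Ventricular host cell (epicardial by default)."""

    name = "ventricular"
    n_cell_states = N_CELL
    n_states = N_STATE
    state_names = STATE_NAMES
    v_index = IV

    def __init__(self, variant: str = "epi", ik1: str = "native",
                 purkinje_gk1: float = GK1_PURK):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if ik1 not in ("native", "purkinje"):
            raise ValueError("ik1 must be 'native' or 'purkinje'")
        self.variant = variant
        self.ik1 = ik1
        self.purkinje_gk1 = purkinje_gk1
        self.gto, self.gks = VARIANTS[variant]
        self.y0 = Y0_EPI.copy()

    @property
    def _ik1_mode(self) -> int:
        return 0 if self.ik1 == "native" else 1

    def rhs(self, t, y, irr, pv):
        return _rhs(y, irr, pv, self.gto, self.gks,
                    1 if self.variant != "endo" else 0,
                    self._ik1_mode, self.purkinje_gk1, 0.0)

    def currents(self, y, pv) -> dict:
        ik1, ichr2 = _currents(np.asarray(y), pv, self._ik1_mode,
                               self.purkinje_gk1)
        return {"IK1": ik1, "IChR2": ichr2}

    def with_ik1(self, formulation: str, **kwargs) -> "TenTusscher2006":
        cell = TenTusscher2006(self.variant, ik1=formulation,
                               purkinje_gk1=kwargs.get("purkinje_gk1",
                                                       self.purkinje_gk1))
        cell.y0 = self.y0.copy()
        return cell
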