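"""Mouse left-ventricular myocyte membrane model (41 differential variables).

Transcription of the Bondarenko et al. mouse apex ventricular cell model:
15 transmembrane currents, Markov-chain gating for the fast Na+ channel
(9 states, 8 explicit), the L-type Ca2+ channel (8 states, 7 explicit), the
rapid delayed rectifier (5 states, 4 explicit) and the ryanodine receptor
(4 states, 3 explicit), Hodgkin-Huxley gates for the transient-outward and
slow K+ currents, and full intracellular Ca2+ handling (subspace, cytosol,
junctional and network SR, troponin/calmodulin/calsequestrin buffering).

Everything model-specific lives in this single file so the transcription can
be audited against the published model description in one diff.  Units: mV,
ms, uM; membrane currents in pA/pF (= mV/ms with Cm factored out).

The apex parameter set is shipped (the transient-outward slow conductance is
zero at the apex; its gates are still integrated).  The default initial
state is the published state relaxed to quiescence for 2000 ms with this
module's own integrator (explicit Euler, dt = 0.0001 ms for the first 10 ms,
then 0.01 ms), frozen below; see ``settle``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import IonicModelSpec

N_VARS = 41

# State vector layout (V first; structure-of-arrays in tissue).
(
    I_V, I_CAI, I_CASS, I_CAJSR, I_CANSR, I_PRYR, I_LTRPN, I_HTRPN,
    I_PO1, I_PO2, I_PC2,
    I_O, I_C2, I_C3, I_C4, I_I1, I_I2, I_I3,
    I_CNA2, I_CNA1, I_ONA, I_IFNA, I_I1NA, I_I2NA, I_ICNA2, I_ICNA3,
    I_NAI, I_KI,
    I_ATOF, I_ITOF, I_NKS, I_ATOS, I_ITOS, I_AUR, I_IUR, I_AKSS, I_IKSS,
    I_CK1, I_CK2, I_OK, I_IK,
) = range(N_VARS)

STATE_NAMES = (
    "V", "Cai", "Cass", "CaJSR", "CaNSR", "P_RyR", "LTRPN_Ca", "HTRPN_Ca",
    "P_O1", "P_O2", "P_C2",
    "O", "C2", "C3", "C4", "I1", "I2", "I3",
    "C_Na2", "C_Na1", "O_Na", "IF_Na", "I1_Na", "I2_Na", "IC_Na2", "IC_Na3",
    "Nai", "Ki",
    "a_to_f", "i_to_f", "n_Ks", "a_to_s", "i_to_s", "a_ur", "i_ur",
    "a_Kss", "i_Kss",
    "C_K1", "C_K2", "O_K", "I_K",
)

MARKOV_GROUPS = {
    # explicit states; the chain's reference state is 1 - sum(explicit)
    "RyR": [I_PO1, I_PO2, I_PC2],                      # implicit P_C1
    "LType": [I_O, I_C2, I_C3, I_C4, I_I1, I_I2, I_I3],  # implicit C1
    "fastNa": [I_CNA2, I_CNA1, I_ONA, I_IFNA, I_I1NA, I_I2NA,
               I_ICNA2, I_ICNA3],                       # implicit C_Na3
    "Kr": [I_CK1, I_CK2, I_OK, I_IK],                   # implicit C_K0
}

# ---------------------------------------------------------------- constants
# Cell geometry and physical constants
ACAP = 1.534e-4      # capacitive membrane area, cm^2
CM = 1.0             # specific membrane capacitance, uF/cm^2
VMYO = 25.84e-6      # cytosolic volume, uL
VJSR = 0.12e-6       # junctional SR volume, uL
VNSR = 2.098e-6      # network SR volume, uL
VSS = 1.485e-9       # subspace volume, uL
FARADAY = 96.5       # C/mmol
TEMP = 298.0         # K
RGAS = 8.314         # J/(mol K)
RT_F = RGAS * TEMP / (FARADAY * 1000.0) * 1000.0  # mV

# Extracellular concentrations, uM
KO = 5400.0
NAO = 140000.0
CAO = 1800.0

# Ca2+ buffering
LTRPN_TOT = 70.0
HTRPN_TOT = 140.0
K_HTRPN_P = 0.00237
K_HTRPN_M = 3.2e-5
K_LTRPN_P = 0.0327
K_LTRPN_M = 0.0196
CMDN_TOT = 50.0
CSQN_TOT = 15000.0
KM_CMDN = 0.238
KM_CSQN = 800.0

# SR Ca2+ fluxes
V1_RYR = 4.5         # RyR release, 1/ms
V2_LEAK = 1.74e-5    # SR leak, 1/ms
V3_UP = 0.45         # SERCA Vmax, uM/ms
KM_UP = 0.5
TAU_TR = 20.0
TAU_XFER = 8.0
# RyR rates
KA_P = 0.006075      # uM^-4 ms^-1
KA_M = 0.07125
KB_P = 0.00405       # uM^-3 ms^-1
KB_M = 0.965
KC_P = 0.009
KC_M = 0.0008

# L-type Ca2+ channel
G_CAL = 0.1729       # mS/uF
E_CAL = 63.0         # mV
KPC_MAX = 0.23324
KPC_HALF = 20.0
KPCB = 0.0005
ICAL_MAX = 7.0       # pA/pF, normalization in the P_RyR drive

# Pumps and exchangers
IPCA_MAX = 1.0
KM_PCA = 0.5
K_NACA = 292.8
KM_NA = 87500.0
KM_CA = 1380.0
KSAT = 0.1
ETA = 0.35
INAK_MAX = 0.88
KM_NAI = 21000.0
KM_KO = 1500.0

# Background and channel conductances (mS/uF), apex parameter set
G_CAB = 0.000367
G_NA = 13.0
G_NAB = 0.0026
G_KTOF = 0.4067      # apex (septum: 0.0798)
G_KTOS = 0.0         # apex (septum: 0.0629)
G_KS = 0.00575
G_KUR = 0.16         # apex (septum: 0.0975)
G_KSS = 0.05         # apex (septum: 0.0324)
G_KR = 0.078
KF_KR = 0.023761
KB_KR = 0.036778
G_CLCA = 10.0
KM_CL = 10.0
E_CL = -40.0

# Published initial conditions (quiescent apex cell).
INITIAL_STATE_PUBLISHED = np.array([
    -82.4202,      # V
    0.115001,      # Cai
    0.115001,      # Cass
    1299.5,        # CaJSR
    1299.5,        # CaNSR
    0.0,           # P_RyR
    11.2684,       # LTRPN_Ca
    125.29,        # HTRPN_Ca
    1.49102e-5,    # P_O1
    9.51726e-11,   # P_O2
    1.6774e-4,     # P_C2
    9.30308e-19,   # O   (L-type)
    1.24216e-4,    # C2
    5.78679e-9,    # C3
    1.19816e-13,   # C4
    4.97923e-19,   # I1
    3.45847e-14,   # I2
    1.85106e-14,   # I3
    0.020752,      # C_Na2
    2.79132e-4,    # C_Na1
    7.13483e-7,    # O_Na
    1.53176e-4,    # IF_Na
    6.73345e-7,    # I1_Na
    1.55787e-9,    # I2_Na
    0.0113879,     # IC_Na2
    0.34278,       # IC_Na3
    14237.1,       # Nai
    143720.0,      # Ki
    2.65563e-3,    # a_to_f
    0.999977,      # i_to_f
    2.62753e-4,    # n_Ks
    4.17069e-4,    # a_to_s
    0.998543,      # i_to_s
    4.17069e-4,    # a_ur
    0.998543,      # i_ur
    4.17069e-4,    # a_Kss
    1.0,           # i_Kss
    9.92513e-4,    # C_K1
    6.41229e-4,    # C_K2
    1.75298e-4,    # O_K
    3.19129e-5,    # I_K
])


@njit(cache=True, fastmath=True)
def _bdk_kernel(S, dS, istim, dt, fused):  # pragma: no cover - compiled
    M = S.shape[1]
    for m in range(M):
        V = S[I_V, m]
        Cai = S[I_CAI, m]
        Cass = S[I_CASS, m]
        CaJSR = S[I_CAJSR, m]
        CaNSR = S[I_CANSR, m]
        PRyR = S[I_PRYR, m]
        LTRPNCa = S[I_LTRPN, m]
        HTRPNCa = S[I_HTRPN, m]
        PO1 = S[I_PO1, m]
        PO2 = S[I_PO2, m]
        PC2 = S[I_PC2, m]
        O = S[I_O, m]
        C2 = S[I_C2, m]
        C3 = S[I_C3, m]
        C4 = S[I_C4, m]
        I1 = S[I_I1, m]
        I2 = S[I_I2, m]
        I3 = S[I_I3, m]
        CNa2 = S[I_CNA2, m]
        CNa1 = S[I_CNA1, m]
        ONa = S[I_ONA, m]
        IFNa = S[I_IFNA, m]
        I1Na = S[I_I1NA, m]
        I2Na = S[I_I2NA, m]
        ICNa2 = S[I_ICNA2, m]
        ICNa3 = S[I_ICNA3, m]
        Nai = S[I_NAI, m]
        Ki = S[I_KI, m]
        atof = S[I_ATOF, m]
        itof = S[I_ITOF, m]
        nKs = S[I_NKS, m]
        atos = S[I_ATOS, m]
        itos = S[I_ITOS, m]
        aur = S[I_AUR, m]
        iur = S[I_IUR, m]
        aKss = S[I_AKSS, m]
        iKss = S[I_IKSS, m]
        CK1 = S[I_CK1, m]
        CK2 = S[I_CK2, m]
        OK = S[I_OK, m]
        IK = S[I_IK, m]

        # ---- reversal potentials
        EK = RT_F * math.log(KO / Ki)
        ENa = RT_F * math.log((0.9 * NAO + 0.1 * KO) / (0.9 * Nai + 0.1 * Ki))
        ECaN = 0.5 * RT_F * math.log(CAO / Cai)
        EKr = RT_F * math.log((0.98 * KO + 0.02 * NAO) / (0.98 * Ki + 0.02 * Nai))

        # ---- L-type Ca2+ current (Markov chain)
        ICaL = G_CAL * O * (V - E_CAL)
        ev12 = math.exp((V + 12.0) / 10.0)
        alpha = (0.4 * ev12
                 * (1.0 + 0.7 * math.exp(-((V + 40.0) ** 2) / 10.0)
                    - 0.75 * math.exp(-((V + 20.0) ** 2) / 400.0))
                 / (1.0 + 0.12 * ev12))
        beta = 0.05 * math.exp(-(V + 12.0) / 13.0)
        gamma = KPC_MAX * Cass / (KPC_HALF + Cass)
        Kpcf = 13.0 * (1.0 - math.exp(-((V + 14.5) ** 2) / 100.0))
        C1 = 1.0 - (O + C2 + C3 + C4 + I1 + I2 + I3)
        dC2 = 4.0 * alpha * C1 + 2.0 * beta * C3 - (beta + 3.0 * alpha) * C2
        dC3 = 3.0 * alpha * C2 + 3.0 * beta * C4 - (2.0 * beta + 2.0 * alpha) * C3
        dC4 = (2.0 * alpha * C3 + 4.0 * beta * O - (3.0 * beta + alpha) * C4
               + 0.01 * (4.0 * KPCB * beta * I1 - alpha * gamma * C4)
               + 0.002 * (4.0 * beta * I2 - Kpcf * C4)
               + 4.0 * beta * KPCB * I3 - gamma * Kpcf * C4)
        dO = (alpha * C4 + KPCB * I1 - (4.0 * beta + gamma) * O
              + 0.001 * (alpha * I2 - Kpcf * O))
        dI1 = (gamma * O + 0.001 * alpha * I3 - (KPCB + 0.001 * Kpcf) * I1
               + 0.01 * (alpha * gamma * C4 - 4.0 * beta * KPCB * I1))
        dI2 = (0.001 * Kpcf * O + KPCB * I3 - (0.001 * alpha + gamma) * I2
               + 0.002 * (Kpcf * C4 - 4.0 * beta * I2))
        dI3 = (0.001 * Kpcf * I1 + gamma * Kpcf * C4 + gamma * I2
               - (0.001 * alpha + KPCB + 4.0 * beta * KPCB) * I3)

        # ---- fast Na+ current (Markov chain)
        INa = G_NA * ONa * (V - ENa)
        aNa11 = 3.802 / (0.1027 * math.exp(-(V + 2.5) / 17.0)
                         + 0.20 * math.exp(-(V + 2.5) / 150.0))
        aNa12 = 3.802 / (0.1027 * math.exp(-(V + 2.5) / 15.0)
                         + 0.23 * math.exp(-(V + 2.5) / 150.0))
        aNa13 = 3.802 / (0.1027 * math.exp(-(V + 2.5) / 12.0)
                         + 0.25 * math.exp(-(V + 2.5) / 150.0))
        bNa11 = 0.1917 * math.exp(-(V + 2.5) / 20.3)
        bNa12 = 0.20 * math.exp(-(V - 2.5) / 20.3)
        bNa13 = 0.22 * math.exp(-(V - 7.5) / 20.3)
        aNa3 = 7.0e-7 * math.exp(-(V + 7.0) / 7.7)
        bNa3 = 0.0084 + 0.00002 * (V + 7.0)
        aNa2 = 1.0 / (0.188495 * math.exp(-(V + 7.0) / 16.6) + 0.393956)
        bNa2 = aNa13 * aNa2 * aNa3 / (bNa13 * bNa3)
        aNa4 = aNa2 / 1000.0
        bNa4 = aNa3
        aNa5 = aNa2 / 95000.0
        bNa5 = aNa3 / 50.0
        CNa3 = 1.0 - (CNa2 + CNa1 + ONa + IFNa + I1Na + I2Na + ICNa2 + ICNa3)
        dCNa2 = (aNa11 * CNa3 + bNa12 * CNa1 + aNa3 * ICNa2
                 - (bNa11 + aNa12 + bNa3) * CNa2)
        dCNa1 = (aNa12 * CNa2 + bNa13 * ONa + aNa3 * IFNa
                 - (bNa12 + aNa13 + bNa3) * CNa1)
        dONa = aNa13 * CNa1 + bNa2 * IFNa - (bNa13 + aNa2) * ONa
        dIFNa = (aNa2 * ONa + bNa3 * CNa1 + bNa4 * I1Na + aNa12 * ICNa2
                 - (bNa2 + aNa3 + aNa4 + bNa12) * IFNa)
        dI1Na = aNa4 * IFNa + bNa5 * I2Na - (bNa4 + aNa5) * I1Na
        dI2Na = aNa5 * I1Na - bNa5 * I2Na
        dICNa2 = (aNa11 * ICNa3 + bNa12 * IFNa + bNa3 * CNa2
                  - (bNa11 + aNa12 + aNa3) * ICNa2)
        dICNa3 = bNa11 * ICNa2 + bNa3 * CNa3 - (aNa11 + aNa3) * ICNa3

        # ---- rapid delayed rectifier K+ (Markov chain)
        IKr = G_KR * OK * (V - EKr)
        aa0 = 0.022348 * math.exp(0.01176 * V)
        ba0 = 0.047002 * math.exp(-0.0631 * V)
        aa1 = 0.013733 * math.exp(0.038198 * V)
        ba1 = 6.89e-5 * math.exp(-0.04178 * V)
        ai = 0.090821 * math.exp(0.023391 * (V + 5.0))
        bi = 0.006497 * math.exp(-0.03268 * (V + 5.0))
        CK0 = 1.0 - (CK1 + CK2 + OK + IK)
        dCK1 = aa0 * CK0 - ba0 * CK1 + KB_KR * CK2 - KF_KR * CK1
        dCK2 = KF_KR * CK1 - KB_KR * CK2 + ba1 * OK - aa1 * CK2
        dOK = aa1 * CK2 - ba1 * OK + bi * IK - ai * OK
        dIK = ai * OK - bi * IK

        # ---- transient outward, slow delayed, ultrarapid, steady-state K+
        Itof = G_KTOF * atof * atof * atof * itof * (V - EK)
        aa_tof = 0.18064 * math.exp(0.03577 * (V + 30.0))
        ba_tof = 0.3956 * math.exp(-0.06237 * (V + 30.0))
        ai_tof = (0.000152 * math.exp(-(V + 13.5) / 7.0)
                  / (0.0067083 * math.exp(-(V + 33.5) / 7.0) + 1.0))
        bi_tof = (0.00095 * math.exp((V + 33.5) / 7.0)
                  / (0.051335 * math.exp((V + 33.5) / 7.0) + 1.0))
        datof = aa_tof * (1.0 - atof) - ba_tof * atof
        ditof = ai_tof * (1.0 - itof) - bi_tof * itof

        ass = 1.0 / (1.0 + math.exp(-(V + 22.5) / 7.7))
        iss = 1.0 / (1.0 + math.exp((V + 45.2) / 5.7))
        Itos = G_KTOS * atos * itos * (V - EK)
        tau_tas = 0.493 * math.exp(-0.0629 * V) + 2.058
        tau_tis = 270.0 + 1050.0 / (1.0 + math.exp((V + 45.2) / 5.7))
        datos = (ass - atos) / tau_tas
        ditos = (iss - itos) / tau_tis

        IKs = G_KS * nKs * nKs * (V - EK)
        vn = V + 26.5
        den = 1.0 - math.exp(-0.128 * vn)
        if den > 1e-9 or den < -1e-9:
            a_n = 4.81333e-6 * vn / den
        else:
            a_n = 4.81333e-6 / 0.128
        b_n = 9.53333e-5 * math.exp(-0.038 * vn)
        dnKs = a_n * (1.0 - nKs) - b_n * nKs

        IKur = G_KUR * aur * iur * (V - EK)
        tau_iur = 1200.0 - 170.0 / (1.0 + math.exp((V + 45.2) / 5.7))
        daur = (ass - aur) / tau_tas
        diur = (iss - iur) / tau_iur

        IKss = G_KSS * aKss * iKss * (V - EK)
        tau_Kss = 39.3 * math.exp(-0.0862 * V) + 13.17
        daKss = (ass - aKss) / tau_Kss
        diKss = 0.0

        # ---- time-independent K+, pumps, exchangers, backgrounds, Cl-
        IK1 = (0.2938 * KO / (KO + 210.0) * (V - EK)
               / (1.0 + math.exp(0.0896 * (V - EK))))
        vfrt = V / RT_F
        sigma_nak = (math.exp(NAO / 67300.0) - 1.0) / 7.0
        fNaK = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * vfrt)
                      + 0.0365 * sigma_nak * math.exp(-vfrt))
        t32 = KM_NAI / Nai
        INaK = (INAK_MAX * fNaK * KO / (KO + KM_KO)
                / (1.0 + t32 * math.sqrt(t32)))
        expeta = math.exp(ETA * vfrt)
        expeta1 = math.exp((ETA - 1.0) * vfrt)
        INaCa = (K_NACA / (KM_NA ** 3 + NAO ** 3) / (KM_CA + CAO)
                 / (1.0 + KSAT * expeta1)
                 * (expeta * Nai ** 3 * CAO - expeta1 * NAO ** 3 * Cai))
        ICab = G_CAB * (V - ECaN)
        IpCa = IPCA_MAX * Cai * Cai / (KM_PCA * KM_PCA + Cai * Cai)
        INab = G_NAB * (V - ENa)
        OClCa = 0.2 / (1.0 + math.exp(-(V - 46.7) / 7.8))
        IClCa = G_CLCA * OClCa * Cai / (Cai + KM_CL) * (V - E_CL)

        # ---- ryanodine receptor and SR Ca2+ fluxes
        ca2 = Cass * Cass
        ca3 = ca2 * Cass
        ca4 = ca3 * Cass
        PC1 = 1.0 - (PO1 + PO2 + PC2)
        dPO1 = (KA_P * ca4 * PC1 - KA_M * PO1 - KB_P * ca3 * PO1 + KB_M * PO2
                - KC_P * PO1 + KC_M * PC2)
        dPO2 = KB_P * ca3 * PO1 - KB_M * PO2
        dPC2 = KC_P * PO1 - KC_M * PC2
        dPRyR = (-0.04 * PRyR
                 - 0.1 * (ICaL / ICAL_MAX)
                 * math.exp(-((V - 5.0) ** 2) / 648.0))

        Jrel = V1_RYR * (PO1 + PO2) * (CaJSR - Cass) * PRyR
        Jtr = (CaNSR - CaJSR) / TAU_TR
        Jxfer = (Cass - Cai) / TAU_XFER
        Jleak = V2_LEAK * (CaNSR - Cai)
        Jup = V3_UP * Cai * Cai / (KM_UP * KM_UP + Cai * Cai)
        Jtrpn = (K_HTRPN_P * Cai * (HTRPN_TOT - HTRPNCa) - K_HTRPN_M * HTRPNCa
                 + K_LTRPN_P * Cai * (LTRPN_TOT - LTRPNCa) - K_LTRPN_M * LTRPNCa)
        dLTRPN = K_LTRPN_P * Cai * (LTRPN_TOT - LTRPNCa) - K_LTRPN_M * LTRPNCa
        dHTRPN = K_HTRPN_P * Cai * (HTRPN_TOT - HTRPNCa) - K_HTRPN_M * HTRPNCa

        Bi = 1.0 / (1.0 + CMDN_TOT * KM_CMDN / ((KM_CMDN + Cai) ** 2))
        Bss = 1.0 / (1.0 + CMDN_TOT * KM_CMDN / ((KM_CMDN + Cass) ** 2))
        BJSR = 1.0 / (1.0 + CSQN_TOT * KM_CSQN / ((KM_CSQN + CaJSR) ** 2))

        acv = ACAP * CM / (2.0 * VMYO * FARADAY)
        dCai = Bi * (Jleak + Jxfer - Jup - Jtrpn
                     - (ICab - 2.0 * INaCa + IpCa) * acv)
        dCass = Bss * (Jrel * VJSR / VSS - Jxfer * VMYO / VSS
                       - ICaL * ACAP * CM / (2.0 * VSS * FARADAY))
        dCaJSR = BJSR * (Jtr - Jrel)
        dCaNSR = (Jup - Jleak) * VMYO / VNSR - Jtr * VJSR / VNSR

        dNai = -(INa + INab + 3.0 * INaCa + 3.0 * INaK) * ACAP * CM / (VMYO * FARADAY)
        dKi = -(Itof + Itos + IK1 + IKs + IKss + IKur + IKr - 2.0 * INaK) \
            * ACAP * CM / (VMYO * FARADAY)

        # ---- membrane potential: sum of the 15 transmembrane currents
        Iion = (ICaL + IpCa + INaCa + ICab + INa + INab + INaK
                + Itof + Itos + IK1 + IKs + IKur + IKss + IKr + IClCa)
        dV = -Iion + istim[m]

        if fused:
            S[I_V, m] = V + dt * dV
            S[I_CAI, m] = Cai + dt * dCai
            S[I_CASS, m] = Cass + dt * dCass
            S[I_CAJSR, m] = CaJSR + dt * dCaJSR
            S[I_CANSR, m] = CaNSR + dt * dCaNSR
            S[I_PRYR, m] = PRyR + dt * dPRyR
            S[I_LTRPN, m] = LTRPNCa + dt * dLTRPN
            S[I_HTRPN, m] = HTRPNCa + dt * dHTRPN
            S[I_PO1, m] = PO1 + dt * dPO1
            S[I_PO2, m] = PO2 + dt * dPO2
            S[I_PC2, m] = PC2 + dt * dPC2
            S[I_O, m] = O + dt * dO
            S[I_C2, m] = C2 + dt * dC2
            S[I_C3, m] = C3 + dt * dC3
            S[I_C4, m] = C4 + dt * dC4
            S[I_I1, m] = I1 + dt * dI1
            S[I_I2, m] = I2 + dt * dI2
            S[I_I3, m] = I3 + dt * dI3
            S[I_CNA2, m] = CNa2 + dt * dCNa2
            S[I_CNA1, m] = CNa1 + dt * dCNa1
            S[I_ONA, m] = ONa + dt * dONa
            S[I_IFNA, m] = IFNa + dt * dIFNa
            S[I_I1NA, m] = I1Na + dt * dI1Na
            S[I_I2NA, m] = I2Na + dt * dI2Na
            S[I_ICNA2, m] = ICNa2 + dt * dICNa2
            S[I_ICNA3, m] = ICNa3 + dt * dICNa3
            S[I_NAI, m] = Nai + dt * dNai
            S[I_KI, m] = Ki + dt * dKi
            S[I_ATOF, m] = atof + dt * datof
            S[I_ITOF, m] = itof + dt * ditof
            S[I_NKS, m] = nKs + dt * dnKs
            S[I_ATOS, m] = atos + dt * datos
            S[I_ITOS, m] = itos + dt * ditos
            S[I_AUR, m] = aur + dt * daur
            S[I_IUR, m] = iur + dt * diur
            S[I_AKSS, m] = aKss + dt * daKss
            S[I_IKSS, m] = iKss + dt * diKss
            S[I_CK1, m] = CK1 + dt * dCK1
            S[I_CK2, m] = CK2 + dt * dCK2
            S[I_OK, m] = OK + dt * dOK
            S[I_IK, m] = IK + dt * dIK
        else:
            dS[I_V, m] = dV
            dS[I_CAI, m] = dCai
            dS[I_CASS, m] = dCass
            dS[I_CAJSR, m] = dCaJSR
            dS[I_CANSR, m] = dCaNSR
            dS[I_PRYR, m] = dPRyR
            dS[I_LTRPN, m] = dLTRPN
            dS[I_HTRPN, m] = dHTRPN
            dS[I_PO1, m] = dPO1
            dS[I_PO2, m] = dPO2
            dS[I_PC2, m] = dPC2
            dS[I_O, m] = dO
            dS[I_C2, m] = dC2
            dS[I_C3, m] = dC3
            dS[I_C4, m] = dC4
            dS[I_I1, m] = dI1
            dS[I_I2, m] = dI2
            dS[I_I3, m] = dI3
            dS[I_CNA2, m] = dCNa2
            dS[I_CNA1, m] = dCNa1
            dS[I_ONA, m] = dONa
            dS[I_IFNA, m] = dIFNa
            dS[I_I1NA, m] = dI1Na
            dS[I_I2NA, m] = dI2Na
            dS[I_ICNA2, m] = dICNa2
            dS[I_ICNA3, m] = dICNa3
            dS[I_NAI, m] = dNai
            dS[I_KI, m] = dKi
            dS[I_ATOF, m] = datof
            dS[I_ITOF, m] = ditof
            dS[I_NKS, m] = dnKs
            dS[I_ATOS, m] = datos
            dS[I_ITOS, m] = ditos
            dS[I_AUR, m] = daur
            dS[I_IUR, m] = diur
            dS[I_AKSS, m] = daKss
            dS[I_IKSS, m] = diKss
            dS[I_CK1, m] = dCK1
            dS[I_CK2, m] = dCK2
            dS[I_OK, m] = dOK
            dS[I_IK, m] = dIK


def settle(duration_ms: float = 2000.0, state: np.ndarray | None = None) -> np.ndarray:
    """Relax a quiescent cell to its rest state with the module's integrator.

    Explicit Euler at dt = 0.0001 ms for the first 10 ms (the published state
    is consistent only to a few digits), then dt = 0.01 ms; no stimulus.
    """
    s = (INITIAL_STATE_PUBLISHED if state is None else state).copy()
    S = np.ascontiguousarray(s[:, None])
    zero = np.zeros(1)
    t, dt = 0.0, 1e-4
    while t < duration_ms - 1e-9:
        if t >= 10.0:
            dt = 0.01
        _bdk_kernel(S, S, zero, dt, True)
        t += dt
    return S[:, 0].copy()


# Rest state produced by ``settle(2000.0)`` (frozen; regenerate with
# scripts/freeze_rest_state.py after any change to the model definition).
RESTING_STATE = np.array([
    -82.42006714856106,  # V
    0.11500085364836404,  # Cai
    0.11500085364876109,  # Cass
    1299.4999214330062,  # CaJSR
    1299.499926014238,  # CaNSR
    6.309804118543064e-23,  # P_RyR
    11.268450596362724,  # LTRPN_Ca
    125.28993935886511,  # HTRPN_Ca
    1.4910295793511385e-05,  # P_O1
    9.517374562082524e-11,  # P_O2
    0.00016774058236463505,  # P_C2
    9.30379768088535e-19,  # O
    0.0001242180167178237,  # C2
    5.787012263668125e-09,  # C3
    1.1982341593976006e-13,  # C4
    2.4812715580096814e-18,  # I1
    3.458700912319361e-14,  # I2
    9.224164656943912e-14,  # I3
    0.020752124119828352,  # C_Na2
    0.0002791371374767836,  # C_Na1
    7.135067504466797e-07,  # O_Na
    0.00015318136083712833,  # IF_Na
    6.733812590776637e-07,  # I1_Na
    1.5579130580468035e-09,  # I2_Na
    0.011388089172479627,  # IC_Na2
    0.3427834894538585,  # IC_Na3
    14237.099933060656,  # Nai
    143720.00012890957,  # Ki
    0.0026556599623436075,  # a_to_f
    0.9999974737484485,  # i_to_f
    0.000262756047028836,  # n_Ks
    0.0004170751798812288,  # a_to_s
    0.9985429076430583,  # i_to_s
    0.0004170751798812288,  # a_ur
    0.9985428986576498,  # i_ur
    0.00041706925202369873,  # a_Kss
    1.0,  # i_Kss
    0.00099252117069422,  # C_K1
    0.0006412337634101707,  # C_K2
    0.00017530061093058767,  # O_K
    3.1913581954528964e-05,  # I_K
])


def bdk_model() -> IonicModelSpec:
    """The 41-variable mouse ventricular (apex) membrane model."""
    return IonicModelSpec(
        name="bdk",
        n_vars=N_VARS,
        initial_state=RESTING_STATE.copy(),
        kernel=_bdk_kernel,
        markov_groups={k: list(v) for k, v in MARKOV_GROUPS.items()},
        rel_cost=100.0,
    )
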