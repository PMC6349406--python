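"""Unit conventions and centralized conversions.

All public interfaces use:

==============  ==========
quantity        unit
==============  ==========
voltage         mV
time            ms
distance        µm
conductance     µS (synaptic peak conductances are accepted in nS)
current         nA
resistance      MΩ
capacitance     nF
specific Ra     Ω·cm
specific Rm     Ω·cm²
specific Cm     µF/cm²
==============  ==========

This system is internally consistent: I = g·V gives µS·mV = nA, and
C·dV/dt gives nF·mV/ms = nA, so no conversion factors appear inside the
integrator.  The only conversions needed are from specific (per-area,
CGS-style) membrane constants to absolute per-compartment values, done
here and nowhere else.
"""

import numpy as np

UM_TO_CM = 1e-4
UM2_TO_CM2 = 1e-8
NS_TO_US = 1e-3
MS_TO_S = 1e-3


def lateral_area_cm2(diam_um, length_um):
    """Cylinder lateral surface area, π·d·L, in cm²."""
    return np.pi * np.asarray(diam_um) * np.asarray(length_um) * UM2_TO_CM2


def membrane_capacitance_nF(cm_uF_per_cm2, area_cm2):
    """Absolute capacitance of a membrane patch (1 µF = 1000 nF)."""
    return cm_uF_per_cm2 * area_cm2 * 1e3


def leak_conductance_uS(rm_ohm_cm2, area_cm2):
    """Absolute leak conductance of a membrane patch (1 S = 1e6 µS)."""
    return area_cm2 / rm_ohm_cm2 * 1e6


def axial_conductance_uS(diam_um, length_um, ra_ohm_cm):
    """Axial conductance of a cylindrical segment: (π d²/4)/(Ra·L) in µS."""
    area = np.pi * np.asarray(diam_um) ** 2 / 4.0 * UM2_TO_CM2
    return area / (ra_ohm_cm * np.asarray(length_um) * UM_TO_CM) * 1e6


def steady_length_constant_um(rm_ohm_cm2, diam_um, ra_ohm_cm):
    """Steady-state space constant λ = √(Rm·d/(4·Ra)) of a uniform cable, µm.

    Analytic reference value; the transient effective length constant
    measured from simulated events is generally shorter.
    """
    lam_cm = np.sqrt(rm_ohm_cm2 * diam_um * UM_TO_CM / (4.0 * ra_ohm_cm))
    return lam_cm / UM_TO_CM
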