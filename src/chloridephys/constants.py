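"""Physical constants and the unit conventions used throughout the package.

Units are fixed globally: potentials in mV, currents in pA, conductances in
nS, capacitance in pF, concentrations in mM, volume in pL, time in s,
temperature in K.  Every unit conversion lives here.
"""

from __future__ import annotations

import numpy as np

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


def rt_over_f(temperature: float) -> float:
    """Thermal voltage RT/F in mV at the given absolute temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive (got {temperature} K)")
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY


def nernst_chloride(cl_in, cl_out, temperature: float = 295.0):
    """Chloride Nernst potential in mV.

    For a monovalent anion E_Cl = (RT/F) * ln([Cl]_in / [Cl]_out), so equal
    concentrations give 0 mV and a cell with less chloride inside than
    outside has a negative E_Cl.

    Parameters
    ----------
    cl_in, cl_out : float or array-like
        Intra-/extracellular chloride concentration, mM.  Must be > 0.
    temperature : float
        Absolute temperature, K (default 295 K, room temperature).
    """
    cl_in = np.asarray(cl_in, dtype=float)
    cl_out = np.asarray(cl_out, dtype=float)
    if np.any(cl_in <= 0) or np.any(cl_out <= 0):
        raise ValueError("chloride concentrations must be positive")
    e = rt_over_f(temperature) * np.log(cl_in / cl_out)
    return float(e) if e.ndim == 0 else e


def chloride_flux_rate(i_cl_pa, cell_volume_pl: float):
    """Rate of change of [Cl-]_i (mM/s) produced by a chloride current.

    Sign convention: conventional current is outward-positive, so a positive
    chloride current corresponds to Cl- *influx* (the carrier is an anion)
    and raises the intracellular concentration.

    d[Cl]/dt = 1000 * I / (F * V)   with I in pA and V in pL.
    """
    if cell_volume_pl <= 0:
        raise ValueError("cell volume must be positive")
    return 1000.0 * np.asarray(i_cl_pa, dtype=float) / (FARADAY * cell_volume_pl)
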