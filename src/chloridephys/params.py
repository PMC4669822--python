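"""Cell parameters, clamp protocols and the bundled condition presets.

The presets encode the experimental conditions of the GlyR alpha3K(185L) /
KCC2 study this package models: cultured hippocampal neurons recorded in
gramicidin perforated-patch at a holding potential of -50 mV, with -5 mV
test pulses and -100 -> -30 mV / 140 ms voltage ramps every 5 s, sampled at
10 kHz after 2.8 kHz low-pass filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .constants import nernst_chloride
from .errors import ConfigError

VOLTAGE_CLAMP = "voltage_clamp"
CURRENT_CLAMP = "current_clamp"


@dataclass
class CellParams:
    """Single-compartment neuron with leak, tonic GlyR and GABA_A chloride
    conductances, and transporter-driven chloride turnover.

    Parameters
    ----------
    membrane_capacitance : float
        pF.  Only relevant in current clamp.
    g_leak, g_glyr, g_gaba_max : float
        nS.  ``g_glyr`` is the tonic chloride conductance of constitutively
        open glycine receptors; ``g_gaba_max`` opens only inside GABA
        application windows.  All >= 0.
    e_leak : float
        Reversal potential of the lumped (mostly K+) leak, mV.
    cl_in_init, cl_out : float
        Initial intra- and fixed extracellular chloride, mM.
    kcc2_rate, nkcc1_rate : float
        First-order relaxation rates (1/s, >= 0) of [Cl-]_i toward the
        extrusion target (``cl_kcc2_target``, low) and the import target
        (``cl_nkcc1_target``, high).  The transporters are characterised
        functionally, not kinetically.
    cell_volume : float
        Effective volume for concentration bookkeeping, pL.
    temperature : float
        K; sets RT/F for the Nernst relation.
    cl_dynamics : bool
        When False, [Cl-]_i is frozen at ``cl_in_init`` (useful for
        closed-form oracle comparisons).
    """

    membrane_capacitance: float = 80.0
    g_leak: float = 2.331
    e_leak: float = -63.6
    g_glyr: float = 0.0
    g_gaba_max: float = 8.0
    cl_in_init: float = 15.0
    cl_out: float = 151.0
    kcc2_rate: float = 0.0
    cl_kcc2_target: float = 5.0
    nkcc1_rate: float = 0.0
    cl_nkcc1_target: float = 40.0
    cell_volume: float = 2.0
    temperature: float = 295.0
    cl_dynamics: bool = True

    def __post_init__(self):
        for name in ("g_leak", "g_glyr", "g_gaba_max", "kcc2_rate", "nkcc1_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0 (got {getattr(self, name)})")
        for name in ("cl_in_init", "cl_out", "cl_kcc2_target", "cl_nkcc1_target",
                     "cell_volume", "membrane_capacitance", "temperature"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0 (got {getattr(self, name)})")

    @property
    def e_cl_init(self) -> float:
        """Nernst chloride potential of the initial concentrations, mV."""
        return nernst_chloride(self.cl_in_init, self.cl_out, self.temperature)

    def replace(self, **kw) -> "CellParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class ProtocolSpec:
    """Timing and acquisition parameters of one clamp experiment.

    In voltage clamp each sweep of length ``inter_ramp_interval`` contains a
    -5 mV test pulse followed by a -100 -> -30 mV ramp; the sweep repeats
    ``n_sweeps`` times.  ``application_windows`` are (label, t_start, t_end)
    agonist applications in *global* time across sweeps.
    """

    mode: str = VOLTAGE_CLAMP
    holding_potential: float = -50.0
    pulse_amplitude: float = -5.0
    pulse_onset: float = 0.8       # s, within sweep
    pulse_duration: float = 0.1    # s
    ramp_start: float = -100.0     # mV
    ramp_end: float = -30.0        # mV
    ramp_onset: float = 1.8        # s, within sweep
    ramp_duration: float = 0.140   # s
    inter_ramp_interval: float = 5.0  # s, sweep length
    n_sweeps: int = 6
    sampling_rate: float = 10_000.0   # Hz
    filter_cutoff: float = 2_800.0    # Hz
    application_windows: list = field(default_factory=list)

    def __post_init__(self):
        if self.mode not in (VOLTAGE_CLAMP, CURRENT_CLAMP):
            raise ConfigError(f"unknown clamp mode {self.mode!r}")
        if self.ramp_end <= self.ramp_start:
            raise ConfigError("ramp_end must exceed ramp_start")
        if self.filter_cutoff and self.sampling_rate <= 2 * self.filter_cutoff:
            raise ConfigError("sampling_rate must exceed twice the filter cutoff")
        if self.n_sweeps < 1:
            raise ConfigError("n_sweeps must be >= 1")
        if self.mode == VOLTAGE_CLAMP:
            if self.pulse_onset + self.pulse_duration > self.ramp_onset:
                raise ConfigError("pulse epoch must end before the ramp")
            if self.ramp_onset + self.ramp_duration > self.inter_ramp_interval:
                raise ConfigError("ramp epoch must fit inside the sweep")
        self.application_windows = [tuple(w) for w in self.application_windows]
        by_label: dict = {}
        for label, t0, t1 in self.application_windows:
            if t1 <= t0:
                raise ConfigError(f"window {label!r} has t_end <= t_start")
            for u0, u1 in by_label.get(label, []):
                if t0 < u1 and u0 < t1:
                    raise ConfigError(f"windows for label {label!r} overlap")
            by_label.setdefault(label, []).append((t0, t1))

    @property
    def ramp_slope(self) -> float:
        """Command ramp slope in mV/ms."""
        return (self.ramp_end - self.ramp_start) / (self.ramp_duration * 1000.0)

    @property
    def total_duration(self) -> float:
        return self.n_sweeps * self.inter_ramp_interval

    def windows(self, label: str) -> list:
        return [(t0, t1) for lab, t0, t1 in self.application_windows if lab == label]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def replace(self, **kw) -> "ProtocolSpec":
        return dataclasses.replace(self, **kw)


# --------------------------------------------------------------------------
# Condition presets.  Conductances and reversals are anchored to the study's
# measured summary statistics: control R_N 429 MOhm and V_rev -63.6 mV;
# 185L R_N 108 MOhm with V_rev/E_GABA pulled to the -50 mV holding potential
# by the tonic GlyR chloride conductance; E_GABA(control) -58.7 mV.
# Capacitance, volume and transporter rates are assumptions (see docs).
# --------------------------------------------------------------------------

def control_cell() -> CellParams:
    """Control neuron (mCherry only): no tonic GlyR conductance."""
    return CellParams(
        g_leak=1000.0 / 429.0,       # 429 MOhm input resistance
        e_leak=-63.6,
        g_glyr=0.0,
        cl_in_init=15.0,             # E_Cl ~ -58.7 mV at 151 mM outside
        kcc2_rate=0.005,
        nkcc1_rate=0.002,            # transporter fixed point = 15 mM
        cl_nkcc1_target=40.0,
        cl_kcc2_target=5.0,
    )


def glyr185l_cell() -> CellParams:
    """Neuron with enduring GlyR alpha3K(185L) activation in 10 uM glycine.

    A large tonic chloride conductance collapses the input resistance to the
    ~108 MOhm scale; chloride has equilibrated to the -50 mV holding
    potential during the preceding days of receptor activation, and the
    lumped leak reversal is depolarised (the long-lasting intrinsic change
    seen after glycine washout).
    """
    g_leak = 1000.0 / 429.0
    g_total = 1000.0 / 108.0
    return CellParams(
        g_leak=g_leak,
        e_leak=-52.1,
        g_glyr=g_total - g_leak,
        cl_in_init=21.1,             # E_Cl ~ -50 mV
        kcc2_rate=0.0,               # KCC2 functionally absent
        nkcc1_rate=0.003,
        cl_nkcc1_target=40.0,
    )


def glyr185l_kcc2wt_cell() -> CellParams:
    """185L + KCC2wt co-expression: transport does not overcome the shunt."""
    cell = glyr185l_cell()
    return cell.replace(kcc2_rate=0.002)


def kcc2pr_cell() -> CellParams:
    """KCC2pr (phosphorylation-resistant) without 185L: lowered [Cl-]_i."""
    cell = control_cell()
    return cell.replace(cl_in_init=11.3, kcc2_rate=0.01, nkcc1_rate=0.002)


CONDITION_PRESETS = {
    "control": control_cell,
    "185L": glyr185l_cell,
    "185L+KCC2wt": glyr185l_kcc2wt_cell,
    "KCC2pr": kcc2pr_cell,
}


def get_preset(name: str) -> CellParams:
    try:
        return CONDITION_PRESETS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown condition preset {name!r}; known: {sorted(CONDITION_PRESETS)}"
        ) from None


def draw_cohort(condition, n: int, seed: int,
                g_cv: float = 0.10, e_leak_sd: float = 2.0,
                cl_cv: float = 0.08) -> list:
    """Draw ``n`` cells around a preset with lognormal conductance spread.

    Cell-to-cell variability emulates the biological scatter of the study's
    per-cell measurements (R_N and V_rev SEMs of order 10-15%).
    """
    base = get_preset(condition) if isinstance(condition, str) else condition
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n):
        cells.append(base.replace(
            g_leak=base.g_leak * float(np.exp(rng.normal(0.0, g_cv))),
            g_glyr=base.g_glyr * float(np.exp(rng.normal(0.0, g_cv))),
            e_leak=base.e_leak + float(rng.normal(0.0, e_leak_sd)),
            cl_in_init=base.cl_in_init * float(np.exp(rng.normal(0.0, cl_cv))),
        ))
    return cells
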