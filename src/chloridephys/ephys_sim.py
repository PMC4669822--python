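"""Synthetic patch-clamp recordings from a chloride-homeostasis point neuron.

The model is a single compartment with a lumped leak, a tonic GlyR chloride
conductance, a GABA_A chloride conductance gated by application windows, and
first-order chloride transport (KCC2 extrusion, NKCC1 import).  Intracellular
chloride integrates the channel flux (converted through Faraday's constant
and the cell volume) plus the transporter terms, so the chloride reversal
potential is a dynamic quantity: under a sustained voltage clamp it relaxes
toward the holding potential, which is the mechanism behind the collapsed
GABA driving force of tonically active GlyR-expressing neurons.

Integration is a fixed-step explicit (forward Euler) scheme on the 10 kHz
sample grid, with an explicit stability check; outputs therefore align
sample-for-sample with the Recording container.  Gaussian current noise and
a single-pole emulation of the 2.8 kHz acquisition filter are applied to the
*recorded* copy of the signal only - the chloride bookkeeping integrates the
noiseless physical current.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import lfilter

from .constants import FARADAY, rt_over_f
from .containers import Recording
from .errors import ConfigError, SimulationError
from .params import CURRENT_CLAMP, VOLTAGE_CLAMP, CellParams, ProtocolSpec

GABA_LABEL = "GABA"


def build_command(protocol: ProtocolSpec):
    """Return (time_base, command) for one voltage-clamp sweep.

    The command holds at the holding potential, steps by the pulse amplitude
    during the test-pulse epoch, and runs the voltage ramp (including its
    exact end point, so the ramp slope is exactly
    (ramp_end - ramp_start)/ramp_duration).
    """
    if protocol.mode != VOLTAGE_CLAMP:
        raise ConfigError("build_command requires a voltage-clamp protocol")
    fs = protocol.sampling_rate
    n = int(round(protocol.inter_ramp_interval * fs))
    t = np.arange(n) / fs
    v = np.full(n, protocol.holding_potential)

    i0 = int(round(protocol.pulse_onset * fs))
    i1 = int(round((protocol.pulse_onset + protocol.pulse_duration) * fs))
    v[i0:i1] = protocol.holding_potential + protocol.pulse_amplitude

    r0 = int(round(protocol.ramp_onset * fs))
    r1 = int(round((protocol.ramp_onset + protocol.ramp_duration) * fs))
    slope_per_sample = (protocol.ramp_end - protocol.ramp_start) / (r1 - r0)
    v[r0:r1 + 1] = protocol.ramp_start + slope_per_sample * np.arange(r1 - r0 + 1)
    return t, v


def gaba_open_mask(protocol: ProtocolSpec, n_total: int, label: str = GABA_LABEL):
    """Boolean per-sample mask (global time) of open GABA_A conductance."""
    fs = protocol.sampling_rate
    t = np.arange(n_total) / fs
    mask = np.zeros(n_total, dtype=bool)
    for t0, t1 in protocol.windows(label):
        mask |= (t >= t0) & (t < t1)
    return mask


def _single_pole(x: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    """Single-pole low-pass, initialised at steady state for x[0]."""
    if not cutoff:
        return x
    alpha = 1.0 - math.exp(-2.0 * math.pi * cutoff / fs)
    zi = np.array([(1.0 - alpha) * x[0]])
    y, _ = lfilter([alpha], [1.0, alpha - 1.0], x, zi=zi)
    return y


def _check_stability_vc(cell: CellParams, dt: float):
    # chloride feedback rate under clamp: g * dE/dcl * flux conversion
    g_cl = cell.g_glyr + cell.g_gaba_max
    if cell.cl_dynamics and g_cl > 0:
        dedcl = rt_over_f(cell.temperature) / min(cell.cl_in_init, cell.cl_kcc2_target)
        lam = g_cl * dedcl * 1000.0 / (FARADAY * cell.cell_volume)
        lam += cell.kcc2_rate + cell.nkcc1_rate
        if dt * lam > 0.2:
            raise SimulationError(
                f"integration step {dt:.2e} s too large for chloride dynamics "
                f"(fastest rate ~{lam:.3g}/s); raise the sampling rate"
            )
    if dt * (cell.kcc2_rate + cell.nkcc1_rate) > 0.2:
        raise SimulationError("integration step too large for transporter rates")


def _integrate_vc(cell: CellParams, v: np.ndarray, gaba_open: np.ndarray, dt: float):
    """Forward-Euler chloride integration under voltage clamp.

    Returns (clean current pA, cl_in trajectory mM).  cl[i] is the
    concentration *entering* sample i; the recorded current at sample i uses
    cl[i], then chloride advances by one step.
    """
    rtf = rt_over_f(cell.temperature)
    kconv = 1000.0 / (FARADAY * cell.cell_volume)
    g_leak, e_leak = cell.g_leak, cell.e_leak
    g_glyr, g_gaba = cell.g_glyr, cell.g_gaba_max
    kcc2, t_kcc2 = cell.kcc2_rate, cell.cl_kcc2_target
    nkcc1, t_nkcc1 = cell.nkcc1_rate, cell.cl_nkcc1_target
    cl_out = cell.cl_out
    log = math.log

    n = v.size
    current = np.empty(n)
    cl_trace = np.empty(n)
    cl = cell.cl_in_init
    vv = v.tolist()
    go = gaba_open.tolist()
    for i in range(n):
        e_cl = rtf * log(cl / cl_out)
        g_cl = g_glyr + (g_gaba if go[i] else 0.0)
        i_cl = g_cl * (vv[i] - e_cl)
        current[i] = g_leak * (vv[i] - e_leak) + i_cl
        cl_trace[i] = cl
        if cl <= 0:  # pragma: no cover - guarded by stability check
            raise SimulationError("chloride concentration became non-positive")
        cl += dt * (i_cl * kconv + kcc2 * (t_kcc2 - cl) + nkcc1 * (t_nkcc1 - cl))
    return current, cl_trace


def simulate_voltage_clamp(cell: CellParams, protocol: ProtocolSpec,
                           noise_sd: float = 0.0, seed: int = 0,
                           cell_id: str = "", condition: str = "") -> Recording:
    """Simulate a gramicidin perforated-patch voltage-clamp experiment.

    The membrane potential follows the command exactly (no series
    resistance); the recorded current is the sum of conductance currents
    g_x * (V - E_x) plus Gaussian noise, low-pass filtered at the protocol's
    acquisition cutoff.  Deterministic given ``seed``.

    Returns a Recording whose ``aux["cl_in"]`` holds the per-sweep
    intracellular chloride trajectory (ground truth for tests).
    """
    if protocol.mode != VOLTAGE_CLAMP:
        raise ConfigError("protocol.mode must be voltage_clamp")
    dt = 1.0 / protocol.sampling_rate
    _check_stability_vc(cell, dt)

    time_base, command = build_command(protocol)
    n_per = command.size
    n_total = n_per * protocol.n_sweeps
    v_flat = np.tile(command, protocol.n_sweeps)
    gaba_open = gaba_open_mask(protocol, n_total)

    if cell.cl_dynamics:
        clean, cl_flat = _integrate_vc(cell, v_flat, gaba_open, dt)
    else:
        e_cl = cell.e_cl_init
        g_cl = cell.g_glyr + np.where(gaba_open, cell.g_gaba_max, 0.0)
        clean = cell.g_leak * (v_flat - cell.e_leak) + g_cl * (v_flat - e_cl)
        cl_flat = np.full(n_total, cell.cl_in_init)

    rng = np.random.default_rng(seed)
    recorded = clean if noise_sd == 0 else clean + rng.normal(0.0, noise_sd, n_total)
    recorded = _single_pole(recorded, protocol.filter_cutoff, protocol.sampling_rate)

    sweeps = [recorded[s * n_per:(s + 1) * n_per] for s in range(protocol.n_sweeps)]
    cl_sweeps = [cl_flat[s * n_per:(s + 1) * n_per] for s in range(protocol.n_sweeps)]
    return Recording(
        sweeps=sweeps, command=command, time_base=time_base, protocol=protocol,
        cell_id=cell_id, condition=condition, seed=seed,
        aux={"cl_in": cl_sweeps, "clean_current": clean, "cell": cell},
    )


def simulate_current_clamp(cell: CellParams, duration: float,
                           injected_current: float = 0.0, seed: int = 0,
                           noise_sd: float = 0.0, sampling_rate: float = 10_000.0,
                           filter_cutoff: float = 2_800.0, init_v: float | None = None,
                           cell_id: str = "", condition: str = "") -> Recording:
    """Simulate a current-clamp recording (dV/dt = -(sum I - I_inj)/C).

    With a large tonic chloride conductance and chloride initialised from a
    -50 mV voltage-clamp steady state, the membrane potential first jumps to
    the conductance-weighted mean of the open reversals and then drifts with
    the slowly evolving chloride gradient - the slow apparent-V_m adaptation
    seen when switching from voltage to current clamp.

    ``init_v`` defaults to the instantaneous conductance-weighted steady
    state for the initial chloride load.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    dt = 1.0 / sampling_rate
    g_total = cell.g_leak + cell.g_glyr
    tau = cell.membrane_capacitance / g_total / 1000.0  # s (pF/nS = ms)
    if dt > 0.2 * tau:
        raise SimulationError(
            f"step {dt:.2e} s exceeds 20% of the membrane time constant "
            f"({tau:.2e} s); raise the sampling rate"
        )
    _check_stability_vc(cell.replace(g_gaba_max=0.0), dt)

    rtf = rt_over_f(cell.temperature)
    kconv = 1000.0 / (FARADAY * cell.cell_volume)
    n = int(round(duration * sampling_rate))
    e_cl0 = rtf * math.log(cell.cl_in_init / cell.cl_out)
    if init_v is None:
        init_v = (cell.g_leak * cell.e_leak + cell.g_glyr * e_cl0
                  + injected_current) / g_total

    v_trace = np.empty(n)
    cl_trace = np.empty(n)
    v = float(init_v)
    cl = cell.cl_in_init
    # dV/dt in mV/s: I(pA)/C(pF) gives mV/ms -> *1000
    c_inv = 1000.0 / cell.membrane_capacitance
    log = math.log
    for i in range(n):
        v_trace[i] = v
        cl_trace[i] = cl
        e_cl = rtf * log(cl / cell.cl_out)
        i_cl = cell.g_glyr * (v - e_cl)
        i_total = cell.g_leak * (v - cell.e_leak) + i_cl - injected_current
        v -= dt * c_inv * i_total
        if cell.cl_dynamics:
            cl += dt * (i_cl * kconv
                        + cell.kcc2_rate * (cell.cl_kcc2_target - cl)
                        + cell.nkcc1_rate * (cell.cl_nkcc1_target - cl))
            if cl <= 0:  # pragma: no cover
                raise SimulationError("chloride concentration became non-positive")
    if not np.all(np.isfinite(v_trace)):
        raise SimulationError("current-clamp integration diverged")

    rng = np.random.default_rng(seed)
    recorded = v_trace if noise_sd == 0 else v_trace + rng.normal(0.0, noise_sd, n)
    recorded = _single_pole(recorded, filter_cutoff, sampling_rate)

    protocol = ProtocolSpec(
        mode=CURRENT_CLAMP, sampling_rate=sampling_rate, filter_cutoff=filter_cutoff,
        inter_ramp_interval=duration, n_sweeps=1, holding_potential=init_v,
    )
    command = np.full(n, injected_current)
    time_base = np.arange(n) / sampling_rate
    return Recording(
        sweeps=[recorded], command=command, time_base=time_base, protocol=protocol,
        cell_id=cell_id, condition=condition, seed=seed,
        aux={"cl_in": [cl_trace], "clean_vm": v_trace, "cell": cell},
    )
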