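"""Voltage-clamp ramp analysis: R_N, V_rev, E_GABA and GABA driving force.

The workflow mirrors the perforated-patch analysis of tonically inhibited
hippocampal neurons: input resistance from -5 mV test pulses, point-wise
averaged IV curves from -100 -> -30 mV ramps recorded inside (IV_GABA) and
outside (IV_bas) GABA applications, E_GABA from the zero crossing of
IV_GABA - IV_bas, V_rev from the zero crossing of IV_bas, and the GABA
driving force E_GABA - V_rev.  ``RampAnalysis`` bundles the steps into a
model object whose ``fit()`` returns a results object with a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import IVCurve, MembraneProperties, Recording
from .errors import AnalysisError, ProtocolError
from .ephys_sim import GABA_LABEL
from .params import CURRENT_CLAMP, VOLTAGE_CLAMP

JUNCTION_POTENTIAL_MV = 3.75  # liquid junction potential of the study's solutions


# ---------------------------------------------------------------- epochs ---

def _sweep_indices(recording: Recording, onset: float, duration: float):
    fs = recording.protocol.sampling_rate
    return int(round(onset * fs)), int(round((onset + duration) * fs))


def _ramp_global_window(recording: Recording, sweep: int):
    p = recording.protocol
    t0 = recording.sweep_start(sweep) + p.ramp_onset
    return t0, t0 + p.ramp_duration


def _sweep_in_label(recording: Recording, sweep: int, label: str) -> bool:
    """True if the sweep's full ramp lies inside a window with this label."""
    t0, t1 = _ramp_global_window(recording, sweep)
    return any(w0 <= t0 and t1 <= w1 for w0, w1 in recording.protocol.windows(label))


def _sweep_outside_all(recording: Recording, sweep: int) -> bool:
    t0, t1 = _ramp_global_window(recording, sweep)
    for _, w0, w1 in recording.protocol.application_windows:
        if t0 < w1 and w0 < t1:
            return False
    return True


# ------------------------------------------------------------ operations ---

def compute_input_resistance(recording: Recording, steady_fraction: float = 0.3,
                             noise_floor_sd: float = 3.0,
                             exclude_label: str = GABA_LABEL) -> float:
    """Input resistance (MOhm) from the -5 mV test pulses.

    For each qualifying sweep (pulse outside any ``exclude_label`` window)
    the steady pulse current is the mean over the last ``steady_fraction``
    of the pulse minus the pre-pulse baseline mean; R_N is the pulse
    amplitude over the mean current deflection, positive by construction.

    Warns (low confidence) when the deflection is within ``noise_floor_sd``
    baseline standard deviations of zero.
    """
    p = recording.protocol
    if p.mode != VOLTAGE_CLAMP:
        raise ProtocolError("input resistance requires a voltage-clamp recording")
    if p.pulse_duration <= 0 or p.pulse_amplitude == 0:
        raise ProtocolError("recording protocol contains no test-pulse epoch")
    i0, i1 = _sweep_indices(recording, p.pulse_onset, p.pulse_duration)
    n_pulse = i1 - i0
    s0 = i1 - max(1, int(round(steady_fraction * n_pulse)))
    b1 = i0
    b0 = max(0, i0 - n_pulse)

    deltas, base_sds = [], []
    for s in range(recording.n_sweeps):
        t0 = recording.sweep_start(s) + p.pulse_onset
        t1 = t0 + p.pulse_duration
        inside = any(t0 < w1 and w0 < t1
                     for lab, w0, w1 in p.application_windows if lab == exclude_label)
        if inside:
            continue
        trace = recording.sweeps[s]
        baseline = trace[b0:b1]
        deltas.append(float(np.mean(trace[s0:i1]) - np.mean(baseline)))
        base_sds.append(float(np.std(baseline)))
    if not deltas:
        raise ProtocolError("no pulse epoch outside the excluded application windows")
    delta_i = float(np.mean(deltas))
    if delta_i == 0:
        raise AnalysisError("zero current deflection: input resistance undefined")
    sd = float(np.mean(base_sds)) / np.sqrt(len(deltas))
    if abs(delta_i) < noise_floor_sd * sd:
        warnings.warn("pulse current deflection below noise floor; "
                      "input resistance is low-confidence", stacklevel=2)
    # mV / pA = GOhm -> MOhm
    return 1000.0 * p.pulse_amplitude / delta_i


def extract_iv(recording: Recording, which: str = "basal",
               gaba_label: str = GABA_LABEL) -> IVCurve:
    """Average the qualifying ramps point-wise onto the command-voltage grid.

    ``which="gaba"`` selects sweeps whose full ramp lies inside a GABA
    window; ``which="basal"`` selects sweeps whose ramp overlaps no
    application window at all.
    """
    p = recording.protocol
    if p.mode != VOLTAGE_CLAMP:
        raise ProtocolError("IV extraction requires a voltage-clamp recording")
    if which not in ("basal", "gaba"):
        raise AnalysisError(f"which must be 'basal' or 'gaba', got {which!r}")
    r0, r1 = _sweep_indices(recording, p.ramp_onset, p.ramp_duration)
    r1 += 1  # command includes the exact ramp end point
    qualifying = [
        s for s in range(recording.n_sweeps)
        if (_sweep_in_label(recording, s, gaba_label) if which == "gaba"
            else _sweep_outside_all(recording, s))
    ]
    if not qualifying:
        missing = f"inside a {gaba_label!r} window" if which == "gaba" \
            else "outside all application windows"
        raise ProtocolError(f"no ramp {missing}")
    currents = np.mean([recording.sweeps[s][r0:r1] for s in qualifying], axis=0)
    return IVCurve(voltages=recording.command[r0:r1], currents=currents,
                   source=which, n_ramps_averaged=len(qualifying))


def subtract_iv(iv_gaba: IVCurve, iv_bas: IVCurve) -> IVCurve:
    """GABA-minus-basal IV; re-grids by linear interpolation when needed."""
    v_lo = max(iv_gaba.voltages[0], iv_bas.voltages[0])
    v_hi = min(iv_gaba.voltages[-1], iv_bas.voltages[-1])
    if v_hi <= v_lo:
        raise AnalysisError("IV curves cover disjoint voltage ranges")
    if (iv_gaba.voltages.size == iv_bas.voltages.size
            and np.array_equal(iv_gaba.voltages, iv_bas.voltages)):
        v = iv_gaba.voltages
        diff = iv_gaba.currents - iv_bas.currents
    else:
        v = iv_gaba.voltages[(iv_gaba.voltages >= v_lo) & (iv_gaba.voltages <= v_hi)]
        diff = (np.interp(v, iv_gaba.voltages, iv_gaba.currents)
                - np.interp(v, iv_bas.voltages, iv_bas.currents))
    return IVCurve(voltages=v, currents=diff, source="subtracted",
                   n_ramps_averaged=min(iv_gaba.n_ramps_averaged,
                                        iv_bas.n_ramps_averaged))


@dataclass
class ReversalDiagnostics:
    n_crossings: int
    ambiguous: bool
    crossings: list


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="valid")


def find_reversal(iv: IVCurve, holding: float = -50.0, smooth: int = 11,
                  full_output: bool = False):
    """Zero-crossing reversal potential of an IV curve, mV.

    The currents are lightly smoothed (moving average, ``smooth`` samples)
    and the crossing is located by linear interpolation between the two
    samples bracketing the sign change.  When several crossings survive
    smoothing, the one closest to ``holding`` is returned and the result is
    flagged ambiguous.
    """
    if iv.voltages.size < 2:
        raise AnalysisError("IV curve needs at least two points")
    # smoothing only makes sense on curves much longer than the window
    w = int(smooth) if iv.currents.size >= 2 * int(smooth) else 1
    cur = _moving_average(iv.currents, w)
    off = (w - 1) // 2
    v = iv.voltages[off:off + cur.size]

    crossings = []
    for i in range(cur.size - 1):
        a, b = cur[i], cur[i + 1]
        if a == 0.0:
            crossings.append(float(v[i]))
        elif a * b < 0:
            crossings.append(float(v[i] - a * (v[i + 1] - v[i]) / (b - a)))
    if cur[-1] == 0.0:
        crossings.append(float(v[-1]))
    if not crossings:
        raise AnalysisError(
            f"no zero crossing in [{v[0]:.1f}, {v[-1]:.1f}] mV: "
            "reversal lies outside the ramp range"
        )
    crossings = sorted(set(crossings))
    value = min(crossings, key=lambda c: abs(c - holding))
    diag = ReversalDiagnostics(n_crossings=len(crossings),
                               ambiguous=len(crossings) > 1, crossings=crossings)
    if diag.ambiguous:
        warnings.warn(f"{diag.n_crossings} zero crossings; reporting the one "
                      f"nearest the holding potential ({value:.2f} mV)", stacklevel=2)
    return (value, diag) if full_output else value


def driving_force(e_gaba: float, v_rev: float) -> float:
    """GABA driving force: E_GABA - V_rev, mV."""
    if not (np.isfinite(e_gaba) and np.isfinite(v_rev)):
        raise AnalysisError("driving force requires finite reversal potentials")
    return e_gaba - v_rev


def correct_junction_potential(props: MembraneProperties,
                               offset: float = JUNCTION_POTENTIAL_MV) -> MembraneProperties:
    """Subtract the liquid junction potential from all absolute potentials.

    The driving force, being a difference, is unchanged.  Applying the
    correction twice raises.
    """
    if props.junction_corrected:
        raise AnalysisError("junction potential already corrected")
    sub = lambda x: None if x is None else x - offset
    return props.replace(v_rev=sub(props.v_rev), e_gaba=sub(props.e_gaba),
                         v_m=sub(props.v_m), junction_corrected=True)


@dataclass
class RuptureFlag:
    ruptured: bool
    onset: float | None = None  # global time, s

    def __bool__(self):
        return self.ruptured


def detect_rupture(recording: Recording, threshold: float = 5.0,
                   min_duration: float = 0.05, lag: float = 1.0,
                   min_sd: float = 0.5) -> RuptureFlag:
    """Detect loss of the perforated patch from a sustained baseline shift.

    Holding-epoch samples (command at the holding potential, outside
    application windows) form the baseline.  Each sample is compared with a
    *running* reference - the median of the preceding ``lag`` seconds of
    baseline - so an abrupt whole-cell breakthrough (the large shift caused
    by the high-chloride pipette solution) is flagged while slow
    physiological drift of the holding current is not.  Rupture requires the
    deviation to exceed ``threshold`` times the high-frequency baseline SD
    (floored at ``min_sd`` pA) for ``min_duration`` seconds.
    """
    p = recording.protocol
    if p.mode != VOLTAGE_CLAMP:
        raise ProtocolError("rupture detection requires a voltage-clamp recording")
    hold_mask = recording.command == p.holding_potential
    times = recording.flat_times()
    full_mask = np.tile(hold_mask, recording.n_sweeps)
    for _, w0, w1 in p.application_windows:
        full_mask &= ~((times >= w0) & (times < w1))
    base = recording.flat()[full_mask]
    base_t = times[full_mask]
    if base.size < 10:
        raise ProtocolError("recording has no usable baseline epochs")

    # block medians give the running reference; residuals give the noise SD
    nb = max(1, int(round(0.05 * p.sampling_rate)))  # 50 ms of baseline samples
    n_blocks = base.size // nb
    if n_blocks < 2:
        raise ProtocolError("baseline too short for rupture detection")
    medians = np.array([np.median(base[k * nb:(k + 1) * nb]) for k in range(n_blocks)])
    resid = base[:n_blocks * nb] - np.repeat(medians, nb)
    n_early = max(nb, int(0.2 * n_blocks) * nb)
    sd = max(1.4826 * float(np.median(np.abs(resid[:n_early]))), min_sd)

    lag_blocks = max(1, int(round(lag / 0.05)))
    n_run = max(1, int(round(min_duration * p.sampling_rate)))
    dev = np.zeros(n_blocks * nb, dtype=bool)
    for k in range(1, n_blocks):  # block 0 is reference-only
        ref = float(np.median(medians[max(0, k - lag_blocks):k]))
        seg = base[k * nb:(k + 1) * nb]
        dev[k * nb:(k + 1) * nb] = np.abs(seg - ref) > threshold * sd
    runsum = np.convolve(dev.astype(int), np.ones(n_run, dtype=int), mode="valid")
    hits = np.nonzero(runsum == n_run)[0]
    if hits.size:
        return RuptureFlag(True, onset=float(base_t[hits[0]]))
    return RuptureFlag(False)


@dataclass
class VmEstimate:
    value: float            # mV
    drift_slope: float      # mV/s over the measurement window
    window: tuple = (0.0, 0.0)


def measure_vm(recording: Recording, stabilization: float = 120.0) -> VmEstimate:
    """Apparent resting potential from a current-clamp recording.

    Discards the first ``stabilization`` seconds (the potential needs
    minutes to settle after switching from voltage clamp), then returns the
    mean over the remaining window plus its linear drift slope as a
    stability diagnostic.
    """
    if recording.mode != CURRENT_CLAMP:
        raise ProtocolError("V_m measurement requires a current-clamp recording")
    t = recording.time_base
    if t[-1] <= stabilization:
        raise ProtocolError(
            f"recording ({t[-1]:.1f} s) shorter than the stabilization "
            f"interval ({stabilization:.1f} s)"
        )
    mask = t >= stabilization
    v = recording.sweeps[0][mask]
    tw = t[mask]
    slope = float(np.polyfit(tw, v, 1)[0]) if v.size > 1 else 0.0
    return VmEstimate(value=float(np.mean(v)), drift_slope=slope,
                      window=(float(tw[0]), float(tw[-1])))


# ------------------------------------------------------------ model shape ---

@dataclass
class RampResults:
    """Results of a RampAnalysis fit."""

    properties: MembraneProperties
    iv_basal: IVCurve | None = None
    iv_gaba: IVCurve | None = None
    iv_subtracted: IVCurve | None = None
    rupture: RuptureFlag | None = None
    excluded: bool = False
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        p = self.properties
        fmt = lambda x, u: "   --  " if x is None else f"{x:7.2f} {u}"
        lines = [
            "Ramp analysis results",
            "=" * 42,
            f"cell_id        : {p.cell_id or '-'}",
            f"condition      : {p.condition or '-'}",
            f"R_N            : {fmt(p.r_n, 'MOhm')}",
            f"V_rev          : {fmt(p.v_rev, 'mV')}",
            f"E_GABA         : {fmt(p.e_gaba, 'mV')}",
            f"driving force  : {fmt(p.driving_force, 'mV')}",
            f"junction corr. : {p.junction_corrected}",
            f"excluded       : {self.excluded}"
            + (f" (rupture at {self.rupture.onset:.2f} s)"
               if self.rupture and self.rupture.ruptured else ""),
        ]
        if self.iv_basal is not None:
            lines.append(f"ramps averaged : basal {self.iv_basal.n_ramps_averaged}"
                         + (f", GABA {self.iv_gaba.n_ramps_averaged}"
                            if self.iv_gaba is not None else ""))
        return "\n".join(lines)


class RampAnalysis:
    """Model object binding a Recording to the full ramp analysis.

    Parameters
    ----------
    recording : Recording (voltage clamp)
    gaba_label : window label identifying GABA applications
    smooth : moving-average width (samples) before zero-crossing detection
    junction_correct : apply the +3.75 mV liquid-junction correction
        (default off, matching the reporting convention of uncorrected
        potentials).
    rupture_threshold : baseline-shift multiple that excludes a recording
    """

    def __init__(self, recording: Recording, gaba_label: str = GABA_LABEL,
                 smooth: int = 11, junction_correct: bool = False,
                 junction_offset: float = JUNCTION_POTENTIAL_MV,
                 rupture_threshold: float = 5.0):
        self.recording = recording
        self.gaba_label = gaba_label
        self.smooth = smooth
        self.junction_correct = junction_correct
        self.junction_offset = junction_offset
        self.rupture_threshold = rupture_threshold

    def fit(self) -> RampResults:
        rec = self.recording
        diag: dict = {}
        rupture = detect_rupture(rec, threshold=self.rupture_threshold)
        if rupture.ruptured:
            props = MembraneProperties(cell_id=rec.cell_id, condition=rec.condition,
                                       qc={"rupture_onset": rupture.onset})
            return RampResults(properties=props, rupture=rupture, excluded=True,
                               diagnostics={"reason": "membrane rupture"})

        r_n = compute_input_resistance(rec, exclude_label=self.gaba_label)
        iv_bas = extract_iv(rec, "basal", gaba_label=self.gaba_label)
        holding = rec.protocol.holding_potential
        v_rev, d1 = find_reversal(iv_bas, holding=holding, smooth=self.smooth,
                                  full_output=True)
        diag["v_rev_ambiguous"] = d1.ambiguous

        iv_gaba = iv_sub = None
        e_gaba = df = None
        try:
            iv_gaba = extract_iv(rec, "gaba", gaba_label=self.gaba_label)
        except ProtocolError:
            diag["e_gaba"] = "no GABA ramps in recording"
        if iv_gaba is not None:
            iv_sub = subtract_iv(iv_gaba, iv_bas)
            e_gaba, d2 = find_reversal(iv_sub, holding=holding, smooth=self.smooth,
                                       full_output=True)
            diag["e_gaba_ambiguous"] = d2.ambiguous
            df = driving_force(e_gaba, v_rev)

        props = MembraneProperties(
            r_n=r_n, v_rev=v_rev, e_gaba=e_gaba, driving_force=df,
            cell_id=rec.cell_id, condition=rec.condition,
        )
        if self.junction_correct:
            props = correct_junction_potential(props, self.junction_offset)
        return RampResults(properties=props, iv_basal=iv_bas, iv_gaba=iv_gaba,
                           iv_subtracted=iv_sub, rupture=rupture, diagnostics=diag)
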