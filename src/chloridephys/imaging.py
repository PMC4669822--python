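"""Calcium-imaging pipeline: background subtraction, ratiometric fura-2
calibration, viability gating, resting [Ca2+]_i and single-channel
F_GABA/F_KCl normalisation.

Background fluorescence is the per-channel mean over the Mn2+-quench window
(Mn2+ quenches the dye, leaving pure background) and is subtracted from all
F340 and F380 values.  Concentration follows the ratiometric relation

    [Ca2+] = K_D * (F380_min / F380_max) * (R - R_min) / (R_max - R)

with K_D = 225 nM the dissociation constant of the fura-2/Ca2+ complex,
R = F340/F380 after background subtraction, and the min/max quantities taken
from the 0 mM (free dye) and 10 mM (bound dye) calibration windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CalibrationConstants, FluorescenceExperiment
from .errors import AnalysisError, CalibrationError, ProtocolError, SaturationError

QUENCH_LABEL = "Mn_quench"
ZERO_CA_LABEL = "ionomycin_0Ca"
SAT_CA_LABEL = "ionophore_10Ca"
KCL_LABEL = "KCl"
GABA_LABEL = "GABA"

RESTING_WINDOW_S = 10.0  # resting [Ca2+]_i window immediately before KCl


@dataclass
class CalciumResult:
    """Per-cell calcium analysis result."""

    resting_ca: float | None      # nM; None when the viability gate failed
    viability: bool
    background: dict              # channel -> a.u.
    calibration: CalibrationConstants | None = None
    cell_id: str = ""
    condition: str = ""
    qc_notes: list = field(default_factory=list)

    def summary(self) -> str:
        ca = "   --  " if self.resting_ca is None else f"{self.resting_ca:7.1f} nM"
        bg = ", ".join(f"{k}={v:.1f}" for k, v in self.background.items())
        lines = [
            "Calcium analysis results",
            "=" * 42,
            f"cell_id      : {self.cell_id or '-'}",
            f"viable       : {self.viability}",
            f"resting Ca   : {ca}",
            f"background   : {bg}",
        ]
        if self.qc_notes:
            lines.append("QC           : " + "; ".join(self.qc_notes))
        return "\n".join(lines)


def _window_mean(expt: FluorescenceExperiment, channel: str, label: str) -> float:
    return float(np.mean(expt.channels[channel][expt.window_mask(label)]))


def estimate_background(expt: FluorescenceExperiment, min_frames: int = 10) -> dict:
    """Per-channel background from the Mn2+ quench window (mean)."""
    if QUENCH_LABEL not in expt.events:
        raise ProtocolError("no Mn_quench window: background cannot be estimated")
    n = int(np.sum(expt.window_mask(QUENCH_LABEL)))
    if n < min_frames:
        raise ProtocolError(f"Mn_quench window has {n} frames; need >= {min_frames}")
    return {ch: _window_mean(expt, ch, QUENCH_LABEL) for ch in expt.channels}


def _ratio(expt: FluorescenceExperiment, background: dict, mask=None) -> np.ndarray:
    """Background-subtracted F340/F380 ratio (negative frames retained)."""
    sel = slice(None) if mask is None else mask
    f340 = expt.channels["F340"][sel] - background["F340"]
    f380 = expt.channels["F380"][sel] - background["F380"]
    return f340 / f380


def derive_calibration(expt: FluorescenceExperiment, background: dict | None = None,
                       k_d: float = 225.0) -> CalibrationConstants:
    """Calibration constants from the 0 mM and 10 mM Ca2+ plateaus.

    Window statistics are means of the background-subtracted signals.
    Raises CalibrationError when the windows are inconsistent
    (r_max <= r_min), e.g. because they were swapped.
    """
    for label in (ZERO_CA_LABEL, SAT_CA_LABEL):
        if label not in expt.events:
            raise ProtocolError(f"missing calibration window {label!r}")
    if not expt.is_ratiometric:
        raise AnalysisError("calibration requires F340/F380 channels")
    background = background or estimate_background(expt)
    m0 = expt.window_mask(ZERO_CA_LABEL)
    m1 = expt.window_mask(SAT_CA_LABEL)
    f380_min = float(np.mean(expt.channels["F380"][m0]) - background["F380"])
    f380_max = float(np.mean(expt.channels["F380"][m1]) - background["F380"])
    r_min = float(np.mean(_ratio(expt, background, m0)))
    r_max = float(np.mean(_ratio(expt, background, m1)))
    if r_max <= r_min:
        raise CalibrationError(
            f"r_max ({r_max:.3f}) <= r_min ({r_min:.3f}): calibration windows "
            "inconsistent (swapped or failed permeabilisation?)"
        )
    return CalibrationConstants(k_d=k_d, r_min=r_min, r_max=r_max,
                                f380_min=f380_min, f380_max=f380_max)


def fura2_concentration(r, cal: CalibrationConstants, qc_notes: list | None = None):
    """[Ca2+] in nM from a background-subtracted F340/F380 ratio.

    Ratios below r_min are clipped to 0 nM with a QC note (noise can push a
    resting cell below the 0-Ca plateau); ratios at or above r_max raise
    SaturationError (the relation diverges there).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr >= cal.r_max):
        raise SaturationError(
            f"ratio >= r_max ({cal.r_max:.3f}): dye saturated, concentration undefined"
        )
    below = r_arr < cal.r_min
    if np.any(below) and qc_notes is not None:
        qc_notes.append("ratio below r_min clipped to 0 nM")
    r_eff = np.where(below, cal.r_min, r_arr)
    ca = cal.k_d * cal.beta * (r_eff - cal.r_min) / (cal.r_max - r_eff)
    return float(ca) if ca.ndim == 0 else ca


def viability_gate(expt: FluorescenceExperiment, threshold_sd: float = 5.0,
                   background: dict | None = None) -> bool:
    """KCl viability gate.

    A cell is viable iff the peak change of the F340/F380 ratio inside the
    KCl window is at least ``threshold_sd`` times the SD of the ratio over
    the resting baseline immediately before KCl (>= comparison, so an
    exactly-threshold response passes).
    """
    if KCL_LABEL not in expt.events:
        raise ProtocolError("no KCl window: viability cannot be assessed")
    background = background or estimate_background(expt)
    t_kcl = expt.events[KCL_LABEL][0]
    base_mask = (expt.frame_times >= t_kcl - RESTING_WINDOW_S) & (expt.frame_times < t_kcl)
    if not np.any(base_mask):
        raise ProtocolError("no pre-KCl baseline frames")
    r_base = _ratio(expt, background, base_mask)
    r_kcl = _ratio(expt, background, expt.window_mask(KCL_LABEL))
    sd = float(np.std(r_base))
    if sd == 0.0:
        return bool(np.max(np.abs(r_kcl - np.mean(r_base))) > 0)
    peak_change = float(np.max(np.abs(r_kcl - np.mean(r_base))))
    return peak_change >= threshold_sd * sd


def resting_calcium(expt: FluorescenceExperiment,
                    cal: CalibrationConstants | None = None,
                    threshold_sd: float = 5.0) -> CalciumResult:
    """Resting [Ca2+]_i from the 10 s window before the KCl application.

    Runs the full per-cell pipeline: quench background, viability gate,
    calibration (derived from the experiment's own plateaus unless given),
    mean background-subtracted ratio over the resting window, ratiometric
    conversion.  A cell failing the gate carries no concentration.
    """
    qc: list = []
    background = estimate_background(expt)
    viable = viability_gate(expt, threshold_sd=threshold_sd, background=background)
    if not viable:
        qc.append("no KCl response: excluded from resting [Ca2+]_i")
        return CalciumResult(resting_ca=None, viability=False, background=background,
                             cell_id=expt.cell_id, condition=expt.condition, qc_notes=qc)
    cal = cal or derive_calibration(expt, background=background)
    t_kcl = expt.events[KCL_LABEL][0]
    mask = (expt.frame_times >= t_kcl - RESTING_WINDOW_S) & (expt.frame_times < t_kcl)
    if not np.any(mask):
        raise ProtocolError("no resting window before KCl")
    r_rest = float(np.mean(_ratio(expt, background, mask)))
    ca = fura2_concentration(r_rest, cal, qc_notes=qc)
    return CalciumResult(resting_ca=ca, viability=True, background=background,
                         calibration=cal, cell_id=expt.cell_id,
                         condition=expt.condition, qc_notes=qc)


def og_ratio(expt: FluorescenceExperiment, stat: str = "peak",
             background: dict | None = None) -> float:
    """Single-channel F_GABA/F_KCl response ratio.

    Responses are background-subtracted peak (default) or window-mean
    fluorescence inside the GABA and KCl windows.
    """
    if expt.is_ratiometric:
        raise AnalysisError("F_GABA/F_KCl requires a single-channel experiment")
    for label in (GABA_LABEL, KCL_LABEL):
        if label not in expt.events:
            raise ProtocolError(f"missing {label!r} window")
    if stat not in ("peak", "mean"):
        raise AnalysisError("stat must be 'peak' or 'mean'")
    background = background or estimate_background(expt)
    b = background["F"]
    reducer = np.max if stat == "peak" else np.mean
    f_gaba = float(reducer(expt.channels["F"][expt.window_mask(GABA_LABEL)])) - b
    f_kcl = float(reducer(expt.channels["F"][expt.window_mask(KCL_LABEL)])) - b
    if f_kcl <= 0:
        raise AnalysisError("non-positive KCl response: F_GABA/F_KCl undefined")
    return max(f_gaba, 0.0) / f_kcl


class CalciumAnalysis:
    """Model object for one imaged cell.

    ``mode="fura2"`` yields resting [Ca2+]_i via the ratiometric pipeline;
    ``mode="og"`` yields the F_GABA/F_KCl response ratio of a single-channel
    experiment.
    """

    def __init__(self, experiment: FluorescenceExperiment, mode: str = "fura2",
                 threshold_sd: float = 5.0, og_stat: str = "peak",
                 calibration: CalibrationConstants | None = None):
        if mode not in ("fura2", "og"):
            raise AnalysisError(f"unknown mode {mode!r}")
        self.experiment = experiment
        self.mode = mode
        self.threshold_sd = threshold_sd
        self.og_stat = og_stat
        self.calibration = calibration

    def fit(self):
        if self.mode == "fura2":
            return resting_calcium(self.experiment, cal=self.calibration,
                                   threshold_sd=self.threshold_sd)
        ratio = og_ratio(self.experiment, stat=self.og_stat)
        background = estimate_background(self.experiment)
        res = CalciumResult(resting_ca=None, viability=True, background=background,
                            cell_id=self.experiment.cell_id,
                            condition=self.experiment.condition,
                            qc_notes=[f"F_GABA/F_KCl = {ratio:.4f} ({self.og_stat})"])
        res.og_ratio = ratio
        return res
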