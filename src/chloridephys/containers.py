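"""In-memory data containers shared by the simulator and the analyses."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigError
from .params import ProtocolSpec


@dataclass
class Recording:
    """A multi-sweep clamped time series plus its protocol.

    ``sweeps`` hold the recorded signal (pA in voltage clamp, mV in current
    clamp); ``command`` is the per-sample command trace of one sweep (mV in
    voltage clamp, pA in current clamp) shared by all sweeps; ``time_base``
    is the within-sweep time axis in seconds.  Sweep *s* starts at global
    time ``s * protocol.inter_ramp_interval``.  ``aux`` carries simulation
    ground truth (e.g. the intracellular chloride trajectory under key
    ``"cl_in"``, a list of per-sweep arrays) and is not serialised.
    """

    sweeps: list
    command: np.ndarray
    time_base: np.ndarray
    protocol: ProtocolSpec
    cell_id: str = ""
    condition: str = ""
    seed: int | None = None
    aux: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # unknown sidecar keys, preserved

    def __post_init__(self):
        self.command = np.asarray(self.command, dtype=float)
        self.time_base = np.asarray(self.time_base, dtype=float)
        self.sweeps = [np.asarray(s, dtype=float) for s in self.sweeps]
        n = self.command.size
        if self.time_base.size != n:
            raise ConfigError("time_base and command must have equal length")
        for i, s in enumerate(self.sweeps):
            if s.size != n:
                raise ConfigError(f"sweep {i} length {s.size} != command length {n}")
        dt = np.diff(self.time_base)
        if n > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9)):
            raise ConfigError("time_base must be strictly increasing and uniform")

    @property
    def mode(self) -> str:
        return self.protocol.mode

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def dt(self) -> float:
        return 1.0 / self.protocol.sampling_rate

    def sweep_start(self, s: int) -> float:
        return s * self.protocol.inter_ramp_interval

    def flat(self) -> np.ndarray:
        """All sweeps concatenated in acquisition order."""
        return np.concatenate(self.sweeps)

    def flat_times(self) -> np.ndarray:
        return np.concatenate(
            [self.time_base + self.sweep_start(s) for s in range(self.n_sweeps)]
        )


@dataclass
class FluorescenceExperiment:
    """One imaged cell: fluorescence channels plus annotated event windows.

    ``channels`` maps channel names to sample arrays: ``{"F340", "F380"}``
    for ratiometric fura-2, ``{"F"}`` for single-channel (Oregon-Green-like)
    experiments.  ``events`` maps labels (``KCl``, ``GABA``,
    ``ionomycin_0Ca``, ``ionophore_10Ca``, ``Mn_quench``) to (t0, t1) in
    seconds.  ``true_ca`` (nM) is present on simulated experiments only.
    """

    frame_times: np.ndarray
    channels: dict
    events: dict = field(default_factory=dict)
    true_ca: np.ndarray | None = None
    cell_id: str = ""
    condition: str = ""
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        n = self.frame_times.size
        for name, ch in self.channels.items():
            if ch.size != n:
                raise ConfigError(f"channel {name!r} length != frame count")
            if np.any(ch < 0):
                raise ConfigError(f"channel {name!r} has negative fluorescence")
        if self.true_ca is not None:
            self.true_ca = np.asarray(self.true_ca, dtype=float)
        t0g, t1g = self.frame_times[0], self.frame_times[-1]
        for label, (t0, t1) in self.events.items():
            if t1 <= t0:
                raise ConfigError(f"event {label!r} has t_end <= t_start")
            if t0 < t0g - 1e-9 or t1 > t1g + 1e-9:
                raise ConfigError(f"event {label!r} lies outside the trace")

    @property
    def is_ratiometric(self) -> bool:
        return "F340" in self.channels and "F380" in self.channels

    def window_mask(self, label: str) -> np.ndarray:
        if label not in self.events:
            raise KeyError(label)
        t0, t1 = self.events[label]
        return (self.frame_times >= t0) & (self.frame_times <= t1)


@dataclass
class IVCurve:
    """Current-voltage relation extracted from voltage ramps."""

    voltages: np.ndarray   # mV, strictly increasing
    currents: np.ndarray   # pA
    source: str = "basal"  # basal | gaba | subtracted
    n_ramps_averaged: int = 1

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.size != self.currents.size:
            raise ConfigError("voltages and currents must have equal length")
        if self.voltages.size >= 2 and np.any(np.diff(self.voltages) <= 0):
            raise ConfigError("voltages must be strictly increasing")
        if self.source not in ("basal", "gaba", "subtracted"):
            raise ConfigError(f"unknown IV source {self.source!r}")


@dataclass
class MembraneProperties:
    """Per-cell intrinsic membrane properties.

    driving_force = e_gaba - v_rev is enforced (to 1e-9 mV) whenever both
    reversals are present.
    """

    r_n: float | None = None          # MOhm
    v_rev: float | None = None        # mV
    e_gaba: float | None = None       # mV
    driving_force: float | None = None
    v_m: float | None = None          # mV (current clamp)
    junction_corrected: bool = False
    cell_id: str = ""
    condition: str = ""
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.r_n is not None and self.r_n <= 0:
            raise ConfigError("r_n must be positive")
        if self.v_rev is not None and self.e_gaba is not None:
            df = self.e_gaba - self.v_rev
            if self.driving_force is None:
                self.driving_force = df
            elif abs(self.driving_force - df) > 1e-9:
                raise ConfigError("driving_force inconsistent with e_gaba - v_rev")

    def replace(self, **kw) -> "MembraneProperties":
        return dataclasses.replace(self, **kw)


@dataclass
class CalibrationConstants:
    """Ratiometric fura-2 calibration constants.

    k_d is the dissociation constant of the fura-2/Ca2+ complex (225 nM);
    r_min / r_max are the F340/F380 ratios at 0 and saturating Ca2+;
    f380_min / f380_max the 380-nm fluorescence of free (0 mM) and bound
    (10 mM) dye.
    """

    k_d: float = 225.0
    r_min: float = 0.3
    r_max: float = 3.0
    f380_min: float = 200.0
    f380_max: float = 80.0

    def __post_init__(self):
        if self.k_d <= 0:
            raise CalibrationError("k_d must be positive")
        if not (self.r_max > self.r_min > 0):
            raise CalibrationError(
                f"need r_max > r_min > 0 (got r_min={self.r_min}, r_max={self.r_max})"
            )
        if self.f380_min <= 0 or self.f380_max <= 0:
            raise CalibrationError("f380 values must be positive")

    @property
    def beta(self) -> float:
        """Ratio of free to bound 380-nm fluorescence, F380_min / F380_max."""
        return self.f380_min / self.f380_max

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
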