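"""Reproducible simulate -> analyze -> stats pipeline.

A RunConfig fully determines a run: identical config + seed give
byte-identical output tables (no timestamps are written).  The default
configuration contrasts control neurons with neurons under enduring tonic
GlyR chloride conductance ("185L"), plus a KCC2 co-expression arm in the
survival stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import MembraneProperties
from .ephys_sim import GABA_LABEL, simulate_voltage_clamp
from .errors import ConfigError
from .fluor_sim import make_fura_experiment
from .imaging import CalciumAnalysis
from .io import write_properties, write_recording, write_survival
from .params import CONDITION_PRESETS, CellParams, ProtocolSpec, draw_cohort, get_preset
from .ramp import RampAnalysis
from .survival import SurvivalAnalysis
from .survival_sim import generate_survival_counts


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  All fields have working defaults."""

    seed: int = 0
    # electrophysiology stage
    ephys_conditions: list = field(default_factory=lambda: ["control", "185L"])
    n_cells_ephys: int = 4
    n_sweeps: int = 6
    noise_sd: float = 5.0            # pA
    gaba_window: tuple = (16.0, 17.5)  # global s; brief application, one full ramp
    cell_overrides: dict = field(default_factory=dict)  # condition -> CellParams fields
    # imaging stage
    n_cells_imaging: int = 5
    resting_ca_mean: float = 80.0    # nM
    resting_ca_sd: float = 15.0
    imaging_noise_sd: float = 2.0
    # survival stage
    survival_fractions: dict = field(default_factory=lambda: {
        "control": 0.92, "185L": 0.46, "185L+KCC2wt": 0.88,
    })
    control_condition: str = "control"
    cells_per_culture: int = 200
    n_cultures: int = 6
    # analysis options
    smooth: int = 11
    threshold_sd: float = 5.0
    junction_correct: bool = False
    write_recordings: bool = False

    def cell_for(self, condition: str) -> CellParams:
        base = get_preset(condition)
        over = self.cell_overrides.get(condition)
        return base.replace(**over) if over else base

    def validate(self):
        """Raise ConfigError on any inconsistency, before any compute."""
        for cond in self.ephys_conditions:
            if cond not in CONDITION_PRESETS and cond not in self.cell_overrides:
                raise ConfigError(f"ephys condition {cond!r} has no parameter set")
            self.cell_for(cond) if cond in CONDITION_PRESETS else None
        for cond, p in self.survival_fractions.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"survival fraction for {cond!r} outside [0, 1]")
        if self.control_condition not in self.survival_fractions:
            raise ConfigError(
                f"control condition {self.control_condition!r} missing from "
                "survival_fractions"
            )
        if self.n_cells_ephys < 1 or self.n_cells_imaging < 1:
            raise ConfigError("cell counts must be >= 1")
        t0, t1 = self.gaba_window
        if t1 <= t0:
            raise ConfigError("gaba_window end must exceed start")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gaba_window"] = list(d["gaba_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "gaba_window" in d:
            d["gaba_window"] = tuple(d["gaba_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def default_protocol(config: RunConfig) -> ProtocolSpec:
    t0, t1 = config.gaba_window
    return ProtocolSpec(n_sweeps=config.n_sweeps,
                        application_windows=[(GABA_LABEL, t0, t1)])


def run_ephys_stage(config: RunConfig, outdir: Path) -> dict:
    protocol = default_protocol(config)
    props: list[MembraneProperties] = []
    excluded = []
    seeds = _child_seeds(config.seed + 1, len(config.ephys_conditions))
    for cond, cond_seed in zip(config.ephys_conditions, seeds):
        cells = draw_cohort(config.cell_for(cond), config.n_cells_ephys, int(cond_seed))
        cell_seeds = _child_seeds(int(cond_seed) + 1, len(cells))
        for i, (cell, s) in enumerate(zip(cells, cell_seeds)):
            cell_id = f"{cond}_{i:02d}"
            rec = simulate_voltage_clamp(cell, protocol, noise_sd=config.noise_sd,
                                         seed=int(s), cell_id=cell_id, condition=cond)
            if config.write_recordings:
                write_recording(rec, outdir / "recordings" / cell_id)
            res = RampAnalysis(rec, smooth=config.smooth,
                               junction_correct=config.junction_correct).fit()
            if res.excluded:
                excluded.append(cell_id)
            else:
                props.append(res.properties)
    write_properties(props, outdir / "membrane_properties.csv")
    return {"n_cells": len(props), "excluded": excluded}


def run_imaging_stage(config: RunConfig, outdir: Path) -> dict:
    import pandas as pd

    rng = np.random.default_rng(config.seed + 2)
    seeds = _child_seeds(config.seed + 3, config.n_cells_imaging)
    rows = []
    for i, s in enumerate(seeds):
        ca_true = max(5.0, float(rng.normal(config.resting_ca_mean,
                                            config.resting_ca_sd)))
        expt = make_fura_experiment(resting_ca=ca_true,
                                    noise_sd=config.imaging_noise_sd,
                                    seed=int(s), cell_id=f"cell_{i:02d}")
        res = CalciumAnalysis(expt, mode="fura2",
                              threshold_sd=config.threshold_sd).fit()
        rows.append({"cell_id": res.cell_id, "viable": res.viability,
                     "resting_ca_nM": res.resting_ca, "true_ca_nM": ca_true})
    pd.DataFrame(rows).to_csv(outdir / "calcium.csv", index=False,
                              float_format="%.17g")
    return {"n_cells": len(rows)}


def run_survival_stage(config: RunConfig, outdir: Path) -> dict:
    table = generate_survival_counts(
        config.survival_fractions, cells_per_culture=config.cells_per_culture,
        n_cultures=config.n_cultures, seed=config.seed + 4,
    )
    write_survival(table, outdir / "survival_counts.csv")
    res = SurvivalAnalysis(table, config.control_condition).fit()
    res.comparisons.to_csv(outdir / "survival_comparisons.csv", index=False,
                           float_format="%.17g")
    res.condition_summary.to_csv(outdir / "survival_summary.csv", index=False,
                                 float_format="%.17g")
    (outdir / "survival_report.txt").write_text(res.summary() + "\n")
    return {"n_conditions": len(config.survival_fractions),
            "anova_p": res.anova.p_value}


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute simulate -> ramp/ca analysis -> stats and write a manifest.

    Any stage failure halts the run with the stage name in the exception.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    stages = {}
    for name, stage in (("ephys", run_ephys_stage),
                        ("imaging", run_imaging_stage),
                        ("survival", run_survival_stage)):
        try:
            stages[name] = stage(config, outdir)
        except Exception as exc:
            raise type(exc)(f"stage {name!r} failed: {exc}") from exc
    manifest = {
        "package": "chloridephys",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return outdir
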