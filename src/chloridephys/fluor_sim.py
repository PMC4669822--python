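"""Forward models of fura-2 ratiometric and single-channel Ca2+ imaging.

The fura-2 generator inverts the ratiometric calibration relation

    [Ca2+] = K_D * (F380_min / F380_max) * (R - R_min) / (R_max - R)

to produce F340/F380 channel pairs from a prescribed calcium trace, appends
the 0 mM and 10 mM calibration plateaus (treated as the exact free/bound
limits of the dye - 10 mM is 4.4e4 times K_D) and a Mn2+ quench tail whose
signal is pure background, then adds per-channel background and Gaussian
noise.  The single-channel (Oregon-Green-like) generator emits fluorescence
proportional to a saturating function of calcium.
"""

from __future__ import annotations

import numpy as np

from .containers import CalibrationConstants, FluorescenceExperiment
from .errors import ConfigError

FURA2 = "fura2"
SINGLE_CHANNEL = "single_channel"

CA_SATURATING_NM = 1.0e7  # 10 mM plateau, nM


def fura_ratio_from_ca(ca_nm, cal: CalibrationConstants):
    """Invert the calibration: F340/F380 ratio produced by [Ca2+] in nM."""
    ca = np.asarray(ca_nm, dtype=float)
    if np.any(ca < 0):
        raise ConfigError("calcium concentrations must be >= 0")
    s = ca / (cal.k_d * cal.beta)
    r = (cal.r_min + cal.r_max * s) / (1.0 + s)
    return float(r) if r.ndim == 0 else r


def fura_f380_from_ca(ca_nm, cal: CalibrationConstants):
    """380-nm fluorescence: free-dye value at 0 Ca relaxing to the bound value."""
    ca = np.asarray(ca_nm, dtype=float)
    f = (cal.f380_min * cal.k_d + cal.f380_max * ca) / (cal.k_d + ca)
    return float(f) if f.ndim == 0 else f


def simulate_fluorescence(ca_trace, dye: str = FURA2,
                          cal: CalibrationConstants | None = None,
                          background=(50.0, 40.0), noise_sd: float = 0.0,
                          seed: int = 0, frame_rate: float = 1.0,
                          events: dict | None = None,
                          append_calibration: bool = True,
                          plateau_duration: float = 20.0,
                          quench_duration: float = 20.0,
                          og_gain: float = 400.0, og_k_half: float = 10_000.0,
                          cell_id: str = "", condition: str = "") -> FluorescenceExperiment:
    """Generate a FluorescenceExperiment from a prescribed calcium trace (nM).

    Parameters
    ----------
    ca_trace : array-like
        Physiological [Ca2+]_i samples at ``frame_rate`` Hz, nM.
    dye : "fura2" or "single_channel"
    background : (b340, b380) for fura-2, scalar (or 1-tuple) otherwise.
        Added to every frame; the Mn2+ quench tail contains background only,
        so its mean recovers the injected value.
    events : dict label -> (t0, t1)
        Windows (KCl, GABA, ...) on the physiological portion; calibration
        and quench windows are appended automatically.
    """
    cal = cal or CalibrationConstants()
    ca = np.asarray(ca_trace, dtype=float)
    if np.any(ca < 0):
        raise ConfigError("ca_trace must be >= 0")
    if dye not in (FURA2, SINGLE_CHANNEL):
        raise ConfigError(f"unknown dye {dye!r}")
    rng = np.random.default_rng(seed)
    events = dict(events or {})
    n_phys = ca.size
    dt = 1.0 / frame_rate
    n_plateau = int(round(plateau_duration * frame_rate))
    n_quench = int(round(quench_duration * frame_rate))

    if dye == FURA2:
        b340, b380 = background
        seg_ca = [ca]
        seg_r = [fura_ratio_from_ca(ca, cal)]
        seg_f380 = [fura_f380_from_ca(ca, cal)]
        if append_calibration:
            # exact free / fully-bound plateaus
            seg_ca += [np.zeros(n_plateau), np.full(n_plateau, CA_SATURATING_NM)]
            seg_r += [np.full(n_plateau, cal.r_min), np.full(n_plateau, cal.r_max)]
            seg_f380 += [np.full(n_plateau, cal.f380_min), np.full(n_plateau, cal.f380_max)]
        # quench: dye signal fully quenched, background only
        seg_ca += [np.full(n_quench, np.nan)]
        seg_r += [np.zeros(n_quench)]
        seg_f380 += [np.zeros(n_quench)]

        r_sig = np.concatenate(seg_r)
        f380_sig = np.concatenate(seg_f380)
        true_ca = np.concatenate(seg_ca)
        n = r_sig.size
        f380 = f380_sig + b380 + (rng.normal(0.0, noise_sd, n) if noise_sd else 0.0)
        f340 = r_sig * f380_sig + b340 + (rng.normal(0.0, noise_sd, n) if noise_sd else 0.0)
        channels = {"F340": np.clip(f340, 0.0, None), "F380": np.clip(f380, 0.0, None)}
        offset = n_phys * dt
        if append_calibration:
            events["ionomycin_0Ca"] = (offset, offset + (n_plateau - 1) * dt)
            offset += n_plateau * dt
            events["ionophore_10Ca"] = (offset, offset + (n_plateau - 1) * dt)
            offset += n_plateau * dt
        events["Mn_quench"] = (offset, offset + (n_quench - 1) * dt)
    else:
        b = background[0] if np.ndim(background) else float(background)
        f_sig = og_gain * ca / (ca + og_k_half)
        f_sig = np.concatenate([f_sig, np.zeros(n_quench)])
        true_ca = np.concatenate([ca, np.full(n_quench, np.nan)])
        n = f_sig.size
        f = f_sig + b + (rng.normal(0.0, noise_sd, n) if noise_sd else 0.0)
        channels = {"F": np.clip(f, 0.0, None)}
        offset = n_phys * dt
        events["Mn_quench"] = (offset, offset + (n_quench - 1) * dt)

    frame_times = np.arange(n) * dt
    return FluorescenceExperiment(
        frame_times=frame_times, channels=channels, events=events,
        true_ca=true_ca, cell_id=cell_id, condition=condition, seed=seed,
    )


def make_fura_experiment(resting_ca: float = 80.0, kcl_ca: float = 600.0,
                         rest_duration: float = 40.0, kcl_duration: float = 20.0,
                         cal: CalibrationConstants | None = None,
                         background=(50.0, 40.0), noise_sd: float = 2.0,
                         seed: int = 0, frame_rate: float = 1.0,
                         cell_id: str = "", condition: str = "") -> FluorescenceExperiment:
    """Canonical ratiometric experiment: rest, 50 mM KCl viability challenge,
    calibration plateaus and Mn2+ quench.

    ``resting_ca`` defaults to the ~80 nM resting level of healthy cultured
    hippocampal neurons; the KCl depolarisation raises calcium well above
    baseline so a responsive cell passes the viability gate.
    """
    n_rest = int(round(rest_duration * frame_rate))
    n_kcl = int(round(kcl_duration * frame_rate))
    ca = np.concatenate([np.full(n_rest, resting_ca), np.full(n_kcl, kcl_ca)])
    events = {"KCl": (rest_duration, rest_duration + kcl_duration - 0.5 / frame_rate)}
    return simulate_fluorescence(
        ca, dye=FURA2, cal=cal, background=background, noise_sd=noise_sd,
        seed=seed, frame_rate=frame_rate, events=events,
        cell_id=cell_id, condition=condition,
    )


def make_og_experiment(gaba_ca: float = 230.0, kcl_ca: float = 1000.0,
                       baseline_ca: float = 80.0, noise_sd: float = 1.0,
                       seed: int = 0, frame_rate: float = 3.0,
                       background: float = 30.0, og_gain: float = 400.0,
                       og_k_half: float = 10_000.0,
                       cell_id: str = "", condition: str = "") -> FluorescenceExperiment:
    """Canonical single-channel experiment: baseline, GABA response, recovery,
    KCl response, quench."""
    seg = lambda dur, level: np.full(int(round(dur * frame_rate)), level)
    ca = np.concatenate([
        seg(20.0, baseline_ca), seg(10.0, gaba_ca), seg(20.0, baseline_ca),
        seg(10.0, kcl_ca), seg(10.0, baseline_ca),
    ])
    events = {"GABA": (20.0, 30.0 - 0.5 / frame_rate),
              "KCl": (50.0, 60.0 - 0.5 / frame_rate)}
    return simulate_fluorescence(
        ca, dye=SINGLE_CHANNEL, background=background, noise_sd=noise_sd,
        seed=seed, frame_rate=frame_rate, events=events, og_gain=og_gain,
        og_k_half=og_k_half, cell_id=cell_id, condition=condition,
    )
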