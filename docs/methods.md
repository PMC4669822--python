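# Methods

## Biophysical model

The simulator is a single-compartment (point) neuron in which the membrane
carries three conductances and the intracellular chloride concentration is a
state variable:

- a lumped leak `g_leak` with reversal `E_leak` (mostly K⁺; it absorbs every
  non-chloride pathway),
- a tonic glycine-receptor chloride conductance `g_glyr` (constitutively open
  when the condition models enduring receptor activation),
- a GABA_A chloride conductance `g_gaba_max` that is open only inside
  annotated application windows (agonist wash-in is fast relative to the
  analysed signals, so the conductance steps on and off instantaneously).

Chloride currents use the Nernst potential
`E_Cl = (RT/F)·ln([Cl]ᵢ/[Cl]ₒ)` (negative when the cell contains less
chloride than the bath).  Intracellular chloride integrates the channel flux
plus first-order transporter terms:

```
d[Cl]ᵢ/dt = 1000·I_Cl/(F·V)  +  k_KCC2·(c_KCC2 − [Cl]ᵢ)  +  k_NKCC1·(c_NKCC1 − [Cl]ᵢ)
```

with `I_Cl` in pA (outward-positive conventional current, i.e. Cl⁻ influx),
`V` the effective volume in pL, and the transporters modelled functionally as
relaxations toward a low extrusion target (`c_KCC2`, default 5 mM) and a high
import target (`c_NKCC1`, default 40 mM) — the data this package analyses
characterise transport by its effect on E_GABA, not kinetically, so
first-order relaxation is the simplest adequate description.

In voltage clamp the membrane potential follows the command exactly (no
series-resistance error is modelled); in current clamp
`dV/dt = −(ΣI − I_inj)/C`.  Under a sustained −50 mV clamp, chloride relaxes
until `E_Cl` reaches the holding potential — the mechanism that collapses the
GABA driving force of tonically conducting cells.  After switching to current
clamp the potential first jumps to the conductance-weighted mean of the open
reversals and then drifts on the slow timescale set by volume, conductance
and transport, reproducing the slow apparent-V_m adaptation of such
recordings.

### Integration and acquisition emulation

Integration is fixed-step forward Euler on the acquisition sample grid
(10 kHz by default), so simulated traces align sample-for-sample with the
`Recording` container.  A stability guard rejects steps larger than 20% of
the fastest time constant (membrane τ = C/g in current clamp; chloride
feedback and transporter rates in both modes) with an explicit
`SimulationError` rather than silent divergence.  Gaussian current noise and
a single-pole low-pass at the 2.8 kHz acquisition cutoff are applied to the
*recorded* copy of the signal only; chloride bookkeeping integrates the
noiseless physical current, which makes the conservation identity
`Δ[Cl]·V·F = ∫I_Cl dt + transporter fluxes` exact to integrator precision
(a property the test suite checks at 10⁻⁶ relative).

### Default parameters

| parameter | default | basis |
|---|---|---|
| holding / pulse / ramp | −50 mV, −5 mV, −100→−30 mV in 140 ms every 5 s | the recording protocol being modelled |
| sampling / filter | 10 kHz / 2.8 kHz single-pole | acquisition settings being modelled |
| [Cl]ₒ | 151 mM | summed chloride of the standard bath solution |
| control `g_leak`, `E_leak`, [Cl]ᵢ | 2.33 nS, −63.6 mV, 15 mM | anchored to the measured control R_N (429 MΩ), V_rev and E_GABA (≈−58.7 mV) |
| 185L `g_glyr`, `E_leak`, [Cl]ᵢ | 6.93 nS, −52.1 mV, 21.1 mM | total conductance matches the measured shunted R_N (108 MΩ); chloride equilibrated to the −50 mV holding potential; the depolarised leak reversal represents the reported long-lasting intrinsic change |
| capacitance, volume, temperature | 80 pF, 2 pL, 295 K | assumptions typical of cultured hippocampal somata at room temperature; not fits |
| transporter rates | ≤0.01 s⁻¹ | assumptions; chosen so the transporter fixed point reproduces each preset's resting [Cl]ᵢ |
| noise | 5 pA SD | typical perforated-patch baseline noise |

Cohort draws add lognormal scatter (10% CV on conductances, 2 mV SD on
`E_leak`, 8% CV on chloride) emulating the between-cell spread of the
measured summary statistics.

## Ramp analysis

`R_N` is the pulse amplitude over the mean steady current deflection (last
30% of the pulse, a window comfortably longer than the filter time constant,
minus the pre-pulse baseline), averaged over pulses outside agonist
applications.  IV curves map each ramp sample to its command voltage and
average all qualifying ramps point-wise; a ramp belongs to `IV_GABA` when its
full 140 ms lies inside a GABA window and to `IV_bas` when it overlaps no
application window.  Reversals are located by linear interpolation between
the two samples bracketing a sign change after light smoothing (11-sample
moving average; curves shorter than twice the window are left unsmoothed).
When several crossings survive smoothing the one nearest the holding
potential is reported and the result flagged ambiguous — the physiologically
expected root under a −50 mV clamp.  Potentials are reported uncorrected for
the +3.75 mV liquid junction potential by default (the correction is an
explicit, once-only operation that leaves the driving force unchanged).

Rupture of the perforated patch (transition to whole-cell, which the
high-chloride pipette solution turns into a large abrupt baseline shift) is
detected on holding-epoch samples against a 1-s lagged running median:
deviations above 5 high-frequency baseline SDs sustained for 50 ms flag the
recording, which is then excluded, never imputed.  The lagged reference makes
the detector insensitive to slow physiological drift of the holding current
(e.g. transporter-driven chloride creep).  The SD estimate is floored at
0.5 pA so that noiseless synthetic recordings are not flagged on numerical
residue.

## Calcium imaging

Background is the per-channel mean over the Mn²⁺-quench window and is
subtracted from all F340/F380 values; post-subtraction negative frames are
retained (clipping would bias window means).  Calibration constants come from
the 0 mM and 10 mM plateau means; the forward model treats those plateaus as
the exact free/bound limits of the dye — at 10 mM ≈ 4.4·10⁴ × K_D the
deviation from the true limit is O(K/c) ≈ 10⁻⁴ and would otherwise dominate
the round-trip error budget.  Cells must respond to 50 mM KCl (peak ratio
change ≥ 5 baseline SDs, a `≥` comparison so an exactly-threshold response
passes) to enter the resting-[Ca²⁺] estimate, which is the mean
background-subtracted ratio over the 10 s before KCl converted through the
ratiometric relation.  Ratios below `R_min` clip to 0 nM with a QC note
(noise can push resting cells below the 0-Ca plateau); ratios at or above
`R_max` raise, because the relation diverges there.  Window statistics are
means, matching the fluorescence-value convention of the procedure modelled;
single-channel F_GABA/F_KCl uses background-subtracted peaks by default with
window means as an option.

## Survival statistics

The culture, not the neuron, is the experimental unit: each culture
contributes one vital fraction per condition, and at least three cultures per
condition are required for inference.  Displayed values are normalised per
culture to the control condition (control ≡ 1.0).  Inference (one-way ANOVA
followed by Tukey's HSD, Tukey–Kramer SE for unbalanced designs, studentized
range p-values, stars at strict 0.05/0.01/0.001) runs on the **raw**
per-culture fractions: after per-culture ratio normalisation the reference
condition has zero within-group variance and all other groups share its
denominator, which deflates the pooled error term, correlates the groups and
inflates the family-wise error of the post-hoc comparisons above its nominal
level.  Keeping normalisation as a reporting scale and inference on raw
fractions preserves both the familiar display and the error guarantee
(verified by null simulation in the test suite); `scale="normalized"` remains
available for comparison.  Both statistics are implemented long-hand
(explicit sums of squares, studentized-range survival function) and are
cross-checked in the tests against independent routines to 10⁻⁸.

## What the generator does and does not emulate

The generator reproduces the *structure* the analyses assume: clamp
protocols on a sample grid, conductance currents with dynamic chloride,
calibration plateaus and quench tails, binomial survival counts.  It does
not model space (no dendrites), receptor gating or desensitisation kinetics,
series resistance or capacitance transients, bicarbonate permeation (the
modelled solutions are CO₂/HCO₃⁻-free, so GABA_A current is pure Cl⁻),
voltage-gated calcium dynamics (the imaging calcium trace is prescribed, not
emergent), dye bleaching, or between-culture overdispersion of survival
counts.  Passing tests therefore demonstrate correctness of the analysis
chain under these idealised conditions, not robustness to every artefact of
real recordings.

## Problem sizes

The bundled pipeline and the acceptance script use cohorts of 4–6 cells with
six 5-s sweeps per recording, 50 cells for the noise-recovery estimate, and
200 / 1000 replicates for the survival power / family-wise-error estimates —
sizes at which every reported quantity is stable to well within its
acceptance margin while a full run completes in about a minute on one CPU.
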