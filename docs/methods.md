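# Methods

`clc4pipe` couples a phenomenological simulator of whole-cell recordings from
cells expressing CLC-type Cl⁻/H⁺ exchangers (ClC-4 and its disease-associated
variants) with the analysis pipeline used to characterize such recordings:
P/8 leak subtraction, steady-state current and off-gating charge measurement,
Boltzmann activation fits, transport-efficiency statistics, colocalization and
gel densitometry, and gated group statistics. This note documents the model,
its assumptions, the numerical choices, and what the synthetic data do and do
not establish about real recordings.

## Whole-cell model

Each simulated cell superimposes a nonlinear transporter on a linear passive
subsystem, sampled at the protocol's rate (default 100 kHz) with additive
Gaussian noise per sample.

**Transporter.** Activation is a two-state Boltzmann gate

    p∞(V) = 1 / (1 + exp(−(V − V½)/k)),

relaxing mono-exponentially toward `p∞(V)` with τ_act = 1 ms at every
potential. The steady transport current is

    I_ss(V) = I_max · p∞(V) · r(V),      r(V) = 1 / (1 + exp(−V/V_rect)),

where `r` is a soft outward rectifier (V_rect = 35 mV by default) and
`I_max = i_max_density · expr_scale · surface_fraction · c`, with `c` a
per-cell lognormal expression factor (σ_ln = 0.5). On return to the holding
potential after a prepulse to V, an off-gating charge

    Q_off(V) = Q_max · (p∞(V) − p∞(V_hold))

flows as a single exponential with τ_off = 0.5 ms; pulse onset carries the
charge-conservative mirror (on-gating) transient. `Q_max` is calibrated per
cell so that `Q_off/I_ss` at the variant's reference prepulse (+135 mV for
full-length constructs, +95 mV for linker chimeras) equals the designed ratio
ρ_ref — the simulator's ground truth for the transport-efficiency statistic.

Three modelling conventions matter for interpretation:

* **The capacitive tail is the nonlinear tail.** During the tail segment the
  transport current sits at its constant holding-level value; the relaxing
  nonlinear component of the tail is *defined* to be the off-gating
  exponential. Layering a separate gate-relaxation transport transient on top
  would make the integrated tail charge exceed the designed
  `Q_max·(p∞(V)−p∞(V_hold))` by a ρ-dependent factor and the design would no
  longer round-trip. The simulator is agnostic about whether such tails arise
  from incomplete transport cycles or from gating transitions; it reproduces
  their phenomenology only.
* **P/8 subpulses are linear.** Subpulse sweeps contain leak, capacitance
  transient and noise, but no transporter response: the subtraction procedure
  assumes the conductance of interest is silent in the subpulse range, and
  with the deliberately shallow default gate (k = 25 mV) the model transporter
  would otherwise leak measurably into the template at −30 mV. Subtraction is
  still performed numerically on sampled sweeps (averaging eight noisy
  subpulses, baseline removal, scaling by 8, sample-wise subtraction), so its
  arithmetic — including the 3× noise amplification — is exercised honestly.
* **Activation kinetics are nominal.** τ_act = 1 ms and τ_off = 0.5 ms are
  chosen so the 10 ms pulse reaches steady state and the 20 ms tail captures
  >99.9% of the charge; no kinetic measurements are represented, and the
  pipeline deliberately performs no τ–V analysis.

**Passive subsystem.** Linear leak `g_leak·V` (default 1 nS) and an RC
transient of amplitude `c_m·ΔV/τ_c` with τ_c = r_s·c_m (defaults 10 pF, 5 MΩ
→ 50 µs) at every voltage step. Defaults are small because the emulated
recordings are capacitance-cancelled and series-resistance-compensated; no
residual voltage error is modelled. Noise is white Gaussian, 10 pA sd per
sample at 100 kHz.

**Fluorescence.** `F = gain·expr_scale·c + background` (defaults 100 a.u. per
expression unit, 20 a.u. background), so current–fluorescence plots have the
linear structure with nonzero abscissa offset seen in eGFP-fusion expression
series.

## Variant table

Activation midpoints of the measurable variants are the published values
(WT +75.0, D15N +77.0, V275M +64.0, V536M +112.0, G544R +89.2, R718W +80.0 mV;
chimeric WT +72.0, V212G +51.2, L221V +27.8, G731R +70.0 mV). The Boltzmann
slope is never printed; k = 25 mV is used for every variant, an
order-of-magnitude typical value for CLC gating charge, and is configurable.
ρ_ref values are *designed*, not measured: they honour the published rank
statements (V275M, G544R and R718W raise the Q_off/current ratio; chimeric
V212G and L221V raise it relative to the chimeric WT) with WT at
0.30 pC/nA. Loss-of-function variants (L221P, L221V, S534L and their
chimeras with no measurable currents) are given surface densities that place
their currents below the analysis noise floor, so the pipeline flags their
activation and ρ as undefined rather than reporting numbers, as in the
experiments. Chimeric constructs double the WT surface fraction
(0.20 vs 0.10), reflecting removal of the ER-retention signal in the
inter-CBS linker.

## Trace processing

* **P/8 subtraction** averages the eight subpulse sweeps per test voltage,
  removes their own pre-segment baseline, scales by 8 (the signed
  test/subpulse amplitude ratio) and subtracts sample-wise. Components linear
  in voltage cancel exactly in the noise-free limit. The subpulse residuals
  about their mean are retained in place of the subpulses, making a second
  pass a no-op up to noise (idempotence).
* **Steady-state current** is the mean over the last 2 ms of the 10 ms pulse
  (the 1 ms gate has settled to e⁻⁸ of its excursion); the window is a
  parameter.
* **Q_off integration**: the tail baseline is the mean of the final 20% of
  the tail; the baseline-corrected tail is integrated by the trapezoid rule
  at native sampling from repolarization to 10 ms. No guard interval is used
  by default: after P/8 subtraction the linear capacitive transient is
  cancelled, and with τ_off = 0.5 ms even a 0.1 ms guard would discard 18% of
  the charge. The guard remains configurable for data with residual
  transients. Sign convention: outward current positive; the returned charge
  is the negated tail integral, so depolarizing prepulses give positive
  charges, and prepulses below the holding potential give small negative
  ones.

## Activation fits and transport statistics

The measured charge is the charge moved between the prepulse and the holding
potential, so the pipeline fits the holding-referenced single Boltzmann

    Q(V) = Q_max · (σ(V) − σ(V_hold)),   σ(V) = 1/(1+exp(−(V−V½)/k)),

which is exactly zero at the holding potential and slightly negative below
it, as the data are. A plain three-parameter fit `Q_max·σ(V)` is available
(`v_ref=None`) but cannot represent the sub-holding branch and would bias V½
upward by a few mV at k = 25 mV. Fits are nonlinear least squares
(trust-region reflective) with data-driven starts (V½ from the half-rise
crossing, k from the 10–90% rise span divided by ln 81) and box bounds
(k ∈ (10⁻³, 10³) mV, V½ within the stimulated range ±50 mV). Non-convergence
returns a flagged result with diagnostics; flagged values propagate as
missing into all downstream statistics, never as zeros. Q–V curves are fitted
per cell and V½ averaged across cells (not pooled), matching how per-variant
means are reported.

ρ = Q_off/I_ss at the reference prepulse; currents below 0.05 nA are treated
as at the noise floor and ρ is flagged undefined. Transport activity is the
normalized charge `Q/Q_max` divided by ρ, per prepulse, restricted to
prepulses with normalized charge above 0.05 (below that the ratio is
noise-dominated); it is invariant under rescaling of absolute expression.
Normalized charges are not clipped at 1 so the normalization stays linear.
Current–fluorescence slope factors are ordinary least squares with a free
intercept — background fluorescence is nonzero and forcing the line through
the origin would bias slopes; the intercept is reported for transparency.

## Colocalization

Synthetic image pairs place Gaussian puncta (psf σ = 2 px) uniformly in the
field; each channel-1 punctum is duplicated into channel 2 with probability
`overlap_prob` — a duplicated punctum is the same structure and keeps its
position and brightness — and channel 2 receives additional puncta of its
own. Brightness is lognormal (σ_ln = 0.3) around 100 a.u. on a 5 a.u.
background with Gaussian noise (sd 2). The duplication draw compares one
uniform variate per punctum against `overlap_prob`, so for a fixed seed the
shared set grows monotonically with the probability; calibration to a target
coefficient bisects on the noise-free oracle (the coefficient computed
exactly on the stored ground-truth channels), averaged over a fixed seed set.

Analysis thresholds each channel (Otsu by default; fixed values for constant
or pathological images) and computes, on background-subtracted intensities
over the union of the foreground masks, the intensity-weighted overlap
coefficient R = Σ(ch1·ch2)/√(Σch1²·Σch2²) — the headline value — together
with the split coefficients M1 and M2. All three are invariant under
multiplying either channel by a positive constant. Single-image R scatters
with sd ≈ 0.05 at intermediate overlap; cohort means are the meaningful
readout. No Costes randomization test, 3-D stacks, or organelle morphometry
are implemented.

## Densitometry

Lanes are 1-D intensity profiles on a migration axis linear in log molecular
weight (`position = a − b·log₁₀(MW)`, defaults a = 140 mm, b = 55 mm/decade).
The baseline is estimated by grey-scale morphological opening with a window
of 10× the widest band sigma, after light Gaussian smoothing (0.2 mm) —
without smoothing the erosion step tracks noise minima and biases the
baseline low. Band areas inside an ROI given in kDa come from a constrained
Gaussian decomposition: centres bounded to ±2σ of the expected migration,
widths *fixed* to the band table (fitting widths makes co-migrating doublets
degenerate), plus a constant offset absorbing residual baseline error; a
failed fit falls back to ±3σ interval sums. Fractions are
glycosylated/(glycosylated+non-glycosylated) and Σ heterodimer bands / Σ all
labelled bands; both are exposure-independent by construction and round-trip
designed proportions within 2% under the default noise.

## Group statistics

Per metric, Shapiro–Wilk normality in every group and Levene's equal-variance
test across groups gate the comparison at α = 0.05: both pass → one-way ANOVA
with Tukey HSD comparisons against the reference group (WT, or the chimeric
WT for chimera panels); otherwise pairwise two-sided Mann–Whitney tests
against the reference. With exactly two groups the Tukey comparison is
computed as the pooled t-test, to which it is mathematically identical.
Stars: * p<0.05, ** p<0.01, *** p<0.001. Groups with fewer than three defined
values are excluded with a warning; undefined entries are dropped but
counted. No multiplicity correction is applied beyond Tukey (none is applied
on the Mann–Whitney branch). Under a global null the gated procedure's
empirical type-I rate is ≈5% (calibrated in the test suite at 1000
replicates).

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the pipeline must
handle: Boltzmann-activated rectifying currents with capacitive tails,
lognormal expression linked to fluorescence, punctate two-channel images with
tunable overlap, Gaussian gel bands on a log-MW axis. Passing tests therefore
demonstrate that the estimators recover known ground truth under these
conditions at the published sample sizes. They do not establish robustness to
features the generator omits: series-resistance voltage errors, seal drift
and rundown, voltage-dependent gating kinetics, endogenous background
conductances, depth-dependent optical blur or bleed-through, gel smearing and
lane distortion. Real-data entry points (HDF5/CSV sweep tables, TIFF pairs,
lane CSVs) accept such data, but the validation here does not cover those
artifacts.

## Problem sizes

Default test and acceptance runs use the published cohort sizes (5–19 cells
per variant, 30 voltages × 9 sweeps × 32 ms per cell at 100 kHz), 11 images
of 256×256 px per colocalization cohort, 1200-point lane profiles, and 1000
replicates for the type-I calibration; a full acceptance pass computes in a
few seconds on one CPU.
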