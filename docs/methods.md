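# Methods

## Scope

`mcurrent` analyses whole-cell voltage-clamp recordings of KCNQ2/KCNQ3
(M-current) channels from automated patch-clamp plates and classifies
channel variants by their functional consequences.  Because no public
repository of raw automated patch-clamp traces exists, the package ships a
calibrated generative model of such recordings; every analysis stage is
validated against that simulator's closed forms, and the headline
calibration numbers (WT gating, retigabine effects, TEA block, expression
contrast) are recovered end to end by `scripts/acceptance.py`.

## Generative model

**Gating.**  One first-order Hodgkin–Huxley gate per conductance.
Steady-state activation is Boltzmann, `p_inf(V) = 1/(1+exp((V½−V)/k))`;
on a voltage step the gate relaxes as
`p(t) = p_inf + (p0 − p_inf)·exp(−t/τ(V))` from the steady state at the
previous potential.  The activation time constant is a sigmoid of voltage,
`τ(V) = τ_min + τ_amp/(1+exp((V−V_τ)/k_τ))` with defaults τ_min = 60 ms,
τ_amp = 240 ms, V_τ = −30 mV, k_τ = 15 mV — monotonically faster with
depolarization (τ ≈ 62 ms at +40 mV, ≈ 180 ms at −30 mV), chosen so the
single-exponential fit over 50–1000 ms is well posed across −30…+40 mV.
Deactivation at the 0 mV tail uses the same τ(V); sweeps are delivered at
0.05 Hz, slow enough that gating fully re-equilibrates at −80 mV between
sweeps.  WT calibration: g_max = 6.5 nS, V½ = −18.9 mV, k = 7.6 mV.

**Reversal potentials.**  E_K from the Nernst equation with 4 mM external
and 110 mM internal K⁺ at 295 K → −84.2 mV; the ohmic leak reverses at
0 mV.

**Whole-cell current.**  Per sweep,
`I(t) = expr·g_max·p(t)·(V−E_K) + g_leak·V + (Cm/8 pF)·g_bg·p_bg(t)·(V−E_K) + ε(t)`,
with ε white Gaussian noise (5 pA RMS; the 3 kHz hardware filter is not
emulated because all analysis quantities are window statistics).  The
endogenous background conductance g_bg (V½ = −10 mV, k = 12 mV, fast τ) is
XE991-insensitive and scales with capacitance as a proxy for membrane
area; its default magnitude is computed from the covariate population
moments so that the expected nontransfected outward density at +40 mV is
1/20 of the WT-transfected mean — the observed expression contrast of the
assay.

**Population heterogeneity.**  Per cell, log-normal draws: capacitance
(median 8 pF, σ = 0.4), seal resistance (median 1 GΩ, σ = 0.824, putting
~20 % of cells below the 0.5 GΩ cut so the QC gate is genuinely
exercised), series resistance (median 8 MΩ, σ = 0.4), leak conductance
(median 0.3 nS, σ = 0.5), and an expression factor with mean 1 and
CV = 0.5 emulating electroporation variability (0 for nontransfected
cells).  Each cell is recorded twice — drug-free and after saturating
XE991 — with identical covariates and an independent noise stream drawn
from the cell's own seed substream (derived from the master seed by cell
counter, so enlarging a cohort never reshuffles earlier cells).

**Variants.**  A `VariantEffect` perturbs WT gating: conductance scale s,
V½ shift, slope and τ scales, and a dominance coefficient d ∈ [0, 1].
Heterozygous (1:1) co-expression assumes two KCNQ2 slots per channel
(2:2 stoichiometry with KCNQ3) filled independently, giving WW/WV/VV
classes with weights ¼/½/¼.  The mixed WV class has conductance factor
`(1−d)(1+s)/2 + d·s`, interpolating between allelic additivity (d = 0,
haploinsufficiency) and full mutant poisoning (d = 1, dominant-negative:
a null variant then leaves 25 % of WT current, below the 50 % DN rule);
WV gating parameters are conductance-weighted means of the WT and variant
values.  The simulator collapses the three classes into one effective
Boltzmann gate — a deliberate simplification that keeps the generative
truth analytically available to the tests.

**Drugs.**  XE991 removes a fraction (default all) of the M-conductance;
TEA scales it by `1/(1+(c/IC₅₀)^h)` with IC₅₀ = 10.7 mM, h = 1;
retigabine shifts V½ by −28.8 mV (so −18.9 → −47.7 mV), sets k to 9.9 mV,
scales g_max by 1.4 and τ by 0.5.  The τ speeding is applied uniformly in
voltage (the real drug's effect is concentrated near −30…−10 mV — a known
simplification).  The endogenous background is insensitive to all three.
Drug-response experiments simulate paired cohorts sharing one seed
lineage, i.e. the same virtual cells with and without drug, the in-silico
analogue of applying drug to each recorded cell; with fully independent
cohorts the expression CV would dominate the concentration–response and
the IC₅₀ estimate becomes unusably noisy (SD ≈ 2.6 mM across seeds versus
0.02 mM paired).

## Quality control

A recording enters analysis only if seal ≥ 0.5 GΩ (relaxed to 0.3 GΩ for
post-XE991 recordings, > 50 MΩ on multi-hole chips), series resistance
≤ 20 MΩ, capacitance ≥ 1 pF, and the baseline is stable.  Stability is
the relative standard error SE/|mean| of per-sweep baseline currents,
required strictly below 10 %; "baseline" is the mean current over the
final 50 ms at holding before each step (the assay does not define the
window; 50 ms is our operationalization, hence the protocol's 100 ms
holding segment).  The relative reading of "standard error … for baseline
current" is interpretive — an absolute SE has no 10 % scale.  Boundary
values are inclusive exactly as worded.  A cell is analysed only if both
recordings of its XE991 pair pass under their own condition's threshold.

## Trace processing

The M-current is defined operationally as the XE991-sensitive current:
the post-XE991 trace is subtracted pointwise from the paired drug-free
trace (no other leak subtraction anywhere).  Peak current is read 999 ms
into the step and the tail 5 ms into the 0 mV step, each as the mean over
a ±1 ms window clamped to its voltage segment (window width configurable;
0 gives single-sample exactness).  Densities divide by capacitance.

**Tail normalization.**  The tail at 5 ms inevitably contains an additive
pedestal — channels opening *during* the tail step itself (at 0 mV the
channel is mostly open at steady state), identical across sweeps — plus
the prepulse-dependent signal attenuated by 5 ms of relaxation.  Tails are
therefore normalized min-max per cell: the tail after the most negative
(fully deactivated) prepulse is the tail-step baseline, and the maximal
tail maps to 1.  This removes the affine contamination exactly; normalizing
by the maximum alone would leave a ≈ −0.8 mV bias in fitted V½.  Cells
whose tail span does not exceed 3× the noise floor (holding-segment
residual RMS) are flagged unfittable — the operational version of
"activation determined only when current exceeds background".

## Curve fitting

All fits use damped least squares (trust-region reflective, tolerance
1e−10, ≤ 500 evaluations) with data-driven starts and report a
`converged` flag instead of raising on degenerate data.  Bounds: k ∈
[1, 40] mV, τ ∈ [5, 2000] ms, h ∈ [0.3, 4]; an estimate pinned at a bound
is reported non-converged.

* **Boltzmann** `Imax/(1+exp((V½−V)/k))`; V½ starts at the interpolated
  half-crossing, k at 8 mV.  When fitting min-max-normalized tails the
  model is the identically normalized Boltzmann
  `Imax·(B(V)−B(V_lo))/(B(V_hi)−B(V_lo))` (`span_voltages` option): this
  inverts the normalization exactly, which matters once the activation
  foot lies below the lowest protocol voltage — under retigabine the
  plain zero-floor fit is ≈ 1 mV too depolarized, the span-aware fit is
  exact on noiseless data.  No pedestal parameter is introduced.
* **Activation kinetics** `A₀·exp(−t/τ)+C` on 50–1000 ms after step
  onset, voltages −30…+40 mV, initialized by log-linear regression.
  Fits are per cell (whether the source assay fit per cell or on averaged
  traces is unstated; per-cell matches its per-cell n accounting and a
  config switch is unnecessary given `cohort_iv` provides averages).
* **Hill block** `1/(1+(IC₅₀/c)^h)` in log-concentration, IC₅₀ started at
  the geometric mean of tested concentrations.

Group summaries are means ± SEM of per-cell estimates over converged
fits, not single fits to pooled means.

## Variant analysis

Metrics are relative to the WT cohort assayed in parallel (cross-plate
comparisons are refused): percent of WT mean density at +40 mV, ΔV½ of
cohort means, and per-voltage τ ratios.  Significance uses a two-tailed
two-sample t test (one variant) or one-way ANOVA (several), α = 0.01,
with p = 1 by convention for degenerate zero-variance equal-mean input.
Classification is total over the metric space; the |ΔV½| ≥ 5 mV magnitude
rule is applied uniformly (it is stated only for population variants in
the source assay; uniform application keeps the rule consistent), and the
heterozygous "enhanced" class (> 100 % of WT, significant) makes the
rescue scale total.  Density bins take precedence over gating-shift
classes; all bins require statistical significance.  Exactly 50 % falls
in pR (DN is strictly below 50 %), exactly 75 % falls outside the partial
band, both half-open as stated.  The retigabine response is quantified at
−20 mV — near the foot of the WT activation curve, where M-current shapes
excitability — as a percentage of untreated parallel WT density, with the
no-drug control percentage and the full-voltage table alongside.

## Problem sizes and test design

Cohort experiments run the activation protocol at 1 ms sampling (the
instrument default of 0.1 ms is retained as the protocol default); the
999 ms/5 ms measurement points and the 50–1000 ms kinetics window fall on
exact samples either way, and an n = 900 cohort stays in ordinary memory.
Calibration experiments use the assay's scales: 900 attempted cells
(~700–720 passing QC and fitting) for gating, 75 attempted (~60 passing)
per TEA concentration, 150 attempted (~115) for the expression contrast.

The classification truth-recovery test sweeps conductance scale
{0, 0.25, 0.5, 1} × dominance {0, 1} × ΔV½ {−10, 0, +10} mV in both
zygosities at n = 40 cells/group.  The "truth" label passes the exact
population metrics through the same classification bins while using the
cohort's own hypothesis-test outcome for the significance gates — the
test targets the estimation and binning, not t-test power at n = 40 —
and a truth lying exactly on a bin edge (25 % homozygous, 50 %
heterozygous are grid points) accepts both adjacent labels, since the
one-label question is ill-posed on the edge.  Agreement is ≥ 95 % across
seeded replicates.

## What the simulator does and does not show

Passing tests demonstrate that the analysis chain is unbiased and correctly
calibrated for data whose structure matches the generative model:
first-order gating, Boltzmann activation, log-normal covariates, white
noise, and drug effects acting through the modelled parameters.  Real
recordings add phenomena the simulator deliberately omits: series-
resistance voltage errors, Markov-state kinetics and inactivation, PIP₂-
and temperature-dependent gating, seal drift within a recording, and
filter dynamics.  Conclusions about estimator behaviour under those
phenomena are outside what this test suite can establish.

## Known limitations

* The effective-single-gate reduction of heterozygous mixtures ignores
  the curvature a true three-component Boltzmann mixture would add to the
  activation curve.
* The dominance coefficient is a phenomenological interpolation, not a
  biophysical subunit model.
* Retigabine τ and slope effects are uniform in voltage.
* QC covariates are static per cell; no within-recording degradation.
* The CLI writes long-format trace tables that grow large for big
  cohorts; they are meant for inspection and interchange, not bulk
  storage.
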