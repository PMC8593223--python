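# Methods

`scanmap` analyses charged-residue scanning-mutagenesis data measured by
yeast surface display (YSD) coupled to flow cytometry. A disordered protein
segment is displayed on the yeast cell wall, each single mutant is stained
for surface expression (one fluorophore) and for binding of a purified
partner protein (a second fluorophore), and the mean fluorescence
intensities (MFIs) over ~10,000 gated cells are exported per construct and
replicate. Everything below operates on those exported summaries; raw
cytometry files, compensation and gating are out of scope.

## Scores

For each mutant and replicate the package computes two unitless scores:

* expression score `MFI_exp = expression MFI(mutant) / expression MFI(WT)`,
  from replicate-mean expression intensities;
* binding-activity score `MFI_ratio`, the mean per-cell binding:expression
  intensity ratio of the mutant normalized to the WT value of the *same*
  replicate, then averaged across replicates (standard deviation with the
  n−1 denominator; for two replicates this is |x₁−x₂|/√2).

Normalizing each replicate against its own WT makes the score exactly
invariant to per-experiment channel gains (a tested property) and pins the
WT entry to 1 by construction. The per-cell-mean form of the ratio is used
when per-cell data are available; with summary exports the instrument's
ratio-MFI column is trusted. Mutants with zero binding signal score 0; they
are data, not errors.

## Interface calls

Aspartate-substitution scores are partitioned into a WT-like class and a
binding-defective class by **exact** 1-D 2-means clustering: the optimal
two-cluster partition of scalars is contiguous in sorted order, so the
global optimum is found by scanning all n−1 sorted splits with prefix sums
(O(n log n), deterministic, no Lloyd iteration or seeding). The
binding-defective cutoff is `mean(class1) − sd(class1)` of the WT-like
(higher-mean) class. A residue is called part of the binding interface when
**any** charged substitution (Asp or Arg) at that position scores strictly
below the cutoff ("lower than", so exact ties are not called). Positions
with no charged-substitution data are reported as *uncovered*, never as
negatives. Clustering is fit on Asp scores only; the cutoff is applied to
both substitution types.

## Local structure from periodicity

If the segment folds into a helix on binding with one face contacting the
partner, mutational sensitivity oscillates along the sequence with the
helical repeat. The stages:

1. **Fill** — positions with no Asp measurement receive the WT score (1.0)
   and are flagged; flagged positions can be excluded downstream.
2. **Detrend** — subtract a centred sliding-window mean (default window 5;
   7/9/11 supported). At the edges the window truncates so all positions
   keep corrected values. Window-5 is the default because shorter windows
   preserve phase discontinuities that longer windows smear out. Note the
   truncated-window detrend does *not* make every interior window of the
   corrected series zero-mean; correctness is checked against a direct
   re-computation oracle instead.
3. **Fit** — least squares of `y = a·sin(2πx/b + c)` per segment, x the
   absolute residue index. For fixed periodicity b the model is linear in
   `(a cos c, a sin c)`, so a deterministic grid over b (2–8 residues/cycle,
   step 0.1) with a profiled linear solve locates the basin and bounded
   nonlinear least squares refines (a, b, c) from the five best starts.
   Amplitude is reported non-negative (the (−a, c+π) equivalence is
   resolved by phase wrapping into [0, 2π)); parameter uncertainties are
   asymptotic standard errors from the Jacobian; `r` is the Pearson
   correlation between observed and fitted values. The fit matches a dense
   (b, c) grid oracle to 1e-6 in SSE and recovers noiseless parameters to
   1e-6.
4. **Segment** — manual breakpoints (segment-start positions) are the
   primary mode; `scan_breakpoints` automates the choice by exhaustive
   search over up to two breakpoints (segments ≥ 8 residues), scored by
   small-sample AIC with 3 parameters per segment plus a shared noise
   variance, so a single pure sinusoid is not split. Near-ties prefer
   fewer, later breakpoints. The single-segment fit is always reported for
   comparison.
5. **Assign** — periodicity 3.2–4.1 residues/cycle is labelled
   `alpha-helix` (canonical repeat 3.6), 1.8–2.2 `strand-like` (extended
   register), anything else `irregular/ambiguous`.

## Dissociation constants and calibration

Titrations of binding MFI versus ligand **dimer** concentration (held in nM
internally; readers convert fM/pM/µM) are fit to the one-site hyperbola
`MFI = Bmax·[L]/(Kd+[L])` by nonlinear least squares with deterministic
initialization (Bmax₀ = max MFI; Kd₀ = concentration nearest half-max).
The fit is performed against [L] directly; log-concentration axes are a
plotting convention only. No additive baseline is fit by default
(background-subtracted MFIs are assumed). Curves whose top concentration is
below Kd/10 are flagged `poorly_constrained`; flat curves are errors. Kd
rescales exactly with the concentration unit (tested).

An ordinary least-squares line `Kd = slope·MFI_ratio + intercept` over ≥ 3
reference variants converts scores into apparent Kd values for unmeasured
mutants. The true score→Kd relation is exponential, so the linear map is a
local interpolation over the calibrated score range, not an extrapolation
device; predictions at or below 0 are clamped to a configurable floor and
flagged. Higher scores mean tighter binding, so the slope is negative.

## Conservation

Per-position conservation (a pre-computed ConSurf-style export; the package
does not build alignments) is inner-joined with per-position Asp scores and
both Pearson and Spearman correlations are reported, with excluded
positions counted. Filled (unmeasured) positions can be masked out.

## Synthetic data generator

The generator emulates the measurement process so every stage is testable
with recorded ground truth:

* **Binding thermodynamics** — each position carries a penalty
  `ΔΔG(pos) = max(0, base + amp·sin(2π·pos/period + phase))` over one or
  more interface segments; the rectification encodes one helical face
  contacting the partner. `Kd_mut = Kd_wt·exp(ΔΔG/RT)` with RT = 0.593
  kcal/mol (25 °C); fraction bound `f = L/(Kd+L)` at probe concentration L.
* **Readout** — per cell, expression ~ LogNormal(ln 1000, 0.5); binding =
  `f·expression·(1+ε)`, ε ~ N(0, 0.2), plus additive autofluorescence
  N(25, 25) floored at 0; 10,000 cells per construct, two replicates, MFIs
  summarized exactly as the scoring stage expects. Identical seeds give
  bit-identical panels.
* **Defaults** — Kd_wt = 1 nM with the probe at 1 nM (so f_wt = ½ and the
  assay is maximally sensitive to Kd shifts); three interface segments:
  31–44 (period 4.0, base 0.25, amp 0.75; a distorted helix), 45–66
  (period 3.6, base 0.30, amp 0.90; canonical helix), 67–82 (period 3.3,
  base 0.10, amp 0.45; weak C-terminal contribution). These effect sizes
  were fixed by a closed-form design calculation so that a noise-free
  default panel shows the class structure typical of charged scans of
  toxin–antitoxin interfaces (defective-class mean MFI_ratio ≈ 0.45–0.6,
  roughly half the positions carrying a detectable effect).
* **Truth labels** — a position is ground-truth *interface* when its
  ΔΔG ≥ 0.25 kcal/mol (≈ a 1.5-fold Kd shift, the smallest effect the
  1-nM-probe design resolves cleanly); smaller rectified-sine tails are
  real but unmeasurable and counting them would make any benchmark
  undefined at the crossing points.
* **Scan design** — Asp at every window position; positions whose synthetic
  WT residue is Asp get Arg instead, so interface membership there is still
  callable while the Asp-based periodicity series uses WT fill at those
  positions (the synthetic 82-residue sequence places four Asp residues
  inside the scanned window for exactly this purpose).

What the generator does **not** emulate: instrument spillover, doublets,
gating artifacts, day effects beyond per-replicate resampling, expression
knock-downs by mutation (expression is mutation-independent), and
autofluorescence on the expression channel. One consequence is tested and
documented: additive binding-channel autofluorescence biases weak-binder
scores upward by `autofluor_mean·E[1/expression]` relative to the ideal
`f_mut/f_wt`, so large-sample convergence to the closed form holds exactly
only with autofluorescence off. Passing recovery benchmarks therefore show
the pipeline is correct under log-normal display noise and modest additive
background — not that it is robust to every cytometry artifact.

## Problem sizes and determinism

The recovery benchmarks use 50 seeds (periodicity; 52-position panels,
10,000 cells, two replicates) and 20 seeds (interface-call F1), which give
seed-to-seed standard errors well below the asserted margins while keeping
a full run in seconds. All stochastic tests fix seeds; the pipeline report
is byte-identical across reruns of the same configuration.

## Known limitations

* The linear Kd calibration degrades away from the calibrated score range
  (the underlying relation is exponential in ΔΔG).
* Breakpoint auto-scan compares at most three segments and assumes
  homoscedastic residuals.
* The 2-means cutoff `mean − sd` is a convention, not an error-rate
  guarantee; with a very tight WT-like class it approaches the class mean
  and call precision depends on the defective class being well separated.
* Scores below ~0.05 saturate (the probe cannot distinguish very large
  penalties), so fitted sinusoid amplitudes compress in strongly binding-
  defective stretches.
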