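# Methods

This note documents the models behind each `stabkit` module, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Mutation selection

Two independent routes propose stabilizing single-point substitutions.

**Energy route.** The input is a full point-mutation scan: for every
position, ΔΔG predictions (kcal/mol, negative = stabilizing) from two
force-field predictors (`ddg_pred1`, `ddg_pred2` — FoldX-like and
Rosetta-like columns). A substitution passes iff **both** predictors are
strictly below −1.0 kcal/mol, the position's conservation grade is ≤ 7,
and the position is not annotated as a receptor- or heparin-binding
residue. The AND rule over predictors is a deliberate conservative choice:
it minimizes false stabilizers at the cost of recall, which suits a
campaign where each candidate is expressed and measured. Conservation uses
the 1–9 ConSurf-style convention (9 = most conserved), so the gate excludes
only the two most conserved grades.

**Back-to-consensus route.** Column frequencies are computed over *all*
analyzed sequences — the target row and gapped sequences count in the
denominator, read literally from the 50%-of-all-sequences definition. A
consensus residue exists iff a single residue reaches frequency ≥ 0.5
(inclusive); a tied maximum calls no consensus. A candidate is proposed
where the target deviates from the consensus, and passes iff the reversion
is not destabilizing (both predictors strictly < +0.5 kcal/mol) and the
position is outside binding sites. No conservation-grade gate applies on
this route (conservation is what the consensus already encodes); the flag
is recorded as passed so the "selected iff all flags" invariant is uniform.
A proposal whose substitution lacks a ΔΔG record is retained in the audit
output, flagged, and logged — it can never be selected.

Every examined substitution is returned with its verdict flags
(`passed_ddg`, `passed_conservation`, `passed_site_exclusion`), so
selected ∪ rejected = input always holds and filter decisions are
auditable.

**Combination.** Position-disjoint subsets of order 2..max_order are
enumerated exhaustively and ranked by predicted ΔΔG (sum of member scalar
ΔΔG, the mean of the two predictors) ascending. Ties break by fewer
mutations, then lexicographic position order, making the ranking a total
order. An enumeration guard (200 000 plans by default) refuses silent
combinatorial explosions; the error says how to raise it. When measured
single-mutant ΔTm values are attached, candidates are gated at
ΔTm ≥ 2.0 °C (inclusive) before combination, and a plan's predicted ΔTm is
the exact sum of its members' measured values — the additivity assumption
under which multi-point stabilization is designed. Expressibility failures
(mutants that cannot be produced) are handled as a manual exclusion list,
not predicted.

## Thermal analysis

**Two-state model.** Fraction unfolded f(T) = K/(1+K) with
K = exp[−(ΔH_vH/R)(1/T − 1/T_m)], temperatures converted to kelvin
internally (user-facing units stay °C), R = 1.9872 cal/(mol·K). Sigmoidal
modalities (DSF 330/350 fluorescence ratio, CD ellipticity) observe
(1−f)·pre(T) + f·post(T) with linear baselines; DSC observes the excess
heat capacity ΔH·df/dT over a baseline. No ΔCp term is modelled: the
analysis stops at the van't Hoff parameterization.

**Baseline windows.** The transition region is located from the smoothed
signal gradient (moving average, window 7; region where |gradient| stays
above 25% of its peak, expanded by a half-width margin), and baselines are
fit to the points outside it. This adaptive choice — rather than fixed
first/last-15% flanks — keeps the normalization usable when T_m sits near
a scan edge, where a fixed flank would swallow half the transition.
Baseline windows shorter than 8 points get a constant (mean) baseline: a
slope estimated from a handful of noisy points extrapolates worse than
ignoring the small true slope. If no gradient peak stands out of the noise
floor (3× the median |gradient|), the curve has no resolvable transition
and normalization raises rather than returning noise.

**T_m estimators.** (1) *Midpoint*: the 0.5-crossing of the normalized
transition, linearly interpolated after a window-3 moving average —
the smoothing resolves noise-induced multiple crossings deterministically
to the first crossing. (2) *Full fit*: nonlinear least squares of the
6-parameter model (T_m, ΔH_vH, two baselines), initialized from the
midpoint and flank fits; non-convergence is reported on the result object,
not raised, to keep batch tables intact. (3) *DSC peak*: baseline
(line through flank means) subtracted, optional smoothing, tallest peak
with parabolic sub-grid refinement; all local maxima above quarter height
are reported for bimodal diagnostics, and a maximum on the scan edge is
flagged. For a two-state transition the ΔH·df/dT maximum lies ~0.05–0.1 °C
below T_m (the 1/T² factor); this bias is far inside the estimator's noise
floor and is left uncorrected. On noiseless fixtures the three estimators
agree within 0.5 °C; at 1% amplitude noise the median recovery error is
< 0.1 °C for midpoint and fit and < 0.15 °C for the DSC peak (measured by
the acceptance script).

**Decays.** y(t) = plateau + A·e^(−λt) by nonlinear least squares;
τ = 1/λ and t_1/2 = τ·ln 2 (the identity holds to machine precision by
construction, since t_1/2 is computed as τ·ln 2). A curve is flagged
*stable within the observation window* when the fitted half-life exceeds
3× the window, or the fitted amplitude is within 3× the residual noise —
the latter stops the fit from reporting a sharp "decay" of pure noise on a
flat trace. Fitting is per-curve; a shared-plateau multi-curve mode exists
for decays recorded under identical buffer conditions, since whether any
parameters should be shared across variants is an open protocol question.

## Binding analysis

The 1:1 Langmuir model throughout; no bivalent or heterogeneous-ligand
extensions, no drift or reference-sensor model (synthetic traces are
pre-referenced; drift correction is the natural extension point).

Default concentrations follow the instrument protocol: a twofold dilution
series 31.25–250 nM with 300 s association and dissociation. Two routes to
K_D are reported. *Kinetic*: a global fit of (k_a, k_d, R_max) shared
across all traces (standard practice — the shared parameters are exactly
what the 1:1 model asserts); K_D = k_d/k_a holds to machine precision in
the report. *Saturation*: per-concentration equilibrium responses R_eq fit
to R_eq(C) = R_max·C/(C+K_D). R_eq extraction fits all traces jointly with
per-trace (R_eq, k_obs) and one shared k_d (the off-rate does not depend
on analyte concentration); the dissociation amplitude
R_eq(1 − e^(−k_obs·t_assoc)) ties the phases together and substantially
tightens R_eq at low-signal concentrations. On clean synthetic data the
two routes agree within 1%; their divergence on real data is a
model-violation diagnostic.

Identifiability: with the series topping out at 250 nM against a ~764 nM
site, the isotherm is sampled only below half-saturation, so the
saturation K_D is intrinsically wide — at 2% response noise the median
recovery error is ~10–15% (acceptance script), and a fit whose K_D
standard error exceeds the estimate, or lands far beyond the measured
range, is flagged `poorly_constrained`. An association fit whose k_obs
does not exceed the supplied k_d is rejected as non-physical.

## Brightness (FIF) analysis

ROIs are tiled into non-overlapping 15×15-pixel (225-pixel) segments,
anchored at the ROI bounding-box origin (anchor offsets are exposed, since
grid registration is not standardized); partial tiles are discarded.
Per-segment brightness is ε = (1/γ)(σ²/I − 1) with γ = 0.5 and σ² the
unbiased (ddof = 1) variance of the photon counts. Negative ε from
under-dispersed segments is retained — discarding it would bias the
distributions upward. The detector is assumed photon-counting
(Poisson-dominated); no read-noise term.

Distributions pool the segments of at least 100 cells (the protocol
minimum; relaxable only explicitly), histogrammed over 50 linear bins
spanning the pooled 1st–99th percentile by default — the binning is not
standardized, so the spec is data-driven and recorded in the result, and
raw values are kept so distributions can be re-binned for comparison.
Against a monomer control the comparison reports mean and median ratios,
median shift, and the bin-wise-minimum overlap coefficient; with a dimer
control the sample is classified by the position of its mean on the
monomer→dimer axis (< 0.25 monomer-like, > 0.75 dimer-like, otherwise
intermediate — symmetric quartile cuts chosen for robustness to the
mixture fraction).

## Synthetic data: what it does and does not emulate

Generators are deterministic functions of their seed (NumPy PCG64);
identical seeds reproduce byte-identical outputs. Defaults encode the
standard protocol: melts scanned 25–90 °C at 0.5 °C sampling; decays
sampled every 5 min over 24 h; the 31.25–250 nM BLI series; γ = 0.5,
μ = 5 oligomers/pixel and q = 10 photons/fluorophore for images (shot
noise realistic without saturating a 16-bit counter). Noise is additive
Gaussian on optical signals and Poisson on photon counts; instrument noise
magnitudes are not published for the reference protocols, so the defaults
(1% of amplitude for melts, 5% for decays, 2% of R_max for BLI) are chosen
as typical instrument performance, not inferred.

Alignments use deterministic per-column counts (⌈freq·n⌉ rows carry the
dominant residue) rather than Bernoulli draws, so planted consensus
deviations are recoverable *exactly* at any alignment size; at planted
columns the count is additionally floored at a majority of all n+1
analyzed sequences because the consensus denominator includes the target
row. Gaps never occur in planted columns. ΔΔG backgrounds are
Normal(+1.0, 0.5) — mildly destabilizing on average, as real scans are —
with planted stabilizers strictly below the requested value in both
predictors.

Membrane images are compound-Poisson: per pixel, Poisson(μ·p_k) k-mers per
size class (equivalent by Poisson thinning to Poisson(μ) oligomers with
sizes from the mix) and Poisson(q·fluorophores) photons. The closed form
E[Var/Mean − 1] = q·E[k²]/E[k] is the module's independent oracle. Pixels
are independent: no point-spread function, no blinking or photobleaching
(single-scan protocol), no cell-to-cell expression variability. Passing
tests therefore validate the segmentation and brightness arithmetic and
the estimator statistics — not robustness to optical correlations between
neighbouring pixels, which real confocal data has and which would inflate
σ² relative to this model.

Because every analysis is validated against data from these generators,
the recovery numbers quoted here are generator-conditional: they show the
estimators are correct and well-calibrated under instrument-appropriate
noise, not that real instruments achieve these errors.

## Problem sizes

The test suite and acceptance script use 100-replicate recovery studies
per estimator (melts across a 45–80 °C grid, decays across 1–24 h
half-lives, BLI across 100 noise seeds), 100-cell populations per
brightness condition on 60×60-pixel cells (16 segments/cell, 1600
segments/condition), and 100 randomized tables for filter-oracle
equivalence — sizes at which the measured medians are stable to well
inside the tolerances they are compared against.

## Known limitations

- Single-transition two-state analysis only; multi-domain proteins with
  two resolvable transitions are reported via DSC peak diagnostics, not
  deconvolved.
- The saturation K_D is weakly identified when the concentration series
  stays well below K_D (by design of the reference protocol); use the
  kinetic route or extend the series when possible.
- The consensus caller operates on the alignment as given; it does not
  weight sequences by redundancy or phylogeny.
- Brightness classification assumes monomer/dimer controls bracket the
  sample; higher oligomers are out of scope.
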