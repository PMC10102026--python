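# Methods

## Scope

`nct` packages three computational pieces around one biological question —
why activation of an ErbB (HER2) receptor heterodimer drives only a fraction
of clonal epithelial outgrowths into a DCIS-escapee-like (DE) phenotype:

1. a deterministic mass-action model of karyopherin-mediated
   nucleocytoplasmic transport with cargo reporters (`nct.transport`),
2. a steady-state feedback extension in which internalized ErbB heterodimers
   are themselves classical import cargo, closing a toggle-switch loop
   through CSE1L and importin-α (`nct.feedback`),
3. the stochastic frequency-matching statistic that nominates candidate
   regulators from 10-cell outgrowth transcriptomes (`nct.freqmatch`),
   with the supporting image-quantification operators (`nct.morphometry`)
   and seeded synthetic-data generators (`nct.synthetic`).

## Transport model

### Structure

Three well-mixed compartments: cytoplasm (1200 fL), nucleus (500 fL) and a
small nuclear-pore transit compartment (10 fL).  All binding steps are
reversible elementary mass-action reactions; translocation is facilitated
diffusion with flux `P·C(source)` per step (permeability `P` in fL/s summed
over pore classes and proportional to pore count), so equal concentrations
across compartments carry zero net flux.  Directionality of cargo transport
is therefore *emergent*: it comes entirely from the RanGTP gradient that the
RCC1-in-nucleus / RanGAP-plus-RanBP1-in-cytoplasm asymmetry maintains, not
from any one-way reaction.

Species: Ran (GTP/GDP states), NTF2, RCC1, RanGAP, RanBP1, RanBP3,
importin-α (`ImpA`, the lumped KPNA1–7 pool), importin-β (`ImpB`), CAS
(CSE1L), CRM1 (XPO1), and every binary/ternary complex the reactions create.
The cargo-free base network has 22 species, 57 state variables and 97
reactions; each cargo adds its free and carrier-bound states.

Key mechanistic choices, each of which is load-bearing for the qualitative
behaviour documented below:

- **Cargo loading is association-limited.** Reporter cargo binds its carrier
  with a deliberately slow default `k_on` (0.1 µM⁻¹s⁻¹, `kon_cargo`), with
  `k_off = K_D·k_on`.  In this regime import flux rises with free-carrier
  abundance over the whole physiological range instead of saturating at
  sub-nM occupancy, which is what makes steady-state N/C increase with
  importin-α — at equilibrium-limited loading, carrier recapture of nuclear
  cargo rises exactly as fast as cytoplasmic loading and the dependence
  cancels.
- **Free cargo permeates slowly** (`k_passive_cargo`, 0.005 s⁻¹).  Reporter
  constructs are near the passive size limit of the pore; the slow leak is
  the carrier-independent return path that lets a steady state exist with a
  finite, carrier-dependent N/C ratio.  Setting it to 0 models a strictly
  excluded cargo: with no import route the nuclear concentration is exactly
  zero.
- **CAS competes for importin-α** (`CAS + ImpA ⇌ CAS:ImpA`, K_D 10 nM in
  both compartments) in addition to its RanGTP-dependent export of
  importin-α from the nucleus.  The competition pathway makes classical
  cargo import *decrease* with CAS abundance; the recycling pathway alone
  would do the opposite.  Free importin-α is also given a slow
  CAS-independent shuttle (`k_trans_impa`, 0.1 s⁻¹) so that importin-α
  recycling is never the hard bottleneck at low CAS — without it the CAS
  dose response is non-monotone because nuclear importin-α trapping
  dominates below ~0.5× base CAS.
- **Exportin–RanGTP binary complexes are weak** (K_D 2 µM for CAS:RanGTP and
  CRM1:RanGTP) while cargo-loaded ternary complexes are tight.  This
  cooperativity limits futile Ran cycling; with tight binary complexes the
  karyopherin pool drains the RanGTP gradient faster than NTF2 can refill
  it.
- **NES export requires RanBP3-primed CRM1** (CRM1:RanBP3:RanGTP is the only
  loader).  RanBP3 is limiting at base abundance (0.05 µM), so an NES
  changes reporter N/C by <1% until RanBP3 is raised ~10-fold — matching the
  observation that NES-bearing and NES-free reporters behave alike except at
  high RanBP3.
- **Pore classes.** One or two pore classes are supported; a selective class
  gates only cargo-bearing complexes by import-signal class (`classical`,
  `ibb`, or `nls` = any signal).  With the default counts (2770 pores,
  selective minority class) the 1-class and 2-class configurations agree to
  well under 1% because translocation is not rate-limiting for any shipped
  reporter.

### Parameterization

All abundances (µM) and rate constants live in
`src/nct/data/base_model.toml` and can be overridden from a user TOML file.
The shipped values are *reconstructed* order-of-magnitude defaults chosen to
put the network in the physiological operating regime (strong nuclear RanGTP
gradient, importin-α partially sequestered by CAS, importin-β partially
sequestered by dimer formation); they are not fitted to data, and the
package performs no fitting.  Abundances of Ran (25 µM) and NTF2 (16 µM) are
high relative to the karyopherins (≈6 µM total) because the Ran import
branch must at least match the aggregate carrier flux or the gradient
collapses; both proteins are indeed among the most abundant transport
factors in epithelial cells.

### Solving

`integrate` uses `scipy.solve_ivp` (BDF, analytic Jacobian, rtol 1e-8,
atol 1e-12).  `steady_state` runs staged integration (200 s stages, ×5
escalation) to max |dC/dt| < 1e-9 µM/s, then polishes with a damped Newton
(Levenberg–Marquardt) step; the polish is accepted only if it lowers the
residual while preserving nonnegativity and every volume-weighted moiety
total to 1e-6 relative, otherwise the integration result stands.  The
steady state at fixed conserved totals is unique in all tested
configurations; agreement between the solver and direct integration to
t = 1e5 s is verified to 0.1% on jittered parameterizations.

Moiety conservation (Ran, NTF2, RCC1, RanGAP, RanBP1, RanBP3, ImpA, ImpB,
CAS, CRM1 and each cargo) is checked through the left null space of the
stoichiometry: the composition matrix annihilates the right-hand side
exactly, so trajectories conserve to solver precision (<1e-12 relative in
practice; 1e-6 asserted).

### Readout

N/C is total cargo concentration (free plus every cargo-containing complex)
in the nucleus divided by the same in the cytoplasm; pore-resident cargo is
excluded.  This matches an immunofluorescence readout of total reporter.
Transcript profiles scale initial abundances linearly (relative mRNA →
relative protein); KPNA1–7 map onto importin-α as the mean of their relative
levels (equal base isoform shares).  The 65th-percentile stratified test
places the top ⌈0.35·n⌉ samples in the high group (ties broken by stable
sample order) and uses a one-sided Mann-Whitney test.

## Feedback switch

Internalized ErbB heterodimers are classical cargo with unknown Imp-α:Imp-β
affinity; the shipped K_D ladder {strong 2.5, medium 32, weak 320 nM} is
illustrative and configurable.  ErbB cargo uses `k_on` = 1 µM⁻¹s⁻¹ — faster
than the reporter default — so that affinity (through `k_off`) shapes the
dose response; at the reporter `k_on` the three ladder rungs would be almost
indistinguishable, and the affinity-ordering prediction would be vacuous.

Two proportional feedbacks act as algebraic constraints on effective totals,
with ErbB amount fractions (volume-weighted) as inputs:

    CAS_eff  = CAS₀ · (1 + g_cas · f_cyt)          g_cas  = 8   (default)
    ImpA_eff = ImpA₀ · max(0, 1 − g_impa · f_nuc)  g_impa = 0.3 (default)

They are co-solved with the transport steady state by damped fixed-point
iteration (damping 0.5, relative tolerance 1e-6, ≤200 iterations), with
continuation along the CSE1L grid from either end; a persistent gap between
forward and backward branches is reported as bistability, not an error.
The linear form is one admissible reading of "proportional feedback"; any
saturating variant must preserve the reduction property (gains → 0 recovers
the base model exactly, which is asserted) and the ordering properties.

The gain defaults are the smallest round values at which the closed-loop
log-log slope of C/N versus initial CSE1L clearly exceeds the open-loop
slope across the affinity ladder.  The loop gain of the CAS feedback is
`(d ln C/N / d ln CAS) · g/(1+g·f_cyt) · f_cyt(1−f_cyt)`; with the open-loop
slope ≈3 near the transition the product crosses 1 and the response becomes
switch-like over a narrow CSE1L range.  The open-loop steepness itself comes
from molecular titration: CAS and importin-α are comparable in abundance and
bind tightly, so free importin-α collapses as CSE1L crosses the equivalence
point.

Ultrasensitivity is quantified as the maximum local log-log slope (apparent
Hill coefficient, central differences on the log grid) plus the fold-range
of input spanning 10→90% of the response span (interpolated in log-input).
Non-monotone curves are first isotonic-regressed and flagged.

## Stochastic frequency matching

`binomial_band(n, p)` inverts the exact binomial CDF
(endpoint = min{k : CDF(k) ≥ level}); for n = 20, p = 0.35 this gives
expectation 7, interquartile range [6, 8] and 90% interval [4, 11].  Event
thresholds are per-gene empirical 10th/90th percentiles of the untreated
condition (linear interpolation between order statistics, the numpy
default); events are counted with strict inequalities, so threshold ties are
conservative non-events.  The matched count is max(n_above, n_below) by
default (a bidirectional gene is not double-counted; `mode="sum"` pools).
Counts inside the IQR are high-priority, inside the 90% CI candidates,
otherwise unmatched.  Classification is invariant under any monotone
transformation applied jointly to values and thresholds.

The heterogeneity screen is a deliberately simplified surrogate for the full
stochastic-profiling filter: genes detected in at least half of the
condition's biological samples and reproducible across pool-and-split
replicates (≤5-fold span) are tested with a one-sided F test of biological
log-variance against max(pool-split variance, CV floor), then BH-adjusted at
FDR 0.1.  The reference CV (0.2) maps to the log2 scale via the small-CV
lognormal approximation, variance floor (0.2/ln 2)².  The printed parameter
set (detection P 0.1, max fold-change 5, sampling FDR 0.05, reference CV
0.2, heterogeneity FDR 0.1) is carried in `HeterogeneityParams` so the full
pipeline can be substituted; `fdr_sampling` is accepted but unused by the
surrogate.

Penetrance summaries use the variance-stabilizing arcsine-square-root
transform with two-sided t tests on the transformed scale; zero-total
replicates are excluded with a note.

## Morphometry

- **Circularity** = 4π·area/perimeter².  Perimeter comes from
  marching-squares contours simplified by Douglas-Peucker (tolerance 1 px).
  Unsimplified digital perimeters overestimate smooth shapes (disc
  circularity ≈0.92) while Crofton-style estimators underestimate polygons
  (square ≈0.88); the simplified contour recovers both analytic limits
  (disc 0.99, square 0.795 vs π/4 ≈ 0.785) within the documented digital
  tolerance δ = 0.05.  Border-touching objects are measured but flagged.
- **Size stratification** keeps objects with area at or above the
  (100−35)th percentile; ties at the threshold are kept.
- **PLA spot calling**: 15×15 Laplacian-of-Gaussian (σ = 1 px, implemented
  as `gaussian_laplace` with truncation at 7σ), response negated so bright
  spots are positive, threshold 5 photons on the filtered response,
  connected components collapse to one spot at the response maximum.  Spots
  are assigned to the nearest nucleus by centroid distance (no distance cap
  by default); nuclei outside 100–400 µm² are dropped together with their
  assigned spots.
- **Colocalized N/C**: per channel morphological top-hat (structuring
  element radius 50 px, much larger than a cell, so cell-scale signal
  survives; a decomposed disk footprint keeps it fast), quantile
  normalization of the two channels onto their average sorted profile,
  pixel-wise geometric mean, then per-cell nuclear mean ÷ cytoplasmic mean.
  The average-profile target makes channel rescaling invariant in
  distribution and per-cell ratios stable to ≲1%.

## Synthetic data

Generators are pure functions of parameters + seed and always return ground
truth.  The expression cohort mirrors the experimental design: 20 biological
outgrowths plus 16 pool-and-split 10-cell equivalents per condition;
frequency-matched genes occupy a high expression state (default +2 log2)
in each treated outgrowth with probability 0.35 and in each untreated
outgrowth at the 10% background rate that motivated the percentile
thresholds.  The background state matters: without it the expected matched
count would be ~8.3 (7 true events plus ~10% null exceedances) rather than
the binomial mean 7 that the statistic is built around.  Pool-and-split
values carry technical noise around the condition mean computed in linear
intensity space, since a pooled lysate averages cell states linearly.

Outgrowth masks are unions of overlapping discs whose exact area and
perimeter (hence circularity) come from analytic geometry (`shapely`).  PLA
images are Poisson photon counts with Gaussian spots (default peak 25
photons, giving a ≈12.5-photon matched-filter response and a ≈5σ margin
over the 5-photon threshold; spots are placed ≥8σ apart so they remain
resolvable, and closer pairs would be flagged); nuclear areas span the
100–400 µm² gate with the first and last nucleus deliberately outside it.
Generation validates that filtered pure-background images cannot approach
the spot threshold.

What passing on this synthetic data does *not* show: microarray probe-level
artifacts, normalization effects, correlated gene-gene structure, realistic
outgrowth shapes beyond disc unions, optical aberrations, or any absolute
agreement with measured reporter N/C values — the model outputs are
compared only at the level of directions, orderings and intervals stated for the
experimental system.

## Numerical and degenerate-input policy

Missing rate constants are errors, never silent defaults.  Non-converged
steady states are returned flagged, never fabricated.  Degenerate inputs
(all-tied stratifier, empty masks, missing pool-split reference,
out-of-range probabilities) raise `ValueError` with the offending field.
All randomness flows through explicit integer seeds; there is no hidden
global RNG state.

## Known limitations

- The transport parameterization is a reconstruction; absolute N/C values
  (NLS ≈ 4.60, 2xNLS ≈ 4.62, IBB ≈ 18.6 at base) are not calibrated to
  measured reporter data and should be read comparatively, not absolutely.
- The feedback is a steady-state constraint; no kinetics of CSE1L induction
  or miR-205 maturation are modelled.
- The heterogeneity screen is a surrogate, not the published
  stochastic-profiling algorithm; dataset-level gene counts from the real
  microarray cohort
  are out of scope.
- Deterministic ODEs only; no stochastic simulation.
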