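# Methods

## Expected values over kinetic priors

For a reaction network M with rate parameters θ and a bounded objective
f(θ) computed from a simulated trajectory, the quantity of interest is the
prior-averaged expected value

    Z = ∫ f(θ) P(θ | M) dθ,

the same integral as a Bayesian evidence with the objective in place of the
likelihood.  Z measures how reliably a network wiring produces an outcome
*across all plausible kinetics*, which makes it usable when rate constants
are unknown: no calibration or time-course data enters the calculation.
Because the prior is normalized per model, comparing Z across models of
different size automatically charges larger models for their larger
parameter spaces, exactly as evidence-based model comparison does.

### Priors

Each elementary reaction carries one rate constant, classed by reaction
type, with independent log10-uniform priors spanning four orders of
magnitude around generic plausible rates:

| class                | log10 range | units                        |
|----------------------|-------------|------------------------------|
| 1st-order forward    | [−4, 0]     | s⁻¹                          |
| 2nd-order forward    | [−8, −4]    | (molecules/cell)⁻¹·s⁻¹       |
| 1st-order reverse    | [−4, 0]     | s⁻¹                          |
| catalysis            | [−1, 3]     | s⁻¹                          |

Subnetworks keep the parameter identifiers of the full model, so a shared
reaction has an identical prior in every variant.

### Nested sampling

`evnest.sampler.run` implements the classic nested-sampling estimator: N
live points are drawn from the prior and scored; at each iteration the
worst point (objective L_low) is replaced by a new prior draw constrained
to score at least L_low, the enclosed prior mass shrinks as X_i = e^(−i/N),
and the rectangle-rule sum Σ L_low,i (X_{i−1} − X_i) accumulates.  The run
terminates when the largest possible remaining contribution L_high·X_i
falls below the termination tolerance (default 1e-4), after which the mean
live objective times X_final is added; this final correction is what makes
the constant-objective identity Z = c hold exactly.  Defaults are
n_live = 16,000 and tolerance 1e-4 (full-scale settings); desk-scale
analyses and the test suite use 100–500 live points.

Additional termination paths:

* **plateau** — when every live point is tied to within `plateau_tol`
  (default 1e-9, i.e. less than the ODE integrator's own tolerance), the
  live set carries no ordering information and the run stops with the live
  correction applied.  For objectives that saturate (a cleavage fraction
  pinned at 1.0) the correction is exact; without this rule a saturated run
  stalls trying to beat a bit-for-bit tie.
* **max_evaluations / stalled** — the evaluation budget, or the
  per-iteration proposal try cap, was exhausted; the estimate is returned
  with the mass accounted so far plus the live correction and flagged
  accordingly.

Failed objective evaluations (ODE integration failures on pathological
corners of the prior) score 0 and count toward the evaluation total, so the
integral remains defined over the whole prior box.  Runs are bit-for-bit
reproducible for a fixed (seed, configuration, objective) in serial mode.

### Constrained proposals

Replacement draws must be uniform on the prior restricted to
{θ : f(θ) ≥ L_low}.  The bound is a single enlarged ellipsoid of the live
points (covariance ellipsoid scaled so the farthest point lies on its
surface, then enlarged by 1.25 in radius) intersected with the prior box.
Uniformity on the intersection is obtained by drawing from whichever
container — ellipsoid or box — has smaller volume and rejecting draws
outside the other.

When n_live < 2·dim the sample covariance is unreliable: it develops
spuriously thin axes whose ellipsoid geometrically rejects nearly every
draw and stalls the run (observed directly on the 62-parameter complete
network at n_live ≈ 100).  In that regime, and whenever the covariance is
singular, the bound is instead the enlarged axis-aligned bounding box of
the live points clipped to the prior: robust in any dimension, exact to
sample from, and still shrinking with the constrained region.  Multi-modal
mode separation (multi-ellipsoid clustering) is deliberately out of scope;
the objectives here are smooth and effectively unimodal at desk scale.

Ties at L_low are broken by uniform random choice among the tied points.

### Error estimate

The reported uncertainty is the standard information-based estimate: with
H = Σ p_i ln(L_i/Z) (p_i the posterior mass of each dead/live
contribution), the ln Z uncertainty is √(H/N), propagated to Z as
Z·√(H/N).  An identically-zero objective carries no information; its error
is reported as 0 with a warning.  On the Gaussian fixture the reported
error tracks the empirical replicate spread within a factor of ~1.5 and
shrinks as n_live^(−1/2); evaluation counts grow roughly linearly in
n_live (both checked in the test suite).

## The apoptosis model

`evnest.apoptosis.build_full_model` constructs a reduced extrinsic-apoptosis
network at EARM scale: 50 species, 62 elementary mass-action reactions, 62
rate parameters, 16 species at nonzero initial copies.  Mechanism, by motif
(reversible binding = 2 elementary reactions; catalysis = bind/unbind/convert
= 3; translocation = 2):

| stage | motifs |
|-------|--------|
| DISC assembly | Ligand+Receptor ⇌; L:R+FADD ⇌ DISC; DISC catalyzes pC8→C8 |
| direct caspase (Type I) | C8 catalyzes pC3→C3 |
| execution | C3 catalyzes PARP→cPARP; XIAP catalyzes C3 degradation (sequestration + ubiquitin-mediated loss) |
| feed-forward loop | C3 catalyzes pC6→C6; C6 catalyzes pC8→C8 |
| MOMP (Type II) | C8 catalyzes Bid→tBid; tBid ⇌ tBid_mito; tBid_mito catalyzes Bax→aBax; aBax ⇌ Bax_mito; Bax_mito+Bax_mito ⇌ Bax2; Bax2+Bax2 ⇌ Bax4 (pore) |
| Bcl-2 regulation | Bcl2 binds tBid_mito, Bax_mito, Bax2; Bad (sensitizer) binds Bcl2 |
| release | Bax4 catalyzes CytoC_mito→CytoC and Smac_mito→Smac |
| apoptosome | CytoC catalyzes Apaf→aApaf; aApaf+pC9 ⇌ Apop; Apop catalyzes pC3→C3 |
| XIAP opposition | Apop+XIAP ⇌; Smac+XIAP ⇌ |

That is 12 catalysis motifs (36 reactions), 11 reversible bindings (22) and
2 reversible translocations (4) — 62 reactions, one parameter each.  Two
accumulators integrate the instantaneous rate of the two Caspase-3
conversion reactions as extra ODE components, so cumulative pathway
attribution is exact regardless of the output grid.  Attribution follows
the *immediate* catalyst: Caspase-3 activated by feedback-derived Caspase-8
still counts as the direct-caspase route.

State is in molecules per cell (deterministic continuum approximation, no
compartment-volume corrections).  Default initial copy numbers live in
`src/evnest/data/initial_conditions.yaml`; FADD and procaspase-8 (130,000),
procaspase-3 (21,000) and mitochondrial Smac (100,000) are fixed by the
modeled conditions, the remainder are literature-typical Type II
(HeLa/Jurkat-like) abundances and are configurable.  The simulation horizon
defaults to 20,000 s with 201 output points (2,001+ recommended for flux
objectives), a convention from the extrinsic-apoptosis modeling literature.

### Integration

`simulate` uses LSODA with the analytic Jacobian at rtol = atol = 1e-6; on
failure it retries once at 10× tighter tolerances and otherwise returns a
trajectory flagged `success=False` (never an exception), so prior-wide
integration loops cannot abort on stiff corners.  Accumulator series are
made exactly nondecreasing with a running maximum, removing solver
round-off at the 1e-9 level.

### Knockout subnetworks

Six variants implement in-silico knockouts by *removing* species content
(and every reaction touching it), not by zeroing abundances — each variant
is a distinct model whose expected value integrates over a correspondingly
reduced parameter space:

| code | catalogue name     | removed content |
|------|--------------------|-----------------|
| A    | `caspase`          | everything mitochondrial |
| B    | `caspase+mito_act` | Smac arm (Smac, its release, Smac:XIAP) |
| C    | `caspase+xiap_inh` | apoptosome arm (CytoC, Apaf, pC9, Apop and partners) |
| D    | `mito_act`         | direct C8→C3 link and the Smac arm |
| E    | `full`             | nothing |
| F    | `mito_full`        | direct C8→C3 link |

Species nesting A ⊂ B ⊂ E and D ⊂ F ⊂ E holds by construction.

## Objectives

* **PARP cleavage** (`parp_cleavage`): cPARP(T) divided by the conserved
  PARP-moiety total (PARP + C3:PARP + cPARP), evaluated at the final time.
* **Pathway flux** (`pathway_flux`): Σ_t [cum_pathway(t)/cum_total(t)] ×
  [cPARP(t) − cPARP(t−1)] / tPARP over the trajectory grid, with the
  fraction defined as 0 before any Caspase-3 activation.  Normalizing by
  the PARP total makes the two pathway fluxes sum to the cleavage fraction
  term by term, so flux and cleavage trends are directly comparable on one
  axis.

Both are dimensionless fractions in [0, 1].  `make_objective` composes
simulation and objective into a map θ → value, scoring failed integrations
as 0 with a logged warning.

## Scans, ratios, trend analysis

`run_scan` produces one independent nested-sampling estimate per
(variant, regulator value) with per-point seeds derived from
SHA-256(base seed, variant, grid index) — reproducible, independent
streams; records append to CSV as they complete so interrupted scans
resume.  The expected-value ratio

    EVR(Z1, Z2) = Z1/Z2 − 1   if Z1 > Z2,    −Z2/Z1 + 1   if Z1 < Z2,    0 at equality

is a signed, antisymmetric Bayes-factor analogue that is continuous across
Z1 = Z2.  Level crossings are located by linear interpolation between the
bracketing grid points (first downward crossing, extra crossings logged);
peaks by argmax after a centered moving average (default window 5,
ties → smallest regulator value).  Crossing and peak detection operate on
raw Z values; errors are carried through outputs but not used as weights.

## Fixtures (synthetic benchmarks)

Every sampler claim is calibrated on fixtures with executable, independent
truth recipes: `constant` (closed form), `linear` (mean of a uniform
coordinate), `gaussian2d` (adaptive quadrature at 1e-10), `chain3` (a
two-step conversion chain with a closed-form per-point objective,
quadrature over the prior), and `toy_inhibitor` (catalyst/substrate/
inhibitor network; truth by plain Monte-Carlo prior integration).  These
fixtures exercise the estimator, the error scale, the cost scaling, and
scan monotonicity without apoptosis-model cost.  What they do *not*
establish: fixture objectives are smooth and unimodal, so passing tests say
nothing about multimodal integrands, and the apoptosis model itself is a
reconstruction (see limitations).

## Problem sizes used by the shipped tests and script

The test suite and `scripts/acceptance.py` run at desk scale as the
package's default analysis setting: n_live 100–200, coarse XIAP grids
(4–8 points between 0 and 150,000), evaluation caps of 20,000–50,000, and
termination tolerance 1e-4.  At these settings an expected-value estimate
on the apoptosis networks carries a reported error of roughly 0.02–0.04,
and a 0.5-crossing position estimated from a scan inherits roughly 15–25%
uncertainty (objective error propagated through the local trend slope).
Full-resolution scans (801 grid points, n_live = 16,000) are
config-selectable but take cluster-scale resources.

## Known limitations

* The apoptosis network is a reconstruction from the published structural
  counts and mechanism description; the original model's exact reaction
  list, most initial abundances, and simulation horizon are not public.
  The mitochondrial arm of this reconstruction transmits the death signal
  somewhat less reliably than the original: the mitochondria-only variants
  D and F average ≈0.93 cleavage at XIAP = 0 (verified against plain
  Monte-Carlo integration) rather than >0.98, and their XIAP
  half-suppression points sit correspondingly lower.  Comparisons *between*
  variants and trend shapes are the intended use, and those reproduce the
  published qualitative behavior.
* Single-bound constrained sampling: no multi-ellipsoid clustering, no
  importance nested sampling, no posterior samples.
* Deterministic ODE semantics only: no stochastic simulation, no spatial
  or rule-based modeling.
* Parallel objective evaluation is not implemented; the sampler contract
  (order-stable, seed-reproducible results) is satisfied trivially in
  serial mode.
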