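# evnest

Probabilistic exploration of signal-execution mechanisms in mass-action
reaction networks when rate constants are unknown.

Biochemical network models typically depend on dozens of kinetic parameters
that are poorly characterized, and calibrating them needs time-course data
that often does not exist.  `evnest` sidesteps calibration: instead of one
fitted parameter set, it computes the **expected value of a simulated
outcome over the entire prior distribution of rate constants**,

    Z = ∫ f(θ) P(θ | M) dθ,

the same integral as a Bayesian evidence with the objective f in place of a
likelihood, estimated by **nested sampling** (live-point population,
geometric prior-mass shrinkage X_i = e^(−i/N), rectangle-rule accumulation
Σ L_i (X_{i−1} − X_i)).  Trends in Z across network variants and regulator
concentrations identify which wiring executes a signal and which molecular
players control the route — with no fitted parameters anywhere.

The package ships a worked application: a reduced extrinsic-apoptosis
network (50 species, 62 mass-action reactions) and its six knockout
subnetworks, used to map Type I (direct caspase) versus Type II
(mitochondria-dependent) apoptosis execution as functions of the inhibitor
XIAP, DISC strength, and Bcl-2.  Two objectives quantify execution:

* **PARP cleavage** — cPARP(T)/tPARP, the fraction of the conserved PARP
  pool cleaved by the end of the simulation (the standard cell-death proxy);
* **pathway flux** — the fraction of PARP cleavage attributable to each
  Caspase-3-activation route (direct Caspase-8 vs. apoptosome), computed
  from exact cumulative-flux accumulators integrated alongside the ODEs.

Signed expected-value ratios, EVR = Z1/Z2 − 1 (Z1 > Z2) or −Z2/Z1 + 1
(Z1 < Z2), compare variants the way Bayes factors compare models.

Intended users: systems/computational biologists who want
evidence-style comparisons of network hypotheses from structure alone, and
anyone needing a compact, tested nested-sampling integrator for expensive
simulation objectives over box priors.

## Worked example

Expected PARP cleavage of all six knockout variants with the inhibitors
XIAP and Bcl-2 removed (`python examples/03_knockout_subnetworks.py`,
n_live = 100, about two minutes):

```
A (caspase         ) Z = 0.9993 +/- 0.0002   direct caspase pathway only
B (caspase+mito_act) Z = 0.9997 +/- 0.0001   direct caspase + mitochondrial activation (no Smac arm)
C (caspase+xiap_inh) Z = 0.9995 +/- 0.0002   direct caspase + mitochondrial inhibition of XIAP (no apoptosome arm)
D (mito_act        ) Z = 0.9719 +/- 0.0142   mitochondrial activation only (no direct caspase link, no Smac arm)
E (full            ) Z = 0.9963 +/- 0.0016   complete network
F (mito_full       ) Z = 0.9039 +/- 0.0272   full mitochondrial subnetwork (no direct caspase link)
```

Every Z is the prior-averaged cleavage fraction for that wiring: values
near 1 mean the variant executes apoptosis across essentially all plausible
kinetics once its inhibitors are absent.  The purely mitochondrial routes
(D, F) are the least reliable transmitters because their longer reaction
chain fails to complete within the simulated window on a larger share of
the prior.

Pathway-flux attribution on the complete network
(`python examples/05_pathway_flux.py`, XIAP = 50,000) shows the execution
route switching with signal strength:

```
high DISC (XIAP=50,000, Bcl-2=0):
  flux_caspase         Z = 0.4608 +/- 0.0434
  flux_mitochondrial   Z = 0.0956 +/- 0.0170

low DISC (XIAP=50,000, Bcl-2=0):
  flux_caspase         Z = 0.2562 +/- 0.0341
  flux_mitochondrial   Z = 0.2209 +/- 0.0306
```

With strong receptor signaling (130,000 copies of FADD and procaspase-8)
the direct caspase route carries most of the death signal; weakening the
DISC to 100 copies pulls the routes to near-parity — weak signal initiation
pushes execution through the mitochondrial amplifier, the Type II trait.

The remaining examples simulate a single parameter draw
(`01_simulate_apoptosis_model.py`), calibrate the sampler against fixtures
with closed-form or quadrature ground truth
(`02_expected_value_fixtures.py`), and sweep XIAP to locate half-maximal
cleavage crossings and the EVR peak (`04_xiap_scan_and_evr.py`; at its
quick settings — five grid points, n_live = 100 — single-run noise of
±0.03 on each Z is clearly visible in the printed trends, which is the
point: the example also prints the per-estimate errors that quantify it).

## Command line

A thin CLI wraps the library:

```bash
evnest model show full                 # structure of a catalogue model
evnest sample --model caspase --set XIAP=0 --n-live 150 --seed 1
evnest scan --config config.yaml      # regulator grid scan -> CSV (resumable)
evnest evr --scan-csv scan.csv --numerator E --denominator A
evnest precision --fixture gaussian2d --populations 100,200,400
evnest export --model full --out model.yaml
```

Scan configs are strict-schema YAML; unknown keys are rejected and defaults
(n_live 16,000, termination tolerance 1e-4) are materialized and logged.
Networks serialize losslessly to a structured-text YAML format.

## Layout

```
src/evnest/
  network.py     mass-action networks, stiff ODE simulation, conservation analysis
  apoptosis.py   the reduced apoptosis model, knockout variants, regulator settings
  objectives.py  PARP-cleavage and pathway-flux objectives
  sampler.py     nested-sampling expected-value estimator
  scan.py        regulator scans, EVR, crossings/peaks, precision study
  fixtures.py    benchmark objectives with executable ground truth
  config.py      strict YAML run configuration
  serialize.py   lossless network (de)serialization
  cli.py         command-line interface
docs/methods.md  model, estimator, numerical choices, limitations
examples/        one narrative script per capability
```
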