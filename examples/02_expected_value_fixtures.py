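"""Nested-sampling expected values on fixtures with known ground truth.

Each fixture carries an independent truth recipe (closed form or adaptive
quadrature); the sampler estimate should agree within about three times its
reported error.  This is the calibration exercise to run before trusting
estimates on networks where no truth is available.
"""

from evnest import SamplerConfig, build_fixture, run

for name in ("constant", "linear", "gaussian2d", "chain3"):
    fx = build_fixture(name, t_end=2000.0)
    est = run(fx.objective, fx.prior, SamplerConfig(n_live=200, seed=1))
    print(f"{name:10s} Z = {est.value:.4f} +/- {est.error:.4f}   "
          f"truth = {fx.truth:.4f}  ({fx.provenance}; {est.n_evaluations} evaluations)")
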