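"""Benchmark fixtures with executable ground-truth recipes.

Each fixture bundles an objective (analytic, or a small reaction network
plus simulation-backed objective), the prior it is integrated over, and a
recipe that computes the true expected value independently of the nested
sampler (closed form, deterministic quadrature, or plain Monte Carlo).
They calibrate and regression-test the sampler without the cost of the
apoptosis model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate

from .network import ParameterVector, Reaction, ReactionNetwork, Species, simulate
from .objectives import make_objective
from .sampler import PriorSpec

FIXTURE_NAMES = ("constant", "linear", "gaussian2d", "chain3", "toy_inhibitor")

_CONSTANT_VALUE = 0.7
_GAUSS_SIGMA = 0.2
_GAUSS_CENTER = 0.5


@dataclass
class Fixture:
    """A named objective with its prior and an independent truth recipe."""

    name: str
    objective: Callable[[ParameterVector], float]
    prior: PriorSpec
    truth_recipe: Callable[[], float]
    provenance: str
    network: ReactionNetwork | None = None
    _truth: float | None = field(default=None, repr=False)

    @property
    def truth(self) -> float:
        if self._truth is None:
            self._truth = float(self.truth_recipe())
        return self._truth


def _unit_prior(dim: int) -> PriorSpec:
    """Log10-uniform prior over ``dim`` generic first-order rates ([-4, 0])."""
    ids = tuple(f"x{i + 1}" for i in range(dim))
    return PriorSpec(parameter_ids=ids, classes={i: "first_order_forward" for i in ids})


def _unit_coords(prior: PriorSpec, theta: ParameterVector) -> np.ndarray:
    lo, hi = prior.bounds()
    x = np.array([math.log10(theta[p]) for p in prior.parameter_ids])
    return (x - lo) / (hi - lo)


def _chain3_network() -> ReactionNetwork:
    """Linear conversion chain PARP -> M -> cPARP with two first-order steps.

    Species are named so the PARP-cleavage objective applies: the terminal
    product plays the role of cleaved PARP and the closed-form two-step
    conversion fraction is the exact objective value.
    """
    return ReactionNetwork(
        species=(
            Species("PARP", "cytosol", 1000.0),
            Species("M", "cytosol", 0.0),
            Species("cPARP", "cytosol", 0.0),
        ),
        reactions=(
            Reaction("step1", ("PARP",), ("M",), "first_order_forward", "k1"),
            Reaction("step2", ("M",), ("cPARP",), "first_order_forward", "k2"),
        ),
    )


def chain3_fraction(k1: float, k2: float, t: float) -> float:
    """Closed-form terminal fraction of the two-step chain at time ``t``."""
    if math.isclose(k1, k2, rel_tol=1e-12):
        return 1.0 - (1.0 + k1 * t) * math.exp(-k1 * t)
    return 1.0 - (k2 * math.exp(-k1 * t) - k1 * math.exp(-k2 * t)) / (k2 - k1)


def _toy_inhibitor_network(inhibitor_copies: float = 0.0) -> ReactionNetwork:
    """Catalyst E converts S to the product; an inhibitor sequesters E.

    The product species is named ``cPARP`` (and the substrate ``PARP``) so
    the standard cleavage objective reads the conversion fraction; the
    inhibitor copy number is the scan regulator.
    """
    return ReactionNetwork(
        species=(
            Species("E", "cytosol", 100.0),
            Species("PARP", "cytosol", 1000.0),
            Species("cPARP", "cytosol", 0.0),
            Species("I", "cytosol", inhibitor_copies),
            Species("E:PARP", "cytosol", 0.0),
            Species("E:I", "cytosol", 0.0),
        ),
        reactions=(
            Reaction("bind_E_PARP", ("E", "PARP"), ("E:PARP",),
                     "second_order_forward", "k_bind"),
            Reaction("unbind_E_PARP", ("E:PARP",), ("E", "PARP"),
                     "first_order_reverse", "k_unbind"),
            Reaction("cat_E_PARP", ("E:PARP",), ("E", "cPARP"),
                     "catalysis", "k_cat"),
            Reaction("bind_E_I", ("E", "I"), ("E:I",),
                     "second_order_forward", "k_inh_bind"),
            Reaction("unbind_E_I", ("E:I",), ("E", "I"),
                     "first_order_reverse", "k_inh_unbind"),
        ),
    )


def monte_carlo_expected_value(
    objective, prior: PriorSpec, n_samples: int, seed: int = 0
) -> float:
    """Plain Monte-Carlo prior integration (the brute-force oracle)."""
    rng = np.random.default_rng(seed)
    xs = prior.sample(rng, n_samples)
    return float(np.mean([float(objective(prior.to_params(x))) for x in xs]))


def build_fixture(name: str, t_end: float = 20_000.0, **kwargs) -> Fixture:
    """Construct one of the named benchmark fixtures.

    ``constant``
        Objective identically 0.7 on a 2-D prior; truth is 0.7 exactly.
    ``linear``
        Objective equal to the first coordinate mapped to [0, 1]; truth 0.5
        (mean of a uniform variate).
    ``gaussian2d``
        Isotropic Gaussian bump on the unit square; truth by adaptive
        quadrature at tolerance 1e-10.
    ``chain3``
        Two-step conversion chain; simulation objective with a closed-form
        per-point value, truth by quadrature of the closed form over the prior.
    ``toy_inhibitor``
        Catalyst/substrate/inhibitor network (``inhibitor_copies`` keyword
        sets the regulator); truth by plain Monte-Carlo prior integration
        (``n_samples`` keyword, default 300; ``seed`` keyword).
    """
    if name == "constant":
        prior = _unit_prior(2)
        return Fixture(
            name, lambda theta: _CONSTANT_VALUE, prior,
            truth_recipe=lambda: _CONSTANT_VALUE,
            provenance="closed form: constant integrand",
        )

    if name == "linear":
        prior = _unit_prior(2)
        return Fixture(
            name, lambda theta: float(_unit_coords(prior, theta)[0]), prior,
            truth_recipe=lambda: 0.5,
            provenance="closed form: mean of a uniform coordinate",
        )

    if name == "gaussian2d":
        prior = _unit_prior(2)
        s2 = 2.0 * _GAUSS_SIGMA**2

        def bump(theta: ParameterVector) -> float:
            u = _unit_coords(prior, theta)
            return math.exp(-((u[0] - _GAUSS_CENTER) ** 2 + (u[1] - _GAUSS_CENTER) ** 2) / s2)

        def quadrature_truth() -> float:
            val, _ = integrate.dblquad(
                lambda v, u: math.exp(
                    -((u - _GAUSS_CENTER) ** 2 + (v - _GAUSS_CENTER) ** 2) / s2
                ),
                0.0, 1.0, 0.0, 1.0, epsabs=1e-10, epsrel=1e-10,
            )
            return val

        return Fixture(name, bump, prior, quadrature_truth,
                       provenance="adaptive quadrature, tolerance 1e-10")

    if name == "chain3":
        network = _chain3_network()
        prior = PriorSpec.for_network(network)
        objective = make_objective(network, "parp_cleavage", t_end=t_end)

        def quadrature_truth() -> float:
            val, _ = integrate.dblquad(
                lambda b, a: chain3_fraction(10.0**a, 10.0**b, t_end),
                -4.0, 0.0, -4.0, 0.0, epsabs=1e-10, epsrel=1e-10,
            )
            return val / 16.0  # normalize by the prior box area

        return Fixture(name, objective, prior, quadrature_truth,
                       provenance="quadrature of the closed-form two-step conversion",
                       network=network)

    if name == "toy_inhibitor":
        inhibitor = float(kwargs.pop("inhibitor_copies", 0.0))
        n_samples = int(kwargs.pop("n_samples", 300))
        seed = int(kwargs.pop("seed", 0))
        network = _toy_inhibitor_network(inhibitor)
        prior = PriorSpec.for_network(network)
        objective = make_objective(network, "parp_cleavage", t_end=t_end)
        return Fixture(
            name, objective, prior,
            truth_recipe=lambda: monte_carlo_expected_value(objective, prior, n_samples, seed),
            provenance=f"plain Monte-Carlo prior integration, n={n_samples}",
            network=network,
        )

    raise ValueError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
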