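"""Objective functions integrated by the sampler.

Two objectives quantify apoptotic signal execution on a simulated
trajectory, both as dimensionless fractions in [0, 1]:

* :func:`parp_cleavage` -- the fraction of the conserved PARP pool cleaved
  by the end of the simulation (the standard proxy for cell death).
* :func:`pathway_flux` -- the fraction of PARP cleavage attributable to one
  of the two Caspase-3-activation routes (direct caspase vs. mitochondrial),
  computed by weighting each increment of PARP cleavage with the cumulative
  share of Caspase-3 activated via the target route up to that time.

Pathway fluxes are normalized by the total PARP pool so that
``flux(caspase) + flux(mitochondrial) == parp_cleavage`` term by term
whenever any Caspase-3 has been activated; both can then be plotted on the
same axis as the cleavage objective.  Caspase-3 activation is attributed
to its *immediate* catalyst: feedback-derived Caspase-8 activity still
counts as the direct-caspase route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import NetworkConfigError, ParameterVector, ReactionNetwork, Trajectory, simulate
from .apoptosis import CASPASE_ACC, MITO_ACC

logger = logging.getLogger(__name__)

#: pathway tag -> registered Caspase-3-activation accumulator
PATHWAY_ACCUMULATORS = {
    "caspase": CASPASE_ACC,
    "mitochondrial": MITO_ACC,
}

#: selector string -> objective kind (for configs and the CLI)
OBJECTIVE_KINDS = ("parp_cleavage", "flux_caspase", "flux_mitochondrial", "flux_total")

_PARP_SPECIES = ("PARP", "C3:PARP", "cPARP")


@dataclass(frozen=True)
class ObjectiveValue:
    """A dimensionless objective value, clipped to round-off, in [0, 1]."""

    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"objective value {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


def _clip01(x: float) -> float:
    return float(min(max(x, 0.0), 1.0))


def _parp_total(traj: Trajectory) -> float:
    """Conserved PARP-moiety total (PARP + C3:PARP + cPARP at t=0)."""
    missing = [s for s in ("PARP", "cPARP") if s not in traj.species_names]
    if missing:
        raise NetworkConfigError(f"trajectory lacks PARP-moiety species: {missing}")
    total = sum(
        traj.series(s)[0] for s in _PARP_SPECIES if s in traj.species_names
    )
    if total <= 0:
        raise NetworkConfigError("PARP-moiety total is zero; cleavage fraction undefined")
    return total


def parp_cleavage(traj: Trajectory) -> ObjectiveValue:
    """Fraction of the PARP pool cleaved at the final time point."""
    return ObjectiveValue(_clip01(traj.series("cPARP")[-1] / _parp_total(traj)))


def pathway_flux(traj: Trajectory, pathway: str) -> ObjectiveValue:
    """Fraction of PARP cleavage carried by one Caspase-3-activation route.

    Computes ``sum_t f_pathway(t) * (cPARP(t) - cPARP(t-1)) / tPARP`` over
    the trajectory grid, where ``f_pathway(t)`` is the share of cumulative
    Caspase-3 activation contributed by the target route up to time ``t``.
    Before any Caspase-3 has been activated the share is defined as 0 (no
    PARP can have been cleaved, so those terms vanish anyway).
    """
    if pathway not in PATHWAY_ACCUMULATORS:
        raise NetworkConfigError(
            f"unknown pathway {pathway!r}; valid tags: {sorted(PATHWAY_ACCUMULATORS)}"
        )
    acc_name = PATHWAY_ACCUMULATORS[pathway]
    if acc_name not in traj.accumulator_values:
        raise NetworkConfigError(
            f"trajectory carries no {acc_name!r} accumulator; network not instrumented "
            f"for pathway {pathway!r}"
        )
    total_parp = _parp_total(traj)
    cum_path = traj.accumulator_values[acc_name]
    cum_total = np.zeros_like(cum_path)
    for name in PATHWAY_ACCUMULATORS.values():
        if name in traj.accumulator_values:
            cum_total = cum_total + traj.accumulator_values[name]
    cparp = traj.series("cPARP")
    d_cparp = np.diff(cparp)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cum_total[1:] > 0, cum_path[1:] / cum_total[1:], 0.0)
    return ObjectiveValue(_clip01(float(np.sum(frac * d_cparp)) / total_parp))


def make_objective(
    network: ReactionNetwork,
    kind: str = "parp_cleavage",
    t_end: float = 20_000.0,
    n_points: int = 201,
):
    """Compose ``simulate`` with an objective into a map ``theta -> ObjectiveValue``.

    Failed integrations score 0 (with a logged warning) so that prior
    integrals remain defined over the whole parameter box.  Flux objectives
    require the corresponding accumulator to be registered on ``network``.
    """
    if kind not in OBJECTIVE_KINDS:
        raise NetworkConfigError(
            f"unknown objective kind {kind!r}; valid kinds: {OBJECTIVE_KINDS}"
        )
    acc_names = set(network.accumulator_names)
    needed = {
        "flux_caspase": {CASPASE_ACC},
        "flux_mitochondrial": {MITO_ACC},
        "flux_total": set(),  # sum over whichever routes the network carries
    }.get(kind, set())
    if not needed <= acc_names:
        raise NetworkConfigError(
            f"objective {kind!r} needs accumulators {sorted(needed)}; "
            f"network carries {sorted(acc_names)}"
        )
    if kind != "parp_cleavage" and not acc_names:
        raise NetworkConfigError(f"objective {kind!r} needs at least one accumulator")

    def objective(theta: ParameterVector) -> ObjectiveValue:
        traj = simulate(network, theta, t_end=t_end, n_points=n_points)
        if not traj.success:
            logger.warning("integration failed; objective scored 0 (%s)", traj.message)
            return ObjectiveValue(0.0)
        if kind == "parp_cleavage":
            return parp_cleavage(traj)
        if kind == "flux_caspase":
            return pathway_flux(traj, "caspase")
        if kind == "flux_mitochondrial":
            return pathway_flux(traj, "mitochondrial")
        total = 0.0
        for tag, acc in PATHWAY_ACCUMULATORS.items():
            if acc in traj.accumulator_values:
                total += float(pathway_flux(traj, tag))
        return ObjectiveValue(_clip01(total))

    objective.kind = kind
    return objective
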