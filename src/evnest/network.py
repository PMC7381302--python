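"""Mass-action reaction networks simulated as deterministic ODE systems.

A :class:`ReactionNetwork` is a list of species with initial copy numbers
and a list of elementary mass-action reactions (at most bimolecular).
Networks may register *accumulators*: cumulative integrals of the
instantaneous rates of selected reactions, integrated as extra ODE
components so that pathway attribution is exact regardless of the output
grid.  All state is in molecules per cell (dimensionless counts) under a
deterministic continuum approximation; no compartment-volume corrections
are applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

logger = logging.getLogger(__name__)

RATE_CLASSES = (
    "first_order_forward",
    "second_order_forward",
    "first_order_reverse",
    "catalysis",
)

FIRST_ORDER_CLASSES = ("first_order_forward", "first_order_reverse", "catalysis")


class NetworkConfigError(ValueError):
    """Raised when a network, parameter set, or instrumentation request is inconsistent."""


@dataclass(frozen=True)
class Species:
    """A chemical species with an initial copy number (molecules per cell)."""

    name: str
    compartment: str = "none"
    initial_copies: float = 0.0

    def __post_init__(self):
        if self.initial_copies < 0:
            raise NetworkConfigError(
                f"species {self.name!r}: initial_copies must be >= 0"
            )
        if self.compartment not in ("cytosol", "mitochondria", "membrane", "none"):
            raise NetworkConfigError(
                f"species {self.name!r}: unknown compartment {self.compartment!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action reaction (order <= 2).

    ``reactants``/``products`` are tuples of species names; a species
    appearing twice reacts with itself (rate k*A^2, consuming two copies).
    ``rate_class`` selects the prior range of the rate constant and must be
    consistent with the molecularity: two reactant units imply
    ``second_order_forward``; one unit implies a first-order or catalysis
    class.
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_class: str
    parameter_id: str

    def __post_init__(self):
        if self.rate_class not in RATE_CLASSES:
            raise NetworkConfigError(
                f"reaction {self.id!r}: unknown rate_class {self.rate_class!r}"
            )
        if len(self.reactants) > 2:
            raise NetworkConfigError(
                f"reaction {self.id!r}: at most bimolecular reactions are supported"
            )
        if len(self.reactants) == 2 and self.rate_class != "second_order_forward":
            raise NetworkConfigError(
                f"reaction {self.id!r}: two reactant units require rate_class "
                "'second_order_forward'"
            )
        if len(self.reactants) == 1 and self.rate_class not in FIRST_ORDER_CLASSES:
            raise NetworkConfigError(
                f"reaction {self.id!r}: single-reactant reactions require a "
                "first-order or catalysis rate_class"
            )


@dataclass(frozen=True)
class ParameterVector:
    """One point in rate-constant space: parameter_id -> rate constant.

    Units are s^-1 for first-order and catalysis constants and
    (molecules/cell)^-1 s^-1 for second-order constants.  All values must
    be strictly positive.
    """

    values: dict[str, float]

    def __post_init__(self):
        for pid, v in self.values.items():
            if not v > 0:
                raise NetworkConfigError(f"parameter {pid!r}: rate constants must be > 0")

    def __getitem__(self, pid: str) -> float:
        return self.values[pid]


@dataclass(frozen=True)
class ReactionNetwork:
    """Species, mass-action reactions, and cumulative-flux accumulators."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    accumulators: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkConfigError("duplicate species names")
        name_set = set(names)
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkConfigError("duplicate reaction ids")
        pids = [r.parameter_id for r in self.reactions]
        if len(set(pids)) != len(pids):
            raise NetworkConfigError("parameter ids must be unique per reaction")
        rid_set = set(rids)
        for r in self.reactions:
            for nm in (*r.reactants, *r.products):
                if nm not in name_set:
                    raise NetworkConfigError(
                        f"reaction {r.id!r} references unknown species {nm!r}"
                    )
        for acc_name, acc_rids in self.accumulators:
            for rid in acc_rids:
                if rid not in rid_set:
                    raise NetworkConfigError(
                        f"accumulator {acc_name!r} references unknown reaction {rid!r}"
                    )

    # -- lookups -----------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def parameter_ids(self) -> list[str]:
        return [r.parameter_id for r in self.reactions]

    @property
    def accumulator_names(self) -> list[str]:
        return [name for name, _ in self.accumulators]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise NetworkConfigError(f"unknown species {name!r}") from None

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_copies for s in self.species], dtype=float)

    def rate_classes(self) -> dict[str, str]:
        """parameter_id -> rate_class."""
        return {r.parameter_id: r.rate_class for r in self.reactions}

    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometry, shape (n_species, n_reactions)."""
        idx = {s.name: i for i, s in enumerate(self.species)}
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for nm in r.reactants:
                S[idx[nm], j] -= 1
            for nm in r.products:
                S[idx[nm], j] += 1
        return S

    def with_initial(self, name: str, copies: float) -> "ReactionNetwork":
        """Copy of the network with one species' initial copy number replaced."""
        i = self.species_index(name)
        if copies < 0:
            raise NetworkConfigError(f"initial copies for {name!r} must be >= 0")
        new = list(self.species)
        new[i] = replace(new[i], initial_copies=float(copies))
        return replace(self, species=tuple(new))


@dataclass
class Trajectory:
    """Time-gridded species copy numbers plus cumulative-flux accumulators.

    ``states`` has shape (n_times, n_species); ``accumulator_values`` maps
    accumulator name -> nondecreasing series of the same length.  ``success``
    is False for integrations that failed even after the tightened-tolerance
    retry; such trajectories carry whatever grid prefix was reached and must
    not be used for objective evaluation.
    """

    times: np.ndarray
    states: np.ndarray
    species_names: list[str]
    accumulator_values: dict[str, np.ndarray] = field(default_factory=dict)
    success: bool = True
    message: str = ""

    def series(self, name: str) -> np.ndarray:
        try:
            return self.states[:, self.species_names.index(name)]
        except ValueError:
            raise NetworkConfigError(f"trajectory has no species {name!r}") from None

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def _compile(network: ReactionNetwork, params: ParameterVector):
    """Index arrays and rate constants for vectorized RHS/Jacobian evaluation."""
    missing = [pid for pid in network.parameter_ids if pid not in params.values]
    if missing:
        raise NetworkConfigError(f"missing rate constants for parameter ids: {missing}")
    idx = {s.name: i for i, s in enumerate(network.species)}
    n_rxn = len(network.reactions)
    k = np.array([params[r.parameter_id] for r in network.reactions])
    i1 = np.zeros(n_rxn, dtype=int)
    i2 = np.full(n_rxn, -1, dtype=int)
    for j, r in enumerate(network.reactions):
        if len(r.reactants) == 0:
            raise NetworkConfigError(f"reaction {r.id!r} has no reactants")
        i1[j] = idx[r.reactants[0]]
        if len(r.reactants) == 2:
            i2[j] = idx[r.reactants[1]]
    S = network.stoichiometric_matrix()
    rid_to_col = {r.id: j for j, r in enumerate(network.reactions)}
    A = np.zeros((len(network.accumulators), n_rxn))
    for a, (_, rids) in enumerate(network.accumulators):
        for rid in rids:
            A[a, rid_to_col[rid]] = 1.0
    return k, i1, i2, S, A


def build_ode_rhs(network: ReactionNetwork, params: ParameterVector):
    """Return ``(rhs, jac)`` implementing mass-action kinetics.

    ``rhs(t, y)`` maps the extended state ``y`` (species copy numbers
    followed by accumulator values) to its derivative; each reaction
    contributes rate ``k * prod(reactant copies)``.  ``jac(t, y)`` is the
    analytic Jacobian of the same system (accumulator columns are zero
    since rates do not depend on accumulator values).
    """
    k, i1, i2, S, A = _compile(network, params)
    n_sp = len(network.species)
    n_acc = len(network.accumulators)
    n = n_sp + n_acc
    has2 = i2 >= 0
    i2c = np.where(has2, i2, 0)

    def rates(y_sp: np.ndarray) -> np.ndarray:
        r = k * y_sp[i1]
        r[has2] *= y_sp[i2c[has2]]
        return r

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        v = rates(y[:n_sp])
        out = np.empty(n)
        out[:n_sp] = S @ v
        if n_acc:
            out[n_sp:] = A @ v
        return out

    n_rxn = len(k)
    cols = np.arange(n_rxn)

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        y_sp = y[:n_sp]
        # d rate_j / d y_i: k_j * (other reactant copies) at the reactant indices
        D = np.zeros((n_rxn, n_sp))
        d1 = k.copy()
        d1[has2] *= y_sp[i2c[has2]]
        np.add.at(D, (cols, i1), d1)
        d2 = k[has2] * y_sp[i1[has2]]
        np.add.at(D, (cols[has2], i2[has2]), d2)
        J = np.zeros((n, n))
        J[:n_sp, :n_sp] = S @ D
        if n_acc:
            J[n_sp:, :n_sp] = A @ D
        return J

    return rhs, jac


def simulate(
    network: ReactionNetwork,
    params: ParameterVector,
    t_end: float = 20_000.0,
    n_points: int = 201,
    rtol: float = 1e-6,
    atol: float = 1e-6,
) -> Trajectory:
    """Integrate the network on a uniform grid [0, t_end].

    Uses a stiff-capable implicit solver (LSODA with the analytic
    Jacobian).  On solver failure the integration is retried once at
    10x tighter tolerances; if that also fails, the returned trajectory is
    flagged ``success=False`` rather than raising, so that prior-integration
    loops over broad rate-constant ranges never abort.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rhs, jac = build_ode_rhs(network, params)
    n_sp = len(network.species)
    y0 = np.concatenate([network.initial_state(), np.zeros(len(network.accumulators))])
    t_eval = np.linspace(0.0, t_end, n_points)

    sol = None
    for trial_rtol, trial_atol in ((rtol, atol), (rtol / 10.0, atol / 10.0)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sol = solve_ivp(
                    rhs,
                    (0.0, t_end),
                    y0,
                    method="LSODA",
                    jac=jac,
                    t_eval=t_eval,
                    rtol=trial_rtol,
                    atol=trial_atol,
                )
            except Exception as exc:  # defensive: solver internals may raise
                sol = None
                message = f"solver raised: {exc}"
                continue
        if sol.success:
            break
        message = sol.message

    if sol is None or not sol.success:
        logger.warning("integration failed after tightened-tolerance retry: %s", message)
        times = sol.t if sol is not None and sol.t.size else np.array([0.0])
        ys = sol.y.T if sol is not None and sol.t.size else y0[None, :]
        return Trajectory(
            times=times,
            states=ys[:, :n_sp],
            species_names=network.species_names,
            accumulator_values={
                name: ys[:, n_sp + a]
                for a, name in enumerate(network.accumulator_names)
            },
            success=False,
            message=str(message),
        )

    ys = sol.y.T
    # Accumulators are integrals of nonnegative rates; enforce monotonicity
    # against solver round-off.
    acc = {
        name: np.maximum.accumulate(ys[:, n_sp + a])
        for a, name in enumerate(network.accumulator_names)
    }
    return Trajectory(
        times=sol.t,
        states=ys[:, :n_sp],
        species_names=network.species_names,
        accumulator_values=acc,
        success=True,
    )


def conserved_moieties(network: ReactionNetwork, tol: float = 1e-10) -> list[np.ndarray]:
    """Basis of conservation vectors (left null space of the stoichiometric matrix).

    Each returned vector ``w`` satisfies ``w @ S == 0``, i.e. the weighted
    species total ``w @ state`` is constant along any trajectory.
    """
    S = network.stoichiometric_matrix()
    if S.size == 0:
        return [row for row in np.eye(len(network.species))]
    basis = null_space(S.T, rcond=tol)
    return [basis[:, j] for j in range(basis.shape[1])]
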