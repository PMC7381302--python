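"""PARP-cleavage and pathway-flux objectives."""

import math

import numpy as np
import pytest

from evnest import (
    NetworkConfigError,
    ParameterVector,
    Reaction,
    ReactionNetwork,
    Species,
    Trajectory,
    build_full_model,
    make_objective,
    parp_cleavage,
    pathway_flux,
    simulate,
)
from evnest.apoptosis import CASPASE_ACC, MITO_ACC
from evnest.sampler import PriorSpec


def synthetic_trajectory(cparp, cum_caspase, cum_mito, parp_total=100.0):
    """Hand-built trajectory with explicit cPARP and accumulator series."""
    cparp = np.asarray(cparp, dtype=float)
    n = len(cparp)
    times = np.arange(n, dtype=float)
    states = np.zeros((n, 2))
    states[:, 0] = parp_total - cparp  # uncleaved PARP
    states[:, 1] = cparp
    return Trajectory(
        times=times,
        states=states,
        species_names=["PARP", "cPARP"],
        accumulator_values={
            CASPASE_ACC: np.asarray(cum_caspase, dtype=float),
            MITO_ACC: np.asarray(cum_mito, dtype=float),
        },
    )


def flux_oracle(cparp, cum_path, cum_total, parp_total):
    """Term-by-term brute-force evaluation of the pathway-flux double sum."""
    total = 0.0
    for t in range(1, len(cparp)):
        frac = cum_path[t] / cum_total[t] if cum_total[t] > 0 else 0.0
        total += frac * (cparp[t] - cparp[t - 1])
    return total / parp_total


class TestParpCleavage:
    @pytest.mark.parametrize("final,expected", [(0.0, 0.0), (100.0, 1.0), (50.0, 0.5)])
    def test_fraction_of_conserved_pool(self, final, expected):
        traj = synthetic_trajectory([0.0, final], [0, 1], [0, 0])
        assert float(parp_cleavage(traj)) == pytest.approx(expected)

    def test_missing_species_is_configuration_error(self):
        traj = Trajectory(
            times=np.array([0.0, 1.0]),
            states=np.zeros((2, 1)),
            species_names=["A"],
        )
        with pytest.raises(NetworkConfigError):
            parp_cleavage(traj)

    def test_counts_parp_bound_in_cleavage_complex(self):
        # moiety total must include PARP sequestered in the C3:PARP complex
        traj = Trajectory(
            times=np.array([0.0, 1.0]),
            states=np.array([[50.0, 50.0, 0.0], [0.0, 0.0, 100.0]]),
            species_names=["PARP", "C3:PARP", "cPARP"],
        )
        assert float(parp_cleavage(traj)) == pytest.approx(1.0)


class TestPathwayFlux:
    def test_single_pathway_carries_all_flux(self):
        cparp = [0.0, 10.0, 40.0, 80.0]
        traj = synthetic_trajectory(cparp, [0, 5, 9, 12], [0, 0, 0, 0])
        assert float(pathway_flux(traj, "caspase")) == pytest.approx(0.8)
        assert float(pathway_flux(traj, "mitochondrial")) == pytest.approx(0.0)

    def test_zero_cleavage_gives_zero_flux(self):
        traj = synthetic_trajectory([0.0, 0.0, 0.0], [0, 2, 4], [0, 1, 2])
        assert float(pathway_flux(traj, "caspase")) == 0.0
        assert float(pathway_flux(traj, "mitochondrial")) == 0.0

    def test_even_split_halves_the_cleavage(self):
        cparp = [0.0, 20.0, 60.0]
        traj = synthetic_trajectory(cparp, [0, 3, 7], [0, 3, 7])
        assert float(pathway_flux(traj, "caspase")) == pytest.approx(0.3)
        assert float(pathway_flux(traj, "mitochondrial")) == pytest.approx(0.3)

    def test_general_case_matches_double_sum_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = 40
            cparp = np.cumsum(rng.uniform(0, 3, n))
            cparp[0] = 0.0
            cum_c = np.cumsum(rng.uniform(0, 2, n))
            cum_m = np.cumsum(rng.uniform(0, 2, n))
            total = float(cparp[-1]) * 1.5
            traj = synthetic_trajectory(cparp, cum_c, cum_m, parp_total=total)
            expected = flux_oracle(cparp, cum_c, cum_c + cum_m, total)
            assert float(pathway_flux(traj, "caspase")) == pytest.approx(expected, abs=1e-12)

    def test_flux_conservation_sums_to_cleavage(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 30
            cparp = np.concatenate([[0.0], np.cumsum(rng.uniform(0, 2, n - 1))])
            cum_c = np.concatenate([[0.0], np.cumsum(rng.uniform(0.01, 1, n - 1))])
            cum_m = np.concatenate([[0.0], np.cumsum(rng.uniform(0.01, 1, n - 1))])
            traj = synthetic_trajectory(cparp, cum_c, cum_m, parp_total=cparp[-1] * 2)
            total = float(pathway_flux(traj, "caspase")) + float(
                pathway_flux(traj, "mitochondrial")
            )
            assert total == pytest.approx(float(parp_cleavage(traj)), abs=1e-9)

    def test_unknown_pathway_rejected(self):
        traj = synthetic_trajectory([0.0, 1.0], [0, 1], [0, 1])
        with pytest.raises(NetworkConfigError):
            pathway_flux(traj, "nuclear")

    def test_flux_conservation_on_simulated_full_model(self):
        net = build_full_model({"XIAP": 0.0, "Bcl2": 0.0})
        prior = PriorSpec.for_network(net)
        theta = prior.to_params(prior.sample(np.random.default_rng(3), 1)[0])
        traj = simulate(net, theta, t_end=20_000.0, n_points=2001)
        assert traj.success
        total = float(pathway_flux(traj, "caspase")) + float(
            pathway_flux(traj, "mitochondrial")
        )
        # grid discretization of the attribution fractions costs ~1e-3
        assert total == pytest.approx(float(parp_cleavage(traj)), abs=1e-3)

    def test_grid_refinement_stability(self):
        net = build_full_model({"XIAP": 0.0, "Bcl2": 0.0})
        prior = PriorSpec.for_network(net)
        theta = prior.to_params(prior.sample(np.random.default_rng(5), 1)[0])
        coarse = simulate(net, theta, t_end=20_000.0, n_points=2001)
        fine = simulate(net, theta, t_end=20_000.0, n_points=4001)
        for tag in ("caspase", "mitochondrial"):
            assert abs(
                float(pathway_flux(coarse, tag)) - float(pathway_flux(fine, tag))
            ) < 1e-3


class TestMakeObjective:
    def test_no_reaction_network_scores_zero(self):
        net = ReactionNetwork(
            species=(Species("PARP", initial_copies=10.0), Species("cPARP")),
            reactions=(),
        )
        objective = make_objective(net, "parp_cleavage", t_end=10.0, n_points=5)
        theta = ParameterVector({})
        assert float(objective(theta)) == 0.0

    def test_deterministic_pipeline(self):
        net = build_full_model()
        prior = PriorSpec.for_network(net)
        theta = prior.to_params(prior.sample(np.random.default_rng(11), 1)[0])
        objective = make_objective(net)
        assert float(objective(theta)) == float(objective(theta))

    def test_two_step_chain_matches_closed_form(self):
        # PARP -> M -> cPARP; terminal fraction has an analytic solution
        net = ReactionNetwork(
            species=(Species("PARP", initial_copies=500.0), Species("M"), Species("cPARP")),
            reactions=(
                Reaction("s1", ("PARP",), ("M",), "first_order_forward", "k1"),
                Reaction("s2", ("M",), ("cPARP",), "first_order_forward", "k2"),
            ),
        )
        k1, k2, t = 0.02, 0.005, 300.0
        objective = make_objective(net, "parp_cleavage", t_end=t)
        expected = 1.0 - (k2 * math.exp(-k1 * t) - k1 * math.exp(-k2 * t)) / (k2 - k1)
        assert float(objective(ParameterVector({"k1": k1, "k2": k2}))) == pytest.approx(
            expected, rel=1e-5
        )

    def test_flux_objective_requires_instrumentation(self):
        net = ReactionNetwork(
            species=(Species("PARP", initial_copies=10.0), Species("cPARP")),
            reactions=(),
        )
        with pytest.raises(NetworkConfigError):
            make_objective(net, "flux_caspase")

    def test_objective_values_in_unit_interval(self):
        net = build_full_model()
        prior = PriorSpec.for_network(net)
        objective = make_objective(net)
        rng = np.random.default_rng(2)
        for x in prior.sample(rng, 5):
            v = float(objective(prior.to_params(x)))
            assert 0.0 <= v <= 1.0
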