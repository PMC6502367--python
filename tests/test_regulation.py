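"""Self-regulation: cost function, gradients, Haldane constraint, convergence."""

import numpy as np
import pytest

import metstab as ms
from metstab.kinetics import KineticModel
from metstab.library import toy_chain_condition
from metstab.network import EXTERNAL_ID
from metstab.regulation import (
    _fd_cost_gradients,
    _weights,
    cost_gradients_explicit,
    cost_psi,
    draw_initial_rates,
    enforce_haldane,
    enforce_haldane_compiled,
    regulation_rhs,
)

from conftest import random_reversible_kinetics


class TestCostPsi:
    def test_zero_at_balanced_state(self, chain3_converged):
        model, condition, trace = chain3_converged
        assert cost_psi(trace.x_final, model, condition) < 1e-12

    def test_carbon_weighted_hand_value(self):
        """c = (3, 0), f = (1, -2) -> psi = 4*1 + 1*4 = 8."""
        mets = [
            ms.Metabolite(EXTERNAL_ID, "e", 0, True),
            ms.Metabolite("A", carbon_count=3),
            ms.Metabolite("B", carbon_count=0),
        ]
        rxns = [
            ms.ReactionSpec("exa", ((("A"), 1),), ((EXTERNAL_ID, 1),),
                            ms.ReactionKinetics(1.0, 0.0, (1.0,), (1.0,))),
            ms.ReactionSpec("exb", (("B", 1),), ((EXTERNAL_ID, 1),),
                            ms.ReactionKinetics(1.0, 0.0, (1.0,), (1.0,))),
        ]
        model = ms.NetworkModel(mets, rxns)
        # all exchanges closed; virtual probe sinks realize f = (1, -2)
        condition = ms.Condition(
            name="probe", open_intakes=frozenset(),
            probe_biases={"A": -1.0, "B": 2.0},
        )
        psi = cost_psi(np.array([1.0, 1.0]), model, condition)
        assert psi == pytest.approx(8.0)

    def test_met_demand_gives_zero_cost(self, chain3_converged):
        """Exactly satisfied output demand contributes nothing to the cost."""
        model, condition, trace = chain3_converged
        km = KineticModel(model, condition)
        f = km.cost_imbalance(trace.x_final)
        assert np.max(np.abs(f)) < 1e-6


class TestRegulationRhs:
    def test_zero_at_fully_balanced_state(self, chain3_converged):
        model, condition, trace = chain3_converged
        km = KineticModel(model, condition)
        dvf, dvb = regulation_rhs(km, trace.x_final)
        assert np.max(np.abs(dvf)) < 1e-6
        assert np.max(np.abs(dvb)) < 1e-6

    def test_under_supplied_pump_speeds_up(self):
        """External -> A with unmet demand b: dV_F/dt > 0 for the intake."""
        mets = [ms.Metabolite(EXTERNAL_ID, "e", 0, True),
                ms.Metabolite("A", carbon_count=1)]
        rxns = [
            ms.ReactionSpec("EX_A_in", ((EXTERNAL_ID, 1),), (("A", 1),),
                            ms.ReactionKinetics(0.05, 0.0, (1.0,), (1.0,))),
            ms.ReactionSpec("EX_A_out", (("A", 1),), ((EXTERNAL_ID, 1),),
                            ms.ReactionKinetics(1.0, 0.0, (1.0,), (1.0,))),
        ]
        model = ms.NetworkModel(mets, rxns)
        condition = ms.Condition(
            name="demand", open_intakes=frozenset({"EX_A_in"}),
            output_biases={"A": 0.5},
        )
        km = KineticModel(model, condition)
        x = np.array([0.5])  # intake 0.025 << demand 0.5
        dvf, _ = regulation_rhs(km, x)
        assert dvf[0] > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_explicit_gradients_match_finite_differences(self, seed):
        """Analytic d(psi)/dV at fixed x agrees with central differences."""
        model = ms.build_random_network(4, 6, seed=seed)
        condition = ms.Condition(
            name="d", open_intakes=frozenset({"EX_M1_in"}),
            output_biases={"M4": 0.05},
        )
        km = KineticModel(model, condition)
        rng = np.random.default_rng(seed)
        cfg = ms.RegulationConfig(seed=seed)
        draw_initial_rates(km, rng, cfg)
        x = rng.uniform(0.3, 2.0, model.n_internal)
        w = _weights(km, cfg)
        a_f, a_b = cost_gradients_explicit(km, x, w)
        fd_f, fd_b = _fd_cost_gradients(km, x, w, coupling="global")
        free = ~km.fixed_mask
        scale = np.maximum(np.abs(fd_f[free]), 1e-4)
        assert np.all(np.abs(a_f[free] - fd_f[free]) / scale < 1e-5)
        rev = free & (km.vb > 0)
        if rev.any():
            scale_b = np.maximum(np.abs(fd_b[rev]), 1e-4)
            assert np.all(np.abs(a_b[rev] - fd_b[rev]) / scale_b < 1e-5)


class TestHaldane:
    def test_already_consistent_kinetics_unchanged(self):
        rxn = ms.ReactionSpec("r", (("A", 1),), (("P", 1),),
                              ms.ReactionKinetics(2.0, 1.0, (1.0,), (0.5,), k_eq=1.0))
        kin, rescale = enforce_haldane(rxn)
        assert kin == rxn.kinetics and rescale == {}

    def test_one_dimensional_scaling_example(self):
        """VF=2, VB=1, K=K'=1, K_eq=4: the product constant doubles."""
        rxn = ms.ReactionSpec("r", (("A", 1),), (("P", 1),),
                              ms.ReactionKinetics(2.0, 1.0, (1.0,), (1.0,), k_eq=4.0))
        kin, rescale = enforce_haldane(rxn)
        assert kin.km_products == (2.0,)
        assert rescale == {"P": 2.0}
        ratio = kin.v_forward * kin.km_products[0] / (
            kin.v_backward * kin.km_substrates[0]
        )
        assert ratio == pytest.approx(4.0)

    def test_irreversible_reaction_is_noop(self):
        rxn = ms.ReactionSpec("r", (("A", 1),), (("P", 1),),
                              ms.ReactionKinetics(2.0, 0.0, (1.0,), (1.0,)))
        kin, rescale = enforce_haldane(rxn)
        assert kin == rxn.kinetics and rescale == {}

    def test_ratio_exact_over_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            kin = random_reversible_kinetics(rng, n_sub, n_prod)
            subs = tuple((f"S{i}", int(rng.integers(1, 3))) for i in range(n_sub))
            prods = tuple((f"P{i}", int(rng.integers(1, 3))) for i in range(n_prod))
            rxn = ms.ReactionSpec("r", subs, prods, kin)
            new, _ = enforce_haldane(rxn)
            ratio = new.v_forward * np.prod(
                [k**m for k, (_, m) in zip(new.km_products, prods)]
            ) / (new.v_backward * np.prod(
                [k**m for k, (_, m) in zip(new.km_substrates, subs)]
            ))
            assert abs(ratio / kin.k_eq - 1.0) < 1e-12


class TestRunRegulation:
    def test_chain_demand_met_and_descent(self, chain3_converged):
        model, condition, trace = chain3_converged
        assert trace.converged
        assert np.allclose(trace.fluxes_final, 0.1, atol=1e-6)
        psi = np.array(trace.psi)
        assert np.all(np.diff(psi) <= 1e-8)

    def test_same_seed_reproduces_bitwise(self, chain3):
        model, condition = chain3
        cfg = ms.RegulationConfig(seed=4)
        _, t1 = ms.run_regulation(model, condition, cfg)
        _, t2 = ms.run_regulation(model, condition, cfg)
        assert t1.psi == t2.psi
        assert np.array_equal(t1.fluxes_final, t2.fluxes_final)
        assert np.array_equal(t1.x_final, t2.x_final)

    def test_different_seeds_reach_different_parameter_sets(self, chain3):
        """Steady states are not unique: distinct draws keep distinct V."""
        model, condition = chain3
        m1, t1 = ms.run_regulation(model, condition, ms.RegulationConfig(seed=1))
        m2, t2 = ms.run_regulation(model, condition, ms.RegulationConfig(seed=2))
        assert t1.converged and t2.converged
        v1 = np.array([r.kinetics.v_forward for r in m1.reactions])
        v2 = np.array([r.kinetics.v_forward for r in m2.reactions])
        assert not np.allclose(v1, v2)
        # but both satisfy the same demand
        assert np.allclose(t1.fluxes_final, t2.fluxes_final, atol=1e-5)

    def test_rates_stay_positive_throughout(self, chain3_converged):
        _, _, trace = chain3_converged
        for vf in trace.vf_history:
            assert np.all(vf[:3] > 0)  # regulated columns

    def test_haldane_holds_at_convergence(self, core_model, ensemble):
        cfg = ms.RegulationConfig(seed=0)
        regulated, trace = ms.run_regulation(
            core_model, ensemble.conditions[0], cfg
        )
        assert trace.converged
        for rxn in regulated.reactions:
            kin = rxn.kinetics
            if not kin.reversible or kin.k_eq is None or rxn.is_exchange:
                continue
            ratio = kin.v_forward * np.prod(
                [k**m for k, (_, m) in zip(kin.km_products, rxn.products)]
            ) / (kin.v_backward * np.prod(
                [k**m for k, (_, m) in zip(kin.km_substrates, rxn.substrates)]
            ))
            assert ratio == pytest.approx(kin.k_eq, rel=1e-9), rxn.id


class TestInitialDraw:
    def test_initial_fluxes_small_and_uniform(self, core_model, ensemble):
        km = KineticModel(core_model, ensemble.conditions[0])
        cfg = ms.RegulationConfig(seed=3)
        draw_initial_rates(km, np.random.default_rng(3), cfg)
        u0 = km.fluxes(np.ones(core_model.n_internal))
        free = ~km.fixed_mask
        capped = np.isfinite(km.vf_cap)
        lo, hi = cfg.u_init_range
        assert np.all(u0[free & ~capped] >= lo - 1e-12)
        assert np.all(u0[free] <= hi + 1e-12)
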