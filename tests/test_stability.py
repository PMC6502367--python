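"""Jacobian, relaxation time, efficiency and steady-state characterization."""

import numpy as np
import pytest

import metstab as ms
from metstab.kinetics import KineticModel
from metstab.network import EXTERNAL_ID
from metstab.stability import StructuralError, EfficiencyError, relaxation_time


def _kin(vf, vb, ks, kp, k_eq=None):
    return ms.ReactionKinetics(vf, vb, tuple(ks), tuple(kp), k_eq)


class TestJacobian:
    def test_single_decay_matches_rate_law_derivative(self):
        """One exporting pool: J = [-du/dx] of the saturating drain."""
        mets = [ms.Metabolite(EXTERNAL_ID, "e", 0, True),
                ms.Metabolite("A", carbon_count=1)]
        rxn = ms.ReactionSpec("EX_A_out", (("A", 1),), ((EXTERNAL_ID, 1),),
                              _kin(2.0, 0.0, [1.0], [1.0]))
        m = ms.NetworkModel(mets, [rxn])
        x = np.array([0.8])
        J = ms.jacobian(x, m)
        # u = VF a/(1+a); du/dx = VF / (1+a)^2
        expected = -2.0 / (1 + 0.8) ** 2
        assert J[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_matches_central_differences_on_chain(self, chain3_converged):
        model, condition, trace = chain3_converged
        km = KineticModel(model, condition)
        x = trace.x_final
        J = ms.jacobian(x, km)
        h = 1e-6
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (km.imbalance(xp) - km.imbalance(xm)) / (2 * h)
            assert np.allclose(J[:, i], fd, rtol=1e-6, atol=1e-8)

    def test_symmetric_two_pool_exchange_spectrum(self):
        """Closed A <-> B: eigenvalues {0, -(k12 + k21)} at the chosen point."""
        mets = [ms.Metabolite(EXTERNAL_ID, "e", 0, True),
                ms.Metabolite("A", carbon_count=1),
                ms.Metabolite("B", carbon_count=1)]
        rxn = ms.ReactionSpec("ab", (("A", 1),), (("B", 1),),
                              _kin(1.0, 1.0, [1.0], [1.0], k_eq=1.0))
        m = ms.NetworkModel(mets, [rxn])
        x = np.array([1.0, 1.0])
        J = ms.jacobian(x, m)
        lam = np.sort(np.linalg.eigvals(J).real)
        k12 = -ms.jacobian(x, m)[0, 0]
        assert lam[1] == pytest.approx(0.0, abs=1e-14)
        assert lam[0] == pytest.approx(-2 * k12, rel=1e-12)


class TestRelaxationTime:
    def test_one_dimensional_closed_form(self):
        assert relaxation_time(np.array([-2.0]), 1) == pytest.approx(0.5)

    def test_two_real_modes(self):
        rt = relaxation_time(np.array([-1.0, -4.0]), 2)
        assert rt == pytest.approx(0.625)

    def test_complex_conjugate_pair(self):
        rt = relaxation_time(np.array([-1 + 2j, -1 - 2j]), 2)
        assert rt == pytest.approx(0.2)

    def test_scaling_halves_under_double_rates(self):
        lam = np.array([-0.5, -1.3, -2.0])
        assert relaxation_time(2 * lam, 3) == pytest.approx(
            relaxation_time(lam, 3) / 2
        )

    def test_null_modes_excluded_by_rank(self):
        lam = np.array([-1.0, -4.0, 1e-14])
        assert relaxation_time(lam, 2) == pytest.approx(0.625)

    def test_rank_mismatch_raises(self):
        with pytest.raises(StructuralError):
            relaxation_time(np.array([-1.0, -2.0]), 3)

    def test_unstable_mode_gives_nan(self):
        assert np.isnan(relaxation_time(np.array([0.5, -1.0]), 2))


class TestEfficiency:
    def _two_reaction_model(self):
        mets = [ms.Metabolite(EXTERNAL_ID, "e", 0, True),
                ms.Metabolite("HEX", carbon_count=6),
                ms.Metabolite("TRI", carbon_count=3)]
        rxns = [
            ms.ReactionSpec("EX_HEX_in", ((EXTERNAL_ID, 1),), (("HEX", 1),),
                            _kin(1.0, 0.0, [1.0], [1.0])),
            ms.ReactionSpec("split", (("HEX", 1),), (("TRI", 2),),
                            _kin(1.0, 0.0, [1.0], [1.0])),
            ms.ReactionSpec("EX_TRI_out", (("TRI", 1),), ((EXTERNAL_ID, 1),),
                            _kin(1.0, 0.0, [1.0], [1.0])),
        ]
        return ms.NetworkModel(mets, rxns)

    def test_balanced_conversion_has_unit_efficiency(self):
        """6 C in at flux 1, 3 C out at flux 2 -> ratio 1."""
        m = self._two_reaction_model()
        cond = ms.Condition("c", frozenset({"EX_HEX_in"}),
                            output_biases={"TRI": 2.0})
        u = np.array([1.0, 1.0, 2.0])
        assert ms.efficiency(u, m, cond) == pytest.approx(1.0)

    def test_carbon_leak_raises_the_ratio(self):
        """Venting carbon as waste costs intake without biomass credit."""
        mets = [ms.Metabolite(EXTERNAL_ID, "e", 0, True),
                ms.Metabolite("HEX", carbon_count=6),
                ms.Metabolite("TRI", carbon_count=3),
                ms.Metabolite("W", carbon_count=1)]
        rxns = [
            ms.ReactionSpec("EX_HEX_in", ((EXTERNAL_ID, 1),), (("HEX", 1),),
                            _kin(1.0, 0.0, [1.0], [1.0])),
            ms.ReactionSpec("split", (("HEX", 1),), (("TRI", 1), ("W", 3)),
                            _kin(1.0, 0.0, [1.0], [1.0, 1.0])),
            ms.ReactionSpec("EX_TRI_out", (("TRI", 1),), ((EXTERNAL_ID, 1),),
                            _kin(1.0, 0.0, [1.0], [1.0])),
            ms.ReactionSpec("EX_W_out", (("W", 1),), ((EXTERNAL_ID, 1),),
                            _kin(1.0, 0.0, [1.0], [1.0])),
        ]
        m = ms.NetworkModel(mets, rxns)
        cond = ms.Condition("c", frozenset({"EX_HEX_in", "EX_W_out"}),
                            output_biases={"TRI": 1.0})
        u = np.array([1.0, 1.0, 1.0, 3.0])
        assert ms.efficiency(u, m, cond) == pytest.approx(2.0)

    def test_zero_biomass_output_is_undefined(self):
        m = self._two_reaction_model()
        cond = ms.Condition("c", frozenset({"EX_HEX_in"}),
                            output_biases={"TRI": 2.0})
        u = np.array([1.0, 0.0, 0.0])
        with pytest.raises(EfficiencyError):
            ms.efficiency(u, m, cond)


class TestCharacterizeSteadyState:
    def test_chain_is_stable_with_consistent_rt(self, chain3):
        model, condition = chain3
        result, trace = ms.characterize_steady_state(
            model, condition, ms.RegulationConfig(seed=1)
        )
        assert result.converged and result.stable
        lam = result.eigenvalues
        nonzero = lam[np.abs(lam) > 1e-9 * np.max(np.abs(lam))]
        rt_direct = float(-np.sum(1.0 / nonzero).real / result.stoich_rank)
        assert result.rt == pytest.approx(rt_direct, rel=1e-12)
        assert result.rt > 0

    def test_null_space_consistency(self, chain3):
        """Number of near-zero modes equals N - rank(S restricted)."""
        model, condition = chain3
        result, _ = ms.characterize_steady_state(
            model, condition, ms.RegulationConfig(seed=1)
        )
        lam = result.eigenvalues
        n_null = int(np.sum(np.abs(lam) <= 1e-9 * np.max(np.abs(lam))))
        assert n_null == model.n_internal - result.stoich_rank

    def test_rt_scales_inversely_with_rates(self, chain3_converged):
        """Multiplying every peak rate by s divides RT by s."""
        model, condition, trace = chain3_converged
        km = KineticModel(model, condition)
        x = trace.x_final
        lam = np.linalg.eigvals(km.imbalance_jacobian(x))
        km.vf = km.vf * 2.0
        km.vb = km.vb * 2.0
        km.fixed_values = km.fixed_values * 2.0
        lam2 = np.linalg.eigvals(km.imbalance_jacobian(x))
        nz = np.abs(lam) > 1e-9 * np.max(np.abs(lam))
        rt1 = relaxation_time(lam, int(nz.sum()))
        rt2 = relaxation_time(lam2, int(nz.sum()))
        assert rt2 == pytest.approx(rt1 / 2.0, rel=1e-9)

    def test_autocatalytic_loop_flagged_unstable(self):
        """A self-amplifying pool with saturated removal is not stable."""
        # A catalyses its own production from an open intake; its removal
        # saturates, so at the balanced point production grows faster than
        # removal: the single mode is positive.
        mets = [ms.Metabolite(EXTERNAL_ID, "e", 0, True),
                ms.Metabolite("A", carbon_count=1)]
        rxns = [
            # autocatalytic: A -> 2A (net +1 A), rate grows with [A]
            ms.ReactionSpec("auto", (("A", 1),), (("A", 2),),
                            _kin(1.0, 0.0, [10.0], [1.0])),
            ms.ReactionSpec("EX_A_out", (("A", 1),), ((EXTERNAL_ID, 1),),
                            _kin(0.5, 0.0, [0.01], [1.0])),
        ]
        m = ms.NetworkModel(mets, rxns)
        x = np.array([2.0])
        J = ms.jacobian(x, m)
        assert J[0, 0] > 0
        assert np.isnan(relaxation_time(np.linalg.eigvals(J), 1))
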