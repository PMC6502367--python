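"""Landscape analyses: classification, switches, knockouts, Boolean circuit."""

import numpy as np
import pandas as pd
import pytest

import metstab as ms
from metstab.landscape import (
    BooleanCircuit,
    FluxLandscape,
    boolean_attractors,
    default_circuit_interactions,
    secondary_flux,
)
from metstab.stability import SteadyStateResult


def _landscape_from_matrix(matrix, model):
    return FluxLandscape(
        fluxes=matrix,
        meta=pd.DataFrame(index=matrix.index),
        model=model,
    )


class TestClassification:
    def test_two_template_matrix_recovered_exactly(self):
        """Two sign templates plus small noise split into k = 2 perfectly."""
        rng = np.random.default_rng(0)
        t1 = np.array([1.0, -1.0, 1.0, 1.0, -1.0, 0.5])
        t2 = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, 0.5])
        rows, truth = [], []
        for i in range(8):
            base = t1 if i % 2 == 0 else t2
            truth.append(i % 2)
            rows.append(base + rng.normal(0, 0.05, base.size))
        norm = pd.DataFrame(rows, index=[f"c{i}" for i in range(8)])
        labels, k = ms.classify_states(norm)
        assert k == 2
        split = [set(labels.index[labels == lab]) for lab in sorted(labels.unique())]
        expected = {frozenset(f"c{i}" for i in range(8) if i % 2 == 0),
                    frozenset(f"c{i}" for i in range(8) if i % 2 == 1)}
        assert {frozenset(s) for s in split} == expected

    def test_identical_rows_collapse_to_one_class(self):
        norm = pd.DataFrame([[1.0, 2.0, 3.0]] * 5,
                            index=[f"c{i}" for i in range(5)])
        labels, k = ms.classify_states(norm)
        assert k == 1
        assert labels.nunique() == 1

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        t1 = np.array([1.0, -1.0, 0.5, 1.0])
        t2 = np.array([-1.0, 1.0, 0.5, -1.0])
        rows = [t1 + rng.normal(0, 0.03, 4) for _ in range(4)]
        rows += [t2 + rng.normal(0, 0.03, 4) for _ in range(4)]
        idx = [f"c{i}" for i in range(8)]
        norm = pd.DataFrame(rows, index=idx)
        labels, _ = ms.classify_states(norm)
        perm = norm.iloc[::-1]
        labels_p, _ = ms.classify_states(perm)
        # same partition regardless of row order
        part = frozenset(
            frozenset(labels.index[labels == lab]) for lab in labels.unique()
        )
        part_p = frozenset(
            frozenset(labels_p.index[labels_p == lab]) for lab in labels_p.unique()
        )
        assert part == part_p

    def test_too_few_rows_raise(self):
        norm = pd.DataFrame([[1.0, 2.0]] * 3)
        with pytest.raises(ValueError):
            ms.classify_states(norm)


class TestIdentifySwitches:
    def test_single_condition_landscape_has_no_switches(self, core_model):
        row = pd.DataFrame(
            [np.zeros(core_model.n_reactions)],
            columns=[r.id for r in core_model.reactions],
            index=["only"],
        )
        ls = _landscape_from_matrix(row, core_model)
        report = ms.identify_switches(ls, 0.1)
        assert report.switching_reactions == []

    def test_only_the_varying_column_is_flagged(self, core_model):
        cols = [r.id for r in core_model.reactions]
        base = np.full(len(cols), 0.2)
        m = pd.DataFrame([base, base.copy()], columns=cols, index=["a", "b"])
        m.loc["b", "pyk"] = 0.7  # range 0.5 > threshold
        ls = _landscape_from_matrix(m, core_model)
        report = ms.identify_switches(ls, 0.1)
        assert report.switching_reactions == ["pyk"]
        assert report.central_switching == ["pyk"]

    def test_sign_reversal_counts_even_below_range_threshold(self, core_model):
        cols = [r.id for r in core_model.reactions]
        base = np.full(len(cols), 0.2)
        m = pd.DataFrame([base, base.copy()], columns=cols, index=["a", "b"])
        m.loc["a", "mdh"] = 0.04
        m.loc["b", "mdh"] = -0.04  # range 0.08 < 0.1 but direction flips
        ls = _landscape_from_matrix(m, core_model)
        report = ms.identify_switches(ls, 0.1)
        assert report.switching_reactions == ["mdh"]
        assert report.sign_reversals == ["mdh"]

    def test_exchange_and_transport_columns_excluded(self, core_model):
        cols = [r.id for r in core_model.reactions]
        m = pd.DataFrame([np.zeros(len(cols)), np.zeros(len(cols))],
                         columns=cols, index=["a", "b"])
        m.loc["b", "EX_MLT_in"] = 5.0
        m.loc["b", "mlt_uptake"] = 5.0
        ls = _landscape_from_matrix(m, core_model)
        assert ms.identify_switches(ls, 0.1).switching_reactions == []

    def test_nonpositive_threshold_raises(self, core_landscape):
        with pytest.raises(ValueError):
            ms.identify_switches(core_landscape, 0.0)


class TestKnockout:
    def test_empty_set_leaves_model_unchanged(self, core_model):
        assert ms.knockout_secondary_metabolism(core_model, set()) == core_model

    def test_double_knockout_zeroes_secondary_fluxes(self, core_model, ensemble):
        from metstab.kinetics import KineticModel

        ko = ms.knockout_secondary_metabolism(core_model, "both")
        km = KineticModel(ko, ensemble.conditions[0])
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 3.0, ko.n_internal)
        u = km.fluxes(x)
        for j, r in enumerate(ko.reactions):
            if "knocked_out" in r.tags:
                assert u[j] == 0.0

    def test_topology_is_retained(self, core_model):
        ko = ms.knockout_secondary_metabolism(core_model, "xiamenmycin")
        assert [r.id for r in ko.reactions] == [r.id for r in core_model.reactions]
        assert np.array_equal(ko.stoich_matrix, core_model.stoich_matrix)

    def test_unknown_pathway_raises(self, core_model):
        with pytest.raises(ValueError):
            ms.knockout_secondary_metabolism(core_model, "nonexistent")

    def test_missing_tag_raises(self, chain3):
        model, _ = chain3
        with pytest.raises(ValueError):
            ms.knockout_secondary_metabolism(model, "both")


class TestCompareRt:
    def _result(self, cond, seed, rt):
        return SteadyStateResult(
            condition=cond, seed=seed, x_star=None, u_star=None,
            eigenvalues=None, rt=rt, stable=True, efficiency=1.0,
            converged=True,
        )

    def test_identical_sets_give_zero_differences(self):
        a = [self._result("c", s, 1.0 + s) for s in range(3)]
        comp = ms.compare_rt(a, a)
        assert (comp.differences == 0).all()
        assert comp.sign_test_p == 1.0

    def test_shifted_sets_median_difference(self):
        a = [self._result("c", s, rt) for s, rt in enumerate((1.0, 2.0, 3.0))]
        b = [self._result("c", s, rt) for s, rt in enumerate((2.0, 3.0, 4.0))]
        comp = ms.compare_rt(a, b)
        assert comp.differences.median() == pytest.approx(1.0)
        assert comp.median_b - comp.median_a == pytest.approx(1.0)

    def test_unmatched_seeds_raise(self):
        a = [self._result("c", 0, 1.0)]
        b = [self._result("c", 1, 1.0)]
        with pytest.raises(ValueError):
            ms.compare_rt(a, b)


class TestBooleanCircuit:
    def test_default_circuit_two_antagonistic_fixed_points(self):
        attractors = boolean_attractors(BooleanCircuit())
        fixed = [a[0] for a in attractors if len(a) == 1]
        assert len(attractors) == 2
        assert sorted(fixed) == [(-1, -1, 1, 1), (1, 1, -1, -1)]

    def test_zero_interactions_freeze_every_state(self):
        circ = BooleanCircuit(interactions=np.zeros((4, 4)))
        attractors = boolean_attractors(circ)
        assert len(attractors) == 16
        assert all(len(a) == 1 for a in attractors)

    def test_single_mutual_activation_pair(self):
        circ = BooleanCircuit(nodes=("a", "b"),
                              interactions=np.array([[0, 1], [1, 0]]))
        attractors = boolean_attractors(circ)
        fixed = sorted(a[0] for a in attractors if len(a) == 1)
        assert fixed == [(-1, -1), (1, 1)]
        assert len(attractors) == 2

    def test_synchronous_mode_reports_parasitic_cycles(self):
        circ = BooleanCircuit(update="synchronous")
        attractors = boolean_attractors(circ)
        fixed = [a for a in attractors if len(a) == 1]
        cycles = [a for a in attractors if len(a) > 1]
        assert sorted(a[0] for a in fixed) == [(-1, -1, 1, 1), (1, 1, -1, -1)]
        assert cycles  # the odd synchronous map always carries 2-cycles

    def test_interaction_signs_encode_the_stated_wiring(self):
        J = default_circuit_interactions()
        # mutual activation within (ME, MDH) and within (AST, TKT)
        assert J[0, 1] > 0 and J[1, 0] > 0
        assert J[2, 3] > 0 and J[3, 2] > 0
        # mutual antagonism across the pairs
        for i in (0, 1):
            for j in (2, 3):
                assert J[i, j] < 0 and J[j, i] < 0


class TestScanOnCore:
    def test_one_row_per_condition_all_converged(self, core_landscape, ensemble):
        assert len(core_landscape.fluxes) == len(ensemble)
        assert core_landscape.failures == {}

    def test_normalized_view_bounded_and_sign_consistent(self, core_landscape):
        norm = core_landscape.normalized()
        assert (norm.abs() <= 1.0 + 1e-12).all().all()
        signs_match = np.sign(norm.to_numpy()) == np.sign(
            core_landscape.fluxes.to_numpy()
        )
        assert signs_match.all()

    def test_rt_dispersion_across_states(self, core_landscape):
        rts = core_landscape.meta.rt.dropna()
        assert len(rts) >= 10
        assert rts.max() / rts.min() > 1.5

    def test_wildtype_secondary_flux_is_nonzero(self, core_landscape, core_model):
        total = [
            secondary_flux(res, core_model)
            for res in core_landscape.results.values()
        ]
        assert max(total) > 0
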