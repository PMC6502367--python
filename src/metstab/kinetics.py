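"""Generic reversible enzymatic rate law and the network ODE right-hand side.

Every reaction rate follows one saturating reversible form

    u = (V_F prod_i a_i  -  V_B prod_j p_j)
        / (f1 prod_i (1 + a_i) + f2 prod_j (1 + p_j)),

with a_i = [A_i]/K_i, p_j = [P_j]/K'_j, one factor per stoichiometric
multiplicity, and slowly varying normalization factors f1 + f2 = 1 that
vanish with the corresponding peak rate (implemented as V_F/(V_F+V_B) and
V_B/(V_F+V_B)).  With V_B = 0 the form reduces to irreversible
multi-substrate Michaelis-Menten kinetics.  The External node enters with a
fixed reference concentration of 1.

The network dynamics are dx/dt = S u(x), with concentration components
clamped at zero from below.  Exchange reactions can be held at a constant
flux to encode biomass-output demands (bias fluxes), and conditions may add
constant virtual sinks/sources used by the switch-metabolite probes.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import EXTERNAL_ID, NetworkModel, ReactionSpec

if TYPE_CHECKING:  # pragma: no cover
    from .library import Condition


class KineticsError(ValueError):
    pass


def normalization_factors(v_forward: float, v_backward: float) -> tuple[float, float]:
    """Normalization factor pair (f1, f2) of the rate law denominator.

    Satisfies f1 + f2 = 1, f1 = 0 when the forward peak rate vanishes and
    f2 = 0 when the backward peak rate vanishes.
    """
    if v_forward < 0 or v_backward < 0:
        raise KineticsError("peak rates must be non-negative")
    total = v_forward + v_backward
    if total == 0:
        raise KineticsError("degenerate reaction: both peak rates are zero")
    return v_forward / total, v_backward / total


def reaction_rate(
    concentrations: dict[str, float] | np.ndarray,
    reaction: ReactionSpec,
    model: NetworkModel | None = None,
) -> float:
    """Net rate of one reaction at the given concentrations.

    ``concentrations`` is either a mapping from metabolite id to value or a
    vector ordered as the internal metabolites of ``model``.  The External
    node is pinned at concentration 1.
    """
    if isinstance(concentrations, np.ndarray):
        if model is None:
            raise KineticsError("vector input requires the model for ordering")
        conc = {
            m.id: float(c)
            for m, c in zip(model.internal_metabolites, concentrations)
        }
    else:
        conc = dict(concentrations)
    conc[EXTERNAL_ID] = 1.0
    kin = reaction.kinetics
    f1, f2 = normalization_factors(kin.v_forward, kin.v_backward)
    num_f, den_f = 1.0, 1.0
    for (sp, mult), km in zip(reaction.substrates, kin.km_substrates):
        a = conc[sp] / km
        num_f *= a**mult
        den_f *= (1.0 + a) ** mult
    num_b, den_b = 1.0, 1.0
    for (sp, mult), km in zip(reaction.products, kin.km_products):
        p = conc[sp] / km
        num_b *= p**mult
        den_b *= (1.0 + p) ** mult
    num = kin.v_forward * num_f - kin.v_backward * num_b
    den = f1 * den_f + f2 * den_b
    u = num / den
    if not np.isfinite(u):
        raise KineticsError(f"non-finite rate for reaction {reaction.id!r}")
    return u


class KineticModel:
    """Vectorized evaluator for fluxes, imbalances and their derivatives.

    Compiles a :class:`NetworkModel` (plus, optionally, a condition fixing
    exchange fluxes) into dense index arrays so that the rate law, the ODE
    right-hand side, the Jacobian and the parameter sensitivities can be
    evaluated with numpy array operations.
    """

    def __init__(self, model: NetworkModel, condition: "Condition | None" = None):
        self.model = model
        self.condition = condition
        N, M = model.n_internal, model.n_reactions
        self.S = model.stoich_matrix.astype(float)
        self.carbon = model.carbon_vector()

        self.ES = np.zeros((N, M))
        self.EP = np.zeros((N, M))
        self.KS = np.ones((N, M))
        self.KP = np.ones((N, M))
        self.ext_num_s = np.ones(M)
        self.ext_num_p = np.ones(M)
        self.ext_den_s = np.ones(M)
        self.ext_den_p = np.ones(M)
        # per-reaction sparse views for the analytic Jacobian; Michaelis
        # constants are always read back from KS/KP so that Haldane
        # rescaling stays consistent everywhere
        self._sub_entries: list[list[tuple[int, int]]] = []
        self._prod_entries: list[list[tuple[int, int]]] = []

        for j, rxn in enumerate(model.reactions):
            subs, prods = [], []
            for (sp, mult), km in zip(rxn.substrates, rxn.kinetics.km_substrates):
                if sp == EXTERNAL_ID:
                    self.ext_num_s[j] *= (1.0 / km) ** mult
                    self.ext_den_s[j] *= (1.0 + 1.0 / km) ** mult
                else:
                    i = model.metabolite_index(sp)
                    self.ES[i, j] = mult
                    self.KS[i, j] = km
                    subs.append((i, mult))
            for (sp, mult), km in zip(rxn.products, rxn.kinetics.km_products):
                if sp == EXTERNAL_ID:
                    self.ext_num_p[j] *= (1.0 / km) ** mult
                    self.ext_den_p[j] *= (1.0 + 1.0 / km) ** mult
                else:
                    i = model.metabolite_index(sp)
                    self.EP[i, j] = mult
                    self.KP[i, j] = km
                    prods.append((i, mult))
            self._sub_entries.append(subs)
            self._prod_entries.append(prods)

        self.vf = np.array([r.kinetics.v_forward for r in model.reactions])
        self.vb = np.array([r.kinetics.v_backward for r in model.reactions])
        self.k_eq = np.array(
            [
                r.kinetics.k_eq if r.kinetics.k_eq is not None else np.nan
                for r in model.reactions
            ]
        )

        # boundary handling: fixed-flux (bias) columns, closed exchanges,
        # virtual constant sinks from probe biases.  In the dynamics a
        # demand drain saturates when its pool empties (nothing can be
        # exported from an empty pool); in the regulation cost the full
        # demand is charged regardless, so unmet demand stays visible.
        self.fixed_mask = np.zeros(M, dtype=bool)
        self.fixed_values = np.zeros(M)
        self.vf_cap = np.full(M, np.inf)  # transporter capacity per column
        self.drain_source = np.full(M, -1, dtype=int)  # pool feeding a bias drain
        self.virtual_sink = np.zeros(N)
        exchange = np.array([r.is_exchange for r in model.reactions])
        self.is_exchange = exchange
        if condition is not None:
            open_ids = set(condition.open_intakes)
            for mid, b in condition.output_biases.items():
                j = self._export_column(mid)
                self.fixed_mask[j] = True
                self.fixed_values[j] = float(b)
                self.drain_source[j] = model.metabolite_index(mid)
            for j, rxn in enumerate(model.reactions):
                if exchange[j] and not self.fixed_mask[j] and rxn.id not in open_ids:
                    self.fixed_mask[j] = True
                    self.fixed_values[j] = 0.0
            for mid, b in getattr(condition, "probe_biases", {}).items():
                self.virtual_sink[model.metabolite_index(mid)] += float(b)
            for rid, cap in getattr(condition, "intake_caps", {}).items():
                self.vf_cap[model.reaction_index(rid)] = float(cap)
        # reactions with both peak rates zero (knockouts) carry no flux
        self.active = (self.vf + self.vb) > 0
        self.fixed_mask |= ~self.active
        # columns whose flux depends on concentrations
        self.kinetic_columns = np.flatnonzero(~self.fixed_mask)

    # -- boundary helpers -------------------------------------------------
    def _export_column(self, met_id: str) -> int:
        """Index of the declared export exchange ``EX_<id>_out`` for a pool.

        The id convention keeps the lookup unambiguous when a metabolite
        also has an overflow valve to the External node.
        """
        try:
            self.model.metabolite_index(met_id)
        except Exception as exc:
            raise KineticsError(str(exc)) from exc
        try:
            j = self.model.reaction_index(f"EX_{met_id}_out")
        except Exception as exc:
            raise KineticsError(
                f"no export exchange reaction declared for metabolite {met_id!r}"
            ) from exc
        rxn = self.model.reactions[j]
        subs = {s for s, _ in rxn.substrates}
        prods = {s for s, _ in rxn.products}
        if subs != {met_id} or prods != {EXTERNAL_ID}:
            raise KineticsError(
                f"reaction EX_{met_id}_out is not a simple export of {met_id!r}"
            )
        return j

    def set_rates(self, vf: np.ndarray, vb: np.ndarray) -> None:
        self.vf = np.asarray(vf, dtype=float).copy()
        self.vb = np.asarray(vb, dtype=float).copy()

    # -- core evaluations -------------------------------------------------
    def _saturation_products(self, x: np.ndarray):
        xc = np.maximum(x, 0.0)[:, None]
        a = xc / self.KS
        p = xc / self.KP
        A = np.prod(a**self.ES, axis=0) * self.ext_num_s
        P = np.prod(p**self.EP, axis=0) * self.ext_num_p
        DA = np.prod((1.0 + a) ** self.ES, axis=0) * self.ext_den_s
        DP = np.prod((1.0 + p) ** self.EP, axis=0) * self.ext_den_p
        return A, P, DA, DP

    def _f1f2(self):
        total = np.where(self.active, self.vf + self.vb, 1.0)
        f1 = np.where(self.active, self.vf / total, 0.0)
        f2 = np.where(self.active, self.vb / total, 0.0)
        return f1, f2

    #: pool size over which a constant drain ramps down to zero as the
    #: pool empties; above it drains run at their full bias value
    clamp_width: float = 1e-4

    def _drain_ramp(self, x: np.ndarray) -> np.ndarray:
        """Per-column multiplier saturating bias drains at empty pools."""
        ramp = np.ones(self.model.n_reactions)
        cols = np.flatnonzero(self.drain_source >= 0)
        src = self.drain_source[cols]
        ramp[cols] = np.clip(x[src] / self.clamp_width, 0.0, 1.0)
        return ramp

    def fluxes(self, x: np.ndarray, ramped: bool = True) -> np.ndarray:
        """Net reaction rates u(x), with boundary columns at their fixed values.

        With ``ramped`` (the dynamical view) a bias drain shuts down
        linearly as its pool empties; without it (the cost view) the drain
        is charged at the full demand.
        """
        A, P, DA, DP = self._saturation_products(x)
        f1, f2 = self._f1f2()
        den = f1 * DA + f2 * DP
        den = np.where(self.active, den, 1.0)
        u = (self.vf * A - self.vb * P) / den
        fixed = self.fixed_values
        if ramped:
            fixed = fixed * self._drain_ramp(x)
        u = np.where(self.fixed_mask, fixed, u)
        if not np.all(np.isfinite(u)):
            bad = self.model.reactions[int(np.flatnonzero(~np.isfinite(u))[0])].id

            raise KineticsError(f"non-finite flux in reaction {bad!r}")
        return u

    def _virtual(self, x: np.ndarray, ramped: bool) -> np.ndarray:
        sink = self.virtual_sink
        if not ramped:
            return sink
        ramp = np.clip(x / self.clamp_width, 0.0, 1.0)
        return np.where(sink > 0, sink * ramp, sink)

    def imbalance(self, x: np.ndarray) -> np.ndarray:
        """Dynamical imbalance f(x) = S u(x) - virtual sinks (drains ramped)."""
        return self.S @ self.fluxes(x) - self._virtual(x, True)

    def cost_imbalance(self, x: np.ndarray) -> np.ndarray:
        """Imbalance charged by the regulation cost: full demands, unramped."""
        return self.S @ self.fluxes(x, ramped=False) - self._virtual(x, False)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """ODE right-hand side; non-negativity is intrinsic.

        Enzymatic consumption of a species vanishes with its concentration
        and constant drains ramp down over the last ``clamp_width`` units,
        so the flow cannot push a pool negative; a residual guard zeroes
        numerically negative excursions.
        """
        f = self.imbalance(x)
        return np.where((x <= 0.0) & (f < 0.0), 0.0, f)

    # -- derivatives ------------------------------------------------------
    def flux_v_partials(self, x: np.ndarray):
        """du/dV_F and du/dV_B per reaction (zero for fixed columns)."""
        A, P, DA, DP = self._saturation_products(x)
        f1, f2 = self._f1f2()
        den = np.where(self.active, f1 * DA + f2 * DP, 1.0)
        u = (self.vf * A - self.vb * P) / den
        total = np.where(self.active, self.vf + self.vb, 1.0)
        dden_dvf = (self.vb / total**2) * (DA - DP)
        dden_dvb = (self.vf / total**2) * (DP - DA)
        du_dvf = A / den - u * dden_dvf / den
        du_dvb = -P / den - u * dden_dvb / den
        du_dvf = np.where(self.fixed_mask, 0.0, du_dvf)
        du_dvb = np.where(self.fixed_mask, 0.0, du_dvb)
        return du_dvf, du_dvb

    def flux_x_partials(self, x: np.ndarray) -> np.ndarray:
        """Dense M x N matrix of du_r/dx_n from the rate-law partials."""
        N, M = self.model.n_internal, self.model.n_reactions
        xc = np.maximum(x, 0.0)
        A, P, DA, DP = self._saturation_products(x)
        f1, f2 = self._f1f2()
        den = np.where(self.active, f1 * DA + f2 * DP, 1.0)
        u = (self.vf * A - self.vb * P) / den
        J = np.zeros((M, N))
        for j in range(M):
            if self.fixed_mask[j]:
                continue
            for i, mult in self._sub_entries[j]:
                km = self.KS[i, j]
                a = xc[i] / km
                if a > 0:
                    dA = A[j] * mult / xc[i]
                elif mult == 1:
                    others = 1.0
                    for i2, m2 in self._sub_entries[j]:
                        if i2 != i:
                            others *= (xc[i2] / self.KS[i2, j]) ** m2
                    dA = others * self.ext_num_s[j] / km
                else:
                    dA = 0.0
                dDA = DA[j] * mult / (km * (1.0 + a))
                J[j, i] += (self.vf[j] * dA - u[j] * f1[j] * dDA) / den[j]
            for i, mult in self._prod_entries[j]:
                km = self.KP[i, j]
                p = xc[i] / km
                if p > 0:
                    dP = P[j] * mult / xc[i]
                elif mult == 1:
                    others = 1.0
                    for i2, m2 in self._prod_entries[j]:
                        if i2 != i:
                            others *= (xc[i2] / self.KP[i2, j]) ** m2
                    dP = others * self.ext_num_p[j] / km
                else:
                    dP = 0.0
                dDP = DP[j] * mult / (km * (1.0 + p))
                J[j, i] += (-self.vb[j] * dP - u[j] * f2[j] * dDP) / den[j]
        return J

    def imbalance_jacobian(self, x: np.ndarray) -> np.ndarray:
        """d f / d x = S du/dx, an N x N matrix (rate-law terms only).

        Bias drains are locally constant away from the ramp zone, so at an
        interior steady state this is the exact dynamical Jacobian.
        """
        return self.S @ self.flux_x_partials(x)

    def dynamic_jacobian(self, x: np.ndarray) -> np.ndarray:
        """Jacobian of the dynamical imbalance, including drain-ramp terms.

        Inside the ramp zone a bias drain responds steeply to its source
        pool (slope b / clamp_width), which is what pins an exhausted pool
        near zero; the regulation's quasi-steady-state sensitivities need
        these terms to stay well conditioned.
        """
        J = self.imbalance_jacobian(x)
        for j in np.flatnonzero(self.drain_source >= 0):
            i = self.drain_source[j]
            if 0.0 <= x[i] < self.clamp_width:
                J[:, i] += self.S[:, j] * (self.fixed_values[j] / self.clamp_width)
        for i in np.flatnonzero(self.virtual_sink > 0):
            if 0.0 <= x[i] < self.clamp_width:
                J[i, i] -= self.virtual_sink[i] / self.clamp_width
        return J

    # -- integration ------------------------------------------------------
    def relax(
        self,
        x0: np.ndarray,
        horizon: float,
        rtol: float = 1e-7,
        atol: float = 1e-9,
    ) -> np.ndarray:
        """Integrate dx/dt = S u toward quasi-steady state for one horizon."""
        sol = solve_ivp(
            self.rhs,
            (0.0, horizon),
            np.maximum(x0, 0.0),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise KineticsError(f"concentration relaxation failed: {sol.message}")
        return np.maximum(sol.y[:, -1], 0.0)

    def polish_steady_state(self, x0: np.ndarray, tol: float = 1e-12):
        """Newton-polish the full-demand balance f(x) = 0 from x0."""
        res = root(
            self.cost_imbalance,
            np.maximum(x0, 1e-12),
            jac=self.imbalance_jacobian,
            method="hybr",
            tol=tol,
        )
        x = res.x
        if not res.success or np.any(x < -1e-9):
            return x0, False
        return np.maximum(x, 0.0), True


def imbalance_vector(
    x: np.ndarray, model: NetworkModel, condition: "Condition | None" = None
) -> np.ndarray:
    """Metabolite imbalance f = S u(x) for a plain model (convenience path)."""
    return KineticModel(model, condition).imbalance(np.asarray(x, dtype=float))


def ode_rhs(
    t: float, x: np.ndarray, model: NetworkModel, condition: "Condition | None" = None
) -> np.ndarray:
    """dx/dt = S u(x) with non-negativity clamping at x = 0."""
    return KineticModel(model, condition).rhs(t, np.asarray(x, dtype=float))
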