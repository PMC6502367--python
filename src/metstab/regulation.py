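"""Self-regulation of kinetic parameters toward stable steady states.

A living cell keeps its metabolism near a steady state by adjusting enzyme
levels; here that adjustment is emulated by a deterministic regulation flow
derived from a Lyapunov analysis of the network dynamics.  The regulation
minimizes the non-negative cost

    psi(x, V) = sum_n (1 + c_n) * f_n(x, V)^2,

where f = S u is the metabolite imbalance (bias fluxes for demanded
outputs and virtual probe sinks already folded in) and c_n is the carbon
count of metabolite n, so that carbon-rich imbalances are penalized more.
Each regulated peak rate V_k in {V_F, V_B} follows

    dV_k/dt = -V_k^2 d/dV_k [ (1 / (V_k N_k)) * g_k(x, V) ]
            = (g_k - V_k dg_k/dV_k) / N_k,

with g_k the cost summed over the N_k metabolites affected by V_k.  In a
connected network at steady state every rate constant affects every
metabolite, so by default g_k is the full network cost (N_k = N,
``coupling="global"``): any residual imbalance anywhere drives enzyme
growth throughout the network, locally modulated by the gradient term.
The strictly local variant (``coupling="local"``: only the metabolites of
reaction k) is kept for comparison; it cannot propagate a boundary demand
through interior metabolites, whose imbalances vanish at quasi-steady
state.  At a fully balanced state every dV_k/dt vanishes either way.

Concentrations and parameters evolve on separated timescales: x is relaxed
toward quasi-steady state between parameter updates, and parameters are
advanced in log space (which preserves positivity).  Because the plain
flow approaches the balanced manifold only algebraically, a damped
Gauss-Newton terminal phase on (x, ln V) finishes the descent of psi once
the imbalance is small; steps are accepted only when they reduce psi, so
the cost trace stays non-increasing.  The thermodynamic (Haldane)
constraint V_F prod K'_j / (V_B prod K_i) = K_eq is re-enforced on
reversible reactions at each outer iteration by rescaling the product-side
Michaelis constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

from .kinetics import KineticModel
from .network import NetworkModel, ReactionKinetics, ReactionSpec

if TYPE_CHECKING:  # pragma: no cover
    from .library import Condition


class RegulationFailure(RuntimeError):
    """Persistent cost increase or stall along the regulation trajectory."""

    def __init__(self, message: str, trace: "RegulationTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class RegulationConfig:
    """Tunable knobs of the self-regulation loop.

    All quantities are in the model's reduced units (concentrations of
    order the Michaelis constants, fluxes of order the demand biases).
    """

    eps_f: float = 1e-6            # convergence threshold on ||f||_inf
    inner_horizon: float = 3.0     # concentration relaxation span per outer step
    inner_rounds: int = 6          # extra relaxation rounds if not yet quasi-steady
    qss_tol: float = 1e-4          # quasi-steadiness threshold on clamped dx/dt
    gn_trigger: float = 2e-2       # ||f||_inf below which the terminal phase starts
    gn_every: int = 10             # also attempt the terminal solve this often
    settle_rounds: int = 5         # nudge-and-relax rounds to leave saddles
    settle_horizon: float = 200.0  # relaxation span of each settling round
    max_outer: int = 400           # outer-iteration budget
    max_time: float = 1e8          # total regulation-time budget
    max_step_log: float = 0.25     # per-step cap on |delta ln V|
    dt_max: float = 1e4            # cap on the parameter-time step
    divergence_patience: int = 80  # outer steps without cost improvement
    coupling: str = "global"       # "global" | "local" cost footprint per V_k
    u_init_range: tuple[float, float] = (0.01, 0.05)
    rev_gamma_range: tuple[float, float] = (0.2, 0.8)
    x0_value: float = 1.0
    gradient_mode: str = "analytic"          # or "finite_difference"
    haldane_mode: str = "each_iteration"     # "each_iteration" | "init" | "never"
    sigma_weights: dict[str, float] | None = None  # override of the (1+c) weights
    seed: int = 0


@dataclass
class RegulationTrace:
    """Time course of the regulation run."""

    times: list[float] = field(default_factory=list)
    psi: list[float] = field(default_factory=list)
    vf_history: list[np.ndarray] = field(default_factory=list)
    vb_history: list[np.ndarray] = field(default_factory=list)
    converged: bool = False
    x_final: np.ndarray | None = None
    fluxes_final: np.ndarray | None = None
    n_outer: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "psi": self.psi})


def _weights(km: KineticModel, config: RegulationConfig | None) -> np.ndarray:
    w = 1.0 + km.carbon
    if config is not None and config.sigma_weights:
        for mid, value in config.sigma_weights.items():
            if value <= 0:
                raise ValueError(f"sigma weight for {mid!r} must be positive")
            w[km.model.metabolite_index(mid)] = value
    return w


def cost_psi(
    x: np.ndarray,
    model: NetworkModel | KineticModel,
    condition: "Condition | None" = None,
    config: RegulationConfig | None = None,
) -> float:
    """Carbon-weighted quadratic cost of the metabolite imbalance."""
    km = model if isinstance(model, KineticModel) else KineticModel(model, condition)
    f = km.cost_imbalance(np.asarray(x, dtype=float))
    return float(np.sum(_weights(km, config) * f**2))


def regulation_rhs(
    km: KineticModel,
    x: np.ndarray,
    config: RegulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Parameter derivatives (dV_F/dt, dV_B/dt) of the regulation flow.

    Entries are zero for boundary columns (closed or bias-fixed exchanges)
    and for the backward rate of irreversible reactions.
    """
    config = config or RegulationConfig()
    w = _weights(km, config)
    f = km.cost_imbalance(x)

    if config.coupling == "local":
        # strictly local footprint with explicit partials at fixed x
        mask = (km.S != 0).astype(float)
        g = mask.T @ (w * f**2)
        n_k = np.maximum((km.S != 0).sum(axis=0), 1)
        if config.gradient_mode == "finite_difference":
            dg_dvf, dg_dvb = _fd_cost_gradients(km, x, w, "local")
        else:
            du_dvf, du_dvb = km.flux_v_partials(x)
            s_dot = km.S.T @ (w * f)
            dg_dvf = 2.0 * s_dot * du_dvf
            dg_dvb = 2.0 * s_dot * du_dvb
        free = ~km.fixed_mask
        dvf = np.where(free, (g - km.vf * dg_dvf) / n_k, 0.0)
        dvb = np.where(free & (km.vb > 0), (g - km.vb * dg_dvb) / n_k, 0.0)
        return dvf, dvb

    # default: preconditioned descent of the network cost along the
    # quasi-steady manifold, W = diag(N / V_k^2)
    n = km.model.n_internal
    dpsi_dvf, dpsi_dvb = _total_cost_gradients(km, x, w)
    free = ~km.fixed_mask
    dvf = np.where(free, -(km.vf**2 / n) * dpsi_dvf, 0.0)
    dvb = np.where(free & (km.vb > 0), -(km.vb**2 / n) * dpsi_dvb, 0.0)
    return dvf, dvb


def _response_factor(Jd: np.ndarray, horizon: float) -> np.ndarray:
    """Finite-horizon linear response matrix phi(J) = (e^{JT} - I) J^{-1}.

    The concentration shift produced by a small parameter step dV over one
    relaxation span T is dx = phi(J) (df/dV) dV.  Modes faster than T reach
    their quasi-steady shift (-1/lambda), slow and near-null modes saturate
    at T, so the response never extrapolates beyond what the dynamics can
    actually follow -- the natural regularization of the singular
    quasi-steady sensitivity.  Locally unstable modes are clamped to the
    neutral response.
    """
    lam, Q = np.linalg.eig(Jd)
    lam = np.where(lam.real > 0, 1j * lam.imag, lam)
    z = lam * horizon
    small = np.abs(z) < 1e-8
    lam_safe = np.where(small, 1.0, lam)
    phi = np.where(small, horizon, (np.exp(z) - 1.0) / lam_safe)
    return (Q * phi) @ np.linalg.inv(Q)


def _total_cost_gradients(km: KineticModel, x: np.ndarray, w: np.ndarray):
    """Total derivative of psi with respect to each peak rate.

    The state is not frozen while a parameter moves: over one relaxation
    span the concentrations respond by dx = phi(J) df/dV, so the gradient
    carries this implicit term in addition to the explicit rate-law
    partial.  Without it a boundary demand cannot propagate to upstream
    enzymes, whose own metabolites are balanced at quasi-steady state.
    """
    f = km.cost_imbalance(x)
    du_dvf, du_dvb = km.flux_v_partials(x)
    horizon = getattr(km, "_response_horizon", 18.0)
    try:
        R = _response_factor(km.dynamic_jacobian(x), horizon)
    except np.linalg.LinAlgError:  # pragma: no cover - defective Jacobian
        R = np.zeros((km.model.n_internal, km.model.n_internal))
    Jc = km.imbalance_jacobian(x)
    JcR = np.real(Jc @ R)
    wf = w * f

    def total(du_dv):
        cols = np.flatnonzero(du_dv != 0)
        out = np.zeros(km.model.n_reactions)
        if cols.size == 0:
            return out
        B = km.S[:, cols] * du_dv[cols]          # df/dV_k, one column per k
        out[cols] = 2.0 * (wf @ (B + JcR @ B))
        return out

    return total(du_dvf), total(du_dvb)


def cost_gradients_explicit(km: KineticModel, x: np.ndarray, w: np.ndarray):
    """Analytic explicit partials (d psi / d V_F, d psi / d V_B) at fixed x."""
    f = km.cost_imbalance(x)
    du_dvf, du_dvb = km.flux_v_partials(x)
    s_dot = km.S.T @ (w * f)
    return 2.0 * s_dot * du_dvf, 2.0 * s_dot * du_dvb


def _fd_cost_gradients(km: KineticModel, x: np.ndarray, w: np.ndarray,
                       coupling: str = "global"):
    """Central finite differences of g_k with respect to V_F and V_B."""
    dg_dvf = np.zeros(km.model.n_reactions)
    dg_dvb = np.zeros(km.model.n_reactions)
    mask = (km.S != 0).astype(float)

    def g_of(j):
        f = km.cost_imbalance(x)
        if coupling == "local":
            return float(mask[:, j] @ (w * f**2))
        return float(np.sum(w * f**2))

    for j in np.flatnonzero(~km.fixed_mask):
        for arr, out in ((km.vf, dg_dvf), (km.vb, dg_dvb)):
            v0 = arr[j]
            if v0 <= 0:
                continue
            h = 1e-6 * max(v0, 1e-3)
            arr[j] = v0 + h
            up = g_of(j)
            arr[j] = v0 - h
            lo = g_of(j)
            arr[j] = v0
            out[j] = (up - lo) / (2 * h)
    return dg_dvf, dg_dvb


# -- Haldane / thermodynamic constraint -----------------------------------

def enforce_haldane(reaction: ReactionSpec) -> tuple[ReactionKinetics, dict[str, float]]:
    """Rescale product-side Michaelis constants so the Haldane ratio is K_eq.

    Returns the adjusted kinetics and the concentration rescaling (per
    product species) that would keep every saturation ratio [P]/K'
    unchanged.  Irreversible reactions are returned untouched.
    """
    kin = reaction.kinetics
    if not kin.reversible or kin.k_eq is None:
        return kin, {}
    exp_p = sum(m for _, m in reaction.products)
    ratio = (
        kin.v_forward
        * math.prod(k**m for k, (_, m) in zip(kin.km_products, reaction.products))
        / (
            kin.v_backward
            * math.prod(
                k**m for k, (_, m) in zip(kin.km_substrates, reaction.substrates)
            )
        )
    )
    scale = (kin.k_eq / ratio) ** (1.0 / exp_p)
    if abs(scale - 1.0) < 1e-15:
        return kin, {}
    new = replace(kin, km_products=tuple(k * scale for k in kin.km_products))
    rescale = {sp: scale for sp, _ in reaction.products}
    return new, rescale


def enforce_haldane_compiled(km: KineticModel) -> None:
    """In-place Haldane enforcement on the compiled arrays (reversible only)."""
    for j, rxn in enumerate(km.model.reactions):
        if km.vb[j] <= 0 or not np.isfinite(km.k_eq[j]) or rxn.is_exchange:
            continue
        exp_p = sum(m for _, m in km._prod_entries[j])
        if exp_p == 0:
            continue
        num = km.vf[j] * math.prod(km.KP[i, j] ** m for i, m in km._prod_entries[j])
        den = km.vb[j] * math.prod(km.KS[i, j] ** m for i, m in km._sub_entries[j])
        scale = (km.k_eq[j] / (num / den)) ** (1.0 / exp_p)
        for i, _ in km._prod_entries[j]:
            km.KP[i, j] *= scale


# -- initialization --------------------------------------------------------

def draw_initial_rates(
    km: KineticModel, rng: np.random.Generator, config: RegulationConfig
) -> None:
    """Seeded initial {V_F, V_B}: small uniform fluxes across the network.

    Each regulated reaction's rates are scaled so its initial net flux at
    the uniform starting concentrations lies in ``u_init_range``.
    """
    x0 = np.full(km.model.n_internal, config.x0_value)
    lo, hi = config.u_init_range
    targets = rng.uniform(lo, hi, size=km.model.n_reactions)
    gammas = rng.uniform(*config.rev_gamma_range, size=km.model.n_reactions)
    vf = km.vf.copy()
    vb = km.vb.copy()
    for j in np.flatnonzero(~km.fixed_mask):
        reversible = km.model.reactions[j].kinetics.reversible
        gamma = gammas[j] if reversible else 0.0
        km.vf[j], km.vb[j] = 1.0, gamma
        u_unit = km.fluxes(x0)[j]
        if u_unit <= 1e-12:
            gamma = 0.0
            km.vf[j], km.vb[j] = 1.0, 0.0
            u_unit = km.fluxes(x0)[j]
        s = min(targets[j] / u_unit, km.vf_cap[j])
        vf[j], vb[j] = s, gamma * s
        km.vf[j], km.vb[j] = vf[j], vb[j]
    km.set_rates(vf, vb)


def _model_from_compiled(km: KineticModel) -> NetworkModel:
    """Materialize the compiled (possibly Haldane-adjusted) kinetics."""
    updates = {}
    for j, rxn in enumerate(km.model.reactions):
        kmp = []
        for (sp, _), k_old in zip(rxn.products, rxn.kinetics.km_products):
            if sp == "External":
                kmp.append(k_old)
            else:
                kmp.append(float(km.KP[km.model.metabolite_index(sp), j]))
        updates[rxn.id] = replace(
            rxn.kinetics,
            v_forward=float(km.vf[j]),
            v_backward=float(km.vb[j]),
            km_products=tuple(kmp),
        )
    return km.model.replace_kinetics(updates)


# -- Gauss-Newton terminal phase ------------------------------------------

_LOGV_SPAN = 30.0  # |ln V| bound in the terminal phase
_RIDGE = 1e-8      # ridge weight tying the step to the current parameters


def _gauss_newton_phase(
    km: KineticModel, x: np.ndarray, w: np.ndarray, eps_f: float
) -> tuple[np.ndarray, bool]:
    """Damped least-squares descent of psi over (x, ln V); returns (x, ok).

    The problem is underdetermined (more parameters than balance
    equations), so a small ridge term keeps the solution near the state the
    regulation flow reached; bounds keep concentrations non-negative.
    """
    free_f = np.flatnonzero(~km.fixed_mask)
    free_b = free_f[km.vb[free_f] > 0]
    n = km.model.n_internal
    sw = np.sqrt(w)
    ridge = math.sqrt(_RIDGE)
    z0 = np.concatenate([
        np.maximum(x, 0.0),
        np.log(km.vf[free_f]),
        np.log(km.vb[free_b]) if len(free_b) else np.empty(0),
    ])
    p = len(free_f) + len(free_b)

    def set_state(z):
        km.vf[free_f] = np.exp(z[n:n + len(free_f)])
        if len(free_b):
            km.vb[free_b] = np.exp(z[n + len(free_f):])
        return z[:n]

    def residual(z):
        xx = set_state(z)
        f = km.cost_imbalance(xx)
        return np.concatenate([sw * f, ridge * (z[n:] - z0[n:])])

    def jac(z):
        xx = set_state(z)
        J = np.zeros((n + p, n + p))
        J[:n, :n] = sw[:, None] * km.imbalance_jacobian(xx)
        du_dvf, du_dvb = km.flux_v_partials(xx)
        for col, j in enumerate(free_f):
            J[:n, n + col] = sw * km.S[:, j] * du_dvf[j] * km.vf[j]
        for col, j in enumerate(free_b):
            J[:n, n + len(free_f) + col] = sw * km.S[:, j] * du_dvb[j] * km.vb[j]
        J[n:, n:] = ridge * np.eye(p)
        return J

    lower = np.concatenate([np.zeros(n), np.full(p, -_LOGV_SPAN)])
    cap_f = np.minimum(_LOGV_SPAN, np.log(km.vf_cap[free_f]))
    upper = np.concatenate([np.full(n, np.inf), cap_f, np.full(len(free_b), _LOGV_SPAN)])
    res = least_squares(
        residual,
        np.clip(z0, lower + 1e-12, upper),
        jac=jac,
        bounds=(lower, upper),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=300,
    )
    x_new = set_state(res.x)
    ok = bool(np.max(np.abs(km.cost_imbalance(x_new))) < eps_f)
    return x_new, ok


def _gauss_newton_rounds(
    km: KineticModel, x: np.ndarray, w: np.ndarray, eps_f: float, rounds: int = 6
) -> tuple[np.ndarray, bool]:
    """Repeat the damped solve while it keeps making clear progress."""
    best = float(np.max(np.abs(km.cost_imbalance(x))))
    for _ in range(rounds):
        x, ok = _gauss_newton_phase(km, x, w, eps_f)
        if ok:
            return x, True
        now = float(np.max(np.abs(km.cost_imbalance(x))))
        if now > 0.9 * best:
            break
        best = now
    return x, False


# -- the main loop ---------------------------------------------------------

def run_regulation(
    model: NetworkModel,
    condition: "Condition | None",
    config: RegulationConfig | None = None,
    warm_start: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[NetworkModel, RegulationTrace]:
    """Co-evolve concentrations and peak rates until the network balances.

    Returns the regulated model (with converged {V_F, V_B} and
    Haldane-consistent Michaelis constants) and the trace of the run.
    ``warm_start`` optionally provides (vf, vb, x) to continue from, e.g.
    when re-running a perturbed condition from a converged reference state.

    Raises :class:`RegulationFailure` when the cost increases or stalls
    persistently above the terminal-phase trigger.
    """
    config = config or RegulationConfig()
    km = KineticModel(model, condition)
    km._response_horizon = config.inner_horizon * config.inner_rounds
    rng = np.random.default_rng(config.seed)
    trace = RegulationTrace()

    if warm_start is not None:
        vf0, vb0, x = (np.asarray(a, dtype=float).copy() for a in warm_start)
        km.set_rates(vf0, vb0)
    else:
        draw_initial_rates(km, rng, config)
        x = np.full(model.n_internal, config.x0_value)

    if config.haldane_mode in ("each_iteration", "init"):
        enforce_haldane_compiled(km)

    w = _weights(km, config)
    t = 0.0
    best_psi = np.inf
    prev_psi = np.inf
    n_stalled = 0
    step_cap = config.max_step_log  # trust-region-style cap on |delta ln V|

    for outer in range(config.max_outer):
        trace.n_outer = outer + 1
        # inner relaxation of concentrations at fixed parameters
        for _ in range(config.inner_rounds):
            x = km.relax(x, config.inner_horizon)
            if np.max(np.abs(km.rhs(0.0, x))) < config.qss_tol:
                break
        f = km.cost_imbalance(x)
        psi = float(np.sum(w * f**2))
        trace.times.append(t)
        trace.psi.append(psi)
        trace.vf_history.append(km.vf.copy())
        trace.vb_history.append(km.vb.copy())

        # shrink the step cap after a clear uphill step, restore gradually
        if psi > prev_psi * (1.0 + 1e-3):
            step_cap = max(step_cap / 2.0, config.max_step_log / 64.0)
        else:
            step_cap = min(step_cap * 1.3, config.max_step_log)
        prev_psi = psi

        if psi < best_psi * (1.0 - 1e-10):
            best_psi = psi
            n_stalled = 0
        else:
            n_stalled += 1
            if n_stalled > config.divergence_patience:
                trace.x_final = x
                trace.fluxes_final = km.fluxes(x)
                raise RegulationFailure(
                    f"cost stalled at {psi:.3e} for {n_stalled} iterations", trace
                )

        # terminal phase: always once the imbalance is small, and
        # periodically from farther out (accepted only on clear descent)
        try_gn = np.max(np.abs(f)) < config.gn_trigger or (
            outer > 0 and outer % config.gn_every == 0
        )
        if try_gn:
            saved = (km.vf.copy(), km.vb.copy(), x.copy())
            x_gn, ok = _gauss_newton_rounds(km, x, w, config.eps_f)
            psi_gn = float(np.sum(w * km.cost_imbalance(x_gn) ** 2))
            if psi_gn <= psi:
                x = x_gn
            else:
                km.set_rates(saved[0], saved[1])
                x = saved[2]
                ok = False
            if ok:
                # dynamical settling: a balanced state found by the
                # terminal solve may sit on a repelling branch; kick
                # along the most unstable eigenvector, ride the drift,
                # and re-balance until the state is also attracting
                for _ in range(config.settle_rounds):
                    lam, vecs = np.linalg.eig(km.dynamic_jacobian(x))
                    k = int(np.argmax(lam.real))
                    if lam.real[k] < 1e-8:
                        break
                    vec = np.real(vecs[:, k])
                    vec = vec / max(np.max(np.abs(vec)), 1e-12)
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    x_kick = np.maximum(
                        x + 0.05 * sign * (1.0 + x) * vec, 0.0
                    )
                    for _ in range(20):
                        x_kick = km.relax(x_kick, config.settle_horizon)
                        if np.max(np.abs(km.cost_imbalance(x_kick))) > 5e-3:
                            break
                    x_new, ok2 = _gauss_newton_rounds(
                        km, x_kick, w, config.eps_f, rounds=3
                    )
                    if not ok2:
                        break  # keep the previous balanced state
                    x = x_new
                if ok and config.haldane_mode != "never":
                    # thermodynamic finalization: rescale the product-side
                    # constants exactly, then re-balance concentrations at
                    # fixed parameters so both the Haldane ratio and the
                    # steady state hold simultaneously; if no nearby x-root
                    # exists, let the parameters move and re-enforce
                    for attempt in range(5):
                        enforce_haldane_compiled(km)
                        if np.max(np.abs(km.cost_imbalance(x))) < config.eps_f:
                            break  # enforcement left the balance intact
                        x_p, ok_p = km.polish_steady_state(x)
                        if ok_p and np.max(
                            np.abs(km.cost_imbalance(x_p))
                        ) < config.eps_f:
                            x = x_p
                            break
                        x, ok = _gauss_newton_rounds(
                            km, x, w, config.eps_f, rounds=2
                        )
                        if not ok:
                            break
                    else:
                        enforce_haldane_compiled(km)
                        ok = bool(
                            np.max(np.abs(km.cost_imbalance(x))) < config.eps_f
                        )
                if ok:
                    trace.times.append(t)
                    trace.psi.append(float(np.sum(w * km.cost_imbalance(x) ** 2)))
                    trace.vf_history.append(km.vf.copy())
                    trace.vb_history.append(km.vb.copy())
                    trace.converged = True
                    break

        # parameter update in log space, then thermodynamic re-enforcement
        dvf, dvb = regulation_rhs(km, x, config)
        with np.errstate(divide="ignore", invalid="ignore"):
            dlnf = np.where(km.vf > 0, dvf / km.vf, 0.0)
            dlnb = np.where(km.vb > 0, dvb / km.vb, 0.0)
        rate = max(np.max(np.abs(dlnf)), np.max(np.abs(dlnb)), 1e-300)
        dt = min(config.dt_max, step_cap / rate)
        bound = math.exp(_LOGV_SPAN)
        km.vf = np.clip(km.vf * np.exp(dlnf * dt), 0.0,
                        np.minimum(bound, km.vf_cap))
        km.vb = np.clip(km.vb * np.exp(dlnb * dt), 0.0, bound)
        if config.haldane_mode == "each_iteration":
            enforce_haldane_compiled(km)
        t += dt
        if t > config.max_time:
            break

    trace.x_final = x
    trace.fluxes_final = km.fluxes(x)
    return _model_from_compiled(km), trace
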