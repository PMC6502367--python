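"""Steady-state characterization: Jacobian, relaxation time, efficiency.

The robustness of a steady state is summarized by its relaxation time

    RT = -(1/N) sum_i 1/lambda_i,

the mean negative inverse of the nonzero Jacobian eigenvalues, where N is
the number of nonzero modes -- fixed by the rank of the stoichiometric
matrix restricted to concentration-dependent reaction columns (constant
bias fluxes and closed exchanges contribute no mode, and conservation laws
contribute exact zeros).  A state is stable when every nonzero mode has a
negative real part; a shorter RT means faster return from fluctuations,
i.e. a more robust state.  Efficiency is the ratio of carbon imported
through intakes to carbon exported as demanded biomass; lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .kinetics import KineticModel
from .network import NetworkModel
from .regulation import RegulationConfig, RegulationTrace, run_regulation

if TYPE_CHECKING:  # pragma: no cover
    from .library import Condition


class StructuralError(RuntimeError):
    """Nonzero-eigenvalue count disagrees with the stoichiometric rank."""


class EfficiencyError(RuntimeError):
    """No biomass carbon is exported; the efficiency ratio is undefined."""


@dataclass
class SteadyStateResult:
    """A converged, characterized steady state of one (condition, seed) run."""

    condition: str
    seed: int
    x_star: np.ndarray
    u_star: np.ndarray
    eigenvalues: np.ndarray
    rt: float
    stable: bool
    efficiency: float
    converged: bool
    vf: np.ndarray = field(repr=False, default=None)
    vb: np.ndarray = field(repr=False, default=None)
    stoich_rank: int = 0


def jacobian(
    x: np.ndarray,
    model: NetworkModel | KineticModel,
    condition: "Condition | None" = None,
) -> np.ndarray:
    """Analytic Jacobian d(Su)/dx of the network dynamics at ``x``."""
    km = model if isinstance(model, KineticModel) else KineticModel(model, condition)
    J = km.imbalance_jacobian(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite Jacobian entries")
    return J


def x_dependent_columns(km: KineticModel) -> list[int]:
    """Reaction columns whose flux actually responds to concentrations.

    Fixed-flux and closed exchanges never do; an irreversible intake with
    only the External node upstream has constant flux at given V_F and is
    excluded as well.
    """
    cols = []
    for j in np.flatnonzero(~km.fixed_mask):
        has_sub = bool(km.ES[:, j].any())
        has_rev_prod = km.vb[j] > 0 and bool(km.EP[:, j].any())
        if has_sub or has_rev_prod:
            cols.append(int(j))
    return cols


def relaxation_time(
    eigenvalues: np.ndarray,
    stoich_rank: int,
    null_tol: float = 1e-9,
    imag_tol: float = 1e-10,
) -> float:
    """RT from a Jacobian spectrum; NaN when a nonzero mode is unstable.

    Eigenvalues with magnitude below ``null_tol`` times the spectral radius
    are structural zeros (conservation laws); their count must equal the
    dimension minus the stoichiometric rank, otherwise a
    :class:`StructuralError` is raised.  Complex pairs enter as full
    complex inverses, which cancel to a real sum by conjugacy.
    """
    lam = np.asarray(eigenvalues, dtype=complex)
    if lam.size == 0 or stoich_rank <= 0:
        raise StructuralError("empty spectrum or non-positive rank")
    scale = np.max(np.abs(lam))
    if scale == 0:
        raise StructuralError("all eigenvalues are zero")
    nonzero = lam[np.abs(lam) > null_tol * scale]
    if nonzero.size != stoich_rank:
        raise StructuralError(
            f"{nonzero.size} nonzero eigenvalues but stoichiometric rank "
            f"{stoich_rank}"
        )
    if np.any(nonzero.real >= 0):
        return float("nan")
    total = np.sum(1.0 / nonzero)
    if abs(total.imag) > imag_tol * max(1.0, abs(total.real)):
        raise StructuralError("non-conjugate spectrum: imaginary RT residue")
    return float(-total.real / stoich_rank)


def efficiency(
    u: np.ndarray,
    model: NetworkModel,
    condition: "Condition",
) -> float:
    """Carbon imported via intakes per carbon exported as demanded biomass."""
    km = KineticModel(model, condition)
    carbon_cols = km.carbon @ km.S  # net internal carbon created per unit flux
    carbon_in = 0.0
    biomass_out = 0.0
    bias_cols = set()
    for mid in condition.output_biases:
        bias_cols.add(km._export_column(mid))
    for j, rxn in enumerate(model.reactions):
        if not rxn.is_exchange:
            continue
        created = carbon_cols[j] * u[j]
        if j in bias_cols:
            biomass_out += -created
        elif created > 0:
            carbon_in += created
    if biomass_out <= 0:
        raise EfficiencyError(
            f"condition {condition.name!r}: no biomass carbon exported"
        )
    return float(carbon_in / biomass_out)


def characterize_steady_state(
    model: NetworkModel,
    condition: "Condition",
    config: RegulationConfig | None = None,
    warm_start=None,
) -> tuple[SteadyStateResult, RegulationTrace]:
    """Run the self-regulation to convergence and characterize the state."""
    config = config or RegulationConfig()
    regulated, trace = run_regulation(model, condition, config, warm_start=warm_start)
    x = trace.x_final
    u = trace.fluxes_final
    km = KineticModel(regulated, condition)
    J = jacobian(x, km)
    lam = np.linalg.eigvals(J)
    rank = int(np.linalg.matrix_rank(km.S[:, x_dependent_columns(km)]))
    try:
        rt = relaxation_time(lam, rank)
    except StructuralError:
        # pools sitting exactly at zero can decouple modes beyond the
        # stoichiometric count; fall back to the Jacobian's own rank
        rank = int(np.linalg.matrix_rank(J, tol=1e-9 * max(np.abs(lam))))
        rt = relaxation_time(lam, rank)
    stable = bool(np.isfinite(rt))
    try:
        eff = efficiency(u, regulated, condition)
    except EfficiencyError:
        eff = float("nan")
    result = SteadyStateResult(
        condition=condition.name,
        seed=config.seed,
        x_star=x,
        u_star=u,
        eigenvalues=lam,
        rt=rt,
        stable=stable,
        efficiency=eff,
        converged=trace.converged,
        vf=km.vf.copy(),
        vb=km.vb.copy(),
        stoich_rank=rank,
    )
    return result, trace
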