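"""Flux-landscape experiments: scanning, classification, switches, knockouts.

Scanning the condition ensemble yields a conditions x reactions matrix of
converged steady-state fluxes.  On top of it sit the analyses: two-class
classification of the flux landscape, identification of the few reactions
that switch (flux range above threshold or direction reversal) while the
rest stay buffered, probing which metabolite demands can flip the network
between classes, knockouts of the secondary-metabolite pathways with a
paired relaxation-time comparison, and the effective four-enzyme switching
circuit whose attractors reproduce the two flux configurations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import binomtest, spearmanr
from sklearn.metrics import silhouette_score

from .library import Condition, ConditionEnsemble
from .network import NetworkModel
from .regulation import RegulationConfig, RegulationFailure
from .stability import SteadyStateResult, characterize_steady_state

log = logging.getLogger(__name__)

CENTRAL_TAGS = frozenset({"glycolysis", "ppp", "tca", "amino_acid"})

#: reactions whose peak |flux| across conditions falls below this carry no
#: usable class signal (smallest demand biases are ~0.02 flux units)
_MIN_CLASS_ACTIVITY = 0.02
SECONDARY_TAGS = {
    "xiamenmycin": "secondary_xiamenmycin",
    "ptm": "secondary_ptm",
}


class ScanError(RuntimeError):
    pass


@dataclass
class FluxLandscape:
    """Conditions x reactions steady-state flux matrix with metadata."""

    fluxes: pd.DataFrame               # absolute (signed) fluxes
    meta: pd.DataFrame                 # rt, efficiency, seed, stable per row
    model: NetworkModel = field(repr=False, default=None)
    results: dict[str, SteadyStateResult] = field(repr=False, default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def normalized(self) -> pd.DataFrame:
        """Each reaction column scaled to [-1, 1] by its maximum |flux|."""
        scale = self.fluxes.abs().max(axis=0).replace(0.0, 1.0)
        return self.fluxes / scale

    def non_exchange_columns(self) -> list[str]:
        """Interior reaction columns: everything except exchanges.

        Sugar transport steps are also excluded from switch candidacy --
        their flux is dictated by which nutrient intakes a condition
        opens, so their variation is imposed rather than emergent.
        """
        return [
            r.id
            for r in self.model.reactions
            if not r.is_exchange and "transport" not in r.tags
        ]


def scan_conditions(
    model: NetworkModel,
    ensemble: ConditionEnsemble,
    config: RegulationConfig | None = None,
) -> FluxLandscape:
    """One converged steady state per (condition, seed); failures logged."""
    config = config or RegulationConfig()
    rows, meta_rows, results, failures = [], [], {}, {}
    for condition, seed in ensemble:
        result = None
        # retry a few initial-parameter draws: not every draw settles into
        # a stable steady state, matching the many-starts protocol
        for attempt in range(3):
            cfg = replace(config, seed=seed + 7919 * attempt)
            try:
                candidate, _ = characterize_steady_state(model, condition, cfg)
            except RegulationFailure as exc:
                failures[condition.name] = str(exc)
                log.warning("condition %s seed %d failed: %s",
                            condition.name, cfg.seed, exc)
                continue
            if candidate.converged and (result is None or
                                        (candidate.stable and not result.stable)):
                result = candidate
            if result is not None and result.stable:
                break
        if result is None:
            failures.setdefault(condition.name, "no converged steady state")
            log.warning("condition %s: no converged steady state", condition.name)
            continue
        failures.pop(condition.name, None)
        rows.append(pd.Series(result.u_star, index=[r.id for r in model.reactions],
                              name=condition.name))
        meta_rows.append(
            {
                "condition": condition.name,
                "seed": result.seed,
                "rt": result.rt,
                "stable": result.stable,
                "efficiency": result.efficiency,
            }
        )
        results[condition.name] = result
    if not rows:
        raise ScanError("all conditions failed to converge")
    fluxes = pd.DataFrame(rows)
    meta = pd.DataFrame(meta_rows).set_index("condition")
    return FluxLandscape(fluxes=fluxes, meta=meta, model=model, results=results,
                         failures=failures)


# -- classification --------------------------------------------------------

def _correlation_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise correlation distance with a convention for flat rows."""
    n = X.shape[0]
    D = np.zeros((n, n))
    sd = X.std(axis=1)
    for i, j in itertools.combinations(range(n), 2):
        if sd[i] < 1e-15 and sd[j] < 1e-15:
            d = 0.0 if np.allclose(X[i], X[j]) else 1.0
        elif sd[i] < 1e-15 or sd[j] < 1e-15:
            d = 1.0
        else:
            d = 1.0 - np.corrcoef(X[i], X[j])[0, 1]
        D[i, j] = D[j, i] = max(d, 0.0)
    return D


def classify_states(
    landscape: FluxLandscape | pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4),
) -> tuple[pd.Series, int]:
    """Group normalized flux rows by hierarchical clustering.

    Correlation distance with average linkage; the number of classes is
    chosen within ``k_range`` by silhouette score over partitions whose
    classes all contain at least two states (a singleton outlier state is
    not a flux-landscape group).  Returns (labels, k).
    """
    if isinstance(landscape, FluxLandscape):
        # the class signature is the interior flux pattern; boundary and
        # transport columns mechanically mirror how a condition is built,
        # and near-silent reactions would contribute pure noise once
        # normalized by their tiny maxima
        interior = landscape.non_exchange_columns()
        active = landscape.fluxes[interior].abs().max(axis=0)
        keep = active[active >= _MIN_CLASS_ACTIVITY].index.tolist()
        norm = landscape.normalized()[keep]
    else:
        norm = landscape
    X = norm.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 converged rows to classify")
    D = _correlation_distances(X)
    if D.max() < 1e-12:
        return pd.Series(1, index=norm.index), 1
    Z = linkage(squareform(D, checks=False), method="average")
    best = None
    for k in k_range:
        if k < 2 or k > n - 1:
            continue
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        counts = np.bincount(labels)
        if counts[counts > 0].min() < 2:
            continue
        score = silhouette_score(D, labels, metric="precomputed")
        if best is None or score > best[0]:
            best = (score, k, labels)
    if best is None:
        raise ValueError("no valid clustering in k_range")
    _, k, labels = best
    return pd.Series(labels, index=norm.index), k


# -- switches --------------------------------------------------------------

@dataclass
class SwitchReport:
    """Reactions whose flux switches across conditions, and switch metabolites."""

    switching_reactions: list[str]
    central_switching: list[str]
    switch_metabolites: list[str] = field(default_factory=list)
    threshold: float = 0.1
    ranges: pd.Series = field(repr=False, default=None)
    sign_reversals: list[str] = field(default_factory=list)


def identify_switches(
    landscape: FluxLandscape, threshold: float = 0.1
) -> SwitchReport:
    """Flag non-exchange reactions with flux range > threshold or reversal.

    Exchange fluxes vary with the imposed boundary conditions by
    construction, so only interior reactions are candidates; `central`
    switches are those tagged glycolysis/ppp/tca/amino_acid.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cols = landscape.non_exchange_columns()
    flux = landscape.fluxes[cols]
    rng = flux.max(axis=0) - flux.min(axis=0)
    reversal = (flux.max(axis=0) > 1e-6) & (flux.min(axis=0) < -1e-6)
    if len(flux) < 2:
        switching: list[str] = []
    else:
        switching = sorted(flux.columns[(rng > threshold) | reversal])
    tags = {r.id: r.tags for r in landscape.model.reactions}
    central = [rid for rid in switching if tags[rid] & CENTRAL_TAGS]
    return SwitchReport(
        switching_reactions=switching,
        central_switching=central,
        threshold=threshold,
        ranges=rng,
        sign_reversals=sorted(flux.columns[reversal]) if len(flux) >= 2 else [],
    )


# -- switch metabolites ----------------------------------------------------

def _class_centroids(norm: pd.DataFrame, labels: pd.Series) -> dict[int, np.ndarray]:
    return {
        int(lab): norm.loc[labels[labels == lab].index].mean(axis=0).to_numpy()
        for lab in sorted(labels.unique())
    }


def _nearest_class(row: np.ndarray, centroids: dict[int, np.ndarray]) -> int:
    def dist(a, b):
        if a.std() < 1e-15 or b.std() < 1e-15:
            return 1.0
        return 1.0 - np.corrcoef(a, b)[0, 1]

    return min(centroids, key=lambda lab: dist(row, centroids[lab]))


def probe_switch_metabolites(
    model: NetworkModel,
    ensemble: ConditionEnsemble,
    config: RegulationConfig | None = None,
    candidate_metabolites: list[str] | None = None,
    landscape: FluxLandscape | None = None,
    reference: str | None = None,
    delta_frac: float = 0.5,
    probe_scale: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Which metabolite demands can flip the network between flux classes.

    Each candidate's input/output flux is perturbed by +-delta on a
    reference condition, where delta is half the candidate's baseline bias
    but at least ``probe_scale`` -- the same flux scale against which a
    reaction counts as switching, so probes are commensurate with the
    changes that distinguish the classes; the regulation is re-run warm-started from the
    reference steady state and the perturbed state is assigned to the
    nearest of the two flux classes.  A candidate is a switch metabolite
    iff either perturbation lands in the opposite class.  Returns the
    switch list and a per-probe detail table.
    """
    config = config or RegulationConfig()
    if landscape is None:
        landscape = scan_conditions(model, ensemble, config)
    labels, k = classify_states(landscape)
    if k != 2:
        labels, _ = classify_states(landscape, k_range=(2,))
    interior = landscape.non_exchange_columns()
    active = landscape.fluxes[interior].abs().max(axis=0)
    interior = active[active >= _MIN_CLASS_ACTIVITY].index.tolist()
    norm = landscape.normalized()[interior]
    scale = landscape.fluxes.abs().max(axis=0).replace(0.0, 1.0)
    centroids = _class_centroids(norm, labels)

    ref_name = reference or landscape.fluxes.index[0]
    ref_condition = next(c for c, _ in ensemble if c.name == ref_name)
    ref_seed = next(s for c, s in ensemble if c.name == ref_name)
    ref_class = int(labels[ref_name])
    ref_result = landscape.results[ref_name]
    warm = (ref_result.vf, ref_result.vb, ref_result.x_star)

    if candidate_metabolites is None:
        candidate_metabolites = [m.id for m in model.internal_metabolites]
    # supply-side probes are physical only for species the cell can
    # import: those with a declared intake exchange reaction
    transportable = {
        sp
        for r in model.reactions
        if r.is_exchange
        for sp, _ in r.products
        if sp != "External"
    }

    records = []
    switches: list[str] = []
    for mid in candidate_metabolites:
        base = ref_condition.output_biases.get(mid, 0.0)
        delta = max(delta_frac * base, probe_scale)
        flipped = False
        signs = (+1.0, -1.0) if mid in transportable else (+1.0,)
        for sign in signs:
            if delta == 0.0:
                records.append(
                    {"metabolite": mid, "delta": 0.0, "class": ref_class,
                     "flip": False, "status": "zero-perturbation"}
                )
                continue
            probe_cond = ref_condition.with_probe(mid, sign * delta)
            cfg = replace(config, seed=ref_seed)
            try:
                res, _ = characterize_steady_state(
                    model, probe_cond, cfg, warm_start=warm
                )
                status = "ok" if res.converged else "not-converged"
            except RegulationFailure as exc:
                records.append(
                    {"metabolite": mid, "delta": sign * delta, "class": -1,
                     "flip": False, "status": f"failed: {exc}"}
                )
                continue
            if not res.converged:
                records.append(
                    {"metabolite": mid, "delta": sign * delta, "class": -1,
                     "flip": False, "status": status}
                )
                continue
            row = (pd.Series(res.u_star, index=landscape.fluxes.columns)
                   / scale)[interior]
            assigned = _nearest_class(row.to_numpy(), centroids)
            flip = assigned != ref_class
            flipped = flipped or flip
            records.append(
                {"metabolite": mid, "delta": sign * delta, "class": assigned,
                 "flip": flip, "status": status}
            )
        if flipped:
            switches.append(mid)
    return switches, pd.DataFrame.from_records(records)


# -- knockouts and RT comparison ------------------------------------------

def knockout_secondary_metabolism(
    model: NetworkModel, which: str | set[str]
) -> NetworkModel:
    """Zero out secondary-metabolite pathways; topology is retained.

    ``which`` is 'xiamenmycin', 'ptm', 'both', or a set of those names.
    Knocked-out reactions get V_F = V_B = 0 and are excluded from
    regulation (marked with the 'knocked_out' tag).
    """
    if isinstance(which, str):
        names = {"xiamenmycin", "ptm"} if which == "both" else {which}
    else:
        names = set(which)
    unknown = names - set(SECONDARY_TAGS)
    if unknown:
        raise ValueError(f"unknown secondary pathways: {sorted(unknown)}")
    tags_to_kill = {SECONDARY_TAGS[n] for n in names}
    all_tags = set().union(*(r.tags for r in model.reactions))
    missing = tags_to_kill - all_tags
    if missing:
        raise ValueError(f"model lacks tags {sorted(missing)}")
    new_rxns = []
    for r in model.reactions:
        if r.tags & tags_to_kill:
            kin = replace(r.kinetics, v_forward=0.0, v_backward=0.0)
            new_rxns.append(replace(r, kinetics=kin, tags=r.tags | {"knocked_out"}))
        else:
            new_rxns.append(r)
    return model.with_reactions(new_rxns)


@dataclass
class RTComparison:
    """Paired relaxation-time comparison between two result sets."""

    differences: pd.Series        # rt_b - rt_a per shared key
    median_a: float
    median_b: float
    sign_test_p: float            # one-sided: median(b) > median(a)
    n_pairs: int


def compare_rt(
    results_a: list[SteadyStateResult],
    results_b: list[SteadyStateResult],
) -> RTComparison:
    """Per-seed RT differences (b - a) with a one-sided sign test."""
    key = lambda r: (r.condition, r.seed)
    a = {key(r): r.rt for r in results_a}
    b = {key(r): r.rt for r in results_b}
    shared = sorted(set(a) & set(b))
    if not shared or len(shared) != len(a) or len(shared) != len(b):
        raise ValueError("result sets must share identical (condition, seed) pairs")
    diffs = pd.Series({k: b[k] - a[k] for k in shared})
    nonzero = diffs[diffs != 0]
    n_pos = int((nonzero > 0).sum())
    p = (
        binomtest(n_pos, len(nonzero), 0.5, alternative="greater").pvalue
        if len(nonzero)
        else 1.0
    )
    return RTComparison(
        differences=diffs,
        median_a=float(np.median(list(a.values()))),
        median_b=float(np.median(list(b.values()))),
        sign_test_p=float(p),
        n_pairs=len(shared),
    )


def secondary_flux(result: SteadyStateResult, model: NetworkModel) -> float:
    """Total export flux of the secondary metabolites at a steady state."""
    total = 0.0
    for j, r in enumerate(model.reactions):
        if r.is_exchange and (r.tags & set(SECONDARY_TAGS.values())):
            total += result.u_star[j]
    return float(total)


def rt_vs_secondary_correlation(
    results: list[SteadyStateResult], model: NetworkModel
) -> float:
    """Spearman correlation between RT and secondary-metabolite output."""
    rts = [r.rt for r in results]
    fluxes = [secondary_flux(r, model) for r in results]
    rho, _ = spearmanr(rts, fluxes)
    return float(rho)


# -- the effective enzyme circuit ------------------------------------------

CIRCUIT_NODES = (
    "malic_enzyme",
    "malate_dehydrogenase",
    "aspartate_transaminase",
    "transketolase",
)


@dataclass
class BooleanCircuit:
    """Threshold switching circuit over enzyme activity states (+1/-1).

    The default wiring couples malic enzyme and malate dehydrogenase by
    mutual activation, aspartate transaminase and transketolase by mutual
    activation, and the two pairs by mutual antagonism.  States are
    updated by thresholding the weighted input sum; on a tie a node holds
    its state.  Updates are applied either as deterministic asynchronous
    sweeps (the default: with symmetric interactions these descend an
    energy and always terminate in a fixed point) or synchronously.
    """

    nodes: tuple[str, ...] = CIRCUIT_NODES
    interactions: np.ndarray = None
    update: str = "asynchronous"

    def __post_init__(self):
        if self.interactions is None:
            self.interactions = default_circuit_interactions()
        self.interactions = np.asarray(self.interactions, dtype=float)
        n = len(self.nodes)
        if self.interactions.shape != (n, n):
            raise ValueError("interaction matrix shape mismatch")

    def step_sync(self, state: tuple[int, ...]) -> tuple[int, ...]:
        h = self.interactions @ np.array(state)
        return tuple(
            1 if hi > 0 else (-1 if hi < 0 else si) for hi, si in zip(h, state)
        )

    def sweep_async(self, state: tuple[int, ...]) -> tuple[int, ...]:
        s = list(state)
        for i in range(len(s)):
            h = float(self.interactions[i] @ np.array(s))
            if h > 0:
                s[i] = 1
            elif h < 0:
                s[i] = -1
        return tuple(s)


def default_circuit_interactions() -> np.ndarray:
    return np.array(
        [
            [0, 1, -1, -1],
            [1, 0, -1, -1],
            [-1, -1, 0, 1],
            [-1, -1, 1, 0],
        ],
        dtype=float,
    )


def boolean_attractors(circuit: BooleanCircuit) -> list[tuple[tuple[int, ...], ...]]:
    """Exhaustive attractor enumeration over all 2^n states.

    Returns each attractor as a tuple of states (length 1 = fixed point),
    sorted for determinism.  Under asynchronous sweeps every trajectory
    ends in a fixed point; under synchronous updates cycles may appear and
    are reported as such.
    """
    n = len(circuit.nodes)
    step = circuit.sweep_async if circuit.update == "asynchronous" else circuit.step_sync
    attractors: set[tuple[tuple[int, ...], ...]] = set()
    for state in itertools.product((-1, 1), repeat=n):
        seen: dict[tuple[int, ...], int] = {}
        s = state
        while s not in seen:
            seen[s] = len(seen)
            s = step(s)
        cycle = [s]
        t = step(s)
        while t != s:
            cycle.append(t)
            t = step(t)
        start = min(range(len(cycle)), key=lambda i: cycle[i])
        canon = tuple(cycle[start:] + cycle[:start])
        attractors.add(canon)
    return sorted(attractors)
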