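"""Orchestration: run the full scan/classify/switch/knockout/circuit pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import (
    BooleanCircuit,
    boolean_attractors,
    classify_states,
    compare_rt,
    identify_switches,
    knockout_secondary_metabolism,
    rt_vs_secondary_correlation,
    scan_conditions,
)
from .library import (
    ConditionEnsemble,
    build_core_model,
    default_condition_ensemble,
    load_conditions,
    save_conditions,
)
from .network import NetworkModel, load_network, save_network
from .regulation import RegulationConfig, RegulationFailure
from .stability import characterize_steady_state

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    model_path: str | None = None          # None -> built-in core fixture
    condition_path: str | None = None      # None -> default ensemble
    out_dir: str = "results"
    seed: int = 0
    switch_threshold: float = 0.1
    n_knockout_seeds: int = 10
    knockout_condition: str | None = None  # None -> first ensemble condition
    regulation: RegulationConfig = field(default_factory=RegulationConfig)


def _resolve(config: RunConfig) -> tuple[NetworkModel, ConditionEnsemble]:
    model = (
        load_network(config.model_path) if config.model_path else build_core_model()
    )
    if config.condition_path:
        ensemble = load_conditions(config.condition_path)
    else:
        ensemble = default_condition_ensemble(model, base_seed=config.seed)
    if not ensemble.conditions:
        raise ValueError("empty condition ensemble")
    return model, ensemble


def knockout_rt_experiment(
    model: NetworkModel,
    condition,
    config: RegulationConfig,
    seeds: list[int],
):
    """Paired wild-type vs double-knockout runs over a seed list.

    For each seed the wild type is regulated to a stable steady state;
    the secondary pathways are then knocked out in that adapted state and
    the network re-converges from it, so each pair isolates the loss of
    the secondary-metabolite disposal routes.
    """
    ko_model = knockout_secondary_metabolism(model, "both")
    knocked = np.array(
        ["knocked_out" in r.tags for r in ko_model.reactions]
    )
    wt_results, ko_results = [], []
    for seed in seeds:
        cfg = replace(config, seed=seed)
        try:
            wt, _ = characterize_steady_state(model, condition, cfg)
            warm_vf = np.where(knocked, 0.0, wt.vf)
            warm_vb = np.where(knocked, 0.0, wt.vb)
            ko, _ = characterize_steady_state(
                ko_model, condition, cfg,
                warm_start=(warm_vf, warm_vb, wt.x_star),
            )
        except RegulationFailure as exc:
            log.warning("seed %d failed: %s", seed, exc)
            continue
        if wt.converged and ko.converged and wt.stable and ko.stable:
            wt_results.append(wt)
            ko_results.append(ko)
    return wt_results, ko_results


def run_full_pipeline(config: RunConfig) -> dict:
    """Scan -> classify -> switches -> knockout RT comparison -> circuit.

    Writes the landscape table, switch report, RT comparison and a run
    manifest under ``config.out_dir`` and returns a summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, ensemble = _resolve(config)

    landscape = scan_conditions(model, ensemble, config.regulation)
    landscape.fluxes.to_csv(out / "landscape.tsv", sep="\t")
    landscape.normalized().to_csv(out / "landscape_normalized.tsv", sep="\t")
    landscape.meta.to_csv(out / "steady_states.tsv", sep="\t")

    labels, k = classify_states(landscape)
    report = identify_switches(landscape, config.switch_threshold)

    ko_condition_name = config.knockout_condition or ensemble.conditions[0].name
    ko_condition = next(
        c for c in ensemble.conditions if c.name == ko_condition_name
    )
    all_tags = set().union(*(r.tags for r in model.reactions))
    has_secondary = {"secondary_xiamenmycin", "secondary_ptm"} <= all_tags
    if has_secondary:
        seeds = [config.seed + 1000 + i for i in range(config.n_knockout_seeds)]
        wt, ko = knockout_rt_experiment(model, ko_condition, config.regulation, seeds)
    else:
        wt, ko = [], []
    comparison = compare_rt(wt, ko) if wt else None
    rho = rt_vs_secondary_correlation(wt, model) if len(wt) >= 3 else float("nan")

    circuit = BooleanCircuit()
    attractors = boolean_attractors(circuit)
    fixed_points = [a[0] for a in attractors if len(a) == 1]

    switch_doc = {
        "threshold": report.threshold,
        "switching_reactions": report.switching_reactions,
        "central_switching": report.central_switching,
        "sign_reversals": report.sign_reversals,
        "classes": {str(idx): int(lab) for idx, lab in labels.items()},
        "n_classes": int(k),
    }
    (out / "switches.json").write_text(json.dumps(switch_doc, indent=1) + "\n")

    if comparison is not None:
        comparison.differences.rename("rt_diff").to_csv(
            out / "rt_comparison.tsv", sep="\t"
        )
    rt_doc = {
        "wildtype_median_rt": comparison.median_a if comparison else None,
        "knockout_median_rt": comparison.median_b if comparison else None,
        "sign_test_p": comparison.sign_test_p if comparison else None,
        "n_pairs": comparison.n_pairs if comparison else 0,
        "rt_vs_secondary_spearman": rho,
    }
    (out / "rt_comparison.json").write_text(json.dumps(rt_doc, indent=1) + "\n")

    circuit_doc = {
        "nodes": list(circuit.nodes),
        "interactions": circuit.interactions.tolist(),
        "fixed_points": [list(s) for s in fixed_points],
        "n_attractors": len(attractors),
    }
    (out / "circuit.json").write_text(json.dumps(circuit_doc, indent=1) + "\n")

    save_network(model, out / "model.json")
    save_conditions(ensemble, out / "conditions.yaml")
    from . import __version__ as pkg_version

    manifest = {
        "package_version": pkg_version,
        "seed": config.seed,
        "switch_threshold": config.switch_threshold,
        "n_knockout_seeds": config.n_knockout_seeds,
        "knockout_condition": ko_condition_name,
        "regulation": dataclasses.asdict(config.regulation),
        "condition_seeds": list(ensemble.seed_list),
        "failures": landscape.failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")

    return {
        "landscape": landscape,
        "labels": labels,
        "n_classes": k,
        "switches": report,
        "rt_comparison": comparison,
        "rt_vs_secondary_spearman": rho,
        "circuit_fixed_points": fixed_points,
        "n_attractors": len(attractors),
    }
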