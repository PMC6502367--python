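"""Reference networks and condition ensembles.

`build_core_model` reconstructs a core metabolic network for
*Streptomyces xiamenensis* 318: lumped glycolysis, both branches of the
pentose phosphate pathway (with both transketolase reactions and
transaldolase), the full TCA cycle with malate dehydrogenase and malic
enzyme, glutamate metabolism including the GABA shunt, both
glutamate-to-ornithine routes and a urea-cycle segment, plus lumped
biosynthesis of the two secondary metabolites: xiamenmycin (benzopyran
skeleton from PEP, erythrose-4-P, acetyl-CoA, a threonine equivalent and
NADPH) and the polycyclic tetramate macrolactams (PTMs; one ornithine
condensed with two 12-carbon polyketide chains, i.e. twelve acetyl-CoA).
Cofactors (ATP, NADH, NADPH) are carbon-count-zero internal species; only
the reduced/charged partner of each pair is a state variable.

Stoichiometries of the lumped reactions are fixture choices: the topology
follows the organism's annotated central metabolism, while coefficient
detail beyond carbon balance (and the one-ornithine/two-chain PTM skeleton)
is deliberately coarse.  All quantities are in reduced units: Michaelis
constants set the concentration unit, demand biases the flux unit.

`default_condition_ensemble` spans the nutrient-intake and biomass-output
scenarios used for the flux-landscape experiments: maltose vs glucose vs
mixed carbon, amino-acid-rich vs -depleted intakes, heat shock (doubled
acetyl-CoA/NADPH/ATP demand), elevated NADH demand, and nitrogen
starvation (glutamate intake closed, glutamate-derived demand doubled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .network import (
    EXTERNAL_ID,
    Metabolite,
    NetworkModel,
    ReactionKinetics,
    ReactionSpec,
    validate_network,
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Condition:
    """One nutrient-intake / biomass-output scenario.

    ``open_intakes`` lists exchange reactions whose kinetic parameters the
    regulation is free to adjust (nutrient availability and free waste or
    product exports); every other exchange is closed (flux zero) unless a
    bias fixes it.  ``output_biases`` maps metabolites to fixed export
    demands b_n >= 0 drained through their declared export exchange.
    ``probe_biases`` are signed constant virtual fluxes (positive = extra
    sink) used by the switch-metabolite probes.
    """

    name: str
    open_intakes: frozenset[str]
    output_biases: dict[str, float] = field(default_factory=dict)
    probe_biases: dict[str, float] = field(default_factory=dict)
    intake_caps: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def validate(self, model: NetworkModel) -> None:
        from .kinetics import KineticModel, KineticsError

        km = KineticModel(model)
        for rid in self.open_intakes:
            j = model.reaction_index(rid)
            if not model.reactions[j].is_exchange:
                raise ConfigurationError(f"{rid!r} is not an exchange reaction")
        for mid, b in self.output_biases.items():
            if b < 0:
                raise ConfigurationError(f"negative output bias for {mid!r}")
            try:
                km._export_column(mid)
            except KineticsError as exc:
                raise ConfigurationError(str(exc)) from exc
        carbon_intakes = [
            rid
            for rid in self.open_intakes
            if _is_carbon_intake(model, rid)
        ]
        if not carbon_intakes:
            raise ConfigurationError(
                f"condition {self.name!r} keeps no carbon-source intake open"
            )

    def with_probe(self, met_id: str, delta: float) -> "Condition":
        probes = dict(self.probe_biases)
        probes[met_id] = probes.get(met_id, 0.0) + delta
        return Condition(
            name=f"{self.name}+probe_{met_id}_{delta:+g}",
            open_intakes=self.open_intakes,
            output_biases=dict(self.output_biases),
            probe_biases=probes,
            intake_caps=dict(self.intake_caps),
            notes=self.notes,
        )


def _is_carbon_intake(model: NetworkModel, rid: str) -> bool:
    rxn = model.reaction(rid)
    if not rxn.is_exchange:
        return False
    carbons = {m.id: m.carbon_count for m in model.metabolites}
    gained = sum(
        c * carbons.get(sp, 0)
        for sp, c in rxn.net_stoichiometry().items()
        if sp != EXTERNAL_ID
    )
    return gained > 0


@dataclass
class ConditionEnsemble:
    """Ordered set of conditions with one initial-parameter seed each."""

    conditions: list[Condition]
    seed_list: list[int]

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ConfigurationError("condition names must be unique")
        if len(self.seed_list) < len(self.conditions):
            raise ConfigurationError("seed_list shorter than condition list")

    def __iter__(self):
        return iter(zip(self.conditions, self.seed_list))

    def __len__(self) -> int:
        return len(self.conditions)


# -- kinetics helpers ------------------------------------------------------

def _kin(n_sub: int, n_prod: int, reversible: bool, k_eq: float | None = None):
    return ReactionKinetics(
        v_forward=1.0,
        v_backward=0.5 if reversible else 0.0,
        km_substrates=(1.0,) * n_sub,
        km_products=(1.0,) * n_prod,
        k_eq=k_eq if reversible else None,
    )


def _rxn(rid, subs, prods, tags, reversible=False, k_eq=1.0):
    subs = tuple(subs)
    prods = tuple(prods)
    return ReactionSpec(
        id=rid,
        substrates=subs,
        products=prods,
        kinetics=_kin(len(subs), len(prods), reversible, k_eq),
        tags=frozenset(tags),
    )


def _exchange_in(met_id):
    return _rxn(f"EX_{met_id}_in", [(EXTERNAL_ID, 1)], [(met_id, 1)], {"exchange"})


def _exchange_out(met_id, extra_tags=(), km=1.0):
    rxn = _rxn(
        f"EX_{met_id}_out", [(met_id, 1)], [(EXTERNAL_ID, 1)], {"exchange", *extra_tags}
    )
    if km != 1.0:
        return replace(rxn, kinetics=replace(rxn.kinetics, km_substrates=(km,)))
    return rxn


# -- the core fixture ------------------------------------------------------

_CORE_METABOLITES = [
    # id, carbon count, long name
    ("MLT", 12, "maltose"),
    ("GLC", 6, "glucose"),
    ("G6P", 6, "glucose-6-phosphate"),
    ("F6P", 6, "fructose-6-phosphate"),
    ("TP", 3, "triose phosphate"),
    ("PEP", 3, "phosphoenolpyruvate"),
    ("PYR", 3, "pyruvate"),
    ("Ru5P", 5, "ribulose-5-phosphate"),
    ("R5P", 5, "ribose-5-phosphate"),
    ("Xu5P", 5, "xylulose-5-phosphate"),
    ("S7P", 7, "sedoheptulose-7-phosphate"),
    ("E4P", 4, "erythrose-4-phosphate"),
    ("AcCoA", 2, "acetyl-CoA"),
    ("ACE", 2, "acetate"),
    ("CIT", 6, "citrate"),
    ("AKG", 5, "2-oxoglutarate"),
    ("SUCC", 4, "succinate"),
    ("FUM", 4, "fumarate"),
    ("MAL", 4, "malate"),
    ("OAA", 4, "oxaloacetate"),
    ("GLU", 5, "glutamate"),
    ("ASP", 4, "aspartate"),
    ("GSA", 5, "glutamate-5-semialdehyde"),
    ("ORN", 5, "ornithine"),
    ("ARG", 6, "arginine"),
    ("THR", 4, "threonine pool"),
    ("XIA", 16, "xiamenmycin"),
    ("PTM", 29, "polycyclic tetramate macrolactam"),
    ("CO2", 1, "carbon dioxide"),
    ("ATP", 0, "ATP (charged adenylate pool)"),
    ("NADH", 0, "NADH (reduced pool)"),
    ("NADPH", 0, "NADPH (reduced pool)"),
]

# Demand biases set the flux unit of the model: they are chosen so that
# condition-to-condition changes of buffered backbone reactions stay below
# the published 0.1 flux-unit switch threshold while genuine reroutes
# exceed it, and so that demands are commensurate with the small initial
# fluxes of the regulation protocol.
BASELINE_BIASES = {
    "ATP": 0.06,
    "NADH": 0.02,
    "NADPH": 0.02,
    "AcCoA": 0.04,
    "GLU": 0.03,
    "ASP": 0.02,
    "R5P": 0.012,
    "PYR": 0.03,
}

# amino-acid transporter capacities (peak intake rate); sugars are the
# unconstrained bulk carbon source
AA_INTAKE_CAPS = {"EX_GLU_in": 0.2, "EX_ASP_in": 0.12}


FREE_EXPORTS = frozenset(
    {"EX_CO2_out", "EX_XIA_out", "EX_PTM_out", "EX_ARG_out", "EX_THR_out",
     "nadh_oxidase", "atp_maintenance"}
)

SWITCH_ENZYMES = {
    "malic_enzyme": "mae",
    "malate_dehydrogenase": "mdh",
    "aspartate_transaminase": "ast",
    "transketolase": "tkt2",
}

SWITCH_METABOLITES = ("NADH", "NADPH", "AcCoA", "GLU")


def build_core_model() -> NetworkModel:
    """Core central-carbon + secondary-metabolism network of strain 318."""
    mets = [Metabolite(EXTERNAL_ID, "the rest of the cell", 0, True)] + [
        Metabolite(mid, name, c) for mid, c, name in _CORE_METABOLITES
    ]

    rxns = [
        # sugar entry and glycolysis (lumped); uptake is modelled
        # phosphorolysis/PTS-style without net ATP investment so carbon
        # entry is not gated on the energy state
        _rxn("mlt_uptake", [("MLT", 1)], [("G6P", 2)], {"transport"}),
        _rxn("glc_uptake", [("GLC", 1)], [("G6P", 1)], {"transport"}),
        _rxn("pgi", [("G6P", 1)], [("F6P", 1)], {"glycolysis"}, reversible=True),
        _rxn("pfk_ald", [("F6P", 1), ("ATP", 1)], [("TP", 2)], {"glycolysis"}),
        _rxn(
            "gapdh_eno",
            [("TP", 1)],
            [("PEP", 1), ("NADH", 1), ("ATP", 1)],
            {"glycolysis"},
            reversible=True,
        ),
        _rxn("pyk", [("PEP", 1)], [("PYR", 1), ("ATP", 1)], {"glycolysis"}),
        # pentose phosphate pathway
        _rxn(
            "g6pdh_gnd",
            [("G6P", 1)],
            [("Ru5P", 1), ("CO2", 1), ("NADPH", 2)],
            {"ppp"},
        ),
        _rxn("rpi", [("Ru5P", 1)], [("R5P", 1)], {"ppp"}, reversible=True),
        _rxn("rpe", [("Ru5P", 1)], [("Xu5P", 1)], {"ppp"}, reversible=True),
        _rxn(
            "tkt1",
            [("Xu5P", 1), ("R5P", 1)],
            [("S7P", 1), ("TP", 1)],
            {"ppp"},
            reversible=True,
        ),
        _rxn(
            "tal",
            [("S7P", 1), ("TP", 1)],
            [("E4P", 1), ("F6P", 1)],
            {"ppp"},
            reversible=True,
        ),
        _rxn(
            "tkt2",
            [("Xu5P", 1), ("E4P", 1)],
            [("F6P", 1), ("TP", 1)],
            {"ppp"},
            reversible=True,
        ),
        # pyruvate node and TCA cycle
        _rxn("pdh", [("PYR", 1)], [("AcCoA", 1), ("CO2", 1), ("NADH", 1)], {"tca"}),
        _rxn("cs", [("AcCoA", 1), ("OAA", 1)], [("CIT", 1)], {"tca"}),
        _rxn("idh", [("CIT", 1)], [("AKG", 1), ("CO2", 1), ("NADPH", 1)], {"tca"}),
        _rxn(
            "kgdh_sucoas",
            [("AKG", 1)],
            [("SUCC", 1), ("CO2", 1), ("NADH", 1), ("ATP", 1)],
            {"tca"},
        ),
        _rxn("sdh", [("SUCC", 1)], [("FUM", 1), ("NADH", 1)], {"tca"}, reversible=True),
        _rxn("fum", [("FUM", 1)], [("MAL", 1)], {"tca"}, reversible=True),
        _rxn("mdh", [("MAL", 1)], [("OAA", 1), ("NADH", 1)], {"tca"}, reversible=True),
        _rxn("mae", [("MAL", 1)], [("PYR", 1), ("CO2", 1), ("NADPH", 1)], {"tca"}),
        _rxn("ppc", [("PEP", 1), ("CO2", 1)], [("OAA", 1)], {"tca"}),
        # glutamate metabolism and urea-cycle segment
        _rxn(
            "gdh",
            [("AKG", 1), ("NADPH", 1)],
            [("GLU", 1)],
            {"amino_acid"},
            reversible=True,
        ),
        _rxn(
            "ast",
            [("ASP", 1), ("AKG", 1)],
            [("OAA", 1), ("GLU", 1)],
            {"amino_acid"},
            reversible=True,
        ),
        _rxn(
            "gaba_shunt",
            [("GLU", 1)],
            [("SUCC", 1), ("CO2", 1), ("NADH", 1)],
            {"amino_acid"},
        ),
        _rxn(
            "orn_nag",
            [("GLU", 1), ("AcCoA", 1), ("ATP", 1), ("NADPH", 1)],
            [("ORN", 1), ("ACE", 1)],
            {"amino_acid"},
        ),
        _rxn("acs", [("ACE", 1), ("ATP", 1)], [("AcCoA", 1)], {"other"}),
        _rxn(
            "orn_gsa",
            [("GLU", 1), ("ATP", 1), ("NADPH", 1)],
            [("GSA", 1)],
            {"amino_acid"},
        ),
        _rxn(
            "orn_ota",
            [("GSA", 1), ("GLU", 1)],
            [("ORN", 1), ("AKG", 1)],
            {"amino_acid"},
        ),
        _rxn(
            "urea_seg",
            [("ORN", 1), ("CO2", 1), ("ASP", 1), ("ATP", 2)],
            [("ARG", 1), ("FUM", 1)],
            {"amino_acid"},
        ),
        _rxn(
            "thr_synth",
            [("ASP", 1), ("ATP", 1), ("NADPH", 2)],
            [("THR", 1)],
            {"amino_acid"},
            reversible=True,
            k_eq=50.0,
        ),
        # secondary metabolism (lumped biosynthesis)
        # lumped secondary-metabolite synthases are high-affinity, slow
        # machines: sub-unit Michaelis constants keep them responsive at
        # ordinary precursor levels despite their high molecularity
        replace(
            _rxn(
                "xia_synth",
                [("PEP", 2), ("E4P", 1), ("AcCoA", 2), ("THR", 1), ("NADPH", 4)],
                [("XIA", 1), ("CO2", 2)],
                {"secondary_xiamenmycin"},
            ),
            kinetics=replace(_kin(5, 2, False), km_substrates=(0.3,) * 5),
        ),
        replace(
            _rxn(
                "ptm_synth",
                [("ORN", 1), ("AcCoA", 12), ("NADPH", 10)],
                [("PTM", 1)],
                {"secondary_ptm"},
            ),
            kinetics=replace(_kin(3, 1, False), km_substrates=(0.5, 0.2, 0.2)),
        ),
        # respiration and energy dissipation: oxidative phosphorylation,
        # a transhydrogenase, an uncoupled NADH oxidase and ATP
        # maintenance hydrolysis -- without dissipation routes the energy
        # byproducts of carbon flux would have no sink and almost no
        # demand pattern would admit a steady state
        _rxn("oxphos", [("NADH", 1)], [("ATP", 2)], {"other"}),
        _rxn("pnt", [("NADPH", 1)], [("NADH", 1)], {"other"}, reversible=True),
        replace(
            _rxn("nadh_oxidase", [("NADH", 1)], [(EXTERNAL_ID, 1)],
                 {"exchange", "other"}),
            kinetics=replace(_kin(1, 1, False), km_substrates=(10.0,)),
        ),
        replace(
            _rxn("atp_maintenance", [("ATP", 1)], [(EXTERNAL_ID, 1)],
                 {"exchange", "other"}),
            kinetics=replace(_kin(1, 1, False), km_substrates=(10.0,)),
        ),
        # exchanges: nutrient intakes
        _exchange_in("MLT"),
        _exchange_in("GLC"),
        _exchange_in("GLU"),
        _exchange_in("ASP"),
        # exchanges: biomass/demand exports
        _exchange_out("ATP"),
        _exchange_out("NADH"),
        _exchange_out("NADPH"),
        _exchange_out("AcCoA"),
        _exchange_out("GLU"),
        _exchange_out("ASP"),
        _exchange_out("R5P"),
        _exchange_out("PYR"),
        # exchanges: free exports (waste and products), kept in the
        # linear regime by a high Michaelis constant
        _exchange_out("CO2", km=10.0),
        _exchange_out("ARG", km=10.0),
        _exchange_out("THR", km=10.0),
        _exchange_out("XIA", {"secondary_xiamenmycin"}, km=10.0),
        _exchange_out("PTM", {"secondary_ptm"}, km=10.0),
    ]
    model = NetworkModel(mets, rxns, name="sxiamenensis_core")
    report = validate_network(model)
    if not report.ok:  # pragma: no cover - fixture is static
        raise ConfigurationError("core fixture invalid: " + "; ".join(report.entries()))
    return model


def default_condition_ensemble(
    model: NetworkModel, base_seed: int = 0, stress_factor: float = 2.0
) -> ConditionEnsemble:
    """The twelve nutrient/output scenarios scanned by the experiments."""

    def cond(name, intakes, scale=(), notes=""):
        biases = dict(BASELINE_BIASES)
        for mid in scale:
            biases[mid] = biases[mid] * stress_factor
        return Condition(
            name=name,
            open_intakes=frozenset(intakes) | FREE_EXPORTS,
            output_biases=biases,
            intake_caps={k: v for k, v in AA_INTAKE_CAPS.items() if k in intakes},
            notes=notes,
        )

    mlt, glc = "EX_MLT_in", "EX_GLC_in"
    glu, asp = "EX_GLU_in", "EX_ASP_in"
    conditions = [
        cond("maltose_baseline", {mlt}),
        cond("glucose_baseline", {glc}),
        cond("mixed_carbon_baseline", {mlt, glc}),
        cond("aa_rich_maltose", {mlt, glu, asp}),
        cond("aa_rich_glucose", {glc, glu, asp}),
        cond("aa_rich_mixed", {mlt, glc, glu, asp}),
        cond(
            "heat_shock_maltose",
            {mlt},
            scale=("AcCoA", "NADPH", "ATP"),
            notes="lipid-turnover stress: doubled AcCoA/NADPH/ATP demand",
        ),
        cond("heat_shock_glucose", {glc}, scale=("AcCoA", "NADPH", "ATP")),
        cond("heat_shock_aa_rich", {glc, glu, asp}, scale=("AcCoA", "NADPH", "ATP")),
        cond("nadh_demand_maltose", {mlt}, scale=("NADH",)),
        cond("nadh_demand_aa_rich", {mlt, glu, asp}, scale=("NADH",)),
        cond(
            "nitrogen_starvation",
            {mlt, glc},
            scale=("GLU",),
            notes="amino-acid intakes closed, glutamate-derived demand doubled",
        ),
    ]
    for c in conditions:
        c.validate(model)
    # one shared initial-parameter seed: conditions then differ only in
    # their boundary set-up, isolating condition response from draw noise
    ensemble = ConditionEnsemble(conditions, [base_seed] * len(conditions))
    return ensemble


# -- analytic toy fixtures -------------------------------------------------

def build_toy_chain(length: int, intake_flux: float = 0.05) -> NetworkModel:
    """Linear pathway External -> X1 -> ... -> Xn -> External.

    Irreversible Michaelis-Menten steps with unit constants; the unique
    steady state and the linearized Jacobian have closed forms, which makes
    the chain the oracle fixture for the regulation and stability tests.
    """
    if length < 1:
        raise ValueError("chain length must be >= 1")
    mets = [Metabolite(EXTERNAL_ID, "external", 0, True)] + [
        Metabolite(f"X{i}", f"species {i}", 1) for i in range(1, length + 1)
    ]
    rxns = [_exchange_in("X1")]
    for i in range(1, length):
        rxns.append(_rxn(f"step{i}", [(f"X{i}", 1)], [(f"X{i+1}", 1)], {"other"}))
    rxns.append(_exchange_out(f"X{length}"))
    # scale the default rates so the initial flux is near intake_flux
    rxns = [
        replace(
            r,
            kinetics=ReactionKinetics(
                v_forward=2.0 * intake_flux,
                v_backward=0.0,
                km_substrates=r.kinetics.km_substrates,
                km_products=r.kinetics.km_products,
            ),
        )
        for r in rxns
    ]
    return NetworkModel(mets, rxns, name=f"toy_chain_{length}")


def toy_chain_condition(model: NetworkModel, demand: float) -> Condition:
    """Open the chain intake and fix the terminal export at ``demand``."""
    last = model.internal_metabolites[-1].id
    return Condition(
        name=f"chain_demand_{demand:g}",
        open_intakes=frozenset({"EX_X1_in"}),
        output_biases={last: demand},
    )


def build_random_network(
    n_metabolites: int, n_reactions: int, seed: int
) -> NetworkModel:
    """Connected, carbon-balanced random single-carbon network (seeded).

    A chain backbone guarantees connectivity; extra 1:1 conversions are
    drawn at random.  One intake feeds the first species and one export
    drains the last.  Same seed, same model.
    """
    if n_metabolites < 1:
        raise ValueError("need at least one metabolite")
    if n_reactions < n_metabolites - 1:
        raise ValueError("too few reactions to connect the network")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(EXTERNAL_ID, "external", 0, True)] + [
        Metabolite(f"M{i}", f"species {i}", 1) for i in range(1, n_metabolites + 1)
    ]
    rxns: list[ReactionSpec] = []
    pairs: set[tuple[int, int]] = set()
    for i in range(1, n_metabolites):
        pairs.add((i, i + 1))
    while len(pairs) < n_reactions:
        a, b = rng.integers(1, n_metabolites + 1, size=2)
        if a != b:
            pairs.add((int(a), int(b)))
    for idx, (a, b) in enumerate(sorted(pairs)):
        reversible = bool(rng.random() < 0.4)
        vf = float(rng.uniform(0.5, 2.0))
        vb = float(rng.uniform(0.2, 1.0)) if reversible else 0.0
        rxns.append(
            ReactionSpec(
                id=f"r{idx}",
                substrates=((f"M{a}", 1),),
                products=((f"M{b}", 1),),
                kinetics=ReactionKinetics(
                    v_forward=vf,
                    v_backward=vb,
                    km_substrates=(float(rng.uniform(0.5, 2.0)),),
                    km_products=(float(rng.uniform(0.5, 2.0)),),
                    k_eq=1.0 if reversible else None,
                ),
                tags=frozenset({"other"}),
            )
        )
    rxns.insert(0, _exchange_in("M1"))
    rxns.append(_exchange_out(f"M{n_metabolites}"))
    return NetworkModel(mets, rxns, name=f"random_{n_metabolites}_{n_reactions}_{seed}")


# -- condition file IO -----------------------------------------------------

def save_conditions(ensemble: ConditionEnsemble, path) -> None:
    doc = {
        "seed_list": list(ensemble.seed_list),
        "conditions": [
            {
                "name": c.name,
                "open_intakes": sorted(c.open_intakes),
                "output_biases": dict(c.output_biases),
                "intake_caps": dict(c.intake_caps),
                "notes": c.notes,
            }
            for c in ensemble.conditions
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def load_conditions(path) -> ConditionEnsemble:
    with open(path, "r", encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            doc = json.load(fh)
        else:
            doc = yaml.safe_load(fh)
    conditions = [
        Condition(
            name=c["name"],
            open_intakes=frozenset(c["open_intakes"]),
            output_biases={k: float(v) for k, v in c.get("output_biases", {}).items()},
            intake_caps={k: float(v) for k, v in c.get("intake_caps", {}).items()},
            notes=c.get("notes", ""),
        )
        for c in doc["conditions"]
    ]
    return ConditionEnsemble(conditions, [int(s) for s in doc["seed_list"]])
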