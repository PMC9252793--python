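"""Parameterized generators for models and archives.

Everything test-shaped in this package flows through here: curated textbook
models (exponential decay, isomerization, production/decay, a two-node
toggle), random mass-action reaction networks, random Boolean networks, and
the wrapping of any of them into a complete COMBINE archive (model file +
SED-ML document + manifest).  All generators are deterministic for a fixed
seed.

The module also hosts the catalogue of *seeded defects*: twelve mutation
classes, each of which corrupts a pristine archive in exactly one way and
states the validation code the corruption must trigger.  The validator's
kill-rate test and the acceptance checks both draw from this catalogue.
"""

from __future__ import annotations

import io
import math
import zipfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._errors import SimexError
from . import omex, sedml
from .expressions import BoolExpression, MathExpression
from .model_io import (
    AttributeChange,
    BooleanNetworkModel,
    BooleanNode,
    Parameter,
    Reaction,
    ReactionNetworkModel,
    Species,
    write_boolnet,
    write_sbml,
)

SBML_LANGUAGE = "urn:sedml:language:sbml"
BOOLNET_LANGUAGE = "urn:sedml:language:boolnet"


# ---------------------------------------------------------------------------
# Curated models


def decay_model(k: float = 0.5, s1_0: float = 10.0) -> ReactionNetworkModel:
    """S1 -> S2 with rate k*S1: the closed-form exponential-decay fixture."""
    return ReactionNetworkModel(
        species=[Species("S1", s1_0), Species("S2", 0.0)],
        parameters=[Parameter("k", k)],
        reactions=[
            Reaction(
                "J1",
                (("S1", 1),),
                (("S2", 1),),
                MathExpression.parse("k * S1"),
            )
        ],
    )


def isomerization_model(x0: float = 20.0) -> ReactionNetworkModel:
    """X <-> Y with both rates 1 (two-state Markov chain per molecule)."""
    return ReactionNetworkModel(
        species=[Species("X", x0), Species("Y", 0.0)],
        parameters=[Parameter("kf", 1.0), Parameter("kr", 1.0)],
        reactions=[
            Reaction("Jf", (("X", 1),), (("Y", 1),), MathExpression.parse("kf * X")),
            Reaction("Jr", (("Y", 1),), (("X", 1),), MathExpression.parse("kr * Y")),
        ],
    )


def immigration_death_model(birth: float = 10.0, death: float = 1.0, x0: float = 0.0) -> ReactionNetworkModel:
    """0 -> X at rate `birth`; X -> 0 at rate `death`*X (Poisson stationary law)."""
    return ReactionNetworkModel(
        species=[Species("X", x0)],
        parameters=[Parameter("lam", birth), Parameter("mu", death)],
        reactions=[
            Reaction("Jb", (), (("X", 1),), MathExpression.parse("lam")),
            Reaction("Jd", (("X", 1),), (), MathExpression.parse("mu * X")),
        ],
    )


def production_decay_model(production: float = 2.0, decay: float = 0.5, s1_0: float = 0.0) -> ReactionNetworkModel:
    """0 -> S1 at constant rate; S1 -> 0 at decay*S1; steady state production/decay."""
    return ReactionNetworkModel(
        species=[Species("S1", s1_0)],
        parameters=[Parameter("kp", production), Parameter("kd", decay)],
        reactions=[
            Reaction("Jp", (), (("S1", 1),), MathExpression.parse("kp")),
            Reaction("Jd", (("S1", 1),), (), MathExpression.parse("kd * S1")),
        ],
    )


def toggle_boolean_model() -> BooleanNetworkModel:
    """A := !B, B := A from (1, 1): a period-4 synchronous cycle."""
    return BooleanNetworkModel(
        nodes=[
            BooleanNode("A", 1, BoolExpression.parse("!B")),
            BooleanNode("B", 1, BoolExpression.parse("A")),
        ]
    )


# ---------------------------------------------------------------------------
# Random generators


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_species_range: Tuple[int, int] = (2, 8)
    n_reactions_range: Tuple[int, int] = (2, 12)
    rate_bounds: Tuple[float, float] = (0.01, 10.0)
    initial_amount_range: Tuple[int, int] = (5, 30)
    n_nodes_range: Tuple[int, int] = (2, 10)

    def check(self) -> None:
        for lo, hi in (self.n_species_range, self.n_reactions_range, self.n_nodes_range):
            if lo < 1 or hi < lo:
                raise SimexError("BAD_CONFIG", "ranges must be non-empty and positive")
        lo, hi = self.rate_bounds
        if lo <= 0 or hi < lo:
            raise SimexError("BAD_CONFIG", "rate bounds must be positive")


def random_mass_action_network(config: GeneratorConfig) -> ReactionNetworkModel:
    """A connected random mass-action network, deterministic for a fixed seed.

    Connectivity comes from a conversion chain S1 -> S2 -> ... -> Sn; extra
    reactions draw up to two reactants and products uniformly.  Rate
    constants are log-uniform within ``config.rate_bounds``.
    """
    config.check()
    rng = np.random.default_rng(config.seed)
    n = int(rng.integers(config.n_species_range[0], config.n_species_range[1] + 1))
    m_lo, m_hi = config.n_reactions_range
    m = int(rng.integers(m_lo, m_hi + 1))
    m = min(max(m, max(1, n - 1)), max(m_hi, n - 1))
    lo, hi = config.rate_bounds
    amounts = rng.integers(
        config.initial_amount_range[0], config.initial_amount_range[1] + 1, size=n
    )
    model = ReactionNetworkModel(
        species=[Species(f"S{i + 1}", float(amounts[i])) for i in range(n)]
    )

    def add_reaction(idx: int, reactants: Sequence[str], products: Sequence[str]) -> None:
        k_id = f"k{idx}"
        k_value = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        model.parameters.append(Parameter(k_id, k_value))
        rate = MathExpression.sym(k_id)
        for sid in reactants:
            rate = MathExpression.call("times", rate, MathExpression.sym(sid))
        counted: Dict[str, int] = {}
        for sid in reactants:
            counted[sid] = counted.get(sid, 0) + 1
        prod_counted: Dict[str, int] = {}
        for sid in products:
            prod_counted[sid] = prod_counted.get(sid, 0) + 1
        model.reactions.append(
            Reaction(
                f"J{idx}",
                tuple(sorted(counted.items())),
                tuple(sorted(prod_counted.items())),
                rate,
            )
        )

    idx = 1
    if n == 1:
        add_reaction(idx, ["S1"], [])
        idx += 1
    else:
        for i in range(n - 1):
            add_reaction(idx, [f"S{i + 1}"], [f"S{i + 2}"])
            idx += 1
    while idx <= m:
        n_reactants = int(rng.integers(1, 3))
        n_products = int(rng.integers(0, 3))
        reactants = [f"S{int(rng.integers(1, n + 1))}" for _ in range(n_reactants)]
        products = [f"S{int(rng.integers(1, n + 1))}" for _ in range(n_products)]
        add_reaction(idx, reactants, products)
        idx += 1
    model.check()
    return model


def random_boolean_network(config: GeneratorConfig) -> BooleanNetworkModel:
    """Random Boolean network with 2-input update rules and random initial state."""
    config.check()
    rng = np.random.default_rng(config.seed)
    n = int(rng.integers(config.n_nodes_range[0], config.n_nodes_range[1] + 1))
    names = [f"N{i + 1}" for i in range(n)]
    nodes: List[BooleanNode] = []
    for name in names:
        a, b = (names[int(rng.integers(0, n))] for _ in range(2))
        ea = BoolExpression.sym(a)
        eb = BoolExpression.sym(b)
        if rng.random() < 0.3:
            ea = BoolExpression(("not", ea))
        if rng.random() < 0.3:
            eb = BoolExpression(("not", eb))
        if rng.random() < 0.15:
            update = ea
        else:
            op = "and" if rng.random() < 0.5 else "or"
            update = BoolExpression((op, ea, eb))
        nodes.append(BooleanNode(name, int(rng.integers(0, 2)), update))
    model = BooleanNetworkModel(nodes=nodes)
    model.check()
    return model


# ---------------------------------------------------------------------------
# Archive assembly


@dataclass
class SimulationRequest:
    kisao_id: str = "KISAO:0000032"
    kind: str = "time_course"  # "time_course" | "steady_state"
    initial_time: float = 0.0
    output_start_time: float = 0.0
    output_end_time: float = 10.0
    number_of_points: int = 10
    parameters: List[Tuple[str, str]] = field(default_factory=list)


@dataclass
class ArchiveOptions:
    with_changes: bool = False
    change_new_value: str = "20"
    with_plot: bool = False


MODEL_LOCATION = "model.xml"
BOOLNET_LOCATION = "model.bnet"
SEDML_LOCATION = "sim.sedml"


def species_target(species_id: str) -> str:
    return f"/sbml/model/listOfSpecies/species[@id='{species_id}']"


def build_archive(
    model: Union[ReactionNetworkModel, BooleanNetworkModel],
    request: Optional[SimulationRequest] = None,
    options: Optional[ArchiveOptions] = None,
) -> omex.CombineArchive:
    """Wrap a model into a full archive: model file, SED-ML document, manifest.

    The SED-ML document carries one simulation, one task, identity data
    generators for time (time courses only) and every observable, one report,
    and optionally one 2-D plot and one attribute change.
    """
    request = request or SimulationRequest()
    options = options or ArchiveOptions()
    is_boolean = isinstance(model, BooleanNetworkModel)
    if is_boolean:
        model_bytes = write_boolnet(model)
        location, language, fmt = BOOLNET_LOCATION, BOOLNET_LANGUAGE, omex.FORMAT_BOOLNET
        observables = model.node_ids()
    else:
        model_bytes = write_sbml(model)
        location, language, fmt = MODEL_LOCATION, SBML_LANGUAGE, omex.FORMAT_SBML
        observables = model.species_ids()

    doc = sedml.SedDocument()
    sed_model = sedml.SedModel("model1", location, language)
    if options.with_changes:
        if is_boolean:
            raise SimexError("BAD_CONFIG", "attribute changes apply to XML models only")
        sed_model.changes.append(
            AttributeChange(species_target(observables[0]) + "/@initialAmount", options.change_new_value)
        )
    doc.models.append(sed_model)

    algorithm = sedml.AlgorithmSpec(
        sedml.normalize_kisao_id(request.kisao_id),
        [sedml.AlgorithmParameter(sedml.normalize_kisao_id(k), v) for k, v in request.parameters],
    )
    if request.kind == "steady_state":
        doc.simulations.append(sedml.SedSteadyState("sim1", algorithm))
    else:
        doc.simulations.append(
            sedml.SedUniformTimeCourse(
                "sim1",
                request.initial_time,
                request.output_start_time,
                request.output_end_time,
                request.number_of_points,
                algorithm,
            )
        )
    doc.tasks.append(sedml.SedTask("task1", "model1", "sim1"))

    data_sets: List[sedml.SedDataSet] = []
    if request.kind != "steady_state":
        doc.data_generators.append(
            sedml.SedDataGenerator(
                "dg_time",
                [sedml.SedVariable("var_time", "task1", symbol=sedml.TIME_SYMBOL)],
                MathExpression.sym("var_time"),
            )
        )
        data_sets.append(sedml.SedDataSet("ds_time", "time", "dg_time"))
    for obs in observables:
        target = obs if is_boolean else species_target(obs)
        doc.data_generators.append(
            sedml.SedDataGenerator(
                f"dg_{obs}",
                [sedml.SedVariable(f"var_{obs}", "task1", target=target)],
                MathExpression.sym(f"var_{obs}"),
            )
        )
        data_sets.append(sedml.SedDataSet(f"ds_{obs}", obs, f"dg_{obs}"))
    doc.outputs.append(sedml.SedReport("report1", data_sets))
    if options.with_plot and request.kind != "steady_state":
        doc.outputs.append(
            sedml.SedPlot2D(
                "plot1", [sedml.SedCurve("curve1", "dg_time", f"dg_{observables[0]}")]
            )
        )

    archive = omex.CombineArchive(
        entries=[
            omex.ContentEntry(".", omex.FORMAT_OMEX),
            omex.ContentEntry(location, fmt),
            omex.ContentEntry(SEDML_LOCATION, omex.FORMAT_SEDML, is_master=True),
        ],
        payload={location: model_bytes, SEDML_LOCATION: sedml.write_sedml(doc)},
    )
    archive.check()
    return archive


# ---------------------------------------------------------------------------
# Seeded defect catalogue

DEFECT_CLASSES = (
    "manifest_missing",
    "entry_file_missing",
    "duplicate_id",
    "dangling_ref",
    "model_source_unresolved",
    "variable_target_unresolved",
    "change_target_unresolved",
    "time_order_invalid",
    "algorithm_id_invalid",
    "model_syntax_error",
    "schema_invalid",
    "target_ambiguous",
)

#: defect class -> validation code the validator must emit
DEFECT_EXPECTED_CODES = {
    "manifest_missing": "OMEX_MANIFEST_MISSING",
    "entry_file_missing": "OMEX_ENTRY_FILE_MISSING",
    "duplicate_id": "SEDML_DUPLICATE_ID",
    "dangling_ref": "SEDML_DANGLING_REF",
    "model_source_unresolved": "SEDML_MODEL_SOURCE_UNRESOLVED",
    "variable_target_unresolved": "SEDML_TARGET_UNRESOLVED",
    "change_target_unresolved": "SEDML_TARGET_UNRESOLVED",
    "time_order_invalid": "SEDML_TIME_ORDER_INVALID",
    "algorithm_id_invalid": "SEDML_ALGORITHM_ID_INVALID",
    "model_syntax_error": "MODEL_SYNTAX_ERROR",
    "schema_invalid": "SEDML_SCHEMA_INVALID",
    "target_ambiguous": "SEDML_TARGET_AMBIGUOUS",
}


def defect_base_archive(seed: int) -> omex.CombineArchive:
    """A pristine randomized archive with every anchor the mutators rely on."""
    config = GeneratorConfig(seed=seed, n_species_range=(2, 6), n_reactions_range=(2, 8))
    model = random_mass_action_network(config)
    return build_archive(
        model,
        SimulationRequest(kisao_id="KISAO:0000032", number_of_points=10),
        ArchiveOptions(with_changes=True),
    )


def _replace_once(data: bytes, old: bytes, new: bytes) -> bytes:
    if old not in data:
        raise SimexError("UNKNOWN_MUTATION", f"anchor {old!r} not found")
    return data.replace(old, new, 1)


def inject_defect(archive: omex.CombineArchive, defect: str) -> Tuple[bytes, str]:
    """Corrupt a pristine archive with one defect class.

    Returns the mutated archive as zip bytes plus the validation code the
    defect must trigger.  Mutations are textual so exactly one aspect of the
    project changes.
    """
    if defect not in DEFECT_CLASSES:
        raise SimexError("UNKNOWN_MUTATION", f"unknown defect class {defect!r}")
    expected = DEFECT_EXPECTED_CODES[defect]
    payload = dict(archive.payload)
    entries = list(archive.entries)
    sed = payload[SEDML_LOCATION]

    if defect == "manifest_missing":
        buffer = io.BytesIO()
        with zipfile.ZipFile(buffer, "w") as zf:
            for location in sorted(payload):
                zf.writestr(zipfile.ZipInfo(location, date_time=(1980, 1, 1, 0, 0, 0)), payload[location])
        return buffer.getvalue(), expected
    if defect == "entry_file_missing":
        del payload[MODEL_LOCATION]
        mutated = omex.CombineArchive(entries=entries, payload=payload)
        return omex.archive_to_bytes(mutated, _check=False), expected
    if defect == "duplicate_id":
        sed = _replace_once(sed, b'id="sim1"', b'id="model1"')
    elif defect == "dangling_ref":
        sed = _replace_once(sed, b'simulationReference="sim1"', b'simulationReference="sim9"')
    elif defect == "model_source_unresolved":
        sed = _replace_once(sed, b'source="model.xml"', b'source="missing.xml"')
    elif defect == "variable_target_unresolved":
        sed = _replace_once(sed, b"species[@id='S1']\"", b"species[@id='S9']\"")
    elif defect == "change_target_unresolved":
        sed = _replace_once(
            sed, b"species[@id='S1']/@initialAmount", b"species[@id='S9']/@initialAmount"
        )
    elif defect == "time_order_invalid":
        sed = _replace_once(sed, b'initialTime="0.0"', b'initialTime="5.0"')
    elif defect == "algorithm_id_invalid":
        sed = _replace_once(sed, b'kisaoID="KISAO:0000032"', b'kisaoID="KISAO:32"')
    elif defect == "model_syntax_error":
        payload[MODEL_LOCATION] = payload[MODEL_LOCATION][:-25]
    elif defect == "schema_invalid":
        sed = _replace_once(sed, b' numberOfPoints="10"', b"")
    elif defect == "target_ambiguous":
        sed = _replace_once(sed, b"species[@id='S1']\"", b'species"')
    payload[SEDML_LOCATION] = sed
    mutated = omex.CombineArchive(entries=entries, payload=payload)
    return omex.archive_to_bytes(mutated), expected
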