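"""Core SED-ML subset: data model, parser, writer, data-generator evaluation.

The subset is the executable heart of SED-ML Level 1 Version 3: models with
attribute changes, uniform time courses and steady states with KiSAO-typed
algorithms, tasks, data generators over task variables, and report /
2-D-plot outputs.  ``repeatedTask``, functional ranges and 3-D plots are
deliberately out of scope.

Conventions worth stating because they are classic interop traps:

* ``numberOfPoints`` counts *intervals*; a simulation records
  ``numberOfPoints + 1`` rows spanning the output window uniformly.
* the only recognized symbol is ``urn:sedml:symbol:time``.
* KiSAO ids are accepted in both ``KISAO:0000032`` and ``KISAO_0000032``
  spellings and normalized to the colon form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from lxml import etree

from ._errors import SimexError
from .expressions import MathExpression, iter_local
from .model_io import AttributeChange

SEDML_NS = "http://sed-ml.org/sed-ml/level1/version3"
TIME_SYMBOL = "urn:sedml:symbol:time"

KISAO_ID_RE = re.compile(r"^KISAO[:_]\d{7}$")


def normalize_kisao_id(raw: str) -> str:
    """Normalize ``KISAO_0000032`` to ``KISAO:0000032``; other strings pass through."""
    if KISAO_ID_RE.match(raw or ""):
        return "KISAO:" + raw[6:]
    return raw


def is_valid_kisao_id(raw: str) -> bool:
    return bool(KISAO_ID_RE.match(raw or ""))


# ---------------------------------------------------------------------------
# Document model


@dataclass
class SedModel:
    id: str
    source: str
    language: str
    changes: List[AttributeChange] = field(default_factory=list)


@dataclass(frozen=True)
class AlgorithmParameter:
    kisao_id: str
    value: str


@dataclass
class AlgorithmSpec:
    kisao_id: str
    parameters: List[AlgorithmParameter] = field(default_factory=list)


@dataclass
class SedUniformTimeCourse:
    id: str
    initial_time: float
    output_start_time: float
    output_end_time: float
    number_of_points: int
    algorithm: AlgorithmSpec


@dataclass
class SedSteadyState:
    id: str
    algorithm: AlgorithmSpec


Simulation = Union[SedUniformTimeCourse, SedSteadyState]


@dataclass
class SedTask:
    id: str
    model_ref: str
    simulation_ref: str


@dataclass
class SedVariable:
    id: str
    task_ref: str
    target: Optional[str] = None
    symbol: Optional[str] = None


@dataclass
class SedDataGenerator:
    id: str
    variables: List[SedVariable]
    math: MathExpression


@dataclass
class SedDataSet:
    id: str
    label: str
    data_generator_ref: str


@dataclass
class SedReport:
    id: str
    data_sets: List[SedDataSet]


@dataclass
class SedCurve:
    id: str
    x_generator_ref: str
    y_generator_ref: str


@dataclass
class SedPlot2D:
    id: str
    curves: List[SedCurve]


Output = Union[SedReport, SedPlot2D]


@dataclass
class SedDocument:
    models: List[SedModel] = field(default_factory=list)
    simulations: List[Simulation] = field(default_factory=list)
    tasks: List[SedTask] = field(default_factory=list)
    data_generators: List[SedDataGenerator] = field(default_factory=list)
    outputs: List[Output] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    # lookup helpers ---------------------------------------------------
    def model(self, model_id: str) -> SedModel:
        return _lookup(self.models, model_id, "model")

    def simulation(self, sim_id: str) -> Simulation:
        return _lookup(self.simulations, sim_id, "simulation")

    def data_generator(self, gen_id: str) -> SedDataGenerator:
        return _lookup(self.data_generators, gen_id, "data generator")

    def task(self, task_id: str) -> SedTask:
        return _lookup(self.tasks, task_id, "task")

    def all_ids(self) -> List[str]:
        ids: List[str] = []
        for group in (self.models, self.simulations, self.tasks, self.data_generators, self.outputs):
            ids.extend(item.id for item in group)
        for gen in self.data_generators:
            ids.extend(v.id for v in gen.variables)
        for out in self.outputs:
            if isinstance(out, SedReport):
                ids.extend(d.id for d in out.data_sets)
            else:
                ids.extend(c.id for c in out.curves)
        return ids

    def check(self) -> None:
        ids = self.all_ids()
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise SimexError("DUPLICATE_ID", f"duplicate ids {dupes}")
        model_ids = {m.id for m in self.models}
        sim_ids = {s.id for s in self.simulations}
        task_ids = {t.id for t in self.tasks}
        gen_ids = {g.id for g in self.data_generators}
        for model in self.models:
            if not model.source:
                raise SimexError("SEDML_SCHEMA_INVALID", f"model {model.id} has empty source")
        for task in self.tasks:
            if task.model_ref not in model_ids:
                raise SimexError("DANGLING_REF", f"task {task.id} references model {task.model_ref!r}")
            if task.simulation_ref not in sim_ids:
                raise SimexError(
                    "DANGLING_REF", f"task {task.id} references simulation {task.simulation_ref!r}"
                )
        for gen in self.data_generators:
            var_ids = set()
            for var in gen.variables:
                var_ids.add(var.id)
                if var.task_ref not in task_ids:
                    raise SimexError(
                        "DANGLING_REF", f"variable {var.id} references task {var.task_ref!r}"
                    )
                if (var.target is None) == (var.symbol is None):
                    raise SimexError(
                        "SEDML_SCHEMA_INVALID",
                        f"variable {var.id} must set exactly one of target/symbol",
                    )
            unknown = gen.math.identifiers() - var_ids
            if unknown:
                raise SimexError(
                    "DANGLING_REF", f"generator {gen.id} math references {sorted(unknown)}"
                )
        for out in self.outputs:
            if isinstance(out, SedReport):
                for ds in out.data_sets:
                    if ds.data_generator_ref not in gen_ids:
                        raise SimexError(
                            "DANGLING_REF",
                            f"data set {ds.id} references generator {ds.data_generator_ref!r}",
                        )
            else:
                for curve in out.curves:
                    for ref in (curve.x_generator_ref, curve.y_generator_ref):
                        if ref not in gen_ids:
                            raise SimexError(
                                "DANGLING_REF", f"curve {curve.id} references generator {ref!r}"
                            )


def _lookup(items, item_id, kind):
    for item in items:
        if item.id == item_id:
            return item
    raise SimexError("DANGLING_REF", f"unknown {kind} {item_id!r}")


# ---------------------------------------------------------------------------
# Parser


def _require(element, attr: str) -> str:
    value = element.get(attr)
    if value is None:
        raise SimexError(
            "SEDML_SCHEMA_INVALID",
            f"<{etree.QName(element).localname}> lacks required attribute {attr!r}",
        )
    return value


def _require_float(element, attr: str) -> float:
    raw = _require(element, attr)
    try:
        return float(raw)
    except ValueError:
        raise SimexError("SEDML_SCHEMA_INVALID", f"attribute {attr}={raw!r} is not a number")


def _parse_algorithm(sim_el) -> AlgorithmSpec:
    algorithms = list(iter_local(sim_el, "algorithm"))
    if len(algorithms) != 1:
        raise SimexError("SEDML_SCHEMA_INVALID", "simulation needs exactly one algorithm")
    alg_el = algorithms[0]
    spec = AlgorithmSpec(normalize_kisao_id(_require(alg_el, "kisaoID")))
    for lst in iter_local(alg_el, "listOfAlgorithmParameters"):
        for par in iter_local(lst, "algorithmParameter"):
            spec.parameters.append(
                AlgorithmParameter(normalize_kisao_id(_require(par, "kisaoID")), _require(par, "value"))
            )
    return spec


def _parse_math_child(element) -> MathExpression:
    maths = list(iter_local(element, "math"))
    if len(maths) != 1:
        raise SimexError("SEDML_SCHEMA_INVALID", "element needs exactly one math child")
    try:
        return MathExpression.from_mathml(maths[0])
    except SimexError as exc:
        raise SimexError("SEDML_SCHEMA_INVALID", f"bad math: {exc.message}")


_KNOWN_LISTS = {
    "listOfModels",
    "listOfSimulations",
    "listOfTasks",
    "listOfDataGenerators",
    "listOfOutputs",
}


def parse_sedml(content: bytes) -> SedDocument:
    """Parse a SED-ML document from bytes into :class:`SedDocument`."""
    try:
        root = etree.fromstring(content)
    except etree.XMLSyntaxError as exc:
        raise SimexError("SEDML_SCHEMA_INVALID", f"not valid XML: {exc}")
    if etree.QName(root).localname != "sedML":
        raise SimexError("SEDML_SCHEMA_INVALID", "root element is not sedML")
    doc = SedDocument()
    for section in root:
        if not isinstance(section.tag, str):
            continue
        name = etree.QName(section).localname
        if name not in _KNOWN_LISTS:
            doc.warnings.append(f"ignored unknown element <{name}>")
            continue
        if name == "listOfModels":
            for el in iter_local(section, "model"):
                model = SedModel(_require(el, "id"), _require(el, "source"), _require(el, "language"))
                for lst in iter_local(el, "listOfChanges"):
                    for ch in iter_local(lst, "changeAttribute"):
                        model.changes.append(
                            AttributeChange(_require(ch, "target"), _require(ch, "newValue"))
                        )
                doc.models.append(model)
        elif name == "listOfSimulations":
            for el in section:
                if not isinstance(el.tag, str):
                    continue
                kind = etree.QName(el).localname
                if kind == "uniformTimeCourse":
                    points_raw = _require(el, "numberOfPoints")
                    try:
                        points = int(points_raw)
                    except ValueError:
                        raise SimexError(
                            "SEDML_SCHEMA_INVALID", f"numberOfPoints={points_raw!r} is not an integer"
                        )
                    if points < 1:
                        raise SimexError("SEDML_SCHEMA_INVALID", "numberOfPoints must be >= 1")
                    doc.simulations.append(
                        SedUniformTimeCourse(
                            _require(el, "id"),
                            _require_float(el, "initialTime"),
                            _require_float(el, "outputStartTime"),
                            _require_float(el, "outputEndTime"),
                            points,
                            _parse_algorithm(el),
                        )
                    )
                elif kind == "steadyState":
                    doc.simulations.append(SedSteadyState(_require(el, "id"), _parse_algorithm(el)))
                else:
                    doc.warnings.append(f"ignored unknown simulation <{kind}>")
        elif name == "listOfTasks":
            for el in iter_local(section, "task"):
                doc.tasks.append(
                    SedTask(
                        _require(el, "id"),
                        _require(el, "modelReference"),
                        _require(el, "simulationReference"),
                    )
                )
        elif name == "listOfDataGenerators":
            for el in iter_local(section, "dataGenerator"):
                variables: List[SedVariable] = []
                for lst in iter_local(el, "listOfVariables"):
                    for var in iter_local(lst, "variable"):
                        variables.append(
                            SedVariable(
                                _require(var, "id"),
                                _require(var, "taskReference"),
                                target=var.get("target"),
                                symbol=var.get("symbol"),
                            )
                        )
                doc.data_generators.append(
                    SedDataGenerator(_require(el, "id"), variables, _parse_math_child(el))
                )
        elif name == "listOfOutputs":
            for el in section:
                if not isinstance(el.tag, str):
                    continue
                kind = etree.QName(el).localname
                if kind == "report":
                    data_sets = [
                        SedDataSet(_require(ds, "id"), _require(ds, "label"), _require(ds, "dataReference"))
                        for lst in iter_local(el, "listOfDataSets")
                        for ds in iter_local(lst, "dataSet")
                    ]
                    doc.outputs.append(SedReport(_require(el, "id"), data_sets))
                elif kind == "plot2D":
                    curves = [
                        SedCurve(
                            _require(c, "id"),
                            _require(c, "xDataReference"),
                            _require(c, "yDataReference"),
                        )
                        for lst in iter_local(el, "listOfCurves")
                        for c in iter_local(lst, "curve")
                    ]
                    doc.outputs.append(SedPlot2D(_require(el, "id"), curves))
                else:
                    doc.warnings.append(f"ignored unknown output <{kind}>")
    doc.check()
    return doc


# ---------------------------------------------------------------------------
# Writer


def write_sedml(doc: SedDocument) -> bytes:
    """Deterministic serialization; raises ``INVARIANT_VIOLATION`` on a bad document."""
    try:
        doc.check()
    except SimexError as exc:
        raise SimexError("INVARIANT_VIOLATION", exc.message)
    ns = f"{{{SEDML_NS}}}"
    root = etree.Element(
        f"{ns}sedML", nsmap={None: SEDML_NS}, attrib={"level": "1", "version": "3"}
    )
    if doc.models:
        lst = etree.SubElement(root, f"{ns}listOfModels")
        for model in doc.models:
            el = etree.SubElement(
                lst, f"{ns}model",
                attrib={"id": model.id, "source": model.source, "language": model.language},
            )
            if model.changes:
                ch_lst = etree.SubElement(el, f"{ns}listOfChanges")
                for change in model.changes:
                    etree.SubElement(
                        ch_lst, f"{ns}changeAttribute",
                        attrib={"target": change.target, "newValue": change.new_value},
                    )
    if doc.simulations:
        lst = etree.SubElement(root, f"{ns}listOfSimulations")
        for sim in doc.simulations:
            if isinstance(sim, SedUniformTimeCourse):
                el = etree.SubElement(
                    lst, f"{ns}uniformTimeCourse",
                    attrib={
                        "id": sim.id,
                        "initialTime": repr(sim.initial_time),
                        "outputStartTime": repr(sim.output_start_time),
                        "outputEndTime": repr(sim.output_end_time),
                        "numberOfPoints": str(sim.number_of_points),
                    },
                )
            else:
                el = etree.SubElement(lst, f"{ns}steadyState", attrib={"id": sim.id})
            alg = etree.SubElement(el, f"{ns}algorithm", attrib={"kisaoID": sim.algorithm.kisao_id})
            if sim.algorithm.parameters:
                par_lst = etree.SubElement(alg, f"{ns}listOfAlgorithmParameters")
                for par in sim.algorithm.parameters:
                    etree.SubElement(
                        par_lst, f"{ns}algorithmParameter",
                        attrib={"kisaoID": par.kisao_id, "value": par.value},
                    )
    if doc.tasks:
        lst = etree.SubElement(root, f"{ns}listOfTasks")
        for task in doc.tasks:
            etree.SubElement(
                lst, f"{ns}task",
                attrib={
                    "id": task.id,
                    "modelReference": task.model_ref,
                    "simulationReference": task.simulation_ref,
                },
            )
    if doc.data_generators:
        lst = etree.SubElement(root, f"{ns}listOfDataGenerators")
        for gen in doc.data_generators:
            el = etree.SubElement(lst, f"{ns}dataGenerator", attrib={"id": gen.id})
            if gen.variables:
                var_lst = etree.SubElement(el, f"{ns}listOfVariables")
                for var in gen.variables:
                    attrib = {"id": var.id, "taskReference": var.task_ref}
                    if var.target is not None:
                        attrib["target"] = var.target
                    if var.symbol is not None:
                        attrib["symbol"] = var.symbol
                    etree.SubElement(var_lst, f"{ns}variable", attrib=attrib)
            el.append(gen.math.to_mathml())
    if doc.outputs:
        lst = etree.SubElement(root, f"{ns}listOfOutputs")
        for out in doc.outputs:
            if isinstance(out, SedReport):
                el = etree.SubElement(lst, f"{ns}report", attrib={"id": out.id})
                ds_lst = etree.SubElement(el, f"{ns}listOfDataSets")
                for ds in out.data_sets:
                    etree.SubElement(
                        ds_lst, f"{ns}dataSet",
                        attrib={"id": ds.id, "label": ds.label, "dataReference": ds.data_generator_ref},
                    )
            else:
                el = etree.SubElement(lst, f"{ns}plot2D", attrib={"id": out.id})
                c_lst = etree.SubElement(el, f"{ns}listOfCurves")
                for curve in out.curves:
                    etree.SubElement(
                        c_lst, f"{ns}curve",
                        attrib={
                            "id": curve.id,
                            "xDataReference": curve.x_generator_ref,
                            "yDataReference": curve.y_generator_ref,
                        },
                    )
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Data generators


def evaluate_generator(
    gen: SedDataGenerator, variable_values: Dict[str, Sequence[float]]
) -> np.ndarray:
    """Element-wise evaluation of a generator's math over variable vectors."""
    env: Dict[str, np.ndarray] = {}
    length: Optional[int] = None
    for var in gen.variables:
        if var.id not in variable_values:
            raise SimexError("MISSING_VARIABLE", f"no values for variable {var.id!r}")
        values = np.asarray(variable_values[var.id], dtype=float)
        if values.ndim != 1:
            raise SimexError("LENGTH_MISMATCH", f"variable {var.id!r} is not a vector")
        if length is None:
            length = values.shape[0]
        elif values.shape[0] != length:
            raise SimexError("LENGTH_MISMATCH", "variable vectors differ in length")
        env[var.id] = values
    result = gen.math.evaluate(env)
    if np.isscalar(result) or getattr(result, "ndim", 0) == 0:
        result = np.full(length if length is not None else 1, float(result))
    return np.asarray(result, dtype=float)


def time_grid(sim: SedUniformTimeCourse) -> np.ndarray:
    """The recorded grid: ``number_of_points + 1`` uniform points."""
    return np.linspace(sim.output_start_time, sim.output_end_time, sim.number_of_points + 1)
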