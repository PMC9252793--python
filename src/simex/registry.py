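"""Simulator-capability records, queries and the tool-recommendation procedure.

A :class:`SimulatorSpec` is the atomic registry record: which model formats,
modeling frameworks and algorithms (with typed parameters) a tool supports.
Recommendation works per project: extract each task's (format, algorithm)
requirement, then rank tools by the *worst-case* substitution degree over
the project's tasks — a tool must be able to execute every task, so the
weakest task governs its rank.  Exact-match tools (degree 0 everywhere)
rank first; ties break lexicographically by tool id so output is
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from ._errors import SimexError
from . import omex, sedml, validation
from .kisao import AlgorithmOntology, choose_algorithm, substitution_degree
from .sedml import normalize_kisao_id

DEFAULT_POLICY_MAX_DEGREE = 2


@dataclass(frozen=True)
class AlgorithmParameterSpec:
    kisao_id: str
    data_type: str


@dataclass(frozen=True)
class AlgorithmCapability:
    kisao_id: str
    parameters: Tuple[AlgorithmParameterSpec, ...] = ()
    supported_formats: Tuple[str, ...] = ()


@dataclass(frozen=True)
class SimulatorSpec:
    id: str
    version: str
    model_formats: Tuple[str, ...]
    frameworks: Tuple[str, ...]
    algorithms: Tuple[AlgorithmCapability, ...]
    license: str = ""
    cli_available: bool = False

    def algorithm_ids(self) -> List[str]:
        return sorted(a.kisao_id for a in self.algorithms)

    @staticmethod
    def from_json(document: Union[bytes, dict]) -> "SimulatorSpec":
        report = validation.validate_simulator_spec(document)
        if not report.valid:
            raise SimexError(
                "SPEC_INVALID",
                "; ".join(f"{i.code}: {i.message}" for i in report.errors()),
            )
        spec = json.loads(document) if not isinstance(document, dict) else document
        return SimulatorSpec(
            id=spec["id"],
            version=spec["version"],
            model_formats=tuple(spec["model_formats"]),
            frameworks=tuple(spec["frameworks"]),
            algorithms=tuple(
                AlgorithmCapability(
                    kisao_id=normalize_kisao_id(alg["kisao_id"]),
                    parameters=tuple(
                        AlgorithmParameterSpec(normalize_kisao_id(p["kisao_id"]), p["data_type"])
                        for p in alg.get("parameters", [])
                    ),
                    supported_formats=tuple(alg.get("supported_formats", [])),
                )
                for alg in spec["algorithms"]
            ),
            license=spec.get("license", ""),
            cli_available=bool(spec.get("cli_available", False)),
        )


def load_engine_spec() -> SimulatorSpec:
    """The reference engine's own capability record (bundled, dog-fooded)."""
    raw = resources.files("simex").joinpath("data/engine_spec.json").read_bytes()
    return SimulatorSpec.from_json(raw)


@dataclass
class Registry:
    specs: List[SimulatorSpec] = field(default_factory=list)

    def check(self) -> None:
        keys = [(s.id, s.version) for s in self.specs]
        if len(set(keys)) != len(keys):
            raise SimexError("DUPLICATE_SPEC", "registry has duplicate id+version records")


def load_registry(documents: Iterable[Union[bytes, dict]]) -> Registry:
    registry = Registry()
    for document in documents:
        registry.specs.append(SimulatorSpec.from_json(document))
    registry.check()
    return registry


# ---------------------------------------------------------------------------
# Format matching

_FORMAT_KINDS = (
    ("sbml", omex.is_sbml_format),
    ("sedml", omex.is_sedml_format),
    ("boolnet", omex.is_boolnet_format),
)


def _format_kind(uri: str) -> Optional[str]:
    for kind, matcher in _FORMAT_KINDS:
        if matcher(uri):
            return kind
    return None


def same_format(a: str, b: str) -> bool:
    """URIs denote the same format: exact match, or same recognized family
    (COMBINE and EDAM spellings of SBML/SED-ML/BoolNet are interchangeable)."""
    if a == b:
        return True
    ka, kb = _format_kind(a), _format_kind(b)
    return ka is not None and ka == kb


_LANGUAGE_FORMATS = {
    "sbml": omex.FORMAT_SBML,
    "boolnet": omex.FORMAT_BOOLNET,
}


def _language_format(language: str) -> str:
    low = language.lower()
    for key, uri in _LANGUAGE_FORMATS.items():
        if key in low or (key == "boolnet" and "bnet" in low):
            return uri
    return language


@dataclass(frozen=True)
class TaskRequirement:
    task_id: str
    model_format: str
    kisao_id: str


@dataclass
class Recommendation:
    tool_id: str
    best_degree: int
    per_task: Dict[str, Tuple[str, str, int]]  # task -> (requested, usable, degree)


def project_requirements(archive: omex.CombineArchive) -> List[TaskRequirement]:
    """One (task, model format, algorithm) record per task of the project."""
    report = validation.validate_project(archive)
    if not report.valid:
        raise SimexError(
            "PROJECT_INVALID", "; ".join(f"{i.code}: {i.message}" for i in report.errors())
        )
    requirements: List[TaskRequirement] = []
    for location in omex.list_master_sedml(archive):
        doc = sedml.parse_sedml(archive.payload[location])
        for task in doc.tasks:
            model = doc.model(task.model_ref)
            sim = doc.simulation(task.simulation_ref)
            requirements.append(
                TaskRequirement(task.id, _language_format(model.language), sim.algorithm.kisao_id)
            )
    return requirements


def rank_tools(
    requirements: Sequence[TaskRequirement],
    registry: Registry,
    ontology: AlgorithmOntology,
    policy_max_degree: int = DEFAULT_POLICY_MAX_DEGREE,
) -> List[Recommendation]:
    """Rank tools by worst-case task substitution degree (core of recommend_tools)."""
    recommendations: List[Recommendation] = []
    for spec in registry.specs:
        per_task: Dict[str, Tuple[str, str, int]] = {}
        qualifies = True
        for req in requirements:
            if not any(same_format(req.model_format, fmt) for fmt in spec.model_formats):
                qualifies = False
                break
            choice = choose_algorithm(
                req.kisao_id, set(spec.algorithm_ids()), policy_max_degree, ontology
            )
            if choice is None:
                qualifies = False
                break
            per_task[req.task_id] = (req.kisao_id, choice[0], choice[1])
        if qualifies:
            best = max((d for _, _, d in per_task.values()), default=0)
            recommendations.append(Recommendation(spec.id, best, per_task))
    recommendations.sort(key=lambda r: (r.best_degree, r.tool_id))
    return recommendations


def recommend_tools(
    archive: omex.CombineArchive,
    registry: Registry,
    ontology: AlgorithmOntology,
    policy_max_degree: int = DEFAULT_POLICY_MAX_DEGREE,
) -> List[Recommendation]:
    """Tools able to execute every task of the project, best degree first."""
    return rank_tools(project_requirements(archive), registry, ontology, policy_max_degree)


def recommend_similar_algorithms(
    requested: str, registry: Registry, ontology: AlgorithmOntology
) -> List[Tuple[str, str, int]]:
    """All (tool, algorithm) pairs within substitution degree 2 of a request."""
    requested = normalize_kisao_id(requested)
    ontology.term(requested)  # raises UNKNOWN_TERM for unknown requests
    pairs: List[Tuple[str, str, int]] = []
    for spec in registry.specs:
        for alg in spec.algorithms:
            try:
                degree = substitution_degree(requested, alg.kisao_id, ontology)
            except SimexError:
                continue  # tools may declare algorithms outside the snapshot
            if degree <= 2:
                pairs.append((spec.id, alg.kisao_id, degree))
    pairs.sort(key=lambda p: (p[2], p[0], p[1]))
    return pairs
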