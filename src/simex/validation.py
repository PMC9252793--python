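"""Integrated validation of simulation projects, simulator specs and logs.

``validate_project`` runs the full battery over a COMBINE archive — manifest
structure, SED-ML schema, model parses, and every cross-reference (model
sources, change targets, variable targets against the *change-applied*
model, time-course ordering, algorithm-id patterns).  Problems are
accumulated as issues with stable codes, never raised, so a single pass
reports every defect in the project.

Error-code catalogue (stable strings):

``OMEX_NOT_A_ZIP  OMEX_MANIFEST_MISSING  OMEX_MANIFEST_MALFORMED
OMEX_ENTRY_FILE_MISSING  SEDML_SCHEMA_INVALID  SEDML_DUPLICATE_ID
SEDML_DANGLING_REF  SEDML_MODEL_SOURCE_UNRESOLVED  SEDML_TARGET_UNRESOLVED
SEDML_TARGET_AMBIGUOUS  SEDML_TIME_ORDER_INVALID  SEDML_ALGORITHM_ID_INVALID
MODEL_SYNTAX_ERROR  MODEL_UNSUPPORTED_CONSTRUCT  SPEC_MALFORMED_JSON
SPEC_MISSING_FIELD  SPEC_BAD_ID  SPEC_KISAO_PATTERN  SPEC_BAD_DATA_TYPE
LOG_MALFORMED  LOG_MISSING_ROOT  LOG_BAD_STATUS  LOG_MISSING_FIELD
LOG_BAD_EXCEPTION``
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import yaml

from ._errors import SimexError
from . import model_io, omex, sedml

LOG_STATUSES = {"QUEUED", "RUNNING", "SUCCEEDED", "SKIPPED", "FAILED"}
SPEC_DATA_TYPES = {"integer", "float", "boolean", "string", "kisaoId", "list"}
_TOOL_ID_RE = re.compile(r"^[a-z0-9][a-z0-9-]*$")


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    location: str
    message: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def codes(self) -> List[str]:
        return [i.code for i in self.issues]

    def add_error(self, code: str, location: str, message: str) -> None:
        self.issues.append(ValidationIssue("error", code, location, message))

    def add_warning(self, code: str, location: str, message: str) -> None:
        self.issues.append(ValidationIssue("warning", code, location, message))

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "issues": [
                {
                    "severity": i.severity,
                    "code": i.code,
                    "location": i.location,
                    "message": i.message,
                }
                for i in self.issues
            ],
        }


_READ_ERROR_CODES = {
    "NOT_A_ZIP": "OMEX_NOT_A_ZIP",
    "MANIFEST_MISSING": "OMEX_MANIFEST_MISSING",
    "MANIFEST_MALFORMED": "OMEX_MANIFEST_MALFORMED",
    "ENTRY_FILE_MISSING": "OMEX_ENTRY_FILE_MISSING",
    "INVARIANT_VIOLATION": "OMEX_MANIFEST_MALFORMED",
}

_SEDML_PARSE_CODES = {
    "SEDML_SCHEMA_INVALID": "SEDML_SCHEMA_INVALID",
    "DUPLICATE_ID": "SEDML_DUPLICATE_ID",
    "DANGLING_REF": "SEDML_DANGLING_REF",
}


def validate_archive_file(path: str) -> ValidationReport:
    """Validate an archive on disk; unreadable archives become OMEX_* errors."""
    try:
        archive = omex.read_archive(path)
    except SimexError as exc:
        report = ValidationReport()
        report.add_error(_READ_ERROR_CODES.get(exc.code, exc.code), str(path), exc.message)
        return report
    return validate_project(archive)


def validate_project(archive: omex.CombineArchive) -> ValidationReport:
    """Full project validation over an in-memory archive."""
    report = ValidationReport()
    try:
        archive.check()
    except SimexError as exc:
        report.add_error(_READ_ERROR_CODES.get(exc.code, exc.code), "manifest.xml", exc.message)
        return report
    for location in omex.list_master_sedml(archive):
        _validate_sedml_entry(archive, location, report)
    return report


def _validate_sedml_entry(
    archive: omex.CombineArchive, location: str, report: ValidationReport
) -> None:
    try:
        doc = sedml.parse_sedml(archive.payload[location])
    except SimexError as exc:
        report.add_error(
            _SEDML_PARSE_CODES.get(exc.code, "SEDML_SCHEMA_INVALID"), location, exc.message
        )
        return
    for warning in doc.warnings:
        report.add_warning("SEDML_UNKNOWN_ELEMENT", location, warning)

    # resolve + parse every model (after applying its changes)
    model_bytes: Dict[str, Optional[bytes]] = {}
    model_lang: Dict[str, str] = {}
    for model in doc.models:
        loc = f"{location}#{model.id}"
        raw = _resolve_model_source(archive, doc, model, model_bytes)
        if raw is None:
            report.add_error(
                "SEDML_MODEL_SOURCE_UNRESOLVED", loc, f"source {model.source!r} does not resolve"
            )
            model_bytes[model.id] = None
            continue
        model_lang[model.id] = model.language
        if _is_xml_language(model.language):
            try:
                raw = model_io.apply_changes(raw, model.changes)
            except SimexError as exc:
                code = {
                    "TARGET_NOT_FOUND": "SEDML_TARGET_UNRESOLVED",
                    "TARGET_AMBIGUOUS": "SEDML_TARGET_AMBIGUOUS",
                    "TARGET_UNSUPPORTED_SYNTAX": "SEDML_TARGET_UNRESOLVED",
                }.get(exc.code, "MODEL_SYNTAX_ERROR")
                report.add_error(code, loc, exc.message)
                model_bytes[model.id] = None
                continue
        model_bytes[model.id] = raw
        try:
            _parse_model(raw, model.language)
        except SimexError as exc:
            code = (
                "MODEL_UNSUPPORTED_CONSTRUCT"
                if exc.code == "UNSUPPORTED_CONSTRUCT"
                else "MODEL_SYNTAX_ERROR"
            )
            report.add_error(code, loc, exc.message)
            model_bytes[model.id] = None

    # simulation invariants
    for sim in doc.simulations:
        loc = f"{location}#{sim.id}"
        if isinstance(sim, sedml.SedUniformTimeCourse):
            if not (sim.initial_time <= sim.output_start_time <= sim.output_end_time):
                report.add_error(
                    "SEDML_TIME_ORDER_INVALID",
                    loc,
                    "need initialTime <= outputStartTime <= outputEndTime",
                )
        if not sedml.is_valid_kisao_id(sim.algorithm.kisao_id):
            report.add_error(
                "SEDML_ALGORITHM_ID_INVALID", loc, f"bad KiSAO id {sim.algorithm.kisao_id!r}"
            )
        for par in sim.algorithm.parameters:
            if not sedml.is_valid_kisao_id(par.kisao_id):
                report.add_error(
                    "SEDML_ALGORITHM_ID_INVALID", loc, f"bad parameter KiSAO id {par.kisao_id!r}"
                )

    # variable targets against the change-applied model
    for gen in doc.data_generators:
        for var in gen.variables:
            if var.symbol is not None:
                if var.symbol != sedml.TIME_SYMBOL:
                    report.add_error(
                        "SEDML_TARGET_UNRESOLVED",
                        f"{location}#{var.id}",
                        f"unknown symbol {var.symbol!r}",
                    )
                continue
            task = next((t for t in doc.tasks if t.id == var.task_ref), None)
            if task is None:
                continue  # already reported as a dangling ref at parse time
            raw = model_bytes.get(task.model_ref)
            if raw is None:
                continue  # model itself already failed
            language = model_lang.get(task.model_ref, "")
            loc = f"{location}#{var.id}"
            try:
                count = _count_variable_matches(raw, language, var.target)
            except SimexError as exc:
                report.add_error("SEDML_TARGET_UNRESOLVED", loc, exc.message)
                continue
            if count == 0:
                report.add_error(
                    "SEDML_TARGET_UNRESOLVED", loc, f"target {var.target!r} matches nothing"
                )
            elif count > 1:
                report.add_error(
                    "SEDML_TARGET_AMBIGUOUS", loc, f"target {var.target!r} matches {count} nodes"
                )


def _resolve_model_source(archive, doc, model, model_bytes, _depth: int = 0):
    if _depth > len(doc.models):
        return None
    if model.source in archive.payload:
        return archive.payload[model.source]
    parent = next((m for m in doc.models if m.id == model.source), None)
    if parent is None or parent.id == model.id:
        return None
    if parent.id in model_bytes:
        return model_bytes[parent.id]
    raw = _resolve_model_source(archive, doc, parent, model_bytes, _depth + 1)
    if raw is None:
        return None
    if _is_xml_language(parent.language):
        try:
            raw = model_io.apply_changes(raw, parent.changes)
        except SimexError:
            return None
    return raw


def _is_xml_language(language: str) -> bool:
    return "sbml" in language.lower()


def _parse_model(raw: bytes, language: str):
    low = language.lower()
    if "sbml" in low:
        return model_io.parse_sbml_subset(raw)
    if "boolnet" in low or "bnet" in low:
        return model_io.parse_boolnet(raw)
    raise SimexError("MODEL_SYNTAX_ERROR", f"unsupported model language {language!r}")


def _count_variable_matches(raw: bytes, language: str, target: str) -> int:
    low = language.lower()
    if "sbml" in low:
        return model_io.count_element_matches(raw, target)
    # logical models are plain text: targets are bare node ids
    model = model_io.parse_boolnet(raw)
    return 1 if target in model.node_ids() else 0


# ---------------------------------------------------------------------------
# Simulator capability specs


def validate_simulator_spec(spec_document: Union[bytes, dict]) -> ValidationReport:
    """Check a capabilities document: required fields, id patterns, data types."""
    report = ValidationReport()
    if isinstance(spec_document, dict):
        spec = spec_document
    else:
        try:
            spec = json.loads(spec_document)
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            report.add_error("SPEC_MALFORMED_JSON", "spec", f"not valid JSON: {exc}")
            return report
    if not isinstance(spec, dict):
        report.add_error("SPEC_MALFORMED_JSON", "spec", "document must be a JSON object")
        return report
    for required in ("id", "version", "model_formats", "frameworks", "algorithms"):
        if required not in spec:
            report.add_error("SPEC_MISSING_FIELD", "spec", f"missing field {required!r}")
    tool_id = spec.get("id")
    if tool_id is not None and not (isinstance(tool_id, str) and _TOOL_ID_RE.match(tool_id)):
        report.add_error(
            "SPEC_BAD_ID", "spec.id", f"{tool_id!r} must be lowercase alphanumeric/dashes"
        )
    for list_field in ("model_formats", "frameworks"):
        value = spec.get(list_field)
        if value is not None and not (
            isinstance(value, list) and all(isinstance(v, str) for v in value)
        ):
            report.add_error("SPEC_MISSING_FIELD", f"spec.{list_field}", "must be a list of strings")
    algorithms = spec.get("algorithms")
    if algorithms is not None:
        if not isinstance(algorithms, list):
            report.add_error("SPEC_MISSING_FIELD", "spec.algorithms", "must be a list")
            algorithms = []
        for i, alg in enumerate(algorithms):
            loc = f"spec.algorithms[{i}]"
            if not isinstance(alg, dict) or "kisao_id" not in alg:
                report.add_error("SPEC_MISSING_FIELD", loc, "algorithm needs kisao_id")
                continue
            if not sedml.is_valid_kisao_id(sedml.normalize_kisao_id(alg["kisao_id"])):
                report.add_error("SPEC_KISAO_PATTERN", loc, f"bad KiSAO id {alg['kisao_id']!r}")
            for j, par in enumerate(alg.get("parameters", [])):
                ploc = f"{loc}.parameters[{j}]"
                if not isinstance(par, dict) or "kisao_id" not in par or "data_type" not in par:
                    report.add_error("SPEC_MISSING_FIELD", ploc, "parameter needs kisao_id and data_type")
                    continue
                if not sedml.is_valid_kisao_id(sedml.normalize_kisao_id(par["kisao_id"])):
                    report.add_error("SPEC_KISAO_PATTERN", ploc, f"bad KiSAO id {par['kisao_id']!r}")
                if par["data_type"] not in SPEC_DATA_TYPES:
                    report.add_error(
                        "SPEC_BAD_DATA_TYPE", ploc, f"data type {par['data_type']!r} not in enum"
                    )
    return report


# ---------------------------------------------------------------------------
# Execution logs


def validate_log(log_document: Union[bytes, dict]) -> ValidationReport:
    """Check an execution log: status enums, per-document and per-task records."""
    report = ValidationReport()
    if isinstance(log_document, dict):
        log = log_document
    else:
        try:
            log = yaml.safe_load(log_document)
        except yaml.YAMLError as exc:
            report.add_error("LOG_MALFORMED", "log", f"not valid YAML: {exc}")
            return report
    if not isinstance(log, dict) or "status" not in log:
        report.add_error("LOG_MISSING_ROOT", "log", "log must be a mapping with a status")
        return report
    _check_status(log.get("status"), "log.status", report)
    if "duration_s" in log and not isinstance(log["duration_s"], (int, float)):
        report.add_error("LOG_MISSING_FIELD", "log.duration_s", "duration must be numeric")
    documents = log.get("documents")
    if not isinstance(documents, list):
        report.add_error("LOG_MISSING_FIELD", "log.documents", "missing per-document records")
        return report
    for d, doc in enumerate(documents):
        dloc = f"log.documents[{d}]"
        if not isinstance(doc, dict) or "location" not in doc or "status" not in doc:
            report.add_error("LOG_MISSING_FIELD", dloc, "document record needs location and status")
            continue
        _check_status(doc.get("status"), f"{dloc}.status", report)
        for t, task in enumerate(doc.get("tasks", []) or []):
            tloc = f"{dloc}.tasks[{t}]"
            if not isinstance(task, dict) or "id" not in task or "status" not in task:
                report.add_error("LOG_MISSING_FIELD", tloc, "task record needs id and status")
                continue
            _check_status(task.get("status"), f"{tloc}.status", report)
            exception = task.get("exception")
            if task.get("status") == "FAILED":
                if not (
                    isinstance(exception, dict)
                    and "category" in exception
                    and "message" in exception
                ):
                    report.add_error(
                        "LOG_BAD_EXCEPTION", tloc, "failed task needs exception {category, message}"
                    )
            elif exception is not None:
                report.add_error("LOG_BAD_EXCEPTION", tloc, "non-failed task carries an exception")
        for o, out in enumerate(doc.get("outputs", []) or []):
            oloc = f"{dloc}.outputs[{o}]"
            if not isinstance(out, dict) or "id" not in out or "status" not in out:
                report.add_error("LOG_MISSING_FIELD", oloc, "output record needs id and status")
                continue
            _check_status(out.get("status"), f"{oloc}.status", report)
    return report


def _check_status(value, location: str, report: ValidationReport) -> None:
    if value not in LOG_STATUSES:
        report.add_error("LOG_BAD_STATUS", location, f"status {value!r} not in {sorted(LOG_STATUSES)}")
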