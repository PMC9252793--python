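"""Execute COMBINE archives and write the standardized outputs.

For each executable SED-ML document the engine runs every task through the
same pipeline: resolve the model source (archive member, or another model's
id for change chaining), apply the SED-ML attribute changes, choose the
closest implemented algorithm within the substitution policy, translate the
KiSAO algorithm parameters into kernel options, run the kernel, map task
variables onto trajectory rows (the time symbol onto the grid), evaluate
the data generators, and assemble the declared reports and plots.

Tasks fail independently: one task's exception marks it FAILED in the log
and execution continues with the remaining tasks.  Outputs land in a
directory as ``reports.h5`` (one 2-D dataset per report, addressed by
``<sedml location>/<report id>``), ``log.yml`` (hierarchical status log)
and ``plots/<doc>/<plot id>.pdf``.
"""

from __future__ import annotations

import os
import re
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import yaml

from ._errors import SimexError
from . import kernels, model_io, omex, sedml, validation
from .kisao import choose_algorithm, load_ontology, substitution_degree
from .registry import load_engine_spec

#: among implemented algorithms tied at the minimal substitution degree the
#: engine prefers its higher-order kernels (RK4 before forward Euler)
ALGORITHM_PREFERENCE = (
    kernels.KISAO_RK4,
    kernels.KISAO_EULER,
    kernels.KISAO_GILLESPIE,
    kernels.KISAO_SYNC,
    kernels.KISAO_ASYNC,
)

HDF5_SCHEMA_VERSION = "1"

# explicit, versioned KiSAO parameter -> kernel option mapping
PARAMETER_MAP = {
    "KISAO:0000209": ("rel_tol", float),
    "KISAO:0000211": ("abs_tol", float),
    "KISAO:0000483": ("step_size", float),
    "KISAO:0000488": ("seed", int),
}


@dataclass
class ExecutionOptions:
    out_dir: str
    policy_max_degree: int = 2
    plot_format: str = "pdf"


@dataclass
class ReportData:
    sedml_location: str
    report_id: str
    data_set_ids: List[str]
    labels: List[str]
    values: np.ndarray  # (data_set, point)


@dataclass
class TaskLog:
    id: str
    status: str
    requested_algorithm: Optional[str] = None
    used_algorithm: Optional[str] = None
    substitution_degree: Optional[int] = None
    exception: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {"id": self.id, "status": self.status}
        if self.requested_algorithm is not None:
            out["requested_algorithm"] = self.requested_algorithm
        if self.used_algorithm is not None:
            out["used_algorithm"] = self.used_algorithm
        if self.substitution_degree is not None:
            out["substitution_degree"] = self.substitution_degree
        if self.exception is not None:
            out["exception"] = self.exception
        return out


@dataclass
class OutputLog:
    id: str
    status: str

    def to_dict(self) -> dict:
        return {"id": self.id, "status": self.status}


@dataclass
class DocumentLog:
    location: str
    status: str
    tasks: List[TaskLog] = field(default_factory=list)
    outputs: List[OutputLog] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "location": self.location,
            "status": self.status,
            "tasks": [t.to_dict() for t in self.tasks],
            "outputs": [o.to_dict() for o in self.outputs],
        }


@dataclass
class ExecutionLog:
    status: str = "QUEUED"
    duration_s: float = 0.0
    documents: List[DocumentLog] = field(default_factory=list)
    validation: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "status": self.status,
            "duration_s": round(float(self.duration_s), 6),
            "documents": [d.to_dict() for d in self.documents],
        }
        if self.validation is not None:
            out["validation"] = self.validation
        return out


# ---------------------------------------------------------------------------
# Orchestration


def execute_archive(
    archive_path: str, options: ExecutionOptions
) -> Tuple[List[ReportData], ExecutionLog, List[str]]:
    """Validate and execute an archive; returns reports, the log, written files."""
    started = time.perf_counter()
    os.makedirs(options.out_dir, exist_ok=True)
    log = ExecutionLog(status="RUNNING")
    written: List[str] = []

    report = validation.validate_archive_file(archive_path)
    if not report.valid:
        log.status = "FAILED"
        log.validation = report.to_dict()
        log.duration_s = time.perf_counter() - started
        log_path = os.path.join(options.out_dir, "log.yml")
        write_log_yaml(log, log_path)
        return [], log, [log_path]

    archive = omex.read_archive(archive_path)
    ontology = load_ontology()
    engine_spec = load_engine_spec()
    implemented = set(engine_spec.algorithm_ids())

    reports: List[ReportData] = []
    for location in omex.list_master_sedml(archive):
        doc = sedml.parse_sedml(archive.payload[location])
        doc_log = DocumentLog(location=location, status="RUNNING")
        log.documents.append(doc_log)
        generator_values = _execute_document(
            archive, doc, ontology, implemented, options, doc_log
        )
        doc_reports = _assemble_outputs(doc, location, generator_values, options, doc_log, written)
        reports.extend(doc_reports)
        doc_log.status = "FAILED" if any(t.status == "FAILED" for t in doc_log.tasks) else "SUCCEEDED"

    log.status = "FAILED" if any(d.status == "FAILED" for d in log.documents) else "SUCCEEDED"
    log.duration_s = time.perf_counter() - started

    h5_path = os.path.join(options.out_dir, "reports.h5")
    write_reports_h5(reports, h5_path)
    written.append(h5_path)
    log_path = os.path.join(options.out_dir, "log.yml")
    write_log_yaml(log, log_path)
    written.append(log_path)
    return reports, log, written


def _execute_document(archive, doc, ontology, implemented, options, doc_log):
    """Run every task; returns generator id -> vector for the succeeded tasks."""
    task_results: Dict[str, kernels.TrajectoryResult] = {}
    task_language: Dict[str, str] = {}
    for task in doc.tasks:
        task_log = TaskLog(id=task.id, status="RUNNING")
        doc_log.tasks.append(task_log)
        sim = doc.simulation(task.simulation_ref)
        task_log.requested_algorithm = sim.algorithm.kisao_id
        try:
            model = doc.model(task.model_ref)
            raw = _resolve_model(archive, doc, model)
            choice = choose_algorithm(
                sim.algorithm.kisao_id, implemented, options.policy_max_degree, ontology
            )
            if choice is None:
                raise SimexError(
                    "ALGORITHM_UNAVAILABLE",
                    f"no implemented algorithm within degree {options.policy_max_degree} "
                    f"of {sim.algorithm.kisao_id}",
                )
            used, degree = choice
            for candidate in ALGORITHM_PREFERENCE:
                if candidate in implemented and substitution_degree(
                    sim.algorithm.kisao_id, candidate, ontology
                ) == degree:
                    used = candidate
                    break
            task_log.used_algorithm = used
            task_log.substitution_degree = degree
            config = _build_config(sim, used)
            task_results[task.id] = _run_kernel(model.language, raw, sim, used, config)
            task_language[task.id] = model.language
            task_log.status = "SUCCEEDED"
        except SimexError as exc:
            task_log.status = "FAILED"
            task_log.exception = {"category": exc.code, "message": exc.message}
        except Exception as exc:  # defensive: anything else still lands in the log
            task_log.status = "FAILED"
            task_log.exception = {"category": "UNEXPECTED_ERROR", "message": str(exc)}

    generator_values: Dict[str, np.ndarray] = {}
    for gen in doc.data_generators:
        try:
            variable_values = {}
            for var in gen.variables:
                if var.task_ref not in task_results:
                    raise SimexError("TASK_FAILED", f"task {var.task_ref} produced no results")
                result = task_results[var.task_ref]
                if var.symbol is not None:
                    variable_values[var.id] = result.times
                else:
                    observable = _target_to_observable(var.target, task_language[var.task_ref])
                    variable_values[var.id] = result.row(observable)
            generator_values[gen.id] = sedml.evaluate_generator(gen, variable_values)
        except SimexError:
            continue  # outputs depending on this generator are marked FAILED below
    return generator_values


def _resolve_model(archive, doc, model, _depth: int = 0) -> bytes:
    """Archive member path first, then chaining through another model's id."""
    if _depth > len(doc.models):
        raise SimexError("SEDML_MODEL_SOURCE_UNRESOLVED", f"cyclic model source {model.source!r}")
    if model.source in archive.payload:
        raw = archive.payload[model.source]
    else:
        parent = next((m for m in doc.models if m.id == model.source), None)
        if parent is None:
            raise SimexError(
                "SEDML_MODEL_SOURCE_UNRESOLVED", f"source {model.source!r} does not resolve"
            )
        raw = _resolve_model(archive, doc, parent, _depth + 1)
    if model.changes:
        raw = model_io.apply_changes(raw, model.changes)
    return raw


def _build_config(sim, used_algorithm: str) -> kernels.KernelConfig:
    config = kernels.KernelConfig(algorithm=used_algorithm)
    for par in sim.algorithm.parameters:
        mapping = PARAMETER_MAP.get(par.kisao_id)
        if mapping is None:
            continue  # unknown parameters are logged as warnings upstream, not fatal
        attr, cast = mapping
        try:
            setattr(config, attr, cast(float(par.value)) if cast is int else cast(par.value))
        except ValueError:
            raise SimexError("BAD_CONFIG", f"bad value {par.value!r} for {par.kisao_id}")
    config.check()
    return config


def _run_kernel(language, raw, sim, used, config) -> kernels.TrajectoryResult:
    low = language.lower()
    if "sbml" in low:
        model = model_io.parse_sbml_subset(raw)
        if isinstance(sim, sedml.SedSteadyState):
            state = kernels.solve_steady_state(model, config)
            return kernels.TrajectoryResult(
                np.array([0.0]), state.reshape(-1, 1), model.species_ids()
            )
        if used == kernels.KISAO_GILLESPIE:
            return kernels.simulate_ssa(
                model, sim.initial_time, sim.output_start_time, sim.output_end_time,
                sim.number_of_points, config,
            )
        return kernels.simulate_ode(
            model, sim.initial_time, sim.output_start_time, sim.output_end_time,
            sim.number_of_points, config,
        )
    if "boolnet" in low or "bnet" in low:
        model = model_io.parse_boolnet(raw)
        if isinstance(sim, sedml.SedSteadyState):
            raise SimexError("BAD_CONFIG", "steady state is not defined for logical models")
        scheme = "asynchronous" if used == kernels.KISAO_ASYNC else "synchronous"
        result = kernels.simulate_boolean(model, sim.number_of_points, scheme, config.seed)
        # map the discrete step axis onto the declared SED-ML grid
        return kernels.TrajectoryResult(
            sedml.time_grid(sim), result.values, result.observable_ids, result.warnings
        )
    raise SimexError("MODEL_SYNTAX_ERROR", f"unsupported model language {language!r}")


_ID_PREDICATE_RE = re.compile(r"\[@id='([^']+)'\]\s*$")


def _target_to_observable(target: str, language: str) -> str:
    """Map a variable target onto a trajectory row id."""
    if "sbml" in language.lower():
        m = _ID_PREDICATE_RE.search(target or "")
        if not m:
            raise SimexError(
                "SEDML_TARGET_UNRESOLVED", f"cannot extract an id from target {target!r}"
            )
        return m.group(1)
    return target  # logical models: targets are bare node ids


def _assemble_outputs(doc, location, generator_values, options, doc_log, written):
    reports: List[ReportData] = []
    plot_docs = []
    for out in doc.outputs:
        if isinstance(out, sedml.SedReport):
            refs = [ds.data_generator_ref for ds in out.data_sets]
            if all(ref in generator_values for ref in refs):
                values = np.vstack([generator_values[ref] for ref in refs]) if refs else np.empty((0, 0))
                reports.append(
                    ReportData(
                        sedml_location=location,
                        report_id=out.id,
                        data_set_ids=[ds.id for ds in out.data_sets],
                        labels=[ds.label for ds in out.data_sets],
                        values=values,
                    )
                )
                doc_log.outputs.append(OutputLog(out.id, "SUCCEEDED"))
            else:
                doc_log.outputs.append(OutputLog(out.id, "FAILED"))
        else:
            refs = [r for c in out.curves for r in (c.x_generator_ref, c.y_generator_ref)]
            if all(ref in generator_values for ref in refs):
                plot_docs.append(out)
                doc_log.outputs.append(OutputLog(out.id, "SUCCEEDED"))
            else:
                doc_log.outputs.append(OutputLog(out.id, "FAILED"))
    if plot_docs:
        plot_dir = os.path.join(options.out_dir, "plots", _sanitize(location))
        written.extend(_render_plot_list(plot_docs, generator_values, plot_dir))
    return reports


def _sanitize(location: str) -> str:
    return location.replace("/", "_")


# ---------------------------------------------------------------------------
# HDF5 reports


def write_reports_h5(reports: List[ReportData], path: str) -> None:
    """One 2-D dataset per report at ``<sedml location>/<report id>``."""
    try:
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = HDF5_SCHEMA_VERSION
            for report in reports:
                group = f.require_group(report.sedml_location)
                ds = group.create_dataset(report.report_id, data=np.asarray(report.values, dtype=float))
                str_dtype = h5py.string_dtype(encoding="utf-8")
                ds.attrs.create("dataSetIds", np.array(report.data_set_ids, dtype=str_dtype))
                ds.attrs.create("dataSetLabels", np.array(report.labels, dtype=str_dtype))
                ds.attrs["sedmlId"] = report.report_id
    except OSError as exc:
        raise SimexError("IO_ERROR", f"cannot write {path}: {exc}")


def read_reports_h5(path: str) -> List[ReportData]:
    reports: List[ReportData] = []
    try:
        with h5py.File(path, "r") as f:

            def visit(name, obj):
                if isinstance(obj, h5py.Dataset):
                    location, _, report_id = name.rpartition("/")
                    reports.append(
                        ReportData(
                            sedml_location=location,
                            report_id=report_id,
                            data_set_ids=[_as_str(v) for v in obj.attrs.get("dataSetIds", [])],
                            labels=[_as_str(v) for v in obj.attrs.get("dataSetLabels", [])],
                            values=obj[()],
                        )
                    )

            f.visititems(visit)
    except OSError as exc:
        raise SimexError("IO_ERROR", f"cannot read {path}: {exc}")
    reports.sort(key=lambda r: (r.sedml_location, r.report_id))
    return reports


def _as_str(value) -> str:
    return value.decode("utf-8") if isinstance(value, bytes) else str(value)


# ---------------------------------------------------------------------------
# YAML log


def write_log_yaml(log: ExecutionLog, path: str) -> None:
    try:
        with open(path, "w", encoding="utf-8") as f:
            yaml.safe_dump(log.to_dict(), f, sort_keys=False)
    except OSError as exc:
        raise SimexError("IO_ERROR", f"cannot write {path}: {exc}")


# ---------------------------------------------------------------------------
# PDF plots


def render_plots(doc: sedml.SedDocument, generator_values: Dict[str, np.ndarray], out_dir: str) -> List[str]:
    """One PDF per 2-D plot; curve ids become legend labels."""
    plots = [o for o in doc.outputs if isinstance(o, sedml.SedPlot2D)]
    for plot in plots:
        for curve in plot.curves:
            for ref in (curve.x_generator_ref, curve.y_generator_ref):
                if ref not in generator_values:
                    raise SimexError("MISSING_GENERATOR", f"curve {curve.id} needs generator {ref!r}")
    return _render_plot_list(plots, generator_values, out_dir)


def _render_plot_list(plots, generator_values, out_dir) -> List[str]:
    if not plots:
        return []
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths: List[str] = []
    for plot in plots:
        fig, ax = plt.subplots(figsize=(6.0, 4.0))
        for curve in plot.curves:
            ax.plot(
                generator_values[curve.x_generator_ref],
                generator_values[curve.y_generator_ref],
                label=curve.id,
            )
        if plot.curves:
            ax.legend()
        path = os.path.join(out_dir, f"{plot.id}.pdf")
        # pinned metadata keeps the vector content deterministic across runs
        fig.savefig(path, format="pdf", metadata={"CreationDate": None})
        plt.close(fig)
        paths.append(path)
    return paths
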