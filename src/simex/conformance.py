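"""Simulator conformance testing.

Any command-line simulator that accepts an archive and an output directory
can be tested: the suite materializes test archives, invokes the command
through a ``{archive}``/``{outdir}`` template, and checks the standardized
outputs — exit status, the ``reports.h5`` datasets and shapes, the
``log.yml`` structure, reference values where a case carries them, and
seeded determinism for stochastic cases (two runs with the same declared
seed must agree bitwise, since foreign generators cannot be compared by
value).

Checks short-circuit: a case fails with the *first* violated convention,
which keeps failure codes diagnostic (a tool that writes nothing fails with
``MISSING_REPORT``, not with a pile-up of downstream codes).
"""

from __future__ import annotations

import json
import os
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._errors import SimexError
from . import omex, validation
from .kisao import AlgorithmOntology, load_ontology, substitution_degree
from .model_io import BooleanNetworkModel
from .registry import SimulatorSpec, same_format
from .synthetic_models import (
    ArchiveOptions,
    GeneratorConfig,
    SimulationRequest,
    build_archive,
    decay_model,
    isomerization_model,
    production_decay_model,
    random_boolean_network,
    random_mass_action_network,
    toggle_boolean_model,
    SEDML_LOCATION,
)

FRAMEWORK_OF_KISAO = {
    "KISAO:0000030": "continuous-kinetic",
    "KISAO:0000032": "continuous-kinetic",
    "KISAO:0000019": "continuous-kinetic",
    "KISAO:0000029": "discrete-stochastic",
    "KISAO:0000449": "logical",
    "KISAO:0000450": "logical",
}


@dataclass
class CaseExpectation:
    report_path: str  # "<sedml location>/<report id>"
    data_set_ids: List[str]
    n_points: int
    reference: Optional[np.ndarray] = None
    rel_tol: float = 1e-3
    check_determinism: bool = False
    validation_error: Optional[str] = None


@dataclass
class TestCase:
    id: str
    archive: omex.CombineArchive
    required_format: str
    required_kisao: str
    required_framework: str
    expected: CaseExpectation
    archive_bytes: Optional[bytes] = None  # set for mutations that break the zip itself

    def to_bytes(self) -> bytes:
        if self.archive_bytes is not None:
            return self.archive_bytes
        return omex.archive_to_bytes(self.archive)


@dataclass
class CaseResult:
    case_id: str
    status: str  # PASS | FAIL | SKIPPED
    failure_codes: List[str] = field(default_factory=list)
    messages: List[str] = field(default_factory=list)


@dataclass
class ConformanceReport:
    cases: List[CaseResult] = field(default_factory=list)

    @property
    def summary(self) -> Dict[str, int]:
        out = {"PASS": 0, "FAIL": 0, "SKIPPED": 0}
        for case in self.cases:
            out[case.status] = out.get(case.status, 0) + 1
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": self.summary,
                "cases": [
                    {
                        "case_id": c.case_id,
                        "status": c.status,
                        "failure_codes": c.failure_codes,
                        "messages": c.messages,
                    }
                    for c in self.cases
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Oracles used for expectations


def boolean_truth_table_trajectory(model: BooleanNetworkModel, n_steps: int) -> np.ndarray:
    """Synchronous trajectory via exhaustive transition-map enumeration.

    Builds the full 2^n state-transition table first, then walks it — an
    independent route to the same trajectory the step-by-step kernel records.
    """
    node_ids = model.node_ids()
    n = len(node_ids)
    table: Dict[Tuple[int, ...], Tuple[int, ...]] = {}
    for code in range(2 ** n):
        state = tuple((code >> i) & 1 for i in range(n))
        env = dict(zip(node_ids, state))
        table[state] = tuple(node.update.evaluate(env) for node in model.nodes)
    state = tuple(node.initial_state for node in model.nodes)
    rows = [state]
    for _ in range(n_steps):
        state = table[state]
        rows.append(state)
    return np.array(rows, dtype=float).T  # (node, step)


# ---------------------------------------------------------------------------
# Corpus generation


def generate_fixture_corpus(seed: int, counts: Optional[Dict[str, int]] = None) -> List[TestCase]:
    """Curated cases plus seeded random archives, each with its expectations."""
    counts = dict(counts or {})
    n_ode = counts.get("ode", 2)
    n_boolean = counts.get("boolean", 2)
    if n_ode < 1 or n_boolean < 1:
        raise SimexError("BAD_CONFIG", "need at least one generated case per class")
    cases: List[TestCase] = []

    # -- curated -------------------------------------------------------
    k, s1_0 = 0.5, 10.0
    grid = np.linspace(0.0, 10.0, 11)
    decay_reference = np.vstack([grid, s1_0 * np.exp(-k * grid), s1_0 - s1_0 * np.exp(-k * grid)])
    cases.append(
        TestCase(
            id="curated/ode-decay",
            archive=build_archive(decay_model(k, s1_0), SimulationRequest("KISAO:0000032")),
            required_format=omex.FORMAT_SBML,
            required_kisao="KISAO:0000032",
            required_framework="continuous-kinetic",
            expected=CaseExpectation(
                report_path=f"{SEDML_LOCATION}/report1",
                data_set_ids=["ds_time", "ds_S1", "ds_S2"],
                n_points=11,
                reference=decay_reference,
            ),
        )
    )
    cases.append(
        TestCase(
            id="curated/ssa-isomerization",
            archive=build_archive(
                isomerization_model(),
                SimulationRequest(
                    "KISAO:0000029",
                    output_end_time=5.0,
                    number_of_points=20,
                    parameters=[("KISAO:0000488", "42")],
                ),
            ),
            required_format=omex.FORMAT_SBML,
            required_kisao="KISAO:0000029",
            required_framework="discrete-stochastic",
            expected=CaseExpectation(
                report_path=f"{SEDML_LOCATION}/report1",
                data_set_ids=["ds_time", "ds_X", "ds_Y"],
                n_points=21,
                check_determinism=True,
            ),
        )
    )
    toggle = toggle_boolean_model()
    toggle_reference = np.vstack(
        [np.arange(9.0), boolean_truth_table_trajectory(toggle, 8)]
    )
    cases.append(
        TestCase(
            id="curated/boolean-toggle",
            archive=build_archive(
                toggle, SimulationRequest("KISAO:0000449", output_end_time=8.0, number_of_points=8)
            ),
            required_format=omex.FORMAT_BOOLNET,
            required_kisao="KISAO:0000449",
            required_framework="logical",
            expected=CaseExpectation(
                report_path=f"{SEDML_LOCATION}/report1",
                data_set_ids=["ds_time", "ds_A", "ds_B"],
                n_points=9,
                reference=toggle_reference,
                rel_tol=1e-9,
            ),
        )
    )
    cases.append(
        TestCase(
            id="curated/steady-state",
            archive=build_archive(
                production_decay_model(), SimulationRequest("KISAO:0000032", kind="steady_state")
            ),
            required_format=omex.FORMAT_SBML,
            required_kisao="KISAO:0000032",
            required_framework="continuous-kinetic",
            expected=CaseExpectation(
                report_path=f"{SEDML_LOCATION}/report1",
                data_set_ids=["ds_S1"],
                n_points=1,
                reference=np.array([[4.0]]),
            ),
        )
    )
    changed_reference = np.vstack(
        [grid, 20.0 * np.exp(-k * grid), s1_0 - s1_0 * np.exp(-k * grid)]
    )
    changed_reference[2] = 20.0 - 20.0 * np.exp(-k * grid)
    cases.append(
        TestCase(
            id="curated/change-applied",
            archive=build_archive(
                decay_model(k, s1_0),
                SimulationRequest("KISAO:0000032"),
                ArchiveOptions(with_changes=True, change_new_value="20"),
            ),
            required_format=omex.FORMAT_SBML,
            required_kisao="KISAO:0000032",
            required_framework="continuous-kinetic",
            expected=CaseExpectation(
                report_path=f"{SEDML_LOCATION}/report1",
                data_set_ids=["ds_time", "ds_S1", "ds_S2"],
                n_points=11,
                reference=changed_reference,
            ),
        )
    )
    cases.append(
        TestCase(
            id="curated/substitutable-algorithm",
            archive=build_archive(decay_model(k, s1_0), SimulationRequest("KISAO:0000019")),
            required_format=omex.FORMAT_SBML,
            required_kisao="KISAO:0000019",
            required_framework="continuous-kinetic",
            expected=CaseExpectation(
                report_path=f"{SEDML_LOCATION}/report1",
                data_set_ids=["ds_time", "ds_S1", "ds_S2"],
                n_points=11,
                reference=decay_reference,
            ),
        )
    )

    # -- generated -----------------------------------------------------
    for i in range(n_ode):
        model = random_mass_action_network(
            GeneratorConfig(seed=seed * 1000 + i, n_species_range=(2, 8), n_reactions_range=(2, 12))
        )
        archive = build_archive(model, SimulationRequest("KISAO:0000032", output_end_time=2.0))
        cases.append(
            TestCase(
                id=f"generated/ode-{i}",
                archive=archive,
                required_format=omex.FORMAT_SBML,
                required_kisao="KISAO:0000032",
                required_framework="continuous-kinetic",
                expected=CaseExpectation(
                    report_path=f"{SEDML_LOCATION}/report1",
                    data_set_ids=["ds_time"] + [f"ds_{s}" for s in model.species_ids()],
                    n_points=11,
                ),
            )
        )
    for i in range(n_boolean):
        model = random_boolean_network(GeneratorConfig(seed=seed * 2000 + i))
        steps = 8
        reference = np.vstack(
            [np.arange(steps + 1, dtype=float), boolean_truth_table_trajectory(model, steps)]
        )
        archive = build_archive(
            model,
            SimulationRequest("KISAO:0000449", output_end_time=float(steps), number_of_points=steps),
        )
        cases.append(
            TestCase(
                id=f"generated/boolean-{i}",
                archive=archive,
                required_format=omex.FORMAT_BOOLNET,
                required_kisao="KISAO:0000449",
                required_framework="logical",
                expected=CaseExpectation(
                    report_path=f"{SEDML_LOCATION}/report1",
                    data_set_ids=["ds_time"] + [f"ds_{n}" for n in model.node_ids()],
                    n_points=steps + 1,
                    reference=reference,
                    rel_tol=1e-9,
                ),
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Case selection


def select_cases(
    spec: SimulatorSpec, corpus: Sequence[TestCase], ontology: Optional[AlgorithmOntology] = None
) -> List[TestCase]:
    """Cases the tool's declared capabilities can execute (substitution <= 2)."""
    ontology = ontology or load_ontology()
    selected = []
    for case in corpus:
        if _case_matches(spec, case, ontology):
            selected.append(case)
    return selected


def _case_matches(spec: SimulatorSpec, case: TestCase, ontology: AlgorithmOntology) -> bool:
    if not any(same_format(case.required_format, fmt) for fmt in spec.model_formats):
        return False
    for alg_id in spec.algorithm_ids():
        try:
            if substitution_degree(case.required_kisao, alg_id, ontology) <= 2:
                return True
        except SimexError:
            continue
    return False


# ---------------------------------------------------------------------------
# Execution


def run_conformance(
    command_template: str,
    cases: Sequence[TestCase],
    spec: Optional[SimulatorSpec] = None,
    ontology: Optional[AlgorithmOntology] = None,
    timeout_s: float = 300.0,
) -> ConformanceReport:
    """Run a CLI simulator over the cases and grade the outputs."""
    ontology = ontology or load_ontology()
    report = ConformanceReport()
    for case in cases:
        if spec is not None and not _case_matches(spec, case, ontology):
            report.cases.append(CaseResult(case.id, "SKIPPED"))
            continue
        result = _run_case(command_template, case, timeout_s)
        report.cases.append(result)
    return report


def _invoke(command_template: str, archive_path: str, out_dir: str, timeout_s: float):
    tokens = shlex.split(command_template)
    args = [t.format(archive=archive_path, outdir=out_dir) for t in tokens]
    try:
        return subprocess.run(args, capture_output=True, timeout=timeout_s)
    except FileNotFoundError:
        raise SimexError("COMMAND_NOT_FOUND", f"cannot execute {args[0]!r}")


def _run_case(command_template: str, case: TestCase, timeout_s: float) -> CaseResult:
    from .engine import read_reports_h5  # local import: engine pulls in h5py/matplotlib

    result = CaseResult(case.id, "PASS")
    with tempfile.TemporaryDirectory() as tmp:
        archive_path = os.path.join(tmp, "case.omex")
        with open(archive_path, "wb") as f:
            f.write(case.to_bytes())

        if case.expected.validation_error is not None:
            # breaking mutations: the archive itself must be flagged
            vreport = validation.validate_archive_file(archive_path)
            if case.expected.validation_error not in vreport.codes():
                result.status = "FAIL"
                result.failure_codes.append("VALIDATION_NOT_FLAGGED")
                result.messages.append(
                    f"expected validation code {case.expected.validation_error}"
                )
            return result

        out_dir = os.path.join(tmp, "out")
        proc = _invoke(command_template, archive_path, out_dir, timeout_s)
        if proc.returncode != 0:
            result.status = "FAIL"
            result.failure_codes.append("EXIT_NONZERO")
            result.messages.append(f"exit code {proc.returncode}")
            return result

        h5_path = os.path.join(out_dir, "reports.h5")
        values = _read_report_matrix(h5_path, case.expected.report_path)
        if values is None:
            result.status = "FAIL"
            result.failure_codes.append("MISSING_REPORT")
            result.messages.append(f"no dataset at {case.expected.report_path}")
            return result
        expected_shape = (len(case.expected.data_set_ids), case.expected.n_points)
        if values.shape != expected_shape:
            result.status = "FAIL"
            result.failure_codes.append("WRONG_SHAPE")
            result.messages.append(f"shape {values.shape} != {expected_shape}")
            return result

        log_path = os.path.join(out_dir, "log.yml")
        if not os.path.exists(log_path):
            result.status = "FAIL"
            result.failure_codes.append("BAD_LOG")
            result.messages.append("log.yml missing")
            return result
        with open(log_path, "rb") as f:
            log_report = validation.validate_log(f.read())
        if not log_report.valid:
            result.status = "FAIL"
            result.failure_codes.append("BAD_LOG")
            result.messages.extend(i.code for i in log_report.errors())
            return result

        if case.expected.reference is not None:
            if not np.allclose(
                values, case.expected.reference, rtol=case.expected.rel_tol, atol=1e-6
            ):
                result.status = "FAIL"
                result.failure_codes.append("VALUE_MISMATCH")
                result.messages.append("report values outside tolerance of the reference")
                return result

        if case.expected.check_determinism:
            out_dir2 = os.path.join(tmp, "out2")
            proc2 = _invoke(command_template, archive_path, out_dir2, timeout_s)
            values2 = _read_report_matrix(
                os.path.join(out_dir2, "reports.h5"), case.expected.report_path
            )
            if proc2.returncode != 0 or values2 is None or not np.array_equal(values, values2):
                result.status = "FAIL"
                result.failure_codes.append("NONDETERMINISTIC")
                result.messages.append("two runs with the same declared seed disagree")
    return result


def _read_report_matrix(h5_path: str, report_path: str) -> Optional[np.ndarray]:
    if not os.path.exists(h5_path):
        return None
    import h5py

    try:
        with h5py.File(h5_path, "r") as f:
            if report_path not in f:
                return None
            return f[report_path][()]
    except OSError:
        return None


# ---------------------------------------------------------------------------
# Archive mutations

MUTATION_CLASSES = (
    "drop_master",
    "rename_report_id",
    "add_seed_parameter",
    "swap_algorithm_degree2",
    "break_variable_target",
    "reorder_manifest",
)


def mutate_archive(case: TestCase, mutation: str) -> TestCase:
    """Derive a new test case probing one specific convention."""
    import copy

    if mutation not in MUTATION_CLASSES:
        raise SimexError("UNKNOWN_MUTATION", f"unknown mutation class {mutation!r}")
    mutated = copy.deepcopy(case)
    mutated.id = f"{case.id}+{mutation}"
    sed = mutated.archive.payload[SEDML_LOCATION]

    if mutation == "drop_master":
        mutated.archive.entries = [
            omex.ContentEntry(e.location, e.format, False) for e in mutated.archive.entries
        ]
    elif mutation == "rename_report_id":
        mutated.archive.payload[SEDML_LOCATION] = sed.replace(b'id="report1"', b'id="reportX"')
        mutated.expected.report_path = mutated.expected.report_path.replace("report1", "reportX")
    elif mutation == "add_seed_parameter":
        old = b'<algorithm kisaoID="' + case.required_kisao.encode() + b'"/>'
        new = (
            b'<algorithm kisaoID="' + case.required_kisao.encode() + b'">'
            b'<listOfAlgorithmParameters>'
            b'<algorithmParameter kisaoID="KISAO:0000488" value="123"/>'
            b'</listOfAlgorithmParameters></algorithm>'
        )
        if old not in sed:
            raise SimexError("UNKNOWN_MUTATION", "case algorithm already carries parameters")
        mutated.archive.payload[SEDML_LOCATION] = sed.replace(old, new, 1)
    elif mutation == "swap_algorithm_degree2":
        old = b'kisaoID="' + case.required_kisao.encode() + b'"'
        swap = {"continuous-kinetic": "KISAO:0000019", "logical": "KISAO:0000450"}.get(
            case.required_framework
        )
        if swap is None or old not in sed:
            raise SimexError("UNKNOWN_MUTATION", "no degree-2 substitute for this case")
        mutated.archive.payload[SEDML_LOCATION] = sed.replace(
            old, b'kisaoID="' + swap.encode() + b'"', 1
        )
        mutated.required_kisao = swap
        if swap == "KISAO:0000450":
            # asynchronous updates are stochastic: keep shape checks only
            mutated.expected.reference = None
            mutated.expected.check_determinism = True
    elif mutation == "break_variable_target":
        if b"species[@id='S1']\"" in sed:
            mutated.archive.payload[SEDML_LOCATION] = sed.replace(
                b"species[@id='S1']\"", b"species[@id='S9']\"", 1
            )
        else:
            raise SimexError("UNKNOWN_MUTATION", "case has no S1 variable target")
        mutated.expected.validation_error = "SEDML_TARGET_UNRESOLVED"
    elif mutation == "reorder_manifest":
        mutated.archive_bytes = _reorder_manifest_bytes(mutated.archive)
    return mutated


def _reorder_manifest_bytes(archive: omex.CombineArchive) -> bytes:
    """Rebuild the zip with manifest entries listed in reverse order."""
    import io
    import zipfile
    from lxml import etree

    root = etree.Element(
        f"{{{omex.MANIFEST_NS}}}omexManifest", nsmap={None: omex.MANIFEST_NS}
    )
    for entry in sorted(archive.entries, key=lambda e: e.location, reverse=True):
        el = etree.SubElement(root, f"{{{omex.MANIFEST_NS}}}content")
        el.set("location", entry.location)
        el.set("format", entry.format)
        if entry.is_master:
            el.set("master", "true")
    manifest = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    buffer = io.BytesIO()
    with zipfile.ZipFile(buffer, "w") as zf:
        zf.writestr(zipfile.ZipInfo("manifest.xml", date_time=(1980, 1, 1, 0, 0, 0)), manifest)
        for location in sorted(archive.payload):
            zf.writestr(
                zipfile.ZipInfo(location, date_time=(1980, 1, 1, 0, 0, 0)),
                archive.payload[location],
            )
    return buffer.getvalue()


# ---------------------------------------------------------------------------
# Sabotage stubs (negative controls for the suite itself)

SABOTAGE_KINDS = (
    "nonzero_exit",
    "no_outputs",
    "missing_report",
    "wrong_shape",
    "bad_log",
    "wrong_values",
)

#: stub -> the one failure code it must trigger
SABOTAGE_EXPECTED_CODE = {
    "nonzero_exit": "EXIT_NONZERO",
    "no_outputs": "MISSING_REPORT",
    "missing_report": "MISSING_REPORT",
    "wrong_shape": "WRONG_SHAPE",
    "bad_log": "BAD_LOG",
    "wrong_values": "VALUE_MISMATCH",
}

_STUB_TEMPLATE = '''\
import sys
kind = {kind!r}
archive, outdir = sys.argv[1], sys.argv[2]
if kind == "nonzero_exit":
    sys.exit(3)
if kind == "no_outputs":
    sys.exit(0)
from simex.engine import ExecutionOptions, execute_archive
execute_archive(archive, ExecutionOptions(out_dir=outdir))
import os
import h5py
h5_path = os.path.join(outdir, "reports.h5")
if kind == "missing_report":
    with h5py.File(h5_path, "w") as f:
        f.attrs["schema_version"] = "1"
elif kind == "wrong_shape":
    _edit(h5_path, lambda m: m[:, :-1])
elif kind == "wrong_values":
    _edit(h5_path, lambda m: m * 1.5)
elif kind == "bad_log":
    with open(os.path.join(outdir, "log.yml"), "w") as f:
        f.write("status: DONE\\n")
sys.exit(0)
'''

_STUB_HELPER = '''\
def _edit(path, transform):
    import h5py
    names = []
    with h5py.File(path, "a") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                names.append(name)
        f.visititems(visit)
        for name in names:
            data = transform(f[name][()])
            attrs = dict(f[name].attrs)
            del f[name]
            ds = f.create_dataset(name, data=data)
            for key, value in attrs.items():
                ds.attrs[key] = value
'''


def sabotage_command(kind: str, directory: str) -> str:
    """Write a sabotage stub script; returns its command template."""
    if kind not in SABOTAGE_KINDS:
        raise SimexError("UNKNOWN_MUTATION", f"unknown sabotage kind {kind!r}")
    path = os.path.join(directory, f"stub_{kind}.py")
    with open(path, "w", encoding="utf-8") as f:
        f.write(_STUB_HELPER + _STUB_TEMPLATE.format(kind=kind))
    import sys

    return f'{shlex.quote(sys.executable)} {shlex.quote(path)} {{archive}} {{outdir}}'
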