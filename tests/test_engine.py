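"""Archive execution: orchestration, substitution, outputs and reproducibility."""

import math
import os

import numpy as np
import pytest

from simex import kernels, omex, sedml, validation
from simex.engine import (
    ExecutionOptions,
    ReportData,
    execute_archive,
    read_reports_h5,
    render_plots,
    write_reports_h5,
)
from simex._errors import SimexError
from simex.synthetic_models import (
    ArchiveOptions,
    SimulationRequest,
    build_archive,
    decay_model,
    isomerization_model,
    toggle_boolean_model,
)


def run(archive, tmp_path, subdir="out", **options):
    path = os.path.join(tmp_path, "a.omex")
    omex.write_archive(archive, path)
    return execute_archive(
        path, ExecutionOptions(out_dir=os.path.join(tmp_path, subdir), **options)
    )


def test_decay_execution_end_state(decay_archive, tmp_path):
    reports, log, files = run(decay_archive, tmp_path)
    assert log.status == "SUCCEEDED"
    report = reports[0]
    assert report.values.shape == (3, 11)  # time, S1, S2 over 10 intervals
    s1 = report.values[report.data_set_ids.index("ds_S1")]
    assert s1[-1] == pytest.approx(10.0 * math.exp(-5.0), abs=1e-4)


def test_substitution_is_logged(tmp_path):
    archive = build_archive(decay_model(), SimulationRequest("KISAO:0000019"))
    _, log, _ = run(archive, tmp_path)
    task = log.documents[0].tasks[0]
    assert task.requested_algorithm == "KISAO:0000019"
    assert task.used_algorithm == "KISAO:0000032"
    assert task.substitution_degree == 2
    assert log.status == "SUCCEEDED"


def test_strict_policy_fails_task_not_archive_io(tmp_path):
    archive = build_archive(decay_model(), SimulationRequest("KISAO:0000019"))
    _, log, _ = run(archive, tmp_path, policy_max_degree=0)
    task = log.documents[0].tasks[0]
    assert task.status == "FAILED"
    assert task.exception["category"] == "ALGORITHM_UNAVAILABLE"
    assert log.status == "FAILED"


def test_invalid_archive_fails_with_embedded_report(tmp_path, decay_archive):
    decay_archive.payload["sim.sedml"] = decay_archive.payload["sim.sedml"].replace(
        b'source="model.xml"', b'source="missing.xml"'
    )
    _, log, files = run(decay_archive, tmp_path)
    assert log.status == "FAILED"
    assert log.validation is not None
    assert any(
        i["code"] == "SEDML_MODEL_SOURCE_UNRESOLVED" for i in log.validation["issues"]
    )


def test_attribute_change_reaches_the_kernel(tmp_path):
    archive = build_archive(
        decay_model(),
        SimulationRequest("KISAO:0000032"),
        ArchiveOptions(with_changes=True, change_new_value="20"),
    )
    reports, log, _ = run(archive, tmp_path)
    s1 = reports[0].values[reports[0].data_set_ids.index("ds_S1")]
    assert s1[0] == pytest.approx(20.0)


def test_engine_equals_kernel_direct_bitwise(decay_archive, tmp_path):
    reports, _, _ = run(decay_archive, tmp_path)
    direct = kernels.simulate_ode(
        decay_model(), 0.0, 0.0, 10.0, 10, kernels.KernelConfig(algorithm=kernels.KISAO_RK4)
    )
    report = reports[0]
    assert np.array_equal(report.values[report.data_set_ids.index("ds_time")], direct.times)
    assert np.array_equal(report.values[report.data_set_ids.index("ds_S1")], direct.row("S1"))


def test_ssa_seed_parameter_reaches_the_kernel(tmp_path):
    archive = build_archive(
        isomerization_model(),
        SimulationRequest(
            "KISAO:0000029", output_end_time=5.0, number_of_points=20,
            parameters=[("KISAO:0000488", "42")],
        ),
    )
    reports, _, _ = run(archive, tmp_path)
    direct = kernels.simulate_ssa(
        isomerization_model(), 0.0, 0.0, 5.0, 20,
        kernels.KernelConfig(algorithm=kernels.KISAO_GILLESPIE, seed=42),
    )
    report = reports[0]
    assert np.array_equal(report.values[report.data_set_ids.index("ds_X")], direct.row("X"))


def test_boolean_document_executes(tmp_path):
    archive = build_archive(
        toggle_boolean_model(),
        SimulationRequest("KISAO:0000449", output_end_time=4.0, number_of_points=4),
    )
    reports, log, _ = run(archive, tmp_path)
    assert log.status == "SUCCEEDED"
    a_row = reports[0].values[reports[0].data_set_ids.index("ds_A")]
    assert a_row.tolist() == [1.0, 0.0, 0.0, 1.0, 1.0]


def test_rerun_is_bitwise_identical(decay_archive, tmp_path):
    reports1, log1, _ = run(decay_archive, tmp_path, subdir="out1")
    reports2, log2, _ = run(decay_archive, tmp_path, subdir="out2")
    assert np.array_equal(reports1[0].values, reports2[0].values)
    d1, d2 = log1.to_dict(), log2.to_dict()
    d1.pop("duration_s"), d2.pop("duration_s")
    assert d1 == d2


def test_log_yaml_passes_log_validation(decay_archive, tmp_path):
    _, _, files = run(decay_archive, tmp_path)
    log_path = next(f for f in files if f.endswith("log.yml"))
    with open(log_path, "rb") as f:
        assert validation.validate_log(f.read()).valid


class TestReportsH5:
    def test_round_trip_is_bitwise(self, tmp_path):
        values = np.random.default_rng(0).normal(size=(2, 11))
        report = ReportData("sub/sim.sedml", "report1", ["a", "b"], ["A", "B"], values)
        path = os.path.join(tmp_path, "r.h5")
        write_reports_h5([report], path)
        again = read_reports_h5(path)
        assert len(again) == 1
        assert again[0].sedml_location == "sub/sim.sedml"
        assert again[0].data_set_ids == ["a", "b"]
        assert again[0].labels == ["A", "B"]
        assert np.array_equal(again[0].values, values)

    def test_empty_report_list_writes_valid_file(self, tmp_path):
        path = os.path.join(tmp_path, "empty.h5")
        write_reports_h5([], path)
        assert read_reports_h5(path) == []


class TestPlots:
    def _doc(self):
        archive = build_archive(
            decay_model(), SimulationRequest("KISAO:0000032"), ArchiveOptions(with_plot=True)
        )
        return sedml.parse_sedml(archive.payload["sim.sedml"])

    def test_one_pdf_per_plot(self, tmp_path):
        doc = self._doc()
        values = {g.id: np.linspace(0, 1, 11) for g in doc.data_generators}
        paths = render_plots(doc, values, str(tmp_path))
        assert len(paths) == 1
        assert os.path.getsize(paths[0]) > 0

    def test_no_plots_no_files(self, tmp_path, decay_archive):
        doc = sedml.parse_sedml(decay_archive.payload["sim.sedml"])
        assert render_plots(doc, {}, str(tmp_path)) == []

    def test_missing_generator_raises(self, tmp_path):
        doc = self._doc()
        with pytest.raises(SimexError) as err:
            render_plots(doc, {}, str(tmp_path))
        assert err.value.code == "MISSING_GENERATOR"

    def test_plot_written_during_execution(self, tmp_path):
        archive = build_archive(
            decay_model(), SimulationRequest("KISAO:0000032"), ArchiveOptions(with_plot=True)
        )
        _, _, files = run(archive, tmp_path)
        assert any(f.endswith("plot1.pdf") for f in files)
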