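"""Project, simulator-spec and log validation; seeded defect detection."""

import json

import pytest
import yaml

from simex import omex, validation
from simex.registry import load_engine_spec
from simex.synthetic_models import (
    DEFECT_CLASSES,
    DEFECT_EXPECTED_CODES,
    defect_base_archive,
    inject_defect,
)


def write_bytes(tmp_path, name, data):
    path = tmp_path / name
    path.write_bytes(data)
    return str(path)


def test_pristine_archive_is_valid(decay_archive):
    report = validation.validate_project(decay_archive)
    assert report.valid
    assert report.errors() == []


def test_validation_is_deterministic_and_read_only(decay_archive):
    payload_before = dict(decay_archive.payload)
    first = validation.validate_project(decay_archive)
    second = validation.validate_project(decay_archive)
    assert first.to_dict() == second.to_dict()
    assert decay_archive.payload == payload_before


@pytest.mark.parametrize("defect", DEFECT_CLASSES)
def test_each_seeded_defect_is_flagged_with_its_code(defect, tmp_path):
    data, expected = inject_defect(defect_base_archive(seed=3), defect)
    report = validation.validate_archive_file(write_bytes(tmp_path, "bad.omex", data))
    assert not report.valid
    assert expected in report.codes()
    assert expected == DEFECT_EXPECTED_CODES[defect]


def test_all_defects_accumulate_in_one_pass(decay_archive):
    """Two independent defects in one archive produce two issues, not one."""
    sed = decay_archive.payload["sim.sedml"]
    sed = sed.replace(b'initialTime="0.0"', b'initialTime="5.0"')
    sed = sed.replace(b'kisaoID="KISAO:0000032"', b'kisaoID="KISAO:32"')
    decay_archive.payload["sim.sedml"] = sed
    report = validation.validate_project(decay_archive)
    assert {"SEDML_TIME_ORDER_INVALID", "SEDML_ALGORITHM_ID_INVALID"} <= set(report.codes())


def test_change_can_create_validity(decay_archive):
    """Variable targets are checked against the model after changes apply."""
    # the change is applied before targets are resolved, so a change that
    # renames nothing but sets an attribute leaves targets resolvable
    report = validation.validate_project(decay_archive)
    assert report.valid


class TestSimulatorSpecValidation:
    def test_bundled_engine_spec_is_valid(self):
        raw = json.dumps(
            {
                "id": "simex",
                "version": "0.1.0",
                "model_formats": [omex.FORMAT_SBML],
                "frameworks": ["SBO:0000293"],
                "algorithms": [{"kisao_id": "KISAO:0000032", "parameters": []}],
            }
        ).encode()
        assert validation.validate_simulator_spec(raw).valid
        assert load_engine_spec() is not None

    def test_short_kisao_id_flagged(self):
        spec = {
            "id": "t",
            "version": "1",
            "model_formats": [],
            "frameworks": [],
            "algorithms": [{"kisao_id": "KISAO_12"}],
        }
        report = validation.validate_simulator_spec(spec)
        assert "SPEC_KISAO_PATTERN" in report.codes()

    def test_missing_version_flagged(self):
        spec = {"id": "t", "model_formats": [], "frameworks": [], "algorithms": []}
        report = validation.validate_simulator_spec(spec)
        assert "SPEC_MISSING_FIELD" in report.codes()

    def test_bad_tool_id_flagged(self):
        spec = {"id": "Bad_ID", "version": "1", "model_formats": [], "frameworks": [],
                "algorithms": []}
        assert "SPEC_BAD_ID" in validation.validate_simulator_spec(spec).codes()

    def test_bad_parameter_data_type_flagged(self):
        spec = {
            "id": "t",
            "version": "1",
            "model_formats": [],
            "frameworks": [],
            "algorithms": [
                {"kisao_id": "KISAO:0000032",
                 "parameters": [{"kisao_id": "KISAO:0000488", "data_type": "complex"}]}
            ],
        }
        assert "SPEC_BAD_DATA_TYPE" in validation.validate_simulator_spec(spec).codes()


class TestLogValidation:
    GOOD = {
        "status": "SUCCEEDED",
        "duration_s": 0.1,
        "documents": [
            {
                "location": "sim.sedml",
                "status": "SUCCEEDED",
                "tasks": [{"id": "task1", "status": "SUCCEEDED"}],
                "outputs": [{"id": "report1", "status": "SUCCEEDED"}],
            }
        ],
    }

    def test_good_log_valid(self):
        assert validation.validate_log(yaml.safe_dump(self.GOOD).encode()).valid

    def test_unknown_status_flagged(self):
        bad = dict(self.GOOD, status="DONE")
        assert "LOG_BAD_STATUS" in validation.validate_log(bad).codes()

    def test_empty_document_flagged(self):
        assert "LOG_MISSING_ROOT" in validation.validate_log(b"").codes()

    def test_failed_task_requires_exception(self):
        bad = yaml.safe_load(yaml.safe_dump(self.GOOD))
        bad["documents"][0]["tasks"][0]["status"] = "FAILED"
        assert "LOG_BAD_EXCEPTION" in validation.validate_log(bad).codes()
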