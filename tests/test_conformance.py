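"""Conformance suite: corpus generation, case selection, mutations, grading."""

import numpy as np
import pytest

from simex import omex, validation
from simex._errors import SimexError
from simex.conformance import (
    MUTATION_CLASSES,
    SABOTAGE_EXPECTED_CODE,
    generate_fixture_corpus,
    mutate_archive,
    run_conformance,
    sabotage_command,
    select_cases,
)
from simex.registry import SimulatorSpec, load_engine_spec


def ode_only_spec():
    return SimulatorSpec.from_json(
        {
            "id": "ode-only",
            "version": "1",
            "model_formats": [omex.FORMAT_SBML],
            "frameworks": ["SBO:0000293"],
            "algorithms": [{"kisao_id": "KISAO:0000032", "parameters": []}],
        }
    )


def test_corpus_is_seed_deterministic():
    a = generate_fixture_corpus(5)
    b = generate_fixture_corpus(5)
    assert [c.id for c in a] == [c.id for c in b]
    for ca, cb in zip(a, b):
        assert ca.to_bytes() == cb.to_bytes()


def test_every_corpus_archive_validates():
    for case in generate_fixture_corpus(2):
        report = validation.validate_project(case.archive)
        assert report.valid, (case.id, report.codes())


def test_curated_ode_expectation_has_eleven_columns():
    case = next(c for c in generate_fixture_corpus(1) if c.id == "curated/ode-decay")
    assert case.expected.n_points == 11
    assert case.expected.reference.shape == (3, 11)


def test_selection_filters_by_capabilities(ontology):
    corpus = generate_fixture_corpus(1)
    selected = {c.id for c in select_cases(ode_only_spec(), corpus, ontology)}
    assert "curated/ode-decay" in selected
    assert not any("boolean" in cid for cid in selected)
    assert not any("ssa" in cid for cid in selected)


def test_engine_spec_selects_all_curated_cases(ontology):
    corpus = generate_fixture_corpus(1)
    selected = {c.id for c in select_cases(load_engine_spec(), corpus, ontology)}
    assert {c.id for c in corpus if c.id.startswith("curated/")} <= selected


def test_empty_algorithm_spec_selects_nothing(ontology):
    spec = SimulatorSpec.from_json(
        {"id": "noop", "version": "1", "model_formats": [omex.FORMAT_SBML],
         "frameworks": [], "algorithms": []}
    )
    assert select_cases(spec, generate_fixture_corpus(1), ontology) == []


def test_unselected_cases_reported_as_skipped(engine_command):
    corpus = [c for c in generate_fixture_corpus(1) if "boolean" in c.id][:1]
    report = run_conformance(engine_command, corpus, spec=ode_only_spec())
    assert report.cases[0].status == "SKIPPED"


def test_engine_passes_a_curated_case_via_cli(engine_command):
    case = next(c for c in generate_fixture_corpus(1) if c.id == "curated/change-applied")
    report = run_conformance(engine_command, [case])
    assert report.cases[0].status == "PASS", report.cases[0].failure_codes


def test_unknown_command_raises(decay_archive):
    case = next(c for c in generate_fixture_corpus(1) if c.id == "curated/ode-decay")
    with pytest.raises(SimexError) as err:
        run_conformance("/no/such/binary {archive} {outdir}", [case])
    assert err.value.code == "COMMAND_NOT_FOUND"


class TestMutations:
    @pytest.fixture()
    def ode_case(self):
        return next(c for c in generate_fixture_corpus(1) if c.id == "curated/ode-decay")

    def test_unknown_mutation_rejected(self, ode_case):
        with pytest.raises(SimexError) as err:
            mutate_archive(ode_case, "no-such-mutation")
        assert err.value.code == "UNKNOWN_MUTATION"

    def test_swap_algorithm_keeps_case_executable(self, ode_case, engine_command):
        mutated = mutate_archive(ode_case, "swap_algorithm_degree2")
        assert mutated.required_kisao == "KISAO:0000019"
        report = run_conformance(engine_command, [mutated])
        assert report.cases[0].status == "PASS", report.cases[0].failure_codes

    def test_break_target_expects_validation_error(self, ode_case, engine_command):
        mutated = mutate_archive(ode_case, "break_variable_target")
        assert mutated.expected.validation_error == "SEDML_TARGET_UNRESOLVED"
        report = run_conformance(engine_command, [mutated])
        assert report.cases[0].status == "PASS"  # the validator flags it as designed

    def test_reorder_manifest_is_order_insensitive(self, ode_case):
        mutated = mutate_archive(ode_case, "reorder_manifest")
        archive = omex.archive_from_bytes(mutated.to_bytes())
        assert validation.validate_project(archive).valid

    def test_rename_report_updates_expectation(self, ode_case):
        mutated = mutate_archive(ode_case, "rename_report_id")
        assert mutated.expected.report_path.endswith("reportX")


def test_one_sabotage_stub_fails_with_its_exact_code(tmp_path, engine_command):
    """A tool writing reports with one column too few must fail WRONG_SHAPE only."""
    case = next(c for c in generate_fixture_corpus(1) if c.id == "curated/ode-decay")
    command = sabotage_command("wrong_shape", str(tmp_path))
    report = run_conformance(command, [case])
    assert report.cases[0].status == "FAIL"
    assert report.cases[0].failure_codes == [SABOTAGE_EXPECTED_CODE["wrong_shape"]]


def test_report_json_shape():
    corpus = [c for c in generate_fixture_corpus(1) if c.id == "curated/ode-decay"]
    report = run_conformance("true", corpus)  # 'true' exits 0 writing nothing
    data = report.to_json()
    assert '"MISSING_REPORT"' in data
    assert report.summary["FAIL"] == 1
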