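"""Capability registry, project requirements and tool recommendation."""

import json
import random

import pytest

from simex import omex
from simex._errors import SimexError
from simex.kisao import substitution_degree
from simex.registry import (
    Registry,
    SimulatorSpec,
    TaskRequirement,
    load_engine_spec,
    load_registry,
    project_requirements,
    rank_tools,
    recommend_similar_algorithms,
    recommend_tools,
    same_format,
)
from simex.synthetic_models import SimulationRequest, build_archive, decay_model

CVODE = "KISAO:0000019"


def spec_doc(tool_id, formats, algorithms, version="1.0"):
    return {
        "id": tool_id,
        "version": version,
        "model_formats": formats,
        "frameworks": ["SBO:0000293"],
        "algorithms": [{"kisao_id": a, "parameters": []} for a in algorithms],
    }


def test_load_registry_of_three(tool_trio_registry):
    assert [s.id for s in tool_trio_registry.specs] == ["tool-a", "tool-b", "tool-c"]


def test_duplicate_spec_rejected():
    doc = spec_doc("tool-a", [omex.FORMAT_SBML], [CVODE])
    with pytest.raises(SimexError) as err:
        load_registry([doc, doc])
    assert err.value.code == "DUPLICATE_SPEC"


def test_invalid_spec_rejected():
    bad = spec_doc("tool-a", [omex.FORMAT_SBML], ["KISAO_12"])
    with pytest.raises(SimexError) as err:
        load_registry([bad])
    assert err.value.code == "SPEC_INVALID"


def test_engine_spec_loads_and_is_valid():
    spec = load_engine_spec()
    assert spec.id == "simex"
    assert "KISAO:0000029" in spec.algorithm_ids()


def test_format_family_matching():
    assert same_format(
        omex.FORMAT_SBML, "http://purl.org/NET/mediatypes/application/sbml+xml"
    )
    assert not same_format(omex.FORMAT_SBML, omex.FORMAT_BOOLNET)


def test_project_requirements_of_decay_fixture(decay_archive):
    requirements = project_requirements(decay_archive)
    assert requirements == [TaskRequirement("task1", omex.FORMAT_SBML, "KISAO:0000032")]


def test_requirements_reject_invalid_archive(decay_archive):
    decay_archive.payload["sim.sedml"] = decay_archive.payload["sim.sedml"].replace(
        b'simulationReference="sim1"', b'simulationReference="sim9"'
    )
    with pytest.raises(SimexError) as err:
        project_requirements(decay_archive)
    assert err.value.code == "PROJECT_INVALID"


class TestRecommendTools:
    def test_trio_example(self, tool_trio_registry, ontology):
        archive = build_archive(decay_model(), SimulationRequest(CVODE))
        recs = recommend_tools(archive, tool_trio_registry, ontology)
        assert [(r.tool_id, r.best_degree) for r in recs] == [("tool-a", 0), ("tool-b", 2)]

    def test_empty_registry(self, ontology, decay_archive):
        assert recommend_tools(decay_archive, Registry(), ontology) == []

    def test_worst_task_governs(self, tool_trio_registry, ontology):
        requirements = [
            TaskRequirement("t1", omex.FORMAT_SBML, CVODE),       # tool-a exact
            TaskRequirement("t2", omex.FORMAT_SBML, "KISAO:0000088"),  # tool-a at degree 2
        ]
        recs = rank_tools(requirements, tool_trio_registry, ontology)
        tool_a = next(r for r in recs if r.tool_id == "tool-a")
        assert tool_a.per_task["t1"][2] == 0
        assert tool_a.per_task["t2"][2] == 2
        assert tool_a.best_degree == 2

    def test_exact_match_tool_always_at_degree_zero(self, ontology):
        registry = load_registry([spec_doc("exact-tool", [omex.FORMAT_SBML], [CVODE])])
        recs = rank_tools(
            [TaskRequirement("t1", omex.FORMAT_SBML, CVODE)], registry, ontology
        )
        assert recs[0].best_degree == 0

    def test_stability_under_registry_extension(self, tool_trio_registry, ontology):
        requirements = [TaskRequirement("t1", omex.FORMAT_SBML, CVODE)]
        before = [r.tool_id for r in rank_tools(requirements, tool_trio_registry, ontology)]
        extended = Registry(
            specs=list(tool_trio_registry.specs)
            + [SimulatorSpec.from_json(spec_doc("zz-late", [omex.FORMAT_SBML], ["KISAO:0000030"]))]
        )
        after = [r.tool_id for r in rank_tools(requirements, extended, ontology)]
        assert [t for t in after if t in before] == before

    def test_matches_brute_force_on_200_random_instances(self, ontology):
        rng = random.Random(5)
        algorithms = ontology.algorithm_ids()
        formats = [omex.FORMAT_SBML, omex.FORMAT_BOOLNET]
        for _ in range(200):
            n_tools = rng.randint(0, 5)
            specs = []
            for i in range(n_tools):
                tool_formats = rng.sample(formats, rng.randint(1, 2))
                tool_algs = rng.sample(algorithms, rng.randint(1, 4))
                specs.append(SimulatorSpec.from_json(spec_doc(f"tool-{i}", tool_formats, tool_algs)))
            registry = Registry(specs=specs)
            requirements = [
                TaskRequirement(f"t{j}", rng.choice(formats), rng.choice(algorithms))
                for j in range(rng.randint(1, 3))
            ]
            policy = rng.choice([0, 1, 2])
            got = [(r.tool_id, r.best_degree) for r in rank_tools(requirements, registry, ontology, policy)]

            # brute force: nested loops over tools x tasks x algorithms
            expected = []
            for spec in specs:
                degrees = []
                ok = True
                for req in requirements:
                    if not any(same_format(req.model_format, f) for f in spec.model_formats):
                        ok = False
                        break
                    best = min(
                        (substitution_degree(req.kisao_id, a, ontology) for a in spec.algorithm_ids()),
                        default=99,
                    )
                    if best > policy:
                        ok = False
                        break
                    degrees.append(best)
                if ok:
                    expected.append((spec.id, max(degrees)))
            expected.sort(key=lambda p: (p[1], p[0]))
            assert got == expected


class TestRecommendSimilarAlgorithms:
    def test_cvode_over_trio(self, tool_trio_registry, ontology):
        pairs = recommend_similar_algorithms(CVODE, tool_trio_registry, ontology)
        assert pairs == [("tool-a", CVODE, 0), ("tool-b", "KISAO:0000088", 2)]

    def test_unknown_request(self, tool_trio_registry, ontology):
        with pytest.raises(SimexError) as err:
            recommend_similar_algorithms("KISAO:9999999", tool_trio_registry, ontology)
        assert err.value.code == "UNKNOWN_TERM"

    def test_no_kinetic_tools(self, ontology):
        registry = load_registry(
            [spec_doc("logic-only", [omex.FORMAT_BOOLNET], ["KISAO:0000449"])]
        )
        assert recommend_similar_algorithms(CVODE, registry, ontology) == []
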