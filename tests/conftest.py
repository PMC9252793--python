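"""Shared fixtures: archives, ontology, a three-tool registry, CLI command."""

from __future__ import annotations

import os
import sys

import pytest

from simex import omex
from simex.kisao import load_ontology
from simex.registry import load_registry
from simex.synthetic_models import SimulationRequest, build_archive, decay_model

KISAO_CVODE = "KISAO:0000019"
KISAO_LSODA = "KISAO:0000088"
KISAO_RK4 = "KISAO:0000032"
KISAO_ASYNC = "KISAO:0000450"


@pytest.fixture(scope="session")
def ontology():
    return load_ontology()


@pytest.fixture()
def decay_archive():
    """Exponential decay (S1 -> S2, k=0.5, S1(0)=10), RK4, 0..10 in 10 intervals."""
    return build_archive(decay_model(), SimulationRequest(KISAO_RK4))


@pytest.fixture()
def decay_archive_path(decay_archive, tmp_path):
    path = os.path.join(tmp_path, "decay.omex")
    omex.write_archive(decay_archive, path)
    return path


def _tool_spec(tool_id, formats, algorithms):
    return {
        "id": tool_id,
        "version": "1.0",
        "model_formats": list(formats),
        "frameworks": ["SBO:0000293"],
        "algorithms": [
            {"kisao_id": alg, "parameters": [], "supported_formats": list(formats)}
            for alg in algorithms
        ],
        "license": "MIT",
        "cli_available": False,
    }


@pytest.fixture(scope="session")
def tool_trio_registry():
    """tool-a: SBML+CVODE; tool-b: SBML+LSODA; tool-c: BoolNet+async logical."""
    return load_registry(
        [
            _tool_spec("tool-a", [omex.FORMAT_SBML], [KISAO_CVODE]),
            _tool_spec("tool-b", [omex.FORMAT_SBML], [KISAO_LSODA]),
            _tool_spec("tool-c", [omex.FORMAT_BOOLNET], [KISAO_ASYNC]),
        ]
    )


@pytest.fixture(scope="session")
def engine_command():
    """The reference engine's standardized CLI, as a conformance command template."""
    return f"{sys.executable} -m simex.cli execute -i {{archive}} -o {{outdir}}"
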