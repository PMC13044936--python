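"""Shared fixtures: bare projects, template projects, small tool helpers."""

from __future__ import annotations

import sys
import textwrap
from pathlib import Path

import pytest

from mdflow.cwl import parse_tool
from mdflow.model import CommandStep, Workflow, init_project_layout, new_workflow
from mdflow.targets import TargetsTable, make_targets
from mdflow.templates import init_template


@pytest.fixture
def project(tmp_path: Path) -> Path:
    """Bare project directory with the standard layout."""
    return init_project_layout(tmp_path / "proj")


@pytest.fixture
def workflow(project: Path) -> Workflow:
    return new_workflow(project)


@pytest.fixture
def targets2() -> TargetsTable:
    """Two-sample sheet with a metadata factor."""
    return make_targets(
        ["S1", "S2"],
        extra={"FileName": ["data/S1.fq", "data/S2.fq"], "Factor": ["A", "B"]},
        comments=["# toy cohort"],
    )


#: CWL description of a python-backed echo-like tool used across tests;
#: it writes its --out argument and succeeds, letting tests drive real
#: subprocesses without external binaries.
PYTOOL_YAML = textwrap.dedent(
    f"""\
    cwlVersion: v1.2
    class: CommandLineTool
    baseCommand: [{sys.executable}, -c, "import sys;open(sys.argv[2],'w').write(sys.argv[1])"]
    inputs:
      payload:
        type: string
        inputBinding: {{position: 1}}
      outfile:
        type: string
        inputBinding: {{position: 2}}
    outputs:
      out:
        type: File
        outputBinding: {{glob: _SampleName_.txt}}
    """
)


def make_command_step(
    step_id: str,
    targets: TargetsTable,
    deps: list[str] | None = None,
    tool_yaml: str = PYTOOL_YAML,
    values: dict | None = None,
) -> CommandStep:
    tool = parse_tool(tool_yaml, tool_id=step_id)
    return CommandStep(
        id=step_id,
        deps=deps or [],
        tool=tool,
        targets=targets,
        values=values
        or {"payload": "hello-_SampleName_", "outfile": "results/_SampleName_.txt"},
    )


@pytest.fixture
def skeleton_project(tmp_path: Path) -> Path:
    return init_template("skeleton", tmp_path / "skel", seed=7)


@pytest.fixture(scope="session")
def varseq_run(tmp_path_factory: pytest.TempPathFactory):
    """One fully executed varseq_mock project shared across tests."""
    from mdflow.engine import run
    from mdflow.literate import import_workflow, parse_doc

    proj = init_template("varseq_mock", tmp_path_factory.mktemp("vs") / "varseq", seed=3)
    doc = parse_doc(proj / "workflow.md")
    wf = import_workflow(doc, proj)
    run(wf)
    return proj, wf, doc
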