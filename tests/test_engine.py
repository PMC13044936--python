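"""Execution engine: runs, unit semantics, resume, persistence, policies."""

from __future__ import annotations

import json
import sys
import textwrap

import pytest

from mdflow.engine import (
    ALL,
    CodeSession,
    ExecutionUnit,
    ExecutorRef,
    RunRequest,
    execute_code_unit,
    execute_command_unit,
    plan_resume_units,
    run,
)
from mdflow.errors import RunPreconditionError, StateError, WorkflowDefinitionError
from mdflow.literate import import_workflow, parse_doc
from mdflow.model import CodeStep, ResourceSpec, new_workflow
from mdflow.state import load_state, save_state
from mdflow.targets import make_targets

from conftest import make_command_step


def pytool(code: str, glob: str = "_SampleName_.txt", stdout: str | None = None) -> str:
    """CWL for an inline python -c tool (argv[1:] reach the snippet)."""
    doc = textwrap.dedent(
        f"""\
        cwlVersion: v1.2
        class: CommandLineTool
        baseCommand: [{sys.executable}, -c, {json.dumps(code)}]
        inputs:
          a: {{type: string, inputBinding: {{position: 1}}}}
          b: {{type: 'string?', inputBinding: {{position: 2}}}}
        outputs:
          out:
            type: File
            outputBinding: {{glob: {glob}}}
        """
    )
    if stdout:
        doc += f"stdout: {stdout}\n"
    return doc


WRITER = "import sys;open(sys.argv[2],'w').write(sys.argv[1])"
FAILER = "import sys;sys.exit(1)"
NOOP = "pass"


def single_targets():
    return make_targets(["S1"], extra={"FileName": ["data/S1.fq"]})


class TestExecuteCommandUnit:
    def run_one(self, workflow, tool_yaml, values):
        step = make_command_step("s", single_targets(), tool_yaml=tool_yaml,
                                 values=values)
        workflow.append_step(step)
        unit = ExecutionUnit(
            "s", "S1", step.command_for("S1"),
            workflow.state_dir / "logs/s/S1.out",
            workflow.state_dir / "logs/s/S1.err",
        )
        return execute_command_unit(workflow, unit, ResourceSpec())

    def test_stdout_capture_success(self, workflow):
        tool_yaml = textwrap.dedent(
            f"""\
            cwlVersion: v1.2
            class: CommandLineTool
            baseCommand: [{sys.executable}, -c, "print('hi', end='')"]
            inputs: {{}}
            stdout: x.txt
            outputs:
              out: {{type: stdout}}
            """
        )
        step = make_command_step("echoer", make_targets(["S1"]),
                                 tool_yaml=tool_yaml, values={})
        workflow.append_step(step)
        unit = ExecutionUnit(
            "echoer", "S1", step.command_for("S1"),
            workflow.state_dir / "logs/echoer/S1.out",
            workflow.state_dir / "logs/echoer/S1.err",
        )
        status = execute_command_unit(workflow, unit, ResourceSpec())
        assert status.state == "success"
        assert (workflow.project_dir / "results/x.txt").read_text() == "hi"

    def test_nonzero_exit_is_error(self, workflow):
        status = self.run_one(workflow, pytool(FAILER), {"a": "x", "b": "y"})
        assert status.state == "error"

    def test_clean_exit_missing_output_is_warning(self, workflow):
        status = self.run_one(workflow, pytool(NOOP), {"a": "x"})
        assert status.state == "warning"

    def test_outputs_present_is_success(self, workflow):
        status = self.run_one(
            workflow, pytool(WRITER), {"a": "payload", "b": "results/S1.txt"}
        )
        assert status.state == "success"
        assert (workflow.project_dir / "results/S1.txt").read_text() == "payload"
        assert status.duration_s is not None and status.argv[0] == sys.executable

    def test_unresolvable_executable_logged(self, workflow):
        tool_yaml = textwrap.dedent(
            """\
            cwlVersion: v1.2
            class: CommandLineTool
            baseCommand: [no-such-binary-anywhere]
            inputs: {}
            outputs: {}
            """
        )
        step = make_command_step("ghost", make_targets(["S1"]),
                                 tool_yaml=tool_yaml, values={})
        workflow.append_step(step)
        err = workflow.state_dir / "logs/ghost/S1.err"
        unit = ExecutionUnit("ghost", "S1", step.command_for("S1"),
                             workflow.state_dir / "logs/ghost/S1.out", err)
        status = execute_command_unit(workflow, unit, ResourceSpec())
        assert status.state == "error"
        assert "not found" in err.read_text()


class TestExecuteCodeUnit:
    def make_unit(self, workflow, sid, code):
        workflow.append_step(CodeStep(id=sid, code=code))
        return ExecutionUnit(
            sid, "_step_", code,
            workflow.state_dir / f"logs/{sid}/_step_.out",
            workflow.state_dir / f"logs/{sid}/_step_.err",
        )

    def test_session_shares_names_across_steps(self, workflow):
        session = CodeSession(workflow.project_dir)
        u1 = self.make_unit(workflow, "one", "x = 2\n")
        u2 = self.make_unit(
            workflow, "two",
            "with open('results/val.txt', 'w') as fh:\n    fh.write(str(x + 3))\n",
        )
        assert execute_code_unit(workflow, u1, session).state == "success"
        assert execute_code_unit(workflow, u2, session).state == "success"
        assert (workflow.project_dir / "results/val.txt").read_text() == "5"

    def test_exception_is_error_with_traceback(self, workflow):
        session = CodeSession(workflow.project_dir)
        unit = self.make_unit(workflow, "boom", "raise ValueError('nope')\n")
        status = execute_code_unit(workflow, unit, session)
        assert status.state == "error"
        err = (workflow.project_dir / status.log_err).read_text()
        assert "Traceback" in err and "nope" in err

    def test_warning_demotes_state(self, workflow):
        session = CodeSession(workflow.project_dir)
        unit = self.make_unit(
            workflow, "warns", "import warnings\nwarnings.warn('careful')\n"
        )
        assert execute_code_unit(workflow, unit, session).state == "warning"

    def test_artifacts_attributed(self, workflow):
        session = CodeSession(workflow.project_dir)
        unit = self.make_unit(
            workflow, "writer",
            "with open('results/a.tsv', 'w') as fh:\n    fh.write('x\\n')\n",
        )
        status = execute_code_unit(workflow, unit, session)
        assert status.artifacts == ["results/a.tsv"]


def load_workflow(project):
    return import_workflow(parse_doc(project / "workflow.md"), project)


def unit_dep_graph(wf):
    """Brute-force unit-level dependency edges (oracle for resume tests)."""
    edges = set()
    for sid, step in wf.steps.items():
        for sample in step.samples:
            for dep in step.deps:
                dep_samples = wf.steps[dep].samples
                targets = [sample] if sample in dep_samples else dep_samples
                for ds in targets:
                    edges.add(((dep, ds), (sid, sample)))
    return edges


def downstream_units(wf, seeds):
    edges = unit_dep_graph(wf)
    reach = set(seeds)
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            if a in reach and b not in reach:
                reach.add(b)
                changed = True
    return reach


class TestRun:
    def test_fresh_chain_all_success(self, skeleton_project):
        wf = load_workflow(skeleton_project)
        status = run(wf)
        assert all(u.state == "success" for _, _, u in status.units())
        assert (skeleton_project / "results/S1.count.txt").exists()
        assert (skeleton_project / "results/summary.txt").exists()

    def test_resume_is_idempotent(self, skeleton_project):
        run(load_workflow(skeleton_project))
        wf = load_workflow(skeleton_project)
        run(wf, RunRequest(resume=True))
        assert wf.run_meta["executed_units"] == 0

    def test_invalidation_reruns_exact_downstream_closure(self, skeleton_project):
        run(load_workflow(skeleton_project))
        (skeleton_project / "results/S2.count.txt").unlink()
        wf = load_workflow(skeleton_project)
        planned = set(plan_resume_units(wf, wf.steps, ALL))
        expected = downstream_units(wf, {("count_reads", "S2")})
        assert planned == expected
        run(wf, RunRequest(resume=True))
        assert wf.run_meta["executed_units"] == len(expected)
        assert (skeleton_project / "results/S2.count.txt").exists()

    def test_crash_safety_truncated_run(self, skeleton_project):
        """Units recorded success with intact outputs never re-execute."""
        wf = load_workflow(skeleton_project)
        run(wf, RunRequest(step_ids={"setup", "count_reads"}))  # partial ~ crash
        wf2 = load_workflow(skeleton_project)
        run(wf2, RunRequest(resume=True))
        planned_before = {
            (s, n)
            for s, n, u in wf2.status.units()
            if u.state == "success"
        }
        assert {("setup", "_step_")} <= planned_before
        # second full resume re-executes nothing
        wf3 = load_workflow(skeleton_project)
        run(wf3, RunRequest(resume=True))
        assert wf3.run_meta["executed_units"] == 0

    def test_serial_and_parallel_agree(self, tmp_path):
        from mdflow.templates import init_template

        p1 = init_template("skeleton", tmp_path / "a", seed=5)
        p2 = init_template("skeleton", tmp_path / "b", seed=5)
        wf1, wf2 = load_workflow(p1), load_workflow(p2)
        run(wf1, RunRequest(executor=ExecutorRef("serial", 1)))
        run(wf2, RunRequest(executor=ExecutorRef("local_parallel", 4)))
        s1 = {(s, n): u.state for s, n, u in wf1.status.units()}
        s2 = {(s, n): u.state for s, n, u in wf2.status.units()}
        assert s1 == s2

    def test_dry_run_purity(self, skeleton_project):
        def tree(root):
            return {
                str(p.relative_to(root)): p.read_bytes()
                for p in root.rglob("*")
                if p.is_file() and "dryrun.log" not in p.name
            }

        wf = load_workflow(skeleton_project)
        before = tree(skeleton_project)
        run(wf, RunRequest(dry_run=True))
        assert tree(skeleton_project) == before
        assert (skeleton_project / ".sprproject/dryrun.log").exists()
        assert wf.run_meta["executed_units"] == 0

    def test_units_start_after_dep_steps_finish(self, skeleton_project):
        wf = load_workflow(skeleton_project)
        run(wf)
        info = {(s, n): u for s, n, u in wf.status.units()}
        for sid, step in wf.steps.items():
            for dep in step.deps:
                dep_end = max(
                    u.started_at + u.duration_s
                    for (s, n), u in info.items()
                    if s == dep
                )
                starts = [u.started_at for (s, n), u in info.items() if s == sid]
                assert min(starts) >= dep_end - 1e-6

    def test_step_subset_must_be_upstream_closed(self, skeleton_project):
        wf = load_workflow(skeleton_project)
        with pytest.raises(RunPreconditionError, match="upstream-closed"):
            run(wf, RunRequest(step_ids={"normalize"}))

    def test_resume_covers_closure_gap(self, skeleton_project):
        run(load_workflow(skeleton_project))
        wf = load_workflow(skeleton_project)
        run(wf, RunRequest(step_ids={"normalize"}, resume=True))
        assert wf.run_meta["executed_units"] == 0

    def test_unknown_sample_rejected(self, skeleton_project):
        wf = load_workflow(skeleton_project)
        with pytest.raises(RunPreconditionError, match="S99"):
            run(wf, RunRequest(sample_filter={"S99"}))

    def test_sample_filter_restricts_units(self, skeleton_project):
        wf = load_workflow(skeleton_project)
        run(wf, RunRequest(sample_filter={"S1"}))
        states = {(s, n): u.state for s, n, u in wf.status.units()}
        assert states[("count_reads", "S1")] == "success"
        assert states[("count_reads", "S2")] == "pending"


class TestFailurePolicy:
    def build_branching(self, workflow):
        """fail_branch errors; ok_branch is independent and must continue."""
        workflow.append_step(CodeStep(id="root", code="pass\n"))
        workflow.append_step(
            CodeStep(id="bad", deps=["root"], code="raise RuntimeError('x')\n")
        )
        workflow.append_step(CodeStep(id="bad_child", deps=["bad"], code="pass\n"))
        workflow.append_step(CodeStep(id="ok", deps=["root"], code="pass\n"))
        return workflow

    def test_downstream_cancelled_independent_continues(self, workflow):
        wf = self.build_branching(workflow)
        run(wf)
        states = {s: wf.status.step_state(s) for s in wf.steps}
        assert states["bad"] == "error"
        assert states["bad_child"] == "pending"  # cancelled, never ran
        assert states["ok"] == "success"
        assert wf.run_meta["cancelled_steps"] == ["bad_child"]

    def test_halt_all_stops_everything(self, workflow):
        wf = self.build_branching(workflow)
        run(wf, RunRequest(halt_all=True))
        assert wf.status.step_state("ok") == "pending"


class TestStatePersistence:
    def test_save_then_load_equality(self, workflow):
        workflow.append_step(CodeStep(id="a", code="pass\n"))
        run(workflow)
        assert load_state(workflow.project_dir) == workflow.status

    def test_empty_project_loads_empty_matrix(self, project):
        assert len(load_state(project)) == 0

    def test_truncated_json_is_explicit_corruption(self, workflow):
        workflow.append_step(CodeStep(id="a", code="pass\n"))
        path = save_state(workflow)
        path.write_text(path.read_text()[: 40])
        with pytest.raises(StateError, match="corrupt"):
            load_state(workflow.project_dir)

    def test_ignore_state_resets(self, skeleton_project):
        run(load_workflow(skeleton_project))
        wf = load_workflow(skeleton_project)
        run(wf, RunRequest(ignore_state=True))
        assert wf.run_meta["executed_units"] == 8


class TestExecutorRef:
    def test_serial_requires_one_worker(self):
        with pytest.raises(WorkflowDefinitionError):
            ExecutorRef("serial", 4)

    def test_unknown_backend(self):
        with pytest.raises(WorkflowDefinitionError):
            ExecutorRef("slurm", 1)
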