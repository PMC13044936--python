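"""Workflow execution: scatter/gather runs, status tracking, resume.

Execution is unit-based: one :class:`ExecutionUnit` per (step, sample)
pair.  Steps run strictly in topological order; within a command step the
per-sample units may run concurrently (scatter) and the step always
completes before any dependent starts (gather).  Code steps execute in a
single persistent Python session per run, so later code steps see names
defined by earlier ones.

States: ``success`` requires exit code 0 *and* every expected output file
present — output existence is the only tool-agnostic completeness check
and the basis of resume.  Exit 0 with a missing declared output is a
``warning``; non-zero exit (or an unlaunchable executable) is ``error``.

Resume: a unit is skipped iff its recorded state is ``success``, all its
expected outputs exist on disk, and nothing upstream of it re-executes.
Deleting an intermediate output therefore re-runs exactly the downstream
closure of the invalidated unit.

The engine itself is deterministic; code steps wanting randomness must
seed themselves.
"""

from __future__ import annotations

import contextlib
import io
import subprocess
import time
import traceback
import warnings as _warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

from .cwl import RenderedCommand
from .errors import RunPreconditionError, StateError, WorkflowDefinitionError
from .model import (
    CODE_SAMPLE,
    CodeStep,
    CommandStep,
    ResourceSpec,
    StatusMatrix,
    UnitStatus,
    Workflow,
)
from .state import load_state, save_state

ALL = None  # sentinel: run everything / all samples

VERSION_PROBE_TIMEOUT_S = 5.0


@dataclass
class ExecutorRef:
    """Execution backend: serial or thread-parallel on the local machine.

    Remote/HPC schedulers are intentionally represented only by this
    contract (name + worker count); the engine ships local backends only.
    """

    name: str = "serial"
    max_workers: int = 1

    def __post_init__(self) -> None:
        if self.name not in ("serial", "local_parallel"):
            raise WorkflowDefinitionError(f"unknown executor {self.name!r}")
        if self.max_workers < 1:
            raise WorkflowDefinitionError("max_workers must be >= 1")
        if self.name == "serial" and self.max_workers != 1:
            raise WorkflowDefinitionError("serial executor requires max_workers=1")


@dataclass
class RunRequest:
    step_ids: set[str] | None = ALL
    sample_filter: set[str] | None = ALL
    resume: bool = False
    dry_run: bool = False
    executor: ExecutorRef = field(default_factory=ExecutorRef)
    halt_all: bool = False  # strict policy: first error cancels everything
    ignore_state: bool = False  # discard a corrupt/unwanted state store


@dataclass
class ExecutionUnit:
    step: str
    sample: str
    command: RenderedCommand | str  # rendered command or code body
    log_out: Path
    log_err: Path


class CodeSession:
    """Persistent namespace shared by all code steps of one run."""

    def __init__(self, project_dir: Path):
        self.project_dir = project_dir
        self.namespace: dict[str, Any] = {
            "__name__": "__mdflow_code__",
            "PROJECT_DIR": str(project_dir),
        }


def _unit_logs(wf: Workflow, step: str, sample: str) -> tuple[Path, Path]:
    log_dir = wf.state_dir / "logs" / step
    return log_dir / f"{sample}.out", log_dir / f"{sample}.err"


def _expected_output_files(wf: Workflow, cmd: RenderedCommand) -> dict[str, list[Path]]:
    """Resolve each expected-output pattern to matching files (may be empty)."""
    out: dict[str, list[Path]] = {}
    for oid, pattern in cmd.expected_outputs.items():
        p = Path(pattern)
        base = p if p.is_absolute() else wf.project_dir / p
        if any(ch in pattern for ch in "*?["):
            root = wf.project_dir if not p.is_absolute() else Path(p.anchor)
            rel = pattern if not p.is_absolute() else str(p.relative_to(p.anchor))
            out[oid] = sorted(root.glob(rel))
        else:
            out[oid] = [base] if base.exists() else []
    return out


def outputs_intact(wf: Workflow, step: CommandStep, sample: str) -> bool:
    cmd = step.command_for(sample)
    found = _expected_output_files(wf, cmd)
    if not all(found[oid] for oid in cmd.expected_outputs):
        return False
    if cmd.stdout_to is not None:
        path = Path(cmd.stdout_to)
        if not (path if path.is_absolute() else wf.project_dir / path).exists():
            return False
    return True


def _search_path(wf: Workflow) -> str:
    import os

    tools = wf.project_dir / "tools"
    parts = [str(tools)] if tools.is_dir() else []
    parts.append(os.environ.get("PATH", ""))
    return os.pathsep.join(parts)


def execute_command_unit(
    wf: Workflow, unit: ExecutionUnit, res: ResourceSpec
) -> UnitStatus:
    """Run one rendered command as a subprocess (never through a shell)."""
    import os

    cmd = unit.command
    assert isinstance(cmd, RenderedCommand)
    unit.log_out.parent.mkdir(parents=True, exist_ok=True)
    env = dict(os.environ)
    env["PATH"] = _search_path(wf)
    started = time.time()
    stdout_text = ""
    stderr_text = ""
    try:
        proc = subprocess.run(
            cmd.argv,
            cwd=wf.project_dir,
            env=env,
            capture_output=True,
            text=True,
            timeout=res.walltime_min * 60,
        )
        exit_code = proc.returncode
        stdout_text, stderr_text = proc.stdout, proc.stderr
    except FileNotFoundError as exc:
        exit_code = 127
        stderr_text = f"executable not found: {cmd.argv[0]} ({exc})\n"
    except subprocess.TimeoutExpired as exc:
        exit_code = 124
        stderr_text = f"walltime exceeded ({res.walltime_min} min): {exc}\n"
    duration = time.time() - started

    if cmd.stdout_to is not None and exit_code == 0:
        target = Path(cmd.stdout_to)
        target = target if target.is_absolute() else wf.project_dir / target
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(stdout_text, encoding="utf-8")
        unit.log_out.write_text(
            f"(stdout redirected to {cmd.stdout_to})\n", encoding="utf-8"
        )
    else:
        unit.log_out.write_text(stdout_text, encoding="utf-8")
    unit.log_err.write_text(stderr_text, encoding="utf-8")

    if exit_code != 0:
        state = "error"
    elif outputs_intact(wf, wf.steps[unit.step], unit.sample):
        state = "success"
    else:
        state = "warning"  # clean exit but a declared output never appeared

    artifacts: list[str] = []
    for files in _expected_output_files(wf, cmd).values():
        for f in files:
            try:
                artifacts.append(str(f.relative_to(wf.project_dir)))
            except ValueError:
                artifacts.append(str(f))
    if cmd.stdout_to is not None and cmd.stdout_to not in artifacts:
        artifacts.append(cmd.stdout_to)
    return UnitStatus(
        state=state,
        started_at=started,
        duration_s=duration,
        argv=list(cmd.argv),
        log_out=str(unit.log_out.relative_to(wf.project_dir)),
        log_err=str(unit.log_err.relative_to(wf.project_dir)),
        artifacts=sorted(set(artifacts)),
    )


def execute_code_unit(
    wf: Workflow, unit: ExecutionUnit, session: CodeSession
) -> UnitStatus:
    """Evaluate a code step's body inside the shared session."""
    assert isinstance(unit.command, str)
    unit.log_out.parent.mkdir(parents=True, exist_ok=True)
    out_buf, err_buf = io.StringIO(), io.StringIO()
    results_dir = wf.project_dir / "results"
    before = _results_snapshot(results_dir)
    started = time.time()
    state = "success"
    with contextlib.chdir(wf.project_dir):
        with contextlib.redirect_stdout(out_buf), contextlib.redirect_stderr(err_buf):
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                try:
                    exec(compile(unit.command, f"<step {unit.step}>", "exec"),
                         session.namespace)
                except Exception:
                    state = "error"
                    err_buf.write(traceback.format_exc())
    # interpreter housekeeping noise does not demote a unit to "warning"
    ignored = (ResourceWarning, DeprecationWarning, PendingDeprecationWarning,
               ImportWarning, BytesWarning)
    relevant = [w for w in caught if not issubclass(w.category, ignored)]
    if state == "success" and relevant:
        state = "warning"
    for w in relevant:
        err_buf.write(f"warning: {w.message}\n")
    duration = time.time() - started
    unit.log_out.write_text(out_buf.getvalue(), encoding="utf-8")
    unit.log_err.write_text(err_buf.getvalue(), encoding="utf-8")
    after = _results_snapshot(results_dir)
    written = sorted(
        str((results_dir / f).relative_to(wf.project_dir))
        for f in after
        if f not in before or after[f] != before[f]
    )
    return UnitStatus(
        state=state,
        started_at=started,
        duration_s=duration,
        argv=None,
        log_out=str(unit.log_out.relative_to(wf.project_dir)),
        log_err=str(unit.log_err.relative_to(wf.project_dir)),
        artifacts=written,
    )


def _results_snapshot(results_dir: Path) -> dict[str, float]:
    """File → mtime map of the results tree (artifact attribution)."""
    if not results_dir.is_dir():
        return {}
    return {
        str(p.relative_to(results_dir)): p.stat().st_mtime
        for p in results_dir.rglob("*")
        if p.is_file()
    }


# ---------------------------------------------------------------------------
# scheduling
# ---------------------------------------------------------------------------

def _unit_deps(wf: Workflow, step_id: str, sample: str) -> list[tuple[str, str]]:
    """Sample-aware unit lineage.

    A per-sample unit depends on the same-sample unit of each dependency
    step when that step carries the sample, otherwise on every unit of
    the dependency (gather semantics).
    """
    deps: list[tuple[str, str]] = []
    for dep in wf.steps[step_id].deps:
        dep_samples = wf.steps[dep].samples
        if sample in dep_samples:
            deps.append((dep, sample))
        else:
            deps.extend((dep, s) for s in dep_samples)
    return deps


def plan_resume_units(
    wf: Workflow,
    step_ids: Iterable[str],
    sample_filter: set[str] | None = ALL,
) -> list[tuple[str, str]]:
    """Units that must re-execute under resume semantics.

    A unit is invalid if its recorded state is not ``success`` or any of
    its expected outputs is missing; invalidity propagates along the
    sample-aware unit-dependency relation.
    """
    requested = [s for s in wf.topological_order() if s in set(step_ids)]
    rerun: set[tuple[str, str]] = set()
    plan: list[tuple[str, str]] = []
    for sid in requested:
        step = wf.steps[sid]
        for sample in step.samples:
            if (
                sample_filter is not ALL
                and sample != CODE_SAMPLE
                and sample not in sample_filter
            ):
                continue
            key = (sid, sample)
            invalid = False
            if key not in wf.status or wf.status.get(sid, sample).state != "success":
                invalid = True
            elif isinstance(step, CommandStep) and not outputs_intact(wf, step, sample):
                invalid = True
            if not invalid and any(d in rerun for d in _unit_deps(wf, sid, sample)):
                invalid = True  # upstream re-ran: recompute downstream
            if invalid:
                rerun.add(key)
                plan.append(key)
    return plan


def _validate_request(wf: Workflow, req: RunRequest) -> list[str]:
    if req.step_ids is ALL:
        requested = set(wf.steps)
    else:
        requested = set(req.step_ids)
        unknown = requested - set(wf.steps)
        if unknown:
            raise RunPreconditionError(
                f"unknown step ids: {', '.join(sorted(unknown))}"
            )
    if req.sample_filter is not ALL:
        known = set()
        for step in wf.steps.values():
            known.update(step.samples)
        bad = set(req.sample_filter) - known
        if bad:
            raise RunPreconditionError(
                f"unknown sample names: {', '.join(sorted(bad))}"
            )
    # the requested set must be upstream-closed, unless resume can certify
    # the gap with previously recorded successes (outputs intact)
    gaps: list[str] = []
    for sid in requested:
        for dep in wf.steps[sid].deps:
            if dep in requested:
                continue
            if req.resume:
                dep_step = wf.steps[dep]
                ok = all(
                    (dep, s) in wf.status
                    and wf.status.get(dep, s).state == "success"
                    and (
                        not isinstance(dep_step, CommandStep)
                        or outputs_intact(wf, dep_step, s)
                    )
                    for s in dep_step.samples
                )
                if ok:
                    continue
            gaps.append(dep)
    if gaps:
        raise RunPreconditionError(
            "requested steps are not upstream-closed; missing (or not "
            f"successfully completed) dependencies: {', '.join(sorted(set(gaps)))}"
        )
    return [s for s in wf.topological_order() if s in requested]


def _capture_versions(wf: Workflow, executables: Iterable[str]) -> None:
    import os

    env = dict(os.environ)
    env["PATH"] = _search_path(wf)
    for exe in sorted(set(executables)):
        if exe in wf.versions:
            continue
        try:
            proc = subprocess.run(
                [exe, "--version"],
                capture_output=True,
                text=True,
                timeout=VERSION_PROBE_TIMEOUT_S,
                env=env,
                cwd=wf.project_dir,
            )
            line = (proc.stdout or proc.stderr).splitlines()
            wf.versions[exe] = line[0].strip() if line else "unknown"
        except (OSError, subprocess.TimeoutExpired):
            wf.versions[exe] = "unknown"


def run(wf: Workflow, req: RunRequest | None = None) -> StatusMatrix:
    """Execute (part of) a workflow; returns the updated status matrix."""
    req = req or RunRequest()
    if req.ignore_state:
        wf.status = StatusMatrix()
        for sid, step in wf.steps.items():
            for sample in step.samples:
                wf.status.set(sid, sample, UnitStatus(state="pending"))
    ordered = _validate_request(wf, req)

    if req.dry_run:
        return _dry_run(wf, ordered, req)

    if req.resume:
        to_run = set(plan_resume_units(wf, ordered, req.sample_filter))
    else:
        to_run = set()
        for sid in ordered:
            for sample in wf.steps[sid].samples:
                if (
                    req.sample_filter is ALL
                    or sample == CODE_SAMPLE
                    or sample in req.sample_filter
                ):
                    to_run.add((sid, sample))

    # reset scheduled units to pending before execution starts
    for sid, sample in to_run:
        wf.status.mark(sid, sample, "pending", started_at=None, duration_s=None)

    _capture_versions(
        wf,
        (
            wf.steps[sid].command_for(sample).argv[0]
            for sid, sample in to_run
            if isinstance(wf.steps[sid], CommandStep)
        ),
    )

    session = CodeSession(wf.project_dir)
    executed = 0
    skipped = len(
        [
            1
            for sid in ordered
            for s in wf.steps[sid].samples
            if (sid, s) not in to_run
        ]
    )
    cancelled: set[str] = set()  # steps whose pending units were cancelled
    run_started = time.time()
    wf.run_meta["run_id"] = f"run-{int(run_started)}"
    wf.run_meta["started_at"] = run_started

    halted = False
    for sid in ordered:
        step = wf.steps[sid]
        units = [
            (sid, sample) for sample in step.samples if (sid, sample) in to_run
        ]
        if halted or sid in cancelled:
            skipped += len(units)
            continue
        if not units:
            continue

        step_failed = False
        if isinstance(step, CodeStep):
            for sid_, sample in units:
                wf.status.mark(sid_, sample, "running", started_at=time.time())
                save_state(wf)
                unit = ExecutionUnit(
                    sid_, sample, step.code, *_unit_logs(wf, sid_, sample)
                )
                status = execute_code_unit(wf, unit, session)
                wf.status.set(sid_, sample, status)
                executed += 1
                save_state(wf)
                step_failed |= status.state == "error"
        else:
            assert isinstance(step, CommandStep)
            workers = (
                1
                if req.executor.name == "serial"
                else max(1, min(req.executor.max_workers, step.resources.cores * len(units)))
            )

            def _one(key: tuple[str, str]) -> tuple[tuple[str, str], UnitStatus]:
                sid_, sample = key
                unit = ExecutionUnit(
                    sid_,
                    sample,
                    step.command_for(sample),
                    *_unit_logs(wf, sid_, sample),
                )
                return key, execute_command_unit(wf, unit, step.resources)

            for key in units:
                wf.status.mark(*key, "running", started_at=time.time())
            save_state(wf)
            if workers == 1:
                results = [_one(k) for k in units]
            else:
                with ThreadPoolExecutor(max_workers=workers) as pool:
                    results = list(pool.map(_one, units))
            for (sid_, sample), status in results:
                wf.status.set(sid_, sample, status)
                executed += 1
                step_failed |= status.state == "error"
            save_state(wf)

        if step_failed:
            if req.halt_all:
                halted = True
            else:
                cancelled |= wf.dependency_closure({sid}, "downstream") - {sid}

    wf.run_meta["finished_at"] = time.time()
    wf.run_meta["executed_units"] = executed
    wf.run_meta["skipped_units"] = skipped
    wf.run_meta["cancelled_steps"] = sorted(cancelled)
    save_state(wf)
    return wf.status


def _dry_run(wf: Workflow, ordered: list[str], req: RunRequest) -> StatusMatrix:
    """Render and log the would-be commands; touch nothing, change no state."""
    lines = []
    for sid in ordered:
        step = wf.steps[sid]
        if isinstance(step, CommandStep):
            for cmd in step.commands:
                if (
                    req.sample_filter is ALL
                    or cmd.sample in req.sample_filter
                ):
                    lines.append(f"{sid}\t{cmd.sample}\t" + " ".join(cmd.argv))
        else:
            lines.append(f"{sid}\t{CODE_SAMPLE}\t<code: {len(step.code.splitlines())} lines>")
    wf.state_dir.mkdir(exist_ok=True)
    (wf.state_dir / "dryrun.log").write_text("\n".join(lines) + "\n", encoding="utf-8")
    wf.run_meta["executed_units"] = 0
    wf.run_meta["dry_run_units"] = len(lines)
    return wf.status


__all__ = [
    "ALL",
    "CodeSession",
    "ExecutionUnit",
    "ExecutorRef",
    "RunRequest",
    "execute_code_unit",
    "execute_command_unit",
    "load_state",
    "outputs_intact",
    "plan_resume_units",
    "run",
    "save_state",
]
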