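"""Central workflow-management object and its step/dependency algebra.

A :class:`Workflow` is an ordered registry of steps bound to a project
directory.  Steps are either :class:`CommandStep` (an external tool
described in CWL, executed once per sample of its targets table) or
:class:`CodeStep` (native Python source executed in a shared session,
tracked under the single pseudo-sample ``_step_``).

Acyclicity is guaranteed constructively: a step can only be appended
after every step it depends on, so the registry's iteration order is
always a valid topological order.  Deterministic orderings (lexicographic
tie-breaks) are used everywhere so that graphs and reports are
reproducible byte-for-byte.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Literal, Mapping

import networkx as nx

from .cwl import RenderedCommand, ToolDescription, render_step_commands
from .errors import ProjectError, WorkflowDefinitionError
from .targets import TargetsTable

STEP_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")
CODE_SAMPLE = "_step_"

#: severity used for per-step roll-up (worst state wins)
STATE_SEVERITY = {"error": 4, "warning": 3, "running": 2, "pending": 1, "success": 0}
STATES = frozenset(STATE_SEVERITY)

STATE_DIR = ".sprproject"
PROJECT_SUBDIRS = ("data", "results", "param")


def _check_step_id(step_id: str) -> str:
    if not STEP_ID_RE.match(step_id):
        raise WorkflowDefinitionError(
            f"invalid step id {step_id!r}: must match [A-Za-z][A-Za-z0-9_]*"
        )
    return step_id


@dataclass
class ResourceSpec:
    """Per-step resource request (local executors use only ``cores``)."""

    cores: int = 1
    memory_mb: int = 1024
    walltime_min: int = 60

    def __post_init__(self) -> None:
        for name in ("cores", "memory_mb", "walltime_min"):
            if getattr(self, name) < 1:
                raise WorkflowDefinitionError(f"ResourceSpec.{name} must be >= 1")


@dataclass
class Step:
    id: str
    deps: list[str] = field(default_factory=list)
    resources: ResourceSpec = field(default_factory=ResourceSpec)
    doc: str = ""
    run: bool = True

    def __post_init__(self) -> None:
        _check_step_id(self.id)
        if self.id in self.deps:
            raise WorkflowDefinitionError(f"step {self.id!r} depends on itself")
        if len(set(self.deps)) != len(self.deps):
            raise WorkflowDefinitionError(f"step {self.id!r}: duplicate deps")

    @property
    def kind(self) -> str:
        raise NotImplementedError

    @property
    def samples(self) -> list[str]:
        raise NotImplementedError


@dataclass
class CommandStep(Step):
    """External command-line step: CWL tool + job values + targets.

    ``commands`` holds one rendered invocation per targets row and is
    computed eagerly so that definition errors surface at append time.
    """

    tool: ToolDescription | None = None
    values: dict[str, Any] = field(default_factory=dict)
    targets: TargetsTable | None = None
    tool_source: str | None = None  # path of the CWL file, for export/reports
    targets_source: str | None = None  # path or upstream step id, for export
    outputs_map: dict[str, str] = field(default_factory=dict)
    commands: list[RenderedCommand] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.tool is None or self.targets is None:
            raise WorkflowDefinitionError(
                f"command step {self.id!r} requires a tool and a targets table"
            )
        if not self.commands:
            self.commands = render_step_commands(self.tool, self.values, self.targets)

    @property
    def kind(self) -> str:
        return "command"

    @property
    def samples(self) -> list[str]:
        assert self.targets is not None
        return self.targets.sample_names

    def command_for(self, sample: str) -> RenderedCommand:
        for cmd in self.commands:
            if cmd.sample == sample:
                return cmd
        raise WorkflowDefinitionError(f"step {self.id!r}: no sample {sample!r}")


@dataclass
class CodeStep(Step):
    """Native code step: Python source run in the engine's shared session."""

    code: str = ""

    @property
    def kind(self) -> str:
        return "code"

    @property
    def samples(self) -> list[str]:
        return [CODE_SAMPLE]


@dataclass
class UnitStatus:
    state: str = "pending"
    started_at: float | None = None
    duration_s: float | None = None
    argv: list[str] | None = None
    log_out: str | None = None
    log_err: str | None = None
    artifacts: list[str] | None = None  # project-relative files the unit wrote

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise WorkflowDefinitionError(f"unknown state {self.state!r}")
        if self.state == "pending" and self.duration_s is not None:
            raise WorkflowDefinitionError("pending unit cannot carry a duration")


class StatusMatrix:
    """Step × sample execution states with timing."""

    def __init__(self) -> None:
        self._units: dict[tuple[str, str], UnitStatus] = {}

    def set(self, step: str, sample: str, status: UnitStatus) -> None:
        self._units[(step, sample)] = status

    def get(self, step: str, sample: str) -> UnitStatus:
        return self._units[(step, sample)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._units

    def __len__(self) -> int:
        return len(self._units)

    def units(self) -> list[tuple[str, str, UnitStatus]]:
        return [(s, n, u) for (s, n), u in sorted(self._units.items())]

    def step_units(self, step: str) -> list[tuple[str, UnitStatus]]:
        return [(n, u) for (s, n), u in sorted(self._units.items()) if s == step]

    def mark(self, step: str, sample: str, state: str, **kw: Any) -> None:
        cur = self._units.get((step, sample), UnitStatus())
        self._units[(step, sample)] = replace(cur, state=state, **kw)

    def step_state(self, step: str) -> str:
        """Roll-up: worst sample state (error > warning > running > pending > success)."""
        states = [u.state for _, u in self.step_units(step)]
        if not states:
            return "pending"
        return max(states, key=lambda s: STATE_SEVERITY[s])

    def step_success_fraction(self, step: str) -> tuple[int, int]:
        units = self.step_units(step)
        return sum(1 for _, u in units if u.state == "success"), len(units)

    def copy(self) -> "StatusMatrix":
        out = StatusMatrix()
        out._units = {k: replace(v) for k, v in self._units.items()}
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StatusMatrix):
            return NotImplemented
        return self._units == other._units

    # -- (de)serialization --------------------------------------------
    def to_records(self) -> list[dict[str, Any]]:
        recs = []
        for (step, sample), u in sorted(self._units.items()):
            recs.append(
                {
                    "step": step,
                    "sample": sample,
                    "state": u.state,
                    "started_at": u.started_at,
                    "duration_s": u.duration_s,
                    "argv": u.argv,
                    "log_out": u.log_out,
                    "log_err": u.log_err,
                    "artifacts": u.artifacts,
                }
            )
        return recs

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, Any]]) -> "StatusMatrix":
        out = cls()
        for r in records:
            out.set(
                r["step"],
                r["sample"],
                UnitStatus(
                    state=r["state"],
                    started_at=r.get("started_at"),
                    duration_s=r.get("duration_s"),
                    argv=r.get("argv"),
                    log_out=r.get("log_out"),
                    log_err=r.get("log_err"),
                    artifacts=r.get("artifacts"),
                ),
            )
        return out


class Workflow:
    """Ordered step registry + dependency graph + status, bound to a project."""

    def __init__(self, project_dir: str | Path):
        self.project_dir = Path(project_dir).resolve()
        self.steps: dict[str, Step] = {}
        self.status = StatusMatrix()
        self.source_doc: Path | None = None
        self.versions: dict[str, str] = {}
        self.external_deps: dict[str, list[str]] = {}
        self.run_meta: dict[str, Any] = {}

    # -- construction ---------------------------------------------------
    def append_step(self, step: Step) -> "Workflow":
        if step.id in self.steps:
            raise WorkflowDefinitionError(f"duplicate step id {step.id!r}")
        missing = [d for d in step.deps if d not in self.steps]
        if missing:
            raise WorkflowDefinitionError(
                f"step {step.id!r}: unknown dependency "
                + ", ".join(repr(m) for m in missing)
            )
        self.steps[step.id] = step
        for sample in step.samples:
            if (step.id, sample) not in self.status:
                self.status.set(step.id, sample, UnitStatus(state="pending"))
        return self

    # -- graph algebra ----------------------------------------------------
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.steps)
        for step in self.steps.values():
            for dep in step.deps:
                g.add_edge(dep, step.id)
        return g

    def topological_order(self) -> list[str]:
        """Topological order with lexicographic tie-break on step id."""
        return list(nx.lexicographical_topological_sort(self.graph()))

    def dependency_closure(
        self, ids: Iterable[str], direction: Literal["upstream", "downstream"]
    ) -> set[str]:
        ids = set(ids)
        unknown = ids - set(self.steps)
        if unknown:
            raise WorkflowDefinitionError(
                f"unknown step ids: {', '.join(sorted(unknown))}"
            )
        g = self.graph()
        closure = set(ids)
        for i in ids:
            closure |= nx.descendants(g, i) if direction == "downstream" else nx.ancestors(g, i)
        return closure

    def subset_steps(
        self, ids: Iterable[str], allow_unclosed: bool = False
    ) -> "Workflow":
        """Restricted view of the workflow (original untouched)."""
        ids = set(ids)
        unknown = ids - set(self.steps)
        if unknown:
            raise WorkflowDefinitionError(
                f"unknown step ids: {', '.join(sorted(unknown))}"
            )
        missing_upstream = sorted(
            {d for i in ids for d in self.steps[i].deps if d not in ids}
        )
        if missing_upstream and not allow_unclosed:
            raise WorkflowDefinitionError(
                "subset is not closed under dependencies; missing upstream steps: "
                + ", ".join(missing_upstream)
            )
        sub = Workflow(self.project_dir)
        sub.source_doc = self.source_doc
        for sid in self.steps:  # preserve registry order
            if sid not in ids:
                continue
            step = self.steps[sid]
            kept = [d for d in step.deps if d in ids]
            external = [d for d in step.deps if d not in ids]
            sub.steps[sid] = replace(step, deps=kept)
            if external:
                sub.external_deps[sid] = external
            for sample, unit in self.status.step_units(sid):
                sub.status.set(sid, sample, replace(unit))
        return sub

    # -- conveniences ------------------------------------------------------
    @property
    def state_dir(self) -> Path:
        return self.project_dir / STATE_DIR

    def step_samples(self) -> dict[str, list[str]]:
        return {sid: step.samples for sid, step in self.steps.items()}

    def all_samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for step in self.steps.values():
            for s in step.samples:
                seen.setdefault(s, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.steps)

    def __repr__(self) -> str:
        return f"<Workflow {self.project_dir.name}: {len(self.steps)} steps>"


def init_project_layout(project_dir: str | Path) -> Path:
    """Create the standard project layout under *project_dir*."""
    project_dir = Path(project_dir)
    for sub in PROJECT_SUBDIRS:
        (project_dir / sub).mkdir(parents=True, exist_ok=True)
    (project_dir / STATE_DIR).mkdir(exist_ok=True)
    return project_dir


def new_workflow(project_dir: str | Path) -> Workflow:
    """Open a project directory as an empty :class:`Workflow`.

    Requires the standard layout (``data/``, ``results/``, ``param/``);
    creates the hidden state directory if absent and restores a
    previously persisted status matrix when one exists.
    """
    project_dir = Path(project_dir)
    if not project_dir.is_dir():
        raise ProjectError(f"project directory does not exist: {project_dir}")
    missing = [s for s in PROJECT_SUBDIRS if not (project_dir / s).is_dir()]
    if missing:
        raise ProjectError(
            f"{project_dir} lacks the project layout (missing: {', '.join(missing)})"
        )
    wf = Workflow(project_dir)
    wf.state_dir.mkdir(exist_ok=True)
    state_file = wf.state_dir / "status.json"
    if state_file.is_file():
        from .state import load_state

        wf.status = load_state(project_dir)
    return wf


def now() -> float:
    return time.time()
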