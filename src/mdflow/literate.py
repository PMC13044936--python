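"""Literate workflow documents: Markdown in, Workflow out, and back.

A workflow is defined in a CommonMark document whose *annotated* fenced
code blocks become steps.  The fence dialect is::

    ```{python step="qc" kind="code" deps="setup"}
    ...body...
    ```

Attributes: ``step`` (required for a fence to count as a step), ``kind``
(``cmd`` or ``code``, default ``code``), ``deps`` (comma-separated ids of
*earlier* chunks), ``run`` (``true``/``false``, default true; a false
chunk is kept as narrative and not imported).

``kind="cmd"`` chunk bodies are YAML mappings::

    tool: param/align.cwl          # CWL CommandLineTool file, or tool_inline:
    targets: targets.tsv           # path, or the id of an upstream step
    inputs: {reads: _FileName_}    # job values; _Column_ placeholders allowed
    outputs_map: {sam: FileName}   # upstream output id -> new targets column

When ``targets`` names an upstream step, the step's sample sheet is built
from that step's expected outputs via ``outputs_to_targets`` using
``outputs_map``.

Parsing is lossless: the concatenation of all segments reproduces the
source text exactly, which is what allows the scientific report to weave
results back into the original narrative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .cwl import ToolDescription, parse_tool, parse_tool_file
from .errors import LiterateError, WorkflowDefinitionError
from .model import CodeStep, CommandStep, ResourceSpec, Step, Workflow, new_workflow
from .targets import outputs_to_targets, read_targets

_FENCE_OPEN = re.compile(r"^(`{3,})\s*(\{(.*)\})?\s*$|^(`{3,})\s*([A-Za-z0-9_+-]*)\s*$")
_ATTR = re.compile(r'([A-Za-z_][A-Za-z0-9_]*)\s*=\s*"([^"]*)"')


@dataclass
class ChunkAnnotation:
    step: str
    kind: str = "code"  # "cmd" | "code"
    deps: list[str] = field(default_factory=list)
    run: bool = True
    lang: str = ""


@dataclass
class Segment:
    """One document slice: narrative text or an annotated step chunk."""

    text: str  # raw source slice (lossless)
    annotation: ChunkAnnotation | None = None
    body: str = ""  # chunk body without fences
    line: int = 0  # 1-based source line of the opening fence

    @property
    def is_step(self) -> bool:
        return self.annotation is not None


@dataclass
class LiterateDoc:
    segments: list[Segment]
    path: Path | None = None

    @property
    def steps(self) -> list[Segment]:
        return [s for s in self.segments if s.is_step]

    def source(self) -> str:
        return "".join(s.text for s in self.segments)


def _parse_attrs(content: str, lineno: int) -> tuple[str, dict[str, str]]:
    """Parse ``lang key="value" ...`` inside a brace-fence header."""
    rest = content.strip()
    lang = ""
    m = re.match(r"^([A-Za-z0-9_+-]+)(\s+|$)", rest)
    if m and "=" not in m.group(1):
        lang = m.group(1)
        rest = rest[m.end():]
    attrs: dict[str, str] = {}
    pos = 0
    while pos < len(rest):
        if rest[pos].isspace():
            pos += 1
            continue
        m = _ATTR.match(rest, pos)
        if not m:
            raise LiterateError(
                f"line {lineno}: malformed attribute string {content!r}", line=lineno
            )
        attrs[m.group(1)] = m.group(2)
        pos = m.end()
    return lang, attrs


def parse_doc(source: str | Path, *, text: str | None = None) -> LiterateDoc:
    """Segment a literate Markdown document (lossless).

    Pass a path, or ``text=`` with the raw document.  Fences without a
    ``step=`` attribute remain narrative.
    """
    path: Path | None = None
    if text is None:
        path = Path(source)
        if not path.is_file():
            raise LiterateError(f"document not found: {path}")
        text = path.read_text(encoding="utf-8")

    lines = text.splitlines(keepends=True)
    segments: list[Segment] = []
    narrative: list[str] = []
    seen_steps: dict[str, int] = {}
    i = 0

    def flush_narrative() -> None:
        if narrative:
            segments.append(Segment(text="".join(narrative)))
            narrative.clear()

    while i < len(lines):
        line = lines[i]
        stripped = line.rstrip("\n")
        open_match = re.match(r"^(`{3,})(.*)$", stripped)
        if not open_match:
            narrative.append(line)
            i += 1
            continue
        ticks, header = open_match.group(1), open_match.group(2).strip()
        # find closing fence with at least as many backticks
        j = i + 1
        close_re = re.compile(r"^`{%d,}\s*$" % len(ticks))
        while j < len(lines) and not close_re.match(lines[j].rstrip("\n")):
            j += 1
        if j >= len(lines):  # unterminated fence: keep as narrative
            narrative.append(line)
            i += 1
            continue
        raw = "".join(lines[i : j + 1])
        body = "".join(lines[i + 1 : j])
        annotation = None
        if header.startswith("{") and header.endswith("}"):
            content = header[1:-1]
            if re.search(r"\bstep\s*=", content):
                lang, attrs = _parse_attrs(content, i + 1)
                step_id = attrs.get("step", "")
                if not step_id:
                    raise LiterateError(
                        f"line {i + 1}: empty step name", line=i + 1
                    )
                if step_id in seen_steps:
                    raise LiterateError(
                        f"duplicate step name {step_id!r} at lines "
                        f"{seen_steps[step_id]} and {i + 1}",
                        line=i + 1,
                    )
                seen_steps[step_id] = i + 1
                kind = attrs.get("kind", "code")
                if kind not in ("cmd", "code"):
                    raise LiterateError(
                        f"line {i + 1}: kind must be 'cmd' or 'code', got {kind!r}",
                        line=i + 1,
                    )
                run_attr = attrs.get("run", "true").lower()
                if run_attr not in ("true", "false"):
                    raise LiterateError(
                        f"line {i + 1}: run must be 'true' or 'false'", line=i + 1
                    )
                deps = [d.strip() for d in attrs.get("deps", "").split(",") if d.strip()]
                annotation = ChunkAnnotation(
                    step=step_id,
                    kind=kind,
                    deps=deps,
                    run=run_attr == "true",
                    lang=lang,
                )
        if annotation is not None:
            flush_narrative()
            segments.append(
                Segment(text=raw, annotation=annotation, body=body, line=i + 1)
            )
        else:
            narrative.append(raw)
        i = j + 1

    flush_narrative()
    return LiterateDoc(segments=segments, path=path)


def _build_command_step(
    ann: ChunkAnnotation, body: str, wf: Workflow
) -> CommandStep:
    try:
        spec = yaml.safe_load(body) or {}
    except yaml.YAMLError as exc:
        raise LiterateError(f"step {ann.step!r}: body is not valid YAML: {exc}") from exc
    if not isinstance(spec, dict):
        raise LiterateError(f"step {ann.step!r}: cmd body must be a YAML mapping")

    tool: ToolDescription
    tool_source: str | None = None
    if "tool_inline" in spec:
        tool = parse_tool(yaml.safe_dump(spec["tool_inline"]), tool_id=ann.step)
    elif "tool" in spec:
        tool_source = str(spec["tool"])
        tool_path = wf.project_dir / tool_source
        if not tool_path.is_file():
            raise LiterateError(
                f"step {ann.step!r}: tool file not found: {tool_path}"
            )
        tool = parse_tool_file(tool_path)
    else:
        raise LiterateError(f"step {ann.step!r}: cmd chunk needs 'tool' or 'tool_inline'")

    values: dict[str, Any] = dict(spec.get("inputs") or {})
    outputs_map = {str(k): str(v) for k, v in (spec.get("outputs_map") or {}).items()}

    targets_ref = spec.get("targets")
    if targets_ref is None:
        raise LiterateError(f"step {ann.step!r}: cmd chunk needs 'targets'")
    targets_ref = str(targets_ref)
    if targets_ref in wf.steps:
        targets = outputs_to_targets(wf, targets_ref, outputs_map)
    else:
        tpath = wf.project_dir / targets_ref
        if not tpath.is_file():
            raise LiterateError(
                f"step {ann.step!r}: targets {targets_ref!r} is neither an "
                "upstream step id nor an existing file"
            )
        targets = read_targets(tpath)

    res = spec.get("resources") or {}
    return CommandStep(
        id=ann.step,
        deps=list(ann.deps),
        resources=ResourceSpec(
            cores=int(res.get("cores", 1)),
            memory_mb=int(res.get("memory_mb", 1024)),
            walltime_min=int(res.get("walltime_min", 60)),
        ),
        doc=str(spec.get("doc", "")),
        tool=tool,
        values=values,
        targets=targets,
        tool_source=tool_source,
        targets_source=targets_ref,
        outputs_map=outputs_map,
    )


def import_workflow(doc: LiterateDoc, project_dir: str | Path) -> Workflow:
    """Append every runnable chunk of *doc* to a fresh Workflow, in order."""
    wf = new_workflow(project_dir)
    wf.source_doc = doc.path
    imported: set[str] = set()
    for seg in doc.steps:
        ann = seg.annotation
        assert ann is not None
        if not ann.run:
            continue
        missing = [d for d in ann.deps if d not in imported]
        if missing:
            raise LiterateError(
                f"step {ann.step!r}: deps reference earlier chunks only; "
                f"unknown or later: {', '.join(missing)}"
            )
        if ann.kind == "cmd":
            step: Step = _build_command_step(ann, seg.body, wf)
        else:
            step = CodeStep(id=ann.step, deps=list(ann.deps), code=seg.body)
        try:
            wf.append_step(step)
        except WorkflowDefinitionError as exc:
            raise LiterateError(f"step {ann.step!r}: {exc}") from exc
        imported.add(ann.step)
    return wf


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _chunk_body(step: Step) -> tuple[str, str]:
    """Return (lang, body) for a step's exported fence."""
    if isinstance(step, CodeStep):
        return "python", step.code
    assert isinstance(step, CommandStep)
    spec: dict[str, Any] = {}
    if step.tool_source is not None:
        spec["tool"] = step.tool_source
    else:
        from .cwl import tool_to_yaml

        tool_yaml, _ = tool_to_yaml(step.tool, {})
        spec["tool_inline"] = yaml.safe_load(tool_yaml)
    spec["targets"] = step.targets_source or "targets.tsv"
    if step.values:
        spec["inputs"] = step.values
    if step.outputs_map:
        spec["outputs_map"] = step.outputs_map
    return "yaml", yaml.safe_dump(spec, sort_keys=False)


def export_workflow(wf: Workflow, title: str | None = None) -> str:
    """Render the workflow back to a literate Markdown document.

    Importing the exported text yields a workflow with identical step
    ids, kinds, deps and bodies; exporting twice is byte-identical.
    """
    parts: list[str] = []
    parts.append(f"# {title or wf.project_dir.name}\n\n")
    for sid, step in wf.steps.items():
        if step.doc:
            parts.append(step.doc.rstrip("\n") + "\n\n")
        lang, body = _chunk_body(step)
        kind = "cmd" if step.kind == "command" else "code"
        attrs = [f'step="{sid}"', f'kind="{kind}"']
        if step.deps:
            attrs.append(f'deps="{",".join(step.deps)}"')
        if not body.endswith("\n"):
            body += "\n"
        parts.append("```{%s %s}\n%s```\n\n" % (lang, " ".join(attrs), body))
    return "".join(parts)
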