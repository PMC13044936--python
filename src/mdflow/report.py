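"""Technical and scientific run reports.

The *technical report* is the run log for an operator: one section per
step in topological order with the per-sample status table, the exact
argv executed, captured tool versions, and stderr excerpts for anything
that did not succeed.

The *scientific report* re-renders the literate source document: the
narrative is preserved, and every step chunk is replaced by its code
(fenced), a status badge, and the artifacts the step wrote under
``results/`` — images embedded, small tables inlined, everything else
linked.

Both reports are deterministic given fixed run state; the generation
timestamp is isolated to a single front-matter line.
"""

from __future__ import annotations

import html as _html
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .literate import LiterateDoc
from .model import CommandStep, Workflow
from .state import load_meta
from .viz import build_graph, to_svg

STDERR_TAIL_LINES = 20
TABLE_INLINE_MAX_ROWS = 50
REPORT_DIR = "results/reports"

_BADGE = {
    "pending": "⬜ pending",
    "running": "🟦 running",
    "success": "🟩 success",
    "warning": "🟧 warning",
    "error": "🟥 error",
}


@dataclass
class ReportDoc:
    kind: str  # "technical" | "scientific"
    front_matter: list[str] = field(default_factory=list)
    sections: list[str] = field(default_factory=list)  # markdown blocks

    def to_markdown(self) -> str:
        return "\n".join(self.front_matter) + "\n\n" + "\n\n".join(self.sections) + "\n"

    def to_html(self, title: str | None = None) -> str:
        body = markdown_to_html(self.to_markdown())
        title = title or f"{self.kind.capitalize()} report"
        return (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            f"<title>{_html.escape(title)}</title>"
            "<style>body{font-family:sans-serif;max-width:60em;margin:2em auto}"
            "pre{background:#f5f5f5;padding:.7em;overflow-x:auto}"
            "table{border-collapse:collapse}td,th{border:1px solid #999;"
            "padding:2px 8px}</style></head><body>"
            f"{body}</body></html>\n"
        )


# ---------------------------------------------------------------------------
# minimal markdown -> HTML (headers, paragraphs, fences, tables, images, links)
# ---------------------------------------------------------------------------

def _inline(text: str) -> str:
    text = _html.escape(text, quote=False)
    text = re.sub(r"!\[([^\]]*)\]\(([^)]+)\)", r'<img alt="\1" src="\2"/>', text)
    text = re.sub(r"\[([^\]]+)\]\(([^)]+)\)", r'<a href="\2">\1</a>', text)
    text = re.sub(r"\*\*([^*]+)\*\*", r"<strong>\1</strong>", text)
    text = re.sub(r"`([^`]+)`", r"<code>\1</code>", text)
    return text


def markdown_to_html(text: str) -> str:
    """Small converter covering the subset the reports emit."""
    out: list[str] = []
    lines = text.splitlines()
    i = 0
    para: list[str] = []

    def flush() -> None:
        if para:
            out.append("<p>" + _inline(" ".join(para)) + "</p>")
            para.clear()

    while i < len(lines):
        line = lines[i]
        if line.startswith("```"):
            flush()
            j = i + 1
            while j < len(lines) and not lines[j].startswith("```"):
                j += 1
            code = "\n".join(lines[i + 1 : j])
            out.append(f"<pre><code>{_html.escape(code)}</code></pre>")
            i = j + 1
            continue
        if line.startswith("<svg") or line.startswith("<!--raw-->"):
            flush()
            out.append(line.removeprefix("<!--raw-->"))
            i += 1
            continue
        m = re.match(r"^(#{1,6})\s+(.*)$", line)
        if m:
            flush()
            level = len(m.group(1))
            out.append(f"<h{level}>{_inline(m.group(2))}</h{level}>")
            i += 1
            continue
        if line.startswith("|"):
            flush()
            rows = []
            while i < len(lines) and lines[i].startswith("|"):
                rows.append([c.strip() for c in lines[i].strip("|").split("|")])
                i += 1
            html_rows = []
            for r, cells in enumerate(rows):
                if all(re.fullmatch(r":?-{2,}:?", c) for c in cells):
                    continue  # separator row
                tag = "th" if r == 0 else "td"
                html_rows.append(
                    "<tr>" + "".join(f"<{tag}>{_inline(c)}</{tag}>" for c in cells) + "</tr>"
                )
            out.append("<table>" + "".join(html_rows) + "</table>")
            continue
        if line.startswith("- "):
            flush()
            items = []
            while i < len(lines) and lines[i].startswith("- "):
                items.append(f"<li>{_inline(lines[i][2:])}</li>")
                i += 1
            out.append("<ul>" + "".join(items) + "</ul>")
            continue
        if not line.strip():
            flush()
            i += 1
            continue
        para.append(line)
        i += 1
    flush()
    return "\n".join(out)


# ---------------------------------------------------------------------------
# technical report
# ---------------------------------------------------------------------------

def _fmt_duration(d: float | None) -> str:
    return f"{d:.2f}s" if d is not None else "—"


def _fmt_time(t: float | None) -> str:
    if t is None:
        return "—"
    return time.strftime("%Y-%m-%d %H:%M:%S", time.localtime(t))


def _stderr_tail(wf: Workflow, rel: str | None) -> list[str]:
    if rel is None:
        return ["(no stderr log recorded)"]
    path = wf.project_dir / rel
    if not path.is_file():
        return [f"(stderr log missing: {rel})"]
    return path.read_text(encoding="utf-8").splitlines()[-STDERR_TAIL_LINES:]


def technical_report(wf: Workflow) -> ReportDoc:
    """Per-step run log: statuses, commands, versions, error excerpts."""
    meta = load_meta(wf.project_dir)
    versions = wf.versions or meta.get("versions", {})
    run_meta = wf.run_meta or meta.get("run_meta", {})
    doc = ReportDoc(kind="technical")
    doc.front_matter = [
        "# Technical report",
        "",
        f"- Generated: {_fmt_time(time.time())}",
        f"- Run id: {run_meta.get('run_id', 'n/a')}",
        f"- Run started: {_fmt_time(run_meta.get('started_at'))}",
        f"- Run finished: {_fmt_time(run_meta.get('finished_at'))}",
        f"- Engine: mdflow {__version__}",
        f"- Project: {wf.project_dir.name}",
    ]
    for sid in wf.topological_order():
        step = wf.steps[sid]
        lines = [f"## Step `{sid}` ({step.kind})", ""]
        if step.doc:
            lines += [step.doc, ""]
        lines.append("| sample | state | duration |")
        lines.append("|---|---|---|")
        for sample, unit in wf.status.step_units(sid):
            lines.append(f"| {sample} | {unit.state} | {_fmt_duration(unit.duration_s)} |")
        if isinstance(step, CommandStep):
            exe = step.commands[0].argv[0] if step.commands else "?"
            lines += ["", f"Tool: `{exe}` — version: {versions.get(exe, 'unknown')}", ""]
            lines.append("```")
            for sample, unit in wf.status.step_units(sid):
                argv = unit.argv or step.command_for(sample).argv
                lines.append(f"[{sample}] " + " ".join(argv))
            lines.append("```")
        for sample, unit in wf.status.step_units(sid):
            if unit.state in ("warning", "error"):
                lines += [
                    "",
                    f"stderr excerpt for `{sample}` (last {STDERR_TAIL_LINES} lines):",
                    "```",
                    *_stderr_tail(wf, unit.log_err),
                    "```",
                ]
        doc.sections.append("\n".join(lines))
    return doc


# ---------------------------------------------------------------------------
# scientific report
# ---------------------------------------------------------------------------

_IMAGE_EXT = {".svg", ".png", ".jpg", ".jpeg", ".gif"}
_TABLE_EXT = {".tsv", ".csv"}


def _embed_artifact(wf: Workflow, rel: str) -> list[str]:
    path = wf.project_dir / rel
    suffix = Path(rel).suffix.lower()
    link_target = "../../" + rel  # reports live under results/reports/
    if suffix in _IMAGE_EXT:
        return [f"![{rel}]({link_target})"]
    if suffix in _TABLE_EXT and path.is_file():
        rows = path.read_text(encoding="utf-8").splitlines()
        if 0 < len(rows) <= TABLE_INLINE_MAX_ROWS:
            sep = "\t" if suffix == ".tsv" else ","
            cells = [r.split(sep) for r in rows]
            width = max(len(c) for c in cells)
            md = []
            for i, row in enumerate(cells):
                row = row + [""] * (width - len(row))
                md.append("| " + " | ".join(row) + " |")
                if i == 0:
                    md.append("|" + "---|" * width)
            return md
    return [f"[{rel}]({link_target})"]


def scientific_report(
    wf: Workflow, doc: LiterateDoc, include_graph: bool = True
) -> ReportDoc:
    """Weave run results back into the literate narrative."""
    report = ReportDoc(kind="scientific")
    report.front_matter = [
        "# Scientific report",
        "",
        f"- Generated: {_fmt_time(time.time())}",
        f"- Engine: mdflow {__version__}",
        f"- Project: {wf.project_dir.name}",
    ]
    if include_graph:
        report.sections.append(
            "## Workflow topology\n\n<!--raw-->" + to_svg(build_graph(wf))
        )
    mismatches: list[str] = []
    doc_steps: set[str] = set()
    for seg in doc.segments:
        if not seg.is_step:
            if seg.text.strip():
                report.sections.append(seg.text.rstrip("\n"))
            continue
        ann = seg.annotation
        assert ann is not None
        doc_steps.add(ann.step)
        if ann.step not in wf.steps:
            mismatches.append(
                f"chunk {ann.step!r} from the document is not in the workflow"
            )
            continue
        state = wf.status.step_state(ann.step)
        k, n = wf.status.step_success_fraction(ann.step)
        lines = [
            f"### Step `{ann.step}`",
            "",
            f"Status: {_BADGE[state]} ({k}/{n} samples)",
            "",
            f"```{ann.lang or ''}",
            seg.body.rstrip("\n"),
            "```",
        ]
        artifacts: list[str] = []
        for _, unit in wf.status.step_units(ann.step):
            artifacts.extend(unit.artifacts or [])
        for rel in sorted(set(artifacts)):
            lines.append("")
            lines.extend(_embed_artifact(wf, rel))
        report.sections.append("\n".join(lines))
    for sid in wf.steps:
        if sid not in doc_steps:
            mismatches.append(
                f"workflow step {sid!r} does not appear in the document"
            )
    if mismatches:
        report.sections.append(
            "## Appendix: document/workflow mismatches\n\n"
            + "\n".join(f"- {m}" for m in mismatches)
        )
    return report


def write_reports(
    wf: Workflow,
    doc: LiterateDoc | None = None,
    technical: bool = True,
    scientific: bool = True,
    out_dir: str | Path | None = None,
) -> list[Path]:
    """Write requested reports under ``results/reports/`` (or *out_dir*)."""
    out = Path(out_dir) if out_dir else wf.project_dir / REPORT_DIR
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if technical:
        rep = technical_report(wf)
        for suffix, text in (("md", rep.to_markdown()), ("html", rep.to_html())):
            p = out / f"technical_report.{suffix}"
            p.write_text(text, encoding="utf-8")
            written.append(p)
    if scientific and doc is not None:
        rep = scientific_report(wf, doc)
        for suffix, text in (("md", rep.to_markdown()), ("html", rep.to_html())):
            p = out / f"scientific_report.{suffix}"
            p.write_text(text, encoding="utf-8")
            written.append(p)
    return written
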