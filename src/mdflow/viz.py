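"""Workflow topology graphs: DOT, mermaid and standalone HTML/SVG.

Nodes are workflow steps ordered topologically (lexicographic
tie-breaks); edges are exactly the dependency relation.  Each node
carries a color class derived from the per-step status roll-up
(worst sample state wins) plus a ``k/n`` success fraction and mean unit
duration, surfaced as tooltips.  All text outputs are deterministic:
stable ordering, no timestamps.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field

from .model import Workflow

#: palette for the five execution states
STATE_COLORS = {
    "pending": "#9e9e9e",  # gray
    "running": "#2196f3",  # blue
    "success": "#4caf50",  # green
    "warning": "#ff9800",  # orange
    "error": "#f44336",  # red
}


@dataclass
class NodeSpec:
    id: str
    label: str
    color_class: str  # one of the five states
    fraction: str  # "k/n" successes
    mean_duration_s: float | None
    kind: str = "command"


@dataclass
class GraphSpec:
    nodes: list[NodeSpec] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)
    layout: str = "top-down"  # or "left-right"


def build_graph(wf: Workflow, layout: str = "top-down") -> GraphSpec:
    """Summarize a workflow's topology and per-step status."""
    nodes = []
    for sid in wf.topological_order():
        step = wf.steps[sid]
        k, n = wf.status.step_success_fraction(sid)
        durations = [
            u.duration_s
            for _, u in wf.status.step_units(sid)
            if u.duration_s is not None
        ]
        mean = sum(durations) / len(durations) if durations else None
        nodes.append(
            NodeSpec(
                id=sid,
                label=f"{sid}\\n{k}/{n}",
                color_class=wf.status.step_state(sid),
                fraction=f"{k}/{n}",
                mean_duration_s=mean,
                kind=step.kind,
            )
        )
    edges = sorted(
        (dep, sid) for sid, step in wf.steps.items() for dep in step.deps
    )
    return GraphSpec(nodes=nodes, edges=edges, layout=layout)


def _bucket_duration(seconds: float | None) -> str:
    """Coarse human-readable duration for tooltips.

    Graph tooltips summarize; they use whole-second buckets so the
    rendered topology text is reproducible across re-runs of the same
    workflow.  Precise per-unit timings live in the technical report.
    """
    if seconds is None:
        return "n/a"
    if seconds < 1:
        return "<1s"
    if seconds < 60:
        return f"{round(seconds)}s"
    return f"{round(seconds / 60)}m"


def _tooltip(node: NodeSpec) -> str:
    mean = _bucket_duration(node.mean_duration_s)
    return (
        f"{node.id}: {node.fraction} samples succeeded; "
        f"state {node.color_class}; mean duration {mean}"
    )


def to_dot(g: GraphSpec) -> str:
    """Graphviz DOT text (deterministic; tooltips carry sample stats)."""
    rankdir = "TB" if g.layout == "top-down" else "LR"
    lines = [
        "digraph workflow {",
        f"  rankdir={rankdir};",
        '  node [style="filled,rounded" shape=box fontname="Helvetica"];',
    ]
    for node in g.nodes:
        shape = "box" if node.kind == "command" else "ellipse"
        lines.append(
            f'  "{node.id}" [label="{node.label}" shape={shape} '
            f'fillcolor="{STATE_COLORS[node.color_class]}" '
            f'tooltip="{_tooltip(node)}"];'
        )
    for src, dst in g.edges:
        lines.append(f'  "{src}" -> "{dst}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_mermaid(g: GraphSpec) -> str:
    """Mermaid flowchart text."""
    direction = "TD" if g.layout == "top-down" else "LR"
    lines = [f"flowchart {direction}"]
    for node in g.nodes:
        shape = ("[", "]") if node.kind == "command" else ("((", "))")
        label = node.label.replace("\\n", "<br/>")
        lines.append(f'  {node.id}{shape[0]}"{label}"{shape[1]}')
        lines.append(f"  class {node.id} {node.color_class}")
    for src, dst in g.edges:
        lines.append(f"  {src} --> {dst}")
    for state, color in sorted(STATE_COLORS.items()):
        lines.append(f"  classDef {state} fill:{color}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# self-contained SVG/HTML rendering (layered DAG layout)
# ---------------------------------------------------------------------------

_NODE_W, _NODE_H, _GAP_X, _GAP_Y = 150, 44, 30, 50

_PANZOOM_JS = """
const svg=document.querySelector('svg');let vb=svg.viewBox.baseVal;
let drag=null;
svg.addEventListener('wheel',e=>{e.preventDefault();const f=e.deltaY<0?0.9:1.1;
 vb.width*=f;vb.height*=f;});
svg.addEventListener('mousedown',e=>{drag=[e.clientX,e.clientY];});
svg.addEventListener('mousemove',e=>{if(!drag)return;
 vb.x-=(e.clientX-drag[0])*vb.width/svg.clientWidth;
 vb.y-=(e.clientY-drag[1])*vb.height/svg.clientHeight;
 drag=[e.clientX,e.clientY];});
svg.addEventListener('mouseup',()=>drag=null);
""".strip()


def _layers(g: GraphSpec) -> dict[str, int]:
    """Longest-path layering: layer(n) = 1 + max(layer of predecessors)."""
    preds: dict[str, list[str]] = {n.id: [] for n in g.nodes}
    for src, dst in g.edges:
        preds[dst].append(src)
    layer: dict[str, int] = {}
    for node in g.nodes:  # nodes arrive topologically sorted
        layer[node.id] = 1 + max((layer[p] for p in preds[node.id]), default=-1)
    return layer


def to_svg(g: GraphSpec) -> str:
    """Render the DAG as a standalone SVG with <title> tooltips."""
    layer = _layers(g)
    rows: dict[int, list[str]] = {}
    for node in g.nodes:
        rows.setdefault(layer[node.id], []).append(node.id)
    n_rows = len(rows) or 1
    width = max((len(r) for r in rows.values()), default=1) * (_NODE_W + _GAP_X)
    height = n_rows * (_NODE_H + _GAP_Y)
    pos: dict[str, tuple[float, float]] = {}
    for li in sorted(rows):
        ids = rows[li]
        row_w = len(ids) * (_NODE_W + _GAP_X)
        x0 = (width - row_w) / 2
        for i, nid in enumerate(ids):
            pos[nid] = (
                x0 + i * (_NODE_W + _GAP_X) + _GAP_X / 2,
                li * (_NODE_H + _GAP_Y) + _GAP_Y / 2,
            )
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {width} {height}" '
        f'width="{width}" height="{height}" font-family="Helvetica" font-size="12">'
    ]
    parts.append(
        '<defs><marker id="arr" viewBox="0 0 10 10" refX="9" refY="5" '
        'markerWidth="7" markerHeight="7" orient="auto-start-reverse">'
        '<path d="M 0 0 L 10 5 L 0 10 z" fill="#555"/></marker></defs>'
    )
    for src, dst in g.edges:
        x1, y1 = pos[src]
        x2, y2 = pos[dst]
        parts.append(
            f'<line x1="{x1 + _NODE_W / 2}" y1="{y1 + _NODE_H}" '
            f'x2="{x2 + _NODE_W / 2}" y2="{y2}" stroke="#555" '
            'marker-end="url(#arr)"/>'
        )
    by_id = {n.id: n for n in g.nodes}
    for nid, (x, y) in pos.items():
        node = by_id[nid]
        rx = 10 if node.kind == "code" else 4
        parts.append(
            f'<g><rect x="{x}" y="{y}" width="{_NODE_W}" height="{_NODE_H}" '
            f'rx="{rx}" fill="{STATE_COLORS[node.color_class]}" stroke="#333"/>'
            f"<title>{html.escape(_tooltip(node))}</title>"
            f'<text x="{x + _NODE_W / 2}" y="{y + 18}" text-anchor="middle">'
            f"{html.escape(nid)}</text>"
            f'<text x="{x + _NODE_W / 2}" y="{y + 34}" text-anchor="middle">'
            f"{html.escape(node.fraction)}</text></g>"
        )
    parts.append("</svg>")
    return "".join(parts)


def to_html(g: GraphSpec, title: str = "Workflow topology") -> str:
    """Standalone HTML page embedding the SVG with basic pan/zoom."""
    legend = "".join(
        f'<span style="background:{c};padding:2px 8px;margin-right:6px;'
        f'border-radius:4px">{s}</span>'
        for s, c in sorted(STATE_COLORS.items())
    )
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title></head><body>"
        f"<h1>{html.escape(title)}</h1><p>{legend}</p>"
        f"{to_svg(g)}<script>{_PANZOOM_JS}</script></body></html>\n"
    )
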