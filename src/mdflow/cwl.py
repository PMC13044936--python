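"""CWL CommandLineTool subset: parsing, argv binding, per-sample rendering.

Command-line steps are described by CWL ``CommandLineTool`` documents
(YAML).  This module implements the binding subset needed by the engine:

* scalar types ``string``/``int``/``boolean``/``File``/``Directory`` and
  the arrays ``string[]``/``File[]``;
* ``inputBinding`` with ``position`` (default 0), ``prefix``,
  ``separate`` (default true) and ``itemSeparator``;
* literal ``arguments``; ``outputs`` of type ``File`` with a glob; the
  tool-level ``stdout`` capture field.

Anything outside this subset — the ``Workflow`` class, JavaScript
expressions, ``scatter`` — is rejected loudly.  Requirements/hints such
as DockerRequirement are parsed, stored and ignored with a warning.

Argv assembly follows the CWL binding rules: bindings are stable-sorted
by position; ties are broken with arguments (declaration order) ahead of
inputs, and inputs among themselves lexicographically by id.  Boolean
``true`` emits its prefix alone, ``false`` emits nothing;
``separate: false`` concatenates prefix and value into a single token;
an array with ``itemSeparator`` emits one joined token, without it the
prefix is repeated before each element.  argv is never passed through a
shell.

Input values may contain ``_Column_`` placeholders (a column name of the
step's targets table between single underscores, matched
case-insensitively); :func:`render_step_commands` substitutes them per
sample row.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath
from typing import Any, Mapping

import yaml

from .errors import BindingError, TemplateGrammarError, ToolDefinitionError
from .targets import TargetsTable

SCALAR_TYPES = {"string", "int", "boolean", "File", "Directory"}
ARRAY_TYPES = {"string[]", "File[]"}
SUPPORTED_CWL_VERSIONS = {"v1.0", "v1.1", "v1.2"}

PLACEHOLDER_RE = re.compile(r"_([A-Za-z][A-Za-z0-9]*)_")


@dataclass
class Binding:
    position: int = 0
    prefix: str | None = None
    separate: bool = True
    item_separator: str | None = None


@dataclass
class InputSpec:
    id: str
    type: str  # member of SCALAR_TYPES | ARRAY_TYPES
    optional: bool = False
    binding: Binding | None = None
    default: Any = None

    def __post_init__(self) -> None:
        if self.type not in SCALAR_TYPES | ARRAY_TYPES:
            raise ToolDefinitionError(
                f"input {self.id!r}: unsupported type {self.type!r}"
            )
        if self.binding is not None:
            if self.binding.item_separator is not None and self.type not in ARRAY_TYPES:
                raise ToolDefinitionError(
                    f"input {self.id!r}: itemSeparator only applies to array types"
                )
            if not self.binding.separate and self.binding.prefix is None:
                raise ToolDefinitionError(
                    f"input {self.id!r}: separate=false requires a prefix"
                )


@dataclass
class ArgumentSpec:
    """A fixed argument: a literal token, optionally prefixed/positioned."""

    value: str
    position: int = 0
    prefix: str | None = None
    separate: bool = True


@dataclass
class OutputSpec:
    id: str
    glob: str

    def __post_init__(self) -> None:
        if not self.glob:
            raise ToolDefinitionError(f"output {self.id!r}: empty glob pattern")


@dataclass
class ToolDescription:
    tool_id: str
    base_command: list[str]
    inputs: list[InputSpec] = field(default_factory=list)
    arguments: list[ArgumentSpec] = field(default_factory=list)
    outputs: list[OutputSpec] = field(default_factory=list)
    stdout: str | None = None
    hints: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.base_command:
            raise ToolDefinitionError(f"tool {self.tool_id!r}: empty baseCommand")
        ids = [i.id for i in self.inputs]
        if len(set(ids)) != len(ids):
            raise ToolDefinitionError(f"tool {self.tool_id!r}: duplicate input ids")

    def input_by_id(self, input_id: str) -> InputSpec:
        for spec in self.inputs:
            if spec.id == input_id:
                return spec
        raise ToolDefinitionError(f"tool {self.tool_id!r}: no input {input_id!r}")


@dataclass
class RenderedCommand:
    """One concrete invocation: argv plus where outputs are expected."""

    sample: str
    argv: list[str]
    stdout_to: str | None = None
    expected_outputs: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _reject_expressions(obj: Any, where: str) -> None:
    """CWL parameter references / JS expressions are outside the subset."""
    if isinstance(obj, str) and ("$(" in obj or "${" in obj):
        raise ToolDefinitionError(
            f"{where}: expression {obj!r} is not supported "
            "(JavaScript/parameter references are outside the subset)"
        )
    if isinstance(obj, dict):
        for k, v in obj.items():
            _reject_expressions(v, f"{where}.{k}")
    if isinstance(obj, list):
        for i, v in enumerate(obj):
            _reject_expressions(v, f"{where}[{i}]")


def _normalize_type(raw: Any, input_id: str) -> tuple[str, bool]:
    """Return (subset type name, optional flag)."""
    optional = False
    if isinstance(raw, list):
        members = [m for m in raw if m != "null"]
        optional = "null" in raw
        if len(members) != 1:
            raise ToolDefinitionError(
                f"input {input_id!r}: unsupported union type {raw!r}"
            )
        raw = members[0]
    if isinstance(raw, str):
        if raw.endswith("?"):
            optional = True
            raw = raw[:-1]
        return raw, optional
    if isinstance(raw, dict) and raw.get("type") == "array":
        items = raw.get("items")
        if items in ("string", "File"):
            return f"{items}[]", optional
        raise ToolDefinitionError(
            f"input {input_id!r}: unsupported array item type {items!r}"
        )
    raise ToolDefinitionError(f"input {input_id!r}: unsupported type {raw!r}")


def _parse_binding(raw: Mapping | None) -> Binding | None:
    if raw is None:
        return None
    return Binding(
        position=int(raw.get("position", 0)),
        prefix=raw.get("prefix"),
        separate=bool(raw.get("separate", True)),
        item_separator=raw.get("itemSeparator"),
    )


def _as_id_list(section: Any, what: str) -> list[tuple[str, dict]]:
    """CWL allows both mapping and list-of-records forms for inputs/outputs."""
    if section is None:
        return []
    out: list[tuple[str, dict]] = []
    if isinstance(section, dict):
        for key, val in section.items():
            if isinstance(val, str):  # shorthand: id: type
                val = {"type": val}
            out.append((str(key), dict(val)))
    elif isinstance(section, list):
        for rec in section:
            if "id" not in rec:
                raise ToolDefinitionError(f"{what} record without id: {rec!r}")
            rec = dict(rec)
            out.append((str(rec.pop("id")), rec))
    else:
        raise ToolDefinitionError(f"malformed {what} section: {section!r}")
    return out


def parse_tool(text: str, tool_id: str | None = None) -> ToolDescription:
    """Parse a CWL CommandLineTool YAML document into a :class:`ToolDescription`."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ToolDefinitionError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ToolDefinitionError("tool document is not a mapping")
    cls = doc.get("class")
    if cls != "CommandLineTool":
        raise ToolDefinitionError(
            f"unsupported document class {cls!r}; only CommandLineTool is supported"
        )
    version = str(doc.get("cwlVersion", ""))
    if version not in SUPPORTED_CWL_VERSIONS:
        raise ToolDefinitionError(
            f"unsupported cwlVersion {version!r} (accepted: "
            f"{', '.join(sorted(SUPPORTED_CWL_VERSIONS))})"
        )
    for req_section in ("requirements", "hints"):
        reqs = doc.get(req_section) or {}
        if isinstance(reqs, list):
            reqs = {r.get("class", str(i)): r for i, r in enumerate(reqs)}
        for name in reqs:
            if name == "InlineJavascriptRequirement":
                raise ToolDefinitionError(
                    "InlineJavascriptRequirement is not supported"
                )
            warnings.warn(
                f"{req_section[:-1]} {name!r} parsed but ignored", stacklevel=2
            )

    base = doc.get("baseCommand")
    if isinstance(base, str):
        base = [base]
    if not isinstance(base, list) or not base:
        raise ToolDefinitionError("baseCommand missing or empty")
    base = [str(tok) for tok in base]

    _reject_expressions(
        {k: v for k, v in doc.items() if k not in ("requirements", "hints")}, "tool"
    )

    inputs: list[InputSpec] = []
    for input_id, rec in _as_id_list(doc.get("inputs"), "inputs"):
        type_name, optional = _normalize_type(rec.get("type"), input_id)
        inputs.append(
            InputSpec(
                id=input_id,
                type=type_name,
                optional=optional or "default" in rec,
                binding=_parse_binding(rec.get("inputBinding")),
                default=rec.get("default"),
            )
        )

    arguments: list[ArgumentSpec] = []
    for raw in doc.get("arguments") or []:
        if isinstance(raw, (str, int, float)):
            arguments.append(ArgumentSpec(value=str(raw)))
        elif isinstance(raw, dict):
            arguments.append(
                ArgumentSpec(
                    value=str(raw.get("valueFrom", "")),
                    position=int(raw.get("position", 0)),
                    prefix=raw.get("prefix"),
                    separate=bool(raw.get("separate", True)),
                )
            )
        else:
            raise ToolDefinitionError(f"malformed argument: {raw!r}")

    stdout_pattern = doc.get("stdout")

    outputs: list[OutputSpec] = []
    for output_id, rec in _as_id_list(doc.get("outputs"), "outputs"):
        otype = rec.get("type")
        if otype == "stdout":
            if not stdout_pattern:
                raise ToolDefinitionError(
                    f"output {output_id!r} of type stdout but no stdout field"
                )
            outputs.append(OutputSpec(id=output_id, glob=str(stdout_pattern)))
        elif otype == "File":
            glob = (rec.get("outputBinding") or {}).get("glob")
            if not glob:
                raise ToolDefinitionError(
                    f"output {output_id!r}: File output requires outputBinding.glob"
                )
            outputs.append(OutputSpec(id=output_id, glob=str(glob)))
        else:
            raise ToolDefinitionError(
                f"output {output_id!r}: unsupported output type {otype!r}"
            )

    return ToolDescription(
        tool_id=tool_id or str(doc.get("id", base[0])),
        base_command=base,
        inputs=inputs,
        arguments=arguments,
        outputs=outputs,
        stdout=str(stdout_pattern) if stdout_pattern else None,
    )


def parse_tool_file(path: str | Path) -> ToolDescription:
    path = Path(path)
    if not path.is_file():
        raise ToolDefinitionError(f"tool file not found: {path}")
    return parse_tool(path.read_text(encoding="utf-8"), tool_id=path.stem)


def parse_job_values(text: str) -> dict[str, Any]:
    """Parse a CWL job/parameter YAML file into plain id→value form."""
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ToolDefinitionError("job file is not a mapping")
    return {str(k): v for k, v in doc.items()}


# ---------------------------------------------------------------------------
# binding
# ---------------------------------------------------------------------------

def _value_to_string(value: Any) -> str:
    if isinstance(value, dict) and value.get("class") in ("File", "Directory"):
        return str(value["path"])
    if isinstance(value, bool):
        raise BindingError("boolean value reached scalar rendering")
    return str(value)


def _resolve_output_path(pattern: str) -> str:
    """Relative output paths live under the project results/ directory."""
    p = PurePosixPath(pattern)
    if p.is_absolute() or pattern.startswith("results/"):
        return pattern
    return f"results/{pattern}"


def bind_command(
    tool: ToolDescription,
    values: Mapping[str, Any],
    sample: str = "_step_",
) -> RenderedCommand:
    """Assemble argv for *tool* given concrete input *values*."""
    entries: list[tuple[tuple, list[str]]] = []

    for decl_index, arg in enumerate(tool.arguments):
        tokens: list[str] = []
        if arg.prefix is not None:
            if arg.separate:
                tokens.append(arg.prefix)
                if arg.value:
                    tokens.append(arg.value)
            else:
                tokens.append(arg.prefix + arg.value)
        else:
            tokens.append(arg.value)
        # sort group 0: arguments precede inputs on position ties
        entries.append(((arg.position, 0, decl_index), tokens))

    for spec in tool.inputs:
        if spec.binding is None:
            continue
        value = values.get(spec.id, spec.default)
        if value is None:
            if spec.optional:
                continue
            raise BindingError(
                f"missing required input {spec.id!r} for tool {tool.tool_id!r}"
            )
        tokens = _render_input_tokens(spec, value)
        if tokens:
            entries.append(((spec.binding.position, 1, spec.id), tokens))

    for spec in tool.inputs:  # required inputs without a binding still must exist
        if spec.binding is None and not spec.optional and spec.id not in values:
            raise BindingError(
                f"missing required input {spec.id!r} for tool {tool.tool_id!r}"
            )

    entries.sort(key=lambda e: e[0])
    argv = list(tool.base_command)
    for _, tokens in entries:
        argv.extend(tokens)

    expected = {
        out.id: _resolve_output_path(out.glob) for out in tool.outputs
    }
    stdout_to = _resolve_output_path(tool.stdout) if tool.stdout else None
    return RenderedCommand(
        sample=sample, argv=argv, stdout_to=stdout_to, expected_outputs=expected
    )


def _render_input_tokens(spec: InputSpec, value: Any) -> list[str]:
    b = spec.binding
    assert b is not None
    if spec.type == "boolean":
        if not isinstance(value, bool):
            raise BindingError(f"input {spec.id!r}: expected boolean, got {value!r}")
        if value and b.prefix is not None:
            return [b.prefix]
        return []
    if spec.type in ARRAY_TYPES:
        if not isinstance(value, list):
            raise BindingError(f"input {spec.id!r}: expected list, got {value!r}")
        items = [_value_to_string(v) for v in value]
        if not items:
            return []
        if b.item_separator is not None:
            joined = b.item_separator.join(items)
            if b.prefix is None:
                return [joined]
            return [b.prefix + joined] if not b.separate else [b.prefix, joined]
        tokens = []
        for item in items:
            if b.prefix is not None:
                if b.separate:
                    tokens.extend([b.prefix, item])
                else:
                    tokens.append(b.prefix + item)
            else:
                tokens.append(item)
        return tokens
    # scalar
    rendered = _value_to_string(value)
    if b.prefix is not None:
        return [b.prefix, rendered] if b.separate else [b.prefix + rendered]
    return [rendered]


# ---------------------------------------------------------------------------
# per-sample rendering
# ---------------------------------------------------------------------------

def substitute_placeholders(text: str, row: Mapping[str, str]) -> str:
    """Replace every ``_Column_`` placeholder in *text* from *row*.

    Column names match case-insensitively; a placeholder naming no column
    raises :class:`BindingError` listing the available columns.
    """
    lower = {c.lower(): c for c in row}

    def repl(match: re.Match) -> str:
        name = match.group(1)
        col = lower.get(name.lower())
        if col is None:
            raise BindingError(
                f"placeholder _{name}_ names no targets column; "
                f"available columns: {', '.join(row)}"
            )
        return row[col]

    return PLACEHOLDER_RE.sub(repl, text)


def _substitute_value(value: Any, row: Mapping[str, str]) -> Any:
    if isinstance(value, str):
        return substitute_placeholders(value, row)
    if isinstance(value, list):
        return [_substitute_value(v, row) for v in value]
    if isinstance(value, dict) and value.get("class") in ("File", "Directory"):
        out = dict(value)
        out["path"] = substitute_placeholders(str(out.get("path", "")), row)
        return out
    return value


def _specialize_pattern(pattern: str, row: Mapping[str, str]) -> str:
    """Globs may embed placeholders too (typically ``_SampleName_``)."""
    return substitute_placeholders(pattern, row)


def render_step_commands(
    tool: ToolDescription,
    values: Mapping[str, Any],
    targets: TargetsTable,
) -> list[RenderedCommand]:
    """One :class:`RenderedCommand` per targets row, in row order."""
    commands: list[RenderedCommand] = []
    for row in targets.rows:
        sample = row["SampleName"]
        resolved = {k: _substitute_value(v, row) for k, v in values.items()}
        specialized = ToolDescription(
            tool_id=tool.tool_id,
            base_command=list(tool.base_command),
            inputs=tool.inputs,
            arguments=tool.arguments,
            outputs=[
                OutputSpec(id=o.id, glob=_specialize_pattern(o.glob, row))
                for o in tool.outputs
            ],
            stdout=_specialize_pattern(tool.stdout, row) if tool.stdout else None,
        )
        commands.append(bind_command(specialized, resolved, sample=sample))
    return commands


# ---------------------------------------------------------------------------
# annotated command templates → (tool, values)
# ---------------------------------------------------------------------------

_TEMPLATE_PLACEHOLDER = re.compile(
    r"^<([A-Za-z][A-Za-z0-9_]*):(string|int|boolean|File|Directory|out):([^<>]*)>$"
)


def tool_from_template(template: str) -> tuple[ToolDescription, dict[str, Any]]:
    """Build a tool description from an annotated command string.

    Grammar: whitespace-separated tokens.  Plain tokens are literals
    (base command, then fixed arguments).  ``<id:type:default>`` declares
    an input whose prefix is the immediately preceding ``-``-literal (the
    literal is consumed as the prefix); ``<id:out:default>`` declares a
    File output globbed on the default's basename and a string input
    carrying the full default path.  Positions are assigned in order of
    appearance, starting at 1.

    Example::

        tool, values = tool_from_template("echo -m <msg:string:hello>")
        bind_command(tool, values).argv  # ['echo', '-m', 'hello']
    """
    tokens: list[tuple[str, int]] = []
    offset = 0
    for tok in template.split():
        start = template.index(tok, offset)
        tokens.append((tok, start))
        offset = start + len(tok)

    base: list[str] = []
    inputs: list[InputSpec] = []
    outputs: list[OutputSpec] = []
    arguments: list[ArgumentSpec] = []
    values: dict[str, Any] = {}
    position = 1
    pending_prefix: str | None = None
    seen_placeholder = False

    def flush_pending() -> None:
        nonlocal pending_prefix, position
        if pending_prefix is not None:
            arguments.append(ArgumentSpec(value=pending_prefix, position=position))
            position += 1
            pending_prefix = None

    for i, (tok, start) in enumerate(tokens):
        if tok.startswith("<") or tok.endswith(">"):
            m = _TEMPLATE_PLACEHOLDER.match(tok)
            if m is None:
                raise TemplateGrammarError(
                    f"malformed placeholder {tok!r} at offset {start}", offset=start
                )
            pid, ptype, default = m.group(1), m.group(2), m.group(3)
            prefix = pending_prefix
            pending_prefix = None
            seen_placeholder = True
            if ptype == "out":
                glob = PurePosixPath(default).name
                outputs.append(OutputSpec(id=pid, glob=glob))
                inputs.append(
                    InputSpec(
                        id=pid,
                        type="string",
                        binding=Binding(position=position, prefix=prefix),
                    )
                )
                values[pid] = default
            else:
                value: Any = default
                if ptype == "int":
                    try:
                        value = int(default)
                    except ValueError as exc:
                        raise TemplateGrammarError(
                            f"placeholder {pid!r}: non-integer default "
                            f"{default!r} at offset {start}",
                            offset=start,
                        ) from exc
                elif ptype == "boolean":
                    if default not in ("true", "false"):
                        raise TemplateGrammarError(
                            f"placeholder {pid!r}: boolean default must be "
                            f"true/false at offset {start}",
                            offset=start,
                        )
                    value = default == "true"
                inputs.append(
                    InputSpec(
                        id=pid,
                        type=ptype,
                        binding=Binding(position=position, prefix=prefix),
                    )
                )
                values[pid] = value
            position += 1
        else:
            flush_pending()
            next_is_placeholder = (
                i + 1 < len(tokens) and tokens[i + 1][0].startswith("<")
            )
            if tok.startswith("-") and next_is_placeholder:
                pending_prefix = tok
            elif not seen_placeholder:
                base.append(tok)
            else:
                arguments.append(ArgumentSpec(value=tok, position=position))
                position += 1
    flush_pending()

    if not base:
        raise TemplateGrammarError("template has no base command", offset=0)
    tool = ToolDescription(
        tool_id=base[0],
        base_command=base,
        inputs=inputs,
        arguments=arguments,
        outputs=outputs,
    )
    return tool, values


def tool_to_yaml(tool: ToolDescription, values: Mapping[str, Any]) -> tuple[str, str]:
    """Serialize a tool description + job values to CWL/job YAML texts."""
    doc: dict[str, Any] = {
        "cwlVersion": "v1.2",
        "class": "CommandLineTool",
        "baseCommand": list(tool.base_command),
        "inputs": {},
        "outputs": {},
    }
    for spec in tool.inputs:
        rec: dict[str, Any] = {"type": spec.type + ("?" if spec.optional else "")}
        if spec.binding is not None:
            b: dict[str, Any] = {"position": spec.binding.position}
            if spec.binding.prefix is not None:
                b["prefix"] = spec.binding.prefix
            if not spec.binding.separate:
                b["separate"] = False
            if spec.binding.item_separator is not None:
                b["itemSeparator"] = spec.binding.item_separator
            rec["inputBinding"] = b
        doc["inputs"][spec.id] = rec
    if tool.arguments:
        doc["arguments"] = []
        for arg in tool.arguments:
            doc["arguments"].append(
                {"valueFrom": arg.value, "position": arg.position}
                | ({"prefix": arg.prefix} if arg.prefix else {})
            )
    for out in tool.outputs:
        doc["outputs"][out.id] = {"type": "File", "outputBinding": {"glob": out.glob}}
    if tool.stdout:
        doc["stdout"] = tool.stdout
    return (
        yaml.safe_dump(doc, sort_keys=False),
        yaml.safe_dump(dict(values), sort_keys=False),
    )
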