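"""CWL CommandLineTool subset: parsing, argv binding, templates.

Binding conformance is checked two ways on every fixture: against
expected argv derived by hand from the CWL v1.2 binding rules (frozen
below), and against ``naive_bind`` — an independent re-implementation of
the rules written directly from those rules and sharing no code with the
package.
"""

from __future__ import annotations

import textwrap

import pytest
import yaml

from mdflow.cwl import (
    bind_command,
    parse_tool,
    render_step_commands,
    tool_from_template,
    tool_to_yaml,
)
from mdflow.errors import BindingError, TemplateGrammarError, ToolDefinitionError
from mdflow.targets import make_targets


# ---------------------------------------------------------------------------
# independent oracle: a second, minimal implementation of the binding rules
# ---------------------------------------------------------------------------

def naive_bind(tool_yaml: str, job: dict) -> list[str]:
    """Render argv straight from the raw YAML, independently of the package."""
    doc = yaml.safe_load(tool_yaml)
    base = doc["baseCommand"]
    if isinstance(base, str):
        base = [base]
    entries = []  # (position, group, tiebreak, tokens)

    for idx, arg in enumerate(doc.get("arguments", [])):
        if isinstance(arg, dict):
            pos, prefix, val = arg.get("position", 0), arg.get("prefix"), str(arg.get("valueFrom", ""))
            sep = arg.get("separate", True)
        else:
            pos, prefix, val, sep = 0, None, str(arg), True
        if prefix is None:
            toks = [val]
        elif sep:
            toks = [prefix, val] if val else [prefix]
        else:
            toks = [prefix + val]
        entries.append((pos, 0, idx, toks))

    inputs = doc.get("inputs", {})
    items = inputs.items() if isinstance(inputs, dict) else [
        (r["id"], r) for r in inputs
    ]
    for input_id, rec in items:
        if isinstance(rec, str):
            rec = {"type": rec}
        binding = rec.get("inputBinding")
        if binding is None:
            continue
        value = job.get(input_id, rec.get("default"))
        if value is None:
            continue
        pos = binding.get("position", 0)
        prefix = binding.get("prefix")
        sep = binding.get("separate", True)
        isep = binding.get("itemSeparator")

        def scalar(v):
            if isinstance(v, dict):
                return str(v["path"])
            return str(v)

        if isinstance(value, bool):
            toks = [prefix] if value else []
        elif isinstance(value, list):
            vals = [scalar(v) for v in value]
            if isep is not None:
                joined = isep.join(vals)
                toks = (
                    [joined] if prefix is None
                    else ([prefix, joined] if sep else [prefix + joined])
                )
            elif prefix is not None:
                toks = []
                for v in vals:
                    toks += [prefix, v] if sep else [prefix + v]
            else:
                toks = vals
        else:
            v = scalar(value)
            toks = [v] if prefix is None else ([prefix, v] if sep else [prefix + v])
        if toks:
            entries.append((pos, 1, input_id, toks))

    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    argv = list(base)
    for _, _, _, toks in entries:
        argv += toks
    return [str(t) for t in argv]


def tool(body: str) -> str:
    return "cwlVersion: v1.2\nclass: CommandLineTool\n" + textwrap.dedent(body)


# fixture id → (tool yaml, job values, expected argv derived from the
# CWL v1.2 binding rules)
CONFORMANCE = {
    "single_positional": (
        tool("""\
        baseCommand: echo
        inputs:
          msg: {type: string, inputBinding: {position: 1}}
        outputs: {}
        """),
        {"msg": "hello"},
        ["echo", "hello"],
    ),
    "position_sorting_with_prefix": (
        tool("""\
        baseCommand: echo
        inputs:
          threads: {type: int, inputBinding: {position: 2, prefix: -p}}
          msg: {type: string, inputBinding: {position: 1}}
        outputs: {}
        """),
        {"msg": "x", "threads": 4},
        ["echo", "x", "-p", "4"],
    ),
    "separate_false_and_false_boolean": (
        tool("""\
        baseCommand: tool
        inputs:
          out: {type: string, inputBinding: {position: 1, prefix: '--out=', separate: false}}
          verbose: {type: 'boolean?', inputBinding: {position: 2, prefix: --verbose}}
        outputs: {}
        """),
        {"out": "a.txt", "verbose": False},
        ["tool", "--out=a.txt"],
    ),
    "true_boolean_emits_prefix_only": (
        tool("""\
        baseCommand: tool
        inputs:
          verbose: {type: boolean, inputBinding: {position: 1, prefix: --verbose}}
        outputs: {}
        """),
        {"verbose": True},
        ["tool", "--verbose"],
    ),
    "array_with_item_separator": (
        tool("""\
        baseCommand: tool
        inputs:
          regions:
            type: string[]
            inputBinding: {position: 1, prefix: -L, itemSeparator: ','}
        outputs: {}
        """),
        {"regions": ["chr1", "chr2", "chr3"]},
        ["tool", "-L", "chr1,chr2,chr3"],
    ),
    "array_prefix_repeated": (
        tool("""\
        baseCommand: gather
        inputs:
          gvcfs: {type: 'File[]', inputBinding: {position: 1, prefix: -V}}
        outputs: {}
        """),
        {"gvcfs": ["a.g.vcf", {"class": "File", "path": "b.g.vcf"}]},
        ["gather", "-V", "a.g.vcf", "-V", "b.g.vcf"],
    ),
    "array_bare": (
        tool("""\
        baseCommand: cat
        inputs:
          files: {type: 'string[]', inputBinding: {position: 1}}
        outputs: {}
        """),
        {"files": ["x", "y"]},
        ["cat", "x", "y"],
    ),
    "argument_before_input_on_tie": (
        tool("""\
        baseCommand: tool
        arguments:
          - {valueFrom: fixed, position: 1}
        inputs:
          aaa: {type: string, inputBinding: {position: 1}}
        outputs: {}
        """),
        {"aaa": "varying"},
        ["tool", "fixed", "varying"],
    ),
    "inputs_lexicographic_on_tie": (
        tool("""\
        baseCommand: tool
        inputs:
          zeta: {type: string, inputBinding: {position: 1}}
          alpha: {type: string, inputBinding: {position: 1}}
        outputs: {}
        """),
        {"zeta": "z", "alpha": "a"},
        ["tool", "a", "z"],
    ),
    "file_object_and_default": (
        tool("""\
        baseCommand: align
        inputs:
          ref: {type: File, inputBinding: {position: 1, prefix: -x}}
          mode: {type: string, default: fast, inputBinding: {position: 2, prefix: -m}}
        outputs: {}
        """),
        {"ref": {"class": "File", "path": "data/ref.fa"}},
        ["align", "-x", "data/ref.fa", "-m", "fast"],
    ),
    "stdout_capture": (
        tool("""\
        baseCommand: [wc, -l]
        inputs:
          infile: {type: File, inputBinding: {position: 1}}
        stdout: counts.txt
        outputs:
          report: {type: stdout}
        """),
        {"infile": "data/a.txt"},
        ["wc", "-l", "data/a.txt"],
    ),
    "separate_false_joined_array": (
        tool("""\
        baseCommand: tool
        inputs:
          vals:
            type: string[]
            inputBinding: {position: 1, prefix: '-L=', separate: false, itemSeparator: ','}
        outputs: {}
        """),
        {"vals": ["a", "b"]},
        ["tool", "-L=a,b"],
    ),
}


class TestBindingConformance:
    @pytest.mark.parametrize("name", sorted(CONFORMANCE))
    def test_matches_frozen_expectation(self, name):
        tool_yaml, job, expected = CONFORMANCE[name]
        assert bind_command(parse_tool(tool_yaml), job).argv == expected

    @pytest.mark.parametrize("name", sorted(CONFORMANCE))
    def test_matches_independent_oracle(self, name):
        tool_yaml, job, _ = CONFORMANCE[name]
        assert bind_command(parse_tool(tool_yaml), job).argv == naive_bind(
            tool_yaml, job
        )

    def test_stdout_and_outputs_resolved_under_results(self):
        tool_yaml, job, _ = CONFORMANCE["stdout_capture"]
        cmd = bind_command(parse_tool(tool_yaml), job)
        assert cmd.stdout_to == "results/counts.txt"
        assert cmd.expected_outputs == {"report": "results/counts.txt"}

    def test_missing_required_input_named(self):
        tool_yaml, _, _ = CONFORMANCE["single_positional"]
        with pytest.raises(BindingError, match="msg"):
            bind_command(parse_tool(tool_yaml), {})

    def test_declaration_order_is_irrelevant_up_to_tiebreak(self):
        """Permuting input declarations never changes argv (fixed positions)."""
        a = tool("""\
        baseCommand: t
        inputs:
          one: {type: string, inputBinding: {position: 1}}
          two: {type: string, inputBinding: {position: 2}}
        outputs: {}
        """)
        b = tool("""\
        baseCommand: t
        inputs:
          two: {type: string, inputBinding: {position: 2}}
          one: {type: string, inputBinding: {position: 1}}
        outputs: {}
        """)
        job = {"one": "1", "two": "2"}
        assert bind_command(parse_tool(a), job).argv == bind_command(
            parse_tool(b), job
        ).argv


class TestParseTool:
    def test_minimal(self):
        t = parse_tool(CONFORMANCE["single_positional"][0])
        assert t.base_command == ["echo"]
        assert len(t.inputs) == 1 and t.outputs == []
        assert t.inputs[0].binding.position == 1
        assert t.inputs[0].binding.separate is True

    def test_workflow_class_rejected(self):
        with pytest.raises(ToolDefinitionError, match="CommandLineTool"):
            parse_tool("cwlVersion: v1.2\nclass: Workflow\nsteps: {}\n")

    def test_file_array_with_item_separator(self):
        t = parse_tool(tool("""\
        baseCommand: x
        inputs:
          files:
            type: File[]
            inputBinding: {position: 1, itemSeparator: ','}
        outputs: {}
        """))
        spec = t.inputs[0]
        assert spec.type == "File[]"
        assert spec.binding.item_separator == ","

    def test_unsupported_type_names_input(self):
        with pytest.raises(ToolDefinitionError, match="weird"):
            parse_tool(tool("""\
            baseCommand: x
            inputs:
              weird: {type: record}
            outputs: {}
            """))

    def test_javascript_expression_rejected(self):
        with pytest.raises(ToolDefinitionError, match="expression"):
            parse_tool(tool("""\
            baseCommand: x
            inputs:
              a: {type: string, inputBinding: {position: 1}}
            arguments: ["$(inputs.a)"]
            outputs: {}
            """))

    def test_unsupported_cwl_version(self):
        with pytest.raises(ToolDefinitionError, match="cwlVersion"):
            parse_tool("cwlVersion: v0.9\nclass: CommandLineTool\nbaseCommand: x\n")

    def test_item_separator_on_scalar_rejected(self):
        with pytest.raises(ToolDefinitionError, match="itemSeparator"):
            parse_tool(tool("""\
            baseCommand: x
            inputs:
              a: {type: string, inputBinding: {position: 1, itemSeparator: ','}}
            outputs: {}
            """))

    def test_hints_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="DockerRequirement"):
            parse_tool(tool("""\
            baseCommand: x
            hints:
              DockerRequirement: {dockerPull: something}
            inputs: {}
            outputs: {}
            """))


class TestRenderStepCommands:
    def test_placeholder_substitution_per_row(self, targets2):
        t = parse_tool(tool("""\
        baseCommand: align
        inputs:
          reads: {type: string, inputBinding: {position: 1}}
        outputs:
          sam: {type: File, outputBinding: {glob: _SampleName_.sam}}
        """))
        cmds = render_step_commands(t, {"reads": "_FileName_"}, targets2)
        assert [c.argv for c in cmds] == [
            ["align", "data/S1.fq"],
            ["align", "data/S2.fq"],
        ]
        assert cmds[0].expected_outputs == {"sam": "results/S1.sam"}
        assert [c.sample for c in cmds] == ["S1", "S2"]

    def test_unknown_placeholder_lists_columns(self, targets2):
        t = parse_tool(CONFORMANCE["single_positional"][0])
        with pytest.raises(BindingError, match="Factor"):
            render_step_commands(t, {"msg": "_Missing_"}, targets2)

    def test_placeholder_case_insensitive(self, targets2):
        t = parse_tool(CONFORMANCE["single_positional"][0])
        cmds = render_step_commands(t, {"msg": "_FILENAME_"}, targets2)
        assert cmds[0].argv == ["echo", "data/S1.fq"]


class TestToolFromTemplate:
    def test_prefix_consumed_and_rerendered(self):
        t, values = tool_from_template("echo -m <msg:string:hello>")
        assert t.base_command == ["echo"]
        assert t.inputs[0].binding.prefix == "-m"
        assert t.inputs[0].binding.position == 1
        assert bind_command(t, values).argv == ["echo", "-m", "hello"]

    def test_out_placeholder_declares_output(self):
        t, values = tool_from_template(
            "align -x <idx:File:data/ref.fa> -S <sam:out:results/_SampleName_.sam>"
        )
        assert [i.type for i in t.inputs] == ["File", "string"]
        assert len(t.outputs) == 1
        assert t.outputs[0].glob == "_SampleName_.sam"
        assert bind_command(t, values).argv == [
            "align", "-x", "data/ref.fa", "-S", "results/_SampleName_.sam",
        ]

    def test_malformed_placeholder_reports_offset(self):
        with pytest.raises(TemplateGrammarError) as err:
            tool_from_template("echo <bad")
        assert err.value.offset == 5

    @pytest.mark.parametrize(
        "template",
        [
            "echo hello world",
            "echo -m <msg:string:hi> trailing",
            "align -x <idx:File:r.fa> -p <threads:int:4> <reads:string:a.fq>",
            "tool -S <out1:out:results/x.txt> -m <msg:string:y>",
        ],
    )
    def test_roundtrip_reproduces_literals(self, template):
        """Rendering with returned defaults reproduces the template tokens."""
        t, values = tool_from_template(template)
        rendered = bind_command(t, values).argv
        expected = []
        for tok in template.split():
            if tok.startswith("<"):
                kind, default = tok[1:-1].split(":")[1:3]
                expected.append(default)
            else:
                expected.append(tok)
        assert rendered == expected

    def test_serialized_tool_rebinds_identically(self):
        t, values = tool_from_template("echo -m <msg:string:hello> -p <n:int:2>")
        tool_yaml, job_yaml = tool_to_yaml(t, values)
        reparsed = parse_tool(tool_yaml)
        rebound = bind_command(reparsed, yaml.safe_load(job_yaml))
        assert rebound.argv == bind_command(t, values).argv
        assert rebound.argv == naive_bind(tool_yaml, yaml.safe_load(job_yaml))
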