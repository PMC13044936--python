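# mdflow

A workflow management system for hybrid analyses that mix external
command-line tools with native Python code — the common shape of omics
pipelines, where read mapping or variant calling runs as subprocesses
while statistics and reporting live in an interactive language.

Workflows are defined in a **literate Markdown document**: narrative text
interleaved with annotated fenced code blocks, each block one workflow
step. Command-line steps reference a **CWL `CommandLineTool`** description
(a declarative, portable account of an executable, its typed inputs and
the rules binding them to argv) and are rendered once per sample of a
tab-separated **targets** sheet. Code steps are plain Python executed in a
shared session. The engine executes the resulting DAG with
per-step/per-sample (scatter/gather) status tracking, persists every state
transition to an on-disk store so interrupted runs resume exactly where
they stopped, and renders topology graphs plus two kinds of report:

- a **technical report** — statuses, exact commands, tool versions,
  stderr excerpts for anything that failed;
- a **scientific report** — the original narrative re-woven with each
  step's code, status badge, and the artifacts it wrote (images embedded,
  small tables inlined, large files linked).

## Core model

A `Workflow` is an ordered registry of steps bound to a project directory
(`data/`, `param/`, `results/`, `targets.tsv`, `workflow.md`,
`.sprproject/` state). A step can only be appended after all of its
dependencies, so the dependency graph is acyclic by construction and the
registry order is always a valid topological order. Command steps carry
one `RenderedCommand` per sample: argv is assembled from the CWL binding
rules (position sort; ties put fixed arguments before inputs and order
inputs lexicographically; `separate: false` concatenates prefix and
value; arrays repeat the prefix or join on `itemSeparator`; boolean true
emits the prefix alone) and is executed without a shell. A unit is
`success` only if it exits 0 *and* every declared output file exists —
the tool-agnostic completeness check that resume is built on: a unit is
skipped iff it is recorded successful, its outputs are intact, and
nothing upstream of it re-ran.

Sample metadata propagate automatically: a downstream step can declare an
upstream step as its targets source, and its sample sheet is derived from
the files the upstream step promises to produce (`outputs_to_targets`),
so sample labels stay attached to files from raw input to final table.

## Worked example

```bash
mdflow init -t skeleton demo && cd demo
mdflow run
# executed 8 unit(s): 8 success, 0 warning, 0 error, 0 pending
mdflow run --resume
# executed 0 unit(s): 8 success, 0 warning, 0 error, 0 pending
rm results/S2.count.txt
mdflow run --resume
# executed 3 unit(s): 8 success, 0 warning, 0 error, 0 pending
mdflow plot -f html -o results/topology.html
mdflow report
```

The first run executes the four-step chain (a setup code step, per-sample
counting, per-sample normalization driven by the counting step's outputs,
a gather summary) across three toy samples — 8 step×sample units. The
second run resumes and executes nothing. Deleting one intermediate file
invalidates exactly its downstream closure — `count_reads/S2`,
`normalize/S2` and the gather `summarize` step — so the third run executes
exactly 3 units.

The richer `varseq_mock` template is a 35-step cohort variant-calling
demonstration (QC → trimming → alignment → per-sample gVCF calling →
cohort consolidation and joint genotyping → SNP/indel filtering →
annotation → gene burden, pathway enrichment and drug-target mapping).
Every external tool is a deterministic mock text transform, so the whole
workflow runs offline in a few seconds while exercising scatter/gather,
metadata propagation and mixed command/code steps:

```bash
mdflow init -t varseq_mock varseq && cd varseq
mdflow run
# executed 59 unit(s): 59 success, 0 warning, 0 error, 0 pending
```

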