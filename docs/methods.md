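# Methods

## Execution model

A workflow is a DAG of steps; each step expands to one execution unit per
sample of its targets sheet (code steps use the single pseudo-sample
`_step_`, keeping step×sample bookkeeping uniform). Steps run strictly in
topological order with lexicographic tie-breaks, so graphs, reports and
traces are reproducible. Within a command step, units are independent and
may run concurrently (scatter); the step finishes before any dependent
starts (gather). Code steps always run serially in one shared Python
session per run, so later steps see names defined by earlier ones.

Acyclicity is enforced constructively rather than by global cycle
detection: a step's dependencies must already be registered when it is
appended, mirroring one-at-a-time import from the literate document. A
forward or unknown reference fails immediately with the offending id.

### Unit states

`pending → running → {success, warning, error}`.

- **success**: exit code 0 and every declared output file present
  (command steps), or code body completed without exception (code steps).
- **warning**: exit 0 but a declared output never appeared, or a code
  step raised a Python warning (interpreter housekeeping categories such
  as `ResourceWarning`/`DeprecationWarning` are logged but do not demote
  the unit — they say nothing about the analysis).
- **error**: non-zero exit, unlaunchable executable, walltime exceeded,
  or an uncaught exception (traceback captured to the stderr log).

Output existence is the only tool-agnostic notion of "this unit's work is
really done", which is why it gates both success and resume. The
per-step roll-up used for graph coloring is the worst sample state under
`error > warning > running > pending > success`.

### Resume and crash safety

The state store (`.sprproject/status.json`, schema version 1) is written
atomically after every unit, so a killed run resumes from the last
completed unit. Under `resume`, a unit re-executes iff (a) its recorded
state is not success, (b) any of its expected outputs is missing, or
(c) an upstream unit re-executes. Lineage is sample-aware: a per-sample
unit depends on the same-sample unit of each dependency step when that
step carries the sample, otherwise on all of its units (gather
semantics). Deleting one intermediate file therefore re-runs exactly the
downstream closure of the invalidated unit — verified in tests against a
brute-force fixed-point reachability oracle over the unit graph.

### Failure policy

By default an errored step cancels only its downstream closure;
independent branches keep running (maximizes useful work per run under
DAG semantics). `halt_all` switches to stop-everything. Cancelled units
stay `pending` and are picked up by the next resume.

### Executors

`serial` and `local_parallel` (a thread pool; units are subprocesses, so
threads suffice). The executor contract (`name`, `max_workers`, per-step
`ResourceSpec` with cores/memory/walltime) is the integration surface a
cluster backend would implement; scheduler-specific backends are out of
scope and only `walltime_min` is enforced locally (as a subprocess
timeout). Final states are executor-independent — asserted by a
serial-vs-parallel equivalence test.

The engine itself is deterministic: no randomness anywhere in scheduling
or rendering. Code steps wanting randomness must seed themselves.

## CWL subset

Command steps are described by CWL `CommandLineTool` documents
(cwlVersion v1.0–v1.2). Supported: `string`/`int`/`boolean`/`File`/
`Directory`, `string[]`/`File[]`, `inputBinding` with `position`
(default 0), `prefix`, `separate` (default true), `itemSeparator`;
literal `arguments`; `File` outputs with a glob; tool-level `stdout`
capture. Everything else — the `Workflow` class, JavaScript expressions,
`scatter` — is rejected with an explicit error; requirements/hints like
`DockerRequirement` are parsed, stored, and ignored with a warning.

Where the CWL text leaves tie order underspecified, the binder fixes it:
stable sort by position, fixed arguments (declaration order) before
inputs, inputs lexicographic by id. Arrays without `itemSeparator`
repeat the prefix per element. argv is passed to process creation
verbatim — never through a shell — which makes command rendering
reproducible and injection-safe. Binding is verified in tests against
expected token lists derived by hand from the v1.2 binding rules *and*
against an independent minimal re-implementation of those rules, on
fixtures covering position sorting, prefixes, `separate: false`,
booleans, arrays with and without `itemSeparator`, defaults and stdout.

Input values may contain `_Column_` placeholders — a targets column name
between single underscores, matched case-insensitively — substituted per
sample row; output globs are specialized the same way (typically
`_SampleName_`). A placeholder naming no column is an error listing the
available columns. Consequence of the grammar: literal underscored
tokens of the form `_word_` cannot appear in input values.

`tool_from_template` builds a tool description from an annotated command
string (`align -x <idx:File:data/ref.fa> -S <sam:out:results/_SampleName_.sam>`):
plain tokens are literals, a `-`-literal immediately before a placeholder
becomes its prefix, positions follow order of appearance, and `out`
placeholders declare a File output globbed on the default's basename.
Re-rendering with the returned defaults reproduces the template's tokens
— a round-trip property tested directly.

## Literate documents

The fence dialect is `` ```{lang step="id" kind="cmd|code" deps="a,b"
run="true"} ``; fences without `step=` stay narrative. Parsing is
lossless (segments concatenate to the source bytes), which is what lets
the scientific report preserve the narrative exactly. `deps` must point
backwards in the document — the same constraint that keeps append-time
validation sufficient for acyclicity. Command-chunk bodies are YAML
(`tool`, `targets`, `inputs`, `outputs_map`, optional `resources`)
rather than raw shell, so every command goes through the CWL binder.

Two deliberate choices where the design was open:

- `targets:` accepts either a file path or an upstream step id; a value
  matching a registered step id wins, otherwise it must be an existing
  file. Upstream references build the step's sample sheet from the
  upstream step's expected outputs via `outputs_to_targets`.
- `run="false"` chunks are kept as narrative and not imported; the
  annotation is the opt-in marker for execution.

`export_workflow` regenerates a document from the registry; import of
the export preserves step ids, kinds, deps and bodies (checked on 100
randomized synthetic documents), and exporting twice is byte-identical.

## Targets sheets

UTF-8 TSV, no quoting; `#` comment lines precede the header and are
preserved verbatim, making read∘write∘read bit-exact. Only `SampleName`
is mandatory (unique, non-empty); other cells may be empty. Tabs are
forbidden inside values — the price of a quoting-free dialect. Sample
labels are the join key for status, reports and file naming, and the
`outputs_to_targets` propagation keeps the SampleName multiset invariant
along any chain of steps (property-tested).

## Visualization and reports

Topology output (DOT, mermaid, standalone HTML/SVG with a small pan/zoom
script) is deterministic: stable node/edge order, no timestamps. Node
tooltips carry the per-step success fraction and mean unit duration;
tooltip durations use whole-second buckets (`<1s`, `3s`, `2m`) so the
rendered topology text is byte-identical across re-runs of the same
workflow, while precise per-unit timings live in the technical report.
Colors: pending gray, running blue, success green, warning orange, error
red. The layered SVG layout places each node one row below its deepest
predecessor (longest-path layering) — adequate for tens of steps, not a
general graph-drawing algorithm.

The technical report has exactly one section per step in topological
order: the sample/state/duration table, the exact argv per unit, the
tool's captured version string (`<exe> --version`, first line, 5 s
timeout, `unknown` on failure — probed once per distinct executable per
run), and the last 20 lines of stderr for non-success units. The
generation timestamp is isolated to a single front-matter line so
regeneration without a re-run differs only there.

The scientific report re-renders the literate source: narrative
untouched, each step chunk replaced by its code, a status badge, and the
artifacts attributed to it. Command-step artifacts are its declared
outputs; code-step artifacts are detected by snapshotting the `results/`
tree around execution. Images are embedded, tables up to 50 rows are
inlined, anything else is linked. Document/workflow mismatches are
listed in an appendix, never fatal. HTML output uses a small in-package
Markdown converter covering exactly the subset the reports emit
(headers, paragraphs, fenced code, pipe tables, lists, images, links).

## Templates and the fixture generator

`skeleton` is the minimal four-step outline. `varseq_mock` is a 35-step
cohort variant-calling demonstration whose stages mirror a real gVCF
workflow — per-sample QC/trimming/alignment/recalibration/gVCF calling
(scatter), cohort consolidation and joint genotyping (many-to-one
gather), SNP/indel selection and filtering (a branch-and-merge diamond),
annotation, and downstream analytics as code steps: gene-level variant
burden, hypergeometric pathway over-representation on a packaged
20-gene/4-pathway toy table (exact tail probability via binomial
coefficients), and drug-target mapping.

All command-line stages are backed by one deterministic mock script
(`tools/mock-tool`) that prepends a stage marker and passes text
through; gene labels planted in the generated reads therefore survive to
the annotated cohort file, where the code steps count them. The fixture
generator is seeded: 3 samples by default (the smallest cohort where
joint genotyping and per-sample branching are non-trivial), 8 read
records per sample (sparse enough that the toy enrichment is
non-degenerate), one toy reference. Same seed, byte-identical files.

What the mocks do *not* emulate: real sequence alignment or variant
calling, file formats (SAM/VCF are name-deep only), tool failure modes,
or any biological signal. Passing runs demonstrate engine mechanics —
scheduling, propagation, resume, reporting — and say nothing about the
scientific validity of an analysis plugged into the same skeleton.

## Problem sizes and numerical choices

Tests and the acceptance script run the templates at their default sizes
(3 samples; 59 execution units for the 35-step template), chosen so a
full demonstration stays a few seconds on one CPU while every engine
feature is exercised. Timing comparisons in tests allow microsecond
slack (`1e-6`) on start/finish ordering; all other checks are exact. Tie
breaks are lexicographic everywhere; degenerate inputs (empty workflow,
header-only targets, empty arrays) render empty-but-valid outputs rather
than erroring.

## Known limitations

- No container execution, cloud backends, or cluster schedulers; the
  executor contract is the extension point.
- CWL coverage is the declared subset; tools relying on expressions or
  workflow composition must be adapted.
- Code steps execute with the engine's interpreter in-process; they are
  trusted code, not sandboxed.
- `memory_mb` is recorded but not enforced locally.
- The scientific report's artifact attribution for code steps is
  mtime-snapshot based and can over-attribute if unrelated processes
  write into `results/` mid-unit.
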