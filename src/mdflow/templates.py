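"""Bundled workflow templates and the toy-data fixture generator.

Two templates ship with the engine:

``skeleton``
    A minimal four-step chain (code → scatter command → scatter command
    driven by propagated targets → gather code step) meant as a starting
    point for custom workflows.

``varseq_mock``
    A 35-step multi-modal variant-calling demonstration reproducing the
    shape of a cohort VAR-Seq analysis: per-sample read QC, trimming and
    alignment (scatter), per-sample gVCF calling, cohort-level gVCF
    consolidation and joint genotyping (gather, many-to-one), SNP/indel
    filtering, functional annotation, and downstream hypothesis-generating
    analytics (gene-level variant burden, toy pathway enrichment on a
    packaged 20-gene/4-pathway table, drug-target mapping).  All heavy
    bioinformatics tools are replaced by one deterministic mock
    text-transform script so the template runs offline in seconds while
    exercising every engine feature; it makes no biological claims.

Projects are fully materialized by :func:`init_template`; all input data
are generated programmatically (seeded) by :func:`generate_fixtures`.
"""

from __future__ import annotations

import random
import stat
from pathlib import Path

import yaml

from .errors import MdflowError, ProjectError
from .model import init_project_layout

TEMPLATE_NAMES = ("skeleton", "varseq_mock")

# ---------------------------------------------------------------------------
# the mock command-line tool (installed under tools/, executable)
# ---------------------------------------------------------------------------

MOCK_TOOL = '''#!/usr/bin/env python3
"""Deterministic text-transform tool standing in for bioinformatics CLIs.

Reads the input file(s), prepends a stage marker, and writes the result
to --out (or stdout).  Comma-joined positional inputs are split apart.
"""
import argparse
import hashlib
import sys

parser = argparse.ArgumentParser(prog="mock-tool")
parser.add_argument("--version", action="version", version="mock-tool 1.0")
parser.add_argument("--tag", required=True)
parser.add_argument("--out", default=None)
parser.add_argument("--ref", default=None)
parser.add_argument("--verbose", action="store_true")
parser.add_argument("-V", dest="extra", action="append", default=[])
parser.add_argument("inputs", nargs="*")
args = parser.parse_args()

files = []
for tok in args.inputs + args.extra:
    files.extend(tok.split(","))

chunks = ["#stage:" + args.tag]
if args.ref:
    ref_text = open(args.ref, encoding="utf-8").read()
    digest = hashlib.sha1(ref_text.encode()).hexdigest()[:8]
    chunks.append("#ref:" + args.ref + ":" + digest)
for name in files:
    text = open(name, encoding="utf-8").read()
    chunks.append("#from:" + name)
    chunks.append(text.rstrip("\\n"))
body = "\\n".join(chunks) + "\\n"
if args.out:
    with open(args.out, "w", encoding="utf-8") as handle:
        handle.write(body)
else:
    sys.stdout.write(body)
if args.verbose:
    print("processed", len(files), "input file(s)", file=sys.stderr)
'''


# ---------------------------------------------------------------------------
# CWL tool descriptions (one generic transform, parametrized per stage)
# ---------------------------------------------------------------------------

def _transform_tool(
    tag: str,
    glob: str,
    *,
    ref: bool = False,
    verbose: bool = False,
    array: str | None = None,  # None | "prefix" | "join"
) -> dict:
    """CWL doc for one mock-tool stage writing ``--out=<file>``."""
    inputs: dict = {
        "outfile": {
            "type": "string",
            "inputBinding": {"position": 2, "prefix": "--out=", "separate": False},
        }
    }
    if ref:
        inputs["ref"] = {
            "type": "File",
            "inputBinding": {"position": 3, "prefix": "--ref"},
        }
    if array == "prefix":  # repeated -V <file>, GATK-style gather
        inputs["infiles"] = {
            "type": "File[]",
            "inputBinding": {"position": 4, "prefix": "-V"},
        }
    elif array == "join":  # single comma-joined token
        inputs["infiles"] = {
            "type": {"type": "array", "items": "File"},
            "inputBinding": {"position": 4, "itemSeparator": ","},
        }
    else:
        inputs["infile"] = {"type": "File", "inputBinding": {"position": 4}}
    if verbose:
        inputs["verbose"] = {
            "type": "boolean?",
            "inputBinding": {"position": 5, "prefix": "--verbose"},
        }
    return {
        "cwlVersion": "v1.2",
        "class": "CommandLineTool",
        "baseCommand": ["mock-tool"],
        "arguments": [{"prefix": "--tag", "valueFrom": tag, "position": 1}],
        "inputs": inputs,
        "outputs": {"out": {"type": "File", "outputBinding": {"glob": glob}}},
    }


def _stdout_tool(tag: str, stdout_pattern: str) -> dict:
    """CWL doc for a stage captured via the ``stdout`` field."""
    return {
        "cwlVersion": "v1.2",
        "class": "CommandLineTool",
        "baseCommand": ["mock-tool"],
        "arguments": [{"prefix": "--tag", "valueFrom": tag, "position": 1}],
        "inputs": {"infile": {"type": "File", "inputBinding": {"position": 2}}},
        "stdout": stdout_pattern,
        "outputs": {"report": {"type": "stdout"}},
    }


# ---------------------------------------------------------------------------
# fixture generator
# ---------------------------------------------------------------------------

GENES = [
    "TP53", "BRCA1", "BRCA2", "EGFR", "KRAS", "PTEN", "MYC", "RB1", "APC",
    "VHL", "ALK", "BRAF", "NRAS", "PIK3CA", "AKT1", "CDK4", "MDM2", "NOTCH1",
    "JAK2", "FLT3",
]

PATHWAYS = {
    "cell_cycle": ["TP53", "RB1", "CDK4", "MDM2", "MYC"],
    "pi3k_signaling": ["PIK3CA", "AKT1", "PTEN", "EGFR"],
    "ras_mapk": ["KRAS", "NRAS", "BRAF", "EGFR", "ALK"],
    "dna_repair": ["BRCA1", "BRCA2", "TP53", "APC"],
}

DRUG_TARGETS = {
    "TP53": "nutlin-3", "BRCA1": "olaparib", "BRCA2": "talazoparib",
    "EGFR": "erlotinib", "KRAS": "sotorasib", "BRAF": "vemurafenib",
    "ALK": "crizotinib", "CDK4": "palbociclib", "MDM2": "idasanutlin",
    "JAK2": "ruxolitinib", "FLT3": "midostaurin", "PIK3CA": "alpelisib",
    "AKT1": "capivasertib",
}

READS_PER_SAMPLE = 8
READ_LENGTH = 24


def generate_fixtures(
    n_samples: int, seed: int, data_dir: str | Path
) -> dict[str, Path]:
    """Write deterministic toy per-sample read files plus a reference.

    Each "read" line carries a read id, a gene label drawn from the toy
    gene pool and a random sequence; the gene labels are what the
    downstream mock analytics count.  Same seed → byte-identical files.
    """
    if n_samples < 1:
        raise MdflowError(f"n_samples must be >= 1, got {n_samples}")
    rng = random.Random(seed)
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ref_lines = [">toy_reference"]
    for i in range(6):
        ref_lines.append("".join(rng.choice("ACGT") for _ in range(60)))
    ref = data_dir / "ref.fa"
    ref.write_text("\n".join(ref_lines) + "\n", encoding="utf-8")
    paths["ref"] = ref
    for i in range(1, n_samples + 1):
        sample = f"S{i}"
        lines = []
        for r in range(READS_PER_SAMPLE):
            gene = rng.choice(GENES)
            seq = "".join(rng.choice("ACGT") for _ in range(READ_LENGTH))
            lines.append(f"read{r + 1} {gene} {seq}")
        p = data_dir / f"{sample}.fastq"
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[sample] = p
    return paths


def _write_reference_tables(data_dir: Path) -> None:
    lines = ["gene\tpathway"]
    for pw, genes in PATHWAYS.items():
        for g in genes:
            lines.append(f"{g}\t{pw}")
    (data_dir / "pathways.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    lines = ["gene\tdrug"]
    for g, d in DRUG_TARGETS.items():
        lines.append(f"{g}\t{d}")
    (data_dir / "drug.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def _targets_text(n_samples: int, project_name: str) -> str:
    lines = [
        f"# Project: {project_name}",
        "# Toy cohort generated by the bundled fixture generator",
        "FileName\tSampleName\tFactor",
    ]
    for i in range(1, n_samples + 1):
        factor = "A" if i % 2 else "B"
        lines.append(f"data/S{i}.fastq\tS{i}\t{factor}")
    return "\n".join(lines) + "\n"


COHORT_TARGETS = "FileName\tSampleName\n\tcohort\n"


# ---------------------------------------------------------------------------
# document assembly
# ---------------------------------------------------------------------------

def _chunk(step: str, kind: str, deps: list[str], body: str, narrative: str = "") -> str:
    lang = "yaml" if kind == "cmd" else "python"
    attrs = [f'step="{step}"', f'kind="{kind}"']
    if deps:
        attrs.append(f'deps="{",".join(deps)}"')
    if not body.endswith("\n"):
        body += "\n"
    text = ""
    if narrative:
        text += narrative.rstrip("\n") + "\n\n"
    text += "```{%s %s}\n%s```\n\n" % (lang, " ".join(attrs), body)
    return text


def _cmd_body(
    tool: str,
    targets: str,
    inputs: dict | None = None,
    outputs_map: dict | None = None,
) -> str:
    spec: dict = {"tool": tool, "targets": targets}
    if inputs:
        spec["inputs"] = inputs
    if outputs_map:
        spec["outputs_map"] = outputs_map
    return yaml.safe_dump(spec, sort_keys=False)


# ---------------------------------------------------------------------------
# skeleton template
# ---------------------------------------------------------------------------

def _skeleton_doc(n_samples: int) -> str:
    parts = [
        "# Skeleton workflow\n\n"
        "A minimal end-to-end outline: a setup code step, a per-sample\n"
        "command step, a second command step driven by the first step's\n"
        "outputs, and a gather code step summarizing the cohort.\n\n"
    ]
    parts.append(_chunk(
        "setup", "code", [],
        "import os\n"
        "os.makedirs('results', exist_ok=True)\n"
        "print('project ready')\n",
        "## Setup",
    ))
    parts.append(_chunk(
        "count_reads", "cmd", ["setup"],
        _cmd_body(
            "param/count_reads.cwl",
            "targets.tsv",
            inputs={"infile": "_FileName_",
                    "outfile": "results/_SampleName_.count.txt"},
        ),
        "## Per-sample read counting (scatter)",
    ))
    parts.append(_chunk(
        "normalize", "cmd", ["count_reads"],
        _cmd_body(
            "param/normalize.cwl",
            "count_reads",
            inputs={"infile": "_FileName_",
                    "outfile": "results/_SampleName_.norm.txt"},
            outputs_map={"out": "FileName"},
        ),
        "## Normalization driven by propagated targets",
    ))
    parts.append(_chunk(
        "summarize", "code", ["normalize"],
        "import glob\n"
        "lines = []\n"
        "for path in sorted(glob.glob('results/*.norm.txt')):\n"
        "    n = sum(1 for _ in open(path, encoding='utf-8'))\n"
        "    lines.append(f'{path}\\t{n}')\n"
        "with open('results/summary.txt', 'w', encoding='utf-8') as fh:\n"
        "    fh.write('\\n'.join(lines) + '\\n')\n"
        "print('summarized', len(lines), 'samples')\n",
        "## Cohort summary (gather)",
    ))
    return "".join(parts)


def _skeleton_tools() -> dict[str, dict]:
    return {
        "count_reads": _transform_tool("count", "_SampleName_.count.txt"),
        "normalize": _transform_tool("normalize", "_SampleName_.norm.txt"),
    }


# ---------------------------------------------------------------------------
# varseq_mock template (35 steps)
# ---------------------------------------------------------------------------

def _varseq_tools() -> dict[str, dict]:
    return {
        "read_qc": _stdout_tool("qc", "_SampleName_.qc.txt"),
        "trim": _transform_tool("trim", "_SampleName_.trimmed.fastq", verbose=True),
        "trimmed_qc": _stdout_tool("qc2", "_SampleName_.qc2.txt"),
        "index_ref": _transform_tool("index", "genome.idx"),
        "ref_dict": _transform_tool("dict", "genome.dict"),
        "align": _transform_tool("align", "_SampleName_.sam", ref=True),
        "sortaln": _transform_tool("sort", "_SampleName_.sorted.sam"),
        "markdup": _transform_tool("markdup", "_SampleName_.dedup.sam"),
        "alnindex": _transform_tool("alnindex", "_SampleName_.sam.bai"),
        "alnstats": _stdout_tool("alnstats", "_SampleName_.alnstats.txt"),
        "bqsr": _transform_tool("bqsr", "_SampleName_.recal.table", ref=True),
        "applybqsr": _transform_tool("applybqsr", "_SampleName_.recal.sam"),
        "gvcf": _transform_tool("gvcf", "_SampleName_.g.vcf", ref=True),
        "gvcfindex": _transform_tool("gvcfindex", "_SampleName_.g.vcf.idx"),
        "consolidate": _transform_tool("consolidate", "cohort.g.vcf", array="prefix"),
        "joint": _transform_tool("joint", "cohort.vcf", ref=True),
        "selectsnp": _transform_tool("select_snp", "cohort.snp.vcf"),
        "selectindel": _transform_tool("select_indel", "cohort.indel.vcf"),
        "filtersnp": _transform_tool("filter_snp", "cohort.snp.filt.vcf"),
        "filterindel": _transform_tool("filter_indel", "cohort.indel.filt.vcf"),
        "mergevcf": _transform_tool("merge", "cohort.filtered.vcf", array="join"),
        "annotate": _transform_tool("annotate", "cohort.annotated.tsv", ref=True),
    }


_CODE_QC_SUMMARY = """\
import glob
rows = []
for path in sorted(glob.glob('results/*.qc.txt')):
    n_reads = sum(1 for line in open(path, encoding='utf-8')
                  if line.startswith('read'))
    rows.append(f"{path}\\t{n_reads}")
with open('results/qc_summary.tsv', 'w', encoding='utf-8') as fh:
    fh.write('file\\treads\\n' + '\\n'.join(rows) + '\\n')
"""

_CODE_TRIM_SUMMARY = """\
import glob
rows = []
for path in sorted(glob.glob('results/*.qc2.txt')):
    n_reads = sum(1 for line in open(path, encoding='utf-8')
                  if line.startswith('read'))
    rows.append(f"{path}\\t{n_reads}")
with open('results/trim_summary.tsv', 'w', encoding='utf-8') as fh:
    fh.write('file\\treads\\n' + '\\n'.join(rows) + '\\n')
"""

_CODE_ALN_SUMMARY = """\
import glob
rows = []
for path in sorted(glob.glob('results/*.alnstats.txt')):
    aligned = sum(1 for line in open(path, encoding='utf-8')
                  if line.startswith('read'))
    rows.append(f"{path}\\t{aligned}")
with open('results/alignment_summary.tsv', 'w', encoding='utf-8') as fh:
    fh.write('file\\taligned\\n' + '\\n'.join(rows) + '\\n')
"""

_CODE_VARIANT_STATS = """\
text = open('results/cohort.filtered.vcf', encoding='utf-8').read()
records = [l for l in text.splitlines() if l.startswith('read')]
stages = [l for l in text.splitlines() if l.startswith('#stage:')]
with open('results/variant_stats.tsv', 'w', encoding='utf-8') as fh:
    fh.write('metric\\tvalue\\n')
    fh.write(f'records\\t{len(records)}\\n')
    fh.write(f'pipeline_stages\\t{len(stages)}\\n')
"""

_CODE_ANN_SUMMARY = """\
genes = set()
for line in open('data/pathways.tsv', encoding='utf-8'):
    if not line.startswith('gene'):
        genes.add(line.split('\\t')[0])
hits = {}
for line in open('results/cohort.annotated.tsv', encoding='utf-8'):
    for tok in line.split():
        if tok in genes:
            hits[tok] = hits.get(tok, 0) + 1
annotated_genes = sorted(hits)
with open('results/annotation_summary.tsv', 'w', encoding='utf-8') as fh:
    fh.write('metric\\tvalue\\n')
    fh.write(f'genes_hit\\t{len(annotated_genes)}\\n')
    fh.write(f'total_hits\\t{sum(hits.values())}\\n')
"""

_CODE_VAR_FREQ = """\
import re
counts = {}
sample = None
for line in open('results/cohort.annotated.tsv', encoding='utf-8'):
    m = re.match(r'#from:.*?(S\\d+)\\.', line)
    if m:
        sample = m.group(1)
    elif line.startswith('read') and sample:
        counts[sample] = counts.get(sample, 0) + 1
with open('results/variant_frequencies.tsv', 'w', encoding='utf-8') as fh:
    fh.write('sample\\tvariants\\n')
    for s in sorted(counts):
        fh.write(f'{s}\\t{counts[s]}\\n')
"""

_CODE_PLOT = """\
rows = [l.split('\\t') for l in
        open('results/variant_frequencies.tsv', encoding='utf-8')
        .read().splitlines()[1:]]
width, bar_h = 320, 22
parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
         f'height="{(len(rows) + 1) * bar_h}" font-size="12">']
peak = max((int(v) for _, v in rows), default=1)
for i, (s, v) in enumerate(rows):
    w = int(220 * int(v) / peak)
    y = i * bar_h + 4
    parts.append(f'<text x="2" y="{y + 12}">{s}</text>')
    parts.append(f'<rect x="40" y="{y}" width="{w}" height="{bar_h - 8}" '
                 'fill="#4caf50"/>')
    parts.append(f'<text x="{44 + w}" y="{y + 12}">{v}</text>')
parts.append('</svg>')
with open('results/variant_summary.svg', 'w', encoding='utf-8') as fh:
    fh.write(''.join(parts))
"""

_CODE_GENE_BURDEN = """\
genes = set()
for line in open('data/pathways.tsv', encoding='utf-8'):
    if not line.startswith('gene'):
        genes.add(line.split('\\t')[0])
burden = {}
for line in open('results/cohort.annotated.tsv', encoding='utf-8'):
    if line.startswith('read'):
        for tok in line.split():
            if tok in genes:
                burden[tok] = burden.get(tok, 0) + 1
with open('results/gene_burden.tsv', 'w', encoding='utf-8') as fh:
    fh.write('gene\\tburden\\n')
    for g in sorted(burden):
        fh.write(f'{g}\\t{burden[g]}\\n')
"""

_CODE_ENRICHMENT = """\
from math import comb
pathways = {}
universe = set()
for line in open('data/pathways.tsv', encoding='utf-8'):
    if line.startswith('gene'):
        continue
    gene, pw = line.rstrip('\\n').split('\\t')
    pathways.setdefault(pw, set()).add(gene)
    universe.add(gene)
hit = set()
for line in open('results/gene_burden.tsv', encoding='utf-8'):
    if not line.startswith('gene'):
        hit.add(line.split('\\t')[0])
N, n = len(universe), len(hit & universe)
rows = []
for pw, members in sorted(pathways.items()):
    K = len(members)
    k = len(members & hit)
    # hypergeometric upper tail: P(X >= k)
    p = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    p /= comb(N, n)
    rows.append(f'{pw}\\t{K}\\t{k}\\t{p:.4f}')
with open('results/pathway_enrichment.tsv', 'w', encoding='utf-8') as fh:
    fh.write('pathway\\tsize\\thits\\tp_hypergeom\\n' + '\\n'.join(rows) + '\\n')
"""

_CODE_DRUG_MAP = """\
drug_of = {}
for line in open('data/drug.tsv', encoding='utf-8'):
    if not line.startswith('gene'):
        gene, drug = line.rstrip('\\n').split('\\t')
        drug_of[gene] = drug
rows = []
for line in open('results/gene_burden.tsv', encoding='utf-8'):
    if line.startswith('gene'):
        continue
    gene, burden = line.rstrip('\\n').split('\\t')
    if gene in drug_of:
        rows.append(f'{gene}\\t{burden}\\t{drug_of[gene]}')
with open('results/drug_targets.tsv', 'w', encoding='utf-8') as fh:
    fh.write('gene\\tburden\\tdrug\\n' + '\\n'.join(rows) + '\\n')
"""

_CODE_SESSION = """\
import sys
with open('results/session_info.txt', 'w', encoding='utf-8') as fh:
    fh.write('python\\t' + sys.version.split()[0] + '\\n')
    fh.write('platform\\t' + sys.platform + '\\n')
"""


def _varseq_doc(n_samples: int) -> str:
    samples = [f"S{i}" for i in range(1, n_samples + 1)]
    gvcf_paths = [f"results/{s}.g.vcf" for s in samples]
    c: list[str] = [
        "# Multi-modal VAR-Seq workflow (mock)\n\n"
        "Cohort-level variant analysis demonstration: per-sample read QC,\n"
        "trimming and alignment, gVCF-based variant calling with joint\n"
        "genotyping, cohort filtering and annotation, followed by\n"
        "hypothesis-generating analytics (gene burden, pathway enrichment,\n"
        "drug-target mapping). All command-line tools are deterministic\n"
        "mock text transforms; the workflow demonstrates engine mechanics,\n"
        "not biology.\n\n"
    ]
    add = c.append

    add(_chunk("load_packages", "code", [],
               "import os\nimport sys\nos.makedirs('results', exist_ok=True)\n"
               "print('session started:', sys.version.split()[0])\n",
               "## Environment setup"))
    add(_chunk("check_inputs", "code", ["load_packages"],
               "required = ['targets.tsv', 'data/ref.fa', 'data/pathways.tsv',\n"
               "            'data/drug.tsv']\n"
               "missing = [p for p in required if not os.path.exists(p)]\n"
               "assert not missing, f'missing inputs: {missing}'\n"
               "print('all inputs present')\n"))

    add(_chunk("raw_read_qc", "cmd", ["check_inputs"],
               _cmd_body("param/read_qc.cwl", "targets.tsv",
                         inputs={"infile": "_FileName_"}),
               "## Read quality assessment"))
    add(_chunk("qc_summary", "code", ["raw_read_qc"], _CODE_QC_SUMMARY))

    add(_chunk("trim_reads", "cmd", ["check_inputs"],
               _cmd_body("param/trim.cwl", "targets.tsv",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/_SampleName_.trimmed.fastq",
                                 "verbose": True}),
               "## Read preprocessing"))
    add(_chunk("trimmed_read_qc", "cmd", ["trim_reads"],
               _cmd_body("param/trimmed_qc.cwl", "trim_reads",
                         inputs={"infile": "_FileName_"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("trim_summary", "code", ["trimmed_read_qc"], _CODE_TRIM_SUMMARY))

    add(_chunk("index_reference", "cmd", ["check_inputs"],
               _cmd_body("param/index_ref.cwl", "data/cohort.tsv",
                         inputs={"infile": "data/ref.fa",
                                 "outfile": "results/genome.idx"}),
               "## Reference preparation"))
    add(_chunk("reference_dict", "cmd", ["index_reference"],
               _cmd_body("param/ref_dict.cwl", "data/cohort.tsv",
                         inputs={"infile": "data/ref.fa",
                                 "outfile": "results/genome.dict"})))

    add(_chunk("align_reads", "cmd", ["trim_reads", "index_reference"],
               _cmd_body("param/align.cwl", "trim_reads",
                         inputs={"infile": "_FileName_",
                                 "ref": "results/genome.idx",
                                 "outfile": "results/_SampleName_.sam"},
                         outputs_map={"out": "FileName"}),
               "## Alignment (scatter)"))
    add(_chunk("sort_alignments", "cmd", ["align_reads"],
               _cmd_body("param/sortaln.cwl", "align_reads",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/_SampleName_.sorted.sam"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("mark_duplicates", "cmd", ["sort_alignments"],
               _cmd_body("param/markdup.cwl", "sort_alignments",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/_SampleName_.dedup.sam"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("index_alignments", "cmd", ["mark_duplicates"],
               _cmd_body("param/alnindex.cwl", "mark_duplicates",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/_SampleName_.sam.bai"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("alignment_stats", "cmd", ["mark_duplicates"],
               _cmd_body("param/alnstats.cwl", "mark_duplicates",
                         inputs={"infile": "_FileName_"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("alignment_summary", "code", ["alignment_stats"], _CODE_ALN_SUMMARY))

    add(_chunk("base_recalibration", "cmd", ["mark_duplicates", "reference_dict"],
               _cmd_body("param/bqsr.cwl", "mark_duplicates",
                         inputs={"infile": "_FileName_",
                                 "ref": "results/genome.dict",
                                 "outfile": "results/_SampleName_.recal.table"},
                         outputs_map={"out": "FileName"}),
               "## Variant calling (gVCF strategy)"))
    add(_chunk("apply_recalibration", "cmd", ["base_recalibration"],
               _cmd_body("param/applybqsr.cwl", "base_recalibration",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/_SampleName_.recal.sam"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("call_variants_gvcf", "cmd",
               ["apply_recalibration", "index_alignments"],
               _cmd_body("param/gvcf.cwl", "apply_recalibration",
                         inputs={"infile": "_FileName_",
                                 "ref": "results/genome.idx",
                                 "outfile": "results/_SampleName_.g.vcf"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("index_gvcfs", "cmd", ["call_variants_gvcf"],
               _cmd_body("param/gvcfindex.cwl", "call_variants_gvcf",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/_SampleName_.g.vcf.idx"},
                         outputs_map={"out": "FileName"})))

    add(_chunk("consolidate_gvcfs", "cmd", ["call_variants_gvcf", "index_gvcfs"],
               _cmd_body("param/consolidate.cwl", "data/cohort.tsv",
                         inputs={"infiles": gvcf_paths,
                                 "outfile": "results/cohort.g.vcf"}),
               "## Joint genotyping (gather: per-sample gVCFs -> cohort)"))
    add(_chunk("joint_genotyping", "cmd", ["consolidate_gvcfs"],
               _cmd_body("param/joint.cwl", "consolidate_gvcfs",
                         inputs={"infile": "_FileName_",
                                 "ref": "results/genome.idx",
                                 "outfile": "results/cohort.vcf"},
                         outputs_map={"out": "FileName"})))

    add(_chunk("select_snps", "cmd", ["joint_genotyping"],
               _cmd_body("param/selectsnp.cwl", "joint_genotyping",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/cohort.snp.vcf"},
                         outputs_map={"out": "FileName"}),
               "## Cohort-level filtering"))
    add(_chunk("select_indels", "cmd", ["joint_genotyping"],
               _cmd_body("param/selectindel.cwl", "joint_genotyping",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/cohort.indel.vcf"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("filter_snps", "cmd", ["select_snps"],
               _cmd_body("param/filtersnp.cwl", "select_snps",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/cohort.snp.filt.vcf"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("filter_indels", "cmd", ["select_indels"],
               _cmd_body("param/filterindel.cwl", "select_indels",
                         inputs={"infile": "_FileName_",
                                 "outfile": "results/cohort.indel.filt.vcf"},
                         outputs_map={"out": "FileName"})))
    add(_chunk("merge_filtered", "cmd", ["filter_snps", "filter_indels"],
               _cmd_body("param/mergevcf.cwl", "data/cohort.tsv",
                         inputs={"infiles": ["results/cohort.snp.filt.vcf",
                                             "results/cohort.indel.filt.vcf"],
                                 "outfile": "results/cohort.filtered.vcf"})))
    add(_chunk("variant_stats", "code", ["merge_filtered"], _CODE_VARIANT_STATS))

    add(_chunk("annotate_variants", "cmd", ["merge_filtered"],
               _cmd_body("param/annotate.cwl", "merge_filtered",
                         inputs={"infile": "_FileName_",
                                 "ref": "data/pathways.tsv",
                                 "outfile": "results/cohort.annotated.tsv"},
                         outputs_map={"out": "FileName"}),
               "## Functional annotation"))
    add(_chunk("annotation_summary", "code", ["annotate_variants"], _CODE_ANN_SUMMARY))
    add(_chunk("variant_frequencies", "code", ["annotate_variants"], _CODE_VAR_FREQ))
    add(_chunk("plot_variant_summary", "code", ["variant_frequencies"], _CODE_PLOT))

    add(_chunk("gene_burden", "code", ["annotate_variants"], _CODE_GENE_BURDEN,
               "## Hypothesis-generating analytics"))
    add(_chunk("pathway_enrichment", "code", ["gene_burden"], _CODE_ENRICHMENT))
    add(_chunk("drug_target_mapping", "code", ["pathway_enrichment"], _CODE_DRUG_MAP))
    add(_chunk("session_info", "code",
               ["qc_summary", "trim_summary", "alignment_summary", "variant_stats",
                "annotation_summary", "plot_variant_summary", "drug_target_mapping"],
               _CODE_SESSION,
               "## Session provenance"))
    return "".join(c)


VARSEQ_STEP_COUNT = 35
DEFAULT_SAMPLES = {"skeleton": 3, "varseq_mock": 3}


# ---------------------------------------------------------------------------
# project materialization
# ---------------------------------------------------------------------------

def init_template(
    template: str, directory: str | Path, seed: int = 1, n_samples: int | None = None
) -> Path:
    """Materialize a template into *directory* (must be absent or empty)."""
    if template not in TEMPLATE_NAMES:
        raise MdflowError(
            f"unknown template {template!r}; available: {', '.join(TEMPLATE_NAMES)}"
        )
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()):
        raise ProjectError(f"refusing to initialize into non-empty directory {directory}")
    init_project_layout(directory)
    n = n_samples or DEFAULT_SAMPLES[template]

    tools_dir = directory / "tools"
    tools_dir.mkdir(exist_ok=True)
    script = tools_dir / "mock-tool"
    script.write_text(MOCK_TOOL, encoding="utf-8")
    script.chmod(script.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)

    generate_fixtures(n, seed, directory / "data")
    (directory / "targets.tsv").write_text(
        _targets_text(n, template), encoding="utf-8"
    )

    if template == "skeleton":
        tool_docs = _skeleton_tools()
        doc_text = _skeleton_doc(n)
    else:
        tool_docs = _varseq_tools()
        doc_text = _varseq_doc(n)
        _write_reference_tables(directory / "data")
        (directory / "data" / "cohort.tsv").write_text(
            COHORT_TARGETS, encoding="utf-8"
        )

    for name, doc in tool_docs.items():
        (directory / "param" / f"{name}.cwl").write_text(
            yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
        )
    (directory / "workflow.md").write_text(doc_text, encoding="utf-8")
    return directory
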