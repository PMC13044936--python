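"""Sample-sheet (targets) handling.

A targets file is the tab-separated sample sheet that drives per-sample
execution: one row per sample, a mandatory unique ``SampleName`` column,
and arbitrary further metadata columns (input file paths, factors, ...).
Leading lines starting with ``#`` are free-text comments and are preserved
verbatim so that a read/write cycle is bit-exact.

The dialect is deliberately minimal: UTF-8, hard tab separators, no
quoting.  Tab characters are therefore forbidden inside values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import TargetsError

SAMPLE_COLUMN = "SampleName"


@dataclass
class TargetsTable:
    """In-memory sample sheet.

    Attributes
    ----------
    comments:
        Leading comment lines (each starting with ``#``), kept verbatim.
    columns:
        Ordered column names; must contain ``SampleName``.
    rows:
        One mapping per sample, each covering every column (empty string
        for missing optional metadata).
    """

    columns: list[str]
    rows: list[dict[str, str]] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if SAMPLE_COLUMN not in self.columns:
            raise TargetsError(
                f"targets table lacks the mandatory {SAMPLE_COLUMN!r} column "
                f"(columns: {self.columns})"
            )
        if len(set(self.columns)) != len(self.columns):
            raise TargetsError(f"duplicate column names in {self.columns}")
        for c in self.comments:
            if not c.startswith("#"):
                raise TargetsError(f"comment line must start with '#': {c!r}")
        seen: dict[str, int] = {}
        for i, row in enumerate(self.rows):
            if set(row) != set(self.columns):
                raise TargetsError(
                    f"row {i} keys {sorted(row)} do not match columns {self.columns}"
                )
            for col, val in row.items():
                if "\t" in val:
                    raise TargetsError(
                        f"tab character inside value of column {col!r}, row {i} "
                        "(tabs are forbidden in values)"
                    )
            name = row[SAMPLE_COLUMN]
            if not name:
                raise TargetsError(f"empty {SAMPLE_COLUMN} in row {i}")
            seen[name] = seen.get(name, 0) + 1
        dups = sorted(n for n, k in seen.items() if k > 1)
        if dups:
            raise TargetsError(f"duplicate {SAMPLE_COLUMN} values: {', '.join(dups)}")

    # -- accessors ----------------------------------------------------
    @property
    def sample_names(self) -> list[str]:
        return [row[SAMPLE_COLUMN] for row in self.rows]

    def get_column(self, name: str) -> list[str]:
        """Values of column *name* in row order."""
        if name not in self.columns:
            raise TargetsError(
                f"unknown column {name!r}; available columns: {', '.join(self.columns)}"
            )
        return [row[name] for row in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetsTable):
            return NotImplemented
        return (
            self.columns == other.columns
            and self.rows == other.rows
            and self.comments == other.comments
        )


def read_targets(path: str | Path) -> TargetsTable:
    """Read a targets TSV file.

    Comment lines (``#`` prefix) must precede the header; the first
    non-comment line is the header.
    """
    path = Path(path)
    if not path.is_file():
        raise TargetsError(f"targets file not found: {path}")
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    comments: list[str] = []
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        comments.append(lines[i])
        i += 1
    if i >= len(lines):
        raise TargetsError(f"{path}: no header line found")
    columns = lines[i].split("\t")
    rows: list[dict[str, str]] = []
    for lineno, line in enumerate(lines[i + 1 :], start=i + 2):
        if line == "":
            continue
        values = line.split("\t")
        if len(values) != len(columns):
            raise TargetsError(
                f"{path}:{lineno}: ragged row — {len(values)} fields, "
                f"expected {len(columns)}"
            )
        rows.append(dict(zip(columns, values)))
    try:
        return TargetsTable(columns=columns, rows=rows, comments=comments)
    except TargetsError as exc:
        raise TargetsError(f"{path}: {exc}") from exc


def write_targets(table: TargetsTable, path: str | Path) -> Path:
    """Write *table* as TSV; ``read_targets`` on the result is bit-exact."""
    table.validate()
    path = Path(path)
    lines = list(table.comments)
    lines.append("\t".join(table.columns))
    for row in table.rows:
        lines.append("\t".join(row[c] for c in table.columns))
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise TargetsError(f"cannot write targets file {path}: {exc}") from exc
    return path


def make_targets(
    sample_names: Iterable[str],
    extra: Mapping[str, Iterable[str]] | None = None,
    comments: Iterable[str] = (),
) -> TargetsTable:
    """Convenience constructor from parallel column value lists."""
    names = list(sample_names)
    columns = [SAMPLE_COLUMN]
    cols: dict[str, list[str]] = {}
    if extra:
        for k, v in extra.items():
            columns.append(k)
            cols[k] = list(v)
    rows = []
    for i, n in enumerate(names):
        row = {SAMPLE_COLUMN: n}
        for k, v in cols.items():
            row[k] = v[i]
        rows.append(row)
    return TargetsTable(columns=columns, rows=rows, comments=list(comments))


def outputs_to_targets(wf, upstream: str, column_map: Mapping[str, str]) -> TargetsTable:
    """Derive a downstream targets table from an upstream step's outputs.

    One row per upstream sample; ``SampleName`` (and every other metadata
    column) is carried over verbatim, and each ``output id -> column``
    entry of *column_map* adds (or replaces) a column holding that
    sample's expected output path.  This is how sample labels propagate
    through the workflow: downstream steps are driven by the files the
    upstream step promises to produce.
    """
    if upstream not in wf.steps:
        raise TargetsError(f"unknown upstream step {upstream!r}")
    step = wf.steps[upstream]
    if step.kind != "command":
        raise TargetsError(
            f"step {upstream!r} is a code step; only command steps declare outputs"
        )
    known = {o.id for o in step.tool.outputs}
    unknown = sorted(set(column_map) - known)
    if unknown:
        raise TargetsError(
            f"step {upstream!r} has no output id(s) {', '.join(unknown)}; "
            f"available: {', '.join(sorted(known))}"
        )
    base = step.targets
    columns = list(base.columns)
    rows = [dict(r) for r in base.rows]
    for output_id, column in column_map.items():
        if column not in columns:
            columns.append(column)
        for row in rows:
            cmd = step.command_for(row[SAMPLE_COLUMN])
            row[column] = cmd.expected_outputs[output_id]
    return TargetsTable(columns=columns, rows=rows, comments=list(base.comments))
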