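"""On-disk run-state store (``.sprproject/status.json``).

Schema (version 1)::

    {
      "schema_version": 1,
      "saved_at": <unix time>,
      "versions": {"<executable>": "<first line of --version output>"},
      "run_meta": {...},
      "units": [
        {"step": ..., "sample": ..., "state": ...,
         "started_at": ..., "duration_s": ...,
         "argv": [...] | null, "log_out": ..., "log_err": ...},
        ...
      ]
    }

Per-unit logs live under ``.sprproject/logs/<step>/<sample>.{out,err}``.
The store is written atomically (tmp file + rename) after every unit so
an interrupted run can always be resumed from the last completed unit.
"""

from __future__ import annotations

import json
import os
import time
from pathlib import Path

from .errors import StateError
from .model import STATE_DIR, StatusMatrix, Workflow

SCHEMA_VERSION = 1
STATE_FILE = "status.json"


def state_path(project_dir: str | Path) -> Path:
    return Path(project_dir) / STATE_DIR / STATE_FILE


def save_state(wf: Workflow) -> Path:
    """Persist the workflow's status matrix; returns the state file path."""
    path = state_path(wf.project_dir)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "saved_at": time.time(),
        "versions": wf.versions,
        "run_meta": wf.run_meta,
        "units": wf.status.to_records(),
    }
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    os.replace(tmp, path)
    return path


def load_state(project_dir: str | Path) -> StatusMatrix:
    """Restore the persisted status matrix; empty project → empty matrix."""
    path = state_path(project_dir)
    if not path.is_file():
        return StatusMatrix()
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise StateError(
            f"corrupt state file {path}: {exc} "
            "(re-run with ignore_state=True / --ignore-state to start fresh)"
        ) from exc
    if not isinstance(doc, dict) or "units" not in doc:
        raise StateError(
            f"corrupt state file {path}: missing 'units' "
            "(re-run with ignore_state=True / --ignore-state to start fresh)"
        )
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise StateError(f"unsupported state schema version {version!r} in {path}")
    try:
        return StatusMatrix.from_records(doc["units"])
    except (KeyError, TypeError) as exc:
        raise StateError(f"corrupt state file {path}: {exc}") from exc


def load_meta(project_dir: str | Path) -> dict:
    """Versions and run metadata from the state file (empty if none)."""
    path = state_path(project_dir)
    if not path.is_file():
        return {"versions": {}, "run_meta": {}}
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError):
        return {"versions": {}, "run_meta": {}}
    return {
        "versions": doc.get("versions", {}),
        "run_meta": doc.get("run_meta", {}),
    }
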