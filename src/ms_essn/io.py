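"""Cohort-table I/O, packaged fixtures, and run manifests.

Cohort CSVs have one row per subject with columns ``subject_id``,
``group`` and the six analytes (cells/mm^3); comma-separated, ``.``
decimal, UTF-8, header mandatory.  Every CLI run writes a JSON manifest
(command, resolved configuration, seeds, package version, input digests,
outputs) sufficient to re-run it.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd

from .calibration import ANALYTES

__all__ = ["read_cohort", "write_cohort", "load_table1", "load_marking_table",
           "load_packaged_model", "write_manifest", "CohortValidationError"]

REQUIRED_COLUMNS = ("subject_id", "group") + ANALYTES


class CohortValidationError(ValueError):
    pass


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    extra = [c for c in table.columns if c not in REQUIRED_COLUMNS]
    if missing:
        raise CohortValidationError(
            f"missing columns: {missing}" + (f"; extra columns: {extra}" if extra else ""))
    for a in ANALYTES:
        vals = pd.to_numeric(table[a], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise CohortValidationError(f"non-numeric value in {a!r}, row {row}")
        if (vals < 0).any():
            row = int((vals < 0).idxmax())
            raise CohortValidationError(
                f"negative count in column {a!r}, row {row} "
                f"(subject {table['subject_id'].iloc[row]!r})")
    return table[list(REQUIRED_COLUMNS)]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    return validate_cohort(pd.read_csv(path))


def write_cohort(table: pd.DataFrame, path) -> None:
    validate_cohort(table).to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("ms_essn.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """The packaged 16-subject reference cohort (8 MS, 8 HD)."""
    with resources.as_file(_data_path("table1.csv")) as p:
        return read_cohort(p)


def load_marking_table() -> pd.DataFrame:
    """The packaged nonzero rows of the reference initial marking."""
    with resources.as_file(_data_path("marking_table2.csv")) as p:
        return pd.read_csv(p)


def load_packaged_model():
    """The RRMS net from the shipped structured-text model file."""
    from .essn import load_model

    with resources.as_file(_data_path("rrms_net.yaml")) as p:
        return load_model(p)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(out_dir, command: str, config: dict,
                   inputs: list | None = None,
                   outputs: list | None = None) -> Path:
    """One manifest JSON per CLI run, next to its outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _digest(p) for p in (inputs or []) if Path(p).exists()},
        "outputs": [str(p) for p in (outputs or [])],
    }
    path = out_dir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
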