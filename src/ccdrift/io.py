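"""Table validation, config files and run manifests.

All on-disk tables are comma-delimited UTF-8 text with mandatory
headers.  Validation reports every violation with its row number and
distinguishes hard failures (missing columns, cycles in parent links,
non-monotone time grids, negative intensities) from warnings.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationReport",
    "validate_tables",
    "load_config",
    "RunManifest",
]

SCHEMAS = {
    "pedigree": {
        "required": ["cell_id", "parent_id", "birth_time", "t_g1", "t_sg2m"],
        "non_negative": ["t_g1", "t_sg2m", "c0", "g0", "c_end", "g_end"],
    },
    "trajectories": {
        "required": ["cell_id", "time_h", "cdt1", "geminin"],
        "non_negative": ["cdt1", "geminin"],
    },
    "census": {
        "required": ["time", "total"],
        "non_negative": ["total"],
    },
}


@dataclass
class ValidationReport:
    path: str
    schema: str
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self):
        lines = [f"{self.path} [{self.schema}]: {'PASS' if self.ok else 'FAIL'}"]
        lines += [f"  error: {e}" for e in self.errors]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def _check_pedigree_links(df: pd.DataFrame, rep: ValidationReport) -> None:
    parent = {}
    for i, row in enumerate(df.itertuples(index=False)):
        pid = row.parent_id
        if pd.isna(pid) or pid == "":
            pid = None
        parent[str(row.cell_id)] = None if pid is None else str(pid)
    for i, (cid, pid) in enumerate(parent.items()):
        if pid is not None and pid not in parent:
            rep.errors.append(f"row {i}: parent {pid!r} of {cid!r} not in table")
    n = len(parent)
    for cid in parent:
        cur, hops = cid, 0
        while parent.get(cur) is not None:
            cur = parent[cur]
            hops += 1
            if hops > n:
                rep.errors.append(f"pedigree cycle detected involving {cid!r}")
                return


def validate_tables(path, schema: str) -> ValidationReport:
    """Validate a delimited table against a named schema.

    Schemas: ``pedigree``, ``trajectories``, ``census``.
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; available: {sorted(SCHEMAS)}")
    rep = ValidationReport(str(path), schema)
    if not path.exists():
        rep.errors.append("file does not exist")
        return rep
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str} if schema == "pedigree" else None)
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        rep.errors.append(f"missing columns: {missing}")
        return rep
    for col in spec["non_negative"]:
        if col in df.columns:
            bad = np.nonzero(df[col].to_numpy(float) < 0)[0]
            if len(bad):
                rep.errors.append(f"negative values in {col!r} at row {bad[0]} (+{len(bad)-1} more)")
    if schema == "trajectories":
        for cid, sub in df.groupby("cell_id"):
            t = sub["time_h"].to_numpy(float)
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if len(bad):
                rep.errors.append(
                    f"non-monotone grid for cell {cid!r} at first offending row "
                    f"{sub.index[bad[0] + 1]}"
                )
                break
    if schema == "census":
        t = df["time"].to_numpy(float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if len(bad):
            rep.errors.append(f"non-monotone time grid at row {bad[0] + 1}")
    if schema == "pedigree":
        _check_pedigree_links(df, rep)
    return rep


def load_config(path) -> dict:
    """YAML (or JSON) config file -> dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def load_fucci_workbook(path) -> dict[str, pd.DataFrame]:
    """Import a spreadsheet of tracked single-cell marker intensities.

    Reads every sheet of an .xlsx workbook (one sheet per film / cell
    group, columns holding time stamps and the two marker channels) into
    DataFrames keyed by sheet name.  Import-only convenience for working
    with published supplementary recordings; all downstream processing
    uses the plain CSV trajectory dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"workbook not found: {path}; download the supplementary "
            "single-cell recordings and place them at this path"
        )
    return pd.read_excel(path, sheet_name=None)


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    seed: int | None
    config_hash: str
    inputs: list[str]
    outputs: list[str]
    started: float = field(default_factory=time.time)

    @staticmethod
    def hash_config(obj) -> str:
        blob = json.dumps(obj, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "command": self.command,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "wall_time_s": round(time.time() - self.started, 3),
            "versions": {
                "ccdrift": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))
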