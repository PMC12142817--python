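"""Format readers/writers and run manifests shared by the CLI commands.

Canonical interchange is UTF-8 CSV (TSV detected by extension); ``.xlsx``
is supported read-only. Two table dialects exist for prescriptions:

* ``long`` — one row per (formula, term): columns ``formula_id``,
  ``ingredient`` (or ``raw_term`` + ``field_type``), optional ``dose``,
  ``syndrome``, ``symptom``;
* ``wide`` — ``formula_id`` first column, one 0/1 column per ingredient.

Each CLI command appends a stage record to ``manifest.json`` in its output
directory (package version, parameters, input checksums, outputs) so any
run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import pandas as pd

from .standardize import FIELD_TYPES

__all__ = [
    "read_table",
    "read_formula_table",
    "read_lookup",
    "write_graph",
    "append_manifest",
]


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        return pd.read_excel(path)
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_formula_table(path: str | Path, dialect: str = "long") -> pd.DataFrame:
    """Read a prescription table in the given dialect.

    ``long`` returns a raw record table (formula_id, field_type, raw_term,
    dose); extra per-row syndrome/symptom columns are unpivoted into
    additional records. ``wide`` returns a binary incidence DataFrame
    indexed by formula_id; any non-0/1 cell is rejected with its location.
    """
    df = read_table(path)
    if dialect == "long":
        if "formula_id" not in df.columns:
            raise ValueError(f"{path}: long table needs a formula_id column")
        if "raw_term" in df.columns:
            out = df.copy()
            if "field_type" not in out.columns:
                out["field_type"] = "ingredient"
        elif "ingredient" in df.columns:
            records = []
            for line, row in enumerate(df.itertuples(index=False), start=2):
                d = row._asdict()
                dose = d.get("dose", "")
                records.append((d["formula_id"], "ingredient", d["ingredient"], dose))
                for extra in ("syndrome", "symptom", "diagnosis"):
                    if extra in d and str(d[extra]).strip():
                        records.append((d["formula_id"], extra, d[extra], ""))
            out = pd.DataFrame(
                records, columns=["formula_id", "field_type", "raw_term", "dose"]
            )
        else:
            raise ValueError(
                f"{path}: long table needs an ingredient or raw_term column"
            )
        bad = ~out["field_type"].isin(FIELD_TYPES)
        if bad.any():
            lines = [i + 2 for i in out.index[bad][:5]]
            raise ValueError(f"{path}: invalid field_type near line(s) {lines}")
        n_blank = int((out["raw_term"].astype(str).str.strip() == "").sum())
        if n_blank:
            out = out[out["raw_term"].astype(str).str.strip() != ""]
        return out.reset_index(drop=True)
    if dialect == "wide":
        first = df.columns[0]
        out = df.set_index(first)
        for col in out.columns:
            for i, v in enumerate(out[col]):
                if str(v).strip() not in ("0", "1"):
                    raise ValueError(
                        f"{path}: non-binary cell {v!r} at row "
                        f"{out.index[i]!r}, column {col!r}"
                    )
        out = out.astype(int)
        out.index = out.index.astype(str)
        out.index.name = "formula_id"
        return out
    raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")


def read_lookup(path: str | Path):
    from .standardize import LookupTable

    return LookupTable.from_frame(read_table(path))


def write_graph(g: nx.Graph, out_prefix: str | Path) -> list[Path]:
    """Write a graph as GraphML plus an edge-list CSV; returns the paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    graphml = out_prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml)
    rows = [
        {"source": u, "target": v, **data} for u, v, data in g.edges(data=True)
    ]
    edges = out_prefix.with_suffix(".edges.csv")
    pd.DataFrame(rows).to_csv(edges, index=False)
    return [graphml, edges]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def append_manifest(
    outdir: str | Path,
    stage: str,
    params: dict,
    inputs: list[str | Path],
    outputs: list[str | Path],
) -> Path:
    """Append one stage record to ``manifest.json`` in ``outdir``."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = {"fminer_version": __version__, "stages": []}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest["stages"].append(
        {
            "stage": stage,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "parameters": {k: str(v) for k, v in params.items()},
            "inputs": {str(p): _checksum(Path(p)) for p in inputs if Path(p).exists()},
            "outputs": [str(p) for p in outputs],
        }
    )
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
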