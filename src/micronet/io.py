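"""Readers and writers for the pipeline's on-disk formats.

TSV for abundance tables (samples in rows by default; a flag disambiguates
orientation — auto-detection is deliberately not attempted), CSV for sample
metadata and phenotypes, GraphML plus an edge-list TSV for networks, JSON
for stage reports.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import pandas as pd

from micronet.core import AnalysisConfig, DoseDesign, OtuTable, ValidationError


def read_otu_table(
    path: str | Path,
    group_of: Mapping[str, str] | None = None,
    samples_in_rows: bool = True,
) -> OtuTable:
    """Read a TSV count table into a validated :class:`OtuTable`.

    The first column holds sample ids (or OTU ids when
    ``samples_in_rows=False``); the header row holds the other axis.
    ``group_of`` may be omitted only if groups are later attached via
    metadata; in that case every sample is labelled ``"unassigned"``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"ragged or missing cells in {path}")
    if not samples_in_rows:
        df = df.T
    sample_ids = [str(s) for s in df.index]
    otu_ids = [str(o) for o in df.columns]
    values = df.to_numpy()
    for i, row in enumerate(values):
        for j, x in enumerate(row):
            if not float(x).is_integer() or x < 0:
                raise ValidationError(
                    f"invalid count {x!r} at sample {sample_ids[i]!r}, "
                    f"OTU {otu_ids[j]!r}"
                )
    groups = dict(group_of) if group_of else {s: "unassigned" for s in sample_ids}
    return OtuTable(
        sample_ids=tuple(sample_ids),
        otu_ids=tuple(otu_ids),
        counts=values.astype("int64"),
        group_of=groups,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_sample_metadata(
    path: str | Path, design: DoseDesign
) -> dict[str, dict[str, Any]]:
    """Read sample metadata CSV (columns: sample, group, cage).

    Returns ``{sample: {"group": ..., "cage": ..., "dose": ...}}`` with doses
    filled in from the design. Unknown group labels and duplicate samples are
    errors.
    """
    df = pd.read_csv(path)
    required = {"sample", "group", "cage"}
    if not required.issubset(df.columns):
        raise ValidationError(f"metadata must have columns {sorted(required)}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"duplicate sample row: {dup!r}")
    out: dict[str, dict[str, Any]] = {}
    for _, row in df.iterrows():
        group = str(row["group"])
        if group not in design.dose_of:
            raise ValidationError(
                f"unknown group label {group!r}; design has {design.groups}"
            )
        out[str(row["sample"])] = {
            "group": group,
            "cage": str(row["cage"]),
            "dose": float(design.dose_of[group]),
        }
    return out


def export_network(graph: nx.Graph, path: str | Path) -> Path:
    """Write a correlation network as GraphML plus a sibling edge-list TSV.

    Node attributes (taxonomy, module id) and edge attributes (rho, sign)
    survive a round trip through :func:`import_network`.
    """
    path = Path(path)
    clean = nx.Graph()
    for n, attrs in graph.nodes(data=True):
        clean.add_node(n, **{k: v for k, v in attrs.items() if v is not None})
    for u, v, attrs in graph.edges(data=True):
        clean.add_edge(u, v, **attrs)
    nx.write_graphml(clean, path)
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, **attrs}
            for u, v, attrs in graph.edges(data=True)
        ],
        columns=["source", "target", "rho", "sign"],
    )
    edge_path = path.with_suffix(".edges.tsv")
    edges.to_csv(edge_path, sep="\t", index=False)
    return path


def import_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def _jsonable(obj: Any) -> Any:
    """Recursively convert to JSON-serializable; non-finite floats -> null."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        warnings.warn("non-finite value serialized as null", stacklevel=3)
        return None
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    if hasattr(obj, "tolist"):
        return _jsonable(obj.tolist())
    return str(obj)


def export_report(
    results: Mapping[str, Any],
    path: str | Path,
    stage: str,
    config: AnalysisConfig,
) -> dict[str, Any]:
    """Serialize a stage's results as JSON with config echo, seed and version.

    Two runs with the same seed and config produce byte-identical files.
    """
    from micronet import __version__

    payload = {
        "stage": stage,
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": _jsonable(dict(config.__dict__)),
        "config_hash": config.hash(),
        "results": _jsonable(dict(results)),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload
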