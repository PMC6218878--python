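"""Reading and writing the interchange formats.

Signal recordings travel as a ``t_s,ecg,ip`` CSV plus a sidecar YAML with
the sampling rate and labels.  Parameter tables use the canonical
``subject_id,position,HR,...,BR`` schema; external datasets with different
column names are adapted through a column-mapping config.  Graphs are
exported as GraphML, DOT and an edge-list CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cardioresp.types import (
    CausalGraph,
    PARAMETER_COLUMNS,
    ParameterTable,
    SignalRecord,
)

__all__ = [
    "write_signal_record",
    "read_signal_record",
    "write_parameter_table",
    "read_parameter_table",
    "read_external_parameter_table",
    "load_reference_cohort",
    "write_graph",
    "write_edge_list",
    "write_ground_truth",
    "write_correlation_report",
]

#: Default location of the deposited reference parameter dataset (one CSV
#: with both body positions), resolved relative to the repository root.
REFERENCE_DATASHEET = Path(__file__).resolve().parents[2] / "data" / "datasheet1_parameters.csv"


def load_reference_cohort(path: Path | None = None):
    """Load the deposited athlete parameter dataset as (supine, standing).

    The file is expected in the canonical schema
    (``subject_id,position,HR,...,BR``); a sidecar
    ``<name>_mapping.yaml`` next to it can remap foreign column names via
    ``column_map`` / ``position_column`` / ``subject_column`` entries.
    Raises ``FileNotFoundError`` when the dataset has not been placed in
    the data directory.
    """
    path = Path(path) if path is not None else REFERENCE_DATASHEET
    if not path.exists():
        raise FileNotFoundError(
            f"reference parameter dataset not found at {path}; place the "
            "deposited cohort CSV there (see README, 'Reference data')"
        )
    mapping_path = path.with_name(path.stem + "_mapping.yaml")
    if mapping_path.exists():
        cfg = yaml.safe_load(mapping_path.read_text()) or {}
        return tuple(
            read_external_parameter_table(
                path,
                column_map=cfg["column_map"],
                position=pos,
                position_column=cfg.get("position_column"),
                subject_column=cfg.get("subject_column"),
            )
            for pos in ("supine", "standing")
        )
    return (
        read_parameter_table(path, position="supine"),
        read_parameter_table(path, position="standing"),
    )


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def write_signal_record(record: SignalRecord, stem: Path) -> tuple[Path, Path]:
    """Write ``<stem>.csv`` (t_s,ecg,ip) and ``<stem>.yaml`` (metadata)."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    yaml_path = stem.with_suffix(".yaml")
    df = pd.DataFrame({"t_s": record.times, "ecg": record.ecg, "ip": record.ip})
    df.to_csv(csv_path, index=False, float_format="%.6g")
    meta = {
        "fs": float(record.fs),
        "subject_id": record.subject_id,
        "position": record.position,
    }
    yaml_path.write_text(yaml.safe_dump(meta))
    return csv_path, yaml_path


def read_signal_record(stem: Path) -> SignalRecord:
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"))
    meta = yaml.safe_load(stem.with_suffix(".yaml").read_text())
    return SignalRecord(
        ecg=df["ecg"].to_numpy(),
        ip=df["ip"].to_numpy(),
        fs=float(meta["fs"]),
        subject_id=str(meta.get("subject_id", "anonymous")),
        position=str(meta.get("position", "supine")),
    )


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

def write_parameter_table(table: ParameterTable, path: Path) -> Path:
    path = Path(path)
    df = table.data.copy()
    df.insert(0, "position", table.position or "")
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, index=False)
    return path


def read_parameter_table(path: Path, position: str | None = None) -> ParameterTable:
    df = pd.read_csv(path)
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    if "position" in df.columns:
        positions = df["position"].dropna().unique().tolist()
        if position is not None:
            df = df[df["position"] == position]
        elif len(positions) == 1 and positions[0]:
            position = str(positions[0])
        df = df.drop(columns=["position"])
    return ParameterTable(df, position=position)


def read_external_parameter_table(
    path: Path,
    column_map: dict,
    position: str | None = None,
    position_column: str | None = None,
    subject_column: str | None = None,
) -> ParameterTable:
    """Adapt an externally deposited parameter dataset to the canonical schema.

    ``column_map`` maps canonical names (:data:`PARAMETER_COLUMNS`) to the
    source file's column names.  When the source stacks both positions in
    one file, ``position_column`` selects the rows for ``position``.
    """
    df = pd.read_csv(path)
    if position_column is not None:
        if position is None:
            raise ValueError("position required when position_column is used")
        df = df[df[position_column].astype(str).str.lower() == position.lower()]
    if subject_column is not None:
        df = df.set_index(subject_column)
    missing = [v for v in column_map.values() if v not in df.columns]
    if missing:
        raise ValueError(f"columns not found in {path}: {missing}")
    renamed = df[[column_map[c] for c in PARAMETER_COLUMNS if c in column_map]]
    renamed.columns = [c for c in PARAMETER_COLUMNS if c in column_map]
    return ParameterTable(renamed, position=position)


# ---------------------------------------------------------------------------
# graphs & reports
# ---------------------------------------------------------------------------

def _to_networkx(graph: CausalGraph):
    import networkx as nx

    g = nx.DiGraph(method=graph.method)
    g.add_nodes_from(graph.nodes)
    for a, b, kind in graph.edges:
        g.add_edge(a, b, kind=kind)
        if kind == "undirected":
            g.add_edge(b, a, kind=kind)
    return g


def write_graph(graph: CausalGraph, stem: Path) -> tuple[Path, Path]:
    """Write ``<stem>.graphml`` and ``<stem>.dot``."""
    import networkx as nx

    stem = Path(stem)
    graphml = stem.with_suffix(".graphml")
    nx.write_graphml(_to_networkx(graph), graphml)
    lines = [f'digraph "{graph.method}" {{']
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for a, b, kind in graph.edges:
        style = " [dir=none]" if kind == "undirected" else ""
        lines.append(f'  "{a}" -> "{b}"{style};')
    lines.append("}")
    dot = stem.with_suffix(".dot")
    dot.write_text("\n".join(lines) + "\n")
    return graphml, dot


def write_edge_list(graphs: list[CausalGraph], path: Path, support: dict | None = None) -> Path:
    rows = []
    for g in graphs:
        for a, b, kind in g.edges:
            rows.append({
                "from": a, "to": b, "kind": kind, "method": g.method,
                "support": (support or {}).get((a, b), ""),
            })
    pd.DataFrame(rows, columns=["from", "to", "kind", "method", "support"]).to_csv(
        Path(path), index=False
    )
    return Path(path)


def write_ground_truth(truth, path: Path) -> Path:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    payload = {
        "true_dag": _clean(list(truth.true_dag)),
        "true_params": _clean(truth.true_params),
        "scenario": _clean(truth.scenario),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def write_correlation_report(supine_result, standing_result, stem: Path) -> tuple[Path, Path]:
    """Two-triangle masked matrix (upper = supine, lower = standing) + long format."""
    stem = Path(stem)
    cols = supine_result.columns
    sup = supine_result.to_frame(masked=True)
    sta = standing_result.to_frame(masked=True) if standing_result is not None else None
    merged = pd.DataFrame(index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i < j:
                merged.loc[a, b] = sup.loc[a, b]
            elif i > j and sta is not None:
                merged.loc[a, b] = sta.loc[a, b]
    matrix_path = stem.with_name(stem.name + "_matrix.csv")
    merged.round(4).to_csv(matrix_path)

    rows = []
    for label, result in (("supine", supine_result), ("standing", standing_result)):
        if result is None:
            continue
        for res in result.results.values():
            rows.append({
                "position": label, "x": res.x_name, "y": res.y_name,
                "cor": res.cor, "mpe": res.mpe, "significant": res.significant,
            })
    long_path = stem.with_name(stem.name + "_pairs.csv")
    pd.DataFrame(rows).to_csv(long_path, index=False, float_format="%.6g")
    return matrix_path, long_path
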