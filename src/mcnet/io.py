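"""Readers and writers for landmark data, Rv matrices, networks and reports.

Two landmark dialects are supported:

* **TPS** — the classic morphometrics exchange format (``LM=`` record
  count, coordinate lines, ``ID=``/``IMAGE=`` records).  TPS carries no
  role tags, so per-index roles (and optionally labels) are supplied
  side-channel; repeated ``ID=`` records are numbered as successive
  digitization replicates in file order.
* **CSV** — the canonical replicate-aware interchange dialect with fixed
  columns ``specimen,replicate,label,role,x,y``; row order defines the
  landmark order.

Rv matrices are read from labeled square tables, full-symmetric or
lower-triangular (mirrored on read), and always written full-symmetric.
Networks go to GraphML or a whitespace edge list with a node header, both
lossless for labeled weighted graphs with isolated nodes.  Partition and
frequency reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .community import Partition, SolutionEntry, SolutionFrequencyTable
from .data import (
    Dataset,
    LandmarkConfiguration,
    ROLE_MEASUREMENT,
    ROLE_REFERENCE,
    VALID_ROLES,
)
from .errors import ParseError, StructureError
from .rv import CorrelationNetwork, RvMatrix

CSV_COLUMNS = ["specimen", "replicate", "label", "role", "x", "y"]


# ---------------------------------------------------------------- landmarks


def _read_tps(
    path: Path,
    roles: Sequence[str],
    labels: Optional[Sequence[str]],
) -> list[LandmarkConfiguration]:
    roles = tuple(roles)
    if labels is None:
        labels = tuple(f"L{i + 1}" for i in range(len(roles)))
    labels = tuple(labels)
    configs: list[LandmarkConfiguration] = []
    rep_counter: dict[str, int] = {}

    lines = path.read_text().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ParseError(f"{path}:{i + 1}: expected LM= record, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: malformed LM= record") from exc
        i += 1
        coords = []
        for _ in range(k):
            if i >= n_lines:
                raise ParseError(f"{path}:{i}: unexpected end of file in coordinates")
            parts = lines[i].split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{i + 1}: expected 'x y' coordinate line, got {lines[i]!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{i + 1}: non-numeric coordinate {lines[i]!r}"
                ) from exc
            i += 1
        specimen = None
        while i < n_lines and lines[i].strip() and not lines[
            i
        ].strip().upper().startswith("LM="):
            tag = lines[i].strip()
            if tag.upper().startswith("ID="):
                specimen = tag.split("=", 1)[1].strip()
            # IMAGE=, SCALE= and other records are ignored
            i += 1
        if specimen is None:
            raise ParseError(f"{path}: record ending at line {i} has no ID=")
        if k != len(roles):
            raise StructureError(
                f"{path}: specimen {specimen!r} has {k} landmarks, "
                f"role map has {len(roles)}"
            )
        rep_counter[specimen] = rep_counter.get(specimen, 0) + 1
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen,
                replicate_id=rep_counter[specimen],
                coords=np.asarray(coords),
                roles=roles,
                labels=labels,
            )
        )
    return configs


def _read_landmark_csv(path: Path) -> list[LandmarkConfiguration]:
    try:
        df = pd.read_csv(path, dtype={"specimen": str, "label": str, "role": str})
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    bad_roles = set(df["role"]) - VALID_ROLES
    if bad_roles:
        raise ParseError(f"{path}: unknown role(s) {sorted(bad_roles)}")
    configs = []
    for (spec, rep), group in df.groupby(["specimen", "replicate"], sort=False):
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(spec),
                replicate_id=int(rep),
                coords=group[["x", "y"]].to_numpy(dtype=float),
                roles=tuple(group["role"]),
                labels=tuple(group["label"]),
            )
        )
    return configs


def read_landmarks(
    path,
    format: Optional[str] = None,
    *,
    roles: Optional[Sequence[str]] = None,
    labels: Optional[Sequence[str]] = None,
    species_label: str = "",
) -> Dataset:
    """Read a landmark dataset from TPS or CSV.

    For TPS, ``roles`` (per-index, ``"reference"``/``"measurement"``) is
    required and ``labels`` optional; both are ignored for CSV, which is
    self-describing.
    """
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        if roles is None:
            raise StructureError("TPS input requires a side-channel role map")
        configs = _read_tps(path, roles, labels)
    elif format == "csv":
        configs = _read_landmark_csv(path)
    else:
        raise StructureError(f"unknown landmark format {format!r}")
    return Dataset(tuple(configs), species_label)


def write_landmarks(dataset: Dataset, path, format: Optional[str] = None) -> None:
    """Write a dataset as CSV (canonical) or TPS (roles go side-channel)."""
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "csv":
        rows = []
        for cfg in dataset:
            for lab, role, (x, y) in zip(cfg.labels, cfg.roles, cfg.coords):
                rows.append(
                    {
                        "specimen": cfg.specimen_id,
                        "replicate": cfg.replicate_id,
                        "label": lab,
                        "role": role,
                        "x": x,
                        "y": y,
                    }
                )
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    elif format == "tps":
        with open(path, "w") as fh:
            for cfg in dataset:
                fh.write(f"LM={cfg.n_landmarks}\n")
                for x, y in cfg.coords:
                    fh.write(f"{x:.10g} {y:.10g}\n")
                fh.write(f"ID={cfg.specimen_id}\n")
    else:
        raise StructureError(f"unknown landmark format {format!r}")


# --------------------------------------------------------------- Rv matrix


def read_rv_matrix(path) -> RvMatrix:
    """Read a labeled Rv table (full symmetric or lower-triangular).

    Lower-triangular input (blank/NaN above the diagonal) is mirrored; the
    result always has a unit diagonal and entries in [0, 1].
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    row_labels = [str(l) for l in df.index]
    col_labels = [str(c) for c in df.columns]
    if sorted(row_labels) != sorted(col_labels):
        raise StructureError(
            f"{path}: row and column label sets differ (non-square table)"
        )
    df = df[row_labels]  # align column order to row order
    v = df.to_numpy(dtype=float)
    k = len(row_labels)
    full = np.eye(k)
    for i in range(k):
        for j in range(k):
            if i == j or np.isnan(v[i, j]):
                continue
            if not (0.0 <= v[i, j] <= 1.0):
                raise ValueError(
                    f"{path}: Rv entry ({row_labels[i]}, {row_labels[j]}) = "
                    f"{v[i, j]} outside [0, 1]"
                )
            full[i, j] = v[i, j]
    # mirror whichever triangle was provided; reject contradictions
    for i in range(k):
        for j in range(i + 1, k):
            lo, up = full[j, i], full[i, j]
            given_lo = not np.isnan(v[j, i]) if j < k else False
            given_up = not np.isnan(v[i, j])
            if given_lo and given_up and abs(lo - up) > 1e-9:
                raise StructureError(
                    f"{path}: asymmetric entries for "
                    f"({row_labels[i]}, {row_labels[j]}): {up} vs {lo}"
                )
            val = lo if given_lo else up if given_up else 1.0 if i == j else 0.0
            full[i, j] = full[j, i] = val
    return RvMatrix(labels=tuple(row_labels), values=full)


def write_rv_matrix(rv: RvMatrix, path) -> None:
    """Serialize full-symmetric with labels (no lower-triangle ambiguity)."""
    rv.to_dataframe().to_csv(path, float_format="%.10g")


# ---------------------------------------------------------------- networks


def write_network(net: CorrelationNetwork, path, format: Optional[str] = None) -> None:
    """Write a network as GraphML or a whitespace edge list.

    The edge list carries a ``# nodes:`` header so isolated nodes (and the
    node order) survive the round trip; weights keep >= 6 significant
    digits.  Edge-list labels must be whitespace-free.
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "edgelist"
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "edgelist":
        if any(any(c.isspace() for c in l) for l in net.labels):
            raise StructureError("edge-list format requires whitespace-free labels")
        with open(path, "w") as fh:
            if net.threshold is not None:
                fh.write(f"# threshold: {net.threshold:.10g}\n")
            fh.write("# nodes: " + " ".join(net.labels) + "\n")
            for u, v, w in net.edges():
                fh.write(f"{u} {v} {w:.10g}\n")
    else:
        raise StructureError(f"unknown network format {format!r}")


def read_network(path, format: Optional[str] = None) -> CorrelationNetwork:
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "edgelist"
    if format == "graphml":
        return CorrelationNetwork.from_networkx(nx.read_graphml(path))
    if format != "edgelist":
        raise StructureError(f"unknown network format {format!r}")
    labels: Optional[tuple[str, ...]] = None
    threshold = None
    edges = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("threshold:"):
                threshold = float(body.split(":", 1)[1])
            elif body.startswith("nodes:"):
                labels = tuple(body.split(":", 1)[1].split())
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 'u v weight'")
        try:
            edges.append((parts[0], parts[1], float(parts[2])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
    if labels is None:
        raise ParseError(f"{path}: missing '# nodes:' header")
    idx = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    w = np.zeros((k, k))
    for u, v, weight in edges:
        if u not in idx or v not in idx:
            raise ParseError(f"{path}: edge ({u}, {v}) uses an unlisted node")
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = weight
    return CorrelationNetwork(labels, w, threshold)


# ------------------------------------------------------------------ reports


def partition_to_dict(part: Partition) -> dict:
    return {"modules": part.as_lists(), "node_order": list(part.node_order)}


def partition_from_dict(d: dict) -> Partition:
    return Partition(
        tuple(tuple(m) for m in d["modules"]), tuple(d["node_order"])
    )


def frequency_table_to_dict(table: SolutionFrequencyTable) -> dict:
    return {
        "trials": table.trials,
        "entries": [
            {
                "modules": e.partition.as_lists(),
                "count": e.count,
                "frequency": e.frequency,
                "mean_energy": e.mean_energy,
            }
            for e in table.entries
        ],
        "node_order": list(table.entries[0].partition.node_order)
        if table.entries
        else [],
    }


def write_frequency_table(table: SolutionFrequencyTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(frequency_table_to_dict(table), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_frequency_table(path) -> SolutionFrequencyTable:
    with open(path) as fh:
        d = json.load(fh)
    order = tuple(d["node_order"])
    entries = tuple(
        SolutionEntry(
            partition=Partition(tuple(tuple(m) for m in e["modules"]), order),
            count=e["count"],
            frequency=e["frequency"],
            mean_energy=e["mean_energy"],
        )
        for e in d["entries"]
    )
    return SolutionFrequencyTable(entries, d["trials"])


def write_json_report(obj: dict, path) -> None:
    """Deterministic JSON serialization (sorted keys, fixed layout)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
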