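"""Reading abundance tables and serializing networks, CPTs and reports.

Input tables are sample x variable CSVs (RFC-4180, header row required): one
row per photograph or per transect event, integer counts for taxon columns,
finite reals for continuous columns, free category labels for categorical
columns.  Variable roles and discretization rules are declared up front in
:class:`VariableSpec` objects and validated on read.

Consensus networks round-trip through three formats: a canonical TSV edge
list (one row per undirected pair), GraphML (via networkx) and JSON.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "AbundanceTable",
    "SchemaError",
    "ValidationError",
    "ParseError",
    "read_samples",
    "read_variable_specs",
    "write_network",
    "read_network",
    "write_table",
]

ROLES = ("taxon", "continuous", "categorical", "bin_group")
RULES = ("zero_low_high", "quartile", "categorical_passthrough")

#: rule implied by each role
_ROLE_RULE = {
    "taxon": "zero_low_high",
    "bin_group": "zero_low_high",
    "continuous": "quartile",
    "categorical": "categorical_passthrough",
}


class SchemaError(ValueError):
    """A declared column is missing, duplicated, or the spec set is invalid."""


class ValidationError(ValueError):
    """A cell value violates its column's role invariant."""


class ParseError(ValueError):
    """A serialized network/table file is malformed."""


@dataclass(frozen=True)
class VariableSpec:
    """Declares one variable: its name, ecological role, and how it is binned.

    ``taxon`` and ``bin_group`` columns hold non-negative integer counts and
    are discretized zero/low/high; ``continuous`` columns are quartile-binned;
    ``categorical`` columns pass through as labelled states.
    """

    name: str
    role: str
    discretization_rule: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        rule = self.discretization_rule or _ROLE_RULE[self.role]
        object.__setattr__(self, "discretization_rule", rule)
        if rule != _ROLE_RULE[self.role]:
            raise SchemaError(
                f"variable {self.name!r}: role {self.role!r} requires rule "
                f"{_ROLE_RULE[self.role]!r}, got {rule!r}"
            )

    @property
    def is_count(self) -> bool:
        return self.role in ("taxon", "bin_group")


@dataclass
class AbundanceTable:
    """Sample x variable abundance matrix with role metadata.

    ``data`` holds one column per spec, in spec order, indexed by sample id.
    ``grouping`` (optional) maps every sample id to a transect-event id and is
    required to aggregate the table from photo scale to event scale.
    """

    data: pd.DataFrame
    specs: tuple[VariableSpec, ...]
    grouping: Optional[pd.Series] = None
    scale: str = "photo"

    def __post_init__(self):
        self.specs = tuple(self.specs)
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in specs")
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise SchemaError(f"missing declared column(s): {', '.join(missing)}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        self.data = self.data.loc[:, names]
        for spec in self.specs:
            col = self.data[spec.name]
            if spec.is_count:
                arr = pd.to_numeric(col, errors="coerce")
                bad = arr.isna() | (arr < 0) | (arr != arr.round())
                if bad.any():
                    row = bad.idxmax()
                    raise ValidationError(
                        f"column {spec.name!r}, row {row!r}: "
                        f"value {col.loc[row]!r} is not a non-negative integer count"
                    )
                self.data[spec.name] = arr.astype(np.int64)
            elif spec.role == "continuous":
                arr = pd.to_numeric(col, errors="coerce")
                if not np.isfinite(arr.to_numpy(dtype=float)).all():
                    row = (~np.isfinite(arr.to_numpy(dtype=float))).argmax()
                    raise ValidationError(
                        f"column {spec.name!r}, row {self.data.index[row]!r}: "
                        "value is not finite"
                    )
                self.data[spec.name] = arr.astype(float)
            else:
                self.data[spec.name] = col.astype(str)
        if self.grouping is not None:
            self.grouping = pd.Series(self.grouping)
            uncovered = self.data.index.difference(self.grouping.index)
            if len(uncovered):
                raise ValidationError(
                    f"grouping key does not cover sample(s): {list(uncovered)[:5]}"
                )
            self.grouping = self.grouping.loc[self.data.index].astype(str)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def variable_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)


def read_samples(
    path,
    specs: Sequence[VariableSpec],
    grouping_column: Optional[str] = None,
    sample_id_column: Optional[str] = None,
    scale: str = "photo",
) -> AbundanceTable:
    """Read a CSV of samples, validate it against ``specs``.

    Parameters
    ----------
    path
        CSV file with a header row naming every spec (extra columns ignored).
    specs
        Declared variables; column order of the result follows this list.
    grouping_column
        Optional name of a column holding the photo->event key.
    sample_id_column
        Optional column to use as sample ids; defaults to the row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if sample_id_column is not None:
        if sample_id_column not in df.columns:
            raise SchemaError(f"missing sample id column {sample_id_column!r}")
        df = df.set_index(sample_id_column)
        df.index.name = None
    else:
        df.index = pd.RangeIndex(len(df))
    missing = [s.name for s in specs if s.name not in df.columns]
    if missing:
        raise SchemaError(f"missing declared column(s): {', '.join(missing)}")
    grouping = None
    if grouping_column is not None:
        if grouping_column not in df.columns:
            raise SchemaError(f"missing grouping column {grouping_column!r}")
        grouping = df[grouping_column]
    return AbundanceTable(data=df, specs=tuple(specs), grouping=grouping, scale=scale)


def read_variable_specs(path) -> tuple[VariableSpec, ...]:
    """Read variable specs from a plain-text key-value file.

    One line per variable, ``name = role`` or ``name = role:rule``;
    blank lines and ``#`` comments ignored.
    """
    specs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}: line {lineno}: expected 'name = role'")
            name, _, value = line.partition("=")
            role, _, rule = value.strip().partition(":")
            specs.append(VariableSpec(name.strip(), role.strip(), rule.strip()))
    return tuple(specs)


def write_table(table: AbundanceTable, path) -> None:
    """Write an AbundanceTable back to CSV (sample id + grouping included)."""
    df = table.data.copy()
    df.insert(0, "sample_id", table.data.index)
    if table.grouping is not None:
        df["event"] = table.grouping.to_numpy()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Consensus network serialization
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("source", "target", "direction", "occurrence", "mean_is")
_DIRECTIONS = ("forward", "backward", "mutual")


def write_network(network, path, format: str = "tsv") -> None:
    """Serialize a ConsensusNetwork; one row/element per undirected pair.

    ``format`` is one of ``tsv``, ``graphml``, ``json``.  Occurrence and mean
    influence score survive a round trip to 6 decimal places.
    """
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_TSV_COLUMNS)
            for e in network.edges:
                w.writerow(
                    [e.source, e.target, e.direction,
                     f"{e.occurrence:.6f}", f"{e.mean_is:.6f}"]
                )
    elif format == "graphml":
        g = nx.DiGraph()
        for n in network.nodes:
            g.add_node(n)
        for e in network.edges:
            g.add_edge(
                str(e.source), str(e.target),
                direction=str(e.direction),
                occurrence=round(float(e.occurrence), 6),
                mean_is=round(float(e.mean_is), 6),
            )
        nx.write_graphml(g, path)
    elif format == "json":
        payload = {
            "nodes": list(network.nodes),
            "threshold": network.threshold,
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "direction": e.direction,
                    "occurrence": round(float(e.occurrence), 6),
                    "mean_is": round(float(e.mean_is), 6),
                }
                for e in network.edges
            ],
            "summary": network.summary,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r} (expected tsv, graphml or json)")


def read_network(path, format: str = "tsv"):
    """Read a ConsensusNetwork written by :func:`write_network`."""
    from .bootstrap_consensus import ConsensusEdge, ConsensusNetwork

    def _edge(source, target, direction, occurrence, mean_is, where):
        if direction not in _DIRECTIONS:
            raise ParseError(f"{where}: unknown direction {direction!r}")
        try:
            occ, mis = float(occurrence), float(mean_is)
        except ValueError as err:
            raise ParseError(f"{where}: {err}") from None
        return ConsensusEdge(source, target, direction, occ, mis)

    if format == "tsv":
        edges, nodes = [], []
        with open(path, newline="") as fh:
            rd = csv.reader(fh, delimiter="\t")
            try:
                header = next(rd)
            except StopIteration:
                raise ParseError(f"{path}: line 1: empty file") from None
            if tuple(header) != _TSV_COLUMNS:
                raise ParseError(f"{path}: line 1: bad header {header!r}")
            for lineno, row in enumerate(rd, 2):
                if len(row) != 5:
                    raise ParseError(f"{path}: line {lineno}: expected 5 fields")
                edges.append(_edge(*row, where=f"{path}: line {lineno}"))
        for e in edges:
            for n in (e.source, e.target):
                if n not in nodes:
                    nodes.append(n)
        return ConsensusNetwork(nodes=nodes, edges=edges, threshold=None)
    if format == "graphml":
        g = nx.read_graphml(path)
        edges = [
            _edge(u, v, d.get("direction"), d.get("occurrence"), d.get("mean_is"),
                  where=f"{path}: edge {u}->{v}")
            for u, v, d in g.edges(data=True)
        ]
        return ConsensusNetwork(nodes=list(g.nodes), edges=edges, threshold=None)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        edges = [
            _edge(d["source"], d["target"], d["direction"],
                  d["occurrence"], d["mean_is"], where=f"{path}: edge {i}")
            for i, d in enumerate(payload.get("edges", []))
        ]
        return ConsensusNetwork(
            nodes=list(payload.get("nodes", [])),
            edges=edges,
            threshold=payload.get("threshold"),
            summary=payload.get("summary"),
        )
    raise ValueError(f"unknown format {format!r} (expected tsv, graphml or json)")
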