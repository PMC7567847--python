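"""Discretization of counts/continuous/categorical variables and event aggregation.

Count variables (taxa, bin-groups) are split into three states — zero, low and
high — with zero kept as its own state because presence of a single individual
is ecologically distinct from absence.  The low/high boundary is the median of
the *positive* counts only; positive values at or below it are "low", values
above it "high".  Continuous variables (depth, percent encrusting) get four
quartile states, categorical variables a stable lexicographic label map.

Photo-scale tables aggregate to transect-event scale by summing taxon counts,
averaging continuous columns and taking the per-event mode of categoricals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .tabular_io import AbundanceTable

__all__ = [
    "DegenerateVariableError",
    "DiscretizedTable",
    "discretize_counts",
    "discretize_quartiles",
    "discretize_categorical",
    "discretize_table",
    "aggregate_events",
    "load_discretized",
]


class DegenerateVariableError(ValueError):
    """Variable cannot be discretized (all-zero counts, <4 distinct values, ...)."""


@dataclass
class DiscretizedTable:
    """Integer-state matrix plus everything needed to re-derive it.

    ``states`` has one int column per retained variable; ``arity`` gives the
    state count per variable (3 for zero/low/high, 4 for quartiles, observed
    category count for categoricals); ``boundaries`` records the median cut,
    the three quartile cuts, or the category->state map, so that applying the
    recorded rule to the raw values reproduces ``states`` exactly.
    """

    states: pd.DataFrame
    arity: dict[str, int]
    boundaries: dict[str, object]
    rules: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list:
        return list(self.states.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.states.columns)

    @property
    def n_samples(self) -> int:
        return len(self.states)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_samples, n_vars) int8 state matrix and per-variable arities."""
        mat = self.states.to_numpy(dtype=np.int8)
        ar = np.array([self.arity[v] for v in self.states.columns], dtype=np.int64)
        return mat, ar

    def apply_boundaries(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Re-discretize raw values using the recorded boundaries/maps."""
        out = {}
        for name in self.states.columns:
            rule = self.rules.get(name, "zero_low_high")
            col = raw[name]
            if rule == "zero_low_high":
                out[name] = _states_from_median(
                    col.to_numpy(dtype=float), self.boundaries[name]
                )
            elif rule == "quartile":
                out[name] = _states_from_cuts(
                    col.to_numpy(dtype=float), self.boundaries[name]
                )
            else:
                cmap = self.boundaries[name]
                out[name] = col.astype(str).map(cmap).to_numpy()
        return pd.DataFrame(out, index=raw.index, dtype=np.int64)

    def export(self, csv_path, sidecar_path) -> None:
        """CSV of integer states plus a JSON sidecar of boundaries and maps."""
        df = self.states.copy()
        df.insert(0, "sample_id", self.states.index)
        df.to_csv(csv_path, index=False)
        meta = {
            name: {
                "rule": self.rules.get(name, "zero_low_high"),
                "arity": int(self.arity[name]),
                "boundaries": self.boundaries[name]
                if isinstance(self.boundaries[name], dict)
                else np.asarray(self.boundaries[name]).tolist(),
            }
            for name in self.states.columns
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def _states_from_median(values: np.ndarray, boundary: float) -> np.ndarray:
    states = np.zeros(len(values), dtype=np.int64)
    pos = values > 0
    states[pos & (values <= boundary)] = 1
    states[pos & (values > boundary)] = 2
    return states


def _states_from_cuts(values: np.ndarray, cuts) -> np.ndarray:
    # value <= Q1 -> 0, <= Q2 -> 1, <= Q3 -> 2, else 3
    return np.searchsorted(np.asarray(cuts, dtype=float), values, side="left").astype(
        np.int64
    )


def discretize_counts(values) -> tuple[np.ndarray, float]:
    """Zero/low/high states for a non-negative count vector.

    The boundary is the median of the positive values only; zeros are their
    own state 0, positives <= boundary map to 1, positives above to 2.

    Raises
    ------
    DegenerateVariableError
        If the vector has no positive value.
    """
    arr = np.asarray(values, dtype=float)
    pos = arr[arr > 0]
    if pos.size == 0:
        raise DegenerateVariableError(
            "all-zero count vector; rare-taxon filtering should have removed it"
        )
    boundary = float(np.median(pos))
    states = _states_from_median(arr, boundary)
    if not (states == 2).any():
        warnings.warn(
            "no counts above the positive-median boundary; 'high' state is empty",
            stacklevel=2,
        )
    return states, boundary


def discretize_quartiles(values) -> tuple[np.ndarray, np.ndarray]:
    """Four quartile states for a continuous vector.

    Cuts are the empirical Q1/Q2/Q3 (linear-interpolation quantiles); a value
    equal to a cut maps to the lower state.
    """
    arr = np.asarray(values, dtype=float)
    if np.unique(arr).size < 4:
        raise DegenerateVariableError(
            f"quartile discretization needs >=4 distinct values, got "
            f"{np.unique(arr).size}; declare the variable categorical instead"
        )
    cuts = np.quantile(arr, [0.25, 0.5, 0.75])
    return _states_from_cuts(arr, cuts), cuts


def discretize_categorical(values) -> tuple[np.ndarray, dict[str, int]]:
    """Integer states for category labels via a stable lexicographic map."""
    labels = pd.Series(values).astype(str)
    cats = sorted(labels.unique())
    if len(cats) < 2:
        raise DegenerateVariableError("categorical variable has a single level")
    cmap = {c: i for i, c in enumerate(cats)}
    return labels.map(cmap).to_numpy(dtype=np.int64), cmap


def discretize_table(
    table: AbundanceTable,
    keep: Optional[list[str]] = None,
    drop_degenerate: bool = True,
) -> DiscretizedTable:
    """Discretize every (kept) variable of an abundance table.

    With ``drop_degenerate`` (default) a variable that cannot be binned —
    e.g. a depth column with fewer than four distinct values at event scale —
    is dropped with a warning rather than aborting the pipeline.
    """
    names = keep if keep is not None else table.variable_names
    states, arity, boundaries, rules = {}, {}, {}, {}
    for name in names:
        spec = table.spec(name)
        col = table.data[name]
        try:
            if spec.discretization_rule == "zero_low_high":
                st, b = discretize_counts(col.to_numpy())
                arity[name], boundaries[name] = 3, b
            elif spec.discretization_rule == "quartile":
                st, b = discretize_quartiles(col.to_numpy())
                arity[name], boundaries[name] = 4, b
            else:
                st, cmap = discretize_categorical(col)
                arity[name], boundaries[name] = len(cmap), cmap
        except DegenerateVariableError:
            if not drop_degenerate:
                raise
            warnings.warn(
                f"dropping degenerate variable {name!r} from the network",
                stacklevel=2,
            )
            continue
        states[name] = st
        rules[name] = spec.discretization_rule
    return DiscretizedTable(
        states=pd.DataFrame(states, index=table.data.index, dtype=np.int64),
        arity=arity,
        boundaries=boundaries,
        rules=rules,
    )


def load_discretized(csv_path, sidecar_path) -> DiscretizedTable:
    """Reload a table written by :meth:`DiscretizedTable.export`."""
    df = pd.read_csv(csv_path).set_index("sample_id")
    df.index.name = None
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    arity, boundaries, rules = {}, {}, {}
    for name, d in meta.items():
        rules[name] = d["rule"]
        arity[name] = int(d["arity"])
        b = d["boundaries"]
        boundaries[name] = b if isinstance(b, dict) else (
            float(b) if np.isscalar(b) else np.asarray(b, dtype=float)
        )
    return DiscretizedTable(
        states=df[list(meta)].astype(np.int64), arity=arity,
        boundaries=boundaries, rules=rules,
    )


def _mode_lex(series: pd.Series) -> str:
    counts = series.value_counts()
    best = counts.max()
    return sorted(counts.index[counts == best])[0]


def aggregate_events(table: AbundanceTable) -> AbundanceTable:
    """Aggregate a photo-scale table to transect-event scale.

    Taxon and bin-group counts are summed within each event, continuous
    columns averaged, and categorical columns take the per-event mode (ties
    broken by the lexicographically smallest label).
    """
    if table.grouping is None:
        raise ValueError("aggregation requires a photo->event grouping key")
    if table.scale != "photo":
        raise ValueError("table is already at event scale")
    agg = {}
    for spec in table.specs:
        if spec.is_count:
            agg[spec.name] = "sum"
        elif spec.role == "continuous":
            agg[spec.name] = "mean"
        else:
            agg[spec.name] = _mode_lex
    grouped = table.data.groupby(table.grouping.to_numpy()).agg(agg)
    grouped.index.name = None
    return AbundanceTable(data=grouped, specs=table.specs, grouping=None, scale="event")
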