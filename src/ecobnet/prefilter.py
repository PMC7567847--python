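"""Rare-taxon exclusion and contingency-test pre-filtering.

Zero-inflated abundance matrices generate spurious co-absence signal, so two
guards run before structure search:

* taxa (and bin-groups) present in strictly fewer than a third of the samples
  are dropped entirely;
* every remaining variable pair is tested for association with a Pearson
  chi-squared test on the discretized contingency table, and pairs with
  p > 0.25 are barred as edges.  The threshold is deliberately lax so that
  only pairs with essentially no joint signal — typically artefacts of shared
  zeros — are removed, never genuinely dependent pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import chi2_contingency

from .discretize import DiscretizedTable
from .tabular_io import AbundanceTable

__all__ = ["ExclusionSet", "exclude_rare", "contingency_exclusions"]

OCCUPANCY_THRESHOLD = 1.0 / 3.0
PVALUE_THRESHOLD = 0.25


@dataclass
class ExclusionSet:
    """Variables and variable pairs removed from consideration.

    ``excluded_variables`` maps a rare variable's name to its occupancy
    fraction; ``excluded_pairs`` maps an unordered pair (frozenset of two
    names) to its (chi2 statistic, degrees of freedom, p-value).
    """

    excluded_variables: dict[str, float] = field(default_factory=dict)
    excluded_pairs: dict[frozenset, tuple[float, int, float]] = field(
        default_factory=dict
    )
    occupancy_threshold: float = OCCUPANCY_THRESHOLD
    pvalue_threshold: float = PVALUE_THRESHOLD

    def blocks(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.excluded_pairs

    def merged_with(self, other: "ExclusionSet") -> "ExclusionSet":
        return ExclusionSet(
            excluded_variables={**self.excluded_variables, **other.excluded_variables},
            excluded_pairs={**self.excluded_pairs, **other.excluded_pairs},
            occupancy_threshold=self.occupancy_threshold,
            pvalue_threshold=self.pvalue_threshold,
        )

    def export(self, path) -> None:
        payload = {
            "occupancy_threshold": self.occupancy_threshold,
            "pvalue_threshold": self.pvalue_threshold,
            "excluded_variables": self.excluded_variables,
            "excluded_pairs": [
                {
                    "pair": sorted(pair),
                    "chi2": stat,
                    "df": df,
                    "p_value": p,
                }
                for pair, (stat, df, p) in sorted(
                    self.excluded_pairs.items(), key=lambda kv: sorted(kv[0])
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ExclusionSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            excluded_variables=dict(payload.get("excluded_variables", {})),
            excluded_pairs={
                frozenset(d["pair"]): (d["chi2"], d["df"], d["p_value"])
                for d in payload.get("excluded_pairs", [])
            },
            occupancy_threshold=payload.get("occupancy_threshold",
                                            OCCUPANCY_THRESHOLD),
            pvalue_threshold=payload.get("pvalue_threshold", PVALUE_THRESHOLD),
        )


def exclude_rare(
    table: AbundanceTable, threshold: float = OCCUPANCY_THRESHOLD
) -> tuple[list[str], ExclusionSet]:
    """Drop count variables occupied in under a third of samples.

    Occupancy is the fraction of samples with a positive count.  Physical
    (continuous/categorical) variables are never excluded by this rule.
    Returns the kept variable names (original order) and the exclusion record.
    """
    excl = ExclusionSet(occupancy_threshold=threshold)
    kept = []
    n = len(table.data)
    for spec in table.specs:
        if spec.is_count:
            occupancy = float((table.data[spec.name] > 0).sum()) / n
            if occupancy < threshold:
                excl.excluded_variables[spec.name] = occupancy
                continue
        kept.append(spec.name)
    return kept, excl


def _pair_chi2(a: np.ndarray, b: np.ndarray, ka: int, kb: int):
    obs = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(obs, (a, b), 1)
    # drop empty rows/columns so expected counts are all positive
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 0.0, 0, 1.0
    stat, p, df, _ = chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def contingency_exclusions(
    dtable: DiscretizedTable, threshold: float = PVALUE_THRESHOLD
) -> ExclusionSet:
    """Chi-squared-test every unordered variable pair; bar pairs with p > 0.25.

    The test compares the observed joint state distribution with the product
    of the marginals (Pearson chi-squared, no continuity correction, df =
    (r-1)(c-1) after dropping empty rows/columns).
    """
    excl = ExclusionSet(pvalue_threshold=threshold)
    mat, arities = dtable.to_arrays()
    names = dtable.variable_names
    for i, j in combinations(range(len(names)), 2):
        stat, df, p = _pair_chi2(
            mat[:, i].astype(np.int64), mat[:, j].astype(np.int64),
            int(arities[i]), int(arities[j]),
        )
        if p > threshold:
            excl.excluded_pairs[frozenset((names[i], names[j]))] = (stat, df, p)
    return excl
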