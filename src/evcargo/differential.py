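"""Pairwise and histology-group differential abundance, concordance, and Venn set logic.

Differential calls are pure fold-change thresholding (no p-values): a
protein is increased between two EV preparations when the difference of
their reference-normalised log2 ratios exceeds +t, decreased below -t.
Group-versus-group calls use consensus semantics: increased in every
pairwise comparison of a group-A line against a group-B line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import AnalysisThresholds, lines_of
from .ratios import RatioMatrix, merge_plexes

DIRECTIONS = ("increased", "decreased", "neither")


@dataclass
class DifferentialResult:
    """Per-protein direction calls for one comparison."""

    comparison: str
    table: pd.DataFrame  # columns: direction, plus the per-line log2 FCs used

    def proteins_with(self, direction: str) -> frozenset:
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        return frozenset(self.table.index[self.table["direction"] == direction])


@dataclass
class BiomarkerReport:
    """Venn partition of per-histology detection/presence sets.

    ``regions`` maps a frozenset of histology names to the ids found in
    exactly those histologies; regions are pairwise disjoint and their union
    covers every id present in at least one histology.
    """

    detected: dict[str, frozenset]
    regions: dict[frozenset, frozenset] = field(init=False)

    def __post_init__(self) -> None:
        types = list(self.detected)
        regions = {}
        for r in range(1, len(types) + 1):
            from itertools import combinations

            for combo in combinations(types, r):
                inside = frozenset.intersection(*(self.detected[t] for t in combo))
                outside = frozenset().union(*(self.detected[t] for t in types if t not in combo))
                regions[frozenset(combo)] = inside - outside
        self.regions = regions

    def unique_to(self, histology: str) -> frozenset:
        return self.regions[frozenset([histology])]

    def shared_by_all(self) -> frozenset:
        return self.regions[frozenset(self.detected)]

    def region_sizes(self) -> dict[str, int]:
        return {"&".join(sorted(k)): len(v) for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(combo)), "id": member}
            for combo, members in self.regions.items()
            for member in sorted(members)
        ]
        return pd.DataFrame(rows, columns=["region", "id"])


def _delta(ratios: RatioMatrix, line_a: str, line_b: str, fraction: str) -> pd.Series:
    return ratios.column(line_a, fraction) - ratios.column(line_b, fraction)


def _directions(delta: pd.Series, thresholds: AnalysisThresholds) -> pd.Series:
    inc = delta.map(thresholds.exceeds)
    dec = delta.map(thresholds.below_negative)
    return pd.Series(
        np.where(inc, "increased", np.where(dec, "decreased", "neither")), index=delta.index
    )


def differential_pairwise(
    ratios: RatioMatrix,
    line_a: str,
    line_b: str,
    fraction: str = "EV",
    thresholds: AnalysisThresholds | None = None,
) -> DifferentialResult:
    """Direction of each protein between two cell lines in one fraction.

    Missing on either side -> "neither", flagged in the ``missing`` column.
    """
    thresholds = thresholds or AnalysisThresholds()
    ratios = merge_plexes(ratios)
    delta = _delta(ratios, line_a, line_b, fraction)
    table = pd.DataFrame(
        {
            "direction": _directions(delta, thresholds),
            "delta_log2": delta,
            "missing": delta.isna(),
        }
    )
    return DifferentialResult(f"{line_a}_vs_{line_b}_{fraction}", table)


def differential_group(
    ratios: RatioMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    fraction: str = "EV",
    thresholds: AnalysisThresholds | None = None,
    method: str = "all_pairs",
) -> DifferentialResult:
    """Consensus differential between two groups of cell lines.

    Default ``all_pairs`` semantics: increased iff increased in every
    pairwise (a, b) comparison with a in group A, b in group B (decreased
    symmetric); any missing pairwise value -> "neither". The alternative
    ``group_mean`` compares the within-group mean ratios with the same
    threshold.
    """
    thresholds = thresholds or AnalysisThresholds()
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    ratios = merge_plexes(ratios)
    label = f"{'+'.join(group_a)}_vs_{'+'.join(group_b)}_{fraction}"
    if method == "group_mean":
        mean_a = pd.concat([ratios.column(a, fraction) for a in group_a], axis=1).mean(axis=1)
        mean_b = pd.concat([ratios.column(b, fraction) for b in group_b], axis=1).mean(axis=1)
        delta = mean_a - mean_b
        table = pd.DataFrame(
            {"direction": _directions(delta, thresholds), "delta_log2": delta, "missing": delta.isna()}
        )
        return DifferentialResult(label, table)
    if method != "all_pairs":
        raise ValueError(f"unknown method {method!r}")
    deltas = {}
    for a, b in product(group_a, group_b):
        deltas[f"delta_{a}_vs_{b}"] = _delta(ratios, a, b, fraction)
    delta_df = pd.DataFrame(deltas)
    inc = delta_df.apply(lambda col: col.map(thresholds.exceeds)).all(axis=1)
    dec = delta_df.apply(lambda col: col.map(thresholds.below_negative)).all(axis=1)
    any_missing = delta_df.isna().any(axis=1)
    direction = np.where(
        any_missing, "neither", np.where(inc, "increased", np.where(dec, "decreased", "neither"))
    )
    table = pd.DataFrame({"direction": direction, "missing": any_missing}, index=delta_df.index)
    result = pd.concat([table, delta_df], axis=1)
    return DifferentialResult(label, result)


def concordance(
    ratios: RatioMatrix,
    line: str,
    reference_line: str = "HK2",
    thresholds: AnalysisThresholds | None = None,
) -> frozenset:
    """Proteins whose cell-lysate and EV differentials agree in direction.

    Both the CL and EV fractions of ``line`` are compared against the same
    fractions of ``reference_line``; a protein is concordant when the two
    calls are equal and not "neither".
    """
    thresholds = thresholds or AnalysisThresholds()
    cl = differential_pairwise(ratios, line, reference_line, "CL", thresholds).table["direction"]
    ev = differential_pairwise(ratios, line, reference_line, "EV", thresholds).table["direction"]
    same = (cl == ev) & (cl != "neither")
    return frozenset(same.index[same])


def venn_proteins(
    detection: Mapping[str, frozenset], histology: Mapping[str, str]
) -> BiomarkerReport:
    """Detection-based candidate biomarker selection across histologies.

    A protein counts as detected for a histology only when detected in the
    EV preparation of every cell line of that histology; the report carries
    the full Venn partition of the per-histology sets.
    """
    histologies = list(dict.fromkeys(histology.values()))
    per_type = {}
    for h in histologies:
        lines = [l for l in lines_of(histology, h) if l in detection]
        if not lines:
            raise ValueError(f"histology {h!r} has no cell line with a detection set")
        per_type[h] = frozenset.intersection(*(frozenset(detection[l]) for l in lines))
    return BiomarkerReport(per_type)
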