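"""Replicate- and cell-line-level mRNA presence calling and Venn biomarker selection.

A transcript is detected in a sample when its normalized count is strictly
above that sample's background threshold; present in a cell line when
detected in enough replicates (2/3 or 2/2 by default); and present in a
histological type when present in every cell line of that type — scored as
a consensus call only when at least two lines of the type survived QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping
import warnings

import pandas as pd

from .config import PresenceRules, lines_of
from .differential import BiomarkerReport
from .nanostring import CountMatrix, NormalizedMatrix, QCReport


@dataclass
class PresenceMatrix:
    """Gene x cell-line and gene x histology boolean presence with provenance.

    ``provenance`` records, per (gene, cell_line), the replicate detection
    vector behind the call. ``type_consensus`` flags which histology columns
    are genuine multi-line consensus calls.
    """

    by_line: pd.DataFrame
    by_type: pd.DataFrame
    type_consensus: dict[str, bool]
    provenance: pd.DataFrame  # columns: gene, cell_line, n_replicates, n_detected, detections

    def present_in_line(self, line: str) -> frozenset:
        return frozenset(self.by_line.index[self.by_line[line]])

    def present_in_type(self, histology: str) -> frozenset:
        return frozenset(self.by_type.index[self.by_type[histology]])


def detect_replicates(norm: NormalizedMatrix, qc: QCReport) -> pd.DataFrame:
    """Gene x sample boolean detection: normalized count strictly above background."""
    passing = [s for s in norm.values.columns if s in qc.passing]
    return norm.values[passing].gt(norm.background[passing], axis=1)


def call_presence(
    detection: pd.DataFrame,
    samples: pd.DataFrame,
    histology: Mapping[str, str],
    rules: PresenceRules | None = None,
) -> PresenceMatrix:
    """Roll sample-level detections up to cell-line and histology presence."""
    rules = rules or PresenceRules()
    sample_lines = samples.loc[detection.columns, "cell_line"]
    by_line = {}
    prov_rows = []
    for line in dict.fromkeys(sample_lines):
        reps = list(sample_lines.index[sample_lines == line])
        if not reps:
            continue
        required = rules.required_for(len(reps))
        n_det = detection[reps].sum(axis=1)
        by_line[line] = n_det >= required
        prov_rows.append(
            pd.DataFrame(
                {
                    "gene": detection.index,
                    "cell_line": line,
                    "n_replicates": len(reps),
                    "n_detected": n_det.to_numpy(),
                    "detections": [
                        "".join("1" if d else "0" for d in row)
                        for row in detection[reps].to_numpy()
                    ],
                }
            )
        )
    dropped = [l for l in dict.fromkeys(histology) if l not in by_line]
    if dropped:
        warnings.warn(
            f"cell line(s) with zero passing replicates dropped from presence calls: {dropped}",
            stacklevel=2,
        )
    by_line_df = pd.DataFrame(by_line)
    by_type = {}
    consensus = {}
    for h in dict.fromkeys(histology.values()):
        lines = [l for l in lines_of(histology, h) if l in by_line_df.columns]
        if not lines:
            continue
        by_type[h] = by_line_df[lines].all(axis=1)
        consensus[h] = len(lines) >= rules.min_lines_for_type_call
    return PresenceMatrix(
        by_line=by_line_df,
        by_type=pd.DataFrame(by_type),
        type_consensus=consensus,
        provenance=pd.concat(prov_rows, ignore_index=True),
    )


def venn_mrna(
    presence: PresenceMatrix, types: tuple[str, str] = ("benign", "ccRCC")
) -> BiomarkerReport:
    """Unique/shared transcript sets between two histologies, regardless of abundance."""
    missing = [t for t in types if t not in presence.by_type.columns]
    if missing:
        raise ValueError(f"no presence calls for histologies: {missing}")
    non_consensus = [t for t in types if not presence.type_consensus.get(t, False)]
    if non_consensus:
        warnings.warn(
            f"histology presence for {non_consensus} rests on a single cell line "
            "(non-consensus call)",
            stacklevel=2,
        )
    return BiomarkerReport({t: presence.present_in_type(t) for t in types})


def detected_anywhere(
    detection: pd.DataFrame, presence: PresenceMatrix
) -> tuple[frozenset, frozenset]:
    """(genes detected in >= 1 sample, genes present in every cell line).

    The all-lines set uses cell-line-level presence calls, not raw sample
    detections, and is always a subset of the first set.
    """
    any_sample = frozenset(detection.index[detection.any(axis=1)])
    all_lines = frozenset(
        presence.by_line.index[presence.by_line.all(axis=1)]
    )
    return any_sample, all_lines
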