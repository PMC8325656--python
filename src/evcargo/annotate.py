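"""Two-branch EV-association rule, marker QC, and k-of-n consensus counts.

A protein is called EV-associated in a cell line when it is enriched in the
vesicle pellet relative to the depletion fractions:

* branch 1 ("evcl"):  EV - CL log2 fold change > t  (t = 0.58, i.e. 1.5-fold), or
* branch 2 ("evcl_ev2k"):  EV - CL in [0, t]  and  EV - 2K > t.

When a fold change required by the applicable branch is missing, the protein
is "unevaluable" for that cell line rather than silently negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisThresholds, MarkerPanel
from .ratios import RatioMatrix, fraction_logfc, merge_plexes

STATUS_EV = "ev_associated"
STATUS_NOT = "not_ev_associated"
STATUS_UNEVALUABLE = "unevaluable"


@dataclass
class EVAnnotationTable:
    """Long-format per-(protein, cell_line) EV annotation.

    Columns: protein, cell_line, status, branch, ev_cl_logfc, ev_2k_logfc.
    """

    table: pd.DataFrame

    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.table["cell_line"]))

    def ev_sets(self) -> dict[str, frozenset]:
        """Cell line -> set of EV-associated protein ids."""
        ev = self.table[self.table["status"] == STATUS_EV]
        out = {line: frozenset() for line in self.cell_lines()}
        for line, sub in ev.groupby("cell_line", sort=False):
            out[line] = frozenset(sub["protein"])
        return out

    def status_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="protein", columns="cell_line", values="status")


def classify_protein(ev_cl: float, ev_2k: float, thresholds: AnalysisThresholds) -> tuple[str, str]:
    """Scalar two-branch decision; returns (status, branch)."""
    if np.isnan(ev_cl):
        return STATUS_UNEVALUABLE, "none"
    if thresholds.exceeds(ev_cl):
        return STATUS_EV, "evcl"
    if ev_cl >= 0:
        # branch 2: EV-CL in [0, t]; requires the EV-2K fold change
        if np.isnan(ev_2k):
            return STATUS_UNEVALUABLE, "none"
        if thresholds.exceeds(ev_2k):
            return STATUS_EV, "evcl_ev2k"
    return STATUS_NOT, "none"


def annotate_ev(
    ratios: RatioMatrix,
    thresholds: AnalysisThresholds | None = None,
    cell_lines: list[str] | None = None,
) -> EVAnnotationTable:
    """Apply the two-branch EV-association rule per protein per cell line."""
    thresholds = thresholds or AnalysisThresholds()
    ratios = merge_plexes(ratios)
    lines = cell_lines if cell_lines is not None else ratios.cell_lines()
    frames = []
    for line in lines:
        ev_cl = fraction_logfc(ratios, line, "EV", "CL")
        if ratios.has_column(line, "2K"):
            ev_2k = fraction_logfc(ratios, line, "EV", "2K")
        else:
            ev_2k = pd.Series(np.nan, index=ratios.proteins)
        # vectorised two-branch rule (mirrors classify_protein)
        branch1 = ev_cl.map(thresholds.exceeds)
        branch2 = (~branch1) & (ev_cl >= 0) & ev_cl.notna() & ev_2k.map(thresholds.exceeds)
        needs_2k = (~branch1) & (ev_cl >= 0) & ev_cl.notna()
        unevaluable = ev_cl.isna() | (needs_2k & ev_2k.isna())
        status = np.where(
            unevaluable, STATUS_UNEVALUABLE, np.where(branch1 | branch2, STATUS_EV, STATUS_NOT)
        )
        branch = np.where(branch1, "evcl", np.where(branch2, "evcl_ev2k", "none"))
        frames.append(
            pd.DataFrame(
                {
                    "protein": ratios.proteins,
                    "cell_line": line,
                    "status": status,
                    "branch": np.where(unevaluable, "none", branch),
                    "ev_cl_logfc": ev_cl.to_numpy(),
                    "ev_2k_logfc": ev_2k.to_numpy(),
                }
            )
        )
    return EVAnnotationTable(pd.concat(frames, ignore_index=True))


def marker_qc(
    ratios: RatioMatrix,
    panel: MarkerPanel | None = None,
    thresholds: AnalysisThresholds | None = None,
) -> pd.DataFrame:
    """Classify panel markers per cell line as elevated/depleted in the EV fraction.

    ``elevated_in_ev``: EV-CL log2 FC above +t; ``depleted_in_ev``: below -t;
    markers absent from the matrix (or with a missing fold change) are
    ``not_detected``.
    """
    panel = panel or MarkerPanel()
    thresholds = thresholds or AnalysisThresholds()
    ratios = merge_plexes(ratios)
    rows = []
    for role, markers in (("positive", panel.positive_markers), ("negative", panel.negative_markers)):
        for marker in markers:
            for line in ratios.cell_lines():
                if marker not in ratios.proteins:
                    cls, fc = "not_detected", np.nan
                else:
                    fc = fraction_logfc(ratios, line, "EV", "CL").loc[marker]
                    if np.isnan(fc):
                        cls = "not_detected"
                    elif thresholds.exceeds(fc):
                        cls = "elevated_in_ev"
                    elif thresholds.below_negative(fc):
                        cls = "depleted_in_ev"
                    else:
                        cls = "neither"
                rows.append(
                    {"marker": marker, "role": role, "cell_line": line,
                     "ev_cl_logfc": fc, "classification": cls}
                )
    return pd.DataFrame(rows)


def consensus_ev_counts(annot: EVAnnotationTable) -> tuple[dict[int, int], dict[int, frozenset]]:
    """Number (and set) of proteins EV-associated in at least k cell lines.

    Counts are non-increasing in k and the sets are nested by construction.
    """
    ev = annot.table[annot.table["status"] == STATUS_EV]
    per_protein = ev.groupby("protein")["cell_line"].nunique()
    n_lines = len(annot.cell_lines())
    counts, sets = {}, {}
    for k in range(1, n_lines + 1):
        members = frozenset(per_protein.index[per_protein >= k])
        counts[k] = len(members)
        sets[k] = members
    return counts, sets


def ev_detection_sets(ratios: RatioMatrix) -> dict[str, frozenset]:
    """Cell line -> proteins detected in its EV preparation.

    "Detected in the EV preparation" means the protein has a quantified EV
    ratio for that cell line.
    """
    ratios = merge_plexes(ratios)
    out = {}
    for line in ratios.cell_lines():
        if ratios.has_column(line, "EV"):
            col = ratios.column(line, "EV")
            out[line] = frozenset(col.index[col.notna()])
    return out
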