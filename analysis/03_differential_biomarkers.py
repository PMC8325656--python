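#!/usr/bin/env python
"""Proteome stage 2: histology-group consensus differentials, cell/EV
concordance against the benign HK2 line, and the detection-based Venn
selection of candidate protein biomarkers.

Reads results/proteome/ratios.tsv; writes differential tables, the Venn
report, and region sizes under results/proteome/.
"""

import json
from pathlib import Path

from evcargo import io
from evcargo.annotate import ev_detection_sets
from evcargo.config import lines_of
from evcargo.differential import concordance, differential_group, venn_proteins
from evcargo.simulate import STUDY_CELL_LINES

ROOT = Path(__file__).resolve().parents[1] / "results"
HISTOLOGY = dict(STUDY_CELL_LINES)


def main() -> None:
    out = ROOT / "proteome"
    ratios = io.read_ratio_matrix(out / "ratios.tsv")
    groups = {h: lines_of(HISTOLOGY, h) for h in ("benign", "ccRCC", "pRCC")}

    for a, b in (("pRCC", "benign"), ("ccRCC", "benign"), ("pRCC", "ccRCC")):
        res = differential_group(ratios, groups[a], groups[b], "EV")
        res.table.rename_axis("protein").to_csv(out / f"diff_{a}_vs_{b}.tsv", sep="\t")
        print(f"{a} vs {b} EVs (all-pairs consensus): "
              f"{len(res.proteins_with('increased'))} increased, "
              f"{len(res.proteins_with('decreased'))} decreased")

    for line in [l for l in HISTOLOGY if HISTOLOGY[l] not in ("benign",)]:
        conc = concordance(ratios, line, reference_line="HK2")
        print(f"cell/EV concordant proteins in {line} vs HK2: {len(conc)}")

    report = venn_proteins(ev_detection_sets(ratios), HISTOLOGY)
    report.to_frame().to_csv(out / "venn_proteins.tsv", sep="\t", index=False)
    sizes = report.region_sizes()
    (out / "venn_proteins.json").write_text(json.dumps(sizes, indent=2, sort_keys=True) + "\n")
    print(f"detected in all three histologies: {len(report.shared_by_all())}; "
          f"unique to pRCC: {len(report.unique_to('pRCC'))}; "
          f"unique to ccRCC: {len(report.unique_to('ccRCC'))}")


if __name__ == "__main__":
    main()
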