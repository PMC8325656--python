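#!/usr/bin/env python
"""Proteome stage 1: reference-channel ratios, EV marker QC, the two-branch
EV-association rule, and k-of-n consensus counts across the cell line panel.

Reads results/synthetic/, writes ratio/annotation/marker tables and a
consensus-count summary under results/proteome/.
"""

import json
from pathlib import Path

from evcargo import io
from evcargo.annotate import annotate_ev, consensus_ev_counts, marker_qc
from evcargo.ratios import compute_reference_ratios, merge_plexes

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "proteome"
    out.mkdir(parents=True, exist_ok=True)
    quant = io.read_quant_table(ROOT / "synthetic" / "quant.tsv",
                                ROOT / "synthetic" / "quant_design.tsv")
    ratios = merge_plexes(compute_reference_ratios(quant))
    io.write_ratio_matrix(ratios, out / "ratios.tsv")
    both = ratios.all_plex_subset(2)
    print(f"{len(ratios.proteins)} proteins quantified; "
          f"{len(both.proteins)} quantified in both plexes")

    markers = marker_qc(ratios)
    markers.to_csv(out / "marker_qc.tsv", sep="\t", index=False)
    pos = markers[markers["role"] == "positive"]
    neg = markers[markers["role"] == "negative"]
    print(f"positive EV markers elevated in EV fraction: "
          f"{(pos['classification'] == 'elevated_in_ev').sum()}/{len(pos)} marker-line pairs")
    print(f"negative markers depleted: "
          f"{(neg['classification'] == 'depleted_in_ev').sum()}/{len(neg)} marker-line pairs")

    annot = annotate_ev(ratios)
    annot.table.to_csv(out / "ev_annotation.tsv", sep="\t", index=False)
    counts, _ = consensus_ev_counts(annot)
    (out / "consensus_counts.json").write_text(json.dumps(counts, indent=2) + "\n")
    print("proteins EV-associated in >= k cell lines: "
          + ", ".join(f"k={k}: {n}" for k, n in counts.items()))


if __name__ == "__main__":
    main()
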