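#!/usr/bin/env python
"""Transcript stage: nCounter-style QC (negative-control background),
positive-control + global-median normalization, replicate-consensus presence
calls, and the benign-vs-ccRCC mRNA Venn comparison.

Reads results/synthetic/ count tables; writes QC, normalized counts,
presence matrices, and the mRNA Venn under results/transcripts/.
"""

import json
from pathlib import Path

from evcargo import io
from evcargo.nanostring import normalize, qc_samples
from evcargo.presence import call_presence, detect_replicates, detected_anywhere, venn_mrna
from evcargo.simulate import STUDY_CELL_LINES

ROOT = Path(__file__).resolve().parents[1] / "results"
HISTOLOGY = dict(STUDY_CELL_LINES)


def main() -> None:
    out = ROOT / "transcripts"
    out.mkdir(parents=True, exist_ok=True)
    syn = ROOT / "synthetic"
    counts = io.read_count_matrix(syn / "counts.tsv", syn / "probe_classes.tsv",
                                  syn / "count_samples.tsv")

    qc = qc_samples(counts)
    io.write_qc_report(qc, out / "qc.tsv")
    print(f"QC: {len(qc.passing)} samples passed, {len(qc.excluded)} excluded")

    norm = normalize(counts, qc)
    io.write_normalized(norm, out / "normalized.tsv", out / "norm_factors.tsv")

    detection = detect_replicates(norm, qc)
    presence = call_presence(detection, counts.samples, HISTOLOGY)
    presence.by_line.rename_axis("gene").to_csv(out / "presence_by_line.tsv", sep="\t")
    presence.by_type.rename_axis("gene").to_csv(out / "presence_by_type.tsv", sep="\t")
    presence.provenance.to_csv(out / "presence_provenance.tsv", sep="\t", index=False)

    any_set, all_set = detected_anywhere(detection, presence)
    print(f"transcripts detected in >= 1 sample: {len(any_set)}; "
          f"present in all {presence.by_line.shape[1]} cell lines: {len(all_set)}")

    report = venn_mrna(presence)
    report.to_frame().to_csv(out / "venn_mrna.tsv", sep="\t", index=False)
    sizes = report.region_sizes()
    (out / "venn_mrna.json").write_text(json.dumps(sizes, indent=2, sort_keys=True) + "\n")
    print(f"shared benign/ccRCC: {sizes['benign&ccRCC']}; "
          f"unique to benign: {sizes['benign']}; unique to ccRCC: {sizes['ccRCC']}")


if __name__ == "__main__":
    main()
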