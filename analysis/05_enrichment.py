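#!/usr/bin/env python
"""Enrichment stage: rank transcripts by ccRCC-vs-benign log2 fold change of
median-normalized counts, run permutation GSEA against a panel-sized gene-set
collection (the planted subtype cargo sets plus random null sets), and test
the consensus EV proteome for over-representation of the planted cargo.

Reads results/synthetic + results/transcripts; writes GSEA/ORA tables and
the ranked list under results/enrichment/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from evcargo import io
from evcargo.annotate import annotate_ev
from evcargo.config import EnrichmentConfig
from evcargo.enrichment import gsea, ora, rank_genes
from evcargo.nanostring import normalize, qc_samples
from evcargo.simulate import STUDY_CELL_LINES

ROOT = Path(__file__).resolve().parents[1] / "results"
HISTOLOGY = dict(STUDY_CELL_LINES)
SEED = 0


def main() -> None:
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    syn = ROOT / "synthetic"
    counts = io.read_count_matrix(syn / "counts.tsv", syn / "probe_classes.tsv",
                                  syn / "count_samples.tsv")
    truth = pd.read_csv(syn / "truth.tsv", sep="\t")

    qc = qc_samples(counts)
    norm = normalize(counts, qc)
    cc = [s for s in norm.values.columns
          if HISTOLOGY[counts.samples.loc[s, "cell_line"]] == "ccRCC"]
    benign = [s for s in norm.values.columns
              if HISTOLOGY[counts.samples.loc[s, "cell_line"]] == "benign"]
    ranked = rank_genes(norm, cc, benign)
    io.write_rnk(ranked, out / "ccRCC_vs_benign.rnk")

    markers = truth[truth["kind"] == "subtype_marker_gene"]
    sets = {
        "CCRCC_CARGO": set(markers.loc[markers["group"] == "ccRCC", "id"]),
        "BENIGN_CARGO": set(markers.loc[markers["group"] == "benign", "id"]),
    }
    rng = np.random.default_rng(SEED + 13)
    for j in range(35):
        sets[f"RANDOM_{j:02d}"] = set(rng.choice(ranked.index, 18, replace=False))
    io.write_gmt({k: sorted(v) for k, v in sets.items()}, out / "panel_sets.gmt")

    cfg = EnrichmentConfig(n_permutations=1000, seed=SEED)
    result = gsea(ranked, sets, cfg)
    result.to_csv(out / "gsea.tsv", sep="\t")
    sig = result[result["significant"]].sort_values("p_nominal")
    print(f"GSEA ({cfg.n_permutations} gene-label permutations): "
          f"{len(sig)}/{len(result)} sets significant at NOM p<0.05, FDR q<0.25")
    for name, row in sig.iterrows():
        side = "ccRCC" if row["nes"] > 0 else "benign"
        print(f"  {name}: ES={row['es']:+.3f} NES={row['nes']:+.2f} "
              f"p={row['p_nominal']:.4f} q={row['fdr_q']:.3f} (enriched in {side} EVs)")

    # ORA: consensus EV proteome vs the planted vesicle-cargo set
    ratios = io.read_ratio_matrix(ROOT / "proteome" / "ratios.tsv")
    annot = annotate_ev(ratios)
    ev_sets = annot.ev_sets()
    consensus = set.intersection(*(set(s) for s in ev_sets.values()))
    universe = set(ratios.proteins)
    prot_sets = {"PLANTED_EV_CARGO": set(truth.loc[truth["kind"] == "ev_associated", "id"])}
    rng2 = np.random.default_rng(SEED + 17)
    for j in range(10):
        prot_sets[f"RANDOM_{j}"] = set(rng2.choice(sorted(universe), 60, replace=False))
    ora_res = ora(consensus, universe, prot_sets)
    ora_res.to_csv(out / "ora.tsv", sep="\t")
    row = ora_res.loc["PLANTED_EV_CARGO"]
    print(f"ORA of the {len(consensus)}-protein consensus EV set: planted cargo "
          f"overlap {int(row['overlap'])}/{int(row['set_size'])}, p={row['p_value']:.3g}, "
          f"q={row['fdr_q']:.3g}")


if __name__ == "__main__":
    main()
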