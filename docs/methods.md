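# Methods

`evcargo` implements a multi-omic analysis of extracellular-vesicle (EV)
cargo from cultured renal cell lines: a spatial-proteomics EV-association
annotation built on TMT reporter ratios, consensus and differential set
logic across histology groups (benign, clear cell RCC, papillary RCC),
nCounter-style transcript normalization with replicate-consensus presence
calling, and gene-set enrichment statistics. A synthetic-data generator
with planted ground truth stands in for the raw conditioned-media EV data,
which has no public accession.

## TMT reference-channel ratios

Each TMT plex quantifies, per cell line, three fractions — the EV pellet
(EV), the whole cell lysate (CL), and the 2,000×g debris pellet (2K) — plus
one pooled cellular reference channel shared in composition between plexes.
All downstream rules operate on

    r(protein, line, fraction) = log2 A(sample channel) − log2 A(reference channel of its plex),

which removes plex-level offsets exactly: adding a constant to every
channel of one plex leaves every ratio unchanged. Missing channel values
propagate into missing ratios and are never imputed; the filters downstream
operate on observed ratios only. Proteins quantified in a single plex are
retained with per-plex provenance (`n_plexes_quantified`); restriction to
the across-plex subset is an explicit caller-side filter
(`RatioMatrix.all_plex_subset`), never a silent drop. Abundances are
consumed already log2-transformed; `QuantTable.from_linear` accepts linear
intensities and logs them (base 2) on read, mapping zeros to missing.

## The two-branch EV-association rule

A protein is EV-associated in a cell line when either

1. EV − CL log2 fold change > t, or
2. EV − CL lies in [0, t] **and** EV − 2K > t,

with t = 0.58 (1.5-fold) by default. Conventions, fixed here because the
printed rule leaves them open:

* the inequality at t is strict (`>`); `AnalysisThresholds(strict=False)`
  switches to `>=`;
* the printed 0.58 is the default; `AnalysisThresholds.exact()` uses
  log2(1.5) = 0.58496 — the printed value reproduces published counts, the
  exact value is available for sensitivity analysis;
* the branch-2 lower bound at 0 is inclusive;
* a protein whose required fold change is missing is **unevaluable**, not
  negative — in particular, a branch-2 candidate (EV − CL in [0, t]) with
  no 2K measurement.

The rule is monotone in EV − CL at fixed EV − 2K, and the k-of-n consensus
sets ("EV-associated in at least k lines") are nested with non-increasing
counts by construction.

"Detected in the EV preparation", the predicate behind the Venn biomarker
selection, is defined as having a quantified EV-fraction ratio for that
cell line. The source analysis never states its detection definition; this
one is declared here and used consistently.

## Differential abundance and Venn selection

Differential calls are pure fold-change thresholds (no p-values): increased
if Δlog2 > +t, decreased if < −t. Group-versus-group comparisons use
all-pairs consensus semantics — increased means increased in *every*
pairwise comparison of a group-A line against a group-B line — matching the
"increased in all lines relative to all lines" phrasing of the emulated
analysis; a group-mean alternative sits behind `method="group_mean"` but is
not the default. Any missing pairwise value makes a protein "neither".
Cell/EV concordance intersects the direction calls of the CL and EV
comparisons of a line against the benign reference line (HK2).

Per histology, the detected set is the intersection over its member lines;
the candidate-biomarker report carries the full 2^3−1-region Venn partition
(pairwise disjoint, union-covering for any input).

## Transcript QC, normalization, presence

Counts come as probe × sample with probe classes endogenous / positive /
negative. Per sample, the background threshold is

    mean(negative-control counts) + k · SD (sample SD, n−1; k = 2 by default),

the common nSolver-style rule; the emulated study does not print its rule,
so k is configurable. A sample is excluded when the fraction of endogenous
probes strictly above its background falls below
`min_fraction_above_background` (default 0.5, "low binding density");
manual exclusions with stated reasons (e.g. hybridization failures) are
honoured from configuration.

Normalization of passing samples: (1) positive-control scaling — factor =
(arithmetic mean over samples of per-sample geometric means of positive
probes) ÷ this sample's geometric mean; (2) global median scaling — factor
= (mean over samples of per-sample medians of step-1-scaled endogenous
counts) ÷ this sample's median. Both multiplicative, order (1) then (2).
Background is not subtracted; the threshold is carried through the same
two factors so that presence comparisons stay consistent on the normalized
scale. Normalization preserves within-sample rank order, and scaling one
sample's counts (all probe classes) by c > 0 leaves its normalized profile
exactly invariant while shifting the whole matrix by a single cohort-unit
constant — exact per-entry invariance is impossible for any symmetric
data-derived reference level, since the cohort unit necessarily moves with
its members; this formulation is what the property tests assert.

A transcript is detected in a sample when its normalized count is strictly
above the sample's threshold; present in a cell line when detected in at
least 2/3 replicates (2/2 when only two replicates pass QC; simple majority
for other replicate counts); present in a histology when present in every
line of the histology, scored as consensus only when ≥ 2 lines of that
histology survive QC (a single-line histology yields a per-line call
flagged non-consensus — mirroring the exclusion of the single-line pRCC
group from the presence analysis). The benign-vs-ccRCC mRNA Venn compares
type-level presence regardless of abundance.

## Enrichment statistics

**GSEA.** Genes are ranked by log2((mean_A + c)/(mean_B + c)) of
median-normalized counts (pseudocount c = 1 by default), descending, ties
broken by gene id. The enrichment score of a set S is the maximal
deviation from zero of the running sum that adds |r_i|^p / Σ_S |r|^p at
members and subtracts 1/(N − |S|) at non-members (weight p = 1, the
classic weighted statistic); ties between the positive maximum and the
negative minimum (they can coincide exactly) go to the earlier list
position, within a 1e-12 float tolerance. |ES| ≤ 1 always. The null is
gene-label permutation — random same-size gene sets against the fixed
ranking — chosen over phenotype permutation because the emulated design
has too few samples per class; phenotype mode is available via a
caller-supplied re-ranker. The nominal p uses the same-sign convention with
add-one smoothing, p = (1 + #{|ES_π| ≥ |ES|, same sign}) / (1 + #{ES_π of
that sign}); an exhaustive mode enumerates every placement on small lists
and reports the exact tail fraction. NES divides ES by the mean |permuted
ES| of the same sign; the FDR q is the standard NES-pooled ratio clipped to
[0, 1]. A degenerate null (no same-sign permutations) is flagged and
reported as p = 1/(n_perm + 1). Significance applies both cutoffs, NOM
p < 0.05 and FDR q < 0.25.

**ORA.** Upper-tail hypergeometric probability of the observed overlap
between a selected list and each set, within a universe that defaults to
everything quantified in the experiment (detection-conditioned inference,
not the genome), with Benjamini–Hochberg step-up correction across sets
(hand-rolled two-liner, cross-checked against statsmodels in the tests).

## Synthetic data

The generator emulates the study design: seven renal lines (HK2, RPTEC
benign; 786-O, 769-P, Caki1 ccRCC; ACHN, Caki2 pRCC), two TMT plexes of
EV/CL/2K channels linked by a pooled reference, and triplicate
nCounter-like counts per line.

Proteomics: per-protein base abundance N(0, 1.5²) on the log2 scale with
per-line effects N(0, 0.2²) and Gaussian channel noise (`noise_sd`, default
0.3 log2 units — the platform-standard noise model; the emulated study
reports none). Planted EV proteins (default 15% of 2,000) carry an EV − CL
difference of `ev_logfc_mean` (default 2.0); 20% of them instead carry
EV − CL = +0.3 with EV − 2K = `ev_logfc_mean`, exercising the second
annotation branch. Non-planted proteins have EV − CL drawn ≤ 0
(−|N(0.5, 0.3²)|), so at zero noise annotation recovers the plant exactly.
Histology-specific marker proteins (2% per histology, disjoint) are
EV-enriched in their own histology's lines and unquantified in the EV
fraction elsewhere. The six positive / three negative classic EV marker
ids (FLOT1, CD81, CD63, CD9, PDCD6IP, TSG101 / CANX, HSP90B1, CYC1) are
planted elevated / depleted respectively.

Transcripts: endogenous counts are negative binomial (dispersion 0.1)
around gene-by-line means (lognormal, median ≈ 300 counts) scaled by a
per-sample loading factor (lognormal, CV ≈ 15%); absent transcripts and the
eight negative controls draw from a truncated Gaussian background (mean 12,
SD 4, clipped at 0, rounded); six positive controls follow the geometric
ladder 128/32/8/2/0.5/0.125 via Poisson draws, identical in expectation
across samples up to the loading factor. Presence structure: 25% of genes
present in every line, 45% present per-line with probability 0.7, the rest
absent, with subtype marker genes (2% per histology) present only in their
own histology's lines. Samples listed in `qc_fail_samples` have all
endogenous counts forced to background, as QC bait.

What the generator does **not** emulate: reporter-ion interference and
ratio compression, peptide-to-protein rollup, batch/run-order effects,
probe-specific hybridization efficiency, and correlated missingness.
Passing planted-recovery tests therefore demonstrates the correctness of
the decision rules and their thresholds under the declared noise models,
not robustness to those real-data artifacts.

## Problem sizes and numerics

The planted-recovery evaluation and `scripts/acceptance.py` run the
generator at the study scale — 2,000 proteins, 770 transcripts, 7 lines,
3 replicates — in the large-effect / low-noise regime (`ev_logfc_mean` = 3,
`noise_sd` = 0.05) that the recovery criteria address; the analysis drivers
under `analysis/` use the realistic-noise defaults. Null calibration of
the GSEA nominal p uses 150 independent random sets of 20 genes at 1,000
permutations. Exhaustive permutation checks run on 8-gene lists (C(8,3) =
56 placements). Geometric means are computed in log space; a zero
positive-control count or zero endogenous median aborts normalization
naming the offending sample. All randomness in a run flows from a single
seed.

## Known limitations

* The published GSEA significance calls cannot be reproduced bit-for-bit:
  the permutation mode, weight, and permutation count behind them are
  unstated, so they are checked qualitatively (direction and the
  p < 0.05 / q < 0.25 rule) on recomputed ranks.
* Recomputation of the published counts requires the supplementary
  workbook, which has no data accession; the reader and the recomputation
  path are implemented and tested on toy workbooks, and activate when the
  workbook is placed at `data/supplementary_tables.xlsx`.
* The ORA here is a plain hypergeometric test; it does not replicate
  DAVID's EASE-modified Fisher score or WebGestalt's pathway mappings, and
  performs no GO-graph propagation.
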