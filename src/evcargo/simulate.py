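"""Synthetic multi-omic EV-cargo data with known planted truth.

Emulates the study design the pipeline targets: two TMT plexes of
EV/CL/2K fractions per cell line linked by a pooled cellular reference
channel, and nCounter-like probe counts (negative-binomial endogenous
counts, a geometric positive-control ladder, truncated-Gaussian
negative-control background) in replicate per cell line. Planted truth —
which proteins are EV-enriched, which cargo is histology-specific, which
transcripts are present where — is returned alongside the tables so every
downstream rule can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, HISTOLOGIES, MarkerPanel
from .nanostring import CountMatrix
from .ratios import QuantTable, REFERENCE_FRACTION

#: nCounter-convention positive-control ladder (relative concentrations).
POSITIVE_LADDER = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)

#: The study's seven renal lines: 2 benign, 3 ccRCC, 2 pRCC.
STUDY_CELL_LINES = (
    ("HK2", "benign"),
    ("RPTEC", "benign"),
    ("786-O", "ccRCC"),
    ("769-P", "ccRCC"),
    ("Caki1", "ccRCC"),
    ("ACHN", "pRCC"),
    ("Caki2", "pRCC"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_proteins: int = 2000
    n_genes: int = 770
    cell_lines: tuple[tuple[str, str], ...] = STUDY_CELL_LINES
    n_replicates_per_line: int = 3
    frac_ev_associated: float = 0.15
    frac_subtype_markers: float = 0.02
    ev_logfc_mean: float = 2.0
    noise_sd: float = 0.3
    nb_dispersion: float = 0.1
    background_mean: float = 12.0
    background_sd: float = 4.0
    seed: int = 0
    # share of planted EV proteins expressing only moderate EV-CL enrichment
    # but strong EV-2K enrichment (exercises the second annotation branch)
    frac_branch2: float = 0.2
    # baseline transcript presence structure: a core present in every line,
    # a variable tier present per-line with the given probability, rest absent
    frac_present_all: float = 0.25
    frac_present_variable: float = 0.45
    variable_presence_prob: float = 0.7
    include_marker_panel: bool = True
    # sample ids whose endogenous counts are forced to background (QC bait)
    qc_fail_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "frac_ev_associated",
            "frac_subtype_markers",
            "frac_branch2",
            "frac_present_all",
            "frac_present_variable",
            "variable_presence_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.n_replicates_per_line < 2:
            raise ConfigError("need at least 2 replicates per cell line")
        if self.n_proteins < 1 or self.n_genes < 1:
            raise ConfigError("n_proteins and n_genes must be positive")
        bad = {h for _, h in self.cell_lines} - set(HISTOLOGIES)
        if bad:
            raise ConfigError(f"unknown histologies: {sorted(bad)}")
        if self.frac_present_all + self.frac_present_variable > 1.0:
            raise ConfigError("presence tier fractions must sum to <= 1")

    @property
    def histology(self) -> dict[str, str]:
        return dict(self.cell_lines)


@dataclass
class SyntheticTruth:
    """Planted ground truth for the generated tables."""

    ev_associated: dict[str, frozenset] = field(default_factory=dict)
    subtype_marker_proteins: dict[str, frozenset] = field(default_factory=dict)
    present_genes: pd.DataFrame | None = None  # gene x cell line booleans
    subtype_marker_genes: dict[str, frozenset] = field(default_factory=dict)
    ev_branch: dict[str, str] = field(default_factory=dict)  # planted protein -> branch


def _protein_ids(config: SyntheticConfig) -> list[str]:
    ids = [f"P{i:04d}" for i in range(config.n_proteins)]
    if config.include_marker_panel:
        panel = MarkerPanel()
        names = list(panel.positive_markers) + list(panel.negative_markers)
        ids[: len(names)] = names
    return ids


def generate_proteomics(config: SyntheticConfig) -> tuple[QuantTable, SyntheticTruth]:
    """Two-plex TMT quant table with planted EV-enriched and subtype-specific proteins.

    Planted EV proteins carry a mean EV-CL log2 difference of
    ``ev_logfc_mean`` (branch-2 plants: EV-CL = +0.3 with EV-2K =
    ``ev_logfc_mean``); all other proteins have EV-CL centred at or below
    zero, so at zero noise the annotation rule recovers the plant exactly.
    Subtype-marker proteins are quantified in the EV fraction only in their
    own histology's lines and are EV-enriched there.
    """
    rng = np.random.default_rng(config.seed)
    proteins = _protein_ids(config)
    histology = config.histology
    lines = list(histology)
    panel = MarkerPanel() if config.include_marker_panel else MarkerPanel((), ())

    pool = [p for p in proteins if p not in panel.positive_markers + panel.negative_markers]
    n_ev = round(config.frac_ev_associated * config.n_proteins)
    n_sub = round(config.frac_subtype_markers * config.n_proteins)
    drawn = [
        str(p)
        for p in rng.choice(
            pool, size=min(len(pool), n_ev + n_sub * len(HISTOLOGIES)), replace=False
        )
    ]
    core_ev = list(panel.positive_markers) + drawn[:n_ev]
    n_branch2 = round(config.frac_branch2 * len(core_ev))
    branch2 = set(core_ev[:n_branch2]) - set(panel.positive_markers)
    subtype_markers = {}
    offset = n_ev
    for h in HISTOLOGIES:
        subtype_markers[h] = frozenset(drawn[offset : offset + n_sub])
        offset += n_sub

    idx = pd.Index(proteins, name="protein")
    base = pd.Series(rng.normal(0.0, 1.5, config.n_proteins), index=idx)
    # per-protein EV depletion for non-planted proteins (centred below 0,
    # truncated at 0 so no spurious plant survives at zero noise)
    nonplant_delta = -np.abs(rng.normal(0.5, 0.3, config.n_proteins))
    tk_offset = rng.normal(0.0, 0.2, config.n_proteins)

    core_set = set(core_ev)
    neg_set = set(panel.negative_markers)
    all_marker_prot = set().union(*subtype_markers.values())

    ev_delta = np.where(idx.isin(core_set), config.ev_logfc_mean, nonplant_delta)
    ev_delta = np.where(idx.isin(branch2), 0.3, ev_delta)
    ev_delta = np.where(idx.isin(neg_set), -1.5, ev_delta)

    half = (len(lines) + 1) // 2
    plex_of = {line: ("plex1" if i < half else "plex2") for i, line in enumerate(lines)}

    values: dict[str, np.ndarray] = {}
    design_rows = []
    for plex in ("plex1", "plex2"):
        if not any(p == plex for p in plex_of.values()):
            continue
        ref_id = f"{plex}_ref"
        values[ref_id] = (base + rng.normal(0.0, config.noise_sd, config.n_proteins)).to_numpy()
        design_rows.append(
            {"channel": ref_id, "cell_line": "pooled_reference",
             "fraction": REFERENCE_FRACTION, "plex": plex, "is_reference": True}
        )
    truth_ev: dict[str, frozenset] = {}
    for line in lines:
        plex = plex_of[line]
        h = histology[line]
        line_effect = rng.normal(0.0, 0.2, config.n_proteins)
        cl_core = base.to_numpy() + line_effect
        delta = ev_delta.copy()
        own_markers = subtype_markers[h]
        delta = np.where(idx.isin(own_markers), config.ev_logfc_mean, delta)
        ev_core = cl_core + delta
        tk_core = np.where(
            idx.isin(branch2), ev_core - config.ev_logfc_mean, cl_core + tk_offset
        )
        foreign = all_marker_prot - set(own_markers)
        ev_vals = ev_core + rng.normal(0.0, config.noise_sd, config.n_proteins)
        ev_vals = np.where(idx.isin(foreign), np.nan, ev_vals)
        for fraction, vals in (
            ("EV", ev_vals),
            ("CL", cl_core + rng.normal(0.0, config.noise_sd, config.n_proteins)),
            ("2K", tk_core + rng.normal(0.0, config.noise_sd, config.n_proteins)),
        ):
            channel = f"{line}_{fraction}"
            values[channel] = vals
            design_rows.append(
                {"channel": channel, "cell_line": line, "fraction": fraction,
                 "plex": plex, "is_reference": False}
            )
        truth_ev[line] = frozenset(core_set | set(own_markers))

    quant = QuantTable(
        values=pd.DataFrame(values, index=idx),
        design=pd.DataFrame(design_rows).set_index("channel"),
    )
    truth = SyntheticTruth(
        ev_associated=truth_ev,
        subtype_marker_proteins=subtype_markers,
        ev_branch={p: ("evcl_ev2k" if p in branch2 else "evcl") for p in core_set | all_marker_prot},
    )
    return quant, truth


def _truncated_background(rng, mean, sd, size) -> np.ndarray:
    draw = rng.normal(mean, sd, size)
    return np.rint(np.clip(draw, 0.0, None)).astype(int)


def generate_nanostring(config: SyntheticConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """nCounter-like probe x sample counts with planted transcript presence.

    Present transcripts draw negative-binomial counts around a
    gene-by-line mean scaled by a per-sample loading factor; absent
    transcripts and negative controls draw from a truncated-Gaussian
    background; six positive-control probes follow a geometric ladder that
    is identical in expectation across samples up to the loading factor.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    histology = config.histology
    lines = list(histology)

    n_all = round(config.frac_present_all * config.n_genes)
    n_var = round(config.frac_present_variable * config.n_genes)
    n_sub = round(config.frac_subtype_markers * config.n_genes)
    perm = [str(g) for g in rng.permutation(genes)]
    tier_all = perm[:n_all]
    tier_var = perm[n_all : n_all + n_var]
    subtype_genes = {}
    offset = n_all + n_var
    for h in HISTOLOGIES:
        subtype_genes[h] = frozenset(perm[offset : offset + n_sub])
        offset += n_sub

    gidx = pd.Index(genes, name="gene")
    present = pd.DataFrame(False, index=gidx, columns=lines)
    present.loc[tier_all, :] = True
    for g in tier_var:
        present.loc[g] = rng.random(len(lines)) < config.variable_presence_prob
    for h, members in subtype_genes.items():
        for line in lines:
            present.loc[list(members), line] = histology[line] == h

    base_mean = pd.Series(
        np.exp(rng.normal(np.log(300.0), 0.8, config.n_genes)), index=gidx
    )
    line_factor = {line: float(np.exp(rng.normal(0.0, 0.3))) for line in lines}

    pos_probes = [f"POS_{c}" for c in "ABCDEF"]
    neg_probes = [f"NEG_{i}" for i in range(1, 9)]
    pos_unit = 200.0

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for line in lines:
        for r in range(1, config.n_replicates_per_line + 1):
            sample = f"{line}_r{r}"
            scale = float(np.exp(rng.normal(0.0, 0.15)))
            mu = base_mean.to_numpy() * line_factor[line] * scale
            if config.nb_dispersion > 0:
                size_param = 1.0 / config.nb_dispersion
                endo = rng.negative_binomial(size_param, size_param / (size_param + mu))
            else:
                endo = rng.poisson(mu)
            bg = _truncated_background(
                rng, config.background_mean * scale, config.background_sd * scale, config.n_genes
            )
            is_present = present[line].to_numpy()
            if sample in config.qc_fail_samples:
                is_present = np.zeros(config.n_genes, dtype=bool)
            endo_counts = np.where(is_present, endo, bg)
            pos_counts = rng.poisson(np.array(POSITIVE_LADDER) * pos_unit * scale)
            neg_counts = _truncated_background(
                rng, config.background_mean * scale, config.background_sd * scale, len(neg_probes)
            )
            columns[sample] = np.concatenate([endo_counts, pos_counts, neg_counts])
            sample_rows.append({"sample": sample, "cell_line": line, "replicate": r})

    probe_index = pd.Index(genes + pos_probes + neg_probes, name="probe")
    counts = CountMatrix(
        counts=pd.DataFrame(columns, index=probe_index, dtype=int),
        probe_class=pd.Series(
            ["endogenous"] * config.n_genes
            + ["positive"] * len(pos_probes)
            + ["negative"] * len(neg_probes),
            index=probe_index,
        ),
        samples=pd.DataFrame(sample_rows).set_index("sample"),
    )
    truth = SyntheticTruth(present_genes=present, subtype_marker_genes=subtype_genes)
    return counts, truth
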