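"""TMT channel abundances -> per-cell-line, per-fraction log2 ratios to the pooled reference.

An isobaric-labeling experiment quantifies every sample channel of a plex in
one MS run; dividing (subtracting, on the log2 scale) each channel by the
plex's pooled reference channel removes plex-level offsets and makes ratios
comparable across plexes that share the same reference material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FRACTIONS

REFERENCE_FRACTION = "REF"


class DesignError(ValueError):
    """Raised when a channel design violates its invariants."""


@dataclass
class QuantTable:
    """Protein x channel log2 abundances plus the channel design.

    ``values``: DataFrame indexed by protein id, one column per channel id
    (NaN = not quantified). ``design``: DataFrame indexed by channel id with
    columns ``cell_line``, ``fraction`` (EV/CL/2K, or REF for the pooled
    reference), ``plex`` and boolean ``is_reference``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = {"cell_line", "fraction", "plex", "is_reference"} - set(self.design.columns)
        if missing:
            raise DesignError(f"design is missing columns: {sorted(missing)}")
        unknown = set(self.values.columns) - set(self.design.index)
        if unknown:
            raise DesignError(f"channels without design rows: {sorted(unknown)}")
        for plex, sub in self.design.groupby("plex"):
            n_ref = int(sub["is_reference"].sum())
            if n_ref != 1:
                raise DesignError(f"plex {plex!r} has {n_ref} reference channels, expected exactly 1")
        samples = self.design[~self.design["is_reference"]]
        bad = set(samples["fraction"]) - set(FRACTIONS)
        if bad:
            raise DesignError(f"fraction labels outside {FRACTIONS}: {sorted(bad)}")
        dup = samples.duplicated(subset=["cell_line", "fraction", "plex"])
        if dup.any():
            raise DesignError(
                f"duplicate (cell_line, fraction, plex) triples: {samples.index[dup].tolist()}"
            )

    @classmethod
    def from_linear(cls, intensities: pd.DataFrame, design: pd.DataFrame) -> "QuantTable":
        """Build from linear-scale intensities, log2-transforming on read (0 -> NaN)."""
        vals = intensities.where(intensities > 0)
        return cls(values=np.log2(vals), design=design)


@dataclass
class RatioMatrix:
    """Protein x (cell_line, fraction[, plex]) log2 ratios to the pooled reference.

    Before plex merging the columns carry a third ``plex`` level; after
    :func:`merge_plexes` they are (cell_line, fraction) pairs.
    """

    log2_ratio: pd.DataFrame
    n_plexes_quantified: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def merged(self) -> bool:
        return self.log2_ratio.columns.nlevels == 2

    @property
    def proteins(self) -> pd.Index:
        return self.log2_ratio.index

    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.log2_ratio.columns.get_level_values("cell_line")))

    def column(self, cell_line: str, fraction: str) -> pd.Series:
        """The (cell_line, fraction) ratio column of a merged matrix."""
        if fraction not in FRACTIONS:
            raise KeyError(f"unknown fraction {fraction!r}; expected one of {FRACTIONS}")
        df = self.log2_ratio if self.merged else merge_plexes(self).log2_ratio
        if (cell_line, fraction) not in df.columns:
            raise KeyError(f"no column for cell line {cell_line!r}, fraction {fraction!r}")
        return df[(cell_line, fraction)]

    def has_column(self, cell_line: str, fraction: str) -> bool:
        df = self.log2_ratio if self.merged else merge_plexes(self).log2_ratio
        return (cell_line, fraction) in df.columns

    def all_plex_subset(self, n_plexes: int) -> "RatioMatrix":
        """Restrict to proteins quantified in all ``n_plexes`` plexes."""
        keep = self.n_plexes_quantified >= n_plexes
        return RatioMatrix(self.log2_ratio.loc[keep], self.n_plexes_quantified.loc[keep])


def compute_reference_ratios(quant: QuantTable) -> RatioMatrix:
    """Log2 ratio of every sample channel to its plex's pooled reference.

    A ratio is present only when both the sample channel and the reference
    channel were quantified for that protein; missingness propagates, it is
    never imputed.
    """
    quant.validate()
    design = quant.design.loc[[c for c in quant.values.columns if c in quant.design.index]]
    cols: dict[tuple[str, str, object], pd.Series] = {}
    plex_quantified = {}
    for plex, sub in design.groupby("plex", sort=False):
        ref_channel = sub.index[sub["is_reference"]][0]
        if ref_channel not in quant.values.columns:
            raise DesignError(f"reference channel {ref_channel!r} of plex {plex!r} has no values")
        ref = quant.values[ref_channel]
        plex_channels = [c for c in sub.index if c in quant.values.columns]
        plex_quantified[plex] = quant.values[plex_channels].notna().any(axis=1)
        for channel in plex_channels:
            row = sub.loc[channel]
            if row["is_reference"]:
                continue
            cols[(row["cell_line"], row["fraction"], plex)] = quant.values[channel] - ref
    ratios = pd.DataFrame(cols)
    ratios.columns = pd.MultiIndex.from_tuples(cols.keys(), names=["cell_line", "fraction", "plex"])
    n_plexes = pd.DataFrame(plex_quantified).sum(axis=1).astype(int)
    return RatioMatrix(ratios, n_plexes.reindex(ratios.index))


def merge_plexes(ratios: RatioMatrix) -> RatioMatrix:
    """Align plex-level ratio columns into one column per (cell_line, fraction).

    Values are never altered, only re-labelled; the same (cell_line,
    fraction) appearing in more than one plex is a design conflict.
    """
    if ratios.merged:
        return RatioMatrix(ratios.log2_ratio.copy(), ratios.n_plexes_quantified)
    pairs = [(cl, fr) for cl, fr, _ in ratios.log2_ratio.columns]
    seen: set[tuple[str, str]] = set()
    dups = {p for p in pairs if p in seen or seen.add(p)}
    if dups:
        raise DesignError(f"conflicting duplicate columns across plexes: {sorted(dups)}")
    merged = ratios.log2_ratio.copy()
    merged.columns = pd.MultiIndex.from_tuples(pairs, names=["cell_line", "fraction"])
    return RatioMatrix(merged, ratios.n_plexes_quantified)


def fraction_logfc(
    ratios: RatioMatrix, cell_line: str, fraction_a: str, fraction_b: str
) -> pd.Series:
    """Per-protein log2 fold change between two fractions of one cell line.

    Ratios are already on the log2 scale, so the fold change is a plain
    subtraction; a missing value on either side yields a missing fold change.
    """
    return ratios.column(cell_line, fraction_a) - ratios.column(cell_line, fraction_b)
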