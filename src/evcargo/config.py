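"""Shared configuration objects: thresholds, histology maps, presence and enrichment rules.

All fold-change logic in the package flows through :class:`AnalysisThresholds`
so that the strict-inequality convention and the printed-vs-exact log2(1.5)
choice are made in exactly one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

FRACTIONS = ("EV", "CL", "2K")
HISTOLOGIES = ("benign", "ccRCC", "pRCC")

#: Cell line -> histology for the six-line TMT proteome experiment.
PROTEOME_HISTOLOGY: Mapping[str, str] = {
    "HK2": "benign",
    "786-O": "ccRCC",
    "769-P": "ccRCC",
    "Caki1": "ccRCC",
    "ACHN": "pRCC",
    "Caki2": "pRCC",
}

#: Cell line -> histology for the seven-line nCounter transcript experiment.
TRANSCRIPT_HISTOLOGY: Mapping[str, str] = {
    "HK2": "benign",
    "RPTEC": "benign",
    "786-O": "ccRCC",
    "769-P": "ccRCC",
    "Caki1": "ccRCC",
    "ACHN": "pRCC",
    "Caki2": "pRCC",
}


class ConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


def lines_of(histology_map: Mapping[str, str], histology: str) -> list[str]:
    """Cell lines mapped to ``histology``, in insertion order."""
    return [line for line, h in histology_map.items() if h == histology]


@dataclass(frozen=True)
class AnalysisThresholds:
    """Fold-change thresholds for EV annotation and differential abundance.

    The default log2 threshold is the printed 0.58 (1.5-fold); ``exact()``
    switches to log2(1.5) = 0.58496. ``strict`` selects ">" (default)
    versus ">=" at the boundary. The lower bound of the second annotation
    branch ("between 0 and 0.58") is inclusive at 0.
    """

    fc_linear: float = 1.5
    fc_log2: float = 0.58
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.fc_linear > 1:
            raise ConfigError(f"fc_linear must exceed 1, got {self.fc_linear}")
        if abs(self.fc_log2 - math.log2(self.fc_linear)) > 0.01:
            raise ConfigError(
                f"fc_log2={self.fc_log2} is not log2(fc_linear={self.fc_linear}) within 0.01"
            )

    @classmethod
    def exact(cls, fc_linear: float = 1.5, strict: bool = True) -> "AnalysisThresholds":
        """Thresholds using the exact log2 of the linear fold change."""
        return cls(fc_linear=fc_linear, fc_log2=math.log2(fc_linear), strict=strict)

    def exceeds(self, logfc: float) -> bool:
        """True when ``logfc`` passes the positive threshold."""
        if math.isnan(logfc):
            return False
        return logfc > self.fc_log2 if self.strict else logfc >= self.fc_log2

    def below_negative(self, logfc: float) -> bool:
        """True when ``logfc`` passes the negative (depletion) threshold."""
        if math.isnan(logfc):
            return False
        return logfc < -self.fc_log2 if self.strict else logfc <= -self.fc_log2


@dataclass(frozen=True)
class MarkerPanel:
    """Positive/negative EV protein marker panels used for QC summaries."""

    positive_markers: tuple[str, ...] = ("FLOT1", "CD81", "CD63", "CD9", "PDCD6IP", "TSG101")
    negative_markers: tuple[str, ...] = ("CANX", "HSP90B1", "CYC1")

    def __post_init__(self) -> None:
        if set(self.positive_markers) & set(self.negative_markers):
            raise ConfigError("positive and negative marker panels must be disjoint")


@dataclass(frozen=True)
class PresenceRules:
    """Replicate- and cell-line-level mRNA presence rules.

    ``min_detected_replicates`` maps the number of passing replicates of a
    cell line to the count that must be above background (2/3 and 2/2 by
    default). Unlisted replicate counts fall back to a simple majority.
    Type-level presence requires presence in every line of the type, and is
    only scored as consensus when the type retains at least
    ``min_lines_for_type_call`` lines after QC.
    """

    min_detected_replicates: Mapping[int, int] = field(
        default_factory=lambda: {3: 2, 2: 2}
    )
    min_lines_for_type_call: int = 2

    def __post_init__(self) -> None:
        for n, k in self.min_detected_replicates.items():
            if not 1 <= k <= n:
                raise ConfigError(f"required count {k} invalid for {n} replicates")

    def required_for(self, n_replicates: int) -> int:
        if n_replicates < 1:
            raise ConfigError("cell line must have at least one passing replicate")
        if n_replicates in self.min_detected_replicates:
            return self.min_detected_replicates[n_replicates]
        return n_replicates // 2 + 1  # simple majority fallback


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters for the running-sum gene-set enrichment test."""

    weight: float = 1.0
    n_permutations: int = 1000
    permutation_mode: str = "gene"  # or "phenotype"
    nominal_p_cutoff: float = 0.05
    fdr_q_cutoff: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigError("weight exponent must be >= 0")
        if self.n_permutations < 1:
            raise ConfigError("need at least one permutation")
        if self.permutation_mode not in ("gene", "phenotype"):
            raise ConfigError(f"unknown permutation mode {self.permutation_mode!r}")
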