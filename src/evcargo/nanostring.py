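"""nCounter-style count QC and normalization.

The pipeline follows the platform convention: (1) sample-level QC against a
negative-control background; (2) positive-control scaling by geometric
means; (3) global median scaling of endogenous counts. Background
subtraction is deliberately not applied — the per-sample background
threshold is carried alongside the normalized counts and used downstream
for presence calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "positive", "negative")
QC_REASONS = ("low_binding_density", "hybridization_error", "manual", "none")


class NormalizationError(ValueError):
    """Raised when counts cannot be QC'd or normalized."""


@dataclass
class CountMatrix:
    """Probe x sample raw counts with probe classes and sample metadata.

    ``counts``: DataFrame indexed by probe id, one column per sample id,
    non-negative integers. ``probe_class``: Series probe -> class.
    ``samples``: DataFrame indexed by sample id with columns ``cell_line``
    and ``replicate``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if unknown:
            raise NormalizationError(f"unknown probe classes: {sorted(unknown)}")
        if (self.counts.to_numpy() < 0).any():
            raise NormalizationError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.probe_class.index)
        if missing:
            raise NormalizationError(f"probes without a class: {sorted(missing)[:5]} ...")

    def probes_of(self, probe_class: str) -> pd.Index:
        return self.probe_class.index[self.probe_class == probe_class].intersection(
            self.counts.index
        )


@dataclass
class QCReport:
    """Per-sample QC status with the metric values behind each decision."""

    table: pd.DataFrame  # index sample; columns: status, reason, fraction_above_background, background_threshold

    @property
    def passing(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "pass"])

    @property
    def excluded(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "excluded"])


@dataclass
class NormalizedMatrix:
    """Endogenous probe x passing-sample normalized counts plus scale factors.

    ``background`` is the per-sample detection threshold on the *normalized*
    scale (the raw mean + k*SD negative-control threshold multiplied by the
    same factors as the counts), so downstream comparisons are consistent.
    """

    values: pd.DataFrame
    pos_factor: pd.Series
    median_factor: pd.Series
    background: pd.Series
    raw_background: pd.Series


def background_threshold(counts: CountMatrix, sample: str, k: float = 2.0) -> float:
    """Negative-control background: mean + k * SD (sample SD, n-1 denominator)."""
    neg = counts.counts.loc[counts.probes_of("negative"), sample]
    if len(neg) < 2:
        raise NormalizationError(f"sample {sample!r}: need >= 2 negative probes, got {len(neg)}")
    return float(neg.mean() + k * neg.std(ddof=1))


def qc_samples(
    counts: CountMatrix,
    min_fraction_above_background: float = 0.5,
    manual_exclusions: Mapping[str, str] | Iterable[str] | None = None,
    k: float = 2.0,
) -> QCReport:
    """Exclude samples whose endogenous counts sit largely below background.

    A sample fails when the fraction of endogenous probes strictly above its
    negative-control background threshold falls below
    ``min_fraction_above_background`` (low RNA binding density). Manual
    exclusions (e.g. known hybridization failures) are honoured with their
    stated reason.
    """
    if len(counts.probes_of("negative")) == 0:
        raise NormalizationError("QC requires negative-control probes")
    if manual_exclusions is None:
        manual: dict[str, str] = {}
    elif isinstance(manual_exclusions, Mapping):
        manual = dict(manual_exclusions)
    else:
        manual = {s: "manual" for s in manual_exclusions}
    bad_reason = set(manual.values()) - set(QC_REASONS)
    if bad_reason:
        raise NormalizationError(f"unknown exclusion reasons: {sorted(bad_reason)}")
    endo = counts.probes_of("endogenous")
    rows = []
    for sample in counts.counts.columns:
        thr = background_threshold(counts, sample, k=k)
        frac = float((counts.counts.loc[endo, sample] > thr).mean())
        if sample in manual:
            status, reason = "excluded", manual[sample]
        elif frac < min_fraction_above_background:
            status, reason = "excluded", "low_binding_density"
        else:
            status, reason = "pass", "none"
        rows.append(
            {"sample": sample, "status": status, "reason": reason,
             "fraction_above_background": frac, "background_threshold": thr}
        )
    return QCReport(pd.DataFrame(rows).set_index("sample"))


def _geomean(values: pd.Series, sample: str) -> float:
    arr = values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise NormalizationError(
            f"sample {sample!r}: zero positive-control count, geometric mean undefined"
        )
    return float(np.exp(np.log(arr).mean()))


def normalize(counts: CountMatrix, qc: QCReport, k: float = 2.0) -> NormalizedMatrix:
    """Positive-control scaling then global median scaling of passing samples.

    Step 1: factor = mean over samples of positive-probe geometric means,
    divided by this sample's geometric mean. Step 2: factor = mean over
    samples of per-sample medians of (step-1 scaled) endogenous counts,
    divided by this sample's median. Both are applied multiplicatively; the
    background threshold is carried through the same scaling.
    """
    passing = [s for s in counts.counts.columns if s in qc.passing]
    if not passing:
        raise NormalizationError("no samples passed QC")
    pos = counts.probes_of("positive")
    endo = counts.probes_of("endogenous")
    if len(pos) == 0:
        raise NormalizationError("normalization requires positive-control probes")
    geomeans = pd.Series(
        {s: _geomean(counts.counts.loc[pos, s], s) for s in passing}, dtype=float
    )
    pos_factor = geomeans.mean() / geomeans
    scaled = counts.counts.loc[endo, passing].astype(float).mul(pos_factor, axis=1)
    medians = scaled.median(axis=0)
    zero_med = medians.index[medians <= 0]
    if len(zero_med):
        raise NormalizationError(f"zero endogenous median in sample(s) {list(zero_med)}")
    median_factor = medians.mean() / medians
    values = scaled.mul(median_factor, axis=1)
    raw_background = pd.Series(
        {s: background_threshold(counts, s, k=k) for s in passing}, dtype=float
    )
    background = raw_background * pos_factor * median_factor
    return NormalizedMatrix(
        values=values,
        pos_factor=pos_factor,
        median_factor=median_factor,
        background=background,
        raw_background=raw_background,
    )
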