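"""Tabular I/O: TSV matrices with sidecar designs, GMT/RNK gene-set formats,
supplementary-workbook reading, and the run manifest.

All tabular files are plain TSV with a one-line header. Gene and protein
identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .nanostring import CountMatrix, NormalizedMatrix, QCReport
from .ratios import QuantTable, RatioMatrix


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- quant/design


def write_quant_table(quant: QuantTable, values_path, design_path) -> None:
    quant.values.rename_axis("protein").to_csv(values_path, sep="\t")
    quant.design.rename_axis("channel").to_csv(design_path, sep="\t")


def read_quant_table(values_path, design_path, linear: bool = False) -> QuantTable:
    """Read a protein x channel matrix plus its channel design.

    With ``linear=True`` the matrix holds linear intensities and is
    log2-transformed on read (zeros become missing).
    """
    values = pd.read_csv(values_path, sep="\t", index_col="protein")
    design = pd.read_csv(design_path, sep="\t", index_col="channel")
    _require(design, ["cell_line", "fraction", "plex", "is_reference"], design_path)
    design["is_reference"] = design["is_reference"].astype(bool)
    if linear:
        return QuantTable.from_linear(values, design)
    return QuantTable(values, design)


def write_ratio_matrix(ratios: RatioMatrix, path) -> None:
    df = ratios.log2_ratio.copy()
    if df.columns.nlevels == 3:
        df.columns = [f"{cl}|{fr}|{px}" for cl, fr, px in df.columns]
    else:
        df.columns = [f"{cl}|{fr}" for cl, fr in df.columns]
    df["n_plexes_quantified"] = ratios.n_plexes_quantified
    df.rename_axis("protein").to_csv(path, sep="\t")


def read_ratio_matrix(path) -> RatioMatrix:
    df = pd.read_csv(path, sep="\t", index_col="protein")
    n_plexes = df.pop("n_plexes_quantified") if "n_plexes_quantified" in df.columns else None
    parts = [tuple(c.split("|")) for c in df.columns]
    depth = {len(p) for p in parts}
    if depth == {3}:
        names = ["cell_line", "fraction", "plex"]
    elif depth == {2}:
        names = ["cell_line", "fraction"]
    else:
        raise FormatError(f"{path}: mixed or malformed ratio column labels")
    df.columns = pd.MultiIndex.from_tuples(parts, names=names)
    return RatioMatrix(df, n_plexes)


# ---------------------------------------------------------------- counts


def write_count_matrix(counts: CountMatrix, counts_path, probes_path, samples_path) -> None:
    counts.counts.rename_axis("probe").to_csv(counts_path, sep="\t")
    counts.probe_class.rename("probe_class").rename_axis("probe").to_csv(probes_path, sep="\t")
    counts.samples.rename_axis("sample").to_csv(samples_path, sep="\t")


def read_count_matrix(counts_path, probes_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="probe")
    probes = pd.read_csv(probes_path, sep="\t", index_col="probe")
    _require(probes, ["probe_class"], probes_path)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    _require(samples, ["cell_line", "replicate"], samples_path)
    return CountMatrix(counts, probes["probe_class"], samples)


def read_rcc_csv(path) -> tuple[pd.Series, pd.Series]:
    """Read one sample from a minimal RCC-style CSV (CodeClass,Name,...,Count).

    Returns (counts, probe_class) Series indexed by probe name. Only the
    CodeSummary section of the dialect is honoured; header sections are
    skipped.
    """
    rows = []
    in_table = False
    for line in Path(path).read_text().splitlines():
        cells = line.strip().split(",")
        if cells and cells[0] == "CodeClass":
            in_table = True
            header = cells
            continue
        if in_table:
            if not line.strip() or line.startswith("</"):
                in_table = False
                continue
            rows.append(dict(zip(header, cells)))
    if not rows:
        raise FormatError(f"{path}: no CodeClass table found")
    df = pd.DataFrame(rows)
    _require(df, ["CodeClass", "Name", "Count"], path)
    class_map = {"Endogenous": "endogenous", "Positive": "positive", "Negative": "negative"}
    probe_class = df["CodeClass"].map(lambda c: class_map.get(c, "endogenous"))
    counts = pd.to_numeric(df["Count"]).astype(int)
    counts.index = probe_class.index = df["Name"]
    return counts, probe_class


# ---------------------------------------------------------------- gene sets


def read_gmt(path) -> dict[str, list[str]]:
    """Named gene sets from a GMT file (name <tab> description <tab> genes...)."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: GMT lines need name, description, >=1 gene")
        name, genes = fields[0], [g for g in fields[2:] if g]
        if name in sets:
            raise FormatError(f"{path}:{ln}: duplicate gene set {name!r}")
        if not genes:
            raise FormatError(f"{path}:{ln}: gene set {name!r} is empty")
        sets[name] = genes
    return sets


def write_gmt(sets, path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *sorted(sets[name])]) for name in sorted(sets)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rnk(path) -> pd.Series:
    """Two-column RNK ranked list -> Series sorted descending, ties by gene id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate genes in ranked list")
    s = df.set_index("gene")["score"].astype(float).sort_index()
    return s.sort_values(ascending=False, kind="mergesort")


def write_rnk(ranked: pd.Series, path) -> None:
    ranked.rename("score").rename_axis("gene").to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------- workbook

#: column sets the supplementary-workbook reader validates per logical table
WORKBOOK_SCHEMAS = {
    "ratio_matrix": {"index": "protein"},
    "annotation": {"columns": ["protein", "cell_line", "status"]},
    "counts": {"index": "probe"},
    "gene_list": {"columns": ["gene"]},
}


def read_supplementary_tables(workbook_path, sheet: str, kind: str = "ratio_matrix"):
    """Read one sheet of a supplementary workbook as a typed table.

    ``kind`` picks a validation schema; ratio-matrix sheets are returned as
    a merged :class:`RatioMatrix` (columns labelled ``cell_line|fraction``),
    other kinds as validated DataFrames.
    """
    if kind not in WORKBOOK_SCHEMAS:
        raise FormatError(f"unknown table kind {kind!r}")
    try:
        df = pd.read_excel(workbook_path, sheet_name=sheet)
    except ValueError as exc:
        raise FormatError(f"{workbook_path}: cannot read sheet {sheet!r}: {exc}") from exc
    schema = WORKBOOK_SCHEMAS[kind]
    if "columns" in schema:
        missing = [c for c in schema["columns"] if c not in df.columns]
        if missing:
            raise FormatError(f"{workbook_path}[{sheet}]: missing required column(s) {missing}")
        return df
    index_col = schema["index"]
    if index_col not in df.columns:
        raise FormatError(f"{workbook_path}[{sheet}]: missing required column(s) ['{index_col}']")
    df = df.set_index(index_col)
    if kind == "ratio_matrix":
        parts = [tuple(str(c).split("|")) for c in df.columns]
        if any(len(p) != 2 for p in parts):
            raise FormatError(
                f"{workbook_path}[{sheet}]: ratio columns must be 'cell_line|fraction'"
            )
        df.columns = pd.MultiIndex.from_tuples(parts, names=["cell_line", "fraction"])
        return RatioMatrix(df, None)
    return df


# ---------------------------------------------------------------- qc / normalized


def write_qc_report(qc: QCReport, path) -> None:
    qc.table.rename_axis("sample").to_csv(path, sep="\t")


def write_normalized(norm: NormalizedMatrix, values_path, factors_path) -> None:
    norm.values.rename_axis("probe").to_csv(values_path, sep="\t")
    pd.DataFrame(
        {
            "pos_factor": norm.pos_factor,
            "median_factor": norm.median_factor,
            "background": norm.background,
            "raw_background": norm.raw_background,
        }
    ).rename_axis("sample").to_csv(factors_path, sep="\t")


# ---------------------------------------------------------------- config / manifest


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, config: dict, outputs: dict[str, str], row_counts: dict[str, int], version: str) -> dict:
    """Write a run manifest: config hash, per-file hashes, per-stage row counts."""
    manifest = {
        "tool_version": version,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {name: file_sha256(p) for name, p in outputs.items()},
        "row_counts": row_counts,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
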