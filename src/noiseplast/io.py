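"""Readers and writers for the pipeline's external formats.

Formats
-------
* gene table      — TSV, one row per gene, typed columns, missing = empty cell
* compendium      — TSV matrix (genes x mutants of log2 ratios) + class sidecar
* transcripts     — BED6+3 (kind, status, bipromoter extension columns)
* occupancy track — bedGraph of log2 nucleosome occupancy

All genomic coordinates are converted at this boundary to 1-based
inclusive intervals, which is how every window in the analysis is
denominated.  BED/bedGraph on disk remain 0-based half-open.

Missing data is an empty string on disk and NaN/NA in memory — never a
sentinel numeric, since the per-analysis sample sizes differ and
missingness must propagate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GENE_NUMERIC_COLUMNS", "GENE_BOOL_COLUMNS", "MUTANT_CLASSES",
    "Compendium", "OccupancyTrack",
    "read_gene_table", "write_gene_table",
    "read_transcripts", "write_transcripts",
    "read_compendium", "write_compendium",
    "read_occupancy", "write_occupancy",
    "write_result_table", "read_result_table",
]

_VERSION = "0.1.0"

GENE_NUMERIC_COLUMNS = (
    "noise_dm", "plasticity", "divergence", "mrna_level", "orf_length",
    "fop", "translational_efficiency", "ribosome_density", "h2az",
)
GENE_BOOL_COLUMNS = ("tata", "essential", "complex_member", "haploinsufficient")
INITIATION_CLASSES = ("TFIID", "SAGA", "unknown")
MUTANT_CLASSES = ("chromatin", "general", "histone")
TRANSCRIPT_KINDS = ("ORF_T", "CUT", "SUT")
TRANSCRIPT_STATUSES = ("verified", "dubious", "pseudogene", "unknown")


def _provenance(config_digest: str | None) -> str:
    return f"# noiseplast {_VERSION} config={config_digest or 'default'}\n"


def _fmt(value: object) -> str:
    """Serialize one cell; floats at 10 significant digits, missing as ''."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "True" if value else "False"
    if isinstance(value, (float, np.floating)):
        return f"{value:.10g}"
    return str(value)


# ---------------------------------------------------------------------------
# gene table

def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-level TSV into a typed DataFrame.

    Required column: ``gene_id`` (unique).  Known columns are parsed to
    their types; unknown columns are preserved as strings.  Empty cells
    become missing values, never zeros.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: gene table must have a gene_id column")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")

    out = pd.DataFrame({"gene_id": df["gene_id"]})
    for col in df.columns:
        if col == "gene_id":
            continue
        raw = df[col].str.strip()
        empty = raw == ""
        if col in GENE_NUMERIC_COLUMNS:
            parsed = pd.to_numeric(raw.where(~empty), errors="coerce")
            bad = (~empty) & parsed.isna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{path}: unparseable numeric value {raw.iloc[i]!r} "
                    f"in column {col!r}, row {i + 2}"
                )
            if col == "orf_length":
                if (parsed.dropna() <= 0).any():
                    raise ValueError(f"{path}: orf_length must be > 0")
                parsed = parsed.astype("Int64")
            out[col] = parsed
        elif col in GENE_BOOL_COLUMNS:
            mapped = raw.str.lower().map(
                {"true": True, "false": False, "1": True, "0": False, "": pd.NA}
            )
            if mapped.isna().any() and not (empty | raw.str.lower().isin(
                    ["true", "false", "1", "0"])).all():
                i = int(np.flatnonzero(~(empty | raw.str.lower().isin(
                    ["true", "false", "1", "0"])))[0])
                raise ValueError(
                    f"{path}: unparseable boolean {raw.iloc[i]!r} "
                    f"in column {col!r}, row {i + 2}"
                )
            out[col] = mapped.astype("boolean")
        elif col == "initiation_class":
            vals = raw.where(~empty, "unknown")
            bad = ~vals.isin(INITIATION_CLASSES)
            if bad.any():
                raise ValueError(
                    f"{path}: initiation_class must be one of {INITIATION_CLASSES}"
                )
            out[col] = vals
        else:
            out[col] = raw.where(~empty)
    fop = out.get("fop")
    if fop is not None and ((fop.dropna() < 0) | (fop.dropna() > 1)).any():
        raise ValueError(f"{path}: fop must lie in [0, 1]")
    return out


def write_gene_table(df: pd.DataFrame, path: str | Path,
                     config_digest: str | None = None) -> None:
    _write_tsv(df, path, config_digest)


def _write_tsv(df: pd.DataFrame, path: str | Path, config_digest: str | None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config_digest))
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


write_result_table = _write_tsv


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Read back a generic result TSV (all columns numeric where possible)."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=True,
                     na_values=[""])
    return df


# ---------------------------------------------------------------------------
# transcripts

def read_transcripts(path: str | Path) -> pd.DataFrame:
    """Read a BED6+3 transcript file.

    Columns: chrom, start, end, name, score, strand, kind, status,
    bipromoter.  BED is 0-based half-open; internally we keep 1-based
    inclusive coordinates with strand-aware TSS/TES:
    ``+``: tss = start + 1, tes = end;  ``-``: tss = end, tes = start + 1.
    """
    names = ["chrom", "start", "end", "name", "score", "strand",
             "kind", "status", "bipromoter"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype=str,
                     comment="#", keep_default_na=False)
    start = pd.to_numeric(df["start"], errors="raise").astype(int)
    end = pd.to_numeric(df["end"], errors="raise").astype(int)
    if (end <= start).any():
        i = int(np.flatnonzero(end <= start)[0])
        raise ValueError(f"{path}: end <= start at line {i + 1}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        i = int(np.flatnonzero(bad_strand)[0])
        raise ValueError(f"{path}: strand must be + or -, got "
                         f"{df['strand'].iloc[i]!r} at line {i + 1}")
    bad_kind = ~df["kind"].isin(TRANSCRIPT_KINDS)
    if bad_kind.any():
        raise ValueError(f"{path}: kind must be one of {TRANSCRIPT_KINDS}")
    bad_status = ~df["status"].isin(TRANSCRIPT_STATUSES)
    if bad_status.any():
        raise ValueError(f"{path}: status must be one of {TRANSCRIPT_STATUSES}")

    plus = (df["strand"] == "+").to_numpy()
    tss = np.where(plus, start + 1, end)
    tes = np.where(plus, end, start + 1)
    out = pd.DataFrame({
        "transcript_id": df["name"],
        "kind": df["kind"],
        "chrom": df["chrom"],
        "strand": df["strand"],
        "tss": tss,
        "tes": tes,
        "status": df["status"],
        "bipromoter": df["bipromoter"].str.lower().isin(["true", "1"]),
    })
    return out


def write_transcripts(ts: pd.DataFrame, path: str | Path,
                      config_digest: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config_digest))
        for row in ts.itertuples(index=False):
            lo = min(row.tss, row.tes)
            hi = max(row.tss, row.tes)
            fh.write("\t".join([
                row.chrom, str(lo - 1), str(hi), row.transcript_id, "0",
                row.strand, row.kind, row.status,
                "True" if row.bipromoter else "False",
            ]) + "\n")


# ---------------------------------------------------------------------------
# compendium

@dataclass
class Compendium:
    """Genes x mutants matrix of log2 expression ratios with class tags."""

    values: pd.DataFrame                 # index gene_id, columns mutant_id
    mutant_class: pd.Series              # index mutant_id -> class

    def __post_init__(self) -> None:
        missing = [m for m in self.values.columns if m not in self.mutant_class.index]
        if missing:
            raise ValueError(f"mutant {missing[0]!r} has no class tag")
        bad = self.mutant_class[~self.mutant_class.isin(MUTANT_CLASSES)]
        if len(bad):
            raise ValueError(
                f"unknown mutant class {bad.iloc[0]!r} for {bad.index[0]!r}; "
                f"allowed: {MUTANT_CLASSES}"
            )
        self.mutant_class = self.mutant_class.reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def mutant_ids(self) -> pd.Index:
        return self.values.columns

    def mutants_of(self, classes: Iterable[str]) -> list[str]:
        classes = set(classes)
        return [m for m in self.mutant_ids if self.mutant_class[m] in classes]


def read_compendium(matrix_path: str | Path, class_path: str | Path) -> Compendium:
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0,
                      na_values=[""], keep_default_na=True)
    mat.index.name = "gene_id"
    if mat.index.duplicated().any():
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"{matrix_path}: duplicate gene_id {dup!r}")
    classes = pd.read_csv(class_path, sep="\t", comment="#", dtype=str,
                          keep_default_na=False)
    if list(classes.columns[:2]) != ["mutant_id", "mutant_class"]:
        raise ValueError(f"{class_path}: expected columns mutant_id, mutant_class")
    tags = classes.set_index("mutant_id")["mutant_class"]
    return Compendium(values=mat.astype(float), mutant_class=tags)


def write_compendium(comp: Compendium, matrix_path: str | Path,
                     class_path: str | Path,
                     config_digest: str | None = None) -> None:
    with open(matrix_path, "w") as fh:
        fh.write(_provenance(config_digest))
        fh.write("gene_id\t" + "\t".join(map(str, comp.mutant_ids)) + "\n")
        for gid, row in comp.values.iterrows():
            fh.write(str(gid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    with open(class_path, "w") as fh:
        fh.write(_provenance(config_digest))
        fh.write("mutant_id\tmutant_class\n")
        for mid in comp.mutant_ids:
            fh.write(f"{mid}\t{comp.mutant_class[mid]}\n")


# ---------------------------------------------------------------------------
# occupancy track

@dataclass
class OccupancyTrack:
    """Per-chromosome interval-valued log2 nucleosome occupancy.

    Each chromosome maps to a DataFrame with columns ``start``, ``end``
    (1-based inclusive, non-overlapping, sorted) and ``value``.
    """

    chroms: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, df in self.chroms.items():
            if not np.isfinite(df["value"]).all():
                raise ValueError(f"non-finite occupancy value on {chrom}")
            s = df["start"].to_numpy()
            e = df["end"].to_numpy()
            if len(df) > 1 and not (s[1:] > e[:-1]).all():
                raise ValueError(f"overlapping occupancy intervals on {chrom}")

    def midpoints(self, chrom: str) -> np.ndarray:
        df = self.chroms[chrom]
        return (df["start"].to_numpy() + df["end"].to_numpy()) / 2.0

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms


def read_occupancy(path: str | Path) -> OccupancyTrack:
    """Read a bedGraph (0-based half-open) into 1-based inclusive intervals."""
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"],
                         comment="#",
                         dtype={"chrom": str, "start": int, "end": int,
                                "value": float})
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed bedGraph ({exc})") from exc
    if df.empty:
        return OccupancyTrack({})
    df["start"] = df["start"] + 1  # to 1-based inclusive
    chroms = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable").reset_index(drop=True)
        chroms[chrom] = sub[["start", "end", "value"]]
    return OccupancyTrack(chroms)


def write_occupancy(track: OccupancyTrack, path: str | Path,
                    config_digest: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config_digest))
        for chrom, df in track.chroms.items():
            for row in df.itertuples(index=False):
                fh.write(f"{chrom}\t{row.start - 1}\t{row.end}\t{_fmt(row.value)}\n")
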