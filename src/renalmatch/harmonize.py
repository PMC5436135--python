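"""Readers, writers and harmonizing transforms for copy-number, mutation
and expression inputs.

Two cell-line resources and a tumour cohort deliver copy number in different
currencies: segmented log2 ratios (SEG files) versus allele-specific integral
copy numbers (PICNIC-style CSV with total and minor copy number per segment).
This module converts everything to a common representation:

* :class:`SegmentProfile` — per-sample genomic segments, tagged by value kind;
* :class:`GeneMatrix` — genes x samples matrix (log2 CNA, 5-valued
  GISTIC-like score, or expression), with NaN as the missing value;
* :class:`MutationRecord` rows in a plain DataFrame, filtered by the
  depth / allele-fraction / variant-class rules used for somatic calls.

All coordinates are 1-based inclusive. File dialects:

* SEG: tab-delimited, header, columns ``sample, chromosome, start, end,
  [n_markers,] seg_mean``.
* Allele-specific CSV: ``sample, chromosome, start, end, total_cn, minor_cn``.
* MAF-like TSV: ``sample, gene, variant_class, protein_change, depth, vaf``.
* GCT: version line ``#1.2``, dimension line, then ``Name, Description``
  and one column per sample.
* Gene table: BED-like TSV ``gene_id, chromosome, start, end`` (1-based
  inclusive, unlike true BED).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError, ParseError
from .genome import GenomeModel

logger = logging.getLogger(__name__)

LOG2 = "log2_ratio"
TOTAL = "total_cn"
ALLELE = "allele_specific"

#: Variant classes excluded from somatic mutation analyses by default.
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {"intronic", "UTR", "flank", "intergenic", "silent", "RNA"}
)

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "inframe_indel",
     "silent", "RNA", "intronic", "UTR", "flank", "intergenic"}
)


@dataclass
class SegmentProfile:
    """Segmented copy-number profile of one sample.

    ``segments`` has columns ``chromosome, start, end`` plus either ``value``
    (for ``value_kind="log2_ratio"`` or ``"total_cn"``) or the pair
    ``total_cn, minor_cn`` (for ``value_kind="allele_specific"``).
    """

    sample_id: str
    segments: pd.DataFrame
    value_kind: str = LOG2

    def __post_init__(self) -> None:
        seg = self.segments
        if self.value_kind not in (LOG2, TOTAL, ALLELE):
            raise InvalidArgumentError(f"unknown value_kind {self.value_kind!r}")
        needed = {"chromosome", "start", "end"}
        needed |= {"total_cn", "minor_cn"} if self.value_kind == ALLELE else {"value"}
        if not needed.issubset(seg.columns):
            raise InvalidArgumentError(f"segment table must have columns {sorted(needed)}")
        if len(seg) and (seg["start"] > seg["end"]).any():
            raise InvalidArgumentError(f"{self.sample_id}: segment with start > end")
        if self.value_kind == TOTAL and len(seg) and (seg["value"] < 0).any():
            raise InvalidArgumentError(f"{self.sample_id}: negative total copy number")
        if self.value_kind == ALLELE and len(seg):
            if (seg["total_cn"] < 0).any() or (seg["minor_cn"] < 0).any():
                raise InvalidArgumentError(f"{self.sample_id}: negative copy number")
            if (seg["minor_cn"] > seg["total_cn"]).any():
                raise InvalidArgumentError(f"{self.sample_id}: minor_cn > total_cn")

    @property
    def lengths(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"] + 1).to_numpy()


@dataclass
class GeneMatrix:
    """Genes x samples numeric matrix; NaN marks missing values."""

    values: pd.DataFrame
    kind: str = "log2"  # log2 | gistic5 | expression

    def __post_init__(self) -> None:
        if self.kind not in ("log2", "gistic5", "expression"):
            raise InvalidArgumentError(f"unknown matrix kind {self.kind!r}")
        if self.values.index.duplicated().any():
            raise InvalidArgumentError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise InvalidArgumentError("duplicate sample ids")
        if self.kind == "gistic5":
            vals = self.values.to_numpy(dtype=float)
            ok = np.isnan(vals) | np.isin(vals, (-2.0, -1.0, 0.0, 1.0, 2.0))
            if not ok.all():
                raise InvalidArgumentError("gistic5 matrix holds values outside {-2..2}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


MUTATION_COLUMNS = ["sample", "gene", "variant_class", "protein_change", "depth", "vaf"]


def validate_mutations(records: pd.DataFrame) -> pd.DataFrame:
    """Check a mutation table against the record invariants and return it."""
    missing = [c for c in MUTATION_COLUMNS if c not in records.columns]
    if missing:
        raise InvalidArgumentError(f"mutation table missing columns {missing}")
    if len(records):
        if (records["depth"] < 0).any():
            raise InvalidArgumentError("negative read depth")
        if ((records["vaf"] < 0) | (records["vaf"] > 1)).any():
            raise InvalidArgumentError("allele fraction outside [0, 1]")
        bad = set(records["variant_class"]) - VARIANT_CLASSES
        if bad:
            raise InvalidArgumentError(f"unknown variant classes {sorted(bad)}")
    return records


# ---------------------------------------------------------------------------
# SEG files

def read_seg(path: str | Path, known_chromosomes: Iterable[str] | None = None,
             value_kind: str = LOG2) -> list[SegmentProfile]:
    """Read a SEG-style TSV into per-sample profiles.

    Rows on chromosomes not in ``known_chromosomes`` (when given) are skipped
    with a warning; structurally invalid rows raise :class:`ParseError`
    naming the line.
    """
    path = Path(path)
    known = set(known_chromosomes) if known_chromosomes is not None else None
    rows: list[tuple] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) not in (5, 6):
            raise ParseError(f"{path}:1: expected 5 or 6 tab-separated columns, got {len(header)}")
        has_markers = len(header) == 6
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            try:
                sample, chrom = parts[0], parts[1]
                start, end = int(parts[2]), int(parts[3])
                value = float(parts[-1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
            if known is not None and chrom not in known:
                logger.warning("%s:%d: skipping unknown chromosome %r", path, lineno, chrom)
                continue
            rows.append((sample, chrom, start, end, value))
    df = pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "value"])
    profiles = [
        SegmentProfile(sample, grp.drop(columns="sample").reset_index(drop=True), value_kind)
        for sample, grp in df.groupby("sample", sort=False)
    ]
    logger.info("read %d segments, %d samples from %s (markers column: %s)",
                len(df), len(profiles), path, has_markers)
    return profiles


def write_seg(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    """Write log2 profiles as SEG TSV (values to 6 decimals)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample\tchromosome\tstart\tend\tn_markers\tseg_mean\n")
        for prof in profiles:
            for row in prof.segments.itertuples(index=False):
                n_markers = max(1, (row.end - row.start + 1) // 1000)
                fh.write(f"{prof.sample_id}\t{row.chromosome}\t{row.start}\t{row.end}"
                         f"\t{n_markers}\t{row.value:.6f}\n")


# ---------------------------------------------------------------------------
# Allele-specific CSV

def read_allele_csv(path: str | Path) -> list[SegmentProfile]:
    """Read allele-specific integral copy-number segments (CSV)."""
    path = Path(path)
    df = pd.read_csv(path)
    needed = ["sample", "chromosome", "start", "end", "total_cn", "minor_cn"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["chromosome"] = df["chromosome"].astype(str)
    profiles = [
        SegmentProfile(sample, grp.drop(columns="sample").reset_index(drop=True), ALLELE)
        for sample, grp in df.groupby("sample", sort=False)
    ]
    logger.info("read %d allele-specific segments, %d samples from %s", len(df), len(profiles), path)
    return profiles


def write_allele_csv(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    frames = []
    for prof in profiles:
        df = prof.segments[["chromosome", "start", "end", "total_cn", "minor_cn"]].copy()
        df.insert(0, "sample", prof.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MAF-like mutation tables

def read_maf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_mutations(df)
    logger.info("read %d mutation records from %s", len(df), path)
    return df


def write_maf(records: pd.DataFrame, path: str | Path) -> None:
    records[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GCT expression matrices

def read_gct(path: str | Path) -> GeneMatrix:
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}:1: expected GCT version '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ParseError(f"{path}:2: expected two dimensions")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns="Description")
    if df.shape != (n_genes, n_samples):
        raise ParseError(f"{path}: header declares {n_genes}x{n_samples}, found {df.shape}")
    logger.info("read %dx%d expression matrix from %s", *df.shape, path)
    return GeneMatrix(df, kind="expression")


def write_gct(matrix: GeneMatrix, path: str | Path) -> None:
    df = matrix.values
    with Path(path).open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# Gene tables

def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = ["gene_id", "chromosome", "start", "end"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["chromosome"] = df["chromosome"].astype(str)
    return df


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["gene_id", "chromosome", "start", "end"]].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; '#' comments and blanks ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# Transforms

def integral_to_log2(profile: SegmentProfile, zero_floor: float = -8.0) -> SegmentProfile:
    """Convert integral total copy numbers to log2 ratios.

    Each segment value becomes ``log2(total_cn / A)`` where ``A`` is the
    length-weighted mean total copy number of the sample (its average
    ploidy). Zero-copy segments map to ``zero_floor`` with a warning. A
    sample whose average copy number is zero is degenerate.
    """
    seg = profile.segments
    if len(seg) == 0:
        raise DegenerateInputError(f"{profile.sample_id}: empty profile")
    total = seg["total_cn" if profile.value_kind == ALLELE else "value"].to_numpy(dtype=float)
    lengths = profile.lengths.astype(float)
    avg = float(np.average(total, weights=lengths))
    if avg <= 0:
        raise DegenerateInputError(f"{profile.sample_id}: average total copy number is 0")
    with np.errstate(divide="ignore"):
        values = np.log2(total / avg)
    zero = total == 0
    if zero.any():
        logger.warning("%s: %d zero-copy segments floored at %g",
                       profile.sample_id, int(zero.sum()), zero_floor)
        values[zero] = zero_floor
    out = seg[["chromosome", "start", "end"]].copy()
    out["value"] = values
    return SegmentProfile(profile.sample_id, out, LOG2)


def segments_to_genes(profiles: Sequence[SegmentProfile], genome: GenomeModel) -> GeneMatrix:
    """Project segment values onto genes.

    A gene's value is the overlap-length-weighted mean of the segments it
    intersects; a gene with no overlapping segment is missing (NaN).
    """
    genes = genome.genes
    if len(genes) == 0:
        raise InvalidArgumentError("genome carries no genes")
    gene_ids = genes["gene_id"].to_numpy()
    columns = {}
    by_chrom = {chrom: grp for chrom, grp in genes.groupby("chromosome", sort=False)}
    for prof in profiles:
        if prof.value_kind != LOG2:
            raise InvalidArgumentError("segments_to_genes expects log2-ratio profiles")
        col = pd.Series(np.nan, index=gene_ids)
        for chrom, seg in prof.segments.groupby("chromosome", sort=False):
            if chrom not in by_chrom:
                continue
            g = by_chrom[chrom]
            s_start = seg["start"].to_numpy()[None, :]
            s_end = seg["end"].to_numpy()[None, :]
            s_val = seg["value"].to_numpy()[None, :]
            g_start = g["start"].to_numpy()[:, None]
            g_end = g["end"].to_numpy()[:, None]
            overlap = np.minimum(g_end, s_end) - np.maximum(g_start, s_start) + 1
            overlap = np.clip(overlap, 0, None).astype(float)
            weight = overlap.sum(axis=1)
            with np.errstate(invalid="ignore"):
                mean = (overlap * s_val).sum(axis=1) / weight
            col.loc[g["gene_id"].to_numpy()[weight > 0]] = mean[weight > 0]
        columns[prof.sample_id] = col
    return GeneMatrix(pd.DataFrame(columns), kind="log2")


def discretize_gistic(matrix: GeneMatrix, shallow_thresh: float = 0.2,
                      deep_thresh: float = 1.0) -> GeneMatrix:
    """Discretize log2 values into 5-valued GISTIC-like scores.

    ``+2`` high-level amplification (v >= deep), ``+1`` gain
    (shallow <= v < deep), ``-2`` deep deletion (v <= -deep), ``-1`` shallow
    loss (-deep < v <= -shallow), ``0`` otherwise. Thresholds inclusive;
    missing stays missing.
    """
    if not (0 < shallow_thresh < deep_thresh):
        raise InvalidArgumentError("need 0 < shallow_thresh < deep_thresh")
    v = matrix.values.to_numpy(dtype=float)
    out = np.zeros_like(v)
    out[v >= shallow_thresh] = 1
    out[v >= deep_thresh] = 2
    out[v <= -shallow_thresh] = -1
    out[v <= -deep_thresh] = -2
    out[np.isnan(v)] = np.nan
    return GeneMatrix(pd.DataFrame(out, index=matrix.values.index,
                                   columns=matrix.values.columns), kind="gistic5")


def filter_mutations(
    records: pd.DataFrame,
    min_depth: int = 15,
    min_vaf: float = 0.15,
    excluded_classes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CLASSES,
) -> tuple[pd.DataFrame, Counter]:
    """Apply the somatic confidence filter and variant-class exclusions.

    A record survives iff depth >= ``min_depth`` and allele fraction >=
    ``min_vaf`` (both inclusive) and its class is not excluded. Returns the
    surviving records (order preserved) and a per-criterion audit counter of
    removals; a record failing several criteria is counted under each.
    """
    validate_mutations(records)
    audit: Counter = Counter()
    if len(records) == 0:
        return records.copy(), audit
    low_depth = records["depth"] < min_depth
    low_vaf = records["vaf"] < min_vaf
    excluded = records["variant_class"].isin(excluded_classes)
    audit["low_depth"] = int(low_depth.sum())
    audit["low_vaf"] = int(low_vaf.sum())
    audit["excluded_class"] = int(excluded.sum())
    keep = ~(low_depth | low_vaf | excluded)
    audit["kept"] = int(keep.sum())
    audit["removed"] = int((~keep).sum())
    logger.info("mutation filter: kept %d / %d records", audit["kept"], len(records))
    return records[keep].copy(), audit


def restrict_to_panel(data, gene_list: Sequence[str]):
    """Restrict a mutation table or :class:`GeneMatrix` to a gene panel.

    Returns ``(restricted, intersection_size)``.
    """
    panel = set(gene_list)
    if not panel:
        raise InvalidArgumentError("empty gene panel")
    if isinstance(data, GeneMatrix):
        keep = [g for g in data.values.index if g in panel]
        return GeneMatrix(data.values.loc[keep], kind=data.kind), len(keep)
    keep_mask = data["gene"].isin(panel)
    inter = data.loc[keep_mask, "gene"].nunique()
    return data[keep_mask].copy(), int(inter)
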