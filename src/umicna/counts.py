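"""UMI extraction and per-region unique-UMI depth matrices.

The per-region signal is the number of distinct UMI sequences among
passing reads overlapping the region by at least one aligned base; the
per-sample total U is the number of distinct UMIs genome-wide. Matrices
are normalized by U so samples of different library size are comparable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import Panel

#: UMI length of the targeted chemistry modelled here (12 random nt,
#: i.e. a barcode space of 4**12 possible sequences per adapter).
UMI_LENGTH = 12


def umi_space_size(length: int = UMI_LENGTH) -> int:
    """Number of distinct UMI sequences of the given length (4**length)."""
    if length < 1:
        raise ValueError("UMI length must be >= 1")
    return 4 ** length


@dataclass(frozen=True)
class UmiSource:
    """Where to find the UMI of a read.

    policy "name": the UMI is the last delimiter-separated field of the
    read name (the umi_tools extract convention). policy "tag": the UMI
    is in an alignment tag (default RX). strict=False skips reads with
    no recoverable UMI and counts them instead of raising.
    """

    policy: str = "name"
    delimiter: str = "_"
    tag: str = "RX"
    strict: bool = True

    def __post_init__(self):
        if self.policy not in ("name", "tag"):
            raise ValueError(f"unknown UMI source policy {self.policy!r}")


def extract_umi_from_name(read_name: str, delimiter: str = "_") -> str:
    """Return the UMI appended to a read name as its last delimited field."""
    if delimiter not in read_name:
        raise ValueError(f"read {read_name!r}: no UMI delimiter {delimiter!r} in name")
    return read_name.rsplit(delimiter, 1)[1]


def extract_umi(read, source: UmiSource = UmiSource()) -> str:
    """Extract the UMI of a pysam AlignedSegment under the given policy."""
    if source.policy == "name":
        return extract_umi_from_name(read.query_name, source.delimiter)
    if not read.has_tag(source.tag):
        raise ValueError(f"read {read.query_name!r}: no {source.tag} tag")
    return str(read.get_tag(source.tag))


@dataclass
class SampleCounts:
    """One sample's per-region unique-UMI counts (one matrix column)."""

    panel: Panel
    sample_id: str
    umi_counts: np.ndarray          # (P,) int, distinct UMIs overlapping each region
    total_umis: int                 # U: distinct UMIs genome-wide
    read_counts: np.ndarray | None = None  # (P,) passing non-duplicate reads
    n_skipped: int = 0              # reads without recoverable UMI (lenient mode)

    def __post_init__(self):
        self.umi_counts = np.asarray(self.umi_counts, dtype=np.int64)
        if self.umi_counts.shape != (self.panel.n_regions,):
            raise ValueError("umi_counts length does not match panel")
        if np.any(self.umi_counts < 0):
            raise ValueError("negative UMI count")

    @property
    def fractions(self) -> np.ndarray:
        """Normalized counts C_p/U."""
        if self.total_umis <= 0:
            raise ValueError(f"sample {self.sample_id}: total UMI count is not positive")
        return self.umi_counts / float(self.total_umis)


def count_umis(
    bam_path: str | Path,
    panel: Panel,
    min_mapq: int = 20,
    umi_source: UmiSource = UmiSource(),
    sample_id: str | None = None,
) -> SampleCounts:
    """Count distinct UMIs per targeted region and genome-wide for one BAM.

    A read passes if it is primary (not secondary/supplementary), mapped,
    not QC-fail and has MAPQ >= min_mapq. Duplicate-flagged reads take part
    in the UMI union (UMI dedup supersedes positional dedup) but are left
    out of the plain read count. A read overlaps a region when its aligned
    reference span intersects [start, end) by >= 1 base; a UMI seen on both
    mates or on several reads in one region counts once there. U is the
    number of distinct UMIs over all passing reads in the file.
    """
    import pysam

    bam_path = Path(bam_path)
    if sample_id is None:
        sample_id = bam_path.name.removesuffix(".bam")
    P = panel.n_regions

    # per-chrom sorted region arrays for overlap lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in panel.regions}:
        regs = [r for r in panel.regions if r.chrom == chrom]
        starts = np.array([r.start for r in regs])
        ends = np.array([r.end for r in regs])
        idx = np.array([r.index for r in regs])
        by_chrom[chrom] = (starts, ends, idx)

    umi_sets: list[set[str]] = [set() for _ in range(P)]
    read_counts = np.zeros(P, dtype=np.int64)
    global_umis: set[str] = set()
    n_skipped = 0

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(f"{bam_path}: BAM index (.bai) is required")
        header_refs = set(bam.references)
        for chrom in by_chrom:
            if chrom not in header_refs:
                warnings.warn(
                    f"{bam_path}: panel chromosome {chrom!r} absent from BAM header; "
                    "its regions get count 0"
                )
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_qcfail
                or read.mapping_quality < min_mapq
            ):
                continue
            try:
                umi = extract_umi(read, umi_source)
            except ValueError:
                if umi_source.strict:
                    raise
                n_skipped += 1
                continue
            global_umis.add(umi)
            chrom = read.reference_name
            if chrom not in by_chrom:
                continue
            starts, ends, idx = by_chrom[chrom]
            rs, re_ = read.reference_start, read.reference_end
            if re_ is None:
                continue
            hit = (starts < re_) & (ends > rs)
            for p in idx[hit]:
                umi_sets[p].add(umi)
                if not read.is_duplicate:
                    read_counts[p] += 1

    umi_counts = np.array([len(s) for s in umi_sets], dtype=np.int64)
    return SampleCounts(
        panel=panel,
        sample_id=sample_id,
        umi_counts=umi_counts,
        total_umis=len(global_umis),
        read_counts=read_counts,
        n_skipped=n_skipped,
    )


@dataclass
class UmiCountMatrix:
    """Raw per-region unique-UMI counts for S samples plus totals U."""

    panel: Panel
    sample_ids: list[str]
    counts: np.ndarray   # (P, S) int
    totals: np.ndarray   # (S,) int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        P, S = self.counts.shape
        if P != self.panel.n_regions or S != len(self.sample_ids) or S != len(self.totals):
            raise ValueError("matrix dimensions inconsistent with panel/samples")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> SampleCounts:
        s = self.sample_ids.index(sample_id)
        return SampleCounts(self.panel, sample_id, self.counts[:, s], int(self.totals[s]))


@dataclass
class NormalizedCounts:
    """Normalized view counts/U; raw counts retained alongside."""

    panel: Panel
    sample_ids: list[str]
    fractions: np.ndarray  # (P, S) float
    counts: np.ndarray     # raw counts retained
    totals: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def assemble_matrix(columns: Sequence[SampleCounts]) -> UmiCountMatrix:
    """Stack one-sample count columns that share a panel into a matrix."""
    if len(columns) == 0:
        raise ValueError("no count columns supplied")
    panel = columns[0].panel
    for c in columns[1:]:
        if c.panel.content_hash() != panel.content_hash():
            raise ValueError(
                f"sample {c.sample_id}: panel does not match sample {columns[0].sample_id}"
            )
    counts = np.stack([c.umi_counts for c in columns], axis=1)
    totals = np.array([c.total_umis for c in columns], dtype=np.int64)
    return UmiCountMatrix(panel, [c.sample_id for c in columns], counts, totals)


def normalize(matrix: UmiCountMatrix) -> NormalizedCounts:
    """Divide each sample column by its total distinct-UMI count U.

    Applying normalize to an already-normalized matrix is refused: the
    fractions are not counts and renormalizing them is meaningless.
    """
    if isinstance(matrix, NormalizedCounts):
        raise TypeError("matrix is already normalized; normalize() must not be applied twice")
    for s, total in enumerate(matrix.totals):
        if total <= 0:
            raise ValueError(f"sample {matrix.sample_ids[s]}: total UMI count is not positive")
    fractions = matrix.counts / matrix.totals.astype(float)[None, :]
    return NormalizedCounts(
        matrix.panel, list(matrix.sample_ids), fractions, matrix.counts.copy(), matrix.totals.copy()
    )


# ---------------------------------------------------------------------------
# TSV round-trip (the on-disk stage interface between `count` and the rest)

def write_counts_tsv(sample: SampleCounts, path: str | Path) -> None:
    path = Path(path)
    regs = sample.panel.regions
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regs],
            "start": [r.start for r in regs],
            "end": [r.end for r in regs],
            "gene": [r.gene for r in regs],
            "umi_count": sample.umi_counts,
        }
    )
    if sample.read_counts is not None:
        df["read_count"] = sample.read_counts
    with open(path, "w") as fh:
        fh.write(f"# sample_id={sample.sample_id}\n")
        fh.write(f"# total_umis={sample.total_umis}\n")
        fh.write(f"# panel_sha256={sample.panel.content_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | Path, panel: Panel | None = None) -> SampleCounts:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    file_panel = Panel(zip(df["chrom"], df["start"], df["end"], df["gene"]))
    if panel is not None and panel.content_hash() != file_panel.content_hash():
        raise ValueError(f"{path}: panel does not match the expected panel")
    # rows follow panel order after Panel() sorting; re-align explicitly
    order = df.sort_values(["chrom", "start", "end"]).index
    key = {(r.chrom, r.start, r.end): r.index for r in file_panel.regions}
    umi = np.zeros(file_panel.n_regions, dtype=np.int64)
    reads = np.zeros(file_panel.n_regions, dtype=np.int64) if "read_count" in df else None
    for _, row in df.iterrows():
        p = key[(row["chrom"], int(row["start"]), int(row["end"]))]
        umi[p] = int(row["umi_count"])
        if reads is not None:
            reads[p] = int(row["read_count"])
    if "total_umis" not in meta:
        raise ValueError(f"{path}: missing '# total_umis=' header")
    return SampleCounts(
        panel=panel or file_panel,
        sample_id=meta.get("sample_id", path.stem),
        umi_counts=umi,
        total_umis=int(meta["total_umis"]),
        read_counts=reads,
    )
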