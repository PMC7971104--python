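"""Targeted-panel model: regions, per-gene blocks, and BED parsing.

A panel is an ordered list of targeted regions (BED 0-based half-open
coordinates) grouped into contiguous gene blocks. All downstream stages
(counting, reference building, segmentation) address regions by their
dense panel index 0..P-1.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Region:
    """One targeted region. start/end are 0-based half-open (BED)."""

    chrom: str
    start: int
    end: int
    gene: str
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneBlock:
    """A maximal run of consecutive regions sharing one gene symbol.

    ``label`` equals the gene symbol, suffixed ``#k`` when the same symbol
    occurs in several non-adjacent coordinate runs.
    """

    gene: str
    label: str
    start: int  # first region index (inclusive)
    stop: int   # one past last region index

    @property
    def n_regions(self) -> int:
        return self.stop - self.start

    @property
    def indices(self) -> range:
        return range(self.start, self.stop)


def _chrom_key(chrom: str) -> tuple:
    """Natural-order key so chr2 sorts before chr10."""
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", chrom))


class Panel:
    """Ordered targeted regions with contiguous gene blocks."""

    def __init__(self, regions: Iterable[tuple[str, int, int, str]]):
        rows = sorted(regions, key=lambda r: (_chrom_key(r[0]), r[1], r[2]))
        if not rows:
            raise ValueError("panel has no regions")
        self.regions: list[Region] = []
        for i, (chrom, start, end, gene) in enumerate(rows):
            if start >= end:
                raise ValueError(f"region {chrom}:{start}-{end} has start >= end")
            self.regions.append(Region(chrom, int(start), int(end), gene, i))
        self.blocks: list[GeneBlock] = self._build_blocks()

    def _build_blocks(self) -> list[GeneBlock]:
        runs: list[tuple[str, int, int]] = []
        prev_gene = None
        for r in self.regions:
            if prev_gene is not None and r.gene == prev_gene:
                runs[-1] = (runs[-1][0], runs[-1][1], r.index + 1)
            else:
                runs.append((r.gene, r.index, r.index + 1))
            prev_gene = r.gene
        counts: dict[str, int] = {}
        for gene, _, _ in runs:
            counts[gene] = counts.get(gene, 0) + 1
        seen: dict[str, int] = {}
        blocks = []
        for gene, start, stop in runs:
            if counts[gene] > 1:
                seen[gene] = seen.get(gene, 0) + 1
                label = f"{gene}#{seen[gene]}"
            else:
                label = gene
            blocks.append(GeneBlock(gene, label, start, stop))
        return blocks

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def gene_labels(self) -> list[str]:
        return [b.label for b in self.blocks]

    def content_hash(self) -> str:
        """sha256 of the canonical region list; identifies the panel."""
        h = hashlib.sha256()
        for r in self.regions:
            h.update(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n".encode())
        return h.hexdigest()

    def __eq__(self, other) -> bool:
        return isinstance(other, Panel) and self.content_hash() == other.content_hash()

    def __len__(self) -> int:
        return self.n_regions

    def __repr__(self) -> str:
        return f"Panel(P={self.n_regions}, genes={len(self.blocks)})"

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")

    @staticmethod
    def from_frame(df) -> "Panel":
        return Panel(zip(df["chrom"], df["start"], df["end"], df["gene"]))


def read_panel(bed_path: str | Path) -> Panel:
    """Parse a 4+ column BED file (chrom, start, end, gene) into a Panel.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Raises ValueError naming the offending line on malformed input.
    """
    bed_path = Path(bed_path)
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{bed_path}:{lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, end_s, gene = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{bed_path}:{lineno}: start >= end ({start} >= {end})")
            rows.append((chrom, start, end, gene))
    if not rows:
        raise ValueError(f"{bed_path}: empty BED file")
    return Panel(rows)
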