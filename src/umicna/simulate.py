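"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates a targeted amplicon panel: regions grouped into
genes, each with a log-normal capture efficiency; per-region unique-UMI
counts are negative-binomially distributed around the sample's library
size times the region's efficiency share. Tumor samples mix a spiked
integer copy-number profile with normal signal at a programmable tumor
fraction c, so the expected log-ratio at an altered region is
log2(c*CN/2 + (1-c)). Tiny BAM fixtures with UMIs in read-name suffixes
exercise the counting stage end to end.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import Panel
from .counts import SampleCounts, UmiCountMatrix, assemble_matrix, normalize, UMI_LENGTH

# Desk-scale default panel: 20 genes x 15 regions. Real targeted panels
# of this design run to ~70 genes and ~1500 primers; the default keeps
# the recommended >= 6 regions per gene while staying fast to simulate.
DEFAULT_GENES = 20
DEFAULT_REGIONS_PER_GENE = 15
DEFAULT_MEAN_DEPTH = 2000.0
DEFAULT_DISPERSION = 50.0
DEFAULT_EFFICIENCY_SIGMA = 0.5


def expected_log_ratio(copy_number: float, tumor_fraction: float) -> float:
    """Forward mixture model: log2(c*CN/2 + (1-c)).

    A pure single-copy gain gives log2(3/2) ~ 0.58; a pure single-copy
    loss gives log2(1/2) = -1.
    """
    c = tumor_fraction
    val = c * copy_number / 2.0 + (1.0 - c)
    if val <= 0:
        raise ValueError("copy ratio is not positive (homozygous deletion at c=1)")
    return float(np.log2(val))


@dataclass(frozen=True)
class CnvEvent:
    """One spiked event: a gene set to an integer copy number.

    ``region_span`` optionally restricts the event to a (start, stop)
    slice of the gene's regions (sub-gene event).
    """

    gene: str
    copy_number: int
    region_span: tuple[int, int] | None = None


@dataclass
class SimPanel:
    """A synthetic panel plus per-region capture efficiencies."""

    panel: Panel
    efficiencies: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.panel.n_regions

    @classmethod
    def build(
        cls,
        n_genes: int = DEFAULT_GENES,
        regions_per_gene: int | Sequence[int] = DEFAULT_REGIONS_PER_GENE,
        efficiency_sigma: float = DEFAULT_EFFICIENCY_SIGMA,
        region_length: int = 120,
        gap: int = 80,
        seed: int = 0,
    ) -> "SimPanel":
        rng = np.random.default_rng(seed)
        if isinstance(regions_per_gene, int):
            per_gene = [regions_per_gene] * n_genes
        else:
            per_gene = list(regions_per_gene)
            if len(per_gene) != n_genes:
                raise ValueError("regions_per_gene sequence length must equal n_genes")
        rows = []
        pos = 1000
        for g in range(n_genes):
            gene = f"G{g + 1:02d}"
            for _ in range(per_gene[g]):
                rows.append(("chrS", pos, pos + region_length, gene))
                pos += region_length + gap
            pos += 5 * gap  # intergenic spacing
        panel = Panel(rows)
        eff = rng.lognormal(mean=0.0, sigma=efficiency_sigma, size=panel.n_regions)
        return cls(panel=panel, efficiencies=eff)


@dataclass
class SimTruth:
    """Ground truth of one simulated tumor sample."""

    events: tuple[CnvEvent, ...]
    tumor_fraction: float

    def __post_init__(self):
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor fraction must be in [0, 1]")

    def copy_numbers(self, panel: Panel) -> np.ndarray:
        cn = np.full(panel.n_regions, 2.0)
        by_label = {b.label: b for b in panel.blocks}
        by_gene = {}
        for b in panel.blocks:
            by_gene.setdefault(b.gene, []).append(b)
        for ev in self.events:
            blocks = [by_label[ev.gene]] if ev.gene in by_label else by_gene.get(ev.gene)
            if not blocks:
                raise ValueError(f"event gene {ev.gene!r} not in panel")
            for b in blocks:
                idx = np.array(list(b.indices))
                if ev.region_span is not None:
                    idx = idx[ev.region_span[0]: ev.region_span[1]]
                cn[idx] = ev.copy_number
        return cn

    def copy_ratios(self, panel: Panel) -> np.ndarray:
        """Per-region expected copy ratio c*CN/2 + (1-c)."""
        c = self.tumor_fraction
        return c * self.copy_numbers(panel) / 2.0 + (1.0 - c)

    def expected_log_ratios(self, panel: Panel) -> np.ndarray:
        return np.log2(self.copy_ratios(panel))


def _nb_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float | None) -> np.ndarray:
    """Negative-binomial draws with the given means and size parameter.

    dispersion is the NB size r (variance = mu + mu^2/r); None or inf
    gives the Poisson limit.
    """
    means = np.asarray(means, dtype=float)
    if dispersion is None or np.isinf(dispersion):
        return rng.poisson(means)
    if dispersion <= 0:
        raise ValueError("dispersion (NB size) must be positive")
    p = dispersion / (dispersion + means)
    return rng.negative_binomial(dispersion, p)


def _draw_total(rng: np.random.Generator, mean_depth: float, P: int) -> float:
    # library sizes vary ~20% between preparations
    return float(rng.lognormal(np.log(mean_depth * P), 0.2))


def simulate_controls(
    sim_panel: SimPanel,
    n_samples: int = 5,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    dispersion: float | None = DEFAULT_DISPERSION,
    seed: int | None = None,
    sample_prefix: str = "CTL",
) -> UmiCountMatrix:
    """Simulate a control cohort of per-region UMI counts."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    P = sim_panel.n_regions
    share = sim_panel.efficiencies / sim_panel.efficiencies.sum()
    cols = []
    for s in range(n_samples):
        target = _draw_total(rng, mean_depth, P)
        counts = _nb_counts(rng, target * share, dispersion)
        cols.append(
            SampleCounts(
                panel=sim_panel.panel,
                sample_id=f"{sample_prefix}{s + 1:02d}",
                umi_counts=counts,
                total_umis=int(counts.sum()),
            )
        )
    return assemble_matrix(cols)


def simulate_tumor(
    sim_panel: SimPanel,
    truth: SimTruth,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    dispersion: float | None = DEFAULT_DISPERSION,
    seed: int | None = None,
    sample_id: str = "TUMOR",
) -> SampleCounts:
    """Simulate one tumor sample carrying the truth's spiked events.

    Expected counts are proportional to efficiency * copy ratio and are
    renormalized to the target library size, as sequencing a fixed
    number of molecules would do — so the raw log-ratios carry a global
    shift that the centering stage must remove.
    """
    rng = np.random.default_rng(seed)
    ratio = truth.copy_ratios(sim_panel.panel)
    weight = sim_panel.efficiencies * ratio
    share = weight / weight.sum()
    target = _draw_total(rng, mean_depth, sim_panel.n_regions)
    counts = _nb_counts(rng, target * share, dispersion)
    return SampleCounts(
        panel=sim_panel.panel,
        sample_id=sample_id,
        umi_counts=counts,
        total_umis=int(counts.sum()),
    )


# ---------------------------------------------------------------------------
# BAM fixtures

_BASES = np.array(list("ACGT"))


def _int_to_umi(values: np.ndarray, length: int = UMI_LENGTH) -> list[str]:
    out = []
    for v in values:
        chars = []
        for _ in range(length):
            chars.append("ACGT"[v & 3])
            v >>= 2
        out.append("".join(chars))
    return out


def simulate_bam_fixture(
    panel: Panel,
    counts: np.ndarray,
    out_prefix: str | Path,
    read_len: int = 100,
    seed: int | None = None,
    max_dups: int = 3,
) -> dict[str, Path]:
    """Write a tiny sorted+indexed BAM whose per-region distinct-UMI
    counts equal ``counts`` exactly.

    Each region p gets counts[p] globally distinct 12-mer UMIs appended
    to read names; each UMI is emitted as 1..max_dups reads, and all
    copies beyond the first are flagged as PCR duplicates. Reads lie
    fully inside their region, so the overlap assignment is unambiguous.
    Returns paths to the BAM, BAI, BED and toy reference FASTA.
    """
    import pysam

    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (panel.n_regions,):
        raise ValueError("counts length must equal panel size")
    total = int(counts.sum())
    if total > 10_000:
        raise ValueError("BAM fixtures are for tiny scale (<= 10000 UMIs)")

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    chroms: dict[str, int] = {}
    for r in panel.regions:
        chroms[r.chrom] = max(chroms.get(r.chrom, 0), r.end + 200)

    fasta_path = out_prefix.with_suffix(".fa")
    with open(fasta_path, "w") as fh:
        for chrom, length in chroms.items():
            seq = "".join(rng.choice(_BASES, size=length))
            fh.write(f">{chrom}\n")
            for i in range(0, length, 60):
                fh.write(seq[i:i + 60] + "\n")

    # globally distinct UMIs: rejection-sample integers in the 4^12 space
    pool: np.ndarray = np.unique(rng.integers(0, 4 ** UMI_LENGTH, size=2 * total + 16))
    while pool.size < total:
        extra = rng.integers(0, 4 ** UMI_LENGTH, size=total)
        pool = np.unique(np.concatenate([pool, extra]))
    umi_ints = rng.permuted(pool)[:total]
    umis = _int_to_umi(umi_ints)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": length} for c, length in chroms.items()],
    }
    tids = {c: i for i, c in enumerate(chroms)}
    unsorted_path = out_prefix.with_suffix(".unsorted.bam")
    bam_path = out_prefix.with_suffix(".bam")
    serial = 0
    k = 0
    with pysam.AlignmentFile(str(unsorted_path), "wb", header=header) as bam:
        for region in panel.regions:
            rl = min(read_len, region.length)
            for _ in range(int(counts[region.index])):
                umi = umis[k]
                k += 1
                n_copies = int(rng.integers(1, max_dups + 1))
                pos = int(rng.integers(region.start, region.end - rl + 1))
                for copy in range(n_copies):
                    a = pysam.AlignedSegment()
                    a.query_name = f"SIM{serial:06d}_{umi}"
                    serial += 1
                    a.query_sequence = "A" * rl
                    a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    a.reference_id = tids[region.chrom]
                    a.reference_start = pos
                    a.mapping_quality = 60
                    a.cigarstring = f"{rl}M"
                    a.flag = 0x400 if copy > 0 else 0
                    bam.write(a)
    pysam.sort("-o", str(bam_path), str(unsorted_path))
    unsorted_path.unlink()
    pysam.index(str(bam_path))

    bed_path = out_prefix.with_suffix(".bed")
    panel.to_bed(bed_path)
    return {
        "bam": bam_path,
        "bai": Path(str(bam_path) + ".bai"),
        "bed": bed_path,
        "fasta": fasta_path,
    }


# ---------------------------------------------------------------------------
# dilution experiment

DEFAULT_FRACTIONS = (1.0, 0.5, 0.2, 0.1, 0.05)


def default_events(sim_panel: SimPanel) -> tuple[CnvEvent, ...]:
    """The four canonical spiked events on well-separated genes:
    high-level amplification (CN=4), single-copy gain (CN=3),
    heterozygous deletion (CN=1) and homozygous deletion (CN=0)."""
    labels = sim_panel.panel.gene_labels
    if len(labels) < 4:
        raise ValueError("need >= 4 genes for the default event set")
    picks = np.linspace(0, len(labels) - 1, 6).astype(int)[1:5]
    cns = (4, 3, 1, 0)
    return tuple(CnvEvent(labels[g], cn) for g, cn in zip(picks, cns))


def dilution_experiment(
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    events: Sequence[CnvEvent] | None = None,
    n_reps: int = 10,
    seed: int = 0,
    sim_panel: SimPanel | None = None,
    n_controls: int = 5,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    dispersion: float | None = DEFAULT_DISPERSION,
    alpha: float = 0.05,
    seg_params=None,
    centering_seed: int = 17,
) -> pd.DataFrame:
    """Run the full pipeline over an in-silico dilution series.

    One control cohort and pseudo-reference are built per experiment;
    each (fraction, replicate) simulates a fresh tumor sample and runs
    log-ratios -> centering -> segmentation -> calling -> purity. The
    returned frame has one row per (fraction, replicate, event) with the
    detection status, plus the purity estimates of the run.
    """
    from .logratio import log_ratios, center_profile
    from .segmentation import SegParams, segment_sample
    from .reference import build_pseudo_reference
    from .calling import test_segments, estimate_purity, GAIN, LOSS

    master = np.random.default_rng(seed)
    panel_seed = int(master.integers(2**31))
    control_seed = int(master.integers(2**31))
    if sim_panel is None:
        sim_panel = SimPanel.build(seed=panel_seed)
    if events is None:
        events = default_events(sim_panel)
    if seg_params is None:
        seg_params = SegParams(seed=int(master.integers(2**31)))

    controls = simulate_controls(
        sim_panel, n_samples=n_controls, mean_depth=mean_depth,
        dispersion=dispersion, seed=control_seed,
    )
    reference = build_pseudo_reference(normalize(controls))

    block_of = {b.label: set(b.indices) for b in sim_panel.panel.blocks}
    rows = []
    for fraction in fractions:
        for rep in range(n_reps):
            tumor_seed = int(master.integers(2**31))
            truth = SimTruth(tuple(events), fraction)
            tumor = simulate_tumor(
                sim_panel, truth, mean_depth=mean_depth, dispersion=dispersion,
                seed=tumor_seed, sample_id=f"T_f{fraction:g}_r{rep}",
            )
            profile = center_profile(log_ratios(tumor, reference), seed=centering_seed)
            segments = segment_sample(profile, reference, seg_params)
            calls = test_segments(segments, alpha=alpha)
            purity = estimate_purity(calls)
            for ev in events:
                want = GAIN if ev.copy_number > 2 else LOSS
                gene_idx = block_of[ev.gene]
                detected = any(
                    c.status == want and gene_idx.issuperset(c.segment.region_indices)
                    and set(c.segment.region_indices) & gene_idx
                    for c in calls
                )
                rows.append(
                    {
                        "fraction": fraction,
                        "rep": rep,
                        "gene": ev.gene,
                        "copy_number": ev.copy_number,
                        "detected": detected,
                        "c_gain": purity.c_gain,
                        "c_del": purity.c_del,
                        "c_mean": purity.c_mean,
                    }
                )
    return pd.DataFrame(rows)


def detection_limit(results: pd.DataFrame, min_reps_frac: float = 0.9) -> float | None:
    """Smallest fraction at which every event is detected in at least
    ``min_reps_frac`` of replicates; None if no fraction qualifies."""
    ok_fractions = []
    for fraction, sub in results.groupby("fraction"):
        per_event = sub.groupby("gene")["detected"].mean()
        if (per_event >= min_reps_frac).all():
            ok_fractions.append(float(fraction))
    return min(ok_fractions) if ok_fractions else None
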