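"""End-user workflows: build-ref and call, with config and provenance.

Stages communicate only through documented on-disk formats (count TSVs,
the reference bundle directory, the segments CSV), so each stage can be
run standalone. Every output directory gets a meta.json with the full
configuration, seed, input hashes and package version.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .panel import Panel, read_panel
from .counts import (
    SampleCounts,
    UmiSource,
    assemble_matrix,
    normalize,
    count_umis,
    read_counts_tsv,
    write_counts_tsv,
)
from .reference import PseudoReference, build_pseudo_reference
from .logratio import log_ratios, center_profile, LogRatioProfile
from .segmentation import SegParams, segment_sample
from .calling import (
    SegmentCall,
    PurityEstimate,
    test_segments,
    estimate_purity,
    write_report,
)

logger = logging.getLogger("umicna")


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Precedence when building from sources: CLI overrides > config file >
    defaults. Unknown keys are rejected.
    """

    min_mapq: int = 20
    umi_from: str = "name"        # "name" or "tag"
    umi_delimiter: str = "_"
    umi_tag: str = "RX"
    umi_strict: bool = True
    sample_frac: float = 0.20
    region_frac: float = 0.50
    centering: bool = True
    alpha: float = 0.05
    seg_alpha: float = 0.01
    seg_n_perm: int = 10_000
    seg_min_width: int = 2
    seg_undo_sd: float = 1.0
    seed: int = 17

    @classmethod
    def from_sources(cls, config_file: str | Path | None = None, **overrides) -> "RunConfig":
        import tomllib

        values: dict = {}
        known = {f.name for f in fields(cls)}
        if config_file is not None:
            with open(config_file, "rb") as fh:
                data = tomllib.load(fh)
            flat = {}
            for key, val in data.items():
                if isinstance(val, dict):  # allow [seg] tables -> seg_* keys
                    for k2, v2 in val.items():
                        flat[f"{key}_{k2}"] = v2
                else:
                    flat[key] = val
            for key, val in flat.items():
                if key not in known:
                    raise ValueError(f"unknown config key {key!r} in {config_file}")
                values[key] = val
        for key, val in overrides.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            if val is not None:
                values[key] = val
        return cls(**values)

    def umi_source(self) -> UmiSource:
        return UmiSource(
            policy=self.umi_from,
            delimiter=self.umi_delimiter,
            tag=self.umi_tag,
            strict=self.umi_strict,
        )

    def seg_params(self) -> SegParams:
        return SegParams(
            alpha=self.seg_alpha,
            n_perm=self.seg_n_perm,
            min_width=self.seg_min_width,
            undo_sd=self.seg_undo_sd,
            seed=self.seed,
        )


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_meta(out_dir: Path, config: RunConfig, inputs: dict[str, Path], extra: dict) -> None:
    from . import __version__

    meta = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {name: {"path": str(p), "sha256": _sha256_file(p)} for name, p in inputs.items()},
    }
    meta.update(extra)
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_counts(
    path: str | Path, panel: Panel | None, config: RunConfig
) -> SampleCounts:
    """Load a sample either from a count TSV or by counting a BAM."""
    path = Path(path)
    if path.suffix == ".bam":
        if panel is None:
            raise ValueError(f"{path}: counting a BAM requires a panel BED")
        return count_umis(path, panel, min_mapq=config.min_mapq, umi_source=config.umi_source())
    return read_counts_tsv(path, panel=panel)


def run_build_ref(
    control_paths: Sequence[str | Path],
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
    bed_path: str | Path | None = None,
) -> PseudoReference:
    """counts -> normalize -> geometric reference -> filters -> weights -> bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(control_paths) < 2:
        raise ValueError(f"need >= 2 control samples, got {len(control_paths)}")
    panel = read_panel(bed_path) if bed_path is not None else None
    try:
        columns = [load_counts(p, panel, config) for p in control_paths]
        matrix = assemble_matrix(columns)
        norm = normalize(matrix)
        ref = build_pseudo_reference(
            norm, sample_frac=config.sample_frac, region_frac=config.region_frac
        )
    except Exception as exc:
        raise type(exc)(f"build-ref: {exc}") from exc
    for sid, reason in ref.excluded_samples.items():
        logger.info("excluded control %s: %s", sid, reason)
    logger.info(
        "reference built from %d/%d controls; %d regions excluded",
        len(ref.retained_samples), matrix.n_samples, len(ref.excluded_regions),
    )
    ref.save(out_dir)
    inputs = {f"control_{i}": Path(p) for i, p in enumerate(control_paths)}
    if bed_path is not None:
        inputs["bed"] = Path(bed_path)
    _write_meta(
        out_dir, config, inputs,
        {
            "stage": "build-ref",
            "panel_sha256": ref.panel.content_hash(),
            "excluded_samples": ref.excluded_samples,
            "n_excluded_regions": len(ref.excluded_regions),
        },
    )
    return ref


@dataclass
class CallResult:
    profile: LogRatioProfile
    calls: list[SegmentCall]
    purity: PurityEstimate
    paths: dict[str, Path]


def run_call(
    tumor_path: str | Path,
    ref_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
    bed_path: str | Path | None = None,
    plot: bool = True,
) -> CallResult:
    """Full tumor workflow: log-ratios -> centering -> CBS -> tests -> report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = PseudoReference.load(ref_dir)
    panel = read_panel(bed_path) if bed_path is not None else ref.panel
    tumor = load_counts(tumor_path, panel, config)
    if tumor.panel.content_hash() != ref.panel.content_hash():
        raise ValueError(
            f"call: sample {tumor.sample_id} panel does not match the reference bundle"
        )

    profile = center_profile(
        log_ratios(tumor, ref), enabled=config.centering, seed=config.seed
    )
    segments = segment_sample(profile, ref, config.seg_params())
    calls = test_segments(segments, alpha=config.alpha)
    purity = estimate_purity(calls)

    paths = write_report(
        calls, purity, out_dir, tumor.sample_id,
        shift=profile.shift, profile=profile, plot=plot,
    )
    lr_path = out_dir / f"{tumor.sample_id}.logratios.tsv"
    _write_logratios(profile, ref, lr_path)
    paths["logratios"] = lr_path

    mix = profile.mixture
    _write_meta(
        out_dir, config, {"tumor": Path(tumor_path)},
        {
            "stage": "call",
            "sample_id": tumor.sample_id,
            "panel_sha256": ref.panel.content_hash(),
            "shift": profile.shift,
            "mixture": None if mix is None else {
                "k": mix.k,
                "means": [float(x) for x in mix.means],
                "sds": [float(x) for x in mix.sds],
                "props": [float(x) for x in mix.props],
                "selected": mix.selected,
                "bic": {str(k): v for k, v in mix.bic.items()},
            },
            "purity": {
                "c_gain": purity.c_gain,
                "c_del": purity.c_del,
                "c_mean": purity.c_mean,
                "flags": purity.flags,
            },
        },
    )
    return CallResult(profile=profile, calls=calls, purity=purity, paths=paths)


def _write_logratios(profile: LogRatioProfile, ref: PseudoReference, path: Path) -> None:
    import pandas as pd

    regs = profile.panel.regions
    flags = []
    for i in range(len(regs)):
        f = []
        if i in ref.excluded_regions:
            f.append(f"excluded:{ref.excluded_regions[i]}")
        if profile.zero_count_regions is not None and profile.zero_count_regions[i]:
            f.append("zero-count-pseudocounted")
        flags.append(";".join(f))
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regs],
            "start": [r.start for r in regs],
            "end": [r.end for r in regs],
            "gene": [r.gene for r in regs],
            "l_raw": profile.l_raw,
            "l_centered": profile.l,
            "flags": flags,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
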