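"""Segment-level inference: gain/loss calls, FDR control, tumor purity.

Each segment with >= 2 member regions is tested against a diploid
log-ratio of 0 with a two-sided one-sample t-test; p-values are adjusted
across the sample's segments by Benjamini-Hochberg. Tumor content c is
estimated twice — from the pooled log-ratios of gain segments via
c = 2*(2^L - 1) and of loss segments via c = -2*(2^L - 1), both derived
from the single-copy mixture model L = log2(c*CN/2 + (1-c)) — and the
two estimates are averaged.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .segmentation import Segment

GAIN, LOSS, NORMAL, UNTESTED = "gain", "loss", "normal", "untested"


@dataclass
class SegmentCall:
    segment: Segment
    t_statistic: float
    p_value: float
    q_value: float
    status: str
    flags: list[str] = field(default_factory=list)


def test_segments(segments: list[Segment], alpha: float = 0.05) -> list[SegmentCall]:
    """Test each segment's member log-ratios against 0 and adjust by BH.

    Segments with a single member are reported untested. Zero-variance
    segments use the p=0 (mean != 0) / p=1 (mean == 0) convention and
    are flagged.
    """
    tested_idx: list[int] = []
    raw_p: list[float] = []
    prelim: list[tuple[float, float, list[str]]] = []  # (t, p, flags) per segment

    for k, seg in enumerate(segments):
        flags = list(seg.flags)
        if seg.n_regions < 2:
            prelim.append((np.nan, np.nan, flags))
            continue
        vals = seg.values
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            flags.append("zero-variance")
            t = np.inf * np.sign(mean) if mean != 0 else 0.0
            p = 0.0 if mean != 0 else 1.0
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
            t, p = float(t), float(p)
        prelim.append((t, p, flags))
        tested_idx.append(k)
        raw_p.append(p)

    q = np.full(len(segments), np.nan)
    if raw_p:
        _, q_adj, _, _ = multipletests(raw_p, method="fdr_bh")
        q[tested_idx] = q_adj

    calls = []
    for k, seg in enumerate(segments):
        t, p, flags = prelim[k]
        if seg.n_regions < 2:
            status = UNTESTED
        elif q[k] < alpha:
            status = GAIN if np.mean(seg.values) > 0 else LOSS
        else:
            status = NORMAL
        calls.append(SegmentCall(seg, t, p, float(q[k]), status, flags))
    return calls


test_segments.__test__ = False  # not a pytest item despite the domain name


@dataclass
class PurityEstimate:
    """Tumor-cell fraction estimated from significant segments.

    c_gain / c_del come from the pooled member log-ratios of gain / loss
    segments under a single-copy-event model; c_mean averages whichever
    of the two is defined. Raw values beyond 1 (multi-copy events) are
    clamped and flagged.
    """

    c_gain: float | None
    c_del: float | None
    c_mean: float | None
    n_gain_segments: int
    n_loss_segments: int
    raw_c_gain: float | None = None
    raw_c_del: float | None = None
    flags: list[str] = field(default_factory=list)


def estimate_purity(calls: list[SegmentCall]) -> PurityEstimate:
    """Invert the mixture model on pooled gain and loss log-ratios."""
    gain_vals = np.concatenate(
        [c.segment.values for c in calls if c.status == GAIN] or [np.empty(0)]
    )
    loss_vals = np.concatenate(
        [c.segment.values for c in calls if c.status == LOSS] or [np.empty(0)]
    )
    flags: list[str] = []

    def _finish(raw: float | None, side: str) -> float | None:
        if raw is None:
            return None
        if raw > 1.0:
            flags.append(f"{side}-estimate-clamped")
            return 1.0
        if raw < 0.0:
            flags.append(f"{side}-estimate-clamped")
            return 0.0
        return raw

    raw_gain = 2.0 * (2.0 ** float(np.mean(gain_vals)) - 1.0) if gain_vals.size else None
    raw_del = -2.0 * (2.0 ** float(np.mean(loss_vals)) - 1.0) if loss_vals.size else None
    c_gain = _finish(raw_gain, "gain")
    c_del = _finish(raw_del, "del")
    defined = [c for c in (c_gain, c_del) if c is not None]
    c_mean = float(np.mean(defined)) if defined else None
    if c_mean is None:
        flags.append("no-significant-segments")
    return PurityEstimate(
        c_gain=c_gain,
        c_del=c_del,
        c_mean=c_mean,
        n_gain_segments=sum(c.status == GAIN for c in calls),
        n_loss_segments=sum(c.status == LOSS for c in calls),
        raw_c_gain=raw_gain,
        raw_c_del=raw_del,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# report

_CSV_COLUMNS = [
    "gene", "chrom", "start", "end", "n_regions",
    "seg_mean", "t", "p", "q", "status", "flags",
]


def calls_to_frame(calls: list[SegmentCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        s = c.segment
        rows.append(
            {
                "gene": s.gene,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_regions": s.n_regions,
                "seg_mean": s.mean,
                "t": c.t_statistic,
                "p": c.p_value,
                "q": c.q_value,
                "status": c.status,
                "flags": ";".join(c.flags),
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_report(
    calls: list[SegmentCall],
    purity: PurityEstimate,
    out_dir: str | Path,
    sample_id: str,
    shift: float = 0.0,
    profile=None,
    plot: bool = True,
) -> dict[str, Path]:
    """Write the per-segment CSV (with a '#' header block) and the profile plot."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{sample_id}.segments.csv"

    def _fmt(x) -> str:
        return "NA" if x is None else f"{x:.10g}"

    try:
        with open(csv_path, "w", newline="") as fh:
            fh.write(f"# sample_id={sample_id}\n")
            fh.write(f"# shift={shift:.10g}\n")
            fh.write(f"# c_gain={_fmt(purity.c_gain)}\n")
            fh.write(f"# c_del={_fmt(purity.c_del)}\n")
            fh.write(f"# c_mean={_fmt(purity.c_mean)}\n")
            calls_to_frame(calls).to_csv(fh, index=False, float_format="%.10g")
    except OSError as exc:
        raise OSError(f"failed to write report to {csv_path}: {exc}") from exc

    paths = {"csv": csv_path}
    if plot and profile is not None:
        from .plotting import plot_profile

        png_path = out_dir / f"{sample_id}.profile.png"
        plot_profile(profile, calls, png_path)
        paths["plot"] = png_path
    return paths


def read_report(path: str | Path) -> tuple[pd.DataFrame, dict[str, float | str | None]]:
    """Read back a segments CSV; returns (frame, header metadata)."""
    path = Path(path)
    meta: dict[str, float | str | None] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                val = val.strip()
                if val == "NA":
                    meta[key.strip()] = None
                else:
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        meta[key.strip()] = val
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, keep_default_na=False, na_values=["nan", ""])
    return df, meta
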