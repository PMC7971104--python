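"""Pseudo-reference construction from control samples.

The baseline R is the region-wise geometric mean of the controls'
normalized UMI fractions. Outlier control samples and noisy regions are
excluded by comparing per-(region, sample) deviations |x - R| against a
Tukey-fence threshold T = Q3 + 1.5*IQR of the pooled deviation
distribution. Per-region segmentation weights are the min-max scaled
inverse variances of the control fractions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Panel
from .counts import NormalizedCounts

VAR_FLOOR = 1e-12
WEIGHT_FLOOR = 0.01


def geometric_reference(fractions: np.ndarray) -> np.ndarray:
    """Region-wise geometric mean of positive control fractions.

    fractions: (P_active, S) strictly positive values.
    """
    x = np.asarray(fractions, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("fractions must be a (P, S) matrix")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(x), axis=1))


def rmsd_deviations(fractions: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Per-(region, sample) deviation from the baseline.

    With a single (value, reference) pair the root-mean-square deviation
    reduces to the absolute deviation |x - r|.
    """
    x = np.asarray(fractions, dtype=float)
    return np.abs(x - np.asarray(r, dtype=float)[:, None])


def outlier_threshold(deviations: np.ndarray) -> float:
    """Tukey upper fence T = Q3 + 1.5*IQR of the pooled deviations.

    Quartiles use linear interpolation between order statistics.
    """
    d = np.asarray(deviations, dtype=float).ravel()
    d = d[np.isfinite(d)]
    if d.size < 4:
        raise ValueError(f"need >= 4 deviation values to set a threshold, got {d.size}")
    q1, q3 = np.quantile(d, [0.25, 0.75])  # linear interpolation
    return float(q3 + 1.5 * (q3 - q1))


def segmentation_weights(fractions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance weights of retained control fractions, scaled to [0,1].

    Returns (weights, variances). Sample variance (ddof=1) per region,
    floored at VAR_FLOOR; W = 1/var min-max scaled, then floored at
    WEIGHT_FLOOR so the noisiest retained region keeps a small influence.
    Degenerate case max(W)=min(W) gives all-ones.
    """
    x = np.asarray(fractions, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 retained controls to compute weights")
    var = np.var(x, axis=1, ddof=1)
    w_raw = 1.0 / np.maximum(var, VAR_FLOOR)
    lo, hi = w_raw.min(), w_raw.max()
    if hi == lo:
        w = np.ones_like(w_raw)
    else:
        w = (w_raw - lo) / (hi - lo)
        w = np.maximum(w, WEIGHT_FLOOR)
    return w, var


@dataclass
class PseudoReference:
    """Control baseline: per-region reference, exclusions and weights.

    r and weights have length P; excluded regions carry NaN reference and
    weight 0 and are skipped downstream.
    """

    panel: Panel
    r: np.ndarray                      # (P,) baseline fractions, NaN where excluded
    weights: np.ndarray                # (P,) W' in [0,1], 0 where excluded
    control_variance: np.ndarray       # (P,) var of retained controls' fractions
    excluded_samples: dict[str, str]   # sample id -> reason
    excluded_regions: dict[int, str]   # region index -> reason
    retained_samples: list[str]
    threshold: float                   # final T used for the region filter
    sample_frac: float = 0.20
    region_frac: float = 0.50

    @property
    def retained_mask(self) -> np.ndarray:
        mask = np.ones(self.panel.n_regions, dtype=bool)
        mask[list(self.excluded_regions)] = False
        return mask

    # -- persistence ---------------------------------------------------------

    def save(self, out_dir: str | Path, extra_meta: dict | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        regs = self.panel.regions
        df = pd.DataFrame(
            {
                "chrom": [x.chrom for x in regs],
                "start": [x.start for x in regs],
                "end": [x.end for x in regs],
                "gene": [x.gene for x in regs],
                "r": self.r,
                "variance": self.control_variance,
                "weight": self.weights,
                "excluded": [i in self.excluded_regions for i in range(len(regs))],
                "reason": [self.excluded_regions.get(i, "") for i in range(len(regs))],
            }
        )
        df.to_csv(out_dir / "reference.tsv", sep="\t", index=False, float_format="%.12g")
        from . import __version__

        meta = {
            "version": __version__,
            "panel_sha256": self.panel.content_hash(),
            "threshold": self.threshold,
            "sample_frac": self.sample_frac,
            "region_frac": self.region_frac,
            "excluded_samples": self.excluded_samples,
            "retained_samples": self.retained_samples,
        }
        if extra_meta:
            meta.update(extra_meta)
        (out_dir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, ref_dir: str | Path) -> "PseudoReference":
        ref_dir = Path(ref_dir)
        df = pd.read_csv(ref_dir / "reference.tsv", sep="\t")
        meta = json.loads((ref_dir / "meta.json").read_text())
        panel = Panel(zip(df["chrom"], df["start"], df["end"], df["gene"]))
        # re-align rows to panel order
        key = {(r.chrom, r.start, r.end): r.index for r in panel.regions}
        P = panel.n_regions
        r = np.full(P, np.nan)
        w = np.zeros(P)
        var = np.full(P, np.nan)
        excluded: dict[int, str] = {}
        for _, row in df.iterrows():
            p = key[(row["chrom"], int(row["start"]), int(row["end"]))]
            r[p] = row["r"]
            w[p] = row["weight"]
            var[p] = row["variance"]
            if bool(row["excluded"]):
                excluded[p] = str(row["reason"])
        return cls(
            panel=panel,
            r=r,
            weights=w,
            control_variance=var,
            excluded_samples=dict(meta.get("excluded_samples", {})),
            excluded_regions=excluded,
            retained_samples=list(meta.get("retained_samples", [])),
            threshold=float(meta.get("threshold", float("nan"))),
            sample_frac=float(meta.get("sample_frac", 0.20)),
            region_frac=float(meta.get("region_frac", 0.50)),
        )


def build_pseudo_reference(
    norm: NormalizedCounts,
    sample_frac: float = 0.20,
    region_frac: float = 0.50,
) -> PseudoReference:
    """Build the filtered control baseline.

    Steps: (1) flag zero-coverage regions (any control count 0); (2)
    geometric-mean reference over active regions; (3) pooled-deviation
    threshold T; (4) exclude samples with >= sample_frac of regions whose
    deviation exceeds T; (5) if any sample was excluded, rebuild the
    reference and recompute deviations and T on the retained controls;
    (6) exclude regions whose deviation exceeds T in >= region_frac of
    retained controls; (7) inverse-variance weights over what remains.
    """
    P, S = norm.fractions.shape
    if S < 2:
        raise ValueError(f"need >= 2 control samples to build a pseudo-reference, got {S}")

    excluded_regions: dict[int, str] = {}
    zero_cov = np.any(norm.counts == 0, axis=1)
    for p in np.nonzero(zero_cov)[0]:
        excluded_regions[int(p)] = "zero-coverage"
    active = ~zero_cov
    if not active.any():
        raise ValueError("all regions have zero coverage in at least one control")

    x = norm.fractions
    r_active = geometric_reference(x[active])
    dev = rmsd_deviations(x[active], r_active)
    T = outlier_threshold(dev)

    frac_bad = np.mean(dev > T, axis=0)
    excluded_samples = {
        norm.sample_ids[s]: f"{frac_bad[s]:.1%} of regions deviate beyond T"
        for s in range(S)
        if frac_bad[s] >= sample_frac
    }
    keep = np.array([sid not in excluded_samples for sid in norm.sample_ids])
    if not keep.any():
        raise ValueError(
            "all control samples were flagged as outliers; provide more or better controls"
        )
    if keep.sum() < 2:
        raise ValueError(
            "fewer than 2 control samples pass the outlier filter; "
            "provide more or better controls"
        )

    if len(excluded_samples) > 0:
        r_active = geometric_reference(x[active][:, keep])
        dev = rmsd_deviations(x[active][:, keep], r_active)
        T = outlier_threshold(dev)
    else:
        dev = dev[:, keep]

    noisy_frac = np.mean(dev > T, axis=1)
    active_idx = np.nonzero(active)[0]
    for k, p in enumerate(active_idx):
        if noisy_frac[k] >= region_frac:
            excluded_regions[int(p)] = (
                f"deviation beyond T in {noisy_frac[k]:.0%} of retained controls"
            )

    retained = np.array([p not in excluded_regions for p in range(P)])
    if not retained.any():
        raise ValueError("no regions survive the RMSD filters")

    r = np.full(P, np.nan)
    r[active] = r_active
    r[~retained] = np.nan

    weights = np.zeros(P)
    control_variance = np.full(P, np.nan)
    w_ret, var_ret = segmentation_weights(x[retained][:, keep])
    weights[retained] = w_ret
    control_variance[retained] = var_ret

    return PseudoReference(
        panel=norm.panel,
        r=r,
        weights=weights,
        control_variance=control_variance,
        excluded_samples=excluded_samples,
        excluded_regions=excluded_regions,
        retained_samples=[sid for sid, k in zip(norm.sample_ids, keep) if k],
        threshold=T,
        sample_frac=sample_frac,
        region_frac=region_frac,
    )
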