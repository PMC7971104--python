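"""Weighted circular binary segmentation of per-gene log-ratio vectors.

Each gene's ordered log-ratios are segmented independently. The split
statistic for a candidate arc of the circularized sequence is a
pooled-variance weighted two-sample t between in-arc and out-of-arc
values; its significance is assessed by permuting the values while the
weights stay attached to their positions (the weight encodes per-region
assay variance, a property of the position, not of the observation).
Splitting recurses while the permutation p-value is below alpha; small
adjacent segments whose weighted means differ by less than
undo_sd * (pooled residual SD) are merged back.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import Region
from .logratio import LogRatioProfile
from .reference import PseudoReference

_PERM_CHUNK = 2000


@dataclass
class SegParams:
    """Segmentation tunables (PSCBS-lineage defaults)."""

    alpha: float = 0.01      # permutation significance level for a split
    n_perm: int = 10_000     # permutations per split test (early stop allowed)
    min_width: int = 2       # minimum regions per segment
    undo_sd: float = 1.0     # merge-back threshold in pooled-SD units
    seed: int = 17


@dataclass
class GeneSignal:
    """One gene's ordered log-ratios with aligned segmentation weights."""

    gene: str
    regions: list[Region]
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.v.shape != self.w.shape or self.v.ndim != 1 or self.v.size < 1:
            raise ValueError("signal and weights must be 1-D, non-empty and aligned")

    @property
    def region_indices(self) -> np.ndarray:
        return np.array([r.index for r in self.regions])


@dataclass
class Segment:
    """A run of consecutive regions with a common copy-number level."""

    gene: str
    chrom: str
    start: int               # genomic start of first region
    end: int                 # genomic end of last region
    region_indices: np.ndarray
    n_regions: int
    mean: float              # weighted mean of member log-ratios
    values: np.ndarray
    weights: np.ndarray
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# arc statistic

def _arc_candidates(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All arcs [i, j) with both arc and complement >= min_width regions.

    Wrap-around arcs of the circle need not be enumerated: the statistic
    is symmetric under complement, and a wrap arc's complement is linear.
    """
    ii, jj = [], []
    for length in range(min_width, n - min_width + 1):
        for i in range(0, n - length + 1):
            j = i + length
            # pieces left of i and right of j must be empty or >= min_width
            if 0 < i < min_width or 0 < n - j < min_width:
                continue
            ii.append(i)
            jj.append(j)
    return np.array(ii, dtype=np.intp), np.array(jj, dtype=np.intp)


def _max_arc_stat(
    V: np.ndarray, w: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Max |weighted two-sample t| over arcs for each row of V.

    Returns (max_abs_t, argmax_arc_index), each of length V.shape[0].
    The pooled residual variance is floored at a small multiple of the
    signal's mean square, so a perfectly separating arc yields a very
    large but finite statistic (and permutation tests stay well defined).
    """
    V = np.atleast_2d(V)
    R, n = V.shape
    w = np.asarray(w, dtype=float)
    wv = V * w
    wv2 = wv * V
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwv = np.concatenate([np.zeros((R, 1)), np.cumsum(wv, axis=1)], axis=1)
    cwv2 = np.concatenate([np.zeros((R, 1)), np.cumsum(wv2, axis=1)], axis=1)
    W_tot = cw[-1]
    S_tot = cwv[:, -1:]
    Q_tot = cwv2[:, -1:]

    W_A = cw[j_idx] - cw[i_idx]            # (K,)
    W_B = W_tot - W_A
    S_A = cwv[:, j_idx] - cwv[:, i_idx]    # (R, K)
    m_A = S_A / W_A
    m_B = (S_tot - S_A) / W_B
    SS = np.maximum(Q_tot - W_A * m_A**2 - W_B * m_B**2, 0.0)
    scale = np.maximum(Q_tot / W_tot, 1e-300)
    s2 = np.maximum(SS / max(n - 2, 1), 1e-16 * scale)
    t = np.abs(m_A - m_B) / np.sqrt(s2 * (1.0 / W_A + 1.0 / W_B))
    arg = np.argmax(t, axis=1)
    return t[np.arange(R), arg], arg


def _split_pvalue(
    v: np.ndarray,
    w: np.ndarray,
    params: SegParams,
    rng: np.random.Generator,
) -> tuple[float, int, int]:
    """Best arc of v and its permutation p-value.

    Returns (p, i, j) for the maximizing arc [i, j). Permutations shuffle
    the values; the weights stay fixed to positions. Early termination:
    once enough permuted maxima exceed the observed maximum to guarantee
    p >= alpha, remaining permutations are skipped.
    """
    n = v.size
    i_idx, j_idx = _arc_candidates(n, params.min_width)
    obs, arg = _max_arc_stat(v[None, :], w, i_idx, j_idx)
    obs = float(obs[0])
    i, j = int(i_idx[arg[0]]), int(j_idx[arg[0]])

    stop_count = int(np.ceil(params.alpha * (params.n_perm + 1)))
    exceed = 0
    done = 0
    while done < params.n_perm:
        m = min(_PERM_CHUNK, params.n_perm - done)
        perms = rng.permuted(np.tile(v, (m, 1)), axis=1)
        pmax, _ = _max_arc_stat(perms, w, i_idx, j_idx)
        exceed += int(np.sum(pmax >= obs * (1 - 1e-12)))
        done += m
        if exceed >= stop_count:
            break
    p = (1 + exceed) / (1 + done)
    return p, i, j


def _segment_boundaries(
    v: np.ndarray, w: np.ndarray, params: SegParams, rng: np.random.Generator
) -> list[int]:
    """Recursive CBS on one gene; returns sorted boundary positions."""
    bounds = {0, v.size}

    def recurse(a: int, b: int) -> None:
        m = b - a
        if m < 2 * params.min_width or np.ptp(v[a:b]) == 0.0:
            return
        p, i, j = _split_pvalue(v[a:b], w[a:b], params, rng)
        if p >= params.alpha:
            return
        cuts = sorted({a + i, a + j} - {a, b})
        if not cuts:
            return
        bounds.update(cuts)
        edges = [a, *cuts, b]
        for lo, hi in zip(edges[:-1], edges[1:]):
            recurse(lo, hi)

    recurse(0, v.size)
    return sorted(bounds)


def _weighted_mean(v: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * v) / np.sum(w))


def _undo_splits(
    v: np.ndarray, w: np.ndarray, bounds: list[int], undo_sd: float
) -> list[int]:
    """Merge adjacent segments whose weighted means are too close.

    The scale is the pooled weighted residual SD of the current
    segmentation; the closest pair is merged first and the scale is
    recomputed after each merge.
    """
    bounds = list(bounds)
    n = v.size
    while len(bounds) > 2:
        means = np.array(
            [_weighted_mean(v[a:b], w[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]
        )
        ss = 0.0
        for (a, b), m in zip(zip(bounds[:-1], bounds[1:]), means):
            ss += float(np.sum(w[a:b] * (v[a:b] - m) ** 2))
        df = max(n - (len(bounds) - 1), 1)
        s = np.sqrt(ss / df / (np.sum(w) / n))  # per-unit-weight residual SD
        diffs = np.abs(np.diff(means))
        k = int(np.argmin(diffs))
        if diffs[k] < undo_sd * s:
            del bounds[k + 1]
        else:
            break
    return bounds


def segment_gene(
    signal: GeneSignal,
    params: SegParams = SegParams(),
    rng: np.random.Generator | None = None,
) -> list[Segment]:
    """Segment one gene's log-ratio vector.

    Genes with fewer than 2*min_width regions (or a constant signal)
    return a single segment; a single-region gene is flagged as below
    the recommended minimum of 6 non-overlapping regions.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    v, w = signal.v, signal.w
    n = v.size
    if n < 2 * params.min_width or np.ptp(v) == 0.0:
        bounds = [0, n]
    else:
        bounds = _segment_boundaries(v, w, params, rng)
        bounds = _undo_splits(v, w, bounds, params.undo_sd)

    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        regs = signal.regions[a:b]
        flags = []
        if b - a == 1:
            flags.append("single-region")
        if n < 6:
            flags.append("few-regions")
        segments.append(
            Segment(
                gene=signal.gene,
                chrom=regs[0].chrom,
                start=regs[0].start,
                end=regs[-1].end,
                region_indices=signal.region_indices[a:b],
                n_regions=b - a,
                mean=_weighted_mean(v[a:b], w[a:b]),
                values=v[a:b].copy(),
                weights=w[a:b].copy(),
                flags=flags,
            )
        )
    return segments


def _stable_hash(text: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big") % (2**31)


def segment_sample(
    profile: LogRatioProfile,
    reference: PseudoReference,
    params: SegParams = SegParams(),
) -> list[Segment]:
    """Per-gene segmentation of a whole centered log-ratio profile.

    Excluded regions are skipped. Each gene's permutation RNG is seeded
    from (global seed, sample id, gene block position) so results do not
    depend on the order in which genes are processed.
    """
    if not profile.centered:
        raise ValueError(
            "profile is not centered; run center_profile() first "
            "(or call it with enabled=False to skip centering knowingly)"
        )
    mask = reference.retained_mask & np.isfinite(profile.l)
    segments: list[Segment] = []
    sample_key = _stable_hash(profile.sample_id)
    for bi, block in enumerate(profile.panel.blocks):
        idx = [p for p in block.indices if mask[p]]
        if not idx:
            continue
        sig = GeneSignal(
            gene=block.label,
            regions=[profile.panel.regions[p] for p in idx],
            v=profile.l[idx],
            w=reference.weights[idx],
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed % (2**31), sample_key, bi])
        )
        segments.extend(segment_gene(sig, params, rng))
    return segments
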