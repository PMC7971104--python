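import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from umicna.panel import Panel
from umicna.logratio import center_profile, log_ratios
from umicna.segmentation import (
    GeneSignal,
    SegParams,
    _arc_candidates,
    _max_arc_stat,
    segment_gene,
    segment_sample,
)
from umicna.simulate import CnvEvent, SimTruth, simulate_tumor


def _signal(v, w=None, gene="G"):
    v = np.asarray(v, dtype=float)
    w = np.ones_like(v) if w is None else np.asarray(w, dtype=float)
    panel = Panel([("chr1", 100 * i, 100 * i + 50, gene) for i in range(len(v))])
    return GeneSignal(gene, panel.regions, v, w)


def naive_max_arc(v, w, min_width=2):
    """Exhaustive single-split weighted-t search (independent of the
    vectorized prefix-sum implementation)."""
    n = len(v)
    best_t, best_arc = -1.0, None
    q_tot = float(np.sum(w * v * v))
    w_tot = float(np.sum(w))
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            ln = j - i
            if ln < min_width or ln > n - min_width:
                continue
            if 0 < i < min_width or 0 < n - j < min_width:
                continue
            wa = float(np.sum(w[i:j]))
            wb = w_tot - wa
            ma = float(np.sum(w[i:j] * v[i:j])) / wa
            mb = (float(np.sum(w * v)) - wa * ma) / wb
            ss = max(q_tot - wa * ma**2 - wb * mb**2, 0.0)
            s2 = max(ss / max(n - 2, 1), 1e-16 * max(q_tot / w_tot, 1e-300))
            t = abs(ma - mb) / np.sqrt(s2 * (1.0 / wa + 1.0 / wb))
            if t > best_t:
                best_t, best_arc = t, (i, j)
    return best_t, best_arc


def test_noise_free_step_yields_single_breakpoint():
    segs = segment_gene(_signal(np.r_[np.zeros(10), np.ones(10)]), SegParams(seed=1))
    assert [s.n_regions for s in segs] == [10, 10]
    assert segs[0].mean == pytest.approx(0.0) and segs[1].mean == pytest.approx(1.0)


def test_constant_signal_is_one_segment():
    segs = segment_gene(_signal(np.full(12, 0.4)), SegParams(seed=1))
    assert len(segs) == 1 and segs[0].n_regions == 12


def test_short_gene_is_one_segment():
    segs = segment_gene(_signal([0.0, 5.0, 0.0]), SegParams(seed=1, min_width=2))
    assert len(segs) == 1


def test_noisy_step_breakpoint_within_one_of_truth():
    rng = np.random.default_rng(21)
    v = np.r_[rng.normal(0, 0.1, 15), rng.normal(0.6, 0.1, 15)]
    segs = segment_gene(_signal(v), SegParams(seed=2))
    assert len(segs) == 2
    assert abs(segs[0].n_regions - 15) <= 1
    # exhaustive oracle agrees on the maximizing arc boundary
    _, (i, j) = naive_max_arc(v, np.ones_like(v))
    assert segs[0].n_regions in (i, j)


@pytest.mark.parametrize("weighted", [False, True])
def test_max_arc_stat_matches_exhaustive_oracle(weighted):
    rng = np.random.default_rng(22)
    for _ in range(10):
        n = int(rng.integers(5, 28))
        v = rng.normal(size=n)
        w = rng.uniform(0.05, 1.0, size=n) if weighted else np.ones(n)
        i_idx, j_idx = _arc_candidates(n, 2)
        got, arg = _max_arc_stat(v[None, :], w, i_idx, j_idx)
        want_t, want_arc = naive_max_arc(v, w)
        assert got[0] == pytest.approx(want_t, rel=1e-10)
        # the returned arc attains the maximum (complementary arcs tie)
        ii, jj = int(i_idx[arg[0]]), int(j_idx[arg[0]])
        t_at_arc, _ = naive_max_arc(v, w)  # oracle maximum
        mask = np.zeros(n, dtype=bool)
        mask[ii:jj] = True
        wa, wb = w[mask].sum(), w[~mask].sum()
        ma = np.sum(w[mask] * v[mask]) / wa
        mb = np.sum(w[~mask] * v[~mask]) / wb
        ss = max(np.sum(w * v * v) - wa * ma**2 - wb * mb**2, 0.0)
        s2 = max(ss / max(n - 2, 1), 1e-16 * max(np.sum(w * v * v) / w.sum(), 1e-300))
        t_arc = abs(ma - mb) / np.sqrt(s2 * (1 / wa + 1 / wb))
        assert t_arc == pytest.approx(want_t, rel=1e-10)


def test_uniform_weight_stat_equals_classic_two_sample_t():
    """With unit weights the arc statistic is the pooled-variance t."""
    rng = np.random.default_rng(23)
    v = rng.normal(size=16)
    i_idx, j_idx = np.array([3]), np.array([9])
    got, _ = _max_arc_stat(v[None, :], np.ones(16), i_idx, j_idx)
    t_ref, _ = stats.ttest_ind(v[3:9], np.r_[v[:3], v[9:]], equal_var=True)
    assert got[0] == pytest.approx(abs(t_ref), rel=1e-10)


def test_downweighted_outlier_is_not_isolated():
    rng = np.random.default_rng(24)
    v = rng.normal(0, 0.1, 30)
    v[5] = 3.0
    w = np.ones(30)
    w[5] = 0.01
    segs = segment_gene(_signal(v, w), SegParams(seed=3))
    assert len(segs) == 1


def test_segment_means_reconstruct_signal():
    rng = np.random.default_rng(25)
    v = np.r_[rng.normal(0, 0.1, 12), rng.normal(1.0, 0.1, 12)]
    w = rng.uniform(0.2, 1.0, 24)
    for seg in segment_gene(_signal(v, w), SegParams(seed=4)):
        a = seg.region_indices[0]
        b = seg.region_indices[-1] + 1
        want = np.sum(w[a:b] * v[a:b]) / np.sum(w[a:b])
        assert seg.mean == pytest.approx(want, abs=1e-10)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(shift=st.floats(-3.0, 3.0), seed=st.integers(0, 50))
def test_shift_equivariance_property(shift, seed):
    """Adding a constant moves segment means but never breakpoints."""
    rng = np.random.default_rng(seed)
    v = np.r_[rng.normal(0, 0.1, 8), rng.normal(0.8, 0.1, 8)]
    params = SegParams(seed=5, n_perm=2000)
    a = segment_gene(_signal(v), params)
    b = segment_gene(_signal(v + shift), params)
    assert [s.n_regions for s in a] == [s.n_regions for s in b]
    for sa, sb in zip(a, b):
        assert sb.mean - sa.mean == pytest.approx(shift, abs=1e-9)


def test_shift_equivariance():
    rng = np.random.default_rng(26)
    v = np.r_[rng.normal(0, 0.1, 10), rng.normal(0.8, 0.1, 10)]
    a = segment_gene(_signal(v), SegParams(seed=5))
    b = segment_gene(_signal(v + 2.5), SegParams(seed=5))
    assert [s.n_regions for s in a] == [s.n_regions for s in b]
    for sa, sb in zip(a, b):
        assert sb.mean - sa.mean == pytest.approx(2.5, abs=1e-10)


def test_breakpoints_respect_gene_boundaries(sim_panel, reference):
    truth = SimTruth((CnvEvent("G03", 4),), 0.8)
    tumor = simulate_tumor(sim_panel, truth, seed=27)
    prof = center_profile(log_ratios(tumor, reference))
    segs = segment_sample(prof, reference, SegParams(seed=6))
    gene_of = {}
    for b in sim_panel.panel.blocks:
        for p in b.indices:
            gene_of[p] = b.label
    for s in segs:
        genes = {gene_of[p] for p in s.segment_indices} if hasattr(s, "segment_indices") else {
            gene_of[p] for p in s.region_indices
        }
        assert genes == {s.gene}
        assert np.all(np.diff(s.region_indices) >= 1)


def test_gene_order_does_not_matter(sim_panel, reference):
    truth = SimTruth((CnvEvent("G02", 1), CnvEvent("G07", 3)), 0.7)
    tumor = simulate_tumor(sim_panel, truth, seed=28)
    prof = center_profile(log_ratios(tumor, reference))
    segs = segment_sample(prof, reference, SegParams(seed=7))
    segs2 = segment_sample(prof, reference, SegParams(seed=7))
    assert [(s.gene, s.n_regions, s.mean) for s in segs] == [
        (s.gene, s.n_regions, s.mean) for s in segs2
    ]


def test_whole_gene_event_recovers_programmed_mean(sim_panel, reference):
    truth = SimTruth((CnvEvent("G05", 4),), 1.0)
    tumor = simulate_tumor(sim_panel, truth, seed=29)
    prof = center_profile(log_ratios(tumor, reference))
    segs = segment_sample(prof, reference, SegParams(seed=8))
    gain_segs = [s for s in segs if s.gene == "G05"]
    assert len(gain_segs) == 1
    assert gain_segs[0].mean == pytest.approx(1.0, abs=0.15)  # log2(4/2)
    others = [s for s in segs if s.gene != "G05"]
    assert all(abs(s.mean) < 0.2 for s in others)


def test_all_zero_profile_gives_one_segment_per_gene(sim_panel, reference):
    prof = center_profile(
        log_ratios(
            _reference_like_tumor(reference), reference
        ),
        enabled=False,
    )
    prof.l = np.where(np.isfinite(prof.l), 0.0, np.nan)
    segs = segment_sample(prof, reference, SegParams(seed=9))
    n_genes_with_regions = sum(
        1
        for b in sim_panel.panel.blocks
        if any(reference.retained_mask[p] for p in b.indices)
    )
    assert len(segs) == n_genes_with_regions
    assert all(s.mean == 0.0 for s in segs)


def _reference_like_tumor(reference):
    from umicna.counts import SampleCounts

    mask = reference.retained_mask
    counts = np.zeros(reference.panel.n_regions, dtype=np.int64)
    counts[mask] = np.round(reference.r[mask] * 1e6).astype(np.int64)
    return SampleCounts(reference.panel, "flat", counts, 1_000_000)
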