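import numpy as np
import pytest

from umicna.counts import UmiCountMatrix, normalize
from umicna.reference import (
    build_pseudo_reference,
    geometric_reference,
    outlier_threshold,
    rmsd_deviations,
    segmentation_weights,
)
from umicna.simulate import SimPanel, simulate_controls


# ---------------------------------------------------------------------------
# geometric reference


def test_geometric_mean_pair():
    r = geometric_reference(np.array([[0.01, 0.04]]))
    np.testing.assert_allclose(r, [0.02])


def test_geometric_mean_identical_controls_is_identity():
    col = np.array([0.1, 0.2, 0.7])
    x = np.stack([col] * 4, axis=1)
    np.testing.assert_allclose(geometric_reference(x), col)


def test_geometric_mean_matches_logspace_oracle():
    rng = np.random.default_rng(5)
    x = rng.lognormal(size=(40, 5))
    expected = np.exp(np.mean(np.log(x), axis=1))
    np.testing.assert_allclose(geometric_reference(x), expected, rtol=1e-12)


def test_geometric_mean_rejects_nonpositive():
    with pytest.raises(ValueError):
        geometric_reference(np.array([[0.0, 1.0]]))


# ---------------------------------------------------------------------------
# deviations and threshold


def test_deviations_zero_when_equal():
    x = np.full((5, 3), 0.2)
    assert np.all(rmsd_deviations(x, x[:, 0]) == 0)


def test_deviations_shift():
    r = np.array([0.1, 0.2])
    x = (r + 0.03)[:, None]
    np.testing.assert_allclose(rmsd_deviations(x, r), 0.03)


def test_deviations_formula_oracle():
    rng = np.random.default_rng(6)
    x = rng.random((10, 4))
    r = rng.random(10)
    np.testing.assert_allclose(
        rmsd_deviations(x, r), np.sqrt((x - r[:, None]) ** 2)
    )


def test_threshold_on_small_integer_sample():
    # 1..8 under linear-interpolation quartiles: Q3=6.25, IQR=3.5 -> 11.5
    assert outlier_threshold(np.arange(1.0, 9.0)) == pytest.approx(11.5)


def test_threshold_constant_deviations():
    assert outlier_threshold(np.full(10, 0.3)) == pytest.approx(0.3)


def test_threshold_sits_between_q3_and_max_for_heavy_tail():
    rng = np.random.default_rng(7)
    d = rng.exponential(size=2000)
    t = outlier_threshold(d)
    assert np.quantile(d, 0.75) < t < d.max()


def test_threshold_needs_four_values():
    with pytest.raises(ValueError, match="4"):
        outlier_threshold(np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# weights


def test_weights_worked_example():
    # rows engineered to have sample variances 1, 2, 4 across two columns
    d = np.sqrt(np.array([1.0, 2.0, 4.0]) / 2.0)
    x = np.stack([10 - d, 10 + d], axis=1)
    w, var = segmentation_weights(x)
    np.testing.assert_allclose(var, [1.0, 2.0, 4.0])
    np.testing.assert_allclose(w, [1.0, 1.0 / 3.0, 0.01], atol=1e-12)


def test_weights_equal_variances_degenerate():
    x = np.stack([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]], axis=1)  # all var = 2
    w, _ = segmentation_weights(x)
    np.testing.assert_allclose(w, 1.0)


def test_weights_monotone_in_variance():
    rng = np.random.default_rng(8)
    x = rng.lognormal(size=(30, 6))
    w, var = segmentation_weights(x)
    order = np.argsort(var)
    assert np.all(np.diff(w[order]) <= 1e-12)


# ---------------------------------------------------------------------------
# full construction


def _matrix(panel, counts):
    counts = np.asarray(counts)
    ids = [f"C{i + 1}" for i in range(counts.shape[1])]
    return UmiCountMatrix(panel, ids, counts, counts.sum(axis=0))


def test_identical_controls_exclude_nothing(small_panel):
    m = _matrix(small_panel, np.tile([[100], [200], [300]], (1, 4)))
    ref = build_pseudo_reference(normalize(m))
    assert ref.excluded_samples == {}
    assert ref.excluded_regions == {}
    # T collapses to ~0 and the strict ">" rule keeps everything
    assert ref.threshold == pytest.approx(0.0, abs=1e-12)


def test_zero_coverage_region_is_excluded(small_panel):
    counts = np.tile([[100], [0], [300]], (1, 4))
    ref = build_pseudo_reference(normalize(_matrix(small_panel, counts)))
    assert 1 in ref.excluded_regions
    assert "zero" in ref.excluded_regions[1]
    assert np.isnan(ref.r[1]) and ref.weights[1] == 0.0


def test_requires_two_controls(small_panel):
    with pytest.raises(ValueError, match=">= 2"):
        build_pseudo_reference(normalize(_matrix(small_panel, [[10], [10], [10]])))


def _corrupted_cohort(seed, scale=3.0, frac=0.4):
    """5 concordant controls + 1 scaled on the middle-efficiency 40% of regions."""
    sp = SimPanel.build(n_genes=6, regions_per_gene=8, seed=seed)
    ctl = simulate_controls(sp, n_samples=6, seed=1000 + seed)
    counts = ctl.counts.copy()
    n_bad = int(frac * sp.n_regions)
    order = np.argsort(sp.efficiencies)
    mid = len(order) // 2
    bad = order[mid - n_bad // 2: mid + (n_bad + 1) // 2]
    counts[bad, 5] = np.round(counts[bad, 5] * scale)
    m = UmiCountMatrix(sp.panel, ctl.sample_ids, counts, counts.sum(axis=0))
    return m, bad


def test_corrupted_control_is_excluded_and_flagged_fraction_exceeds_rule():
    m, _ = _corrupted_cohort(seed=0)
    norm = normalize(m)
    # oracle: the corrupted column's flagged-region fraction exceeds 20%
    r = geometric_reference(norm.fractions)
    dev = rmsd_deviations(norm.fractions, r)
    t = outlier_threshold(dev)
    assert np.mean(dev[:, 5] > t) > 0.20
    ref = build_pseudo_reference(norm)
    assert set(ref.excluded_samples) == {"CTL06"}


def test_noisy_region_is_excluded(small_panel, sim_panel):
    ctl = simulate_controls(sim_panel, n_samples=5, seed=33)
    counts = ctl.counts.copy()
    # blow up one region in 3/5 controls
    counts[10, :3] = np.round(counts[10, :3] * 8)
    m = UmiCountMatrix(sim_panel.panel, ctl.sample_ids, counts, counts.sum(axis=0))
    ref = build_pseudo_reference(normalize(m))
    assert 10 in ref.excluded_regions
    assert "retained controls" in ref.excluded_regions[10]


def test_exclusion_is_independent_of_sample_order():
    m, _ = _corrupted_cohort(seed=3)
    norm = normalize(m)
    ref = build_pseudo_reference(norm)
    perm = [3, 5, 0, 2, 4, 1]
    m2 = UmiCountMatrix(
        m.panel,
        [m.sample_ids[i] for i in perm],
        m.counts[:, perm],
        m.totals[perm],
    )
    ref2 = build_pseudo_reference(normalize(m2))
    assert set(ref.excluded_samples) == set(ref2.excluded_samples)
    assert ref.excluded_regions == ref2.excluded_regions
    np.testing.assert_allclose(ref.r, ref2.r, equal_nan=True)


def test_weights_invariant_to_depth_scaling(sim_panel, control_matrix):
    m = control_matrix
    m2 = UmiCountMatrix(m.panel, m.sample_ids, m.counts * 3, m.totals * 3)
    ref = build_pseudo_reference(normalize(m))
    ref2 = build_pseudo_reference(normalize(m2))
    np.testing.assert_allclose(ref.weights, ref2.weights)


def test_bundle_roundtrip(tmp_path, reference):
    reference.save(tmp_path / "ref")
    from umicna.reference import PseudoReference

    back = PseudoReference.load(tmp_path / "ref")
    np.testing.assert_allclose(back.r, reference.r, equal_nan=True)
    np.testing.assert_allclose(back.weights, reference.weights)
    assert back.excluded_regions == reference.excluded_regions
    assert back.retained_samples == reference.retained_samples
    assert back.threshold == pytest.approx(reference.threshold)
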