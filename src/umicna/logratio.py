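"""Per-region log2 ratios and Gaussian-mixture signal centering.

The log-ratio of a tumor sample at region p is log2 of its normalized
UMI fraction over the pseudo-reference. Because total library size is
renormalized away, a genome-wide shift remains whenever the sample is
not mostly diploid at face value; a 1-3 component Gaussian mixture is
fitted to the log-ratios and the component closest to zero — assumed to
represent the diploid state — defines the shift that is subtracted.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .counts import SampleCounts
from .reference import PseudoReference

SD_FLOOR = 1e-6


@dataclass
class MixtureModel:
    """A fitted 1-3 component univariate Gaussian mixture.

    ``selected`` indexes the component with the smallest |mean| (ties
    broken toward the larger mixing proportion); its mean is the
    centering shift.
    """

    k: int
    means: np.ndarray
    sds: np.ndarray
    props: np.ndarray
    selected: int
    bic: dict[int, float]
    sd_floored: bool = False

    @property
    def shift(self) -> float:
        return float(self.means[self.selected])


@dataclass
class LogRatioProfile:
    """Per-region log2 ratios of one tumor sample.

    ``l`` is the working signal (centered once centering has run);
    ``l_raw`` the uncentered values. Excluded regions carry NaN.
    """

    panel: object
    sample_id: str
    l: np.ndarray
    l_raw: np.ndarray
    shift: float = 0.0
    mixture: MixtureModel | None = None
    zero_count_regions: np.ndarray | None = None  # bool mask of pseudocounted regions
    centered: bool = False


def log_ratios(tumor: SampleCounts, reference: PseudoReference) -> LogRatioProfile:
    """Uncentered log2(tumor fraction / reference) per retained region.

    Tumor regions with count 0 use a half-count pseudocount 0.5/U and are
    flagged: a zero in a deep targeted assay is informative (homozygous
    deletion) rather than missing data.
    """
    if tumor.panel.content_hash() != reference.panel.content_hash():
        raise ValueError(
            f"sample {tumor.sample_id}: panel does not match the reference bundle"
        )
    P = tumor.panel.n_regions
    frac = tumor.fractions.astype(float).copy()
    zero = tumor.umi_counts == 0
    frac[zero] = 0.5 / float(tumor.total_umis)
    l = np.full(P, np.nan)
    mask = reference.retained_mask
    l[mask] = np.log2(frac[mask] / reference.r[mask])
    return LogRatioProfile(
        panel=tumor.panel,
        sample_id=tumor.sample_id,
        l=l.copy(),
        l_raw=l,
        zero_count_regions=zero & mask,
    )


def fit_mixture(
    values: np.ndarray,
    k_max: int = 3,
    seed: int = 17,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit Gaussian mixtures with k = 1..k_max by EM; pick k by BIC.

    Deterministic k-means++-style initialization from the given seed;
    free per-component variances; collapsed components get their sd
    floored at SD_FLOOR and flagged.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 finite log-ratio values to fit a mixture, got {x.size}")

    if np.ptp(x) == 0.0:
        return MixtureModel(
            k=1,
            means=np.array([x[0]]),
            sds=np.array([SD_FLOOR]),
            props=np.array([1.0]),
            selected=0,
            bic={1: float("nan")},
            sd_floored=True,
        )

    from sklearn.mixture import GaussianMixture

    X = x.reshape(-1, 1)
    fits: dict[int, GaussianMixture] = {}
    bic: dict[int, float] = {}
    for k in range(1, k_max + 1):
        if k > np.unique(x).size:
            continue
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            tol=tol,
            max_iter=max_iter,
            n_init=3,
            init_params="k-means++",
            random_state=seed,
            reg_covar=1e-12,
        )
        try:
            import warnings

            with warnings.catch_warnings():
                # tight tol can leave the last EM step short of the declared
                # tolerance without affecting the selected component
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                gm.fit(X)
        except Exception:
            continue
        fits[k] = gm
        bic[k] = float(gm.bic(X))
    if not fits:
        raise RuntimeError("all mixture fits failed")

    best_k = min(bic, key=bic.get)
    gm = fits[best_k]
    means = gm.means_.ravel().copy()
    sds = np.sqrt(gm.covariances_.reshape(best_k)).copy()
    props = gm.weights_.ravel().copy()
    floored = bool(np.any(sds < SD_FLOOR))
    sds = np.maximum(sds, SD_FLOOR)
    # component closest to 0; ties -> larger mixing proportion
    order = np.lexsort((-props, np.abs(means)))
    selected = int(order[0])
    return MixtureModel(
        k=best_k, means=means, sds=sds, props=props,
        selected=selected, bic=bic, sd_floored=floored,
    )


def center_profile(
    profile: LogRatioProfile,
    enabled: bool = True,
    seed: int = 17,
) -> LogRatioProfile:
    """Subtract the diploid-component mean from the log-ratio signal.

    With centering disabled the signal is passed through unchanged and
    shift = 0 is recorded (recommended for panels where most targets are
    expected to be altered).
    """
    if not enabled:
        return replace(profile, l=profile.l_raw.copy(), shift=0.0, mixture=None, centered=True)
    mixture = fit_mixture(profile.l_raw, seed=seed)
    shift = mixture.shift
    return replace(
        profile, l=profile.l_raw - shift, shift=shift, mixture=mixture, centered=True
    )
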