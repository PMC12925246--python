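"""Per-dataset cleaning chain: missingness filter, variance filter, kNN
imputation and feature standardization, applied in that fixed order.

Both filters operate on features regardless of the file orientation the
matrix was read from; the SD filter threshold is computed on observed
values before imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AbundanceMatrix

logger = logging.getLogger("modmix")


@dataclass
class PreprocessConfig:
    """Cleaning parameters.

    max_missing_frac : features missing in strictly more than this fraction
        of samples are removed (default 0.10, i.e. the >10% rule).
    sd_percentile : features with standard deviation strictly below this
        percentile of the per-feature SDs are removed (default 25).
    knn_k : number of neighbouring features used for imputation.
    max_features : optional cap; if set, only the top-SD features are kept
        after the two filters.  None (library default) disables the cap;
        the command-line interface enables it at 5000.
    """

    max_missing_frac: float = 0.10
    sd_percentile: float = 25.0
    knn_k: int = 10
    max_features: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0.0 <= self.sd_percentile <= 100.0:
            raise ValueError("sd_percentile must be in [0, 100]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be positive")


@dataclass
class PreprocessReport:
    n_features_in: int
    n_removed_missing: int
    n_removed_low_sd: int
    n_removed_cap: int
    n_features_out: int
    n_imputed_cells: int

    def __post_init__(self) -> None:
        kept = self.n_features_in - self.n_removed_missing - self.n_removed_low_sd - self.n_removed_cap
        if kept != self.n_features_out:
            raise ValueError("preprocess report counts do not balance")


def _observed_sd(values: np.ndarray) -> np.ndarray:
    """Per-feature sample SD (ddof=1) over non-missing entries."""
    with np.errstate(invalid="ignore"):
        return np.array([np.nanstd(row, ddof=1) if np.sum(~np.isnan(row)) > 1 else 0.0
                         for row in values])


def filter_missing(m: AbundanceMatrix, max_missing_frac: float = 0.10) -> AbundanceMatrix:
    """Drop features missing in strictly more than ``max_missing_frac`` of samples.

    A feature at exactly the threshold (e.g. 10% with the default) is kept.
    """
    frac = np.isnan(m.values).mean(axis=1)
    keep = frac <= max_missing_frac
    if not keep.any():
        raise ValueError(
            f"all {m.n_features} features exceed the missingness threshold "
            f"{max_missing_frac:g}; relax max_missing_frac"
        )
    return m.select_features(keep)


def filter_low_variance(m: AbundanceMatrix, sd_percentile: float = 25.0) -> AbundanceMatrix:
    """Drop features whose SD falls strictly below the given percentile of SDs.

    SDs use observed values only (sample SD, ddof=1); the percentile uses
    linear interpolation, so ties at the threshold are kept.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to compute standard deviations")
    sds = _observed_sd(m.values)
    threshold = np.percentile(sds, sd_percentile)  # linear interpolation (type 7)
    if np.allclose(sds, sds[0]):
        logger.warning("filter_low_variance: all features have identical SD; nothing removed")
    keep = sds >= threshold
    return m.select_features(keep)


def _pairwise_overlap_distances(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared Euclidean feature-feature distances over mutually observed samples.

    Returns (d2, overlap): pairs with no common observed sample get d2=inf.
    """
    mask = ~np.isnan(values)
    x0 = np.where(mask, values, 0.0)
    maskf = mask.astype(float)
    sq = (x0 ** 2) @ maskf.T          # sum_i x_f(i)^2 over samples observed in both
    cross = x0 @ x0.T
    d2 = sq + sq.T - 2.0 * cross
    np.maximum(d2, 0.0, out=d2)
    overlap = maskf @ maskf.T
    d2[overlap == 0] = np.inf
    return d2, overlap


def knn_impute(m: AbundanceMatrix, k: int = 10) -> tuple[AbundanceMatrix, int]:
    """Impute each missing cell from the k nearest features.

    Nearness is Euclidean distance computed over samples observed in both
    features; the imputed value is the mean of the k nearest features'
    values at that sample (neighbours missing there are skipped).  If no
    feature qualifies, the feature's own observed mean is used.  Returns
    the imputed matrix and the number of imputed cells.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = m.values.copy()
    missing = np.isnan(values)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return AbundanceMatrix(list(m.feature_ids), list(m.sample_ids), values, m.omics_name), 0
    if (missing.all(axis=1)).any():
        bad = [m.feature_ids[i] for i in np.flatnonzero(missing.all(axis=1))]
        raise ValueError(f"feature(s) with no observed value: {', '.join(bad[:10])}")

    d2, _ = _pairwise_overlap_distances(values)
    np.fill_diagonal(d2, np.inf)
    feature_means = np.nanmean(values, axis=1)
    n_fallback = 0
    observed = ~missing
    for f, s in zip(*np.nonzero(missing)):
        candidates = np.flatnonzero(observed[:, s] & np.isfinite(d2[:, f]))
        if candidates.size == 0:
            values[f, s] = feature_means[f]
            n_fallback += 1
            continue
        nearest = candidates[np.argsort(d2[candidates, f], kind="stable")[:k]]
        values[f, s] = values[nearest, s].mean()
    if n_fallback:
        logger.warning("knn_impute: %d cell(s) fell back to the feature mean", n_fallback)
    out = AbundanceMatrix(list(m.feature_ids), list(m.sample_ids), values, m.omics_name)
    return out, n_missing


def standardize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each feature to mean 0 and sample SD 1 (ddof=1)."""
    if np.isnan(m.values).any():
        raise ValueError("standardize requires a complete matrix (impute first)")
    sds = m.values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(f"zero-SD feature(s): {', '.join(m.feature_ids[i] for i in zero[:10])}")
    values = (m.values - m.values.mean(axis=1, keepdims=True)) / sds[:, None]
    return AbundanceMatrix(list(m.feature_ids), list(m.sample_ids), values, m.omics_name)


def preprocess(m: AbundanceMatrix, cfg: PreprocessConfig | None = None) -> tuple[AbundanceMatrix, PreprocessReport]:
    """Run the full cleaning chain and tally every stage.

    Order: missingness filter -> SD filter -> optional top-SD cap -> kNN
    imputation -> standardization.  Deterministic.
    """
    cfg = cfg or PreprocessConfig()
    n_in = m.n_features
    m1 = filter_missing(m, cfg.max_missing_frac)
    n_removed_missing = n_in - m1.n_features
    m2 = filter_low_variance(m1, cfg.sd_percentile)
    n_removed_low_sd = m1.n_features - m2.n_features
    n_removed_cap = 0
    if cfg.max_features is not None and m2.n_features > cfg.max_features:
        sds = _observed_sd(m2.values)
        order = np.argsort(-sds, kind="stable")[: cfg.max_features]
        m2 = m2.select_features(np.sort(order))
        n_removed_cap = (n_in - n_removed_missing - n_removed_low_sd) - cfg.max_features
    m3, n_imputed = knn_impute(m2, cfg.knn_k)
    out = standardize(m3)
    report = PreprocessReport(
        n_features_in=n_in,
        n_removed_missing=n_removed_missing,
        n_removed_low_sd=n_removed_low_sd,
        n_removed_cap=n_removed_cap,
        n_features_out=out.n_features,
        n_imputed_cells=n_imputed,
    )
    logger.info("preprocess[%s]: %d -> %d features (%d missing-filtered, %d low-SD, "
                "%d capped), %d cells imputed", m.omics_name, n_in, out.n_features,
                n_removed_missing, n_removed_low_sd, n_removed_cap, n_imputed)
    return out, report
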