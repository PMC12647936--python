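"""Leakage-aware preprocessing: zero filtering, KNN imputation, min-max
scaling, and a moderated-t differential screen with BH adjustment.

Stage order is fixed: filter -> impute -> scale -> screen. All fitting
operations (scaling stats, screening) are meant to be run on training samples
only and applied to held-out samples; the pipeline runner enforces this. A
``paper_mode`` escape hatch reproducing global (pre-split) scaling exists at
the pipeline level.

The differential screen is an empirical-Bayes moderated two-sample t: the
per-feature pooled variance is shrunk toward a common prior variance whose
weight (prior degrees of freedom) is estimated from the spread of the
log-variances by method of moments. This replaces an external linear-model
screen with a self-contained, testable equivalent; it does not model a
mean-variance trend (no precision weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from sklearn.impute import KNNImputer

from .errors import PreprocessError
from .io_core import LabelTable, Modality, OmicsMatrix

__all__ = [
    "ScalingStats",
    "ScreenResult",
    "filter_low_abundance",
    "knn_impute",
    "fit_minmax",
    "apply_minmax",
    "benjamini_hochberg",
    "moderated_differential_screen",
]


def filter_low_abundance(
    matrix: OmicsMatrix, zero_fraction_threshold: float = 0.6
) -> OmicsMatrix:
    """Drop features whose zero fraction strictly exceeds the threshold.

    A feature with zeros in more than ``zero_fraction_threshold`` of samples
    is excluded; a fraction exactly equal to the threshold is retained.
    Missing entries, if present, are excluded from the denominator.
    """
    vals = matrix.values
    observed = ~np.isnan(vals)
    n_obs = observed.sum(axis=1)
    if (n_obs == 0).any():
        bad = matrix.feature_ids[int(np.argmax(n_obs == 0))]
        raise PreprocessError(f"feature {bad!r} has no observed values")
    zero_frac = np.where(observed, vals == 0, False).sum(axis=1) / n_obs
    keep = zero_frac <= zero_fraction_threshold
    if not keep.any():
        raise PreprocessError("zero filter removed every feature")
    return matrix.subset_features(keep)


def knn_impute(
    matrix: OmicsMatrix, k: int = 5, reference: OmicsMatrix | None = None
) -> OmicsMatrix:
    """Replace each missing entry by the mean over the k nearest samples.

    Sample-to-sample distance is Euclidean over features observed in both
    samples, rescaled by the number of co-observed features, and donors are
    the nearest samples with the feature observed. With ``reference`` given
    (the training matrix in a fold), donor samples are drawn from the
    reference instead of from ``matrix`` itself, so held-out samples never
    inform each other.
    """
    if not matrix.has_missing():
        return OmicsMatrix(
            matrix.modality, list(matrix.feature_ids), list(matrix.sample_ids), matrix.values.copy()
        )
    donor = matrix if reference is None else reference
    if donor.feature_ids != matrix.feature_ids:
        raise PreprocessError("reference feature set must match the matrix feature set")
    donor_X = donor.values.T  # samples x features
    X = matrix.values.T

    n_obs_per_feature = (~np.isnan(donor_X)).sum(axis=0)
    short = n_obs_per_feature == 0
    if short.any():
        bad = matrix.feature_ids[int(np.argmax(short))]
        raise PreprocessError(f"feature {bad!r} is missing in all donor samples")

    obs = ~np.isnan(X)
    donor_obs = ~np.isnan(donor_X)
    co = obs.astype(int) @ donor_obs.astype(int).T  # co-observed feature counts
    if reference is None:
        np.fill_diagonal(co, 1)  # self-pairs are not used as donors
    if (co == 0).any():
        i, j = np.argwhere(co == 0)[0]
        raise PreprocessError(
            f"samples {matrix.sample_ids[i]!r} and {donor.sample_ids[j]!r} share no observed feature"
        )

    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputer.fit(donor_X)
    filled = imputer.transform(X) if reference is not None else imputer.fit_transform(donor_X)
    if np.isnan(filled).any():
        raise PreprocessError("imputation left missing entries (too few donors?)")
    out = filled.T
    # observed entries must be bit-identical
    out[matrix.values == matrix.values] = matrix.values[matrix.values == matrix.values]
    return OmicsMatrix(matrix.modality, list(matrix.feature_ids), list(matrix.sample_ids), out)


@dataclass
class ScalingStats:
    """Per-feature min/max learned on training samples."""

    feature_ids: list[str]
    min: np.ndarray
    max: np.ndarray

    def __post_init__(self) -> None:
        if (self.max < self.min).any():
            raise PreprocessError("per-feature max must be >= min")


def fit_minmax(matrix: OmicsMatrix) -> ScalingStats:
    if matrix.has_missing():
        raise PreprocessError("impute before scaling")
    return ScalingStats(
        list(matrix.feature_ids), matrix.values.min(axis=1), matrix.values.max(axis=1)
    )


def apply_minmax(matrix: OmicsMatrix, stats_: ScalingStats) -> OmicsMatrix:
    """Affine per-feature map to [0,1]; out-of-range held-out values clip.

    Constant training features map to 0 (they carry no information).
    """
    if matrix.feature_ids != stats_.feature_ids:
        raise PreprocessError("scaling stats were fit on a different feature set")
    if matrix.has_missing():
        raise PreprocessError("impute before scaling")
    span = stats_.max - stats_.min
    safe = np.where(span > 0, span, 1.0)
    scaled = (matrix.values - stats_.min[:, None]) / safe[:, None]
    scaled[span == 0, :] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return OmicsMatrix(matrix.modality, list(matrix.feature_ids), list(matrix.sample_ids), scaled)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment.

    Sort ascending, set q_(i) = p_(i) * m / i, enforce monotonicity from the
    largest rank down by cumulative minimum, cap at 1, and return the adjusted
    values in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise PreprocessError("p-values must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise PreprocessError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass
class ScreenResult:
    """Per-feature moderated-t screen output."""

    feature_ids: list[str]
    pvalues: np.ndarray
    adjusted: np.ndarray
    selected: np.ndarray
    t_statistics: np.ndarray
    prior_df: float
    prior_var: float

    @property
    def selected_features(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.selected) if s]


def _estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df, prior_var) from sample variances.

    Under the hierarchical model the log sample variances have excess spread
    trigamma(df/2) attributable to estimation noise; any remaining spread is
    attributed to genuine variance heterogeneity and converted to a finite
    prior df by inverting the trigamma function. If the observed spread does
    not exceed the estimation noise, the prior df is infinite and every
    variance shrinks fully to the common value.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 0.0
    z = np.log(s2)
    e_z = z.mean()
    var_z = z.var(ddof=1)
    noise = float(special.polygamma(1, df / 2))
    excess = var_z - noise
    if excess <= 1e-12:
        d0 = np.inf
        log_s0 = e_z - (special.digamma(df / 2) - np.log(df / 2))
        return d0, float(np.exp(log_s0))
    # invert trigamma(d0/2) = excess by bisection on d0
    lo, hi = 1e-3, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2) > excess:
            lo = mid
        else:
            hi = mid
    d0 = float(np.sqrt(lo * hi))
    log_s0 = (
        e_z
        - (special.digamma(df / 2) - np.log(df / 2))
        + (special.digamma(d0 / 2) - np.log(d0 / 2))
    )
    return d0, float(np.exp(log_s0))


def moderated_differential_screen(
    matrix: OmicsMatrix, labels: LabelTable, alpha: float = 0.001
) -> ScreenResult:
    """Empirical-Bayes moderated two-group t-test per feature, BH-adjusted.

    The pooled per-feature variance s_g^2 (df = n - 2) is shrunk toward the
    prior: s_tilde^2 = (d0*s0^2 + df*s_g^2) / (d0 + df); the t statistic uses
    s_tilde and df + d0 degrees of freedom. Features selected at BH-adjusted
    p < alpha. Features with zero moderated variance and zero mean difference
    report p = 1.
    """
    if matrix.sample_ids != labels.sample_ids:
        raise PreprocessError("labels must be aligned with matrix samples")
    if matrix.has_missing():
        raise PreprocessError("impute before screening")
    y = labels.labels
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 < 2 or n0 < 2:
        raise PreprocessError("each class needs at least 2 samples for the screen")

    X1 = matrix.values[:, y == 1]
    X0 = matrix.values[:, y == 0]
    diff = X1.mean(axis=1) - X0.mean(axis=1)
    ss = X1.var(axis=1, ddof=1) * (n1 - 1) + X0.var(axis=1, ddof=1) * (n0 - 1)
    df = n1 + n0 - 2
    s2 = ss / df

    d0, s0 = _estimate_variance_prior(s2, df)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = 1e6  # effectively normal
    else:
        s2_tilde = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_tilde * (1 / n1 + 1 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[~np.isfinite(t)] = 0.0  # zero variance & zero difference -> no evidence
    p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    adjusted = benjamini_hochberg(p)
    selected = adjusted < alpha
    return ScreenResult(
        list(matrix.feature_ids), p, adjusted, selected, t, float(d0), float(s0)
    )
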