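"""Distributional statistics for the five-attribute Likert ratings.

Per-image rating distributions (with additive smoothing), KL divergence of
grayscale from color with the > 1 threshold rule, skewness shift between
conditions, Kendall tau-b correlations of mean ratings with opacity votes,
and the Bonferroni-corrected attribute correlation matrix.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    ATTRIBUTES,
    AlignmentError,
    DomainError,
    LIKERT_MAX,
    LIKERT_MIN,
)

N_BINS = LIKERT_MAX - LIKERT_MIN + 1

#: Natural log is used throughout; the D_KL > 1 rule is base-dependent.
KL_LOG_BASE = "e"
KL_THRESHOLD = 1.0


@dataclasses.dataclass(frozen=True)
class RatingDistribution:
    """6-bin count and smoothed probability vector for one (image, attribute)."""

    image_id: str
    attribute: str
    condition: str
    counts: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=float)
        if counts.shape != (N_BINS,) or probs.shape != (N_BINS,):
            raise DomainError("distributions must have 6 bins")
        if (counts < 0).any():
            raise DomainError("negative counts")
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-12):
            raise DomainError("probabilities must sum to 1")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probs", probs)


@dataclasses.dataclass(frozen=True)
class KLResult:
    image_id: str
    attribute: str
    d_kl: float
    exceeds_threshold: bool


@dataclasses.dataclass(frozen=True)
class SkewnessShift:
    image_id: str
    attribute: str
    s_color: float
    s_gray: float
    degenerate_color: bool = False
    degenerate_gray: bool = False

    @property
    def d_s(self) -> float:
        return self.s_color - self.s_gray


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    pair: tuple
    tau: float
    p_value: float
    significant: bool
    alpha: float
    degenerate: bool = False


def smooth_counts(counts: np.ndarray) -> np.ndarray:
    """Add-one smoothing over the 6 Likert bins: (c + 1) / (sum(c) + 6)."""
    counts = np.asarray(counts, dtype=float)
    return (counts + 1.0) / (counts.sum() + N_BINS)


def rating_distribution(
    ratings: pd.DataFrame,
    image_id: str,
    attribute: str,
    condition: str,
    smoothing: bool = True,
) -> RatingDistribution:
    """Rating distribution of one attribute for one image.

    ``ratings`` is a long table with ``image_id`` and attribute columns
    (a panel's ``ratings`` frame).  Probabilities use add-one smoothing by
    default so downstream KL is always finite.
    """
    if attribute not in ATTRIBUTES:
        raise DomainError(f"unknown attribute {attribute!r}")
    values = ratings.loc[ratings["image_id"] == image_id, attribute].to_numpy()
    if values.size == 0:
        raise KeyError(f"no ratings for image {image_id!r}")
    counts = np.bincount(values - LIKERT_MIN, minlength=N_BINS)[:N_BINS]
    if smoothing:
        probs = smooth_counts(counts)
    else:
        if counts.sum() == 0:
            raise DomainError("cannot normalize empty counts without smoothing")
        probs = counts / counts.sum()
    return RatingDistribution(image_id, attribute, condition, counts, probs)


def kl_divergence(g: RatingDistribution, c: RatingDistribution,
                  threshold: float = KL_THRESHOLD) -> KLResult:
    """D_KL(G || C) = sum_x G(x) ln(G(x) / C(x)) in nats.

    ``g`` is the grayscale-condition distribution, ``c`` the color one; the
    direction matters (the divergence is asymmetric).
    """
    if (g.image_id, g.attribute) != (c.image_id, c.attribute):
        raise AlignmentError(
            f"key mismatch: ({g.image_id}, {g.attribute}) vs ({c.image_id}, {c.attribute})"
        )
    if g.condition == c.condition:
        raise AlignmentError("distributions must come from opposite conditions")
    if (g.probs <= 0).any() or (c.probs <= 0).any():
        raise DomainError("KL requires strictly positive probabilities (use smoothing)")
    d = float(np.sum(g.probs * np.log(g.probs / c.probs)))
    d = max(d, 0.0)  # guard tiny negative rounding
    return KLResult(g.image_id, g.attribute, d, d > threshold)


def kl_summary(results: Sequence[KLResult], threshold: float = KL_THRESHOLD) -> dict:
    """Per-attribute empirical CDF support and fraction with D_KL > threshold."""
    by_attr: dict = {}
    for r in results:
        by_attr.setdefault(r.attribute, []).append(r.d_kl)
    summary = {}
    for attribute, values in by_attr.items():
        arr = np.sort(np.asarray(values))
        summary[attribute] = {
            "n": int(arr.size),
            "cdf_x": arr.tolist(),
            "cdf_y": (np.arange(1, arr.size + 1) / arr.size).tolist(),
            "fraction_exceeding": float(np.mean(arr > threshold)),
        }
    return summary


def sample_skewness(sample: np.ndarray) -> tuple[float, bool]:
    """Adjusted Fisher-Pearson sample skewness; constant samples map to 0."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise DomainError("empty sample")
    if np.all(sample == sample[0]) or sample.size < 3:
        return 0.0, True
    return float(stats.skew(sample, bias=False)), False


def skewness_shift(
    ratings_color, ratings_gray, image_id: str = "", attribute: str = ""
) -> SkewnessShift:
    """D_s = s_color - s_gray, the between-condition skewness difference."""
    s_c, deg_c = sample_skewness(ratings_color)
    s_g, deg_g = sample_skewness(ratings_gray)
    return SkewnessShift(image_id, attribute, s_c, s_g, deg_c, deg_g)


def _kendall(x: np.ndarray, y: np.ndarray, alpha: float) -> CorrelationResult:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(("x", "y"), float("nan"), float("nan"), False, alpha, True)
    tau, p = stats.kendalltau(x, y)  # tau-b, tie-corrected
    return CorrelationResult(("x", "y"), float(tau), float(p), bool(p < alpha), alpha)


def tau_vs_opacity(
    mean_ratings: Mapping, opaque_votes: Mapping, alpha: float = 0.05
) -> CorrelationResult:
    """Kendall tau-b between per-image mean ratings and opaque-vote counts."""
    mean_ratings = pd.Series(mean_ratings)
    opaque_votes = pd.Series(opaque_votes)
    if set(mean_ratings.index) != set(opaque_votes.index):
        raise AlignmentError("mean ratings and votes cover different images")
    if len(mean_ratings) < 3:
        raise DomainError("need at least 3 images")
    opaque_votes = opaque_votes.loc[mean_ratings.index]
    res = _kendall(mean_ratings.to_numpy(float), opaque_votes.to_numpy(float), alpha)
    return dataclasses.replace(res, pair=("mean_rating", "opaque_votes"))


def bonferroni_alpha(n_variables: int = 5, family_alpha: float = 0.05) -> float:
    """Bonferroni-adjusted per-test alpha over all unordered variable pairs."""
    n_pairs = n_variables * (n_variables - 1) // 2
    return family_alpha / n_pairs


@dataclasses.dataclass(frozen=True)
class CorrelationMatrix:
    tau: pd.DataFrame
    p_value: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    degenerate_attributes: tuple


def attribute_correlation_matrix(
    mean_ratings: pd.DataFrame, alpha: Optional[float] = None
) -> CorrelationMatrix:
    """Kendall tau-b matrix between mean attribute ratings across images.

    Significance uses the Bonferroni-adjusted alpha (0.05 / 10 = 0.005 for
    the five attributes) unless overridden.
    """
    attrs = [a for a in ATTRIBUTES if a in mean_ratings.columns]
    if len(attrs) != len(ATTRIBUTES):
        raise DomainError("mean ratings table must contain all 5 attributes")
    if len(mean_ratings) < 3:
        raise DomainError("need at least 3 images")
    if alpha is None:
        alpha = bonferroni_alpha(len(attrs))
    k = len(attrs)
    tau = np.eye(k)
    pval = np.zeros((k, k))
    sig = np.eye(k, dtype=bool)
    degenerate = []
    cols = {a: mean_ratings[a].to_numpy(float) for a in attrs}
    for a in attrs:
        if np.all(cols[a] == cols[a][0]):
            degenerate.append(a)
    for i in range(k):
        for j in range(i + 1, k):
            if attrs[i] in degenerate or attrs[j] in degenerate:
                tau[i, j] = tau[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            res = _kendall(cols[attrs[i]], cols[attrs[j]], alpha)
            tau[i, j] = tau[j, i] = res.tau
            pval[i, j] = pval[j, i] = res.p_value
            sig[i, j] = sig[j, i] = res.significant
    idx = pd.Index(attrs)
    return CorrelationMatrix(
        pd.DataFrame(tau, idx, idx),
        pd.DataFrame(pval, idx, idx),
        pd.DataFrame(sig, idx, idx),
        alpha,
        tuple(degenerate),
    )
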