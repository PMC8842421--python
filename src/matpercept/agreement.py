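"""Binary-classification agreement statistics.

Percent agreement, 60%-threshold T/U/O labels and label flips between
conditions, normalized-Hamming representational dissimilarity matrices,
pairwise Cohen's kappa with agreement-level binning, and one-sided
Mann-Whitney U comparisons of matrix regions.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .core_data import (
    AlignmentError,
    DomainError,
    ParameterError,
    ResponsePanel,
    ResponseVector,
    VoteCount,
)

LABELS = ("T", "O", "U")

#: Kappa agreement-level bins: half-open, contiguous cover of the printed
#: ranges; the top bin is closed so kappa == 1 maps to "strong".
KAPPA_BINS = (
    ("none", 0.0, 0.20),
    ("minimal", 0.20, 0.40),
    ("weak", 0.40, 0.60),
    ("moderate", 0.60, 0.80),
    ("strong", 0.80, 1.0),
)

FLIP_TYPES = ("T->O", "O->T", "T->U", "U->T", "O->U", "U->O", "none")


@dataclasses.dataclass(frozen=True)
class ImageLabel:
    image_id: str
    label: str
    condition: str


@dataclasses.dataclass(frozen=True)
class FlipRecord:
    image_id: str
    label_color: str
    label_gray: str

    @property
    def flip_type(self) -> str:
        if self.label_color == self.label_gray:
            return "none"
        return f"{self.label_color}->{self.label_gray}"


@dataclasses.dataclass(frozen=True)
class RDM:
    """Symmetric dissimilarity matrix over an ordered identifier axis."""

    axis: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.axis), len(self.axis)):
            raise AlignmentError("RDM axis/matrix shape mismatch")
        if not np.allclose(values, values.T):
            raise AlignmentError("RDM must be symmetric")
        object.__setattr__(self, "values", values)

    def upper_triangle(self, subset: Optional[Sequence] = None) -> np.ndarray:
        """Off-diagonal upper-triangle entries, optionally of a sub-block."""
        if subset is None:
            matrix = self.values
        else:
            idx = [self.axis.index(s) for s in subset]
            matrix = self.values[np.ix_(idx, idx)]
        iu = np.triu_indices(matrix.shape[0], k=1)
        return matrix[iu]


@dataclasses.dataclass(frozen=True)
class KappaResult:
    observer_a: str
    observer_b: str
    kappa: float
    p_observed: float
    p_chance: float
    level: str
    below_chance: bool = False
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class KappaMatrix:
    observers: tuple
    values: np.ndarray
    level_fractions: dict
    degenerate_pairs: tuple

    def mean_offdiagonal(self) -> float:
        iu = np.triu_indices(len(self.observers), k=1)
        return float(self.values[iu].mean())


@dataclasses.dataclass(frozen=True)
class MWUResult:
    statistic: float
    p_value: float
    alternative: str
    method: str
    all_tied: bool = False


def percent_agreement(vote: VoteCount) -> float:
    """Majority fraction max(N_o, N_t) / N; always in [0.5, 1]."""
    if vote.n_total == 0:
        raise DomainError(f"image {vote.image_id!r}: no votes")
    return max(vote.n_opaque, vote.n_translucent) / vote.n_total


def assign_label(vote: VoteCount, threshold: float = 0.6, condition: str = "color") -> ImageLabel:
    """Label an image T/O/U by whether either side reaches the vote threshold.

    The comparison is exact-rational so that e.g. 12/20 >= 0.6 holds.
    """
    if vote.n_total == 0:
        raise DomainError(f"image {vote.image_id!r}: no votes")
    thr = Fraction(str(threshold))
    if not Fraction(1, 2) < thr <= 1:
        raise ParameterError(f"threshold {threshold} must satisfy 0.5 < t <= 1")
    if Fraction(vote.n_translucent, vote.n_total) >= thr:
        label = "T"
    elif Fraction(vote.n_opaque, vote.n_total) >= thr:
        label = "O"
    else:
        label = "U"
    return ImageLabel(vote.image_id, label, condition)


def label_panel(panel: ResponsePanel, threshold: float = 0.6) -> dict:
    """T/U/O label for every image of a panel."""
    return {
        v.image_id: assign_label(v, threshold, panel.condition)
        for v in panel.vote_counts()
    }


def flip_table(labels_color: dict, labels_gray: dict) -> tuple[list, Counter]:
    """Per-image flip records between conditions plus per-type counts."""
    if set(labels_color) != set(labels_gray):
        raise AlignmentError("label sets cover different images")
    records = [
        FlipRecord(i, labels_color[i].label, labels_gray[i].label)
        for i in sorted(labels_color)
    ]
    counts = Counter(r.flip_type for r in records)
    for t in FLIP_TYPES:
        counts.setdefault(t, 0)
    return records, counts


def _as_matrix(vectors: Union[pd.DataFrame, Sequence[ResponseVector]]) -> tuple[tuple, np.ndarray]:
    if isinstance(vectors, pd.DataFrame):
        return tuple(vectors.index), vectors.to_numpy()
    ids = tuple(v.image_id for v in vectors)
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise AlignmentError(f"response vectors have unequal lengths {sorted(lengths)}")
    return ids, np.stack([v.labels for v in vectors])


def hamming_rdm(vectors, axis: str = "image") -> RDM:
    """Normalized-Hamming RDM over images (default) or observers.

    ``vectors`` is either a list of :class:`ResponseVector` (one per image)
    or a panel's images x observers binary DataFrame.  ``axis="observer"``
    transposes the response matrix first.
    """
    ids, matrix = _as_matrix(vectors)
    if axis == "observer":
        if not isinstance(vectors, pd.DataFrame):
            raise ParameterError("axis='observer' requires a panel binary DataFrame")
        ids, matrix = tuple(vectors.columns), matrix.T
    elif axis != "image":
        raise ParameterError(f"axis must be 'image' or 'observer', got {axis!r}")
    if matrix.shape[1] == 0:
        raise AlignmentError("empty response vectors")
    distances = squareform(pdist(matrix, metric="hamming"))
    return RDM(ids, distances)


def kappa_level(kappa: float) -> tuple[str, bool]:
    """Map kappa to its agreement-level bin; below-chance values map to none."""
    if kappa < 0:
        return "none", True
    for name, lo, hi in KAPPA_BINS:
        if lo <= kappa < hi:
            return name, False
    return "strong", False  # kappa == 1.0 (upper closure)


def cohen_kappa(a, b, observer_a: str = "a", observer_b: str = "b") -> KappaResult:
    """Cohen's kappa = (P_a - P_e) / (1 - P_e) for two binary raters.

    P_e is the chance agreement from the raters' marginal label frequencies.
    Degenerate cases (a constant rater) are flagged; two identical constant
    raters give kappa 1, two different constant raters give kappa 0.
    """
    x = a.labels if isinstance(a, ResponseVector) else np.asarray(a)
    y = b.labels if isinstance(b, ResponseVector) else np.asarray(b)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError("rater vectors must be 1-D and equal length")
    if x.size < 2:
        raise DomainError("need at least 2 rated items")
    p_a = float((x == y).mean())
    px, py = float(np.mean(x)), float(np.mean(y))
    p_e = px * py + (1 - px) * (1 - py)
    degenerate = px in (0.0, 1.0) or py in (0.0, 1.0)
    if p_e >= 1.0:
        kappa = 1.0 if p_a == 1.0 else 0.0
        degenerate = True
    else:
        kappa = (p_a - p_e) / (1 - p_e)
    level, below = kappa_level(kappa)
    return KappaResult(observer_a, observer_b, kappa, p_a, p_e, level, below, degenerate)


def kappa_matrix(panel_or_frame) -> KappaMatrix:
    """Pairwise observer kappa matrix plus fraction of pairs per level."""
    frame = panel_or_frame.binary if isinstance(panel_or_frame, ResponsePanel) else panel_or_frame
    observers = tuple(frame.columns)
    if len(observers) < 2:
        raise DomainError("need at least 2 observers")
    data = frame.to_numpy().T  # observers x images
    n = len(observers)
    values = np.ones((n, n))
    level_counts: Counter = Counter()
    degenerate = []
    for i in range(n):
        for j in range(i + 1, n):
            res = cohen_kappa(data[i], data[j], observers[i], observers[j])
            values[i, j] = values[j, i] = res.kappa
            level_counts[res.level] += 1
            if res.degenerate:
                degenerate.append((observers[i], observers[j]))
    n_pairs = n * (n - 1) // 2
    fractions = {name: level_counts.get(name, 0) / n_pairs for name, _, _ in KAPPA_BINS}
    return KappaMatrix(observers, values, fractions, tuple(degenerate))


def compare_distributions_mwu(x, y, alternative: str = "less") -> MWUResult:
    """One-sided (or two-sided) Mann-Whitney U comparison of two samples.

    Exact p for small tie-free samples (both n <= 8), otherwise the normal
    approximation with tie correction.  If every value across both samples
    is identical the test is vacuous and p = 1 is returned with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be non-empty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MWUResult(x.size * y.size / 2, 1.0, alternative, "degenerate", True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    return MWUResult(float(res.statistic), float(res.pvalue), alternative, method)


def compare_rdm_regions(
    rdm_color: RDM, rdm_gray: RDM, subset: Optional[Sequence] = None
) -> MWUResult:
    """One-sided test that a grayscale RDM region exceeds the color region.

    Samples are the off-diagonal upper-triangle cells of the (sub-)block;
    p-values are descriptive (cells are not independent).
    """
    x = rdm_color.upper_triangle(subset)
    y = rdm_gray.upper_triangle(subset)
    return compare_distributions_mwu(x, y, alternative="less")
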