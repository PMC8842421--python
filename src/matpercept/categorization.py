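"""Material-categorization analyses.

Fine-to-major category regrouping, misjudgment counts against ground truth,
food vs. non-food binarization, and person-by-person categorical RDMs.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .agreement import MWUResult, RDM, compare_distributions_mwu
from .core_data import FINE_CATEGORIES, AlignmentError, DomainError

MAJOR_CATEGORIES = (
    "food in general",
    "soap",
    "marble/stone/concrete/ivory",
    "glass",
    "crystal/quartz/mineral/jade",
    "plastic/synthetic/rubber",
    "wax",
    "metal",
)

DISCARDED = frozenset({"chalk", "wood"})


@dataclasses.dataclass(frozen=True)
class CategoryScheme:
    fine: tuple
    major: tuple
    fine_to_major: Mapping[str, str]
    discarded: frozenset
    food_map: Mapping[str, str]

    def regroup(self, fine_category: str) -> Optional[str]:
        """Major group of a fine category; None for discarded names."""
        if fine_category in self.discarded:
            return None
        if fine_category in self.major:   # projection: idempotent on majors
            return fine_category
        return self.fine_to_major[fine_category]

    def food_label(self, category: str) -> Optional[str]:
        major = self.regroup(category)
        return None if major is None else self.food_map[major]


@dataclasses.dataclass(frozen=True)
class MisjudgmentCount:
    image_id: str
    condition: str
    n_incorrect: int


def build_scheme() -> CategoryScheme:
    """The fixed regrouping: 7 food/* names merge into "food in general",
    ivory joins marble/stone/concrete, rubber joins plastic/synthetic,
    chalk and wood are discarded; only "food in general" counts as food."""
    fine_to_major = {}
    for name in FINE_CATEGORIES:
        if name in DISCARDED:
            continue
        if name == "food in general" or name.startswith("food/"):
            fine_to_major[name] = "food in general"
        elif name in ("marble/stone/concrete", "ivory"):
            fine_to_major[name] = "marble/stone/concrete/ivory"
        elif name in ("plastic/synthetic", "rubber"):
            fine_to_major[name] = "plastic/synthetic/rubber"
        else:
            fine_to_major[name] = name
    food_map = {m: ("food" if m == "food in general" else "non-food") for m in MAJOR_CATEGORIES}
    return CategoryScheme(FINE_CATEGORIES, MAJOR_CATEGORIES, fine_to_major, DISCARDED, food_map)


@dataclasses.dataclass(frozen=True)
class MisjudgmentResult:
    counts: pd.DataFrame                 # image_id, condition, major_group, n_incorrect
    mwu_overall: Optional[MWUResult]     # color < grayscale; None if one condition
    mwu_per_group: Mapping[str, MWUResult]
    excluded_images: tuple


def misjudgment_counts(
    categories: pd.DataFrame, scheme: CategoryScheme, ground_truth: pd.Series
) -> MisjudgmentResult:
    """Per-image counts of observers whose major-group choice misses ground truth.

    ``categories`` needs columns condition, observer_id, image_id, category.
    Images whose ground truth is discarded (chalk/wood) or missing are
    excluded; the condition comparison is a one-sided Mann-Whitney U test of
    color counts against grayscale counts.
    """
    excluded = []
    rows = []
    images = sorted(set(categories["image_id"]))
    for image in images:
        if image not in ground_truth.index:
            warnings.warn(f"image {image!r} lacks ground truth; excluded")
            excluded.append(image)
            continue
        gt_major = scheme.regroup(ground_truth.loc[image])
        if gt_major is None:
            excluded.append(image)
            continue
        sub = categories[categories["image_id"] == image]
        for condition, group in sub.groupby("condition"):
            chosen = group["category"].map(scheme.regroup)
            rows.append(
                {
                    "image_id": image,
                    "condition": condition,
                    "major_group": gt_major,
                    "n_incorrect": int((chosen != gt_major).sum()),
                }
            )
    counts = pd.DataFrame(rows)
    if counts.empty:
        raise DomainError("no scorable images")
    color = counts.loc[counts["condition"] == "color", "n_incorrect"]
    gray = counts.loc[counts["condition"] == "grayscale", "n_incorrect"]
    # single-condition input: no between-condition comparison possible
    overall = (
        compare_distributions_mwu(color, gray, alternative="less")
        if len(color) and len(gray)
        else None
    )
    per_group = {}
    for major, sub in counts.groupby("major_group"):
        c = sub.loc[sub["condition"] == "color", "n_incorrect"]
        g = sub.loc[sub["condition"] == "grayscale", "n_incorrect"]
        if len(c) and len(g):
            per_group[major] = compare_distributions_mwu(c, g, alternative="less")
    return MisjudgmentResult(counts, overall, per_group, tuple(excluded))


def food_nonfood_table(categories: pd.DataFrame, scheme: CategoryScheme) -> pd.DataFrame:
    """Stacked food / non-food observer counts per image and condition.

    Discarded fine categories (chalk, wood) contribute to neither stack, so
    the two columns sum to the number of observers who picked a scorable
    category for that image.
    """
    frame = categories.copy()
    frame["food_label"] = frame["category"].map(scheme.food_label)
    frame = frame.dropna(subset=["food_label"])
    table = (
        frame.groupby(["image_id", "condition", "food_label"])
        .size()
        .unstack("food_label", fill_value=0)
        .reindex(columns=["food", "non-food"], fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    return table


def category_person_rdm(categories: pd.DataFrame, condition: str) -> RDM:
    """Observer x observer RDM: fraction of images with different fine choices."""
    sub = categories
    if "condition" in categories.columns:
        sub = categories[categories["condition"] == condition]
    if sub.empty:
        raise DomainError(f"no categorization records for condition {condition!r}")
    wide = sub.pivot(index="observer_id", columns="image_id", values="category")
    if wide.isna().any().any():
        raise AlignmentError("observers categorized different image sets")
    codes = wide.apply(lambda col: pd.Categorical(col).codes, axis=0).to_numpy()
    distances = squareform(pdist(codes, metric="hamming"))
    return RDM(tuple(wide.index), distances)
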