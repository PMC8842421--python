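"""Domain types, validation, and delimited-text I/O for observer-response panels.

A *panel* bundles everything one observer group produced under one viewing
condition: per-image binary translucent/opaque votes, five-attribute Likert
ratings, and (for a subset of observers) material-category choices, plus an
optional ground-truth category map.  Panels are stored as a directory of
plain CSV files so fixtures stay diffable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("color", "grayscale")

#: The five semantic attributes, fixed order.
ATTRIBUTES = ("see_throughness", "glossiness", "softness", "glow", "density")

LIKERT_MIN, LIKERT_MAX = 1, 6

#: The closed 18-name material vocabulary shown to observers.
FINE_CATEGORIES = (
    "food in general",
    "food/cheese",
    "food/fruit/vegetables",
    "food/gummi/jelly",
    "food/meat/seafood",
    "food/candy/sugar",
    "food/shaved ice/ice cream/cream",
    "crystal/quartz/mineral/jade",
    "glass",
    "ivory",
    "marble/stone/concrete",
    "plastic/synthetic",
    "rubber",
    "soap",
    "wax",
    "wood",
    "chalk",
    "metal",
)

_BINARY_FILE = "binary.csv"
_RATINGS_FILE = "ratings.csv"
_CATEGORIES_FILE = "categories.csv"
_GROUND_TRUTH_FILE = "ground_truth.csv"


class PanelFormatError(ValueError):
    """A response file is structurally malformed (missing columns, bad path)."""


class PanelValidationError(ValueError):
    """A record violates a domain invariant; the message locates the record."""


class AlignmentError(ValueError):
    """Two inputs that must share an axis (images, observers) do not."""


class DomainError(ValueError):
    """An operation received input outside its mathematical domain."""


class ParameterError(ValueError):
    """A caller-supplied parameter is out of range."""


def _check_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise PanelValidationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return condition


@dataclasses.dataclass(frozen=True)
class ResponseVector:
    """One image's binary votes across the ordered observer axis."""

    image_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 1 or labels.size == 0:
            raise PanelValidationError(
                f"image {self.image_id!r}: labels must be a non-empty 1-D array"
            )
        if not np.isin(labels, (0, 1)).all():
            raise PanelValidationError(
                f"image {self.image_id!r}: labels must be binary (0/1)"
            )
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclasses.dataclass(frozen=True)
class VoteCount:
    """Tally of translucent vs. opaque votes for one image."""

    image_id: str
    n_translucent: int
    n_opaque: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_translucent, self.n_opaque, self.n_total) < 0:
            raise PanelValidationError(f"image {self.image_id!r}: negative count")
        if self.n_translucent + self.n_opaque != self.n_total:
            raise PanelValidationError(
                f"image {self.image_id!r}: counts do not sum "
                f"({self.n_translucent}+{self.n_opaque} != {self.n_total})"
            )

    @classmethod
    def from_vector(cls, vector: ResponseVector) -> "VoteCount":
        n_t = int(vector.labels.sum())
        return cls(vector.image_id, n_t, len(vector) - n_t, len(vector))


@dataclasses.dataclass(frozen=True)
class RatingRecord:
    """One observer's five Likert ratings for one image."""

    observer_id: str
    image_id: str
    condition: str
    ratings: Mapping[str, int]

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        missing = set(ATTRIBUTES) - set(self.ratings)
        if missing:
            raise PanelValidationError(
                f"observer {self.observer_id!r}, image {self.image_id!r}: "
                f"missing attributes {sorted(missing)}"
            )
        for attr in ATTRIBUTES:
            value = self.ratings[attr]
            if not (isinstance(value, (int, np.integer)) and LIKERT_MIN <= value <= LIKERT_MAX):
                raise PanelValidationError(
                    f"observer {self.observer_id!r}, image {self.image_id!r}, "
                    f"attribute {attr!r}: rating {value!r} outside "
                    f"{LIKERT_MIN}..{LIKERT_MAX}"
                )


@dataclasses.dataclass(frozen=True)
class CategoryRecord:
    """One observer's material-category choice for one image."""

    observer_id: str
    image_id: str
    condition: str
    category: str

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        if self.category not in FINE_CATEGORIES:
            raise PanelValidationError(
                f"observer {self.observer_id!r}, image {self.image_id!r}: "
                f"unknown category {self.category!r}"
            )


@dataclasses.dataclass
class ResponsePanel:
    """All responses of one observer group under one condition.

    Attributes
    ----------
    condition : str
        ``"color"`` or ``"grayscale"``.
    binary : pandas.DataFrame
        Images (rows, sorted) x observers (columns, sorted), entries 0/1.
    ratings : pandas.DataFrame
        Columns ``observer_id``, ``image_id`` plus one integer column per
        attribute; one row per (observer, image).
    categories : pandas.DataFrame or None
        Columns ``observer_id``, ``image_id``, ``category``.  The observer
        set may be a subset of the binary observers.
    ground_truth : pandas.Series or None
        Image id -> fine category.
    """

    condition: str
    binary: pd.DataFrame
    ratings: pd.DataFrame
    categories: Optional[pd.DataFrame] = None
    ground_truth: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        self.binary = self.binary.sort_index(axis=0).sort_index(axis=1).astype(np.int8)
        self.binary.index.name = "image_id"
        self.binary.columns.name = "observer_id"
        if not np.isin(self.binary.to_numpy(), (0, 1)).all():
            raise PanelValidationError("binary matrix contains non-binary entries")
        if self.binary.columns.duplicated().any() or self.binary.index.duplicated().any():
            raise PanelValidationError("duplicate observer or image identifiers")
        self.ratings = (
            self.ratings.sort_values(["observer_id", "image_id"], kind="mergesort")
            .reset_index(drop=True)
        )
        self._validate_ratings()
        if self.categories is not None and len(self.categories):
            self.categories = (
                self.categories.sort_values(["observer_id", "image_id"], kind="mergesort")
                .reset_index(drop=True)
            )
            self._validate_categories()
        elif self.categories is not None and not len(self.categories):
            self.categories = None
        if self.ground_truth is not None:
            self.ground_truth = self.ground_truth.sort_index()
            bad = set(self.ground_truth) - set(FINE_CATEGORIES)
            if bad:
                raise PanelValidationError(f"ground truth uses unknown categories {sorted(bad)}")

    def _validate_ratings(self) -> None:
        required = {"observer_id", "image_id", *ATTRIBUTES}
        missing = required - set(self.ratings.columns)
        if missing:
            raise PanelFormatError(f"ratings table missing columns {sorted(missing)}")
        values = self.ratings[list(ATTRIBUTES)].to_numpy()
        bad = (values < LIKERT_MIN) | (values > LIKERT_MAX)
        if bad.any():
            row = int(np.argwhere(bad.any(axis=1))[0][0])
            rec = self.ratings.iloc[row]
            raise PanelValidationError(
                f"ratings row {row} (observer {rec['observer_id']!r}, image "
                f"{rec['image_id']!r}): rating outside {LIKERT_MIN}..{LIKERT_MAX}"
            )
        unknown_obs = set(self.ratings["observer_id"]) - set(self.binary.columns)
        if unknown_obs:
            raise PanelValidationError(f"rating observers not in panel: {sorted(unknown_obs)}")
        unknown_img = set(self.ratings["image_id"]) - set(self.binary.index)
        if unknown_img:
            raise PanelValidationError(
                f"rated images without a binary response vector: {sorted(unknown_img)[:5]}"
            )

    def _validate_categories(self) -> None:
        required = {"observer_id", "image_id", "category"}
        missing = required - set(self.categories.columns)
        if missing:
            raise PanelFormatError(f"categories table missing columns {sorted(missing)}")
        bad = ~self.categories["category"].isin(FINE_CATEGORIES)
        if bad.any():
            row = int(np.argwhere(bad.to_numpy())[0][0])
            rec = self.categories.iloc[row]
            raise PanelValidationError(
                f"categories row {row} (observer {rec['observer_id']!r}, image "
                f"{rec['image_id']!r}): unknown category {rec['category']!r}"
            )
        if not set(self.categories["observer_id"]) <= set(self.binary.columns):
            raise PanelValidationError("categorization observers must be a subset of binary observers")
        if not set(self.categories["image_id"]) <= set(self.binary.index):
            raise PanelValidationError("categorized images must have binary response vectors")

    # -- accessors ---------------------------------------------------------

    @property
    def observers(self) -> tuple:
        return tuple(self.binary.columns)

    @property
    def images(self) -> tuple:
        return tuple(self.binary.index)

    @property
    def n_observers(self) -> int:
        return self.binary.shape[1]

    def response_vector(self, image_id: str) -> ResponseVector:
        return ResponseVector(image_id, self.binary.loc[image_id].to_numpy())

    def vote_count(self, image_id: str) -> VoteCount:
        return VoteCount.from_vector(self.response_vector(image_id))

    def vote_counts(self) -> list:
        return [self.vote_count(i) for i in self.images]

    def mean_ratings(self) -> pd.DataFrame:
        """Per-image mean of each attribute, images x attributes."""
        return (
            self.ratings.groupby("image_id")[list(ATTRIBUTES)].mean().sort_index()
        )

    def observer_slice(self, observer_id: str) -> tuple[pd.DataFrame, pd.Series]:
        """(image x attribute ratings, binary labels) for one observer."""
        if observer_id not in self.binary.columns:
            raise KeyError(observer_id)
        sub = (
            self.ratings[self.ratings["observer_id"] == observer_id]
            .set_index("image_id")[list(ATTRIBUTES)]
            .sort_index()
        )
        labels = self.binary.loc[sub.index, observer_id]
        return sub, labels

    def iter_rating_records(self) -> Iterable[RatingRecord]:
        for _, row in self.ratings.iterrows():
            yield RatingRecord(
                str(row["observer_id"]),
                str(row["image_id"]),
                self.condition,
                {a: int(row[a]) for a in ATTRIBUTES},
            )


def panel_from_arrays(
    condition: str,
    observers: Sequence[str],
    images: Sequence[str],
    binary: np.ndarray,
    ratings: Optional[pd.DataFrame] = None,
    categories: Optional[pd.DataFrame] = None,
    ground_truth: Optional[pd.Series] = None,
) -> ResponsePanel:
    """Assemble a panel from an images x observers 0/1 array plus long tables."""
    frame = pd.DataFrame(np.asarray(binary), index=list(images), columns=list(observers))
    if ratings is None:
        ratings = pd.DataFrame(columns=["observer_id", "image_id", *ATTRIBUTES])
    return ResponsePanel(condition, frame, ratings, categories, ground_truth)


def read_panel(path, condition: str) -> ResponsePanel:
    """Read a panel directory (binary/ratings/categories CSVs) for one condition."""
    _check_condition(condition)
    root = Path(path)
    binary_path = root / _BINARY_FILE
    ratings_path = root / _RATINGS_FILE
    if not binary_path.exists():
        raise PanelFormatError(f"missing {binary_path}")
    binary_long = pd.read_csv(binary_path, dtype={"observer_id": str, "image_id": str})
    for col in ("condition", "observer_id", "image_id", "label"):
        if col not in binary_long.columns:
            raise PanelFormatError(f"{binary_path}: missing column {col!r}")
    binary_long = binary_long[binary_long["condition"] == condition]
    if binary_long.empty:
        raise PanelFormatError(f"{binary_path}: no rows for condition {condition!r}")
    if not np.isin(binary_long["label"].to_numpy(), (0, 1)).all():
        bad = binary_long[~binary_long["label"].isin((0, 1))].index[0]
        raise PanelValidationError(f"{binary_path}: non-binary label at row {bad}")
    binary = binary_long.pivot(index="image_id", columns="observer_id", values="label")
    if binary.isna().any().any():
        raise PanelValidationError(f"{binary_path}: incomplete observer x image grid")

    if ratings_path.exists():
        ratings = pd.read_csv(ratings_path, dtype={"observer_id": str, "image_id": str})
        missing = {"condition", "observer_id", "image_id", *ATTRIBUTES} - set(ratings.columns)
        if missing:
            raise PanelFormatError(f"{ratings_path}: missing columns {sorted(missing)}")
        ratings = ratings[ratings["condition"] == condition].drop(columns="condition")
    else:
        ratings = pd.DataFrame(columns=["observer_id", "image_id", *ATTRIBUTES])

    categories = None
    categories_path = root / _CATEGORIES_FILE
    if categories_path.exists():
        categories = pd.read_csv(categories_path, dtype={"observer_id": str, "image_id": str})
        missing = {"condition", "observer_id", "image_id", "category"} - set(categories.columns)
        if missing:
            raise PanelFormatError(f"{categories_path}: missing columns {sorted(missing)}")
        categories = categories[categories["condition"] == condition].drop(columns="condition")
        if categories.empty:
            categories = None

    ground_truth = None
    gt_path = root / _GROUND_TRUTH_FILE
    if gt_path.exists():
        gt = pd.read_csv(gt_path, dtype={"image_id": str})
        if not {"image_id", "category"} <= set(gt.columns):
            raise PanelFormatError(f"{gt_path}: expected columns image_id, category")
        ground_truth = gt.set_index("image_id")["category"]

    return ResponsePanel(condition, binary, ratings, categories, ground_truth)


def write_panel(panel: ResponsePanel, path) -> None:
    """Write a panel to a directory of CSVs with canonical (observer, image) order."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    binary_long = (
        panel.binary.stack()
        .rename("label")
        .reset_index()
        .set_axis(["image_id", "observer_id", "label"], axis=1)
        .sort_values(["observer_id", "image_id"], kind="mergesort")
    )
    binary_long.insert(0, "condition", panel.condition)
    binary_long.to_csv(root / _BINARY_FILE, index=False)

    ratings = panel.ratings.copy()
    ratings.insert(0, "condition", panel.condition)
    ratings.to_csv(root / _RATINGS_FILE, index=False)

    if panel.categories is not None:
        categories = panel.categories.copy()
        categories.insert(0, "condition", panel.condition)
        categories.to_csv(root / _CATEGORIES_FILE, index=False)
    if panel.ground_truth is not None:
        panel.ground_truth.rename("category").rename_axis("image_id").reset_index().to_csv(
            root / _GROUND_TRUTH_FILE, index=False
        )
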