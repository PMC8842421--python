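"""Seeded generators for synthetic observer panels and translucent-cube images.

The panel generator emulates the statistical structure the analyses assume:
a latent per-image translucency score drives binary votes and the light-
transmission attributes (see-throughness, glow, glossiness); softness and
density come from an independent anti-correlated latent; the grayscale
condition attenuates the signal and inflates the noise, producing more
interobserver disagreement and label flips; material categories are drawn
from a confusion model with an extra food <-> non-food flip rate in
grayscale.  Defaults are tuning targets for the qualitative directional
findings, not measured facts.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core_data import (
    ATTRIBUTES,
    FINE_CATEGORIES,
    ParameterError,
    ResponsePanel,
    panel_from_arrays,
)

_FOOD_FINE = tuple(
    c for c in FINE_CATEGORIES if c == "food in general" or c.startswith("food/")
)
_NONFOOD_FINE = tuple(
    c for c in FINE_CATEGORIES if c not in _FOOD_FINE and c not in ("chalk", "wood")
)
_DISCARDED_FINE = ("chalk", "wood")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of the simulated study."""

    n_images: int = 300
    n_observers_binary: int = 20
    n_observers_category: int = 15
    #: loading of each attribute's latent on the shared translucency signal
    attribute_loadings: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "see_throughness": 0.95,
            "glow": 0.80,
            "glossiness": 0.60,
            "softness": 0.0,
            "density": 0.0,
        }
    )
    #: loading of softness (+) and density (-) on the independent latent
    hardness_loading: float = 0.8
    sigma_noise: float = 0.12
    sigma_criterion: float = 0.08
    alpha_gray: float = 0.7
    beta_gray: float = 1.5
    #: additive shift of each attribute's rating latent in grayscale
    rating_shift_gray: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "see_throughness": 0.0,
            "glossiness": -0.3,
            "softness": -0.3,
            "glow": -0.3,
            "density": -0.3,
        }
    )
    ordinal_thresholds: tuple = (-1.5, -0.5, 0.0, 0.5, 1.5)
    #: probability an observer's category choice misses the ground truth
    category_error_color: float = 0.15
    category_error_gray_increment: float = 0.15
    #: share of errors crossing the food / non-food boundary
    cross_food_share: float = 0.30
    cross_food_gray_increment: float = 0.20
    #: fraction of images whose ground truth is a discarded category
    discarded_fraction: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_images < 2:
            problems.append("n_images must be >= 2")
        if self.n_observers_binary < 2:
            problems.append("n_observers_binary must be >= 2")
        if not 0 < self.n_observers_category <= self.n_observers_binary:
            problems.append("n_observers_category must be in 1..n_observers_binary")
        if not 0 < self.alpha_gray <= 1:
            problems.append("alpha_gray must be in (0, 1]")
        if self.beta_gray < 1:
            problems.append("beta_gray must be >= 1")
        if self.sigma_noise <= 0 or self.sigma_criterion < 0:
            problems.append("noise scales must be positive")
        for name, value in self.attribute_loadings.items():
            if name not in ATTRIBUTES or not -1 <= value <= 1:
                problems.append(f"bad attribute loading {name}={value}")
        for name in self.rating_shift_gray:
            if name not in ATTRIBUTES:
                problems.append(f"unknown attribute in rating_shift_gray: {name}")
        if list(self.ordinal_thresholds) != sorted(self.ordinal_thresholds):
            problems.append("ordinal thresholds must be sorted")
        p_err_gray = self.category_error_color + self.category_error_gray_increment
        if not 0 <= self.category_error_color <= 1 or not 0 <= p_err_gray <= 1:
            problems.append("category error probabilities must be in [0, 1]")
        share_gray = self.cross_food_share + self.cross_food_gray_increment
        if not 0 <= self.cross_food_share <= 1 or not 0 <= share_gray <= 1:
            problems.append("cross-food shares must be in [0, 1]")
        if not 0 <= self.discarded_fraction < 1:
            problems.append("discarded_fraction must be in [0, 1)")
        if problems:
            raise ParameterError("; ".join(problems))


def _discretize(z: np.ndarray, thresholds) -> np.ndarray:
    """Probit-style 6-level ordinal discretization of a latent array."""
    return (np.searchsorted(np.asarray(thresholds), z, side="left") + 1).astype(np.int64)


def _condition_params(config: SyntheticConfig, condition: str) -> tuple[float, float]:
    if condition == "color":
        return 1.0, 1.0
    return config.alpha_gray, config.beta_gray


def _ground_truth_categories(config: SyntheticConfig, t: np.ndarray, rng) -> np.ndarray:
    """Assign a fine ground-truth category per image.

    Food categories concentrate at mid-to-high translucency so the
    grayscale food-misjudgment pattern has something to act on.
    """
    n = t.size
    gt = np.empty(n, dtype=object)
    discarded = rng.random(n) < config.discarded_fraction
    p_food = np.clip(0.2 + 0.6 * t, 0, 1)
    is_food = rng.random(n) < p_food
    for i in range(n):
        if discarded[i]:
            gt[i] = _DISCARDED_FINE[rng.integers(len(_DISCARDED_FINE))]
        elif is_food[i]:
            gt[i] = _FOOD_FINE[rng.integers(len(_FOOD_FINE))]
        else:
            gt[i] = _NONFOOD_FINE[rng.integers(len(_NONFOOD_FINE))]
    return gt


def _draw_categories(
    config: SyntheticConfig, condition: str, gt: np.ndarray, rng
) -> np.ndarray:
    """images x category-observers array of fine category choices."""
    n_obs = config.n_observers_category
    n_img = gt.size
    p_err = config.category_error_color
    cross = config.cross_food_share
    if condition == "grayscale":
        p_err += config.category_error_gray_increment
        cross += config.cross_food_gray_increment
    is_food_gt = np.isin(gt, _FOOD_FINE)
    choices = np.tile(gt[:, None], (1, n_obs)).astype(object)
    errs = rng.random((n_img, n_obs)) < p_err
    crossing = rng.random((n_img, n_obs)) < cross
    for i in range(n_img):
        gt_food = bool(is_food_gt[i])
        same_side = _FOOD_FINE if gt_food else _NONFOOD_FINE
        other_side = _NONFOOD_FINE if gt_food else _FOOD_FINE
        same_side = tuple(c for c in same_side if c != gt[i])
        for o in range(n_obs):
            if not errs[i, o]:
                continue
            pool = other_side if (crossing[i, o] or not same_side) else same_side
            choices[i, o] = pool[rng.integers(len(pool))]
    return choices


def _generate_condition(
    config: SyntheticConfig,
    condition: str,
    t: np.ndarray,
    hardness: np.ndarray,
    gt: np.ndarray,
    rng,
) -> ResponsePanel:
    alpha, beta = _condition_params(config, condition)
    n_img, n_obs = config.n_images, config.n_observers_binary
    prefix = "c" if condition == "color" else "g"
    observers = [f"{prefix}{k + 1:02d}" for k in range(n_obs)]
    images = [f"img{k + 1:03d}" for k in range(n_img)]

    t_centered = t - 0.5
    sigma_eps = config.sigma_noise * beta
    criteria = rng.normal(0.0, config.sigma_criterion, n_obs)
    u = alpha * t_centered[:, None] + rng.normal(0.0, sigma_eps, (n_img, n_obs))
    labels = (u > criteria[None, :]).astype(np.int8)

    # shared latent standardized so ordinal thresholds act on ~N(0,1)
    sd_u = np.sqrt(alpha**2 / 12.0 + sigma_eps**2)
    z_shared = u / sd_u
    rating_cols = {}
    for attr in ATTRIBUTES:
        lam = config.attribute_loadings.get(attr, 0.0)
        if attr in ("softness", "density"):
            h = config.hardness_loading
            sign = 1.0 if attr == "softness" else -1.0
            z = sign * h * hardness[:, None] + np.sqrt(max(1 - h**2, 0)) * rng.normal(
                0.0, 1.0, (n_img, n_obs)
            )
        else:
            z = lam * z_shared + np.sqrt(max(1 - lam**2, 0)) * rng.normal(
                0.0, 1.0, (n_img, n_obs)
            )
        if condition == "grayscale":
            z = z + config.rating_shift_gray.get(attr, 0.0)
        rating_cols[attr] = _discretize(z, config.ordinal_thresholds)

    obs_grid, img_grid = np.meshgrid(np.arange(n_obs), np.arange(n_img), indexing="ij")
    ratings = pd.DataFrame(
        {
            "observer_id": np.array(observers)[obs_grid.ravel()],
            "image_id": np.array(images)[img_grid.ravel()],
            **{a: rating_cols[a].T.ravel() for a in ATTRIBUTES},
        }
    )

    cat_choices = _draw_categories(config, condition, gt, rng)
    scorable = ~np.isin(gt, _DISCARDED_FINE)
    cat_obs = observers[: config.n_observers_category]
    cat_img_idx = np.where(scorable)[0]
    categories = pd.DataFrame(
        {
            "observer_id": np.repeat(cat_obs, cat_img_idx.size),
            "image_id": np.tile(np.array(images)[cat_img_idx], len(cat_obs)),
            "category": cat_choices[cat_img_idx].T.ravel(),
        }
    )
    ground_truth = pd.Series(gt[scorable], index=np.array(images)[cat_img_idx])

    return panel_from_arrays(condition, observers, images, labels, ratings, categories, ground_truth)


def generate_panel(config: Optional[SyntheticConfig] = None) -> tuple[ResponsePanel, ResponsePanel]:
    """Generate the (color, grayscale) panel pair for a config.

    Pure function of the config (including its seed): the same config yields
    identical panels.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = rng.uniform(0.0, 1.0, config.n_images)        # latent translucency
    hardness = rng.normal(0.0, 1.0, config.n_images)  # independent latent
    gt = _ground_truth_categories(config, t, rng)
    color = _generate_condition(config, "color", t, hardness, gt, rng)
    gray = _generate_condition(config, "grayscale", t, hardness, gt, rng)
    return color, gray


def pyramid_thickness(size: int = 96, margin: int = 8, height: float = 1.0) -> np.ndarray:
    """Square-pyramid thickness profile: zero outside the footprint, peaked center."""
    span = size - 2 * margin
    if span <= 0:
        raise ParameterError("margin too large for size")
    coords = np.arange(size)
    cx = (size - 1) / 2.0
    dx = np.abs(coords - cx)
    cheb = np.maximum(dx[:, None], dx[None, :])
    half = span / 2.0
    t = height * np.clip(1.0 - cheb / half, 0.0, None)
    return t


def generate_cube_image(
    thickness: Optional[np.ndarray] = None,
    sigma_e: float = 3.0,
    channel_extinction: tuple = (0.25, 0.45, 1.6),
    size: int = 96,
    seed: int = 0,
    noise_level: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a Beer-Lambert slab: white backlight through a colored medium.

    Per-pixel linear RGB is exp(-sigma_e * k_c * thickness); thin edges stay
    bright and desaturated, the thick center is dim and saturated, so
    saturation and luminance correlate negatively over the object mask.
    Returns (uint8 sRGB image, boolean mask).
    """
    from .colorimetry import srgb_encode

    if sigma_e <= 0:
        raise ParameterError("sigma_e must be positive")
    if thickness is None:
        thickness = pyramid_thickness(size)
    thickness = np.asarray(thickness, dtype=float)
    if (thickness < 0).any():
        raise ParameterError("thickness must be non-negative")
    mask = thickness > 0
    rng = np.random.default_rng(seed)
    noisy = thickness * (1.0 + noise_level * rng.standard_normal(thickness.shape))
    noisy = np.clip(noisy, 0.0, None)
    k = np.asarray(channel_extinction, dtype=float)
    linear = np.exp(-sigma_e * noisy[..., None] * k[None, None, :])
    linear[~mask] = 0.0  # black background
    return srgb_encode(linear), mask
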