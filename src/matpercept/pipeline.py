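"""End-to-end orchestration: agreement -> ratings -> space -> categorization.

``run_all`` executes the full analysis sequence on a (color, grayscale)
panel pair — loaded from disk or generated synthetically — and emits a
single JSON-serializable report containing every statistic family, all
seeds, and per-module metadata.  Runs are idempotent for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import agreement, categorization, perceptual_space, rating_stats
from .core_data import ATTRIBUTES, ParameterError, ResponsePanel, read_panel
from .synthetic import SyntheticConfig, generate_panel

logger = logging.getLogger("matpercept")


@dataclasses.dataclass
class RunConfig:
    color_path: Optional[str] = None
    gray_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    label_threshold: float = 0.6
    kl_threshold: float = 1.0
    alpha: float = 0.05
    alpha_correlation: float = 0.005
    perplexity: float = 15.0
    seed: int = 0
    include_tsne: bool = False
    output_dir: Optional[str] = None

    def validate(self) -> None:
        if not 0.5 < self.label_threshold <= 1:
            raise ParameterError("label_threshold must be in (0.5, 1]")
        if self.kl_threshold < 0 or not 0 < self.alpha < 1 or not 0 < self.alpha_correlation < 1:
            raise ParameterError("invalid threshold/alpha")
        have_paths = self.color_path is not None and self.gray_path is not None
        if not have_paths and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)


#: Minimal schema the report must satisfy (checked by validate_report).
REPORT_SCHEMA = {
    "required": [
        "meta",
        "labels",
        "flips",
        "kappa_summary",
        "kl_summary",
        "skewness_shift",
        "pca_variance",
        "prediction_accuracy",
        "categorization",
    ]
}


def validate_report(report: dict) -> None:
    missing = [k for k in REPORT_SCHEMA["required"] if k not in report]
    if missing:
        raise ValueError(f"report missing sections: {missing}")


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _load_panels(config: RunConfig) -> tuple[ResponsePanel, ResponsePanel]:
    if config.color_path and config.gray_path:
        return (
            read_panel(config.color_path, "color"),
            read_panel(config.gray_path, "grayscale"),
        )
    return generate_panel(config.synthetic)


def _agreement_stage(color, gray, config) -> dict:
    labels_c = agreement.label_panel(color, config.label_threshold)
    labels_g = agreement.label_panel(gray, config.label_threshold)
    _, flip_counts = agreement.flip_table(labels_c, labels_g)
    kappa_c = agreement.kappa_matrix(color)
    kappa_g = agreement.kappa_matrix(gray)
    rdm_c = agreement.hamming_rdm(color.binary)
    rdm_g = agreement.hamming_rdm(gray.binary)
    mwu_rdm = agreement.compare_rdm_regions(rdm_c, rdm_g)
    mwu_kappa = agreement.compare_distributions_mwu(
        kappa_g.values[np.triu_indices(len(kappa_g.observers), 1)],
        kappa_c.values[np.triu_indices(len(kappa_c.observers), 1)],
        alternative="less",
    )
    return {
        "labels": {
            "color": {i: l.label for i, l in sorted(labels_c.items())},
            "grayscale": {i: l.label for i, l in sorted(labels_g.items())},
        },
        "flips": {
            "counts": dict(sorted(flip_counts.items())),
            "n_flipped": sum(v for k, v in flip_counts.items() if k != "none"),
        },
        "kappa_summary": {
            "color": {
                "mean_offdiagonal": kappa_c.mean_offdiagonal(),
                "level_fractions": kappa_c.level_fractions,
            },
            "grayscale": {
                "mean_offdiagonal": kappa_g.mean_offdiagonal(),
                "level_fractions": kappa_g.level_fractions,
            },
            "mwu_gray_below_color": dataclasses.asdict(mwu_kappa),
        },
        "rdm": {
            "color_mean": float(rdm_c.upper_triangle().mean()),
            "grayscale_mean": float(rdm_g.upper_triangle().mean()),
            "mwu_color_below_gray": dataclasses.asdict(mwu_rdm),
        },
    }


def _ratings_stage(color, gray, config) -> dict:
    images = sorted(set(color.ratings["image_id"]) & set(gray.ratings["image_id"]))
    kl_results = []
    shifts = []
    for attr in ATTRIBUTES:
        for image in images:
            dist_c = rating_stats.rating_distribution(color.ratings, image, attr, "color")
            dist_g = rating_stats.rating_distribution(gray.ratings, image, attr, "grayscale")
            kl_results.append(rating_stats.kl_divergence(dist_g, dist_c, config.kl_threshold))
            shifts.append(
                rating_stats.skewness_shift(
                    color.ratings.loc[color.ratings["image_id"] == image, attr],
                    gray.ratings.loc[gray.ratings["image_id"] == image, attr],
                    image,
                    attr,
                )
            )
    kl_summary = rating_stats.kl_summary(kl_results, config.kl_threshold)
    # trim CDF supports for report size
    for entry in kl_summary.values():
        entry.pop("cdf_x", None)
        entry.pop("cdf_y", None)
    ds_summary = {
        attr: {
            "mean_d_s": float(np.mean([s.d_s for s in shifts if s.attribute == attr])),
            "fraction_positive": float(
                np.mean([s.d_s > 0 for s in shifts if s.attribute == attr])
            ),
        }
        for attr in ATTRIBUTES
    }
    taus = {}
    for panel, cond in ((color, "color"), (gray, "grayscale")):
        mean = panel.mean_ratings()
        votes = {v.image_id: v.n_opaque for v in panel.vote_counts() if v.image_id in mean.index}
        taus[cond] = {
            attr: dataclasses.asdict(
                rating_stats.tau_vs_opacity(mean[attr].to_dict(), votes, config.alpha)
            )
            for attr in ATTRIBUTES
        }
    corr = {
        cond: rating_stats.attribute_correlation_matrix(
            panel.mean_ratings(), config.alpha_correlation
        ).tau.round(6).to_dict()
        for panel, cond in ((color, "color"), (gray, "grayscale"))
    }
    return {
        "kl_summary": {"log_base": rating_stats.KL_LOG_BASE, "threshold": config.kl_threshold,
                       "per_attribute": kl_summary},
        "skewness_shift": ds_summary,
        "tau_vs_opacity": taus,
        "attribute_correlations": corr,
    }


def _space_stage(color, gray, config) -> dict:
    out: dict = {"pca_variance": {}, "prediction_accuracy": {}, "significant_attributes": {}}
    for panel, cond in ((color, "color"), (gray, "grayscale")):
        pca = perceptual_space.pca_mean_ratings(panel.mean_ratings())
        out["pca_variance"][cond] = pca.explained_variance_ratio.tolist()
        results, skipped = perceptual_space.predict_all_observers(panel, config.seed)
        out["prediction_accuracy"][cond] = {
            r.observer_id: r.mean_accuracy for r in results
        }
        out["prediction_accuracy"][f"{cond}_skipped"] = [o for o, _ in skipped]
        if results:
            out["significant_attributes"][cond] = perceptual_space.significant_attribute_counts(results)
        if config.include_tsne:
            emb = perceptual_space.tsne_embed(
                panel.mean_ratings(), config.perplexity, config.seed
            )
            out.setdefault("tsne", {})[cond] = emb.coordinates.round(4).to_dict("index")
    return out


def _categorization_stage(color, gray, config) -> dict:
    if color.categories is None or gray.categories is None:
        return {"categorization": {"skipped": "no categorization records"}}
    scheme = categorization.build_scheme()
    merged = []
    for panel in (color, gray):
        frame = panel.categories.copy()
        frame.insert(0, "condition", panel.condition)
        merged.append(frame)
    both = pd.concat(merged, ignore_index=True)
    ground_truth = color.ground_truth if color.ground_truth is not None else gray.ground_truth
    result = categorization.misjudgment_counts(both, scheme, ground_truth)
    rdm_c = categorization.category_person_rdm(color.categories, "color")
    rdm_g = categorization.category_person_rdm(gray.categories, "grayscale")
    mwu = agreement.compare_distributions_mwu(
        rdm_c.upper_triangle(), rdm_g.upper_triangle(), alternative="less"
    )
    food = categorization.food_nonfood_table(both, scheme)
    return {"categorization": {
        "misjudgment": {
            "mean_incorrect": result.counts.groupby("condition")["n_incorrect"].mean().to_dict(),
            "mwu_color_below_gray": dataclasses.asdict(result.mwu_overall),
            "excluded_images": list(result.excluded_images),
        },
        "food_nonfood": {
            "n_images": int(food["image_id"].nunique()),
            "mean_food_count": food.groupby("condition")["food"].mean().to_dict(),
        },
        "person_rdm": {
            "color_mean": float(rdm_c.upper_triangle().mean()),
            "grayscale_mean": float(rdm_g.upper_triangle().mean()),
            "mwu_color_below_gray": dataclasses.asdict(mwu),
        },
    }}


def run_all(config: RunConfig) -> dict:
    """Run the full analysis sequence and return (and optionally write) the report."""
    config.validate()
    report: dict = {
        "meta": {
            "seed": config.seed,
            "label_threshold": config.label_threshold,
            "kl_threshold": config.kl_threshold,
            "kl_log_base": rating_stats.KL_LOG_BASE,
            "alpha": config.alpha,
            "alpha_correlation": config.alpha_correlation,
            "perplexity": config.perplexity,
            "kappa_bins": "half-open [0,.2,.4,.6,.8,1]; top closed; kappa<0 -> none",
            "synthetic": dataclasses.asdict(config.synthetic) if config.synthetic else None,
        }
    }
    if report["meta"]["synthetic"] is not None:
        report["meta"]["synthetic"]["attribute_loadings"] = dict(
            report["meta"]["synthetic"]["attribute_loadings"]
        )
    color, gray = _load_panels(config)
    stages = (
        ("agreement", lambda: _agreement_stage(color, gray, config)),
        ("rating_stats", lambda: _ratings_stage(color, gray, config)),
        ("perceptual_space", lambda: _space_stage(color, gray, config)),
        ("categorization", lambda: _categorization_stage(color, gray, config)),
    )
    timings = {}
    for name, fn in stages:
        start = time.perf_counter()
        try:
            report.update(fn())
        except Exception as exc:  # abort with stage tag, keep partial report
            report["failed_stage"] = name
            if config.output_dir:
                _write_report(report, config.output_dir)
            raise StageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - start, 3)
        logger.info("stage %s finished in %.3fs", name, timings[name])
    validate_report(report)
    if config.output_dir:
        _write_report(report, config.output_dir)
    return report


def _write_report(report: dict, output_dir) -> Path:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return path
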