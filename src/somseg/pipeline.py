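"""Pipeline orchestration: one run of a training paradigm on a cohort, and the
ablation grid over annotated/unlabeled counts with replicate seeds."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import SlideRecord, write_label_mask
from .estimators import PARADIGMS, SwarmSegmenter
from .evaluation import score_masks
from .models import TrainConfig
from .similarity import SimilarityConfig
from .synthetic import (
    SyntheticCohortConfig, confusable_styles, generate_cohort, generate_eval_slides,
    separable_styles, CONFUSABLE_PALETTE, SEPARABLE_PALETTE,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; serializable, no wall-clock state."""

    paradigm: str = "som_ssl"
    patch_size: int = 64
    annotated_overlap: int = 16
    similarity_patch_size: int = 64
    sim: SimilarityConfig = field(default_factory=SimilarityConfig)
    expert_train: TrainConfig = field(default_factory=lambda: TrainConfig(backend_id="centroid"))
    locator_train: TrainConfig = field(default_factory=lambda: TrainConfig(backend_id="softmax"))
    final_train: TrainConfig = field(default_factory=lambda: TrainConfig(backend_id="softmax"))

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")

    @property
    def annotated_stride(self) -> int:
        return self.patch_size - self.annotated_overlap

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            sim=replace(self.sim, kmeans_seed=seed),
            expert_train=replace(self.expert_train, split_seed=seed),
            locator_train=replace(self.locator_train, split_seed=seed),
            final_train=replace(self.final_train, split_seed=seed),
        )


def build_estimator(cfg: PipelineConfig):
    cls = PARADIGMS[cfg.paradigm]
    kwargs = dict(
        patch_size=cfg.patch_size,
        annotated_stride=cfg.annotated_stride,
        similarity_patch_size=cfg.similarity_patch_size,
        train_cfg=cfg.expert_train,
        final_cfg=cfg.final_train,
    )
    if cls is SwarmSegmenter:
        kwargs.update(locator_cfg=cfg.locator_train, sim_cfg=cfg.sim)
    return cls(**kwargs)


def run_pipeline(
    cfg: PipelineConfig,
    annotated: Sequence[SlideRecord],
    unlabeled: Sequence[SlideRecord] = (),
    out_dir: str | Path | None = None,
):
    """Train one paradigm; return (fitted estimator, run manifest).

    The manifest records the config (hash and full dict), the seeds, the
    stages executed, and — for the swarm — every expert-matching decision.
    """
    if not annotated:
        raise ValueError("no annotated slides supplied")
    if cfg.paradigm != "supervised" and not unlabeled:
        raise ValueError(f"paradigm {cfg.paradigm} requires unlabeled slides")
    est = build_estimator(cfg)
    est.fit(list(annotated), list(unlabeled))
    stages = ["train_supervised"] if cfg.paradigm == "supervised" else (
        ["train_supervised", "pseudolabel", "train_ssl_final"]
        if cfg.paradigm == "traditional_ssl"
        else [
            "train_expert_pool", "train_supervised", "train_tumor_locator",
            "similarity", "pseudolabel", "train_ssl_final",
        ]
    )
    manifest = {
        "paradigm": cfg.paradigm,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "stages": stages,
        "n_annotated": len(annotated),
        "n_unlabeled": len(unlabeled),
        "final_val_score": est.final_model_.best_val_score,
    }
    if hasattr(est, "matches_") and len(getattr(est, "matches_", [])):
        manifest["expert_matches"] = est.matches_.to_dict(orient="records")
        manifest["unmatched"] = est.unmatched_ids_
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        if hasattr(est, "pseudo_"):
            mask_dir = out_dir / "pseudolabels"
            mask_dir.mkdir(exist_ok=True)
            for res in est.pseudo_:
                write_label_mask(res.mask, mask_dir / f"{res.slide_id}.png")
        if getattr(est, "matrix_", None) is not None:
            est.matrix_.to_csv(out_dir / "similarity.csv")
            est.matches_.to_csv(out_dir / "matches.csv", index=False)
    return est, manifest


def evaluate_estimator(est, eval_slides: Sequence[SlideRecord]) -> pd.DataFrame:
    """Per-class scores of a fitted paradigm on held-out annotated slides."""
    frames = [
        score_masks(est.predict(s), s.label_mask, s.slide_id) for s in eval_slides
    ]
    return pd.concat(frames, ignore_index=True)


def cohort_config(
    style_set: str = "separable",
    n_annotated: int = 4,
    n_unlabeled: int = 16,
    seed: int = 0,
    **overrides,
) -> SyntheticCohortConfig:
    """Cohort configs for the two shipped study conditions."""
    if style_set == "separable":
        styles, palette = separable_styles(), SEPARABLE_PALETTE
    elif style_set == "confusable":
        styles, palette = confusable_styles(), CONFUSABLE_PALETTE
    else:
        raise ValueError(f"unknown style set {style_set!r}")
    return SyntheticCohortConfig(
        n_annotated=n_annotated,
        n_unlabeled=n_unlabeled,
        styles=tuple(styles),
        palette=dict(palette),
        seed=seed,
        **overrides,
    )


def run_ablation(
    n_annotated_grid: Sequence[int],
    n_unlabeled_grid: Sequence[int],
    paradigms: Sequence[str],
    base_cfg: PipelineConfig | None = None,
    style_set: str = "separable",
    n_replicates: int = 3,
    n_eval: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid over cohort sizes and paradigms, each cell repeated with
    independent replicate seeds (fresh random cohort subsets per replicate).

    Emits long-format rows (n_annotated, n_unlabeled, paradigm, replicate,
    class, dice). A failing cell is recorded with an ``error`` column and the
    grid continues.
    """
    base_cfg = base_cfg or PipelineConfig()
    rows = []
    for n_a in n_annotated_grid:
        for n_u in n_unlabeled_grid:
            for rep in range(n_replicates):
                rep_seed = seed + 1000 * rep
                cohort = cohort_config(style_set, n_a, n_u, seed=rep_seed)
                annotated, unlabeled, _ = generate_cohort(cohort)
                eval_slides, _ = generate_eval_slides(cohort, n_eval, rep_seed + 7)
                for paradigm in paradigms:
                    cfg = replace(base_cfg, paradigm=paradigm).with_seed(rep_seed)
                    try:
                        est, _ = run_pipeline(cfg, annotated, unlabeled)
                        scores = evaluate_estimator(est, eval_slides)
                        for _, r in scores.groupby("class")["dice"].mean().reset_index().iterrows():
                            rows.append(
                                {
                                    "n_annotated": n_a, "n_unlabeled": n_u,
                                    "paradigm": paradigm, "replicate": rep,
                                    "class": r["class"], "dice": r["dice"],
                                    "error": "",
                                }
                            )
                    except Exception as exc:  # record and continue
                        rows.append(
                            {
                                "n_annotated": n_a, "n_unlabeled": n_u,
                                "paradigm": paradigm, "replicate": rep,
                                "class": "", "dice": np.nan, "error": str(exc),
                            }
                        )
    return pd.DataFrame(rows)
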