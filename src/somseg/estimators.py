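"""The three training paradigms as sklearn-style estimators.

* :class:`SupervisedSegmenter` — fit on annotated slides only.
* :class:`TraditionalSSLSegmenter` — the supervised model pseudo-labels every
  unlabeled slide; a final model trains on labeled + pseudo-labeled patches.
* :class:`SwarmSegmenter` — a per-case expert pool plus slide-similarity
  matching: each unlabeled slide's tumor/stroma pseudo-labels come from the
  expert trained on the most similar annotated case, other classes from the
  pooled supervised model.

All three share ``fit(annotated, unlabeled) -> self`` and
``predict(slide) -> LabelMask``; fitted state lives in trailing-underscore
attributes. The traditional baseline runs through the same pseudo-label code
path as the swarm with the supervised model standing in as the only "expert".
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_io import LabelMask, Patch, SlideRecord, extract_patches
from .encoding import EncoderSpec, encode_patches
from .models import (
    ExpertPool, ModelHandle, TrainConfig, predict_slide_mask,
    split_case_patches, train_expert_pool, train_segmentation, train_supervised,
    train_tumor_locator,
)
from .pseudolabel import assemble_ssl_dataset, generate_pseudolabels
from .similarity import (
    RepresentativeSet, SimilarityConfig, SimilarityMatrix, filter_tumor_patches,
    matching_table, select_representatives,
)


def _slide_representatives(
    slide: SlideRecord,
    mask: LabelMask,
    sim_cfg: SimilarityConfig,
    encoder: EncoderSpec,
    patch_size: int,
    tumor_codes: set[int],
    stride: int | None = None,
) -> RepresentativeSet | None:
    """Representative set from >60%-tumor patches of one slide, or None when
    the slide has no qualifying patches (low-tumor-content failure mode).

    ``stride`` defaults to half the patch size: at toy slide sizes a plain
    tessellation can leave fewer than k qualifying tumor patches, whereas at
    full scale tumor regions span hundreds of patches; the denser sampling
    restores that patch-abundance regime."""
    patches = extract_patches(
        SlideRecord(slide.slide_id, slide.image, slide.mpp, label_mask=mask),
        patch_size, stride or max(1, patch_size // 2), with_mask=True,
    )
    retained = filter_tumor_patches(patches, tumor_codes, sim_cfg)
    if not retained:
        return None
    feats = encode_patches(retained, encoder)
    return select_representatives(feats, sim_cfg)


def compute_expert_matching(
    annotated: Sequence[SlideRecord],
    unlabeled: Sequence[SlideRecord],
    locator: ModelHandle,
    sim_cfg: SimilarityConfig | None = None,
    encoder: EncoderSpec | None = None,
    similarity_patch_size: int = 64,
):
    """Similarity stage on its own: representative sets, the annotated x
    unlabeled similarity matrix, and the matching table.

    Annotated slides use their manual masks for the tumor-content filter;
    unlabeled slides use the tumor locator's predictions. Returns
    (matrix, matches, unmatched_ids) where ``unmatched_ids`` lists slides the
    locator found no qualifying tumor patch on (matrix is None when no query
    qualifies).
    """
    sim_cfg = sim_cfg or SimilarityConfig()
    encoder = encoder or EncoderSpec(input_size=similarity_patch_size)
    scheme = annotated[0].label_mask.scheme
    tumor_code = {scheme.code_of["tumor"]}
    annot_reps = []
    for s in annotated:
        rep = _slide_representatives(
            s, s.label_mask, sim_cfg, encoder, similarity_patch_size, tumor_code
        )
        if rep is None:
            raise ValueError(
                f"annotated slide {s.slide_id} has no patch above the "
                "tumor-content threshold"
            )
        annot_reps.append(rep)
    query_reps, unmatched = [], []
    for s in unlabeled:
        pred = predict_slide_mask(locator, s, similarity_patch_size)
        rep = _slide_representatives(
            s, pred, sim_cfg, encoder, similarity_patch_size,
            set(locator.scheme.tumor_codes),
        )
        if rep is None:
            unmatched.append(s.slide_id)
        else:
            query_reps.append(rep)
    if not query_reps:
        empty = pd.DataFrame(columns=["query_id", "matched_id", "similarity"])
        return None, empty, unmatched
    from .similarity import build_similarity_matrix

    matrix = build_similarity_matrix(annot_reps, query_reps, sim_cfg.metric)
    return matrix, matching_table(matrix), unmatched


class _ParadigmBase(BaseEstimator):
    def __init__(
        self,
        patch_size: int = 64,
        annotated_stride: int = 48,
        similarity_patch_size: int = 64,
        train_cfg: TrainConfig | None = None,
        final_cfg: TrainConfig | None = None,
    ):
        self.patch_size = patch_size
        self.annotated_stride = annotated_stride
        self.similarity_patch_size = similarity_patch_size
        self.train_cfg = train_cfg
        self.final_cfg = final_cfg

    def _train_cfg(self) -> TrainConfig:
        return self.train_cfg or TrainConfig(backend_id="centroid")

    def _final_cfg(self) -> TrainConfig:
        return self.final_cfg or TrainConfig(backend_id="softmax")

    def predict(self, slide: SlideRecord) -> LabelMask:
        return predict_slide_mask(self.final_model_, slide, self.patch_size)

    def _fit_final(self, patches: Sequence[Patch], scheme, source_role: str) -> None:
        cfg = self._final_cfg()
        train, val = split_case_patches(patches, cfg)
        self.final_model_ = train_segmentation(
            train, val, scheme, cfg, model_id="ssl_final", role=source_role
        )


class SupervisedSegmenter(_ParadigmBase):
    """Baseline: one pooled model trained on the annotated slides only."""

    def fit(self, annotated: Sequence[SlideRecord], unlabeled=None) -> "SupervisedSegmenter":
        cfg = self._final_cfg()
        self.supervised_ = train_supervised(
            annotated, cfg, self.patch_size, self.annotated_stride
        )
        self.final_model_ = self.supervised_
        return self


class TraditionalSSLSegmenter(_ParadigmBase):
    """Pseudo-label SSL with the supervised model labelling every slide."""

    def fit(
        self, annotated: Sequence[SlideRecord], unlabeled: Sequence[SlideRecord]
    ) -> "TraditionalSSLSegmenter":
        cfg = self._train_cfg()
        self.supervised_ = train_supervised(
            annotated, cfg, self.patch_size, self.annotated_stride
        )
        # same code path as the swarm, with a pool of one
        pool = ExpertPool(
            experts={self.supervised_.model_id: self.supervised_},
            supervised=self.supervised_,
        )
        matrix = SimilarityMatrix(
            [self.supervised_.model_id],
            [s.slide_id for s in unlabeled],
            np.ones((len(unlabeled), 1)),
        )
        self.pseudo_ = [
            generate_pseudolabels(s, pool, matrix, self.patch_size) for s in unlabeled
        ]
        scheme = annotated[0].label_mask.scheme
        dataset = assemble_ssl_dataset(
            annotated, unlabeled, self.pseudo_, self.patch_size, self.annotated_stride
        )
        self._fit_final(dataset, scheme, "ssl_final")
        return self


class SwarmSegmenter(_ParadigmBase):
    """Similarity-guided swarm-of-models SSL.

    fit() trains the expert pool, the pooled supervised model and the tumor
    locator, builds the annotated x unlabeled similarity matrix from
    representative tumor-patch embeddings, generates expert-matched fused
    pseudo-labels, and trains the final model on labeled + pseudo-labeled
    patches. Unlabeled slides on which the locator finds no qualifying tumor
    patch fall back to supervised pseudo-labels (recorded in
    ``unmatched_ids_``).
    """

    def __init__(
        self,
        patch_size: int = 64,
        annotated_stride: int = 48,
        similarity_patch_size: int = 64,
        train_cfg: TrainConfig | None = None,
        final_cfg: TrainConfig | None = None,
        locator_cfg: TrainConfig | None = None,
        sim_cfg: SimilarityConfig | None = None,
        encoder: EncoderSpec | None = None,
    ):
        super().__init__(
            patch_size, annotated_stride, similarity_patch_size, train_cfg, final_cfg
        )
        self.locator_cfg = locator_cfg
        self.sim_cfg = sim_cfg
        self.encoder = encoder

    def _locator_cfg(self) -> TrainConfig:
        return self.locator_cfg or TrainConfig(backend_id="softmax")

    def fit(
        self, annotated: Sequence[SlideRecord], unlabeled: Sequence[SlideRecord]
    ) -> "SwarmSegmenter":
        cfg = self._train_cfg()
        sim_cfg = self.sim_cfg or SimilarityConfig()
        encoder = self.encoder or EncoderSpec(input_size=self.similarity_patch_size)
        scheme = annotated[0].label_mask.scheme

        self.pool_ = train_expert_pool(annotated, cfg, self.patch_size, self.annotated_stride)
        self.pool_.supervised = train_supervised(
            annotated, cfg, self.patch_size, self.annotated_stride
        )
        self.pool_.tumor_locator = train_tumor_locator(
            annotated, self._locator_cfg(), self.similarity_patch_size
        )

        self.matrix_, self.matches_, self.unmatched_ids_ = compute_expert_matching(
            annotated, unlabeled, self.pool_.tumor_locator, sim_cfg, encoder,
            self.similarity_patch_size,
        )

        self.pseudo_ = []
        matched_ids = set(self.matches_["query_id"]) if len(self.matches_) else set()
        sup = self.pool_.supervised
        fallback_pool = ExpertPool(experts={sup.model_id: sup}, supervised=sup)
        for s in unlabeled:
            if s.slide_id in matched_ids:
                self.pseudo_.append(
                    generate_pseudolabels(s, self.pool_, self.matrix_, self.patch_size)
                )
            else:
                fm = SimilarityMatrix([sup.model_id], [s.slide_id], np.ones((1, 1)))
                self.pseudo_.append(
                    generate_pseudolabels(s, fallback_pool, fm, self.patch_size)
                )

        dataset = assemble_ssl_dataset(
            annotated, unlabeled, self.pseudo_, self.patch_size, self.annotated_stride
        )
        self._fit_final(dataset, scheme, "ssl_final")
        return self


PARADIGMS = {
    "supervised": SupervisedSegmenter,
    "traditional_ssl": TraditionalSSLSegmenter,
    "som_ssl": SwarmSegmenter,
}
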