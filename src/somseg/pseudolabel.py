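"""Pseudo-label generation: fuse the matched expert's tumor/stroma predictions
with the supervised model's other-class predictions, then blank out artifacts.

The fusion rule is per-pixel: where the expert predicts a tumor or tumor-stroma
code, the expert wins; everywhere else the supervised prediction stands. No
confidence values are consulted anywhere — thresholding hooks are deliberately
absent so the comparison between paradigms is not confounded by threshold
choices. The traditional-SSL baseline is the same code path with the
supervised model standing in as its own "expert".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import LabelMask, Patch, SlideRecord, extract_patches
from .models import ExpertPool, predict_slide_mask
from .similarity import SimilarityMatrix, match_expert

PROV_SUPERVISED, PROV_EXPERT, PROV_IGNORE = 0, 1, 2


@dataclass
class PseudoLabelResult:
    slide_id: str
    mask: LabelMask
    matched_expert: str
    similarity: float
    provenance: np.ndarray  # per-pixel: 0 supervised, 1 expert, 2 ignore


def fuse_masks(
    expert_mask: LabelMask, supervised_mask: LabelMask, tumor_codes: set[int] | None = None
) -> LabelMask:
    """Per pixel: expert's code where it is tumor/stroma, else supervised's."""
    if expert_mask.shape != supervised_mask.shape:
        raise ValueError("expert and supervised masks differ in shape")
    tumor_codes = tumor_codes or set(expert_mask.scheme.tumor_codes)
    is_tumor = np.isin(expert_mask.codes, list(tumor_codes))
    fused = np.where(is_tumor, expert_mask.codes, supervised_mask.codes)
    return LabelMask(fused, expert_mask.scheme)


def apply_artifact_mask(mask: LabelMask, artifact: np.ndarray | None) -> LabelMask:
    """Set artifact pixels to the ignore code; idempotent."""
    if artifact is None:
        return mask.copy()
    artifact = np.asarray(artifact).astype(bool)
    if artifact.shape != mask.shape:
        raise ValueError("artifact mask shape does not match label mask")
    out = mask.codes.copy()
    out[artifact] = mask.scheme.ignore_code
    return LabelMask(out, mask.scheme)


def generate_pseudolabels(
    slide: SlideRecord,
    pool: ExpertPool,
    matrix: SimilarityMatrix,
    patch_size: int = 512,
) -> PseudoLabelResult:
    """Expert-matched pseudo-label mask for one unlabeled slide.

    The matched expert and the supervised model each predict the slide on
    non-overlapping tiles; their masks are fused with tumor/stroma precedence
    and artifact pixels are set to ignore.
    """
    if slide.annotated:
        raise ValueError(f"slide {slide.slide_id} is annotated; nothing to pseudo-label")
    try:
        matched = match_expert(matrix, slide.slide_id)
    except KeyError:
        raise KeyError(
            f"slide {slide.slide_id} missing from the similarity matrix; "
            "run the similarity stage first"
        ) from None
    expert = pool.experts[matched]
    if pool.supervised is None:
        raise ValueError("expert pool has no supervised model")
    expert_mask = predict_slide_mask(expert, slide, patch_size)  # no overlap
    supervised_mask = predict_slide_mask(pool.supervised, slide, patch_size)
    fused = fuse_masks(expert_mask, supervised_mask)
    final = apply_artifact_mask(fused, slide.artifact_mask)
    scheme = final.scheme
    provenance = np.full(final.shape, PROV_SUPERVISED, dtype=np.uint8)
    provenance[np.isin(expert_mask.codes, list(scheme.tumor_codes))] = PROV_EXPERT
    provenance[final.codes == scheme.ignore_code] = PROV_IGNORE
    return PseudoLabelResult(
        slide.slide_id, final, matched, matrix.row(slide.slide_id)[matched], provenance
    )


def assemble_ssl_dataset(
    annotated: Sequence[SlideRecord],
    unlabeled: Sequence[SlideRecord],
    pseudo: Sequence[PseudoLabelResult],
    patch_size: int = 512,
    annotated_stride: int = 384,
) -> list[Patch]:
    """Combined labeled + pseudo-labeled patch set for semi-supervised training.

    Annotated slides are tiled with the overlap regime, pseudo-labeled slides
    without overlap; patches that are 100% ignore are dropped. ``unlabeled``
    supplies the rasters for the pseudo-labeled slides (matched by slide id).
    """
    patches: list[Patch] = []
    for slide in annotated:
        patches.extend(extract_patches(slide, patch_size, annotated_stride, with_mask=True))
    by_id = {s.slide_id: s for s in unlabeled}
    for result in pseudo:
        try:
            src = by_id[result.slide_id]
        except KeyError:
            raise KeyError(f"no raster provided for pseudo-labeled slide {result.slide_id}")
        pseudo_slide = SlideRecord(
            result.slide_id, image=src.image, mpp=src.mpp, label_mask=result.mask
        )
        patches.extend(extract_patches(pseudo_slide, patch_size, patch_size, with_mask=True))
    kept = [
        p for p in patches
        if not np.all(p.mask.codes == p.mask.scheme.ignore_code)
    ]
    if not kept:
        raise ValueError("assembled dataset is empty (all patches fully ignored)")
    return kept
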