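"""Training roles on top of the backend contract: per-case expert pool, pooled
supervised model, and the 3-class tumor locator used to find tumor regions on
unlabeled slides.

Every expert is trained on the patches of exactly one annotated case (90/10
train/validation split); the supervised model pools all annotated cases; the
tumor locator collapses the scheme to tumor / non-tumor / background and is
used only to harvest tumor patches for similarity assessment. All models of a
pool share one ``init_checkpoint_id`` — with the deterministic built-in
backends this token doubles as the shared initialization seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import zlib
import numpy as np

from .backends import SegmentationBackend, make_backend
from .core_io import (
    ClassScheme, LabelMask, Patch, SlideRecord, extract_patches, tile_origins,
)

LOCATOR_SCHEME = ClassScheme(
    labels=("background", "tumor", "non_tumor"),
    codes=(0, 1, 2),
    tumor_codes=frozenset({1}),
)


@dataclass(frozen=True)
class TrainConfig:
    """Shared training hyper-parameters.

    epochs/lr_step_size/lr_gamma follow the step-decay regime (36 epochs, decay
    every 10); val_fraction is the per-case hold-out used for checkpoint
    selection; backend_id selects the segmentation backend; backend_params are
    forwarded to its constructor.
    """

    epochs: int = 36
    lr_step_size: int = 10
    lr_gamma: float = 0.5
    val_fraction: float = 0.10
    split_seed: int = 0
    backend_id: str = "centroid"
    backend_params: dict = field(default_factory=dict)
    init_checkpoint_id: str = "shared-init-0"
    stroma_as_tumor: bool = False  # locator: whether tumor stroma maps to "tumor"

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")

    @property
    def backend_seed(self) -> int:
        # shared initialization: every model of a pool starts identically
        return zlib.crc32(self.init_checkpoint_id.encode()) % (2**31)


@dataclass
class ModelHandle:
    """A trained model plus its provenance."""

    model_id: str
    role: str  # expert | supervised | tumor_locator | ssl_final
    source_slides: list[str]
    best_val_score: float
    backend: SegmentationBackend
    scheme: ClassScheme

    def __post_init__(self) -> None:
        if self.role == "expert" and len(self.source_slides) != 1:
            raise ValueError("an expert model must have exactly one source slide")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.backend.save_state(directory / "state.npz")
        manifest = {
            "model_id": self.model_id,
            "role": self.role,
            "source_slides": self.source_slides,
            "best_val_score": self.best_val_score,
            "backend_id": self.backend.backend_id,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path, scheme: ClassScheme) -> "ModelHandle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        from .backends import BACKENDS

        backend = BACKENDS[manifest["backend_id"]].load_state(directory / "state.npz")
        return cls(
            manifest["model_id"], manifest["role"], manifest["source_slides"],
            manifest["best_val_score"], backend, scheme,
        )


@dataclass
class ExpertPool:
    """Per-annotated-slide experts plus the shared supervised model and locator."""

    experts: dict[str, ModelHandle]
    supervised: ModelHandle | None = None
    tumor_locator: ModelHandle | None = None


def split_case_patches(
    patches: Sequence[Patch], cfg: TrainConfig
) -> tuple[list[Patch], list[Patch]]:
    """Deterministic 90/10 split: shuffle by split_seed, |val| = max(1, round(0.1 n))."""
    n = len(patches)
    if n < 2:
        raise ValueError("need at least 2 patches to split")
    rng = np.random.default_rng(cfg.split_seed)
    order = rng.permutation(n)
    n_val = max(1, int(np.floor(cfg.val_fraction * n + 0.5)))
    val_idx = set(order[:n_val].tolist())
    train = [patches[i] for i in range(n) if i not in val_idx]
    val = [patches[i] for i in range(n) if i in val_idx]
    return train, val


def class_weights(
    label_histogram: dict[int, int], all_codes: Sequence[int] | None = None
) -> dict[int, float]:
    """Inverse-frequency weights w_c = N / (K * n_c) over the K observed
    classes; unobserved classes receive the maximum observed weight."""
    observed = {c: n for c, n in label_histogram.items() if n > 0}
    if not observed:
        raise ValueError("all-zero label histogram")
    N = sum(observed.values())
    K = len(observed)
    weights = {c: N / (K * n) for c, n in observed.items()}
    w_max = max(weights.values())
    for c in all_codes or ():
        weights.setdefault(c, w_max)
    return weights


def _histogram(pairs: Sequence[tuple[np.ndarray, np.ndarray]], scheme: ClassScheme) -> dict[int, int]:
    hist: dict[int, int] = {}
    for _, codes in pairs:
        vals, counts = np.unique(codes, return_counts=True)
        for v, c in zip(vals.tolist(), counts.tolist()):
            if v == scheme.ignore_code:
                continue
            hist[v] = hist.get(v, 0) + c
    return hist


def _pairs(patches: Sequence[Patch]) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for p in patches:
        if p.mask is None:
            raise ValueError(f"patch at {p.origin} of slide {p.slide_id} has no mask")
        out.append((p.pixels, p.mask.codes))
    return out


def train_segmentation(
    train: Sequence[Patch],
    val: Sequence[Patch],
    scheme: ClassScheme,
    cfg: TrainConfig,
    model_id: str = "model",
    role: str = "supervised",
) -> ModelHandle:
    """Fit a backend on (patch, mask) pairs with weighted CE (where the backend
    is loss-based) and keep the checkpoint with the best validation mean
    foreground Dice."""
    if not train or not val:
        raise ValueError("train and val must both be non-empty")
    train_pairs, val_pairs = _pairs(train), _pairs(val)
    hist = _histogram(train_pairs, scheme)
    weights = class_weights(hist, scheme.codes)
    params = dict(cfg.backend_params)
    backend = make_backend(cfg.backend_id, **params)
    if hasattr(backend, "epochs") and "epochs" not in params:
        backend.set_params(epochs=cfg.epochs, lr_step_size=cfg.lr_step_size,
                           lr_gamma=cfg.lr_gamma)
    try:
        backend.fit(
            train_pairs, val_pairs, codes=list(hist), class_weights=weights,
            ignore_code=scheme.ignore_code, background_code=scheme.codes[0],
            seed=cfg.backend_seed,
        )
    except Exception as exc:  # surface which backend failed
        raise RuntimeError(f"backend {cfg.backend_id!r} failed: {exc}") from exc
    return ModelHandle(
        model_id, role, sorted({p.slide_id for p in train}),
        float(backend.best_val_score_), backend, scheme,
    )


def _slide_patches(
    slide: SlideRecord, patch_size: int, stride: int
) -> list[Patch]:
    patches = extract_patches(slide, patch_size, stride, with_mask=True)
    if not patches:
        raise ValueError(f"slide {slide.slide_id} produced no patches")
    return patches


def train_expert_pool(
    annotated: Sequence[SlideRecord],
    cfg: TrainConfig,
    patch_size: int = 512,
    stride: int = 384,
) -> ExpertPool:
    """One expert per annotated slide, trained on that slide's patches only."""
    if not annotated:
        raise ValueError("need at least one annotated slide")
    experts = {}
    for slide in annotated:
        patches = _slide_patches(slide, patch_size, stride)
        train, val = split_case_patches(patches, cfg)
        experts[slide.slide_id] = train_segmentation(
            train, val, slide.label_mask.scheme, cfg,
            model_id=f"expert:{slide.slide_id}", role="expert",
        )
    return ExpertPool(experts=experts)


def train_supervised(
    annotated: Sequence[SlideRecord],
    cfg: TrainConfig,
    patch_size: int = 512,
    stride: int = 384,
) -> ModelHandle:
    """Pooled supervised model: patches from all annotated slides, 90/10 split
    at the pooled level."""
    if not annotated:
        raise ValueError("need at least one annotated slide")
    patches: list[Patch] = []
    for slide in annotated:
        patches.extend(_slide_patches(slide, patch_size, stride))
    train, val = split_case_patches(patches, cfg)
    scheme = annotated[0].label_mask.scheme
    return train_segmentation(train, val, scheme, cfg,
                              model_id="supervised", role="supervised")


def remap_to_locator(mask: LabelMask, stroma_as_tumor: bool = False) -> LabelMask:
    """Collapse a full scheme to tumor / non-tumor / background.

    Only the tumor class maps to "tumor" by default; tumor stroma is
    non-tumor unless ``stroma_as_tumor`` is set. Background keeps its code;
    ignore pixels stay ignored.
    """
    scheme = mask.scheme
    tumor_code = scheme.code_of["tumor"]
    tumor_set = set(scheme.tumor_codes) if stroma_as_tumor else {tumor_code}
    src = mask.codes
    out = np.full_like(src, 2)  # non-tumor
    out[src == scheme.codes[0]] = 0  # background
    out[np.isin(src, list(tumor_set))] = 1
    out[src == scheme.ignore_code] = LOCATOR_SCHEME.ignore_code
    return LabelMask(out, LOCATOR_SCHEME)


def train_tumor_locator(
    annotated: Sequence[SlideRecord],
    cfg: TrainConfig,
    patch_size: int = 224,
    stride: int | None = None,
) -> ModelHandle:
    """3-class tumor/non-tumor/background model on 224 x 224 patches (toy
    scale overrides the size); used only to select tumor patches on unlabeled
    slides."""
    if not annotated:
        raise ValueError("need at least one annotated slide")
    stride = stride or patch_size
    patches: list[Patch] = []
    for slide in annotated:
        for p in _slide_patches(slide, patch_size, stride):
            p.mask = remap_to_locator(p.mask, cfg.stroma_as_tumor)
            patches.append(p)
    train, val = split_case_patches(patches, cfg)
    return train_segmentation(train, val, LOCATOR_SCHEME, cfg,
                              model_id="tumor_locator", role="tumor_locator")


def predict_slide_mask(
    model: ModelHandle,
    slide: SlideRecord,
    patch_size: int,
    stride: int | None = None,
) -> LabelMask:
    """Tile the slide, predict per tile, and assemble a slide-sized mask.

    Where tiles overlap, later tiles overwrite earlier predictions except
    pixels already carrying a tumor/stroma code, which persist (the fusion
    precedence rule applied at assembly).
    """
    if not hasattr(model.backend, "predict_mask"):
        raise ValueError("model handle holds no trained backend")
    stride = stride or patch_size
    scheme = model.scheme
    h, w = slide.shape
    out = np.full((h, w), scheme.ignore_code, dtype=np.int64)
    written = np.zeros((h, w), dtype=bool)
    tumor_codes = list(scheme.tumor_codes)
    for x0, y0 in tile_origins(w, h, patch_size, stride):
        pred = model.backend.predict_mask(slide.image[y0:y0 + patch_size, x0:x0 + patch_size])
        region = out[y0:y0 + patch_size, x0:x0 + patch_size]
        wr = written[y0:y0 + patch_size, x0:x0 + patch_size]
        keep = wr & np.isin(region, tumor_codes)
        region[~keep] = pred[~keep]
        wr[:] = True
    return LabelMask(out, scheme)
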