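"""Seeded generator of synthetic slide cohorts with exact masks.

Each slide is a flat-colour class layout (background border, submucosa,
benign mucosa, a tumor region with an adjacent tumor-stroma ring) where the
tumor texture follows a per-case "morphology style": a base colour plus an
oriented sinusoidal stripe pattern and bounded uniform colour jitter. Styles
stand in for inter-case tumor heterogeneity: the built-in histogram encoder
separates them, so expert matching is testable without foundation-model
weights.

Noise is uniform (bounded), and the shipped palettes are chosen so every
class-colour margin exceeds the worst-case noise displacement; pixel-level
class decisions of a nearest-centroid model are then deterministic, which
keeps cohort-level comparisons structural rather than sampling-dependent.

Two palettes ship:

* ``separable_styles`` — four tumor styles far from every non-tumor colour;
  a pooled unimodal model segments every style correctly.
* ``confusable_styles`` — identical except style 0's tumor colour sits close
  to the (global) benign-mucosa colour while remaining far from the pooled
  tumor centroid: a pooled unimodal model systematically mislabels that
  style's tumor as benign mucosa, while the per-case expert separates the
  two. This reproduces, at toy scale, the pooled-model underfitting of tumor
  heterogeneity that similarity-matched experts are designed to fix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ClassScheme, LabelMask, SlideRecord

#: Synthetic cohorts use the first five codes of the default scheme.
SYNTH_CLASS_NAMES = ("background", "tumor", "tumor_stroma", "benign_mucosa", "submucosa")

SEPARABLE_PALETTE = {
    "background": (245, 245, 245),
    "tumor_stroma": (255, 170, 220),
    "benign_mucosa": (130, 255, 255),
    "submucosa": (40, 30, 30),
}

CONFUSABLE_PALETTE = {
    "background": (245, 245, 245),
    "tumor_stroma": (250, 170, 190),
    "benign_mucosa": (200, 200, 60),
    "submucosa": (110, 70, 30),
}


@dataclass(frozen=True)
class StyleSpec:
    """Per-case tumor morphology style."""

    style_id: str
    base_rgb: tuple[int, int, int]
    stripe_orientation_deg: float = 0.0
    stripe_period: float = 12.0
    stripe_amplitude: float = 6.0
    jitter: float = 6.0  # half-width of the uniform per-channel colour noise

    def __post_init__(self) -> None:
        if not all(0 <= c <= 255 for c in self.base_rgb):
            raise ValueError("base colour channels must be in [0, 255]")
        if self.jitter < 0 or self.stripe_amplitude < 0:
            raise ValueError("jitter and amplitude must be non-negative")


def separable_styles(n: int = 4) -> list[StyleSpec]:
    bases = [(220, 50, 50), (50, 220, 50), (50, 50, 220), (220, 220, 50)]
    if n > len(bases):
        raise ValueError("at most 4 shipped separable styles")
    return [
        StyleSpec(f"style{i}", bases[i], stripe_orientation_deg=45.0 * i,
                  stripe_amplitude=6.0, jitter=6.0)
        for i in range(n)
    ]


def confusable_styles() -> list[StyleSpec]:
    """Four styles; style0's tumor colour is a near neighbour of the
    benign-mucosa colour of :data:`CONFUSABLE_PALETTE`."""
    bases = [(230, 230, 30), (60, 60, 200), (40, 200, 220), (150, 30, 230)]
    return [
        StyleSpec(f"style{i}", bases[i], stripe_orientation_deg=45.0 * i,
                  stripe_amplitude=3.0, jitter=8.0)
        for i in range(4)
    ]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort layout and sampling parameters.

    Defaults give 256 x 256 slides whose tumor region covers ~40% of the
    tissue so the 60% tumor-content filter always retains patches at the
    64 px similarity patch size.
    """

    n_annotated: int = 4
    n_unlabeled: int = 16
    styles: tuple[StyleSpec, ...] = tuple(separable_styles())
    palette: dict = field(default_factory=lambda: dict(SEPARABLE_PALETTE))
    slide_size: int = 256
    border: int = 16
    tumor_extent: int = 144
    stroma_width: int = 12
    benign_extent: int = 56
    tissue_jitter: float = 6.0  # uniform noise half-width for non-tumor classes
    n_mixed: int = 0  # unlabeled slides mixing two styles (mid-similarity probes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slide_size < self.tumor_extent + 2 * (self.border + self.stroma_width):
            raise ValueError("layout infeasible: tumor + stroma ring exceed tissue")
        if self.n_annotated < 1 or self.n_unlabeled < 0:
            raise ValueError("invalid cohort counts")


def synth_scheme() -> ClassScheme:
    return ClassScheme(
        labels=SYNTH_CLASS_NAMES,
        codes=tuple(range(len(SYNTH_CLASS_NAMES))),
        tumor_codes=frozenset({1, 2}),
    )


def render_texture(
    style: StyleSpec, size: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Deterministic styled tumor texture: base colour + oriented sinusoidal
    stripes + bounded uniform jitter."""
    if size <= 0:
        raise ValueError("size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.deg2rad(style.stripe_orientation_deg)
    phase = (xx * np.cos(theta) + yy * np.sin(theta)) * 2 * np.pi / style.stripe_period
    stripes = style.stripe_amplitude * np.sin(phase)
    img = np.empty((size, size, 3), dtype=float)
    for c in range(3):
        noise = rng.uniform(-style.jitter, style.jitter, (size, size))
        img[..., c] = style.base_rgb[c] + stripes + noise
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _fill(img: np.ndarray, region: tuple[slice, slice], rgb, jitter: float,
          rng: np.random.Generator) -> None:
    shape = img[region].shape[:2]
    block = np.empty(shape + (3,), dtype=float)
    for c in range(3):
        block[..., c] = rgb[c] + rng.uniform(-jitter, jitter, shape)
    img[region] = np.clip(np.rint(block), 0, 255).astype(np.uint8)


def generate_slide(
    style: StyleSpec,
    cfg: SyntheticCohortConfig,
    seed: int,
    slide_id: str = "slide",
    second_style: StyleSpec | None = None,
) -> SlideRecord:
    """One synthetic slide with an exact ground-truth mask.

    Layout: background border; submucosa tissue; a benign-mucosa block in one
    corner; a styled tumor region with a tumor-stroma ring, position jittered.
    ``second_style`` splits the tumor region vertically between two styles.
    """
    rng = np.random.default_rng(seed)
    scheme = synth_scheme()
    code = scheme.code_of
    S, b = cfg.slide_size, cfg.border
    img = np.empty((S, S, 3), dtype=np.uint8)
    mask = np.full((S, S), code["submucosa"], dtype=np.int64)

    # background border
    mask[:b, :] = mask[-b:, :] = code["background"]
    mask[:, :b] = mask[:, -b:] = code["background"]

    # tumor + stroma ring, jittered position inside the tissue
    t, w = cfg.tumor_extent, cfg.stroma_width
    lo, hi = b + w, S - b - w - t
    ty = int(rng.integers(lo, hi + 1))
    tx = int(rng.integers(lo, hi + 1))
    mask[ty - w : ty + t + w, tx - w : tx + t + w] = code["tumor_stroma"]
    mask[ty : ty + t, tx : tx + t] = code["tumor"]

    # benign mucosa block in the corner farthest from the tumor
    e = cfg.benign_extent
    corner_y = b if ty + t // 2 > S // 2 else S - b - e
    corner_x = b if tx + t // 2 > S // 2 else S - b - e
    benign = (slice(corner_y, corner_y + e), slice(corner_x, corner_x + e))
    mask[benign] = code["benign_mucosa"]

    # paint rasters after the mask is final
    _fill(img, (slice(None), slice(None)), cfg.palette["submucosa"], cfg.tissue_jitter, rng)
    for name in ("background", "tumor_stroma", "benign_mucosa"):
        region = mask == code[name]
        block = np.empty((int(region.sum()), 3), dtype=float)
        for c in range(3):
            block[:, c] = cfg.palette[name][c] + rng.uniform(
                -cfg.tissue_jitter, cfg.tissue_jitter, block.shape[0]
            )
        img[region] = np.clip(np.rint(block), 0, 255).astype(np.uint8)
    texture = render_texture(style, t, rng)
    if second_style is not None:
        texture2 = render_texture(second_style, t, rng)
        texture[:, t // 2 :] = texture2[:, t // 2 :]
    img[ty : ty + t, tx : tx + t] = texture

    return SlideRecord(slide_id, img, mpp=1.0, label_mask=LabelMask(mask, scheme))


def generate_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[list[SlideRecord], list[SlideRecord], dict[str, str]]:
    """Annotated and unlabeled slide lists plus the slide -> style truth table.

    Annotated slides cover the style list round-robin; unlabeled slides cycle
    the same styles with fresh seeds. Unlabeled slides are returned without
    masks (their exact masks can be regenerated from the same config for
    evaluation). Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    styles = cfg.styles
    truth: dict[str, str] = {}
    annotated = []
    for i in range(cfg.n_annotated):
        style = styles[i % len(styles)]
        sid = f"annot{i:03d}"
        annotated.append(
            generate_slide(style, cfg, int(rng.integers(2**31)), sid)
        )
        truth[sid] = style.style_id
    unlabeled = []
    for i in range(cfg.n_unlabeled):
        style = styles[i % len(styles)]
        sid = f"case{i:03d}"
        second = None
        if i >= cfg.n_unlabeled - cfg.n_mixed:
            second = styles[(i + 1) % len(styles)]
        slide = generate_slide(style, cfg, int(rng.integers(2**31)), sid, second)
        truth[sid] = style.style_id if second is None else f"{style.style_id}+{second.style_id}"
        unlabeled.append(
            SlideRecord(slide.slide_id, slide.image, slide.mpp, label_mask=None)
        )
    return annotated, unlabeled, truth


def generate_eval_slides(
    cfg: SyntheticCohortConfig, n: int, seed: int
) -> tuple[list[SlideRecord], dict[str, str]]:
    """Held-out annotated slides (round-robin styles) for final-model scoring."""
    rng = np.random.default_rng(seed)
    truth = {}
    slides = []
    for i in range(n):
        style = cfg.styles[i % len(cfg.styles)]
        sid = f"test{i:03d}"
        slides.append(generate_slide(style, cfg, int(rng.integers(2**31)), sid))
        truth[sid] = style.style_id
    return slides, truth
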