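"""Slide and mask data model, deterministic tiling, resolution handling, raster I/O.

Whole-slide images are modelled as plain ``H x W x 3`` uint8 rasters with a
micrometers-per-pixel (MPP) resolution attached; label masks are single-channel
integer rasters whose values are class codes from a :class:`ClassScheme`.
The magnification convention is 10x = 1.0 um/px (a 40x scanner at ~0.25 MPP
downsampled by 4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

IGNORE_CODE = 255

#: Tissue classes annotated in colorectal resection cohorts, plus background.
DEFAULT_CLASS_NAMES = (
    "background",
    "tumor",
    "tumor_stroma",
    "benign_mucosa",
    "submucosa",
    "smooth_muscle",
    "adventitia",
    "vessels",
    "lymphoid",
    "ulceration_necrosis",
    "mucin",
    "bleeding",
)


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class names, their integer codes, and the tumor-code subset.

    ``tumor_codes`` are the codes treated as "tumor" and "tumor stroma" by the
    pseudo-label fusion precedence rule. ``ignore_code`` marks pixels excluded
    from training and scoring (artifacts, unannotated regions).
    """

    labels: tuple[str, ...]
    codes: tuple[int, ...]
    tumor_codes: frozenset[int]
    ignore_code: int = IGNORE_CODE

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.codes):
            raise ValueError("labels and codes must have equal length")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("class codes must be unique")
        if not self.tumor_codes <= set(self.codes):
            raise ValueError("tumor_codes must be a subset of codes")
        if self.ignore_code in self.codes:
            raise ValueError("ignore_code must not collide with a class code")

    @property
    def code_of(self) -> dict[str, int]:
        return dict(zip(self.labels, self.codes))

    @property
    def name_of(self) -> dict[int, str]:
        return dict(zip(self.codes, self.labels))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": list(self.labels),
            "codes": list(self.codes),
            "tumor_codes": sorted(self.tumor_codes),
            "ignore_code": self.ignore_code,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassScheme":
        payload = json.loads(Path(path).read_text())
        return cls(
            labels=tuple(payload["labels"]),
            codes=tuple(payload["codes"]),
            tumor_codes=frozenset(payload["tumor_codes"]),
            ignore_code=payload["ignore_code"],
        )


def default_scheme() -> ClassScheme:
    """The default 12-code scheme: 11 tissue classes plus background."""
    codes = tuple(range(len(DEFAULT_CLASS_NAMES)))
    return ClassScheme(
        labels=DEFAULT_CLASS_NAMES,
        codes=codes,
        tumor_codes=frozenset({1, 2}),  # tumor, tumor_stroma
    )


@dataclass
class LabelMask:
    """Per-pixel class codes under a :class:`ClassScheme`."""

    codes: np.ndarray  # H x W integer grid
    scheme: ClassScheme

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("label mask must be 2-D")
        self.validate()

    def validate(self) -> None:
        allowed = set(self.scheme.codes) | {self.scheme.ignore_code}
        present = set(np.unique(self.codes).tolist())
        bad = present - allowed
        if bad:
            raise ValueError(f"mask contains codes outside the scheme: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape  # type: ignore[return-value]

    def copy(self) -> "LabelMask":
        return LabelMask(self.codes.copy(), self.scheme)


@dataclass
class SlideRecord:
    """One slide: RGB raster, resolution metadata, optional label/artifact masks."""

    slide_id: str
    image: np.ndarray  # H x W x 3 uint8
    mpp: float
    label_mask: LabelMask | None = None
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("slide image must be H x W x 3")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        hw = self.image.shape[:2]
        if self.label_mask is not None and self.label_mask.shape != hw:
            raise ValueError("label mask does not match image dimensions")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask).astype(bool)
            if self.artifact_mask.shape != hw:
                raise ValueError("artifact mask does not match image dimensions")

    @property
    def annotated(self) -> bool:
        return self.label_mask is not None

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass(frozen=True)
class TileGrid:
    """Tile origins for a slide: 0-based (x, y) top-left corners, half-open tiles."""

    patch_size: int
    stride: int
    origins: tuple[tuple[int, int], ...]


@dataclass
class Patch:
    """One extracted tile with optional aligned mask crop."""

    slide_id: str
    origin: tuple[int, int]
    pixels: np.ndarray
    mask: LabelMask | None = None


def _axis_starts(dim: int, patch_size: int, stride: int) -> list[int]:
    starts = list(range(0, dim - patch_size + 1, stride))
    last = dim - patch_size
    if starts[-1] != last:
        starts.append(last)
    return starts


def tile_origins(width: int, height: int, patch_size: int, stride: int) -> list[tuple[int, int]]:
    """Row-major tile origins covering the whole image.

    Per axis, starts run 0, stride, 2*stride, ...; a final start clamped to
    ``dim - patch_size`` is appended when the regular grid does not reach the
    border, so every pixel is covered by at least one tile without padding.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride > patch_size:
        raise ValueError("stride must not exceed patch_size (gaps would appear)")
    if patch_size > width or patch_size > height:
        raise ValueError(
            f"slide too small for configuration: patch {patch_size} exceeds "
            f"image dimensions {width}x{height}"
        )
    xs = _axis_starts(width, patch_size, stride)
    ys = _axis_starts(height, patch_size, stride)
    return [(x, y) for y in ys for x in xs]


def tile_grid(slide: SlideRecord, patch_size: int, stride: int) -> TileGrid:
    h, w = slide.shape
    return TileGrid(patch_size, stride, tuple(tile_origins(w, h, patch_size, stride)))


def extract_patch(
    slide: SlideRecord,
    origin: tuple[int, int],
    patch_size: int,
    with_mask: bool = False,
) -> Patch:
    """Extract the tile at ``origin`` (copying pixels; mask crop uses identical coords)."""
    x0, y0 = origin
    h, w = slide.shape
    if x0 < 0 or y0 < 0 or x0 + patch_size > w or y0 + patch_size > h:
        raise ValueError(f"tile at {origin} (size {patch_size}) lies outside the slide")
    pixels = slide.image[y0 : y0 + patch_size, x0 : x0 + patch_size].copy()
    mask = None
    if with_mask:
        if slide.label_mask is None:
            raise ValueError(f"slide {slide.slide_id} has no label mask")
        mask = LabelMask(
            slide.label_mask.codes[y0 : y0 + patch_size, x0 : x0 + patch_size].copy(),
            slide.label_mask.scheme,
        )
    return Patch(slide.slide_id, (x0, y0), pixels, mask)


def extract_patches(
    slide: SlideRecord, patch_size: int, stride: int, with_mask: bool = False
) -> list[Patch]:
    return [
        extract_patch(slide, o, patch_size, with_mask)
        for o in tile_grid(slide, patch_size, stride).origins
    ]


def rescale_to_target(slide: SlideRecord, target_mpp: float) -> SlideRecord:
    """Resample a slide to ``target_mpp``.

    The image is resampled with a smooth interpolant; label and artifact masks
    with nearest-neighbour so no new codes appear. Returned record carries
    ``mpp = target_mpp``.
    """
    if target_mpp <= 0:
        raise ValueError("target_mpp must be positive")
    factor = slide.mpp / target_mpp
    if np.isclose(factor, 1.0):
        return replace(slide)
    h, w = slide.shape
    nh, nw = max(1, round(h * factor)), max(1, round(w * factor))
    image = resize(
        slide.image, (nh, nw), order=1, preserve_range=True, anti_aliasing=factor < 1
    )
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    label = None
    if slide.label_mask is not None:
        codes = resize(
            slide.label_mask.codes, (nh, nw), order=0, preserve_range=True,
            anti_aliasing=False,
        ).astype(slide.label_mask.codes.dtype)
        label = LabelMask(codes, slide.label_mask.scheme)
    artifact = None
    if slide.artifact_mask is not None:
        artifact = resize(
            slide.artifact_mask, (nh, nw), order=0, preserve_range=True,
            anti_aliasing=False,
        ).astype(bool)
    return SlideRecord(slide.slide_id, image, target_mpp, label, artifact)


# ---------------------------------------------------------------------------
# Raster I/O. Masks are single-channel 8-bit PNG/TIFF; slide images are RGB
# PNG/TIFF with MPP carried in a JSON sidecar (<stem>.json).
# ---------------------------------------------------------------------------

def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    arr = mask.codes.astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def read_label_mask(path: str | Path, scheme: ClassScheme) -> LabelMask:
    arr = np.asarray(Image.open(Path(path))).astype(np.int64)
    if arr.ndim != 2:
        raise ValueError("label mask file must be single-channel")
    return LabelMask(arr, scheme)  # validates codes against the scheme


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_slide(slide: SlideRecord, path: str | Path) -> None:
    path = Path(path)
    Image.fromarray(slide.image.astype(np.uint8), mode="RGB").save(path)
    meta = {"slide_id": slide.slide_id, "mpp": slide.mpp}
    _sidecar(path).write_text(json.dumps(meta))


def read_slide(path: str | Path, scheme: ClassScheme | None = None) -> SlideRecord:
    """Read a slide raster plus sidecar metadata; optional ``<stem>_mask`` raster."""
    path = Path(path)
    image = np.asarray(Image.open(path).convert("RGB"))
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    mask = None
    mask_path = path.with_name(path.stem + "_mask.png")
    if mask_path.exists():
        if scheme is None:
            raise ValueError("a ClassScheme is required to read the label mask")
        mask = read_label_mask(mask_path, scheme)
    return SlideRecord(meta["slide_id"], image, float(meta["mpp"]), mask)
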