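"""Patch-to-feature-vector contract with a deterministic built-in encoder.

The built-in encoder is a hand-crafted descriptor, not a learned model: per
channel an 8-bin intensity histogram (normalized to sum 1), concatenated with
an 8-bin gradient-orientation histogram of the luminance channel (magnitude
weighted, normalized; all-zero when the patch has no gradient), d = 32. It is
a pure function of pixel content, which is what the similarity engine needs
from any encoder; foundation encoders (UNI, Prov-Gigapath, ...) plug in
through :func:`external_encoder_adapter` without their weights ever being part
of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import json
import numpy as np

from .core_io import Patch

BUILTIN_ENCODER_ID = "histogram32"
_N_BINS = 8


@dataclass(frozen=True)
class EncoderSpec:
    """Identity and geometry of an encoder: input patch size and output dim."""

    encoder_id: str = BUILTIN_ENCODER_ID
    input_size: int = 224
    output_dim: int = 4 * _N_BINS
    resize: bool = True  # resize mismatched patches instead of erroring

    def __post_init__(self) -> None:
        if self.input_size <= 0:
            raise ValueError("input_size must be positive")


@dataclass
class FeatureSet:
    """Per-slide patch embeddings: row i of ``vectors`` encodes ``patch_refs[i]``."""

    slide_id: str
    vectors: np.ndarray  # n x d
    patch_refs: list[tuple[int, int]]
    encoder_id: str = BUILTIN_ENCODER_ID

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be an n x d matrix")
        if self.vectors.shape[0] != len(self.patch_refs):
            raise ValueError("rows must align with patch_refs")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors must be finite")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def save(self, path: str | Path) -> None:
        """Persist as a columnar binary container with a JSON header."""
        path = Path(path)
        np.savez(
            path,
            vectors=self.vectors,
            patch_refs=np.asarray(self.patch_refs, dtype=np.int64),
            header=np.frombuffer(
                json.dumps(
                    {
                        "slide_id": self.slide_id,
                        "encoder_id": self.encoder_id,
                        "d": int(self.vectors.shape[1]),
                    }
                ).encode(),
                dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path: str | Path, expect_encoder_id: str | None = None) -> "FeatureSet":
        data = np.load(Path(path))
        header = json.loads(bytes(data["header"]).decode())
        if expect_encoder_id is not None and header["encoder_id"] != expect_encoder_id:
            raise ValueError(
                f"feature cache was built with encoder {header['encoder_id']!r}, "
                f"expected {expect_encoder_id!r}; re-encode the slide"
            )
        refs = [tuple(int(v) for v in row) for row in data["patch_refs"]]
        return cls(header["slide_id"], data["vectors"], refs, header["encoder_id"])


def _luminance(pixels: np.ndarray) -> np.ndarray:
    p = pixels.astype(float)
    return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]


def _builtin_encode(pixels: np.ndarray) -> np.ndarray:
    parts = []
    for c in range(3):
        hist, _ = np.histogram(pixels[..., c], bins=_N_BINS, range=(0, 256))
        parts.append(hist / hist.sum())
    lum = _luminance(pixels)
    gy, gx = np.gradient(lum)
    mag = np.hypot(gx, gy)
    total = mag.sum()
    if total == 0:
        parts.append(np.zeros(_N_BINS))
    else:
        # orientation (mod pi): a bar and its mirror image share a bin
        theta = np.mod(np.arctan2(gy, gx), np.pi)
        hist, _ = np.histogram(theta, bins=_N_BINS, range=(0.0, np.pi), weights=mag)
        parts.append(hist / total)
    return np.concatenate(parts)


_EXTERNAL: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def _resolve(spec: EncoderSpec) -> Callable[[np.ndarray], np.ndarray]:
    if spec.encoder_id == BUILTIN_ENCODER_ID:
        return _builtin_encode
    try:
        return _EXTERNAL[spec.encoder_id]
    except KeyError:
        raise KeyError(f"no encoder registered under {spec.encoder_id!r}") from None


def _prepare(pixels: np.ndarray, spec: EncoderSpec) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.shape[:2] != (spec.input_size, spec.input_size):
        if not spec.resize:
            raise ValueError(
                f"patch size {pixels.shape[:2]} does not match encoder input "
                f"{spec.input_size} and resizing is disabled"
            )
        img = np.asarray(pixels, dtype=np.uint8)
        from PIL import Image

        pixels = np.asarray(
            Image.fromarray(img).resize((spec.input_size, spec.input_size), Image.BILINEAR)
        )
    return pixels


def encode_patch(patch: Patch, spec: EncoderSpec | None = None) -> np.ndarray:
    """Encode one patch to a length-d feature vector (deterministic)."""
    spec = spec or EncoderSpec()
    vec = _resolve(spec)(_prepare(patch.pixels, spec))
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.shape[0] != spec.output_dim:
        raise ValueError(
            f"encoder {spec.encoder_id!r} returned length {vec.shape[0]}, "
            f"expected {spec.output_dim}"
        )
    return vec


def encode_patches(patches: Sequence[Patch], spec: EncoderSpec | None = None) -> FeatureSet:
    """Encode an ordered list of patches from one slide into a FeatureSet."""
    if not patches:
        raise ValueError("no tumor patches available to encode")
    spec = spec or EncoderSpec()
    slide_ids = {p.slide_id for p in patches}
    if len(slide_ids) != 1:
        raise ValueError("all patches must come from one slide")
    vectors = np.stack([encode_patch(p, spec) for p in patches])
    return FeatureSet(patches[0].slide_id, vectors, [p.origin for p in patches], spec.encoder_id)


def external_encoder_adapter(
    fn: Callable[[np.ndarray], np.ndarray], spec: EncoderSpec
) -> EncoderSpec:
    """Register an external encoder callable under ``spec.encoder_id``.

    Runs conformance probes at registration: output length, determinism, and
    sensitivity to input (two encodes of the same raster must agree exactly;
    output must be a finite length-d vector).
    """
    probe = np.zeros((spec.input_size, spec.input_size, 3), dtype=np.uint8)
    probe[:, spec.input_size // 2 :, :] = 255
    out1 = np.asarray(fn(probe), dtype=float).ravel()
    if out1.shape[0] != spec.output_dim:
        raise ValueError(
            f"adapter output length {out1.shape[0]} != declared dim {spec.output_dim}"
        )
    if not np.all(np.isfinite(out1)):
        raise ValueError("adapter produced non-finite values")
    out2 = np.asarray(fn(probe), dtype=float).ravel()
    if not np.array_equal(out1, out2):
        raise ValueError("adapter is not deterministic: repeated encodes differ")
    uniform = np.full((spec.input_size, spec.input_size, 3), 128, dtype=np.uint8)
    out3 = np.asarray(fn(uniform), dtype=float).ravel()
    if out3.shape[0] != spec.output_dim:
        raise ValueError("adapter output length varies with input")
    _EXTERNAL[spec.encoder_id] = fn
    return spec
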