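"""Reading/writing fundus image + vessel mask pairs and offline augmentation.

Supported directory layouts:

``flat``   root/images/* and root/masks/* paired by file stem (optional
           root/fov/* field-of-view masks).
``drive``  DRIVE convention: root/images/, root/1st_manual/ (vessel masks),
           root/mask/ (FOV); files paired by their leading numeric id.
``stare``  STARE convention: root/images/ and root/masks/ paired by the
           leading ``imNNNN`` token; the canonical 15/5 train/test split is
           taken over sorted ids (first 15 train, last 5 test) when no
           explicit split is supplied.

Images are normalized to float32 [0, 1]; masks are binarized at 0.5 (so
grayscale annotations such as {0, 128, 255} become {0, 1, 1}).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["SegmentationSample", "load_dataset", "write_sample", "augment", "GEOMETRIC_OPS", "NOISE_OPS"]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".gif", ".ppm", ".jpg", ".jpeg", ".bmp")


@dataclass
class SegmentationSample:
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    fov: np.ndarray | None = None  # (H, W) uint8 in {0, 1}
    id: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"sample {self.id!r}: image {self.image.shape[:2]} and mask {self.mask.shape} disagree"
            )


def _to_float01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def _read_image(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 4:  # animated formats (GIF) come back as a frame stack
        arr = arr[0]
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return _to_float01(arr)


def _read_mask(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 4:
        arr = arr[0]
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (_to_float01(arr) > 0.5).astype(np.uint8)


def _list_images(d: Path) -> list[Path]:
    return sorted(p for p in d.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)


def _leading_id(path: Path) -> str:
    m = re.match(r"(\d+|im\d+)", path.stem)
    return m.group(1) if m else path.stem


def _pair_by_key(images: list[Path], masks: list[Path], key, what: str) -> list[tuple[str, Path, Path]]:
    mask_by_key = {key(m): m for m in masks}
    pairs, missing = [], []
    for img in images:
        k = key(img)
        if k in mask_by_key:
            pairs.append((k, img, mask_by_key[k]))
        else:
            missing.append(img.name)
    if missing:
        raise FileNotFoundError(f"no {what} mask found for image(s): {', '.join(missing)}")
    return sorted(pairs)


def load_dataset(root, layout: str = "flat", split: str = "all") -> list[SegmentationSample]:
    """Load an ordered (sorted by id) list of samples from ``root``."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    if layout == "flat":
        pairs = _pair_by_key(_list_images(root / "images"), _list_images(root / "masks"),
                             lambda p: p.stem, "flat-layout")
        fov_dir = root / "fov"
    elif layout == "drive":
        pairs = _pair_by_key(_list_images(root / "images"), _list_images(root / "1st_manual"),
                             _leading_id, "DRIVE manual")
        fov_dir = root / "mask"
    elif layout == "stare":
        pairs = _pair_by_key(_list_images(root / "images"), _list_images(root / "masks"),
                             _leading_id, "STARE")
        fov_dir = root / "fov"
        if split in ("train", "test"):
            # canonical convention: first 15 sorted ids train, last 5 test
            n_test = max(len(pairs) // 4, 1) if len(pairs) != 20 else 5
            pairs = pairs[:-n_test] if split == "train" else pairs[-n_test:]
    else:
        raise ValueError(f"unknown layout {layout!r}; choose flat, drive or stare")
    if layout != "stare" and split not in ("all", "train", "test"):
        raise ValueError(f"unknown split {split!r}")

    fov_by_key = {}
    if fov_dir.is_dir():
        key = _leading_id if layout in ("drive", "stare") else (lambda p: p.stem)
        fov_by_key = {key(p): p for p in _list_images(fov_dir)}

    samples = []
    for sid, img_path, mask_path in pairs:
        fov = _read_mask(fov_by_key[sid]) if sid in fov_by_key else None
        samples.append(SegmentationSample(_read_image(img_path), _read_mask(mask_path), fov, str(sid)))
    if not samples:
        raise FileNotFoundError(f"no image/mask pairs found under {root} (layout={layout})")
    return samples


def write_sample(sample: SegmentationSample, images_dir, masks_dir) -> None:
    """Write a sample as 8-bit PNGs (mask as {0, 255})."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    images_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    img8 = np.round(np.clip(sample.image, 0, 1) * 255).astype(np.uint8)
    iio.imwrite(images_dir / f"{sample.id}.png", img8)
    iio.imwrite(masks_dir / f"{sample.id}.png", (sample.mask * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# augmentation

GEOMETRIC_OPS = ("hflip", "vflip", "rot90", "rot180", "rot270")
NOISE_OPS = ("gaussian_noise", "salt_pepper")

_GEOM = {
    "hflip": lambda a: np.flip(a, axis=1),
    "vflip": lambda a: np.flip(a, axis=0),
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
}


def _apply_gaussian(image: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    return np.clip(image + rng.normal(0.0, sigma, size=image.shape).astype(np.float32), 0.0, 1.0)


def _apply_salt_pepper(image: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    out = image.copy()
    hit = rng.random(image.shape[:2]) < rate
    salt = rng.random(image.shape[:2]) < 0.5
    out[hit & salt] = 1.0
    out[hit & ~salt] = 0.0
    return out


def _normalize_op(op) -> tuple[str, dict]:
    if isinstance(op, str):
        return op, {}
    name, params = op
    return name, dict(params)


def augment(sample: SegmentationSample, ops, seed: int, include_original: bool = False) -> list[SegmentationSample]:
    """Offline expansion: one new sample per op, seeded and reproducible.

    Geometric ops transform image, mask and FOV identically; noise ops perturb
    the image only.  ``ops`` entries are names or ``(name, {param: value})``
    pairs; defaults sigma=0.02 and rate=0.02 on the [0, 1] intensity scale.
    """
    rng = np.random.default_rng(seed)
    out = [sample] if include_original else []
    for op in ops:
        name, params = _normalize_op(op)
        if name in _GEOM:
            f = _GEOM[name]
            out.append(SegmentationSample(
                image=np.ascontiguousarray(f(sample.image)),
                mask=np.ascontiguousarray(f(sample.mask)),
                fov=None if sample.fov is None else np.ascontiguousarray(f(sample.fov)),
                id=f"{sample.id}_{name}",
            ))
        elif name == "gaussian_noise":
            img = _apply_gaussian(sample.image, rng, params.get("sigma", 0.02))
            out.append(SegmentationSample(img, sample.mask.copy(), sample.fov, f"{sample.id}_{name}"))
        elif name == "salt_pepper":
            img = _apply_salt_pepper(sample.image, rng, params.get("rate", 0.02))
            out.append(SegmentationSample(img, sample.mask.copy(), sample.fov, f"{sample.id}_{name}"))
        else:
            raise ValueError(f"unknown augmentation op {name!r}")
    return out
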