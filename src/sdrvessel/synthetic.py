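"""Synthetic fundus-like images with branching vessel trees.

Real fundus photographs pair a bright, red-dominant, radially illuminated
background with a sparse (~6-14% of pixels) network of darker curvilinear
vessels whose width tapers from trunk to capillary.  The generator emulates
exactly those statistics so every stage of the tool is exercisable without
external data: vessel masks come from a recursive random branching walk with
heading jitter (smooth, tortuous strokes; child width = parent width x taper,
clamped at 1 pixel so a thin-capillary regime is always present), and the
rendered image subtracts a fixed contrast from an illumination-graded
background under Gaussian + salt-and-pepper noise.

It does NOT model optic discs, lesions, inter-image color variation, or
annotation noise — results on it say nothing about those aspects of real data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_io import SegmentationSample, write_sample

__all__ = ["SynthConfig", "generate_vessel_mask", "render_fundus", "generate_sample",
           "make_dataset", "regenerate_from_manifest"]


@dataclass
class SynthConfig:
    image_size: int = 64
    n_trees: int = 3
    branch_depth: int = 3
    width_root: float = 2.4
    width_taper: float = 0.7
    vessel_fraction: tuple = (0.06, 0.14)
    heading_jitter: float = 0.25  # radians per step
    branch_angle: float = 0.55  # radians, +/- at each split
    contrast: float = 0.25  # background-minus-vessel intensity drop
    illumination_gradient: float = 0.35  # radial darkening toward the rim
    base_color: tuple = (0.85, 0.55, 0.45)  # red-dominant fundus tint
    noise_sigma: float = 0.02
    salt_pepper_rate: float = 0.005
    max_retries: int = 40

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vessel_fraction"] = list(self.vessel_fraction)
        d["base_color"] = list(self.base_color)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["vessel_fraction"] = tuple(d["vessel_fraction"])
        d["base_color"] = tuple(d["base_color"])
        return cls(**d)


def _stamp_disk(canvas: np.ndarray, y: float, x: float, radius: float) -> None:
    n = canvas.shape[0]
    r = max(radius, 0.5)
    lo_y, hi_y = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
    lo_x, hi_x = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
    lo_y, lo_x = max(lo_y, 0), max(lo_x, 0)
    hi_y, hi_x = min(hi_y, n), min(hi_x, n)
    if lo_y >= hi_y or lo_x >= hi_x:
        return
    yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
    canvas[lo_y:hi_y, lo_x:hi_x] |= (yy - y) ** 2 + (xx - x) ** 2 <= r**2


def _grow_segment(canvas, y, x, heading, width, depth, cfg: SynthConfig, rng) -> None:
    n = canvas.shape[0]
    length = int(n / (cfg.branch_depth + 2)) + rng.integers(0, max(n // 8, 2))
    for _ in range(length):
        _stamp_disk(canvas, y, x, width / 2.0)
        heading += rng.normal(0.0, cfg.heading_jitter)
        y += np.sin(heading)
        x += np.cos(heading)
        if not (-2 <= y < n + 2 and -2 <= x < n + 2):
            return
    if depth > 0:
        child_width = max(width * cfg.width_taper, 1.0)
        for sign in (-1.0, 1.0):
            angle = heading + sign * (cfg.branch_angle + rng.normal(0.0, 0.15))
            _grow_segment(canvas, y, x, angle, child_width, depth - 1, cfg, rng)


def _draw_trees(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.image_size
    # stroke width is defined at the 64-pixel reference scale so the vessel
    # fraction stays resolution-independent (capillaries still bottom out at 1 px)
    width_root = cfg.width_root * n / 64.0
    canvas = np.zeros((n, n), dtype=bool)
    for _ in range(cfg.n_trees):
        side = rng.integers(4)
        t = rng.uniform(0.15, 0.85) * n
        if side == 0:
            y, x, heading = 0.0, t, np.pi / 2
        elif side == 1:
            y, x, heading = float(n - 1), t, -np.pi / 2
        elif side == 2:
            y, x, heading = t, 0.0, 0.0
        else:
            y, x, heading = t, float(n - 1), np.pi
        heading += rng.normal(0.0, 0.3)
        _grow_segment(canvas, y, x, heading, width_root, cfg.branch_depth, cfg, rng)
    return canvas


def generate_vessel_mask(cfg: SynthConfig, seed: int) -> np.ndarray:
    """Binary vessel mask whose foreground fraction lies in cfg.vessel_fraction.

    Headings are resampled (fresh child seeds) until the fraction lands in the
    target interval; raises after cfg.max_retries failures.
    """
    lo, hi = cfg.vessel_fraction
    children = np.random.SeedSequence(seed).spawn(cfg.max_retries)
    last = None
    for child in children:
        rng = np.random.default_rng(child)
        mask = _draw_trees(cfg, rng)
        last = frac = mask.mean()
        if lo <= frac <= hi:
            return mask.astype(np.uint8)
    raise RuntimeError(
        f"could not reach vessel fraction in [{lo}, {hi}] after {cfg.max_retries} retries "
        f"(last fraction {last:.3f}); adjust n_trees, branch_depth or width_root"
    )


def render_fundus(mask: np.ndarray, cfg: SynthConfig, seed: int) -> np.ndarray:
    """RGB float32 image in [0, 1]: illumination-graded background, vessels
    darker by cfg.contrast, plus Gaussian and salt-and-pepper noise."""
    rng = np.random.default_rng(seed)
    n = mask.shape[0]
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    c = (n - 1) / 2.0
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / (2 * c**2 + 1e-9)
    illum = 1.0 - cfg.illumination_gradient * r2
    img = np.stack([b * illum for b in cfg.base_color], axis=-1).astype(np.float32)
    img -= cfg.contrast * mask[..., None].astype(np.float32)
    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, size=img.shape).astype(np.float32)
    if cfg.salt_pepper_rate > 0:
        hit = rng.random((n, n)) < cfg.salt_pepper_rate
        salt = rng.random((n, n)) < 0.5
        img[hit & salt] = 1.0
        img[hit & ~salt] = 0.0
    return np.clip(img, 0.0, 1.0)


def generate_sample(cfg: SynthConfig, mask_seed: int, render_seed: int, sample_id: str) -> SegmentationSample:
    mask = generate_vessel_mask(cfg, mask_seed)
    image = render_fundus(mask, cfg, render_seed)
    return SegmentationSample(image=image, mask=mask, id=sample_id)


def make_dataset(cfg: SynthConfig, n: int, out_dir, seed: int = 0) -> list[SegmentationSample]:
    """Write n image/mask PNG pairs in the flat layout plus a JSON manifest
    recording the config and every per-sample seed (for byte-exact replay)."""
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    records, samples = [], []
    for i in range(n):
        mask_seed = int(rng.integers(2**31))
        render_seed = int(rng.integers(2**31))
        sid = f"sample_{i:03d}"
        s = generate_sample(cfg, mask_seed, render_seed, sid)
        write_sample(s, out_dir / "images", out_dir / "masks")
        records.append({"id": sid, "mask_seed": mask_seed, "render_seed": render_seed})
        samples.append(s)
    manifest = {"config": cfg.to_dict(), "seed": seed, "n": n, "samples": records}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return samples


def regenerate_from_manifest(manifest_path) -> list[SegmentationSample]:
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = SynthConfig.from_dict(manifest["config"])
    return [generate_sample(cfg, r["mask_seed"], r["render_seed"], r["id"]) for r in manifest["samples"]]
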