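"""Synthetic two-photon soma image generation.

Training an instance segmenter needs exhaustively labelled images, which
manual tracing cannot supply at scale.  This module builds labelled images
the copy-paste way: neuropil background tiles are shuffled, randomly placed
and feather-blended into a full-size synthetic background, and annotated
soma crops are cut, pasted at random positions and alpha-blended on top,
recording a per-instance ground-truth mask for every successful paste.
A parametric renderer supplies the soma bank (bright ellipses with smooth
Gaussian-style intensity falloff whose peak brightness depends on the
perfusion condition: NMDA > washout > baseline, mirroring calcium-indicator
fluorescence regimes), and salt-and-pepper corruption is available for
robustness experiments.

All randomness flows from explicit seeds; a dataset is a pure function of
its :class:`GeneratorConfig`.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CONDITIONS",
    "CONDITION_PEAK_RANGES",
    "BackgroundTile",
    "AnnotatedCell",
    "SyntheticImage",
    "GeneratorConfig",
    "extract_tiles",
    "compose_background",
    "render_cell",
    "paste_cells",
    "add_salt_pepper",
    "build_cell_bank",
    "build_tile_bank",
    "generate_dataset",
]

CONDITIONS = ("baseline", "nmda", "washout")

# Peak soma intensity per perfusion condition; NMDA perfusion drives the
# calcium indicator brightest, washout relaxes to mid-high, baseline is dim.
CONDITION_PEAK_RANGES: dict[str, tuple[float, float]] = {
    "baseline": (0.3, 0.6),
    "nmda": (0.6, 1.0),
    "washout": (0.45, 0.8),
}

# mask = pixels where the rendered profile exceeds this fraction of peak
_MASK_FRACTION = 0.3


@dataclass
class BackgroundTile:
    """A rectangular neuropil patch cut from a source image."""

    pixels: np.ndarray
    source_id: str = ""
    box: tuple[int, int, int, int] = (0, 0, 0, 0)  # row, col, height, width

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.size == 0 or self.pixels.ndim != 2:
            raise ValueError("tile pixels must be a nonempty 2D array")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("tile pixel values must lie in [0, 1]")
        if self.box[2:] != (0, 0) and self.box[2:] != self.pixels.shape:
            raise ValueError("box dimensions must match pixel shape")


@dataclass
class AnnotatedCell:
    """A soma crop with its binary mask and perfusion-condition tag."""

    pixels: np.ndarray
    mask: np.ndarray
    condition: str = "baseline"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must equal pixel shape")
        if not self.mask.any():
            raise ValueError("mask must contain at least one pixel")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        _, n = ndimage.label(self.mask)
        if n != 1:
            raise ValueError("mask must be a single connected component")


@dataclass
class SyntheticImage:
    """A composed image with per-instance ground-truth masks."""

    pixels: np.ndarray
    instances: list[np.ndarray] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        for m in self.instances:
            if m.shape != self.pixels.shape:
                raise ValueError("instance masks must match image shape")
            if not m.any():
                raise ValueError("instance masks must be nonempty")


@dataclass
class GeneratorConfig:
    n_images: int = 10
    image_size: tuple[int, int] = (512, 512)
    cells_per_image: tuple[int, int] = (5, 20)       # inclusive range
    max_pairwise_overlap_iou: float = 0.1
    min_separation_px: int = 0            # gap enforced between instance masks
    max_placement_retries: int = 50
    feather_width: int = 3
    noise_density: float = 0.0
    condition_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0
    image_format: str = "tiff"                        # "tiff" (16-bit) or "png" (8-bit)

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.cells_per_image[0] > self.cells_per_image[1] or self.cells_per_image[0] < 0:
            raise ValueError("cells_per_image must be a nonempty nonnegative range")
        if not 0 <= self.max_pairwise_overlap_iou < 1:
            raise ValueError("max_pairwise_overlap_iou must lie in [0, 1)")
        if not 0 <= self.noise_density <= 1:
            raise ValueError("noise_density must lie in [0, 1]")
        if abs(sum(self.condition_mix) - 1.0) > 1e-6:
            raise ValueError("condition_mix must sum to 1")
        if self.image_format not in ("tiff", "png"):
            raise ValueError("image_format must be 'tiff' or 'png'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["cells_per_image"] = list(self.cells_per_image)
        d["condition_mix"] = list(self.condition_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("image_size", "cells_per_image", "condition_mix"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------


def extract_tiles(image: np.ndarray, boxes: list[tuple[int, int, int, int]],
                  source_id: str = "") -> list[BackgroundTile]:
    """Cut background tiles out of an image; boxes are (row, col, h, w), half-open."""
    image = np.asarray(image, dtype=np.float32)
    tiles = []
    for box in boxes:
        r, c, h, w = box
        if r < 0 or c < 0 or h < 1 or w < 1 or r + h > image.shape[0] or c + w > image.shape[1]:
            raise ValueError(f"box {box} lies outside image of shape {image.shape}")
        tiles.append(BackgroundTile(image[r:r + h, c:c + w].copy(), source_id, (r, c, h, w)))
    return tiles


def _feather_weight(h: int, w: int, margin: int) -> np.ndarray:
    """Separable edge-ramp weight, strictly positive so blends normalise."""
    def ramp(n: int) -> np.ndarray:
        x = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(np.float32)
        return np.clip((x + 1.0) / max(margin, 1), 1e-3, 1.0)
    return np.outer(ramp(h), ramp(w))


def compose_background(tiles: list[BackgroundTile], size: tuple[int, int],
                       rng: np.random.Generator, overlap: int = 8) -> np.ndarray:
    """Mosaic shuffled tiles into a full background with feathered seams.

    Tiles are placed on a raster that steps slightly less than a tile, so
    neighbours overlap; each contribution is weighted by an edge ramp and
    the accumulated image is divided by the accumulated weight, making the
    per-pixel blend weights sum to one and seams continuous.
    """
    if not tiles:
        raise ValueError("at least one background tile is required")
    hh, ww = size
    for t in tiles:
        if t.pixels.shape[0] > hh or t.pixels.shape[1] > ww:
            raise ValueError("tiles must be no larger than the target size")
    num = np.zeros(size, dtype=np.float64)
    den = np.zeros(size, dtype=np.float64)
    r = 0
    while r < hh:
        c = 0
        row_step = None
        while c < ww:
            tile = tiles[rng.integers(len(tiles))]
            th, tw = tile.pixels.shape
            rr, cc = min(r, hh - th), min(c, ww - tw)
            wgt = _feather_weight(th, tw, overlap)
            num[rr:rr + th, cc:cc + tw] += tile.pixels * wgt
            den[rr:rr + th, cc:cc + tw] += wgt
            step = max(tw - overlap, 1)
            row_step = th if row_step is None else min(row_step, th)
            c += step
        r += max(row_step - overlap, 1)
    out = num / den
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def render_cell(radius_range: tuple[float, float] = (4.0, 10.0),
                eccentricity_range: tuple[float, float] = (1.0, 1.6),
                peak_intensity_range: tuple[float, float] | None = None,
                condition: str = "baseline",
                rng: np.random.Generator | None = None,
                texture_sd: float = 0.04) -> AnnotatedCell:
    """Render a parametric soma: a bright ellipse with smooth intensity falloff.

    ``radius_range`` samples the geometric-mean radius r (px, >= 2);
    eccentricity stretches one axis by sqrt(e) and shrinks the other, so
    the mask area stays close to pi*r^2.  The profile decays as a Gaussian
    in normalised elliptical radius, scaled so it crosses the mask
    threshold (30% of peak) exactly at the nominal boundary; the mask is
    therefore the discretised ellipse.  Peak intensity is drawn from the
    condition's regime unless an explicit range is given.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if radius_range[0] < 2:
        raise ValueError("radius must be at least 2 px")
    if peak_intensity_range is None:
        peak_intensity_range = CONDITION_PEAK_RANGES[condition]
    lo, hi = peak_intensity_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("peak intensity range must lie within (0, 1]")
    r = rng.uniform(*radius_range)
    e = rng.uniform(*eccentricity_range)
    theta = rng.uniform(0, np.pi)
    peak = rng.uniform(lo, hi)
    ra, rb = r * np.sqrt(e), r / np.sqrt(e)
    pad = 3.0
    half = int(np.ceil(ra + pad))
    n = 2 * half + 1
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32) - half
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * xx + st * yy) / ra
    v = (-st * xx + ct * yy) / rb
    rho2 = u * u + v * v
    # exp(-rho^2/(2 s^2)) == _MASK_FRACTION at rho == 1
    s2 = -0.5 / np.log(_MASK_FRACTION)
    profile = np.exp(-0.5 * rho2 / s2).astype(np.float32)
    mask = profile >= _MASK_FRACTION
    pixels = peak * profile
    if texture_sd > 0:
        pixels = pixels * (1.0 + texture_sd * rng.standard_normal(pixels.shape).astype(np.float32))
    pixels = np.clip(pixels, 0.0, peak).astype(np.float32)
    # re-impose the exact peak at the centre so degenerate ranges are exact
    pixels[half, half] = peak
    return AnnotatedCell(pixels, mask, condition)


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    return inter / np.logical_or(a, b).sum()


def _feathered_alpha(mask: np.ndarray, feather_width: int) -> np.ndarray:
    """Alpha 1 inside the mask eroded by the feather width, 0 beyond the
    dilation, linear in the signed boundary distance in between."""
    if feather_width <= 0:
        return mask.astype(np.float32)
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    signed = d_in - d_out
    return np.clip((signed + feather_width) / (2.0 * feather_width), 0.0, 1.0).astype(np.float32)


def paste_cells(background: np.ndarray, cells: list[AnnotatedCell],
                cfg: GeneratorConfig, rng: np.random.Generator) -> SyntheticImage:
    """Paste soma crops onto a background with feathered alpha compositing.

    Offsets are sampled uniformly; a placement is rejected and resampled
    when its mask IOU with any already-placed instance exceeds
    ``cfg.max_pairwise_overlap_iou``, or, with ``cfg.min_separation_px``
    set, when the new mask dilated by that many pixels touches an existing
    instance.  After ``cfg.max_placement_retries`` failures the cell is
    skipped and the skip recorded in provenance, so instance counts never
    silently drift.
    """
    background = np.asarray(background, dtype=np.float32)
    hh, ww = background.shape
    out = background.copy()
    instances: list[np.ndarray] = []
    provenance: list[dict] = []
    for ci, cell in enumerate(cells):
        ch, cw = cell.pixels.shape
        if ch > hh or cw > ww:
            provenance.append({"cell": ci, "placed": False, "reason": "too_large"})
            continue
        placed = False
        for _ in range(max(cfg.max_placement_retries, 1)):
            r = int(rng.integers(0, hh - ch + 1))
            c = int(rng.integers(0, ww - cw + 1))
            full_mask = np.zeros((hh, ww), dtype=bool)
            full_mask[r:r + ch, c:c + cw] = cell.mask
            ok = all(_mask_iou(full_mask, m) <= cfg.max_pairwise_overlap_iou
                     for m in instances)
            if ok and cfg.min_separation_px > 0 and instances:
                dilated = ndimage.binary_dilation(
                    full_mask, iterations=cfg.min_separation_px)
                ok = not any(np.logical_and(dilated, m).any() for m in instances)
            if ok:
                alpha = _feathered_alpha(cell.mask, cfg.feather_width)
                region = out[r:r + ch, c:c + cw]
                out[r:r + ch, c:c + cw] = alpha * cell.pixels + (1.0 - alpha) * region
                instances.append(full_mask)
                provenance.append({"cell": ci, "placed": True, "offset": (r, c),
                                   "feather_width": cfg.feather_width,
                                   "condition": cell.condition})
                placed = True
                break
        if not placed and ch <= hh and cw <= ww:
            provenance.append({"cell": ci, "placed": False, "reason": "overlap"})
    return SyntheticImage(np.clip(out, 0.0, 1.0), instances, provenance)


def add_salt_pepper(image: np.ndarray, density: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Replace each pixel independently by 0 or 1 (equal odds) with probability ``density``."""
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    image = np.asarray(image, dtype=np.float32)
    hit = rng.random(image.shape) < density
    salt = rng.random(image.shape) < 0.5
    out = image.copy()
    out[hit] = salt[hit].astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# default banks


def build_tile_bank(n_tiles: int = 24, tile_size: tuple[int, int] = (64, 64),
                    rng: np.random.Generator | None = None,
                    neuropil_mean: float = 0.18, neuropil_sd: float = 0.06) -> list[BackgroundTile]:
    """Cut tiles from a synthetic textured neuropil image.

    The source texture is smoothed Gaussian noise around a mean below the
    baseline soma intensity regime, emulating the diffuse neuropil signal.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    th, tw = tile_size
    src_h, src_w = th * 4, tw * 4
    noise = rng.standard_normal((src_h, src_w))
    texture = ndimage.gaussian_filter(noise, sigma=3.0)
    texture = texture / max(texture.std(), 1e-9) * neuropil_sd + neuropil_mean
    fine = ndimage.gaussian_filter(rng.standard_normal((src_h, src_w)), sigma=1.0)
    texture = np.clip(texture + 0.3 * neuropil_sd * fine, 0.0, 1.0).astype(np.float32)
    boxes = []
    for _ in range(n_tiles):
        r = int(rng.integers(0, src_h - th + 1))
        c = int(rng.integers(0, src_w - tw + 1))
        boxes.append((r, c, th, tw))
    return extract_tiles(texture, boxes, source_id="synthetic_neuropil")


def build_cell_bank(n_cells: int = 64, rng: np.random.Generator | None = None,
                    condition_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                    radius_range: tuple[float, float] = (4.0, 10.0)) -> list[AnnotatedCell]:
    """Render a bank of parametric somas across the three perfusion conditions."""
    rng = rng if rng is not None else np.random.default_rng(0)
    conditions = rng.choice(len(CONDITIONS), size=n_cells, p=list(condition_mix))
    return [render_cell(radius_range=radius_range, condition=CONDITIONS[int(k)], rng=rng)
            for k in conditions]


# ---------------------------------------------------------------------------
# dataset generation


def _augment_cell(cell: AnnotatedCell, rng: np.random.Generator) -> AnnotatedCell:
    """Random flip / 90-degree rotation of a bank cell."""
    px, mk = cell.pixels, cell.mask
    k = int(rng.integers(4))
    px, mk = np.rot90(px, k), np.rot90(mk, k)
    if rng.random() < 0.5:
        px, mk = px[:, ::-1], mk[:, ::-1]
    return AnnotatedCell(np.ascontiguousarray(px), np.ascontiguousarray(mk), cell.condition)


def synthesize_image(cfg: GeneratorConfig, cell_bank: list[AnnotatedCell],
                     tile_bank: list[BackgroundTile], seed: int) -> SyntheticImage:
    """Build one synthetic image from its child seed."""
    rng = np.random.default_rng(seed)
    bg = compose_background(tile_bank, cfg.image_size, rng)
    lo, hi = cfg.cells_per_image
    n_cells = int(rng.integers(lo, hi + 1))
    picks = [_augment_cell(cell_bank[int(rng.integers(len(cell_bank)))], rng)
             for _ in range(n_cells)]
    img = paste_cells(bg, picks, cfg, rng)
    if cfg.noise_density > 0:
        img.pixels = add_salt_pepper(img.pixels, cfg.noise_density, rng)
    img.rng_seed = seed
    return img


def generate_dataset(cfg: GeneratorConfig, cell_bank: list[AnnotatedCell] | None,
                     tile_bank: list[BackgroundTile] | None, out_dir) -> dict:
    """Write ``cfg.n_images`` images plus COCO-style annotations and a manifest.

    Per-image child seeds derive deterministically from ``cfg.seed``, so
    re-running with the same config reproduces identical files.  Returns
    the manifest (also written as ``manifest.json``).
    """
    from . import io as sio  # local import to avoid a cycle

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output path {out_dir} is not writable: {exc}") from exc

    bank_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    if cell_bank is None:
        cell_bank = build_cell_bank(rng=bank_rng, condition_mix=cfg.condition_mix)
    if tile_bank is None:
        tile_bank = build_tile_bank(rng=bank_rng)
    if not cell_bank or not tile_bank:
        raise ValueError("cell and tile banks must be nonempty")

    ext = "tif" if cfg.image_format == "tiff" else "png"
    records = []
    images_meta = []
    entries = []
    for i in range(cfg.n_images):
        child_seed = int(np.random.SeedSequence([int(cfg.seed), 2, i]).generate_state(1)[0] % (2 ** 31))
        img = synthesize_image(cfg, cell_bank, tile_bank, child_seed)
        fname = f"synthetic_{i:05d}.{ext}"
        sio.write_image(out_dir / fname, img.pixels, bit_depth=16 if ext == "tif" else 8)
        images_meta.append({"id": i, "file_name": fname,
                            "height": img.pixels.shape[0], "width": img.pixels.shape[1]})
        for m in img.instances:
            records.append({"image_id": i, "mask": m, "category": "neuron_soma", "score": None})
        entries.append({"file": fname, "seed": child_seed,
                        "n_instances": len(img.instances),
                        "n_skipped": sum(1 for p in img.provenance if not p.get("placed"))})
    ann_path = out_dir / "annotations.json"
    sio.write_annotations(ann_path, records, images_meta)
    manifest = {
        "config": cfg.to_dict(),
        "annotations": ann_path.name,
        "images": entries,
        "n_images": cfg.n_images,
        "total_instances": int(sum(e["n_instances"] for e in entries)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def file_digest(path) -> str:
    """SHA-256 of a file, for byte-reproducibility checks."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
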