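"""Image and annotation I/O.

Images are single- or multi-page grayscale TIFF (16-bit) or PNG (8-bit).
Annotations use a COCO-style JSON layout (images / annotations /
categories, one category ``neuron_soma``) with masks stored as
uncompressed column-major run-length counts — the same RLE convention as
the COCO tools, which makes the round trip bit-exact.  Coordinates are
0-based, row-major; rectangles are half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio

__all__ = [
    "rle_encode", "rle_decode",
    "read_image", "write_image", "read_stack",
    "read_annotations", "write_annotations",
]


def rle_encode(mask: np.ndarray) -> dict:
    """Encode a binary mask as COCO-style uncompressed RLE.

    Runs are counted down the columns (Fortran order) and the counts list
    always starts with the number of leading zeros, possibly 0.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.reshape(-1, order="F").astype(np.int8)
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    if sum(counts) != h * w:
        raise ValueError(f"RLE counts sum to {sum(counts)}, expected {h * w}")
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for n in counts:
        if val:
            flat[pos:pos + n] = True
        pos += n
        val = not val
    return flat.reshape((h, w), order="F")


def _to_float01(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.float32) / info.max).astype(np.float32)
    return arr.astype(np.float32)


def write_image(path, image: np.ndarray, bit_depth: int | None = None) -> None:
    """Write a grayscale image; floats in [0,1] are scaled to the bit depth.

    TIFF paths get 16-bit by default, PNG 8-bit.  Integer input is written
    unchanged (its dtype must match the requested depth).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if bit_depth is None:
        bit_depth = 16 if suffix in (".tif", ".tiff") else 8
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.floating):
        if image.min() < -1e-6 or image.max() > 1 + 1e-6:
            raise ValueError("float images must lie in [0, 1]")
        scale = 2 ** bit_depth - 1
        data = np.round(np.clip(image, 0, 1) * scale).astype(
            np.uint16 if bit_depth == 16 else np.uint8)
    else:
        data = image
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif suffix == ".png":
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format: {suffix}")


def read_image(path, normalize: bool = True) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> grayscale
        arr = arr[..., :3].mean(axis=-1)
    return _to_float01(arr) if normalize else arr


def read_stack(path, z_step_um: float = 2.0, pixel_size_um: float = 1.0):
    """Read a multi-page TIFF as a Z-stack (single page -> one slice)."""
    from .preprocess import ZStack

    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"could not read stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"stack {path} has unexpected shape {arr.shape}")
    slices = [_to_float01(s) for s in arr]
    return ZStack(slices, z_step_um=z_step_um, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# COCO-style annotations


def write_annotations(path, records: list[dict], images: list[dict]) -> None:
    """Write instance records as COCO-style JSON.

    ``records`` entries carry ``image_id``, a boolean ``mask`` and optional
    ``score``; ``images`` entries carry ``id``, ``file_name``, ``height``,
    ``width``.
    """
    annotations = []
    for i, rec in enumerate(records):
        mask = np.asarray(rec["mask"], dtype=bool)
        ys, xs = np.nonzero(mask)
        if len(ys) == 0:
            raise ValueError(f"record {i}: empty mask")
        bbox = [int(xs.min()), int(ys.min()),
                int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)]
        ann = {
            "id": i,
            "image_id": int(rec["image_id"]),
            "category_id": 1,
            "segmentation": rle_encode(mask),
            "area": int(mask.sum()),
            "bbox": bbox,
            "iscrowd": 0,
        }
        if rec.get("score") is not None:
            ann["score"] = float(rec["score"])
        annotations.append(ann)
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "neuron_soma"}],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_annotations(path) -> tuple[list[dict], list[dict]]:
    """Read COCO-style JSON back into (records, images).

    Masks are decoded from RLE; each record is validated against its
    image's declared size, and errors name the file and record index.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"could not parse annotations {path}: {exc}") from exc
    images = doc.get("images", [])
    sizes = {im["id"]: (im["height"], im["width"]) for im in images}
    records = []
    for i, ann in enumerate(doc.get("annotations", [])):
        try:
            image_id = ann["image_id"]
            if image_id not in sizes:
                raise ValueError(f"unknown image_id {image_id}")
            h, w = sizes[image_id]
            seg = ann["segmentation"]
            if list(seg["size"]) != [h, w]:
                raise ValueError(f"mask size {seg['size']} != image size {[h, w]}")
            mask = rle_decode(seg)
            x, y, bw, bh = ann.get("bbox", [0, 0, w, h])
            if x < 0 or y < 0 or x + bw > w or y + bh > h:
                raise ValueError(f"bbox {ann['bbox']} outside image bounds {(h, w)}")
            records.append({
                "image_id": image_id,
                "mask": mask,
                "category": "neuron_soma",
                "score": ann.get("score"),
            })
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"{path}: invalid annotation record {i}: {exc}") from exc
    return records, images
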