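"""Readers and writers for ROIs, partitions, trees, UCMs and label maps.

Conventions used throughout: pixel coordinates are 0-based (row, col),
rasters are row-major, and contours are closed polylines in (x=col, y=row)
order.  16-bit and Hounsfield-unit inputs are linearly rescaled to
[0, 255] with the min-max mapping recorded in the returned metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hierarchy import SegmentationTree, UCMap
from .srm import Partition

__all__ = [
    "load_roi",
    "save_partition",
    "load_seed_raster",
    "save_labelmap",
    "save_ucm_png",
    "save_ucm_edges",
    "load_ucm_edges",
    "tree_to_json",
    "save_tree",
    "write_manifest",
]

#: palette for label maps: green parenchyma, blue wall, yellow GGO/vessel,
#: red solid nodule
LABEL_COLORS = {
    0: (0, 0, 0),
    1: (0, 176, 80),
    2: (0, 112, 192),
    3: (255, 255, 0),
    4: (255, 0, 0),
}


def _rescale_to_u8(arr: np.ndarray) -> tuple[np.ndarray, dict]:
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        out = np.zeros(arr.shape, dtype=np.uint8)
    else:
        out = np.rint((arr.astype(np.float64) - lo) / (hi - lo) * 255.0)
        out = out.astype(np.uint8)
    return out, {"in_min": lo, "in_max": hi, "out_range": [0, 255]}


def load_roi(path: str | Path,
             crop: tuple[int, int, int, int] | None = None
             ) -> tuple[np.ndarray, dict]:
    """Load a grayscale ROI from PNG/TIFF or a DICOM slice.

    ``crop`` is an optional (row0, col0, height, width) rectangle, required
    to make sense of a full DICOM slice.  Returns the 8-bit image and a
    metadata dict recording the source and any intensity rescale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {"source": str(path)}
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        meta["units"] = "HU" if slope != 1.0 or intercept != 0.0 else "raw"
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError("multi-channel input; a single-channel "
                             "grayscale raster is required")
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("ROI must be a non-empty 2-D raster")
    if crop is not None:
        r0, c0, ch, cw = crop
        if ch <= 0 or cw <= 0 or r0 < 0 or c0 < 0 \
                or r0 + ch > arr.shape[0] or c0 + cw > arr.shape[1]:
            raise ValueError("empty or out-of-bounds crop rectangle")
        arr = arr[r0:r0 + ch, c0:c0 + cw]
        meta["crop"] = [r0, c0, ch, cw]
    if arr.dtype == np.uint8:
        img = arr.copy()
        meta["rescale"] = None
    else:
        img, rescale = _rescale_to_u8(arr)
        meta["rescale"] = rescale
    return img, meta


def save_partition(png_path: str | Path, json_path: str | Path,
                   part: Partition) -> None:
    """Write a partition as a 16-bit region-id PNG plus a JSON stats sidecar."""
    import imageio.v3 as iio

    if part.n_regions > 2**16:
        raise ValueError("more regions than a 16-bit raster can carry")
    iio.imwrite(str(png_path), part.labels.astype(np.uint16))
    stats = {
        "n_regions": part.n_regions,
        "sizes": part.sizes.tolist(),
        "means": [float(m) for m in part.means],
    }
    Path(json_path).write_text(json.dumps(stats))


def load_seed_raster(path: str | Path) -> np.ndarray:
    """Read a seed raster: an integer PNG (0 = unlabeled) or a palette/RGB
    PNG using the documented class colors."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 2:
        return arr.astype(np.int64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[:, :, :3]
        out = np.zeros(rgb.shape[:2], dtype=np.int64)
        for label, color in LABEL_COLORS.items():
            if label == 0:
                continue
            out[np.all(rgb == np.array(color), axis=2)] = label
        return out
    raise ValueError("unsupported seed raster format")


def save_labelmap(path: str | Path, labelmap: np.ndarray,
                  raster_path: str | Path | None = None) -> None:
    """Write a label map as a palette PNG (class colors); optionally also as
    a plain integer raster."""
    from PIL import Image

    lab = np.asarray(labelmap)
    pal_img = Image.fromarray(lab.astype(np.uint8), mode="P")
    palette = [0] * 768
    for label, color in LABEL_COLORS.items():
        palette[3 * label: 3 * label + 3] = list(color)
    pal_img.putpalette(palette)
    pal_img.save(str(path))
    if raster_path is not None:
        import imageio.v3 as iio

        iio.imwrite(str(raster_path), lab.astype(np.uint16))


def save_ucm_png(path: str | Path, ucm: UCMap) -> None:
    """Visualize a UCM at doubled resolution ((2H+1) x (2W+1)).

    Interpixel edges become drawable pixels; saliency is linearly rescaled
    to [0, 255].
    """
    import imageio.v3 as iio

    h, w = ucm.shape
    canvas = np.zeros((2 * h + 1, 2 * w + 1), dtype=np.float64)
    scale = 255.0 / max(ucm.n_levels, 1)
    # a horizontal couple (r,c)-(r,c+1) is separated by a vertical contour
    canvas[1::2, 2:-1:2] = ucm.horiz * scale
    canvas[2:-1:2, 1::2] = ucm.vert * scale
    iio.imwrite(str(path), np.rint(canvas).astype(np.uint8))


def save_ucm_edges(path: str | Path, ucm: UCMap) -> None:
    """Lossless edge-list export: one ``r1,c1,r2,c2,saliency`` row per
    interpixel edge."""
    lines = [f"# shape {ucm.shape[0]} {ucm.shape[1]} levels {ucm.n_levels}"]
    h, w = ucm.shape
    for r in range(h):
        for c in range(w - 1):
            lines.append(f"{r},{c},{r},{c + 1},{int(ucm.horiz[r, c])}")
    for r in range(h - 1):
        for c in range(w):
            lines.append(f"{r},{c},{r + 1},{c},{int(ucm.vert[r, c])}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_ucm_edges(path: str | Path) -> UCMap:
    """Exact inverse of :func:`save_ucm_edges`."""
    text = Path(path).read_text().strip().splitlines()
    head = text[0].split()
    h, w, n_levels = int(head[2]), int(head[3]), int(head[5])
    horiz = np.zeros((h, w - 1), dtype=np.int32)
    vert = np.zeros((h - 1, w), dtype=np.int32)
    for line in text[1:]:
        r1, c1, r2, c2, sal = (int(v) for v in line.split(","))
        if r1 == r2:
            horiz[r1, min(c1, c2)] = sal
        else:
            vert[min(r1, r2), c1] = sal
    return UCMap(horiz=horiz, vert=vert, n_levels=n_levels)


def tree_to_json(tree: SegmentationTree) -> dict:
    """JSON-serializable description of a segmentation tree."""
    return {
        "n_levels": tree.n_levels,
        "root": tree.root,
        "nodes": [
            {
                "id": i,
                "parent": int(tree.parent[i]),
                "children": list(tree.children[i]),
                "birth_level": int(tree.birth_level[i]),
                "death_level": int(tree.death_level[i]),
                "size": int(tree.sizes[i]),
            }
            for i in range(tree.n_nodes)
        ],
    }


def save_tree(path: str | Path, tree: SegmentationTree) -> None:
    Path(path).write_text(json.dumps(tree_to_json(tree)))


def write_manifest(path: str | Path, config_dict: dict, extra: dict | None = None) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    import aphseg

    manifest = {
        "aphseg_version": aphseg.__version__,
        "numpy_version": np.__version__,
        "config": config_dict,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
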