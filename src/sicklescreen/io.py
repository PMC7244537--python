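"""File formats: images as PNG/TIFF, masks as palette PNG, tables as CSV."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .synthetic import CellSpec, annotation_point

# palette for label masks: background, normal (red), sickle (blue)
_MASK_PALETTE = [0, 0, 0, 220, 60, 60, 60, 60, 220]


def save_image(img: np.ndarray, path) -> None:
    """Unit-range RGB to 8-bit PNG or 16-bit TIFF by extension."""
    path = Path(path)
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (img * 65535 + 0.5).astype(np.uint16))
    else:
        Image.fromarray((img * 255 + 0.5).astype(np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(float)
        return arr / 65535.0 if arr.max() > 1.5 else arr
    arr = np.asarray(Image.open(path), dtype=float)
    return arr[..., :3] / 255.0


def save_mask(mask: np.ndarray, path) -> None:
    im = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    im.putpalette(_MASK_PALETTE + [0] * (768 - len(_MASK_PALETTE)))
    im.save(path)


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def save_probmap(p: np.ndarray, path) -> None:
    """Class probabilities as 3-channel 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(p, dtype=np.float32),
                     photometric="rgb")


def load_probmap(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def save_field(field: np.ndarray, path) -> None:
    """Displacement field as 2-channel 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(field, dtype=np.float32))


def load_field(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def save_affine(matrix: np.ndarray, path) -> None:
    """2x3 affine as a single 6-number CSV row."""
    np.savetxt(path, np.asarray(matrix, dtype=float).reshape(1, 6),
               delimiter=",")


def load_affine(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",").reshape(2, 3)


def cells_to_frame(fov_id: int, cells: Sequence[CellSpec]) -> pd.DataFrame:
    ann = [annotation_point(c) for c in cells]
    return pd.DataFrame({
        "fov_id": fov_id,
        "row": [c.center[0] for c in cells],
        "col": [c.center[1] for c in cells],
        # where an annotator would click (on the cell body)
        "ann_row": [a[0] for a in ann],
        "ann_col": [a[1] for a in ann],
        "kind": [c.kind for c in cells],
        "radius": [c.radius for c in cells],
        "orientation": [c.orientation for c in cells],
    })


def load_annotations(path) -> dict[int, list[tuple[float, float]]]:
    """CSV of fov_id,row,col point annotations grouped by FOV."""
    df = pd.read_csv(path)
    out: dict[int, list[tuple[float, float]]] = {}
    for _, r in df.iterrows():
        out.setdefault(int(r["fov_id"]), []).append((float(r["row"]),
                                                     float(r["col"])))
    return out
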