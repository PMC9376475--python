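"""Tile and table I/O: 8-bit RGB TIFF/PNG in, float TIFF / CSV / PNG out."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import InvalidInputError
from .segmentation import REGION_NAMES, CellSegment, RegionMap
from .stain import RGBImage, StainChannels


def load_rgb_tile(path, microns_per_pixel: float | None = None) -> RGBImage:
    """Load an 8-bit RGB tile from TIFF or PNG.

    For TIFF, the resolution tags supply microns_per_pixel when present and
    no explicit value is given.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            if microns_per_pixel is None:
                page = tf.pages[0]
                xres = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if xres is not None and unit is not None and getattr(unit, "value", None) is not None:
                    num, den = xres.value
                    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))  # inch / cm
                    if unit_um and num:
                        microns_per_pixel = unit_um * den / num
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise InvalidInputError(f"{path} is not an RGB image")
    if microns_per_pixel is None:
        microns_per_pixel = 0.5
    return RGBImage(pixels=arr[..., :3], microns_per_pixel=float(microns_per_pixel))


def save_rgb_tile(img: RGBImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels.astype(np.uint8))
    else:
        Image.fromarray(img.pixels.astype(np.uint8)).save(path)


def save_stain_channels(channels: StainChannels, out_dir) -> dict[str, Path]:
    """One 32-bit float TIFF per stain channel."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("hema", channels.hema), ("dab", channels.dab), ("residual", channels.residual)):
        p = out_dir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths[name] = p
    return paths


def cells_to_frame(cells, microns_per_pixel: float) -> pd.DataFrame:
    """One row per cell: id, class, centroid, areas, mean ODs, positivity."""
    rows = []
    for cell in cells:
        rows.append({
            "cell_id": cell.nucleus.id,
            "class": cell.cell_class,
            "centroid_row": cell.nucleus.centroid[0],
            "centroid_col": cell.nucleus.centroid[1],
            "nucleus_area_um2": cell.nucleus.area_um2,
            "cell_area_um2": cell.area_um2(microns_per_pixel),
            "mean_od_hema": cell.mean_od_hema,
            "mean_od_dab": cell.mean_od_dab,
            "pimo_positive": cell.pimo_positive,
        })
    return pd.DataFrame(rows)


def save_region_map(region: RegionMap, path_png, path_json=None) -> None:
    """Region map as a paletted PNG plus a JSON legend."""
    palette_rgb = {
        0: (255, 255, 255),  # background
        1: (220, 60, 60),    # epithelial
        2: (70, 110, 220),   # stromal_cellular
        3: (170, 200, 255),  # stromal_acellular
        4: (240, 210, 80),   # other
    }
    im = Image.fromarray(region.labels.astype(np.uint8), mode="P")
    flat = []
    for code in range(5):
        flat.extend(palette_rgb[code])
    im.putpalette(flat)
    im.save(path_png)
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump({str(k): v for k, v in REGION_NAMES.items()}, fh, indent=2)


def load_annotations(path, annotator_id: str | None = None):
    """Annotation CSV (cell_id, annotator_id, class_label[, stain_call]) -> AnnotationSet."""
    from .classify import AnnotationSet

    df = pd.read_csv(path)
    if annotator_id is not None:
        df = df[df["annotator_id"].astype(str) == str(annotator_id)]
    if df.empty:
        raise InvalidInputError(f"no annotations in {path}")
    labels = pd.Series(df["class_label"].values, index=df["cell_id"].values)
    stain = None
    if "stain_call" in df.columns:
        stain = pd.Series(df["stain_call"].values, index=df["cell_id"].values)
    aid = str(df["annotator_id"].iloc[0]) if "annotator_id" in df.columns else (annotator_id or "?")
    return AnnotationSet(annotator_id=aid, labels=labels, stain_call=stain)
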