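"""Nucleus segmentation and cell-body simulation.

Nuclei are segmented from the hematoxylin concentration channel (high
hematoxylin = chromatin) by Otsu thresholding, morphological cleanup and a
distance-transform watershed to split touching nuclei.  Each nucleus is then
expanded into a cell body by a class-specific radius — epithelial cells get
more cytoplasm than fibroblasts, which get more than lymphocytes — with
contested pixels going to the nearest nucleus.  Finally the tissue is
partitioned into epithelial / cellular-stroma / acellular-stroma / other
regions by subtracting cell bodies from the tissue mask.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed

from .errors import InvalidInputError

#: Class vocabulary used throughout the pipeline.
EPITHELIAL = "epithelial"
STROMAL = "stromal"
INFLAMMATORY = "inflammatory_other"
CELL_CLASSES = (EPITHELIAL, STROMAL, INFLAMMATORY)

#: Region-map codes.
REGION_BACKGROUND = 0
REGION_EPITHELIAL = 1
REGION_STROMAL_CELLULAR = 2
REGION_STROMAL_ACELLULAR = 3
REGION_OTHER = 4
REGION_NAMES = {
    REGION_BACKGROUND: "background",
    REGION_EPITHELIAL: "epithelial",
    REGION_STROMAL_CELLULAR: "stromal_cellular",
    REGION_STROMAL_ACELLULAR: "stromal_acellular",
    REGION_OTHER: "other",
}
#: Region codes that count as analyzed tumor tissue (the HP denominator).
ANALYZED_REGIONS = (REGION_EPITHELIAL, REGION_STROMAL_CELLULAR, REGION_STROMAL_ACELLULAR)


def _default_radii() -> dict[str, float]:
    return {EPITHELIAL: 4.0, STROMAL: 2.0, INFLAMMATORY: 1.0}


@dataclasses.dataclass(frozen=True)
class SizingHeuristics:
    """Cell-type-specific geometry priors.

    ``expansion_radius_um`` maps a cell class to the cytoplasm radius grown
    around its nucleus.  ``fibroblast_mean_area_um2`` is the average stromal
    cell footprint used when reasoning about cellular vs acellular stroma.
    Nucleus area bounds filter segmentation debris and clumps.
    """

    expansion_radius_um: Mapping[str, float] = dataclasses.field(default_factory=_default_radii)
    fibroblast_mean_area_um2: float = 40.0
    min_nucleus_area_um2: float = 8.0
    max_nucleus_area_um2: float = 300.0
    #: Floor on the Otsu nuclear threshold, in OD units.
    min_nuclear_od: float = 0.15

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.expansion_radius_um.values()):
            raise InvalidInputError("expansion radii must be non-negative")
        if self.fibroblast_mean_area_um2 <= 0 or self.min_nucleus_area_um2 <= 0:
            raise InvalidInputError("areas must be positive")
        if self.max_nucleus_area_um2 <= self.min_nucleus_area_um2:
            raise InvalidInputError("max_nucleus_area_um2 must exceed min_nucleus_area_um2")


@dataclasses.dataclass
class NucleusSegment:
    """One segmented nucleus: labelled pixel set plus derived geometry."""

    id: int
    rows: np.ndarray
    cols: np.ndarray
    centroid: tuple[float, float]
    area_um2: float

    @property
    def n_pixels(self) -> int:
        return len(self.rows)


@dataclasses.dataclass
class CellSegment:
    """A nucleus plus its simulated cytoplasm and, once known, its class and
    stain measurements."""

    nucleus: NucleusSegment
    cyto_rows: np.ndarray
    cyto_cols: np.ndarray
    cell_class: str
    mean_od_hema: float | None = None
    mean_od_dab: float | None = None
    pimo_positive: bool | None = None

    @property
    def all_rows(self) -> np.ndarray:
        return np.concatenate([self.nucleus.rows, self.cyto_rows])

    @property
    def all_cols(self) -> np.ndarray:
        return np.concatenate([self.nucleus.cols, self.cyto_cols])

    @property
    def n_pixels(self) -> int:
        return self.nucleus.n_pixels + len(self.cyto_rows)

    def area_um2(self, microns_per_pixel: float) -> float:
        return self.n_pixels * microns_per_pixel**2


@dataclasses.dataclass
class RegionMap:
    """Tissue partition: every pixel carries exactly one region code."""

    labels: np.ndarray  # H x W of REGION_* codes

    def areas_um2(self, microns_per_pixel: float) -> dict[str, float]:
        out = {}
        for code, name in REGION_NAMES.items():
            out[name] = float(np.count_nonzero(self.labels == code)) * microns_per_pixel**2
        return out

    def analyzed_area_um2(self, microns_per_pixel: float) -> float:
        mask = np.isin(self.labels, ANALYZED_REGIONS)
        return float(np.count_nonzero(mask)) * microns_per_pixel**2


def _label_pixel_sets(labels: np.ndarray) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Pixel coordinates per nonzero label, in one pass over the image."""
    flat = labels.ravel()
    idx = np.nonzero(flat)[0]
    if idx.size == 0:
        return {}
    labs = flat[idx]
    order = np.argsort(labs, kind="stable")
    idx = idx[order]
    labs = labs[order]
    bounds = np.nonzero(np.diff(labs))[0] + 1
    chunks = np.split(idx, bounds)
    width = labels.shape[1]
    out = {}
    for chunk in chunks:
        lab = int(flat[chunk[0]])
        out[lab] = (chunk // width, chunk % width)
    return out


def _merge_small_fragments(labels: np.ndarray, min_px: float) -> np.ndarray:
    """Reassign watershed fragments below ``min_px`` to their dominant
    touching neighbor (smallest first, lowest label on ties); fragments with
    no labelled neighbor are left for the size filter."""
    labels = labels.copy()
    h, w = labels.shape
    while True:
        sizes = np.bincount(labels.ravel())
        small = [lab for lab in np.nonzero(sizes)[0]
                 if lab > 0 and sizes[lab] < min_px]
        if not small:
            return labels
        small.sort(key=lambda lab: (sizes[lab], lab))
        changed = False
        for lab in small:
            rows, cols = np.nonzero(labels == lab)
            r0, r1 = max(rows.min() - 1, 0), min(rows.max() + 2, h)
            c0, c1 = max(cols.min() - 1, 0), min(cols.max() + 2, w)
            sub = labels[r0:r1, c0:c1]
            frag = sub == lab
            ring = ndi.binary_dilation(frag) & ~frag
            neighbors = sub[ring]
            neighbors = neighbors[(neighbors != 0) & (neighbors != lab)]
            if neighbors.size == 0:
                continue
            vals, counts = np.unique(neighbors, return_counts=True)
            target = int(vals[np.argmax(counts)])
            sub[frag] = target
            changed = True
        if not changed:
            return labels


def segment_nuclei(
    hema: np.ndarray,
    microns_per_pixel: float,
    heuristics: SizingHeuristics | None = None,
) -> list[NucleusSegment]:
    """Segment nuclei from a hematoxylin concentration channel.

    Otsu's threshold over the nonzero signal (floored at
    ``heuristics.min_nuclear_od``) selects chromatin, a one-pixel opening
    removes speckle, and a distance-transform watershed splits touching
    nuclei.  Segments outside the configured area bounds are dropped.
    Output ids are assigned in raster order of the centroids, so the result
    is deterministic.
    """
    heuristics = heuristics or SizingHeuristics()
    hema = np.asarray(hema, dtype=float)
    if hema.ndim != 2:
        raise InvalidInputError("hema channel must be 2-D")
    nonzero = hema[hema > 0]
    if nonzero.size == 0:
        return []
    if np.ptp(nonzero) == 0:
        thr = max(float(nonzero.flat[0]), heuristics.min_nuclear_od)
    else:
        thr = max(float(threshold_otsu(nonzero)), heuristics.min_nuclear_od)
    mask = hema >= thr
    mask = ndi.binary_opening(mask, structure=disk(1).astype(bool))
    if not mask.any():
        return []

    dist = ndi.distance_transform_edt(mask)
    # smoothing suppresses the plateau of near-equal maxima that elongated
    # (fibroblast) nuclei produce along their ridge line
    dist_s = ndi.gaussian_filter(dist, sigma=1.0)
    min_r_px = math.sqrt(heuristics.min_nucleus_area_um2 / math.pi) / microns_per_pixel
    min_distance = max(int(round(min_r_px)), 1)
    coords = peak_local_max(dist_s, min_distance=min_distance, labels=mask, exclude_border=False)
    if coords.shape[0] == 0:
        return []
    markers = np.zeros(mask.shape, dtype=np.int32)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    for k, (r, c) in enumerate(coords[order], start=1):
        markers[r, c] = k
    labels = watershed(-dist_s, markers, mask=mask)
    labels = _merge_small_fragments(
        labels, heuristics.min_nucleus_area_um2 / microns_per_pixel**2)

    px_area = microns_per_pixel**2
    segments = []
    for lab, (rows, cols) in _label_pixel_sets(labels).items():
        area = len(rows) * px_area
        if not (heuristics.min_nucleus_area_um2 <= area <= heuristics.max_nucleus_area_um2):
            continue
        centroid = (float(rows.mean()), float(cols.mean()))
        segments.append(NucleusSegment(id=lab, rows=rows, cols=cols, centroid=centroid, area_um2=area))
    # deterministic ids in raster order of centroid
    segments.sort(key=lambda s: s.centroid)
    for new_id, seg in enumerate(segments, start=1):
        seg.id = new_id
    return segments


def expand_cytoplasm(
    nuclei: Sequence[NucleusSegment],
    classes: Sequence[str],
    heuristics: SizingHeuristics,
    tissue_mask: np.ndarray,
    microns_per_pixel: float,
) -> list[CellSegment]:
    """Grow each nucleus into a cell body by its class-specific radius.

    A pixel joins the cell of the nearest nucleus among those whose dilation
    reaches it; exact distance ties go to the lowest nucleus id.  Growth is
    restricted to ``tissue_mask`` and never overwrites another nucleus, so
    cells are mutually disjoint and their union equals the union of the
    individual dilations (intersected with tissue).
    """
    if len(nuclei) != len(classes):
        raise InvalidInputError("one class label per nucleus required")
    for cls in classes:
        if cls not in heuristics.expansion_radius_um:
            raise InvalidInputError(f"unknown cell class {cls!r}")
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    shape = tissue_mask.shape

    nucleus_label = np.zeros(shape, dtype=np.int32)
    for seg in nuclei:
        nucleus_label[seg.rows, seg.cols] = seg.id

    best_dist = np.full(shape, np.inf, dtype=float)
    best_id = np.zeros(shape, dtype=np.int32)
    # ascending id order + strict < means ties resolve to the lowest id
    for seg, cls in sorted(zip(nuclei, classes), key=lambda t: t[0].id):
        r_px = heuristics.expansion_radius_um[cls] / microns_per_pixel
        pad = int(math.ceil(r_px)) + 1
        r0 = max(int(seg.rows.min()) - pad, 0)
        r1 = min(int(seg.rows.max()) + pad + 1, shape[0])
        c0 = max(int(seg.cols.min()) - pad, 0)
        c1 = min(int(seg.cols.max()) + pad + 1, shape[1])
        sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        sub[seg.rows - r0, seg.cols - c0] = True
        d = ndi.distance_transform_edt(~sub)
        cand = d <= r_px
        view_d = best_dist[r0:r1, c0:c1]
        view_i = best_id[r0:r1, c0:c1]
        upd = cand & (d < view_d)
        view_d[upd] = d[upd]
        view_i[upd] = seg.id

    claim = best_id.copy()
    claim[~tissue_mask] = 0
    claim[nucleus_label > 0] = 0  # nucleus pixels stay with their own cell
    cyto_sets = _label_pixel_sets(claim)

    cells = []
    empty = np.empty(0, dtype=np.int64)
    for seg, cls in zip(nuclei, classes):
        rows, cols = cyto_sets.get(seg.id, (empty, empty))
        cells.append(CellSegment(nucleus=seg, cyto_rows=rows, cyto_cols=cols, cell_class=cls))
    return cells


def expand_cytoplasm_generic(
    nuclei: Sequence[NucleusSegment],
    tissue_mask: np.ndarray,
    microns_per_pixel: float,
    classes: Sequence[str] | None = None,
    radius_um: float = 2.0,
) -> list[CellSegment]:
    """Uniform expansion: every nucleus grows the same ``radius_um`` (default
    2 µm), mirroring the generic one-size-fits-all cytoplasm simulation of
    tissue-level platforms.  Equivalent to :func:`expand_cytoplasm` with all
    class radii set to ``radius_um``."""
    if classes is None:
        classes = [STROMAL] * len(nuclei)
    radii = {cls: radius_um for cls in set(classes)}
    heur = SizingHeuristics(expansion_radius_um=radii)
    return expand_cytoplasm(nuclei, classes, heur, tissue_mask, microns_per_pixel)


def measure_cells(cells: Sequence[CellSegment], hema: np.ndarray, dab: np.ndarray) -> None:
    """Fill in per-cell mean hematoxylin / DAB OD over nucleus + cytoplasm."""
    for cell in cells:
        rows, cols = cell.all_rows, cell.all_cols
        if rows.size == 0:
            cell.mean_od_hema = 0.0
            cell.mean_od_dab = 0.0
            continue
        cell.mean_od_hema = float(hema[rows, cols].mean())
        cell.mean_od_dab = float(dab[rows, cols].mean())


def build_region_map(
    cells: Sequence[CellSegment],
    tissue_mask: np.ndarray,
    heuristics: SizingHeuristics | None = None,
) -> RegionMap:
    """Partition the tissue mask into regions by painting cell bodies.

    Epithelial cells paint epithelial, stromal cells cellular stroma,
    inflammatory/other cells the excluded "other" region; tissue left over
    after subtracting all cell bodies is acellular stroma, and everything
    outside the mask is background.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    labels = np.full(tissue_mask.shape, REGION_BACKGROUND, dtype=np.uint8)
    labels[tissue_mask] = REGION_STROMAL_ACELLULAR
    code = {
        EPITHELIAL: REGION_EPITHELIAL,
        STROMAL: REGION_STROMAL_CELLULAR,
        INFLAMMATORY: REGION_OTHER,
    }
    for cell in cells:
        c = code.get(cell.cell_class)
        if c is None:
            raise InvalidInputError(f"unknown cell class {cell.cell_class!r}")
        rows, cols = cell.all_rows, cell.all_cols
        keep = tissue_mask[rows, cols]
        labels[rows[keep], cols[keep]] = c
    return RegionMap(labels=labels)
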