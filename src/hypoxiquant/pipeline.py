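"""End-to-end tile analysis: stain prep -> segmentation -> typing -> scoring.

This module wires the stage modules together the way the tool is meant to be
run: white-balance a tile, deconvolve it, segment nuclei from the
hematoxylin channel, classify them (with a trained model), expand class-
specific cell bodies, score positivity and compute the HP record.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi

from . import classify, scoring, segmentation, stain
from .classify import ClassifierModel
from .scoring import HPRecord, PositivityRule
from .segmentation import CellSegment, NucleusSegment, RegionMap, SizingHeuristics
from .stain import RGBImage, StainBasis, StainChannels

#: Total OD below this is treated as glass/whitespace, not tissue.
TISSUE_OD_THRESHOLD = 0.06


def tissue_mask_from_od(od: np.ndarray, threshold: float = TISSUE_OD_THRESHOLD) -> np.ndarray:
    """Analyzable-tissue mask: pixels with appreciable total absorbance.

    A binary closing fills small intracellular gaps so faintly stained
    cytoplasm is not punched out of the mask.
    """
    total = np.asarray(od).sum(axis=-1)
    mask = total > threshold
    return ndi.binary_closing(mask, structure=np.ones((3, 3)), iterations=2)


@dataclasses.dataclass
class TileAnalysis:
    """All intermediate and final products of one tile."""

    white_point: stain.WhitePoint
    channels: StainChannels
    tissue_mask: np.ndarray
    nuclei: list[NucleusSegment]
    classes: list[str]
    cells: list[CellSegment]
    region_map: RegionMap
    hp_record: HPRecord


def analyze_tile(
    img: RGBImage,
    model: ClassifierModel | None = None,
    classes: Sequence[str] | None = None,
    basis: StainBasis | None = None,
    heuristics: SizingHeuristics | None = None,
    rule: PositivityRule | None = None,
    patient_id: str = "",
    section_id: str = "",
    roi_id: str | None = None,
) -> TileAnalysis:
    """Run the full pipeline on one tile.

    Cell classes come from ``model`` (pixel-wise forest + per-cell vote) or,
    for oracle runs, from an explicit ``classes`` sequence parallel to the
    detected nuclei.
    """
    basis = basis or StainBasis.hdab()
    heuristics = heuristics or SizingHeuristics()
    rule = rule or PositivityRule()

    wp = stain.estimate_white_balance(img)
    od = stain.rgb_to_od(img, wp)
    channels = stain.deconvolve(od, basis)
    mask = tissue_mask_from_od(od.od)

    nuclei = segmentation.segment_nuclei(channels.hema, img.microns_per_pixel, heuristics)
    if classes is None:
        if model is None:
            raise ValueError("either a trained model or explicit classes is required")
        classes = classify.predict_cell_classes(model, nuclei, channels)
    else:
        classes = list(classes)

    cells = segmentation.expand_cytoplasm(nuclei, classes, heuristics, mask, img.microns_per_pixel)
    segmentation.measure_cells(cells, channels.hema, channels.dab)
    scoring.score_cells(cells, rule)
    region_map = segmentation.build_region_map(cells, mask)
    hp = scoring.compute_hp(cells, region_map, img.microns_per_pixel,
                            patient_id=patient_id, section_id=section_id, roi_id=roi_id)
    return TileAnalysis(
        white_point=wp, channels=channels, tissue_mask=mask, nuclei=nuclei,
        classes=classes, cells=cells, region_map=region_map, hp_record=hp,
    )


def match_nuclei_to_truth(
    nuclei: Sequence[NucleusSegment],
    truth_label_image: np.ndarray,
    truth_labels: Mapping[int, str],
) -> dict[int, str]:
    """Transfer ground-truth (or consensus) labels onto detected nuclei.

    Each detected nucleus takes the label of the truth nucleus that covers
    the plurality of its pixels; nuclei with no overlap stay unannotated.
    """
    out = {}
    for seg in nuclei:
        overlap = truth_label_image[seg.rows, seg.cols]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            out[seg.id] = classify.UNANNOTATED
            continue
        ids, counts = np.unique(overlap, return_counts=True)
        truth_id = int(ids[np.argmax(counts)])
        out[seg.id] = truth_labels.get(truth_id, classify.UNANNOTATED)
    return out


def truth_label_image(truth) -> np.ndarray:
    """Nucleus-id label image from a :class:`~hypoxiquant.synth.SynthGroundTruth`."""
    shape = truth.region_map.labels.shape
    img = np.zeros(shape, dtype=np.int32)
    for seg in truth.nuclei:
        img[seg.rows, seg.cols] = seg.id
    return img
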