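"""Pimonidazole positivity and hypoxic-percentage (HP) scoring.

A cell is pimonidazole positive when more than half of its mean optical
density comes from the DAB channel and the DAB density clears a minimum
threshold.  HP is area-based: the area of positive cells in a compartment
divided by the total analyzed tumor area.  Because both compartments share
one denominator, HP-whole-tumor = HP-epithelial + HP-stromal exactly, at
every aggregation level.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedRecordError
from .segmentation import (
    ANALYZED_REGIONS,
    EPITHELIAL,
    STROMAL,
    CellSegment,
    RegionMap,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PositivityRule:
    """Decision rule for pimonidazole positivity.

    ``dab_fraction_threshold``: minimum DAB share of the cell's mean OD
    (strict inequality).  ``min_od``: minimum DAB mean OD asserting that
    stain is actually present.
    """

    dab_fraction_threshold: float = 0.5
    min_od: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.dab_fraction_threshold < 1:
            raise InvalidInputError("dab_fraction_threshold must be in (0, 1)")
        if self.min_od < 0:
            raise InvalidInputError("min_od must be non-negative")


def score_cell_positivity(cell: CellSegment, rule: PositivityRule | None = None) -> bool:
    """Apply the positivity rule to one measured cell.

    Positive iff dab / (dab + hema) > threshold and dab >= min_od; cells
    with zero total stain are negative.
    """
    rule = rule or PositivityRule()
    if cell.mean_od_dab is None or cell.mean_od_hema is None:
        raise InvalidInputError("cell mean ODs must be measured before scoring")
    dab, hema = cell.mean_od_dab, cell.mean_od_hema
    total = dab + hema
    if total <= 0:
        return False
    return (dab / total > rule.dab_fraction_threshold) and (dab >= rule.min_od)


def score_cells(cells: Sequence[CellSegment], rule: PositivityRule | None = None) -> None:
    """Set ``pimo_positive`` on every cell in place."""
    rule = rule or PositivityRule()
    for cell in cells:
        cell.pimo_positive = score_cell_positivity(cell, rule)


@dataclasses.dataclass
class HPRecord:
    """Hypoxic percentages for one ROI / section / patient unit.

    ``hp_wt`` is a derived property, so the additivity identity
    hp_wt = hp_epi + hp_str holds exactly by construction.
    """

    patient_id: str
    section_id: str
    roi_id: str | None
    hp_epi: float
    hp_str: float
    area_analyzed_um2: float
    areas_um2: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.hp_epi and 0 <= self.hp_str and self.hp_epi + self.hp_str <= 100 + 1e-9):
            raise InvalidInputError("HP components must be in [0, 100] and sum to <= 100")

    @property
    def hp_wt(self) -> float:
        return self.hp_epi + self.hp_str


def compute_hp(
    cells: Sequence[CellSegment],
    region: RegionMap,
    microns_per_pixel: float,
    patient_id: str = "",
    section_id: str = "",
    roi_id: str | None = None,
) -> HPRecord:
    """Compute area-based hypoxic percentages for one ROI.

    The denominator is the whole analyzed tumor area (epithelial +
    cellular-stromal + acellular-stromal regions); numerators are the areas
    of positive epithelial and positive stromal cells.  Inflammatory/other
    cells are excluded from the numerators (and their region from the
    denominator).
    """
    labels = region.labels
    denom_px = int(np.count_nonzero(np.isin(labels, ANALYZED_REGIONS)))
    if denom_px == 0:
        raise UndefinedRecordError("zero analyzed tissue area")
    pos_px = {EPITHELIAL: 0, STROMAL: 0}
    for cell in cells:
        if cell.pimo_positive is None:
            raise InvalidInputError("cells must be scored for positivity first")
        if cell.pimo_positive and cell.cell_class in pos_px:
            pos_px[cell.cell_class] += cell.n_pixels
    px_area = microns_per_pixel**2
    return HPRecord(
        patient_id=patient_id,
        section_id=section_id,
        roi_id=roi_id,
        hp_epi=100.0 * pos_px[EPITHELIAL] / denom_px,
        hp_str=100.0 * pos_px[STROMAL] / denom_px,
        area_analyzed_um2=denom_px * px_area,
        areas_um2=region.areas_um2(microns_per_pixel),
    )


def aggregate_hp(records: Sequence[HPRecord], level: str) -> list[HPRecord]:
    """Area-weighted aggregation of HP records to section or patient level.

    Weighting by analyzed area makes the aggregate identical to pooling the
    underlying pixels, and preserves hp_wt = hp_epi + hp_str.
    """
    if level not in ("section", "patient"):
        raise InvalidInputError("level must be 'section' or 'patient'")
    key = (lambda r: (r.patient_id, r.section_id)) if level == "section" else (lambda r: (r.patient_id,))
    groups: dict[tuple, list[HPRecord]] = {}
    for rec in records:
        groups.setdefault(key(rec), []).append(rec)
    out = []
    for k, group in groups.items():
        w = np.array([r.area_analyzed_um2 for r in group])
        if w.sum() <= 0:
            logger.warning("skipping empty group %s", k)
            continue
        hp_epi = float(np.average([r.hp_epi for r in group], weights=w))
        hp_str = float(np.average([r.hp_str for r in group], weights=w))
        out.append(
            HPRecord(
                patient_id=group[0].patient_id,
                section_id=group[0].section_id if level == "section" else "",
                roi_id=None,
                hp_epi=hp_epi,
                hp_str=hp_str,
                area_analyzed_um2=float(w.sum()),
            )
        )
    return out


def records_to_frame(records: Sequence[HPRecord]) -> pd.DataFrame:
    """Flatten records to the canonical HP table schema."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "section_id": r.section_id,
                "roi_id": r.roi_id,
                "hp_epi": r.hp_epi,
                "hp_str": r.hp_str,
                "hp_wt": r.hp_wt,
                "area_analyzed_um2": r.area_analyzed_um2,
            }
            for r in records
        ]
    )
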