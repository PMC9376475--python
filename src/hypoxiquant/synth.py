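"""Synthetic H-DAB histology and hierarchical HP tables with full ground truth.

The tissue generator emulates a PDAC field: clustered round epithelial
nuclei arranged in gland-like rings around empty lumina, sparse elongated
fibroblast nuclei in the intervening stroma, and small dense
inflammatory-cell nuclei.  A diffusion-limited hypoxia gradient is rendered
as DAB optical density decaying exponentially with distance from randomly
placed line sources ("hypoxic cords", the poorly perfused regions remote
from vasculature); cells inside the gradient become pimonidazole positive
under the same positivity rule the pipeline applies.  The tile is composed
through the stain basis and inverse Beer-Lambert transform, so the analysis
pipeline sees exactly the physics it assumes, plus Gaussian sensor noise.

The HP-table generator draws the nested random-effects model directly:
value_psr = clip(mu + b_p + s_ps + e_psr, 0, 100).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .classify import AnnotationSet, UNANNOTATED
from .errors import InvalidInputError, PackingError
from .scoring import HPRecord, PositivityRule, compute_hp, score_cells
from .segmentation import (
    CELL_CLASSES,
    EPITHELIAL,
    INFLAMMATORY,
    STROMAL,
    CellSegment,
    NucleusSegment,
    RegionMap,
    SizingHeuristics,
    build_region_map,
    expand_cytoplasm,
    measure_cells,
)
from .stain import RGBImage, StainBasis, compose_od


def _default_hema_od() -> dict[str, float]:
    # inflammatory nuclei are chromatin-dense, fibroblasts intermediate
    return {EPITHELIAL: 0.65, STROMAL: 0.45, INFLAMMATORY: 0.95}


@dataclasses.dataclass
class TissueSynthConfig:
    """Geometry, staining and noise parameters of a synthetic tile.

    Defaults emulate a 512 x 384 µm ROI at 0.5 µm/px with a desmoplastic
    PDAC morphology: ~45% of the area is cell bodies, the rest acellular
    stroma and gland lumina.
    """

    width_um: float = 512.0
    height_um: float = 384.0
    microns_per_pixel: float = 0.5
    # cell counts and geometry
    n_epithelial: int = 220
    n_stromal: int = 140
    n_inflammatory: int = 40
    n_glands: int = 6
    gland_radius_um: float = 28.0
    lumen_fraction: float = 0.35  # lumen radius as fraction of gland radius
    epi_nucleus_radius_um: float = 3.2
    stromal_major_um: float = 4.5
    stromal_minor_um: float = 1.4
    infl_nucleus_radius_um: float = 2.0
    # staining
    hema_od: dict = dataclasses.field(default_factory=_default_hema_od)
    cytoplasm_hema_od: float = 0.08
    nucleus_od_jitter: float = 0.05
    # hypoxia field
    n_hypoxia_sources: int = 2
    dab_decay_um: float = 45.0
    dab_max_od: float = 0.9
    target_hp_wt: float | None = None  # calibrate DAB scale to hit this HP
    # composition
    basis: StainBasis = dataclasses.field(default_factory=StainBasis.hdab)
    white_point: tuple[float, float, float] = (246.0, 248.0, 245.0)
    noise_sigma: float = 1.5  # RGB intensity units
    heuristics: SizingHeuristics = dataclasses.field(default_factory=SizingHeuristics)
    rule: PositivityRule = dataclasses.field(default_factory=PositivityRule)
    seed: int = 0
    max_placement_tries: int = 200

    def __post_init__(self) -> None:
        if min(self.n_epithelial, self.n_stromal, self.n_inflammatory) < 0:
            raise InvalidInputError("cell counts must be non-negative")
        if self.microns_per_pixel <= 0:
            raise InvalidInputError("microns_per_pixel must be positive")

    @property
    def shape_px(self) -> tuple[int, int]:
        return (int(round(self.height_um / self.microns_per_pixel)),
                int(round(self.width_um / self.microns_per_pixel)))


@dataclasses.dataclass
class SynthGroundTruth:
    """Everything the generator knows about a rendered tile."""

    nuclei: list[NucleusSegment]
    classes: list[str]
    cells: list[CellSegment]
    region_map: RegionMap
    tissue_mask: np.ndarray
    hp_record: HPRecord
    dab_scale: float
    config: TissueSynthConfig

    @property
    def positivity(self) -> list[bool]:
        return [bool(c.pimo_positive) for c in self.cells]


def _place_disk(rng, occupied, shape, radius_px, region=None, max_tries=200):
    """Rejection-sample a disk center so the disk stays free and in-bounds."""
    h, w = shape
    r = int(math.ceil(radius_px))
    if r + 1 >= h - r - 2 or r + 1 >= w - r - 2:
        return None  # disk cannot fit in the tile at all
    for _ in range(max_tries):
        if region is None:
            cy = rng.uniform(r + 1, h - r - 2)
            cx = rng.uniform(r + 1, w - r - 2)
        else:
            cy, cx = region(rng)
            if not (r + 1 <= cy < h - r - 2 and r + 1 <= cx < w - r - 2):
                continue
        rr, cc = draw_disk((cy, cx), radius_px, shape=shape)
        if rr.size and not occupied[rr, cc].any():
            return (cy, cx), rr, cc
    return None


def generate_tissue_tile(cfg: TissueSynthConfig) -> tuple[RGBImage, SynthGroundTruth]:
    """Render one synthetic H-DAB tile and its exhaustive ground truth."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape_px
    mpp = cfg.microns_per_pixel
    shape = (h, w)

    # --- tissue mask: everything except gland lumina ---------------------
    tissue_mask = np.ones(shape, dtype=bool)
    gland_r_px = cfg.gland_radius_um / mpp
    gland_centers = []
    glo_r = min(gland_r_px, h / 2, w / 2)
    for _ in range(cfg.n_glands):
        for _try in range(cfg.max_placement_tries):
            cy = rng.uniform(glo_r, max(h - glo_r, glo_r + 1e-9))
            cx = rng.uniform(glo_r, max(w - glo_r, glo_r + 1e-9))
            if all((cy - gy) ** 2 + (cx - gx) ** 2 > (1.6 * gland_r_px) ** 2
                   for gy, gx in gland_centers):
                gland_centers.append((cy, cx))
                break
    for cy, cx in gland_centers:
        rr, cc = draw_disk((cy, cx), cfg.lumen_fraction * gland_r_px, shape=shape)
        tissue_mask[rr, cc] = False

    # --- nucleus placement ------------------------------------------------
    occupied = ~tissue_mask.copy()  # nuclei must not invade lumina
    # keep a 2 px margin between nuclei so the watershed can separate them
    margin = ndi.binary_dilation(occupied, iterations=2)

    nuclei: list[NucleusSegment] = []
    classes: list[str] = []

    def commit(rr, cc, cls):
        nid = len(nuclei) + 1
        nuclei.append(NucleusSegment(
            id=nid, rows=rr, cols=cc,
            centroid=(float(rr.mean()), float(cc.mean())),
            area_um2=len(rr) * mpp**2,
        ))
        classes.append(cls)
        occupied[rr, cc] = True
        r0, r1 = max(rr.min() - 2, 0), min(rr.max() + 3, h)
        c0, c1 = max(cc.min() - 2, 0), min(cc.max() + 3, w)
        sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        sub[rr - r0, cc - c0] = True
        margin[r0:r1, c0:c1] |= ndi.binary_dilation(sub, iterations=2)

    failures = 0

    def fail():
        nonlocal failures
        failures += 1
        if failures > cfg.max_placement_tries:
            raise PackingError("could not place requested nuclei: tile too crowded")

    # epithelial nuclei ring the glands
    epi_r_px = cfg.epi_nucleus_radius_um / mpp
    for i in range(cfg.n_epithelial):
        placed = None
        if gland_centers:
            gy, gx = gland_centers[i % len(gland_centers)]

            def ring(rng, gy=gy, gx=gx):
                ang = rng.uniform(0, 2 * math.pi)
                rad = gland_r_px * rng.uniform(0.45, 1.05)
                return gy + rad * math.sin(ang), gx + rad * math.cos(ang)

            placed = _place_disk(rng, margin, shape, epi_r_px, region=ring,
                                 max_tries=cfg.max_placement_tries)
        if placed is None:  # fall back to anywhere in tissue
            placed = _place_disk(rng, margin, shape, epi_r_px,
                                 max_tries=cfg.max_placement_tries)
        if placed is None:
            fail()
            continue
        _, rr, cc = placed
        commit(rr, cc, EPITHELIAL)

    # stromal nuclei: sparse elongated ellipses anywhere
    smaj = cfg.stromal_major_um / mpp
    smin = cfg.stromal_minor_um / mpp
    for _ in range(cfg.n_stromal):
        ok = False
        if smaj + 1 >= h - smaj - 2 or smaj + 1 >= w - smaj - 2:
            for _ in range(cfg.n_stromal):
                fail()
            break
        for _try in range(cfg.max_placement_tries):
            cy = rng.uniform(smaj + 1, h - smaj - 2)
            cx = rng.uniform(smaj + 1, w - smaj - 2)
            rot = rng.uniform(0, math.pi)
            rr, cc = draw_ellipse(cy, cx, smaj, smin, shape=shape, rotation=rot)
            if rr.size and not margin[rr, cc].any():
                commit(rr, cc, STROMAL)
                ok = True
                break
        if not ok:
            fail()

    # inflammatory nuclei: small dense round, in loose clusters
    infl_r_px = cfg.infl_nucleus_radius_um / mpp
    n_clusters = max(cfg.n_inflammatory // 8, 1)
    cluster_centers = [(rng.uniform(0, h), rng.uniform(0, w)) for _ in range(n_clusters)]
    for i in range(cfg.n_inflammatory):
        ky, kx = cluster_centers[i % n_clusters]

        def near(rng, ky=ky, kx=kx):
            return (ky + rng.normal(0, 12.0 / mpp), kx + rng.normal(0, 12.0 / mpp))

        placed = _place_disk(rng, margin, shape, infl_r_px, region=near,
                             max_tries=cfg.max_placement_tries)
        if placed is None:
            placed = _place_disk(rng, margin, shape, infl_r_px,
                                 max_tries=cfg.max_placement_tries)
        if placed is None:
            fail()
            continue
        _, rr, cc = placed
        commit(rr, cc, INFLAMMATORY)

    # --- cell bodies and regions -----------------------------------------
    cells = expand_cytoplasm(nuclei, classes, cfg.heuristics, tissue_mask, mpp)
    region_map = build_region_map(cells, tissue_mask)

    # --- stain images -----------------------------------------------------
    hema_img = np.zeros(shape)
    hema_img[tissue_mask] = cfg.cytoplasm_hema_od
    for seg, cls in zip(nuclei, classes):
        level = cfg.hema_od[cls] * (1.0 + rng.normal(0, cfg.nucleus_od_jitter))
        hema_img[seg.rows, seg.cols] = max(level, 0.05)

    # hypoxia field: exponential decay from random line sources
    source_mask = np.zeros(shape, dtype=bool)
    for _ in range(cfg.n_hypoxia_sources):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        r1, c1 = rng.integers(0, h), rng.integers(0, w)
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        source_mask[rr, cc] = True
    if source_mask.any():
        d_um = ndi.distance_transform_edt(~source_mask) * mpp
        field = np.exp(-d_um / cfg.dab_decay_um)
    else:
        field = np.zeros(shape)

    # per-cell mean field / hema, for positivity and optional calibration
    mean_field = np.empty(len(cells))
    mean_hema = np.empty(len(cells))
    for i, cell in enumerate(cells):
        rows, cols = cell.all_rows, cell.all_cols
        mean_field[i] = field[rows, cols].mean() if rows.size else 0.0
        mean_hema[i] = hema_img[rows, cols].mean() if rows.size else 0.0

    scale = cfg.dab_max_od
    if cfg.target_hp_wt is not None:
        scale = _calibrate_dab_scale(cfg, cells, region_map, mean_field, mean_hema, mpp)

    dab_img = np.zeros(shape)
    for cell in cells:
        rows, cols = cell.all_rows, cell.all_cols
        dab_img[rows, cols] = scale * field[rows, cols]

    # truth: measure and score cells on the noiseless stain images
    measure_cells(cells, hema_img, dab_img)
    score_cells(cells, cfg.rule)
    hp_record = compute_hp(cells, region_map, mpp, patient_id="synthetic",
                           section_id="synthetic", roi_id=f"seed{cfg.seed}")

    # --- compose RGB ------------------------------------------------------
    od = compose_od(hema_img, dab_img, cfg.basis)
    intensity = np.asarray(cfg.white_point) * np.power(10.0, -od)
    if cfg.noise_sigma > 0:
        intensity = intensity + rng.normal(0, cfg.noise_sigma, intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    img = RGBImage(pixels=pixels, microns_per_pixel=mpp)

    truth = SynthGroundTruth(
        nuclei=nuclei, classes=classes, cells=cells, region_map=region_map,
        tissue_mask=tissue_mask, hp_record=hp_record, dab_scale=scale, config=cfg,
    )
    return img, truth


def _calibrate_dab_scale(cfg, cells, region_map, mean_field, mean_hema, mpp,
                         tol: float = 0.05, iters: int = 60) -> float:
    """Bisect the global DAB amplitude so true HP-wt hits ``cfg.target_hp_wt``.

    The positive-cell area is monotone non-decreasing in the amplitude, so
    bisection converges; granularity is limited by individual cell areas.
    """
    from .segmentation import ANALYZED_REGIONS

    denom_px = int(np.count_nonzero(np.isin(region_map.labels, ANALYZED_REGIONS)))
    areas = np.array([c.n_pixels for c in cells], dtype=float)
    is_scored = np.array([c.cell_class in (EPITHELIAL, STROMAL) for c in cells])
    thr = cfg.rule.dab_fraction_threshold
    min_od = cfg.rule.min_od

    def hp_at(s):
        dab = s * mean_field
        total = dab + mean_hema
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, dab / np.maximum(total, 1e-12), 0.0)
        pos = (frac > thr) & (dab >= min_od) & is_scored
        return 100.0 * areas[pos].sum() / denom_px

    lo, hi = 0.0, 20.0
    if hp_at(hi) < cfg.target_hp_wt:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if hp_at(mid) < cfg.target_hp_wt:
            lo = mid
        else:
            hi = mid
        if abs(hp_at(hi) - cfg.target_hp_wt) <= tol:
            break
    return hi


def simulate_annotators(
    truth: SynthGroundTruth,
    err_a: float,
    err_b: float,
    seed: int,
) -> tuple[AnnotationSet, AnnotationSet]:
    """Simulate two independent annotators with symmetric flip errors.

    With probability ``err`` each annotator relabels a cell with one of the
    other two classes, chosen uniformly; stained/unstained calls carry the
    true positivity through.
    """
    for err in (err_a, err_b):
        if not 0 <= err < 1:
            raise InvalidInputError("error rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cell_ids = [seg.id for seg in truth.nuclei]
    out = []
    for name, err in (("A", err_a), ("B", err_b)):
        labels = []
        for cls in truth.classes:
            if rng.random() < err:
                others = [c for c in CELL_CLASSES if c != cls]
                labels.append(others[rng.integers(len(others))])
            else:
                labels.append(cls)
        stain = ["stained" if pos else "unstained" for pos in truth.positivity]
        out.append(AnnotationSet(
            annotator_id=name,
            labels=pd.Series(labels, index=cell_ids),
            stain_call=pd.Series(stain, index=cell_ids),
        ))
    return out[0], out[1]


@dataclasses.dataclass
class HPTableSynthConfig:
    """Generating model for hierarchical HP tables."""

    n_patients: int = 100
    n_sections: int = 5
    n_rois: int = 10
    mean: float = 10.0
    sigma2_patient: float = 3.0
    sigma2_section: float = 0.5
    sigma2_roi: float = 1.0
    clip_bounds: tuple[float, float] = (0.0, 100.0)
    clip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma2_patient, self.sigma2_section, self.sigma2_roi) < 0:
            raise InvalidInputError("variances must be non-negative")
        lo, hi = self.clip_bounds
        if not lo <= self.mean <= hi:
            raise InvalidInputError("mean must lie within the clip bounds")


def generate_hp_table(cfg: HPTableSynthConfig) -> pd.DataFrame:
    """Draw value_psr = clip(mu + b_p + s_ps + e_psr, bounds) for a full grid.

    Returns a long table (patient_id, section_id, roi_id, hp_wt); the number
    of clipped observations is recorded in ``df.attrs['n_clipped']``.
    """
    rng = np.random.default_rng(cfg.seed)
    b = rng.normal(0, math.sqrt(cfg.sigma2_patient), cfg.n_patients)
    s = rng.normal(0, math.sqrt(cfg.sigma2_section), (cfg.n_patients, cfg.n_sections))
    e = rng.normal(0, math.sqrt(cfg.sigma2_roi), (cfg.n_patients, cfg.n_sections, cfg.n_rois))
    values = cfg.mean + b[:, None, None] + s[:, :, None] + e
    n_clipped = 0
    if cfg.clip:
        lo, hi = cfg.clip_bounds
        n_clipped = int(np.count_nonzero((values < lo) | (values > hi)))
        values = np.clip(values, lo, hi)
    p_idx, s_idx, r_idx = np.meshgrid(
        np.arange(cfg.n_patients), np.arange(cfg.n_sections), np.arange(cfg.n_rois),
        indexing="ij",
    )
    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in p_idx.ravel()],
        "section_id": [f"S{i}" for i in s_idx.ravel()],
        "roi_id": [f"R{i}" for i in r_idx.ravel()],
        "hp_wt": values.ravel(),
    })
    df.attrs["n_clipped"] = n_clipped
    df.attrs["config"] = dataclasses.asdict(cfg)
    return df
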