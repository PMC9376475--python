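"""Consensus annotation, pixel-wise random-forest cell typing, concordance.

Two pathologists annotate the same cells; disagreements are resolved with a
deliberately anti-epithelial precedence (epithelial < stromal <
inflammatory/other) so that cells are only called epithelial when nothing
argues otherwise.  A random forest is then trained on pixels sampled from
consensus-labelled nuclei and applied pixel-wise to new nuclei, with per-cell
majority voting.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .errors import DegenerateTrainingError, InvalidInputError
from .segmentation import CELL_CLASSES, EPITHELIAL, INFLAMMATORY, STROMAL, NucleusSegment
from .stain import StainChannels

UNANNOTATED = "unannotated"
ANNOTATION_VOCAB = CELL_CLASSES + (UNANNOTATED,)

#: Consensus precedence: the merge of two labels is the maximum under this
#: order, with ``unannotated`` as the identity element.
_PRECEDENCE = {UNANNOTATED: 0, EPITHELIAL: 1, STROMAL: 2, INFLAMMATORY: 3}

#: Per-cell vote ties break toward the front of this list (stroma first).
_TIE_ORDER = (STROMAL, INFLAMMATORY, EPITHELIAL)


@dataclasses.dataclass
class AnnotationSet:
    """One annotator's per-cell labels (and optional stained/unstained calls)."""

    annotator_id: str
    labels: pd.Series  # index: cell_id, values in ANNOTATION_VOCAB
    stain_call: pd.Series | None = None  # values in {"stained", "unstained"}

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(ANNOTATION_VOCAB)
        if bad:
            raise InvalidInputError(f"labels outside vocabulary: {sorted(bad)}")
        if self.labels.index.has_duplicates:
            raise InvalidInputError("at most one label per cell id")


@dataclasses.dataclass
class ConsensusLabels:
    """Merged two-annotator labels with per-cell provenance."""

    labels: pd.Series
    provenance: pd.Series  # {"agreed", "single_annotator", "mismatch_resolved"}


def merge_labels(a: str, b: str) -> str:
    """Merge one pair of annotations under the consensus precedence.

    Agreement keeps the label; a single annotation is adopted; an
    epithelial/stromal mismatch resolves to stromal; any inflammatory/other
    call dominates.  Symmetric and idempotent.
    """
    for lab in (a, b):
        if lab not in _PRECEDENCE:
            raise InvalidInputError(f"label outside vocabulary: {lab!r}")
    return a if _PRECEDENCE[a] >= _PRECEDENCE[b] else b


def merge_consensus(a: AnnotationSet, b: AnnotationSet) -> ConsensusLabels:
    """Merge two annotation sets cell-by-cell (see :func:`merge_labels`)."""
    cells = a.labels.index.union(b.labels.index)
    la = a.labels.reindex(cells, fill_value=UNANNOTATED)
    lb = b.labels.reindex(cells, fill_value=UNANNOTATED)
    merged = [merge_labels(x, y) for x, y in zip(la, lb)]
    prov = []
    for x, y in zip(la, lb):
        if x == y:
            prov.append("agreed")
        elif x == UNANNOTATED or y == UNANNOTATED:
            prov.append("single_annotator")
        else:
            prov.append("mismatch_resolved")
    return ConsensusLabels(
        labels=pd.Series(merged, index=cells, name="consensus"),
        provenance=pd.Series(prov, index=cells, name="provenance"),
    )


def split_rois(roi_ids: Sequence, n_train: int, seed: int) -> dict:
    """Seeded random partition of ROIs into training and validation sets."""
    roi_ids = list(roi_ids)
    if n_train > len(roi_ids):
        raise InvalidInputError("n_train exceeds the number of ROIs")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(roi_ids))
    split = {}
    for pos, idx in enumerate(perm):
        split[roi_ids[idx]] = "training" if pos < n_train else "validation"
    return split


# --- pixel features -------------------------------------------------------

#: Versioned feature recipes: name -> ordered feature labels.
FEATURE_RECIPES = {
    "v1": (
        "od_hema", "od_dab",
        "hema_g1", "hema_g2", "hema_g4",
        "dab_g1", "dab_g2", "dab_g4",
        "hema_grad", "dab_grad",
    ),
    # v2 appends 3x3 local standard deviation of each channel
    "v2": (
        "od_hema", "od_dab",
        "hema_g1", "hema_g2", "hema_g4",
        "dab_g1", "dab_g2", "dab_g4",
        "hema_grad", "dab_grad",
        "hema_std3", "dab_std3",
    ),
}
DEFAULT_RECIPE = "v1"


def _local_std(img: np.ndarray, size: int = 3) -> np.ndarray:
    mean = ndi.uniform_filter(img, size=size)
    sq = ndi.uniform_filter(img * img, size=size)
    return np.sqrt(np.maximum(sq - mean * mean, 0.0))


def _grad_mag(img: np.ndarray) -> np.ndarray:
    gr, gc = np.gradient(img)
    return np.hypot(gr, gc)


def compute_feature_stack(channels: StainChannels, recipe: str = DEFAULT_RECIPE) -> np.ndarray:
    """Compute the full H x W x F feature image for a recipe."""
    if recipe not in FEATURE_RECIPES:
        raise InvalidInputError(f"unknown feature recipe {recipe!r}")
    hema = np.asarray(channels.hema, dtype=float)
    dab = np.asarray(channels.dab, dtype=float)
    feats = [hema, dab]
    for sigma in (1.0, 2.0, 4.0):
        feats.append(ndi.gaussian_filter(hema, sigma))
    for sigma in (1.0, 2.0, 4.0):
        feats.append(ndi.gaussian_filter(dab, sigma))
    feats.append(_grad_mag(hema))
    feats.append(_grad_mag(dab))
    if recipe == "v2":
        feats.append(_local_std(hema))
        feats.append(_local_std(dab))
    return np.stack(feats, axis=-1)


def extract_pixel_features(
    channels: StainChannels,
    rows: np.ndarray,
    cols: np.ndarray,
    recipe: str = DEFAULT_RECIPE,
    stack: np.ndarray | None = None,
) -> np.ndarray:
    """Feature vectors for a pixel set; pass a precomputed ``stack`` to amortize."""
    if stack is None:
        stack = compute_feature_stack(channels, recipe)
    h, w = stack.shape[:2]
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if rows.size and (rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w):
        raise InvalidInputError("pixel set outside image bounds")
    return stack[rows, cols]


@dataclasses.dataclass
class ClassifierModel:
    """Trained pixel-wise forest plus the metadata needed to reuse it."""

    forest: RandomForestClassifier
    recipe: str
    seed: int
    classes: tuple[str, ...]

    def save(self, path: str) -> None:
        joblib.dump(self.forest, path)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"recipe": self.recipe, "seed": self.seed, "classes": list(self.classes)}, fh)

    @classmethod
    def load(cls, path: str) -> "ClassifierModel":
        forest = joblib.load(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(forest=forest, recipe=meta["recipe"], seed=meta["seed"], classes=tuple(meta["classes"]))


def train_classifier(
    nuclei: Sequence[NucleusSegment],
    labels: Mapping[int, str] | Sequence[str],
    channels: StainChannels,
    seed: int,
    recipe: str = DEFAULT_RECIPE,
    max_pixels_per_cell: int = 100,
    max_pixels_per_class: int = 20000,
    n_estimators: int = 200,
    min_pixels_per_class: int = 50,
    _feature_batches: Sequence[tuple[Sequence[NucleusSegment], StainChannels]] | None = None,
) -> ClassifierModel:
    """Train the pixel-wise random forest on consensus-labelled nuclei.

    Pixels are sampled from each labelled nucleus (at most
    ``max_pixels_per_cell`` per nucleus so large nuclei cannot dominate),
    classes are balanced by downsampling, and a seeded forest is fit.
    ``labels`` maps nucleus id to class, or is a sequence parallel to
    ``nuclei``.  ``_feature_batches`` lets callers pool several images:
    a list of (nuclei, channels) pairs sharing the same ``labels`` mapping.
    """
    rng = np.random.default_rng(seed)
    if _feature_batches is None:
        _feature_batches = [(nuclei, channels)]
    if not isinstance(labels, Mapping):
        labels = {seg.id: lab for seg, lab in zip(nuclei, labels)}

    per_class_X: dict[str, list[np.ndarray]] = {}
    for batch_nuclei, batch_channels in _feature_batches:
        stack = compute_feature_stack(batch_channels, recipe)
        for seg in batch_nuclei:
            lab = labels.get(seg.id)
            if lab is None or lab == UNANNOTATED:
                continue
            if lab not in CELL_CLASSES:
                raise InvalidInputError(f"unknown training label {lab!r}")
            n = seg.n_pixels
            if n > max_pixels_per_cell:
                take = rng.choice(n, size=max_pixels_per_cell, replace=False)
            else:
                take = np.arange(n)
            feats = stack[seg.rows[take], seg.cols[take]]
            per_class_X.setdefault(lab, []).append(feats)

    if len(per_class_X) < 2:
        raise DegenerateTrainingError("training requires at least two classes")
    pooled = {c: np.concatenate(v) for c, v in per_class_X.items()}
    for c, X in pooled.items():
        if len(X) < min_pixels_per_class:
            raise DegenerateTrainingError(
                f"class {c!r} has {len(X)} labelled pixels (< {min_pixels_per_class})"
            )
    n_balanced = min(min(len(X) for X in pooled.values()), max_pixels_per_class)
    Xs, ys = [], []
    for c in sorted(pooled):
        X = pooled[c]
        take = rng.choice(len(X), size=n_balanced, replace=False) if len(X) > n_balanced else np.arange(len(X))
        Xs.append(X[take])
        ys.extend([c] * len(take))
    X = np.concatenate(Xs)
    y = np.array(ys)

    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    return ClassifierModel(forest=forest, recipe=recipe, seed=int(seed), classes=tuple(sorted(pooled)))


def predict_cell_classes(
    model: ClassifierModel,
    nuclei: Sequence[NucleusSegment],
    channels: StainChannels,
) -> list[str]:
    """Classify each nucleus by majority vote over its pixel predictions.

    Vote ties break toward stroma (then inflammatory/other), mirroring the
    consensus rule's reluctance to call a cell epithelial.
    """
    if not nuclei:
        return []
    stack = compute_feature_stack(channels, model.recipe)
    all_rows = np.concatenate([s.rows for s in nuclei])
    all_cols = np.concatenate([s.cols for s in nuclei])
    preds = model.forest.predict(stack[all_rows, all_cols])
    out = []
    pos = 0
    for seg in nuclei:
        votes = pd.Series(preds[pos:pos + seg.n_pixels]).value_counts()
        pos += seg.n_pixels
        top = votes.max()
        tied = set(votes[votes == top].index)
        for cls in _TIE_ORDER:
            if cls in tied:
                out.append(cls)
                break
        else:
            out.append(sorted(tied)[0])
    return out


def agreement(predicted: Mapping, reference: Mapping, cls: str) -> float:
    """Percent of reference ``cls`` cells that ``predicted`` also calls ``cls``.

    ``reference`` is the denominator set; returns NaN when the reference
    contains no cell of that class.
    """
    ref_cells = [cid for cid, lab in reference.items() if lab == cls]
    if not ref_cells:
        return float("nan")
    hit = sum(1 for cid in ref_cells if predicted.get(cid) == cls)
    return 100.0 * hit / len(ref_cells)


def agreement_table(predicted: Mapping, reference: Mapping, reference_name: str = "reference") -> pd.DataFrame:
    """Per-class agreement percentages with the reference named in the output."""
    rows = []
    for cls in CELL_CLASSES:
        rows.append({
            "class": cls,
            "agreement_pct": agreement(predicted, reference, cls),
            "n_reference": sum(1 for lab in reference.values() if lab == cls),
            "reference": reference_name,
        })
    return pd.DataFrame(rows)
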