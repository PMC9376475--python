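"""Consensus merge, ROI splits, pixel features, forest training, agreement."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

import hypoxiquant as hq
from hypoxiquant.classify import (
    UNANNOTATED,
    ClassifierModel,
    compute_feature_stack,
    extract_pixel_features,
    merge_labels,
)
from hypoxiquant.errors import DegenerateTrainingError, InvalidInputError

from conftest import make_nucleus

EPI, STR, INF, UNA = "epithelial", "stromal", "inflammatory_other", UNANNOTATED

#: The full resolution table: agreement keeps the label, a single annotation
#: is adopted, epithelial/stromal mismatches resolve to stromal, and any
#: inflammatory/other call dominates.
CONSENSUS_TABLE = {
    (EPI, EPI): EPI, (STR, STR): STR, (INF, INF): INF, (UNA, UNA): UNA,
    (EPI, STR): STR, (STR, EPI): STR,
    (EPI, INF): INF, (INF, EPI): INF,
    (STR, INF): INF, (INF, STR): INF,
    (EPI, UNA): EPI, (UNA, EPI): EPI,
    (STR, UNA): STR, (UNA, STR): STR,
    (INF, UNA): INF, (UNA, INF): INF,
}


class TestConsensus:
    @pytest.mark.parametrize("pair,expected", sorted(CONSENSUS_TABLE.items()))
    def test_all_sixteen_ordered_pairs(self, pair, expected):
        assert merge_labels(*pair) == expected

    def test_symmetric_and_idempotent(self):
        vocab = (EPI, STR, INF, UNA)
        for a in vocab:
            assert merge_labels(a, a) == a
            for b in vocab:
                assert merge_labels(a, b) == merge_labels(b, a)

    def test_merge_sets_with_provenance(self):
        a = hq.AnnotationSet("p1", pd.Series({1: EPI, 2: EPI, 3: STR, 4: EPI}))
        b = hq.AnnotationSet("p2", pd.Series({1: EPI, 2: STR, 3: UNA, 4: INF}))
        out = hq.merge_consensus(a, b)
        assert out.labels.to_dict() == {1: EPI, 2: STR, 3: STR, 4: INF}
        assert out.provenance.to_dict() == {
            1: "agreed", 2: "mismatch_resolved",
            3: "single_annotator", 4: "mismatch_resolved",
        }

    def test_vocabulary_enforced(self):
        with pytest.raises(InvalidInputError):
            hq.AnnotationSet("p1", pd.Series({1: "tumour"}))
        with pytest.raises(InvalidInputError):
            merge_labels("epithelial", "necrotic")


class TestSplitROIs:
    def test_partition_covers_all(self):
        split = hq.split_rois([f"roi{i}" for i in range(50)], 25, seed=11)
        vals = list(split.values())
        assert vals.count("training") == 25 and vals.count("validation") == 25

    def test_deterministic_per_seed(self):
        rois = list(range(50))
        assert hq.split_rois(rois, 25, seed=3) == hq.split_rois(rois, 25, seed=3)
        assert hq.split_rois(rois, 25, seed=3) != hq.split_rois(rois, 25, seed=4)

    def test_zero_training_rois(self):
        split = hq.split_rois([1, 2, 3], 0, seed=0)
        assert set(split.values()) == {"validation"}

    def test_overfull_training_rejected(self):
        with pytest.raises(InvalidInputError):
            hq.split_rois([1, 2], 3, seed=0)


class TestPixelFeatures:
    def test_default_recipe_has_ten_features(self):
        z = np.zeros((8, 8))
        ch = hq.StainChannels(hema=z, dab=z, residual=z)
        assert compute_feature_stack(ch, "v1").shape == (8, 8, 10)
        assert compute_feature_stack(ch, "v2").shape == (8, 8, 12)

    def test_constant_image_features(self):
        ch = hq.StainChannels(hema=np.full((10, 10), 0.4),
                              dab=np.full((10, 10), 0.2),
                              residual=np.zeros((10, 10)))
        stack = compute_feature_stack(ch, "v2")
        # raw + all smoothed features equal the constants
        assert np.allclose(stack[..., 0], 0.4) and np.allclose(stack[..., 1], 0.2)
        for f in range(2, 8):
            const = 0.4 if f < 5 else 0.2
            assert np.allclose(stack[..., f], const, atol=1e-6)
        # gradient and local-std features vanish
        assert np.allclose(stack[..., 8:], 0.0, atol=1e-9)

    def test_bright_pixel_gradient_matches_finite_difference(self):
        hema = np.zeros((11, 11))
        hema[5, 5] = 1.0
        ch = hq.StainChannels(hema=hema, dab=np.zeros_like(hema), residual=np.zeros_like(hema))
        stack = compute_feature_stack(ch, "v1")
        gr, gc = np.gradient(hema)
        assert np.allclose(stack[..., 8], np.hypot(gr, gc))
        assert stack[..., 8].max() == stack[4:7, 4:7, 8].max()

    def test_out_of_bounds_pixels_rejected(self):
        z = np.zeros((5, 5))
        ch = hq.StainChannels(hema=z, dab=z, residual=z)
        with pytest.raises(InvalidInputError):
            extract_pixel_features(ch, np.array([10]), np.array([0]))


def _separable_fixture(seed=0, n_per_class=6, shape=(64, 64)):
    """Nuclei whose DAB OD separates epithelial (high) from stromal (low)."""
    rng = np.random.default_rng(seed)
    hema = np.full(shape, 0.05)
    dab = np.zeros(shape)
    nuclei, labels = [], {}
    nid = 0
    for cls, dab_level in ((EPI, 0.8), (STR, 0.1)):
        for _ in range(n_per_class):
            nid += 1
            cy, cx = rng.uniform(6, shape[0] - 6, 2)
            rr, cc = draw_disk((cy, cx), 4, shape=shape)
            hema[rr, cc] = 0.5
            dab[rr, cc] = dab_level + rng.normal(0, 0.01)
            nuclei.append(make_nucleus(nid, rr, cc))
            labels[nid] = cls
    ch = hq.StainChannels(hema=hema, dab=dab, residual=np.zeros(shape))
    return nuclei, labels, ch


class TestForest:
    def test_separable_classes_reach_perfect_training_accuracy(self):
        nuclei, labels, ch = _separable_fixture()
        model = hq.train_classifier(nuclei, labels, ch, seed=5, n_estimators=50)
        preds = hq.predict_cell_classes(model, nuclei, ch)
        assert preds == [labels[n.id] for n in nuclei]

    def test_same_seed_reproduces_predictions(self):
        nuclei, labels, ch = _separable_fixture(seed=1)
        m1 = hq.train_classifier(nuclei, labels, ch, seed=9, n_estimators=50)
        m2 = hq.train_classifier(nuclei, labels, ch, seed=9, n_estimators=50)
        assert hq.predict_cell_classes(m1, nuclei, ch) == hq.predict_cell_classes(m2, nuclei, ch)

    def test_single_class_training_rejected(self):
        nuclei, labels, ch = _separable_fixture()
        only_epi = {k: EPI for k in labels}
        with pytest.raises(DegenerateTrainingError):
            hq.train_classifier(nuclei, only_epi, ch, seed=0)

    def test_label_permutation_drops_accuracy_to_chance(self):
        nuclei, labels, ch = _separable_fixture(seed=2, n_per_class=20, shape=(160, 160))
        rng = np.random.default_rng(0)
        ids = list(labels)
        shuffled = rng.permutation([labels[i] for i in ids])
        permuted = dict(zip(ids, shuffled))
        model = hq.train_classifier(nuclei, permuted, ch, seed=1, n_estimators=50)
        probe_nuclei, probe_labels, probe_ch = _separable_fixture(seed=3, n_per_class=20, shape=(160, 160))
        preds = hq.predict_cell_classes(model, probe_nuclei, probe_ch)
        acc = np.mean([p == probe_labels[n.id] for p, n in zip(preds, probe_nuclei)])
        # chance for two balanced classes is 0.5; binomial 99.9% band, n=40
        assert 0.5 - 0.27 <= acc <= 0.5 + 0.27

    def test_vote_ties_break_toward_stroma(self):
        class _Stub:
            def predict(self, X):
                # alternate votes pixel by pixel: exact 50/50 for even counts
                out = np.empty(len(X), dtype=object)
                out[::2] = EPI
                out[1::2] = STR
                return out

        model = ClassifierModel(forest=_Stub(), recipe="v1", seed=0, classes=(EPI, STR))
        rr, cc = draw_disk((8, 8), 4, shape=(17, 17))
        if len(rr) % 2:  # force an even pixel count so the vote ties
            rr, cc = rr[:-1], cc[:-1]
        nuc = make_nucleus(1, rr, cc)
        z = np.zeros((17, 17))
        ch = hq.StainChannels(hema=z, dab=z, residual=z)
        assert hq.predict_cell_classes(model, [nuc], ch) == [STR]

    def test_empty_cell_list(self):
        nuclei, labels, ch = _separable_fixture()
        model = hq.train_classifier(nuclei, labels, ch, seed=5, n_estimators=20)
        assert hq.predict_cell_classes(model, [], ch) == []

    def test_model_round_trips_through_disk(self, tmp_path):
        nuclei, labels, ch = _separable_fixture()
        model = hq.train_classifier(nuclei, labels, ch, seed=5, n_estimators=20)
        path = tmp_path / "model.bin"
        model.save(path)
        loaded = ClassifierModel.load(path)
        assert loaded.recipe == model.recipe and loaded.classes == model.classes
        assert hq.predict_cell_classes(loaded, nuclei, ch) == hq.predict_cell_classes(model, nuclei, ch)


class TestAgreement:
    def test_identical_labels_give_hundred_percent(self):
        labels = {1: EPI, 2: STR, 3: EPI}
        for cls in (EPI, STR):
            assert hq.agreement(labels, labels, cls) == 100.0

    def test_disjoint_assignments_give_zero(self):
        assert hq.agreement({1: STR, 2: STR}, {1: EPI, 2: EPI}, EPI) == 0.0

    def test_partial_match_counting(self):
        ref = {i: EPI for i in range(10)}
        pred = {i: (EPI if i < 8 else STR) for i in range(10)}
        assert hq.agreement(pred, ref, EPI) == 80.0

    def test_empty_reference_class_is_not_available(self):
        assert np.isnan(hq.agreement({1: EPI}, {1: EPI}, STR))

    def test_agreement_table_names_its_reference(self):
        tab = hq.agreement_table({1: EPI}, {1: EPI}, reference_name="joint")
        assert (tab["reference"] == "joint").all()
        assert tab.set_index("class").loc[EPI, "agreement_pct"] == 100.0
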