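"""Variance components, ICC extrapolation and rank correlation."""

import numpy as np
import pandas as pd
import pytest

import hypoxiquant as hq
from hypoxiquant.errors import (
    InsufficientGroupingError,
    InvalidInputError,
    InvalidStructureError,
)
from hypoxiquant.reliability import fit_two_level_mom


def toy_balanced_table():
    """3 patients x 2 sections; ANOVA is hand-computable.

    Grand mean 29/6; MSB = 1050/36; MSW = 3/2, so
    sigma2_patient = (MSB - MSW)/2 = 83/6 and sigma2_within = 3/2.
    """
    return pd.DataFrame({
        "patient_id": ["a", "a", "b", "b", "c", "c"],
        "section_id": ["s1", "s2"] * 3,
        "value": [1.0, 2.0, 3.0, 5.0, 8.0, 10.0],
    })


class TestMethodOfMoments:
    def test_hand_worked_anova_oracle(self):
        vc = fit_two_level_mom(toy_balanced_table())
        assert vc.sigma2_patient == pytest.approx(83 / 6, abs=1e-10)
        assert vc.sigma2_section == pytest.approx(1.5, abs=1e-10)
        assert vc.grand_mean == pytest.approx(29 / 6, abs=1e-10)

    def test_identical_values_give_zero_variances(self):
        df = toy_balanced_table().assign(value=7.0)
        vc = hq.fit_two_level(df, method="mom")
        assert vc.sigma2_patient == 0 and vc.sigma2_section == 0

    def test_negative_estimate_truncated_with_warning(self):
        # within-patient spread dwarfs between-patient spread
        df = pd.DataFrame({
            "patient_id": ["a", "a", "b", "b"],
            "section_id": ["s1", "s2"] * 2,
            "value": [0.0, 10.0, 5.0, 5.1],
        })
        with pytest.warns(UserWarning):
            vc = hq.fit_two_level(df, method="mom")
        assert vc.sigma2_patient == 0.0


class TestTwoLevelRecovery:
    def test_reml_recovers_generating_variances(self):
        a, k, s2p, s2w = 200, 5, 3.0, 1.0
        cfg = hq.HPTableSynthConfig(n_patients=a, n_sections=k, n_rois=1,
                                    mean=50.0, sigma2_patient=s2p,
                                    sigma2_section=0.0, sigma2_roi=s2w, seed=21)
        df = hq.generate_hp_table(cfg)
        vc = hq.fit_two_level(df, value="hp_wt")
        # assert within 3 analytic standard errors of each estimator
        se_p = np.sqrt(2.0 / (a - 1)) * (s2p + s2w / k)
        se_w = np.sqrt(2.0 / (a * (k - 1))) * s2w
        assert vc.sigma2_patient == pytest.approx(s2p, abs=3 * se_p)
        assert vc.sigma2_section == pytest.approx(s2w, abs=3 * se_w)

    def test_reml_and_mom_agree_on_balanced_design(self):
        cfg = hq.HPTableSynthConfig(n_patients=150, n_sections=4, n_rois=1,
                                    mean=50.0, sigma2_patient=4.0,
                                    sigma2_section=0.0, sigma2_roi=2.0, seed=8)
        df = hq.generate_hp_table(cfg)
        reml = hq.fit_two_level(df, value="hp_wt", method="reml")
        mom = hq.fit_two_level(df, value="hp_wt", method="mom")
        assert reml.sigma2_patient == pytest.approx(mom.sigma2_patient, rel=0.01)
        assert reml.sigma2_section == pytest.approx(mom.sigma2_section, rel=0.01)

    def test_single_patient_rejected(self):
        df = toy_balanced_table().query("patient_id == 'a'")
        with pytest.raises(InsufficientGroupingError):
            hq.fit_two_level(df)


class TestThreeLevel:
    def test_nested_recovery_and_aggregation_consistency(self):
        cfg = hq.HPTableSynthConfig(n_patients=120, n_sections=5, n_rois=8,
                                    mean=50.0, sigma2_patient=3.0,
                                    sigma2_section=0.5, sigma2_roi=1.0, seed=4)
        df = hq.generate_hp_table(cfg)
        vc3 = hq.fit_three_level(df, value="hp_wt", method="mom")
        assert vc3.sigma2_patient == pytest.approx(3.0, rel=0.25)
        assert vc3.sigma2_section == pytest.approx(0.5, abs=0.25)
        assert vc3.sigma2_roi == pytest.approx(1.0, rel=0.1)
        # collapsing ROIs then fitting two levels agrees on the patient term
        collapsed = (df.groupby(["patient_id", "section_id"], as_index=False)
                       ["hp_wt"].mean())
        vc2 = hq.fit_two_level(collapsed, value="hp_wt", method="mom")
        assert vc2.sigma2_patient == pytest.approx(vc3.sigma2_patient, rel=0.05)

    def test_reml_matches_mom_on_balanced_nested_design(self):
        cfg = hq.HPTableSynthConfig(n_patients=60, n_sections=4, n_rois=5,
                                    mean=40.0, sigma2_patient=4.0,
                                    sigma2_section=1.0, sigma2_roi=2.0, seed=13)
        df = hq.generate_hp_table(cfg)
        reml = hq.fit_three_level(df, value="hp_wt", method="reml")
        mom = hq.fit_three_level(df, value="hp_wt", method="mom")
        assert reml.sigma2_patient == pytest.approx(mom.sigma2_patient, rel=0.05)
        assert reml.sigma2_roi == pytest.approx(mom.sigma2_roi, rel=0.05)

    def test_null_section_component_estimated_near_zero(self):
        cfg = hq.HPTableSynthConfig(n_patients=80, n_sections=4, n_rois=6,
                                    mean=30.0, sigma2_patient=2.0,
                                    sigma2_section=0.0, sigma2_roi=1.0, seed=30)
        df = hq.generate_hp_table(cfg)
        vc = hq.fit_three_level(df, value="hp_wt")
        assert vc.sigma2_section < 0.1  # simulation bound for a true zero

    def test_duplicate_observation_ids_rejected(self):
        df = pd.DataFrame({
            "patient_id": ["a", "a", "b", "b"],
            "section_id": ["s", "s", "s", "s"],
            "roi_id": ["r", "r", "r", "r2"],
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(InvalidStructureError):
            hq.fit_three_level(df)


class TestICC:
    @pytest.mark.parametrize("s2p,s2w,expected", [(1, 0, 1.0), (0, 1, 0.0), (3, 1, 0.75)])
    def test_single_section_icc(self, s2p, s2w, expected):
        vc = hq.VarianceComponents(sigma2_patient=s2p, sigma2_section=s2w)
        assert hq.icc_single(vc) == pytest.approx(expected)

    def test_zero_total_variance_not_available(self):
        vc = hq.VarianceComponents(sigma2_patient=0, sigma2_section=0)
        assert np.isnan(hq.icc_single(vc))

    @pytest.mark.parametrize(
        "icc1,k,expected",
        [(0.728, 5, 0.930), (0.325, 2, 0.490)],
    )
    def test_step_up_matches_published_values(self, icc1, k, expected):
        assert hq.icc_k_sections(icc1, k) == pytest.approx(expected, abs=0.005)

    def test_identity_and_fixed_point(self):
        for x in (0.0, 0.3, 0.97, 1.0):
            assert hq.icc_k_sections(x, 1) == x
        for k in (1, 2, 10):
            assert hq.icc_k_sections(1.0, k) == 1.0

    def test_strictly_increasing_and_bounded(self):
        vals = [hq.icc_k_sections(0.4, k) for k in range(1, 30)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0

    def test_step_up_equals_direct_variance_formula(self):
        vc = hq.VarianceComponents(sigma2_patient=2.7, sigma2_section=1.3)
        for k in range(1, 8):
            direct = vc.sigma2_patient / (vc.sigma2_patient + vc.sigma2_within / k)
            assert hq.icc_k_sections(hq.icc_single(vc), k) == pytest.approx(direct, abs=1e-12)

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidInputError):
            hq.icc_k_sections(0.5, 0)

    def test_published_columns_self_consistent(self, published_icc_table):
        for platform, measures in published_icc_table.items():
            for measure, col in measures.items():
                for k in range(2, 6):
                    derived = hq.icc_k_sections(col[0], k)
                    assert derived == pytest.approx(col[k - 1], abs=0.005), (platform, measure, k)


class TestVarianceFractions:
    @pytest.mark.parametrize(
        "vc,expected",
        [
            (hq.VarianceComponents(3, 1), {"patient": 75.0, "section": 25.0}),
            (hq.VarianceComponents(1, 1), {"patient": 50.0, "section": 50.0}),
            (hq.VarianceComponents(66, 9, 25), {"patient": 66.0, "section": 9.0, "roi": 25.0}),
        ],
    )
    def test_normalization(self, vc, expected):
        fr = hq.variance_fractions(vc)
        for key, val in expected.items():
            assert fr[key] == pytest.approx(val)
        assert sum(fr.values()) == pytest.approx(100.0)

    def test_zero_total_not_available(self):
        with pytest.raises(InvalidInputError):
            hq.variance_fractions(hq.VarianceComponents(0, 0))


class TestSpearman:
    def test_monotone_sequences(self):
        x = [1, 2, 3, 4, 5]
        assert hq.spearman_rho(x, [2, 4, 8, 16, 32]) == pytest.approx(1.0)
        assert hq.spearman_rho(x, [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        assert hq.spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_not_available(self):
        assert np.isnan(hq.spearman_rho([1, 2, 3], [5, 5, 5]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            hq.spearman_rho([1, 2], [3, 4])


class TestModelResultsFrontEnd:
    def test_fit_summary_and_tables(self):
        cfg = hq.HPTableSynthConfig(n_patients=60, n_sections=4, n_rois=1,
                                    mean=20.0, sigma2_patient=3.0,
                                    sigma2_section=0.0, sigma2_roi=1.0, seed=2)
        df = hq.generate_hp_table(cfg)
        res = hq.HPVarianceModel.from_dataframe(df, value="hp_wt").fit()
        text = res.summary()
        assert "sigma2 patient" in text and "ICC (1 section)" in text
        tab = res.icc_table(max_k=5)
        assert list(tab["k"]) == [1, 2, 3, 4, 5]
        assert tab["icc"].is_monotonic_increasing
        assert (tab["icc"] <= 1).all() and (tab["icc"] >= 0).all()
        k_req = res.sections_for_reliability()
        assert k_req is not None and res.icc_k(k_req) >= hq.HIGH_RELIABILITY_ICC

    def test_plot_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        cfg = hq.HPTableSynthConfig(n_patients=30, n_sections=3, n_rois=1,
                                    mean=20.0, sigma2_patient=3.0,
                                    sigma2_section=0.0, sigma2_roi=1.0, seed=2)
        res = hq.HPVarianceModel.from_dataframe(hq.generate_hp_table(cfg), value="hp_wt").fit()
        ax = res.plot_icc()
        assert ax.get_ylabel() == "ICC"
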