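"""Index algebra: hand-checked values, identities, bounds, monotonicity,
classification grades and the removal-sensitivity machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dustqi as dq
from dustqi.indices import (
    AQI_SCHEME,
    CPI_SCHEME,
    EF_SCHEME,
    IGEO_SCHEME,
    NEMEROW_SCHEME,
    PI_SCHEME,
    aqi,
    assess_sites,
    classify,
    compute_ef,
    compute_igeo,
    compute_pi,
    cpi,
    nemerow,
    pli,
)

from conftest import baseline_table

positive_pi_vectors = st.lists(
    st.floats(1e-4, 1e4, allow_nan=False, allow_infinity=False), min_size=1, max_size=12
)


def _table(values: dict, sites=None) -> dq.ConcentrationTable:
    df = pd.DataFrame(values)
    if sites is not None:
        df.index = sites
    else:
        df.index = [f"s{i}" for i in range(len(df))]
    return dq.ConcentrationTable(df)


class TestElementLayers:
    def test_pi_is_elementwise_ratio(self, small_background):
        rng = np.random.default_rng(2)
        conc = rng.lognormal(5, 1, size=(3, 3))
        table = _table({"Fe": conc[:, 0], "Ca": conc[:, 1], "Al": conc[:, 2]})
        pi = compute_pi(table, small_background)
        for el, cb in [("Fe", 41000.0), ("Ca", 25700.0), ("Al", 81500.0)]:
            np.testing.assert_allclose(pi[el], table.data[el] / cb)

    def test_pi_at_background_is_one(self, background):
        pi = compute_pi(baseline_table(background), background)
        np.testing.assert_allclose(pi.to_numpy(), 1.0)

    @pytest.mark.parametrize(
        "factor, expected",
        [(1.5, 0.0), (3.0, 1.0), (1.0, np.log2(2.0 / 3.0))],
    )
    def test_igeo_hand_values(self, background, factor, expected):
        base = baseline_table(background)
        table = dq.ConcentrationTable(base.data * factor)
        igeo = compute_igeo(table, background)
        np.testing.assert_allclose(igeo.to_numpy(), expected, atol=1e-12)

    def test_igeo_identity_with_pi(self, synthetic_table, background):
        pi = compute_pi(synthetic_table, background)
        igeo = compute_igeo(synthetic_table, background)
        np.testing.assert_allclose(
            igeo.to_numpy(), (np.log2(pi) - np.log2(1.5)).to_numpy(), atol=1e-12
        )

    def test_ef_reference_column_is_one(self, synthetic_table, background):
        ef = compute_ef(synthetic_table, background, reference="Al")
        np.testing.assert_allclose(ef["Al"], 1.0)

    def test_ef_hand_value(self, small_background):
        # Fe at 2x background, Al exactly at background -> EF_Fe = 2
        table = _table({"Fe": [2 * 41000.0], "Al": [81500.0]})
        ef = compute_ef(table, small_background, reference="Al")
        assert ef.at["s0", "Fe"] == pytest.approx(2.0, rel=1e-12)

    def test_ef_equals_pi_ratio_identity(self, synthetic_table, background):
        pi = compute_pi(synthetic_table, background)
        for ref in ("Al", "Ca", "Fe"):
            ef = compute_ef(synthetic_table, background, reference=ref)
            np.testing.assert_allclose(
                ef.to_numpy(), pi.div(pi[ref], axis=0).to_numpy(), rtol=1e-12
            )

    def test_missing_reference_errors(self, small_table, small_background):
        with pytest.raises(KeyError, match="Al"):
            compute_ef(small_table, small_background, reference="Al")


class TestSiteAggregates:
    @pytest.mark.parametrize(
        "pis, expected",
        [([1.0, 1.0, 1.0], 1.0), ([4.0, 1.0], 2.0)],
    )
    def test_pli_hand_values(self, pis, expected):
        assert pli(pis).value == pytest.approx(expected, rel=1e-12)

    def test_pli_threshold_drops_small_ratios(self):
        s = pd.Series({"a": 0.01, "b": 1.0, "c": 100.0})
        trimmed = pli(s, exclude_below=0.03)
        assert trimmed.value == pytest.approx(10.0, rel=1e-12)
        assert trimmed.dropped == ("a",)
        assert pli(s).value == pytest.approx(1.0, rel=1e-12)

    def test_pli_all_excluded_errors(self):
        with pytest.raises(ValueError, match="excluded"):
            pli([0.001, 0.002], exclude_below=0.03)

    def test_pli_log_space_survives_extreme_ranges(self):
        # 300 PIs of 1e-300 would underflow a direct product
        assert pli([1e-300] * 300).value == pytest.approx(1e-300, rel=1e-9)

    @pytest.mark.parametrize(
        "pis, expected",
        # (0, 2) is a hypothetical ratio pair: mean 1, max 2
        [([3.0, 3.0, 3.0], 3.0), ([0.0, 2.0], np.sqrt(2.5))],
    )
    def test_nemerow_hand_values(self, pis, expected):
        assert nemerow(pis) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("pis, expected", [([1.0, 1.0, 1.0], 1.0), ([2.0, 4.0], 3.0)])
    def test_cpi_hand_values(self, pis, expected):
        assert cpi(pis) == pytest.approx(expected, rel=1e-12)

    def test_aqi_hand_value(self):
        bg = dq.BackgroundTable.from_mapping({"X": 1.0, "Y": 4.0})
        row = pd.Series({"X": 2.0, "Y": 4.0})
        res = aqi(row, bg)
        np.testing.assert_allclose(res.subindices, [200.0, 100.0])
        np.testing.assert_allclose(res.weights, [0.8, 0.2])
        assert res.value == pytest.approx(180.0, rel=1e-12)

    def test_aqi_baseline_is_100(self, background):
        table = baseline_table(background)
        res = aqi(table.data.iloc[0], background)
        assert res.value == pytest.approx(100.0, rel=1e-12)
        assert res.weights.sum() == pytest.approx(1.0, rel=1e-12)

    def test_aqi_equal_backgrounds_reduce_to_cpi(self):
        bg = dq.BackgroundTable.from_mapping({"X": 10.0, "Y": 10.0, "Z": 10.0})
        row = pd.Series({"X": 5.0, "Y": 20.0, "Z": 35.0})
        assert aqi(row, bg).value == pytest.approx(100.0 * cpi(row / 10.0), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(pis=positive_pi_vectors)
    def test_am_gm_inequality(self, pis):
        assert pli(pis).value <= cpi(pis) * (1 + 1e-12)

    def test_am_gm_equality_iff_uniform(self):
        assert pli([2.0, 2.0, 2.0]).value == pytest.approx(cpi([2.0, 2.0, 2.0]), rel=1e-12)
        assert pli([1.0, 4.0]).value < cpi([1.0, 4.0])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(pis=positive_pi_vectors)
    def test_nemerow_bounds(self, pis):
        ne = nemerow(pis)
        pmax = max(pis)
        assert pmax / np.sqrt(2) - 1e-12 <= ne <= pmax * (1 + 1e-12)
        assert ne >= cpi(pis) / np.sqrt(2) - 1e-12


class TestMonotonicityAndScale:
    def test_each_index_non_decreasing_in_any_concentration(self, background):
        rng = np.random.default_rng(4)
        elements = list(background.values.index)
        base = pd.Series(
            background.values.to_numpy() * rng.lognormal(0, 0.5, len(elements)),
            index=elements,
        )
        bumped = base.copy()
        bumped["Zn"] *= 1.7

        def all_aggregates(row):
            t = dq.ConcentrationTable(pd.DataFrame([row], index=["s"]))
            pi = compute_pi(t, background).loc["s"]
            return {
                "PI_Zn": pi["Zn"],
                "Igeo_Zn": compute_igeo(t, background).at["s", "Zn"],
                "EF_Zn": compute_ef(t, background, "Al").at["s", "Zn"],
                "PLI": pli(pi).value,
                "PINem": nemerow(pi),
                "CPI": cpi(pi),
                "AQI": aqi(row, background).value,
            }

        lo, hi = all_aggregates(base), all_aggregates(bumped)
        for name in lo:
            assert hi[name] >= lo[name], name
            assert hi[name] > lo[name] or name == "PINem"

    def test_scale_invariance_of_ratio_indices(self, synthetic_table, background):
        """Scaling one element's C and CB together changes no ratio index,
        but does change AQI through the 1/CB weights."""
        scaled_bg = background.values.copy()
        scaled_bg["Fe"] *= 3.0
        scaled_table = synthetic_table.data.copy()
        scaled_table["Fe"] *= 3.0
        t2 = dq.ConcentrationTable(scaled_table)
        bg2 = dq.BackgroundTable(scaled_bg)

        np.testing.assert_allclose(
            compute_pi(t2, bg2).to_numpy(),
            compute_pi(synthetic_table, background).to_numpy(),
            rtol=1e-12,
        )
        site = synthetic_table.site_ids[0]
        a1 = aqi(synthetic_table.data.loc[site], background).value
        a2 = aqi(t2.data.loc[site], bg2).value
        assert abs(a1 - a2) > 1e-9 * abs(a1)

    def test_removal_of_extreme_pis(self):
        pis = pd.Series({"lo": 0.1, "mid": 1.0, "hi": 8.0})
        assert pli(pis.drop("lo")).value > pli(pis).value
        assert nemerow(pis.drop("hi")) < nemerow(pis)


class TestClassification:
    @pytest.mark.parametrize(
        "scheme, value, label",
        [
            (PI_SCHEME, 0.5, "no pollution"),
            (PI_SCHEME, 1.0, "low"),
            (PI_SCHEME, 5.0, "strong"),       # grade table: "> 5" is strict
            (PI_SCHEME, 5.01, "very strong"),
            (EF_SCHEME, 1.9, "deficient to minimal"),
            (EF_SCHEME, 2.0, "moderate"),
            (EF_SCHEME, 41.0, "extremely high"),
            (NEMEROW_SCHEME, 0.69, "no pollution"),
            (NEMEROW_SCHEME, 0.7, "warning level"),
            (NEMEROW_SCHEME, 2.5, "moderate pollution"),
            (NEMEROW_SCHEME, 3.2, "heavy contamination"),
            (CPI_SCHEME, 4.0, "heavy contamination"),
            (AQI_SCHEME, 25.0, "unpolluted"),
            (AQI_SCHEME, 25.5, "warning level"),  # gap values grade upward
            (AQI_SCHEME, 100.0, "moderate pollution"),
            (AQI_SCHEME, 101.0, "heavy pollution"),
            (IGEO_SCHEME, -0.585, "uncontaminated"),
            (IGEO_SCHEME, 0.0, "uncontaminated"),
            (IGEO_SCHEME, 1.0, "moderately contaminated"),
            (IGEO_SCHEME, 7.0, "extremely contaminated"),
        ],
    )
    def test_grade_labels(self, scheme, value, label):
        assert classify(scheme, value) == label

    @pytest.mark.parametrize(
        "scheme", [PI_SCHEME, EF_SCHEME, NEMEROW_SCHEME, AQI_SCHEME, IGEO_SCHEME]
    )
    def test_classification_is_monotone(self, scheme):
        lo, hi = scheme.boundaries[0] - 1, scheme.boundaries[-1] + 1
        values = np.linspace(lo, hi, 200)
        ranks = [scheme.labels.index(scheme.classify(v)) for v in values]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            classify(PI_SCHEME, float("nan"))


class TestAssessSites:
    def test_baseline_assessment_and_variant_are_unity(self, background):
        table = baseline_table(background)
        a = assess_sites(table, background)
        np.testing.assert_allclose(a.aggregates[["PLI", "PLI_d", "PINem", "CPI"]], 1.0)
        np.testing.assert_allclose(a.aggregates["AQI"], 100.0)
        var = a.variants[("Ca",)]
        np.testing.assert_allclose(var.aggregates[["PLI", "PINem", "CPI"]], 1.0)
        np.testing.assert_allclose(var.aggregates["AQI"], 100.0)

    def test_dominant_element_removal_reduces_peak_indices(self, background):
        """One element at PI = 50, the rest at PI = 1: dropping it must
        pull PINem, CPI and AQI sharply down and raise nothing."""
        conc = background.values.copy()
        conc["Ca"] *= 50.0
        table = dq.ConcentrationTable(pd.DataFrame([conc, conc], index=["s0", "s1"]))
        a = assess_sites(table, background)
        full = a.aggregates.loc["s0"]
        reduced = a.variants[("Ca",)].aggregates.loc["s0"]
        n = len(background.values)
        assert full["PINem"] == pytest.approx(
            np.sqrt((((n - 1 + 50) / n) ** 2 + 50**2) / 2), rel=1e-12
        )
        assert reduced["PINem"] == pytest.approx(1.0, rel=1e-12)
        assert reduced["CPI"] < full["CPI"]
        assert reduced["AQI"] < full["AQI"]
        assert reduced["PINem"] < full["PINem"]

    def test_aggregates_match_per_site_recomputation(self, synthetic_table, background):
        cfg = dq.AnalysisConfig()
        a = assess_sites(synthetic_table, background, cfg)
        pi = compute_pi(synthetic_table, background)
        for site in synthetic_table.site_ids:
            row = pi.loc[site]
            assert a.aggregates.at[site, "PLI"] == pytest.approx(pli(row).value, rel=1e-12)
            assert a.aggregates.at[site, "PLI_d"] == pytest.approx(
                pli(row, exclude_below=cfg.pli_threshold).value, rel=1e-12
            )
            assert a.aggregates.at[site, "PINem"] == pytest.approx(nemerow(row), rel=1e-12)
            assert a.aggregates.at[site, "CPI"] == pytest.approx(cpi(row), rel=1e-12)
            assert a.aggregates.at[site, "AQI"] == pytest.approx(
                aqi(synthetic_table.data.loc[site], background).value, rel=1e-12
            )
            assert a.aggregates.at[site, "PI_max"] == row.max()
            assert a.aggregates.at[site, "PI_mean"] == pytest.approx(row.mean(), rel=1e-12)

    def test_variant_drops_elements_before_thresholding(self, background):
        # Pb sits below the PLI_d threshold; the Ca variant must still
        # threshold on the reduced panel, not reuse the full-panel drop list
        conc = background.values.copy()
        conc["Pb"] *= 0.01
        table = dq.ConcentrationTable(pd.DataFrame([conc], index=["s0"]))
        a = assess_sites(table, background)
        assert a.pli_dropped["s0"] == ("Pb",)
        var = a.variants[("Ca",)].aggregates.loc["s0"]
        assert var["PLI_d"] == pytest.approx(1.0, rel=1e-12)

    def test_dropping_every_element_rejected(self, background):
        table = baseline_table(background)
        cfg = dq.AnalysisConfig(drop_elements=[list(background.values.index)])
        with pytest.raises(ValueError, match="every element"):
            assess_sites(table, background, cfg)
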