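import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from memsort.assay_analytics import (
    CalceinAssay, FretSample, GateThresholds, KineticsTrace, LuminescenceSet,
    calcein_release, classify_events, correlate_expression_compression, delta_cdch,
    enrichment_mfi, enrichment_positive, fret_cdch, gate_single_dye, gfp_increase,
    normalize_by_max, rapamycin_induced, relative_nanobit,
)
from memsort.synthetic_data import AssayGroundTruth, generate_assay_fixture


class TestGfpKinetics:
    def test_increase_is_endpoint_difference(self):
        t = np.linspace(0.0, 3.0, 13)
        trace = KineticsTrace(t, np.full(13, 100.0))
        assert gfp_increase(trace) == 0.0
        trace2 = KineticsTrace(t, np.linspace(100.0, 350.0, 13))
        assert gfp_increase(trace2) == pytest.approx(250.0)

    def test_trace_ending_early_is_an_error(self):
        t = np.linspace(0.0, 2.0, 9)
        with pytest.raises(ValueError, match="no sample"):
            gfp_increase(KineticsTrace(t, np.ones(9)))

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            KineticsTrace([0.0, 0.5, 0.5], [1.0, 2.0, 3.0])

    def test_normalize_by_max_groups_independently(self):
        df = pd.DataFrame({
            "construct": ["A", "A", "A", "B", "B"],
            "delta_f": [2.0, 4.0, 8.0, 5.0, 10.0],
        })
        out = normalize_by_max(df)
        assert out["normalized"].tolist() == [0.25, 0.5, 1.0, 0.5, 1.0]
        single = normalize_by_max(pd.DataFrame({"construct": ["C"], "delta_f": [3.0]}))
        assert single["normalized"].tolist() == [1.0]
        with pytest.raises(ValueError, match="non-positive"):
            normalize_by_max(pd.DataFrame({"construct": ["D"], "delta_f": [0.0]}))


class TestCalcein:
    @pytest.mark.parametrize("i0, i3, itr, expected", [
        (100.0, 100.0, 400.0, 0.0),
        (100.0, 400.0, 400.0, 100.0),
        (100.0, 250.0, 400.0, 50.0),
    ])
    def test_release_percent(self, i0, i3, itr, expected):
        assert calcein_release(CalceinAssay(i0, i3, itr)) == pytest.approx(expected)

    def test_per_protein_variant_divides_by_band_intensity(self):
        assay = CalceinAssay(100.0, 250.0, 400.0, band_intensity=2.0)
        assert calcein_release(assay, per_protein=True) == pytest.approx(25.0)
        with pytest.raises(ValueError, match="band_intensity"):
            calcein_release(CalceinAssay(100.0, 250.0, 400.0), per_protein=True)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            calcein_release(CalceinAssay(100.0, 100.0, 100.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(1, 1e4), st.floats(0, 1), st.floats(1e-3, 1e4)))
    def test_release_bounded_when_intensities_ordered(self, args):
        i0, frac, span = args
        i3 = i0 + frac * span
        pct = calcein_release(CalceinAssay(i0, i3, i0 + span))
        assert -1e-9 <= pct <= 100.0 + 1e-9


class TestEnrichment:
    def test_mfi_ratio(self):
        assert enrichment_mfi(200.0, 400.0) == pytest.approx(0.5)
        assert enrichment_mfi(5.0, 5.0) == 1.0
        with pytest.raises(ZeroDivisionError):
            enrichment_mfi(1.0, 0.0)

    def test_percent_positive_ratio(self):
        assert enrichment_positive(30.0, 10.0) == pytest.approx(3.0)
        assert enrichment_positive(7.0, 7.0) == 1.0
        with pytest.raises(ZeroDivisionError):
            enrichment_positive(1.0, 0.0)

    def test_mfi_ratio_below_one_in_the_thin_preference_regime(self):
        # fixtures built with thick-channel MFI below thin-channel MFI for
        # every protein thickness keep the enrichment ratio under 1
        for seed, mfi_thick in enumerate([200.0, 300.0, 400.0, 450.0]):
            truth = AssayGroundTruth(mfi_rhodamine_thick=mfi_thick, mfi_cy55_thin=500.0,
                                     n_events=20_000, seed=seed)
            ev = generate_assay_fixture("flow_enrichment", truth).tables["events"]
            thick = ev[ev["true_population"] == "thick"]
            thin = ev[ev["true_population"] == "thin"]
            assert enrichment_mfi(thick["rhodamine"].mean(), thin["cy55"].mean()) < 1.0


class TestGating:
    THR = GateThresholds(rhodamine=100.0, cy55=100.0, af488=300.0)

    def test_noiseless_events_classify_to_their_true_population(self):
        truth = AssayGroundTruth(flow_cv=0.0, n_events=2_000, seed=1)
        ev = generate_assay_fixture("biocytin_flow", truth).tables["events"]
        pop = classify_events(ev, self.THR)
        mapped = pop.map({"rhodamine_only": "thick", "cy55_only": "thin"})
        assert (mapped == ev["true_population"]).all()

    def test_af488_statistics_recover_true_positive_fractions(self):
        truth = AssayGroundTruth(pos_frac_thick=0.30, pos_frac_thin=0.10,
                                 background_pos_frac=0.0, n_events=100_000, seed=2)
        fx = generate_assay_fixture("biocytin_flow", truth)
        out = gate_single_dye(fx.tables["events"], self.THR)
        n = out.loc["rhodamine_only", "n"]
        se30 = 100 * np.sqrt(0.3 * 0.7 / n)
        se10 = 100 * np.sqrt(0.1 * 0.9 / n)
        assert out.loc["rhodamine_only", "pct_positive"] == pytest.approx(30.0, abs=3 * se30)
        assert out.loc["cy55_only", "pct_positive"] == pytest.approx(10.0, abs=3 * se10)
        ratio = enrichment_positive(out.loc["rhodamine_only", "pct_positive"],
                                    out.loc["cy55_only", "pct_positive"])
        assert ratio == pytest.approx(3.0, abs=3 * 3.0 * np.sqrt(
            (se30 / 30) ** 2 + (se10 / 10) ** 2))

    def test_background_equal_to_sample_cancels_to_zero(self):
        truth = AssayGroundTruth(n_events=5_000, seed=3)
        ev = generate_assay_fixture("biocytin_flow", truth).tables["events"]
        out = gate_single_dye(ev, self.THR, background=ev)
        assert (out["pct_positive_bgsub"] == 0.0).all()
        assert (out["mfi_af488_bgsub"] == 0.0).all()

    def test_subtraction_floors_at_zero_with_flag(self):
        truth = AssayGroundTruth(n_events=5_000, pos_frac_thick=0.01, pos_frac_thin=0.01,
                                 background_pos_frac=0.3, seed=4)
        fx = generate_assay_fixture("biocytin_flow", truth)
        out = gate_single_dye(fx.tables["events"], self.THR,
                              background=fx.tables["background"])
        assert (out["pct_positive_bgsub"] >= 0.0).all()

    def test_empty_population_rejected(self):
        ev = pd.DataFrame({"rhodamine": [500.0] * 5, "cy55": [10.0] * 5,
                           "af488": [10.0] * 5})
        with pytest.raises(ValueError, match="cy55_only"):
            gate_single_dye(ev, self.THR)


class TestFret:
    def test_identity_and_zero_cases(self):
        d = FretSample(800.0, 1000.0, "D", 25.0)
        h = FretSample(80.0, 100.0, "H", 25.0)
        assert fret_cdch(d, h) == pytest.approx(1.0)
        no_quench = FretSample(1000.0, 1000.0, "D", 25.0)
        assert fret_cdch(no_quench, h) == 0.0

    def test_log_ratio_value(self):
        d = FretSample(500.0, 1000.0, "D", 25.0)
        h = FretSample(800.0, 1000.0, "H", 25.0)
        assert fret_cdch(d, h) == pytest.approx(np.log(0.5) / np.log(0.8))
        assert fret_cdch(d, h) == pytest.approx(3.106, abs=5e-4)

    def test_invariant_under_common_rescaling(self):
        d = FretSample(500.0, 1000.0, "D", 25.0)
        d_scaled = FretSample(5.0, 10.0, "D", 25.0)
        h = FretSample(800.0, 1000.0, "H", 25.0)
        assert fret_cdch(d, h) == pytest.approx(fret_cdch(d_scaled, h))

    def test_unquenched_homogeneous_sample_rejected(self):
        d = FretSample(500.0, 1000.0, "D", 25.0)
        with pytest.raises(ZeroDivisionError):
            fret_cdch(d, FretSample(1000.0, 1000.0, "H", 25.0))

    def test_delta_over_ramp(self):
        assert delta_cdch({20.0: 0.8, 30.0: 1.0, 45.0: 1.1}) == pytest.approx(0.3)
        assert delta_cdch({20.0: 1.0, 45.0: 1.0}) == 0.0
        with pytest.raises(ValueError, match="no sample"):
            delta_cdch({20.0: 1.0, 30.0: 1.2})

    def test_ramp_fixture_recovers_injected_trend(self):
        truth = AssayGroundTruth(cdch_start=1.3, cdch_end=1.0, fret_noise_cv=0.0, seed=5)
        fx = generate_assay_fixture("fret_ramp", truth)
        df = fx.tables["fret"]
        curve = {}
        for T, g in df.groupby("temperature_C"):
            d = g[g["condition"] == "D"].iloc[0]
            h = g[g["condition"] == "H"].iloc[0]
            curve[T] = fret_cdch(FretSample(d.F, d.F_o, "D", T),
                                 FretSample(h.F, h.F_o, "H", T))
        assert delta_cdch(curve) == pytest.approx(-0.3, abs=1e-9)


class TestLuciferase:
    def test_rapamycin_ratio(self):
        assert rapamycin_induced(LuminescenceSet(lum_plus_rap=500.0, lum_minus_rap=250.0)) == 2.0
        assert rapamycin_induced(LuminescenceSet(lum_plus_rap=5.0, lum_minus_rap=5.0)) == 1.0
        with pytest.raises(ValueError):
            rapamycin_induced(LuminescenceSet(lum_plus_rap=5.0))

    def test_rapamycin_recovery_under_multiplicative_noise(self):
        truth = AssayGroundTruth(rapamycin_ratio=2.0, lum_noise_cv=0.05,
                                 n_replicates=30, seed=6)
        df = generate_assay_fixture("nanobit_ramp", truth).tables["luminescence"]
        plus = df[df["condition"] == "plus_rap"]["lum"].mean()
        minus = df[df["condition"] == "minus_rap"]["lum"].mean()
        se = 2.0 * 0.05 * np.sqrt(2.0 / 30)
        assert rapamycin_induced(LuminescenceSet(lum_plus_rap=plus, lum_minus_rap=minus)) \
            == pytest.approx(2.0, abs=3 * se)

    def test_relative_assembly_identity_and_arithmetic(self):
        hetero_eq = LuminescenceSet(lum_20_50=200.0, lum_20_20=100.0, lum_50_50=300.0)
        assert relative_nanobit(hetero_eq) == pytest.approx(1.0)
        fancy = LuminescenceSet(lum_20_50=300.0, lum_20_20=100.0, lum_50_50=300.0)
        assert relative_nanobit(fancy) == pytest.approx(1.5)

    def test_room_temperature_normalisation_pins_reference_to_one(self):
        lum = LuminescenceSet(lum_20_50=300.0, lum_20_20=100.0, lum_50_50=300.0)
        ref = relative_nanobit(lum)
        assert relative_nanobit(lum, room_temp_reference=ref) == pytest.approx(1.0)

    def test_invariant_under_global_rescaling(self):
        a = LuminescenceSet(lum_20_50=300.0, lum_20_20=100.0, lum_50_50=300.0)
        b = LuminescenceSet(lum_20_50=3.0, lum_20_20=1.0, lum_50_50=3.0)
        assert relative_nanobit(a) == pytest.approx(relative_nanobit(b))


class TestCorrelation:
    def test_collinear_points_have_unit_r_squared(self):
        pairs = [(1.0, 2.0), (2.0, 4.0), (3.0, 6.0)]
        fit = correlate_expression_compression(pairs)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_constant_response_has_zero_slope(self):
        fit = correlate_expression_compression([(1.0, 5.0), (2.0, 5.0), (3.0, 5.0)])
        assert fit.slope == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = 1.7 * x - 0.4 + rng.normal(size=30)
        fit = correlate_expression_compression(np.column_stack([x, y]))
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="three"):
            correlate_expression_compression([(1.0, 2.0), (2.0, 3.0)])
        with pytest.raises(ValueError, match="degenerate"):
            correlate_expression_compression([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
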