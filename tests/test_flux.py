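"""Stress-test arithmetic: normalisation, phase aggregation, ATP accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oncoflux.flux import (
    BioenergeticCoefficients,
    FluxPlate,
    InjectionProtocol,
    NormalizationTable,
    PhaseSummary,
    ProtocolError,
    atp_fluxes,
    group_compare,
    normalize_plate,
    nutrient_stress_ratio,
    respiratory_params,
    star_code,
    summarize_phases,
)

COEF = BioenergeticCoefficients()  # worked-example constants


def make_plate(ocr, ecar, groups=None, normalised=False):
    ocr = np.atleast_2d(np.asarray(ocr, dtype=float))
    ecar = np.atleast_2d(np.asarray(ecar, dtype=float))
    n = ocr.shape[0]
    wells = pd.DataFrame(
        {
            "well_id": [f"w{i}" for i in range(n)],
            "group": groups or ["g"] * n,
            "condition": ["c"] * n,
        }
    )
    return FluxPlate(
        wells=wells,
        cycles=np.arange(1, ocr.shape[1] + 1, dtype=float),
        ocr=ocr,
        ecar=ecar,
        normalised=normalised,
    )


# spec of the canonical 4-phase trace used across the derived examples
TRACE = [100, 98, 102, 40, 38, 36, 150, 160, 155, 20, 18, 19]
PROTOCOL = InjectionProtocol(
    events=(("oligomycin", 3), ("fccp", 6), ("antimycin_rotenone", 9))
)


class TestNormalize:
    def test_divides_by_od(self):
        plate = make_plate([[120.0]], [[60.0]])
        out = normalize_plate(plate, NormalizationTable(od595={"w0": 0.6}))
        assert out.ocr[0, 0] == pytest.approx(200.0)
        assert out.ecar[0, 0] == pytest.approx(100.0)
        assert out.normalised

    def test_od_one_is_identity(self):
        plate = make_plate([TRACE], [TRACE])
        out = normalize_plate(plate, NormalizationTable(od595={"w0": 1.0}))
        assert np.array_equal(out.ocr, plate.ocr)

    def test_zero_od_names_well(self):
        plate = make_plate([[1.0]], [[1.0]])
        with pytest.raises(ValueError, match="w0"):
            normalize_plate(plate, NormalizationTable(od595={"w0": 0.0}))

    def test_missing_well_names_well(self):
        plate = make_plate([[1.0]], [[1.0]])
        with pytest.raises(KeyError, match="w0"):
            normalize_plate(plate, NormalizationTable(od595={"other": 1.0}))

    def test_scale_equivariance(self):
        """Multiplying a well's raw rates and OD by one factor changes nothing."""
        plate1 = make_plate([TRACE], [TRACE])
        plate2 = make_plate([np.array(TRACE) * 3.7], [np.array(TRACE) * 3.7])
        out1 = normalize_plate(plate1, NormalizationTable(od595={"w0": 0.5}))
        out2 = normalize_plate(plate2, NormalizationTable(od595={"w0": 0.5 * 3.7}))
        assert np.allclose(out1.ocr, out2.ocr)
        assert np.allclose(out1.ecar, out2.ecar)

    def test_nan_in_trace_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            make_plate([[1.0, np.nan]], [[1.0, 1.0]])


class TestSummarizePhases:
    def test_default_aggregators_hand_example(self):
        # basal=mean, oligo=min, FCCP=max, AA+Rot=min
        ps = summarize_phases(make_plate([TRACE], [TRACE]), PROTOCOL)
        row = ps.table.iloc[0]
        assert row["basal_ocr"] == pytest.approx(100.0)
        assert row["oligo_ocr"] == pytest.approx(36.0)
        assert row["fccp_ocr"] == pytest.approx(160.0)
        assert row["aarot_ocr"] == pytest.approx(18.0)

    def test_singleton_phases(self):
        proto = InjectionProtocol(
            events=(("oligomycin", 1), ("fccp", 2), ("antimycin_rotenone", 3))
        )
        ps = summarize_phases(make_plate([[5, 6, 7, 8]], [[5, 6, 7, 8]]), proto)
        row = ps.table.iloc[0]
        assert (row[["basal_ocr", "oligo_ocr", "fccp_ocr", "aarot_ocr"]] == [5, 6, 7, 8]).all()

    def test_empty_phase_is_protocol_error(self):
        proto = InjectionProtocol(events=(("oligomycin", 3), ("fccp", 6)))
        with pytest.raises(ProtocolError, match="fccp"):
            summarize_phases(make_plate([TRACE[:6]], [TRACE[:6]]), proto)

    def test_unknown_injection_rejected(self):
        with pytest.raises(ProtocolError, match="unknown"):
            InjectionProtocol(events=(("rotenone_only", 3),))

    def test_aggregates_within_phase_range(self):
        ps = summarize_phases(make_plate([TRACE], [TRACE]), PROTOCOL)
        assert 98 <= ps.table.iloc[0]["basal_ocr"] <= 102


class TestRespiratoryParams:
    def setup_method(self):
        ps = summarize_phases(make_plate([TRACE], [TRACE]), PROTOCOL)
        self.rp = respiratory_params(ps)

    def test_hand_example(self):
        row = self.rp.iloc[0]
        assert row["ocr_mito"] == pytest.approx(82.0)
        assert row["ocr_coupled"] == pytest.approx(64.0)
        assert row["ocr_leak"] == pytest.approx(18.0)
        assert row["mrc"] == pytest.approx(160.0)
        assert row["src"] == pytest.approx(60.0)
        assert row["ocr_nonmito"] == pytest.approx(18.0)

    def test_decomposition_identity(self):
        row = self.rp.iloc[0]
        assert row["ocr_mito"] == row["ocr_coupled"] + row["ocr_leak"]

    def test_src_zero_when_fccp_equals_basal(self):
        table = pd.DataFrame(
            {"basal_ocr": [100.0], "oligo_ocr": [40.0], "fccp_ocr": [100.0], "aarot_ocr": [10.0]},
            index=pd.Index(["w0"], name="well_id"),
        )
        ps = PhaseSummary(table=table, groups=pd.Series(["g"], index=["w0"]), aggregators={})
        assert respiratory_params(ps).iloc[0]["src"] == pytest.approx(0.0)

    def test_negative_leak_clamped_and_flagged(self):
        table = pd.DataFrame(
            {"basal_ocr": [100.0], "oligo_ocr": [20.0], "fccp_ocr": [150.0], "aarot_ocr": [25.0]},
            index=pd.Index(["w0"], name="well_id"),
        )
        ps = PhaseSummary(table=table, groups=pd.Series(["g"], index=["w0"]), aggregators={})
        rp = respiratory_params(ps)
        row = rp.iloc[0]
        assert row["ocr_leak"] == 0.0
        assert row["ocr_leak_raw"] == pytest.approx(-5.0)
        assert row["flagged"]
        assert row["ocr_mito"] == row["ocr_coupled"] + row["ocr_leak"]

    def test_mrc_nonmito_subtraction_switch(self):
        ps = summarize_phases(make_plate([TRACE], [TRACE]), PROTOCOL)
        rp = respiratory_params(ps, subtract_nonmito_from_mrc=True)
        assert rp.iloc[0]["mrc"] == pytest.approx(160.0 - 18.0)


def _phase_summary(basal_ecar=20.0, basal_ocr=100.0, oligo=36.0, fccp=160.0, aarot=18.0, monensin_ecar=40.0):
    table = pd.DataFrame(
        {
            "basal_ocr": [basal_ocr],
            "oligo_ocr": [oligo],
            "fccp_ocr": [fccp],
            "aarot_ocr": [aarot],
            "basal_ecar": [basal_ecar],
            "monensin_ecar": [monensin_ecar],
        },
        index=pd.Index(["w0"], name="well_id"),
    )
    return PhaseSummary(table=table, groups=pd.Series(["g"], index=["w0"]), aggregators={})


class TestAtpFluxes:
    def test_worked_example(self):
        """ECAR 20, OCR_mito 82, OCR_coupled 64 under the default constants."""
        ps = _phase_summary()
        atp = atp_fluxes(ps, respiratory_params(ps), COEF)
        row = atp.iloc[0]
        # frozen from an independent straight-line recomputation of the
        # stated formulas: PPR_tot 200, PPR_resp 78.158, J_glyc 149.242,
        # J_ox 338.052, index 30.627
        assert row["j_atp_glyc_basal"] == pytest.approx(149.242, abs=0.05)
        assert row["j_atp_ox_basal"] == pytest.approx(338.052, abs=0.05)
        assert row["glycolytic_index"] == pytest.approx(30.627, abs=0.05)

    def test_total_is_sum_of_parts(self):
        ps = _phase_summary()
        atp = atp_fluxes(ps, respiratory_params(ps), COEF)
        for s in ("basal", "max"):
            assert atp.iloc[0][f"j_atp_total_{s}"] == pytest.approx(
                atp.iloc[0][f"j_atp_glyc_{s}"] + atp.iloc[0][f"j_atp_ox_{s}"], rel=1e-12
            )

    def test_zero_ocr_gives_index_100(self):
        ps = _phase_summary(basal_ocr=0.0, oligo=0.0, fccp=0.0, aarot=0.0)
        atp = atp_fluxes(ps, respiratory_params(ps), COEF)
        row = atp.iloc[0]
        assert row["j_atp_ox_basal"] == 0.0
        assert row["glycolytic_index"] == pytest.approx(100.0)

    def test_zero_ecar_clamps_glycolytic_ppr(self):
        ps = _phase_summary(basal_ecar=0.0)
        atp = atp_fluxes(ps, respiratory_params(ps), COEF)
        # only the bicarbonate-independent glycolytic term survives
        assert atp.iloc[0]["j_atp_glyc_basal"] == pytest.approx(82 * 2 * COEF.po_glyc)

    def test_dead_well_flagged(self):
        ps = _phase_summary(basal_ecar=0.0, basal_ocr=0.0, oligo=0.0, fccp=0.0, aarot=0.0)
        atp = atp_fluxes(ps, respiratory_params(ps), COEF)
        assert atp.iloc[0]["dead_well"]
        assert np.isnan(atp.iloc[0]["glycolytic_index"])

    def test_missing_monensin_still_yields_basal(self):
        ps = _phase_summary()
        table = ps.table.drop(columns=["monensin_ecar"])
        ps2 = PhaseSummary(table=table, groups=ps.groups, aggregators={})
        atp = atp_fluxes(ps2, respiratory_params(ps2), COEF)
        assert np.isnan(atp.iloc[0]["j_atp_glyc_max"])
        assert np.isfinite(atp.iloc[0]["j_atp_glyc_basal"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ecar=st.floats(0.0, 200.0),
        delta=st.floats(0.1, 50.0),
    )
    def test_index_monotone_in_ecar(self, ecar, delta):
        """Raising basal ECAR never lowers the glycolytic index."""
        ps_lo = _phase_summary(basal_ecar=ecar)
        ps_hi = _phase_summary(basal_ecar=ecar + delta)
        lo = atp_fluxes(ps_lo, respiratory_params(ps_lo), COEF).iloc[0]["glycolytic_index"]
        hi = atp_fluxes(ps_hi, respiratory_params(ps_hi), COEF).iloc[0]["glycolytic_index"]
        assert hi >= lo - 1e-9
        assert 0.0 <= lo <= 100.0 and 0.0 <= hi <= 100.0

    def test_index_antitone_in_coupled_ocr(self):
        # raising oligomycin-sensitive respiration shifts ATP share to OxPhos
        indices = []
        for oligo in (80.0, 60.0, 36.0, 10.0):  # lower oligo -> more coupled OCR
            ps = _phase_summary(oligo=oligo)
            atp = atp_fluxes(ps, respiratory_params(ps), COEF)
            indices.append(atp.iloc[0]["glycolytic_index"])
        assert all(a >= b - 1e-9 for a, b in zip(indices, indices[1:]))


class TestNutrientStressRatio:
    def test_closed_form_example(self):
        rep = nutrient_stress_ratio([0.5, 0.4, 0.6], [1.0, 1.0, 1.0])
        assert rep.mean == pytest.approx(0.5)
        assert rep.t == pytest.approx(-8.660, abs=1e-3)
        assert rep.df == 2
        assert rep.p == pytest.approx(0.0131, abs=5e-4)

    def test_identical_pairs_not_computable(self):
        rep = nutrient_stress_ratio([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert rep.mean == pytest.approx(1.0)
        assert not rep.computable and rep.reason == "zero variance"

    def test_two_equal_ratios_degenerate(self):
        rep = nutrient_stress_ratio([0.5, 1.0], [1.0, 2.0])
        assert rep.mean == pytest.approx(0.5)
        assert not rep.computable

    def test_single_replicate_not_computable(self):
        assert not nutrient_stress_ratio([0.5], [1.0]).computable

    def test_zero_control_names_replicate(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            nutrient_stress_ratio([1.0, 1.0], [1.0, 0.0])


class TestGroupCompare:
    def test_separated_groups_all_stars(self):
        rng = np.random.default_rng(0)
        values, groups = [], []
        for g, mu in (("A", 1.0), ("B", 2.0), ("C", 3.0)):
            values.extend(mu + rng.normal(0, 1e-3, 4))
            groups.extend([g] * 4)
        out = group_compare(values, groups)
        assert out["computable"]
        assert all(c["p"] < 1e-4 and c["stars"] == "****" for c in out["comparisons"])

    def test_null_groups_not_significant(self):
        values = [1.0, 1.1, 0.9] * 3
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        out = group_compare(values, groups)
        assert out["anova_p"] > 0.9
        assert all(c["stars"] == "ns" for c in out["comparisons"])

    def test_student_t_two_groups_single_comparison(self):
        out = group_compare([1, 2, 3, 4, 5, 6], ["A"] * 3 + ["B"] * 3, method="student_t")
        assert len(out["comparisons"]) == 1

    def test_small_group_flagged(self):
        out = group_compare([1.0, 2.0, 3.0], ["A", "A", "B"])
        assert not out["computable"]

    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****")],
    )
    def test_star_thresholds(self, p, stars):
        assert star_code(p) == stars
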