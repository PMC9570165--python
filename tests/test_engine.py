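"""IVIVE scaling, well-stirred clearance and the one-compartment oral engine."""

import math

import numpy as np
import pytest

from mafld_pbpk import (
    CompoundProfile,
    DoseRegimen,
    MichaelisMenten,
    auc_ratio_low_extraction,
    hepatic_clearance,
    oral_auc_inf,
    pk_metrics,
    simulate_regimen,
    whole_liver_clint,
)
from mafld_pbpk.engine import PKProfile, _linear_params

from conftest import make_subject


def low_extraction_compound(**overrides):
    """A linear compound with hepatic extraction well under 0.1."""
    params = dict(
        name="probe",
        dose_mg=100.0,
        ka_per_h=2.0,
        fa_fg=1.0,
        fu=0.05,
        bp_ratio=1.0,
        vss_l_per_kg=0.5,
        clint_per_pmol={"CYP3A4": 0.5},
        clint_other_ul_min_mg=0.0,
        cl_renal_l_per_h=0.0,
    )
    params.update(overrides)
    return CompoundProfile(**params)


class TestClearanceScaling:
    def test_unit_conversion_oracle(self):
        """100 pmol/mg x 1 uL/min/pmol x 40 mg/g x 1650 g = 6.6 L/min = 396 L/h."""
        subject = make_subject({"CYP3A4": 100.0}, mppgl=40.0, liver_g=1650.0)
        compound = low_extraction_compound(clint_per_pmol={"CYP3A4": 1.0})
        assert whole_liver_clint(subject, compound) == pytest.approx(396.0)

    def test_zero_clint_gives_zero(self):
        subject = make_subject()
        compound = low_extraction_compound(clint_per_pmol={}, clint_other_ul_min_mg=0.0)
        assert whole_liver_clint(subject, compound) == 0.0

    def test_linearity_in_abundance(self):
        compound = low_extraction_compound()
        base = whole_liver_clint(make_subject({"CYP3A4": 137.0}), compound)
        doubled = whole_liver_clint(make_subject({"CYP3A4": 274.0}), compound)
        assert doubled == pytest.approx(2.0 * base)

    def test_well_stirred_direct_evaluation(self):
        assert hepatic_clearance(500.0, 0.1, 90.0) == pytest.approx(90.0 * 50.0 / 140.0)

    def test_well_stirred_flow_limit(self):
        assert hepatic_clearance(1e9, 1.0, 90.0) == pytest.approx(90.0, rel=1e-6)

    def test_well_stirred_restrictive_limit(self):
        assert hepatic_clearance(1.0, 0.05, 90.0) == pytest.approx(0.05, rel=1e-3)

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            hepatic_clearance(100.0, 0.1, 0.0)


class TestLinearSimulation:
    def test_bateman_tmax(self):
        """tmax = ln(ka/ke)/(ka-ke) for one dose; ka=2, ke=0.2 -> 1.279 h."""
        subject = make_subject({"CYP3A4": 137.0}, weight_kg=80.0)
        compound = low_extraction_compound()
        _, cl, volume, ke = _linear_params(subject, compound)
        compound = low_extraction_compound(
            vss_l_per_kg=cl / 0.2 / subject.weight_kg  # force ke = 0.2/h
        )
        regimen = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=1, observation_window_h=24.0)
        profile = simulate_regimen(subject, compound, regimen)
        metrics = pk_metrics(profile, (0.0, 24.0))
        assert metrics.tmax_h == pytest.approx(math.log(10.0) / 1.8, abs=0.05)

    def test_trapezoid_auc_matches_closed_form(self):
        """Grid AUC within 0.5% of the analytic F*Dose/CL over a long window."""
        subject = make_subject()
        compound = low_extraction_compound(vss_l_per_kg=0.2)  # short half-life
        _, cl, volume, ke = _linear_params(subject, compound)
        window = 12.0 / ke  # negligible tail
        regimen = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=1, observation_window_h=window)
        profile = simulate_regimen(subject, compound, regimen)
        auc = pk_metrics(profile, (0.0, window)).auc_ng_ml_h
        assert auc == pytest.approx(oral_auc_inf(subject, compound, 100.0), rel=5e-3)

    def test_steady_state_interval_auc_equals_single_dose_auc_inf(self):
        """Superposition: interval AUC at dose 10 ~ single-dose AUC(0,inf) within 1%."""
        subject = make_subject()
        compound = low_extraction_compound(vss_l_per_kg=0.3)
        _, cl, volume, ke = _linear_params(subject, compound)
        assert ke * 24.0 > 0.7  # enough accumulation decay by the 10th dose
        regimen = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=10, observation_window_h=24.0)
        profile = simulate_regimen(subject, compound, regimen)
        ss_auc = pk_metrics(profile, (216.0, 240.0)).auc_ng_ml_h
        assert ss_auc == pytest.approx(oral_auc_inf(subject, compound, 100.0), rel=0.01)

    def test_dose_proportionality(self):
        subject = make_subject()
        compound = low_extraction_compound()
        reg1 = DoseRegimen(dose_mg=50.0, interval_h=24.0, n_doses=1)
        reg2 = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=1)
        m1 = pk_metrics(simulate_regimen(subject, compound, reg1), (0, 24))
        m2 = pk_metrics(simulate_regimen(subject, compound, reg2), (0, 24))
        assert m2.auc_ng_ml_h == pytest.approx(2.0 * m1.auc_ng_ml_h, rel=1e-9)
        assert m2.cmax_ng_ml == pytest.approx(2.0 * m1.cmax_ng_ml, rel=1e-9)

    def test_absorption_equal_elimination_limit_is_finite(self):
        subject = make_subject()
        compound = low_extraction_compound()
        _, cl, volume, ke = _linear_params(subject, compound)
        compound = low_extraction_compound(ka_per_h=ke)
        regimen = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=1)
        profile = simulate_regimen(subject, compound, regimen)
        assert np.all(np.isfinite(profile.concentrations_ng_ml))
        assert profile.concentrations_ng_ml.max() > 0


class TestMetrics:
    def test_constant_profile(self):
        t = np.linspace(0.0, 24.0, 481)
        profile = PKProfile(times_h=t, concentrations_ng_ml=np.full_like(t, 10.0))
        m = pk_metrics(profile, 24.0)
        assert m.auc_ng_ml_h == pytest.approx(240.0)
        assert m.cmax_ng_ml == 10.0

    def test_linear_decay_triangle(self):
        t = np.linspace(0.0, 24.0, 481)
        profile = PKProfile(times_h=t, concentrations_ng_ml=10.0 * (1 - t / 24.0))
        assert pk_metrics(profile, 24.0).auc_ng_ml_h == pytest.approx(120.0)

    def test_window_outside_grid_rejected(self):
        t = np.linspace(0.0, 24.0, 481)
        profile = PKProfile(times_h=t, concentrations_ng_ml=np.zeros_like(t))
        with pytest.raises(ValueError, match="window"):
            pk_metrics(profile, (12.0, 48.0))


class TestAucRatioOracle:
    @pytest.mark.parametrize(
        "fm,scalars,expected",
        [
            ({"CYP3A4": 1.0}, {"CYP3A4": 0.5}, 2.0),
            ({"CYP3A4": 0.6, "CYP1A2": 0.3}, {"CYP3A4": 1.0, "CYP1A2": 1.0}, 1.0),
            ({"CYP1A2": 0.95}, {"CYP1A2": 0.37}, 1.0 / (0.3515 + 0.05)),
        ],
    )
    def test_examples(self, fm, scalars, expected):
        assert auc_ratio_low_extraction(fm, scalars) == pytest.approx(expected, rel=1e-9)

    def test_fm_over_one_rejected(self):
        with pytest.raises(ValueError):
            auc_ratio_low_extraction({"CYP3A4": 0.7, "CYP1A2": 0.4}, {"CYP3A4": 1.0})

    def test_engine_agrees_with_oracle_in_low_extraction_limit(self):
        """Abundance-scaled AUC ratio within 2% of 1/(sum fm*s + 1 - sum fm)."""
        abundances = {"CYP3A4": 137.0, "CYP1A2": 52.0}
        scalars = {"CYP3A4": 0.623, "CYP1A2": 0.37}
        compound = CompoundProfile(
            name="probe",
            dose_mg=100.0,
            ka_per_h=2.0,
            fa_fg=1.0,
            fu=0.01,  # keeps extraction < 0.1
            bp_ratio=1.0,
            vss_l_per_kg=0.4,
            clint_per_pmol={"CYP3A4": 0.5, "CYP1A2": 0.4},
            clint_other_ul_min_mg=20.0,
        )
        healthy = make_subject(dict(abundances))
        diseased = make_subject({k: v * scalars[k] for k, v in abundances.items()})
        # extraction check
        _, cl_h, _, _ = _linear_params(healthy, compound)
        assert cl_h / healthy.hepatic_blood_flow_l_per_h < 0.1
        auc_h = oral_auc_inf(healthy, compound, 100.0)
        auc_d = oral_auc_inf(diseased, compound, 100.0)
        # fm of each CYP within total intrinsic clearance of the healthy subject
        total = sum(abundances[e] * compound.clint_per_pmol[e] for e in abundances) + 20.0
        fm = {e: abundances[e] * compound.clint_per_pmol[e] / total for e in abundances}
        expected = auc_ratio_low_extraction(fm, scalars)
        assert auc_d / auc_h == pytest.approx(expected, rel=0.02)

    def test_cmax_ratio_not_larger_than_auc_ratio(self):
        """Pure clearance reduction raises Cmax less than AUC for oral dosing."""
        compound = low_extraction_compound()
        healthy = make_subject({"CYP3A4": 137.0})
        diseased = make_subject({"CYP3A4": 137.0 * 0.4})
        regimen = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=1, observation_window_h=96.0)
        mh = pk_metrics(simulate_regimen(healthy, compound, regimen), (0, 96))
        md = pk_metrics(simulate_regimen(diseased, compound, regimen), (0, 96))
        auc_ratio = md.auc_ng_ml_h / mh.auc_ng_ml_h
        cmax_ratio = md.cmax_ng_ml / mh.cmax_ng_ml
        assert auc_ratio > 1.0
        assert cmax_ratio <= auc_ratio + 1e-9


class TestHaematocritAdjustment:
    def test_identity_at_reference_haematocrit(self):
        from mafld_pbpk.engine import adjusted_bp_ratio

        assert adjusted_bp_ratio(0.66, 43.0, 43.0) == pytest.approx(0.66)
        assert adjusted_bp_ratio(1.0, 48.2, 43.0) == pytest.approx(1.0)

    def test_higher_haematocrit_amplifies_cell_partitioning(self):
        from mafld_pbpk.engine import adjusted_bp_ratio

        # bp > 1 (red-cell partitioning) grows with haematocrit; bp < 1 shrinks
        assert adjusted_bp_ratio(1.5, 48.2, 43.0) > 1.5
        assert adjusted_bp_ratio(0.66, 48.2, 43.0) < 0.66

    def test_adjustment_changes_simulated_exposure(self):
        subject = make_subject()  # haematocrit 43
        raised = make_subject()
        object.__setattr__(raised, "haematocrit_pct", 48.2)
        # renal clearance keeps B:P from cancelling out of the oral AUC
        compound = low_extraction_compound(
            bp_ratio=0.66, bp_reference_hct_pct=43.0, cl_renal_l_per_h=5.0
        )
        auc_base = oral_auc_inf(subject, compound, 100.0)
        auc_raised = oral_auc_inf(raised, compound, 100.0)
        assert auc_raised != pytest.approx(auc_base, rel=1e-3)
        # without a reference haematocrit the subjects are equivalent
        plain = low_extraction_compound(bp_ratio=0.66)
        assert oral_auc_inf(subject, plain, 100.0) == pytest.approx(
            oral_auc_inf(raised, plain, 100.0)
        )


class TestMichaelisMenten:
    def test_mm_converges_to_linear_far_below_km(self):
        subject = make_subject()
        linear = low_extraction_compound(vss_l_per_kg=0.3)
        clint_l_h = whole_liver_clint(subject, linear)
        km = 1e6  # mg/L, astronomically above any simulated concentration
        mm_compound = low_extraction_compound(
            vss_l_per_kg=0.3,
            mm=MichaelisMenten(vmax_mg_per_h=clint_l_h * km, km_mg_per_l=km),
        )
        regimen = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=2, observation_window_h=24.0)
        lin_profile = simulate_regimen(subject, linear, regimen)
        mm_profile = simulate_regimen(subject, mm_compound, regimen, use_mm=True)
        lin_auc = pk_metrics(lin_profile, (24.0, 48.0)).auc_ng_ml_h
        mm_auc = pk_metrics(mm_profile, (24.0, 48.0)).auc_ng_ml_h
        assert mm_auc == pytest.approx(lin_auc, rel=0.01)

    def test_mm_requires_block(self):
        subject = make_subject()
        regimen = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=1)
        with pytest.raises(ValueError, match="Michaelis"):
            simulate_regimen(subject, low_extraction_compound(), regimen, use_mm=True)

    def test_saturation_raises_exposure_above_linear(self):
        subject = make_subject()
        linear = low_extraction_compound(vss_l_per_kg=0.3)
        clint_l_h = whole_liver_clint(subject, linear)
        km = 0.01  # saturating at simulated concentrations
        mm_compound = low_extraction_compound(
            vss_l_per_kg=0.3,
            mm=MichaelisMenten(vmax_mg_per_h=clint_l_h * km, km_mg_per_l=km),
        )
        regimen = DoseRegimen(dose_mg=100.0, interval_h=24.0, n_doses=1, observation_window_h=24.0)
        lin_auc = pk_metrics(simulate_regimen(subject, linear, regimen), (0, 24)).auc_ng_ml_h
        mm_auc = pk_metrics(
            simulate_regimen(subject, mm_compound, regimen, use_mm=True), (0, 24)
        ).auc_ng_ml_h
        assert mm_auc > lin_auc
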