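import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from hifucea.parameters import (
    ParameterError,
    annual_to_monthly,
    builtin_basecase,
    from_dict,
    get_param,
    iter_leaf_paths,
    load_parameters,
    monthly_to_annual,
    parameters_to_csv,
    save_parameters,
    set_param,
    to_dict,
    validate,
    validation_warnings,
)


class TestBasecase:
    def test_validates_clean(self, base):
        assert validate(base) == []

    @pytest.mark.parametrize(
        "path, value",
        [
            ("treatments.hifu.response.p_complete", 0.230),
            ("treatments.hifu.response.p_partial", 0.410),
            ("treatments.mf_ebrt.response.p_complete", 0.240),
            ("treatments.sf_ebrt.response.p_none", 0.390),
            ("treatments.mf_ebrt.p_retreat_monthly", 0.007),
            ("treatments.sf_ebrt.p_retreat_monthly", 0.018),
            ("treatments.mf_ebrt.p_no_response_retreat", 0.420),
            ("p_relapse_monthly", 0.022),
            ("utilities.u_base", 0.039),
            ("utilities.gain_complete", 0.019),
            ("utilities.du_mf_ebrt", -0.009),
            ("costs.c_hifu_inpatient", 3430.0),
            ("costs.c_fracture_total", 21430.0),
            ("costs.c_opioid_monthly", 210.0),
            ("strategy.share_hifu_firstline_A", 0.60),
            ("strategy.share_sf_ebrt", 0.10),
            ("strategy.share_ebrt_outpatient", 0.70),
            ("discount_annual", 0.03),
        ],
    )
    def test_tabulated_value(self, base, path, value):
        assert get_param(base, path) == pytest.approx(value)

    def test_lung_mortality_schedule(self, base):
        assert base.mortality["lung"].monthly_p_by_year == (0.070, 0.050, 0.050, 0.030, 0.020)

    def test_fracture_components_sum_to_total(self, base):
        c = base.costs
        total = (
            c.c_fracture_outpatient
            + c.c_fracture_inpatient
            + c.c_fracture_rehabilitation
            + c.c_fracture_prescriptions
            + c.c_fracture_aids
        )
        assert total == pytest.approx(c.c_fracture_total)

    def test_response_triplets_on_simplex(self, base):
        for tr in base.treatments.values():
            assert sum(tr.response.as_tuple()) == pytest.approx(1.0, abs=1e-9)

    def test_mortality_extrapolation_holds_year5(self, base):
        mt = base.mortality["breast"]
        assert mt.monthly_p(59) == mt.monthly_p_by_year[4]
        assert mt.monthly_p(60) == mt.monthly_p_by_year[4]
        assert mt.monthly_p(599) == mt.monthly_p_by_year[4]

    def test_survival_consistency_warnings_flag_lung_and_prostate(self, base):
        notes = validation_warnings(base)
        assert any("lung" in n for n in notes)
        assert any("prostate" in n for n in notes)


class TestRateConversion:
    @pytest.mark.parametrize(
        "annual, monthly",
        [(0.20, 0.01842), (0.08, 0.00692), (0.0, 0.0)],
    )
    def test_compounding_conversion(self, annual, monthly):
        assert annual_to_monthly(annual) == pytest.approx(monthly, abs=5e-6)

    def test_rejects_certain_event(self):
        with pytest.raises(ValueError):
            annual_to_monthly(1.0)

    @given(hst.floats(min_value=0.0, max_value=0.999))
    @settings(max_examples=100, deadline=None)
    def test_bijection_on_unit_interval(self, p):
        assert monthly_to_annual(annual_to_monthly(p)) == pytest.approx(p, abs=1e-12)


class TestValidation:
    def test_negative_cost_yields_one_diagnostic(self, base):
        bad = set_param(base, "costs.c_sf_ebrt", -1.0)
        diags = validate(bad)
        assert len(diags) == 1
        assert "c_sf_ebrt" in diags[0]

    def test_cancer_mix_off_simplex(self, base):
        base.cancer_mix = (0.5, 0.5, 0.5)
        assert any("cancer_mix" in d for d in validate(base))

    def test_broken_response_triplet_named(self, base):
        base.treatments["hifu"].response.p_complete = 0.5
        diags = validate(base)
        assert any("treatments.hifu.response" in d for d in diags)


class TestConfigIO:
    def test_round_trip_identity(self, base, tmp_path):
        path = str(tmp_path / "params.yaml")
        save_parameters(base, path)
        again = load_parameters(path)
        assert to_dict(again) == to_dict(base)

    def test_unknown_key_rejected(self, base):
        data = to_dict(base)
        data["utilities"]["u_bogus"] = 0.1
        with pytest.raises(ParameterError, match="u_bogus"):
            from_dict(data)

    def test_missing_field_named(self, base):
        data = to_dict(base)
        del data["costs"]["c_sf_ebrt"]
        with pytest.raises(ParameterError, match="c_sf_ebrt"):
            from_dict(data)

    def test_off_simplex_config_names_triplet(self, base):
        data = to_dict(base)
        data["treatments"]["hifu"]["response"]["p_complete"] = 0.43  # sum 1.2
        with pytest.raises(ParameterError, match="treatments.hifu.response"):
            from_dict(data)

    def test_all_single_fraction_scenario_config_valid(self, base):
        data = to_dict(base)
        data["strategy"]["share_sf_ebrt"] = 1.0
        ps = from_dict(data)
        assert ps.strategy.share_sf_ebrt == 1.0

    def test_csv_export_covers_all_leaves(self, base, tmp_path):
        path = tmp_path / "audit.csv"
        parameters_to_csv(base, str(path))
        lines = path.read_text().strip().splitlines()
        assert len(lines) - 1 == sum(1 for _ in iter_leaf_paths(base))
        assert lines[0] == "parameter,value"


def test_set_param_does_not_mutate_original(base):
    before = get_param(base, "costs.c_hifu_inpatient")
    changed = set_param(base, "costs.c_hifu_inpatient", 9999.0)
    assert get_param(base, "costs.c_hifu_inpatient") == before
    assert get_param(changed, "costs.c_hifu_inpatient") == 9999.0
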