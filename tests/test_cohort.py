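import copy

import numpy as np
import pytest

from hifucea.cohort import (
    ONSET_FRACTION_HIFU,
    discount_factor,
    expected_outcomes,
    expected_outcomes_batch,
    initial_response_distribution,
    retreat_response_distribution,
)
from hifucea.fixtures import perturbed_params
from hifucea.parameters import CANCERS, set_param


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate, cycle, expected",
        [(0.03, 0, 1.0), (0.03, 12, 1 / 1.03), (0.0, 240, 1.0)],
    )
    def test_values(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, rel=1e-9)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 3)


class TestResponseDistributions:
    def test_firstline_profiles(self, base):
        w, f = initial_response_distribution("B", "mf_ebrt", base)
        assert w == pytest.approx([0.24, 0.38, 0.38])
        assert f == 0.0
        w, f = initial_response_distribution("A", "hifu", base)
        assert w == pytest.approx([0.23, 0.41, 0.36])
        assert f == pytest.approx(23 / 30)

    def test_hifu_not_allowed_firstline_in_B(self, base):
        with pytest.raises(ValueError):
            initial_response_distribution("B", "hifu", base)

    def test_degenerate_complete_response(self, base):
        base.treatments["hifu"].response.p_complete = 1.0
        base.treatments["hifu"].response.p_partial = 0.0
        base.treatments["hifu"].response.p_none = 0.0
        w, _ = initial_response_distribution("A", "hifu", base)
        assert w == pytest.approx([1.0, 0.0, 0.0])

    def test_hifu_retreat_equals_firstline(self, base):
        assert retreat_response_distribution("A", "hifu", base) == pytest.approx(
            [0.23, 0.41, 0.36]
        )

    def test_reirradiation_is_inferior(self, base):
        w = retreat_response_distribution("B", "mf_ebrt", base)
        assert w == pytest.approx([0.2245, 0.3555, 0.42], abs=1e-4)

    def test_reirradiation_certain_failure(self, base):
        base.treatments["mf_ebrt"].p_no_response_retreat = 1.0
        w = retreat_response_distribution("B", "mf_ebrt", base)
        assert w == pytest.approx([0.0, 0.0, 1.0])


def _near_immortal(ps):
    for mt in ps.mortality.values():
        mt.monthly_p_by_year = tuple([1e-12] * 5)
    return ps


def _no_events(ps):
    for tr in ps.treatments.values():
        tr.p_retreat_monthly = 0.0
        tr.p_fracture_monthly = 0.0
    ps.p_relapse_monthly = 0.0
    return ps


class TestEngineClosedForms:
    def test_immediate_death_leaves_entry_accrual_only(self, base):
        """With (near-)certain death in month 1, totals equal the entry
        cycle's closed form: treatment cost + one month of opioids, and
        entry disutility + one month of base utility + onset-weighted gain."""
        ps = _no_events(base)
        for mt in ps.mortality.values():
            mt.monthly_p_by_year = tuple([1.0 - 1e-12] * 5)
        res = expected_outcomes("B", ps)
        c = ps.costs
        entry_cost = 0.9 * (0.7 * c.c_mf_ebrt_outpatient + 0.3 * c.c_mf_ebrt_inpatient) + 0.1 * c.c_sf_ebrt
        assert res.mean_cost == pytest.approx(entry_cost + 210.0, abs=1e-6)
        u = ps.utilities
        entry_du = 0.9 * u.du_mf_ebrt + 0.1 * u.du_sf_ebrt
        # EBRT response onset is after four weeks: no gain in the entry cycle
        assert res.mean_qaly == pytest.approx(entry_du + u.u_base, abs=1e-6)
        assert res.mean_pain_months == pytest.approx(0.0, abs=1e-6)

    def test_zero_discount_geometric_pain_months(self, base):
        """Reduced model (constant hazards, no retreat/fracture): responder
        months follow the geometric closed form, cross-checked against an
        independent brute-force summation."""
        p_d, p_r = 0.04, 0.022
        ps = _no_events(base)
        ps.p_relapse_monthly = p_r
        ps.discount_annual = 0.0
        ps.horizon_months = 600
        for mt in ps.mortality.values():
            mt.monthly_p_by_year = tuple([p_d] * 5)
        res = expected_outcomes("B", ps)

        per_responder = 0.0 + sum(
            ((1 - p_d) * (1 - p_r)) ** t for t in range(1, ps.horizon_months)
        )
        responders = 0.9 * (0.24 + 0.38) + 0.1 * (0.23 + 0.38)
        assert res.mean_pain_months == pytest.approx(responders * per_responder, rel=1e-9)
        assert res.mean_pain_months_undiscounted == pytest.approx(res.mean_pain_months)

    def test_hifu_onset_adds_entry_cycle_fraction(self, base):
        """Same reduced model through strategy A at 100% HIFU first line:
        responders additionally accrue 23/30 of the entry month."""
        p_d, p_r = 0.04, 0.022
        ps = _no_events(base)
        ps.p_relapse_monthly = p_r
        ps.discount_annual = 0.0
        ps.strategy.share_hifu_firstline_A = 1.0
        for mt in ps.mortality.values():
            mt.monthly_p_by_year = tuple([p_d] * 5)
        res = expected_outcomes("A", ps)
        per_responder = ONSET_FRACTION_HIFU + sum(
            ((1 - p_d) * (1 - p_r)) ** t for t in range(1, ps.horizon_months)
        )
        assert res.mean_pain_months == pytest.approx(0.64 * per_responder, rel=1e-9)

    def test_persistent_only_cohort_pays_opioids_every_month(self, base):
        """All-no-response, no relapse/retreat/fracture, no discounting, near
        zero mortality: cost = entry + opioids for every month of the horizon."""
        ps = _near_immortal(_no_events(base))
        ps.discount_annual = 0.0
        ps.horizon_months = 120
        for tr in ps.treatments.values():
            tr.response.p_complete = 0.0
            tr.response.p_partial = 0.0
            tr.response.p_none = 1.0
        with pytest.warns(UserWarning, match="alive"):
            res = expected_outcomes("B", ps)
        c = ps.costs
        entry_cost = 0.9 * (0.7 * c.c_mf_ebrt_outpatient + 0.3 * c.c_mf_ebrt_inpatient) + 0.1 * c.c_sf_ebrt
        assert res.mean_cost == pytest.approx(entry_cost + 120 * 210.0, rel=1e-6)
        assert res.mean_pain_months == 0.0

    def test_relapse_rate_moves_expected_mass(self, base):
        """A pure-complete cohort with only relapse active loses 2.2% of its
        response mass per month (geometric decay)."""
        ps = _near_immortal(base)
        ps.discount_annual = 0.0
        for tr in ps.treatments.values():
            tr.p_retreat_monthly = 0.0
            tr.p_fracture_monthly = 0.0
            tr.response.p_complete = 1.0
            tr.response.p_partial = 0.0
            tr.response.p_none = 0.0
        ps.horizon_months = 120
        with pytest.warns(UserWarning, match="alive"):
            res = expected_outcomes("B", ps)
        expected = sum((1 - 0.022) ** t for t in range(1, 120))
        assert res.mean_pain_months == pytest.approx(expected, rel=1e-9)


class TestEngineInvariants:
    def test_mass_conservation_on_randomized_sets(self):
        # the engine raises MassConservationError on any leak > 1e-9
        for seed in range(5):
            ps = perturbed_params(seed, jitter=0.3)
            expected_outcomes("A", ps)
            expected_outcomes("B", ps)

    def test_raising_cost_never_lowers_arm_cost(self, base):
        for path in ("costs.c_hifu_inpatient", "costs.c_opioid_monthly", "costs.c_fracture_total"):
            up = set_param(base, path, 1.5 * float(np.asarray(_get(base, path))))
            for strat in ("A", "B"):
                assert (
                    expected_outcomes(strat, up, check=False).mean_cost
                    >= expected_outcomes(strat, base).mean_cost - 1e-9
                )

    def test_raising_complete_gain_never_lowers_qaly(self, base):
        up = set_param(base, "utilities.gain_complete", 0.03)
        for strat in ("A", "B"):
            assert (
                expected_outcomes(strat, up).mean_qaly
                >= expected_outcomes(strat, base).mean_qaly
            )

    def test_strategy_A_degenerates_to_B(self, base):
        """No first-line HIFU and no retreatment anywhere collapses the two
        strategies onto the same EBRT-only model, exactly."""
        ps = copy.deepcopy(base)
        ps.strategy.share_hifu_firstline_A = 0.0
        for tr in ps.treatments.values():
            tr.p_retreat_monthly = 0.0
        a = expected_outcomes("A", ps)
        b = expected_outcomes("B", ps)
        assert a.mean_cost == pytest.approx(b.mean_cost, abs=1e-9)
        assert a.mean_qaly == pytest.approx(b.mean_qaly, abs=1e-12)
        assert a.mean_pain_months == pytest.approx(b.mean_pain_months, abs=1e-12)

    def test_batch_matches_single_evaluations(self, base):
        sets = [perturbed_params(s, jitter=0.15) for s in range(4)]
        out = expected_outcomes_batch("A", sets)
        for i, ps in enumerate(sets):
            single = expected_outcomes("A", ps)
            assert out["cost"][i] == pytest.approx(single.mean_cost, rel=1e-12)
            assert out["qaly"][i] == pytest.approx(single.mean_qaly, rel=1e-12)

    def test_mixture_consistency_over_cancers(self, base):
        """Base-case arm means equal the cancer-mix-weighted average of the
        three pure-subgroup arm means (cohort engine is linear in the mix)."""
        for strat in ("A", "B"):
            whole = expected_outcomes(strat, base)
            parts = []
            for c in CANCERS:
                mix = tuple(1.0 if k == c else 0.0 for k in CANCERS)
                parts.append(expected_outcomes(strat, set_param(base, "cancer_mix", mix)))
            for field in ("mean_cost", "mean_qaly", "mean_pain_months"):
                mixed = sum(getattr(p, field) for p in parts) / 3.0
                assert getattr(whole, field) == pytest.approx(mixed, abs=1e-9)


def _get(ps, path):
    from hifucea.parameters import get_param

    return get_param(ps, path)
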