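import numpy as np
import pytest

from hifucea.fixtures import gaussian_evpi, gaussian_nb_psa, linear_theta_psa
from hifucea.parameters import builtin_basecase, validate
from hifucea.psa import (
    assign_distributions,
    ce_plane_quadrants,
    ceac,
    draw_parameter_set,
    run_psa,
)
from hifucea.voi import evpi_curve, evpi_per_person, evppi, population_evpi


class TestParameterDraws:
    def test_zero_sd_reproduces_base(self, base):
        base.sd_table = {k: 0.0 for k in base.sd_table}
        rng = np.random.default_rng(0)
        ps, _ = draw_parameter_set(base, rng)
        assert ps.costs.c_hifu_inpatient == base.costs.c_hifu_inpatient
        assert ps.treatments["hifu"].response.p_complete == pytest.approx(0.23)

    def test_moment_match_of_marginals(self, base):
        """Empirical mean/SD of the sampled parameters reproduce the
        tabulated (mean, SD) for representative beta / gamma / Dirichlet
        entries."""
        rng = np.random.default_rng(1)
        assignments = assign_distributions(base)
        draws = [draw_parameter_set(base, rng, assignments)[1] for _ in range(4000)]
        pc = np.array([d["treatments.hifu.response.p_complete"] for d in draws])
        assert pc.mean() == pytest.approx(0.230, abs=0.003)
        assert pc.std() == pytest.approx(0.04, abs=0.004)
        ch = np.array([d["costs.c_hifu_inpatient"] for d in draws])
        assert ch.mean() == pytest.approx(3430.0, rel=0.02)
        assert ch.std() == pytest.approx(686.0, rel=0.05)
        rl = np.array([d["p_relapse_monthly"] for d in draws])
        assert rl.mean() == pytest.approx(0.022, abs=0.001)
        assert rl.std() == pytest.approx(0.008, rel=0.1)

    def test_every_draw_validates(self, base):
        rng = np.random.default_rng(2)
        assignments = assign_distributions(base)
        for _ in range(50):
            ps, _ = draw_parameter_set(base, rng, assignments)
            assert validate(ps) == []

    def test_mortality_never_varied(self, base):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ps, rec = draw_parameter_set(base, rng)
            assert ps.mortality["lung"].monthly_p_by_year == base.mortality["lung"].monthly_p_by_year
            assert not any(p.startswith("mortality") for p in rec)


class TestRunPsa:
    def test_seed_reproducibility(self, base):
        t1 = run_psa(base, n_iter=20, seed=7)
        t2 = run_psa(base, n_iter=20, seed=7)
        assert t1.df.equals(t2.df)

    def test_rejects_single_iteration(self, base):
        with pytest.raises(ValueError):
            run_psa(base, n_iter=1, seed=0)

    def test_quadrant_fractions_sum_to_one(self, psa_small):
        quads = ce_plane_quadrants(psa_small)
        assert sum(quads.values()) == pytest.approx(1.0, abs=1e-12)

    def test_csv_round_trip(self, psa_small, tmp_path):
        path = str(tmp_path / "psa.csv")
        psa_small.to_csv(path)
        from hifucea.psa import PSASampleTable

        again = PSASampleTable.from_csv(path)
        assert np.allclose(again.incremental_nmb(20000), psa_small.incremental_nmb(20000))


class TestCeac:
    def test_infinite_wtp_limit_is_prob_positive_effect(self, psa_small):
        d = psa_small.df
        p_pos = float(((d["A.qaly"] - d["B.qaly"]) > 0).mean())
        curve = ceac(psa_small, [1e12])
        assert curve["p_cost_effective"].iloc[0] == pytest.approx(p_pos, abs=1e-9)

    def test_degenerate_table_steps_at_icer(self):
        # all iterations identical: CEAC is a step function at the ICER
        import pandas as pd

        from hifucea.psa import PSASampleTable

        n = 20
        # deltas chosen exactly representable in binary so the tie at the
        # ICER is exact: dC = 500, dQ = 0.25 -> ICER = 2000 EUR/QALY
        table = PSASampleTable(
            df=pd.DataFrame(
                {
                    "A.cost": [8500.0] * n,
                    "A.qaly": [1.25] * n,
                    "A.pain": [10.0] * n,
                    "B.cost": [8000.0] * n,
                    "B.qaly": [1.0] * n,
                    "B.pain": [9.5] * n,
                }
            )
        )
        icer = 500.0 / 0.25
        curve = ceac(table, [0.5 * icer, icer, 2 * icer])["p_cost_effective"]
        assert list(curve) == [0.0, 0.5, 1.0]

    def test_ties_count_half(self):
        table, _ = gaussian_nb_psa(m=0.0, sigma=0.0, n_iter=10, seed=0)
        assert ceac(table, [20000.0])["p_cost_effective"].iloc[0] == 0.5


class TestEvpi:
    def test_unanimous_table_has_zero_evpi(self):
        table, _ = gaussian_nb_psa(m=1e6, sigma=1.0, n_iter=500, seed=4)
        assert evpi_per_person(table, 20000.0) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("m,sigma", [(0, 1000), (500, 1000), (-500, 1000), (2000, 800)])
    def test_matches_gaussian_closed_form(self, m, sigma):
        """Sample EVPI agrees with the analytic Gaussian value within three
        bootstrap standard errors."""
        table, truth = gaussian_nb_psa(m=m, sigma=sigma, n_iter=20000, seed=abs(m) + 7)
        est = evpi_per_person(table, 20000.0)
        rng = np.random.default_rng(0)
        inb = table.incremental_nmb(20000.0)
        boots = []
        for _ in range(200):
            idx = rng.integers(0, len(inb), len(inb))
            s = inb[idx]
            boots.append(np.mean(np.maximum(s, 0)) - max(s.mean(), 0.0))
        se = np.std(boots, ddof=1)
        assert abs(est - truth) <= 3 * se

    def test_curve_nonnegative(self, psa_small):
        curve = evpi_curve(psa_small, [0, 10000, 20000, 40000])
        assert (curve["evpi"] >= 0).all()


@pytest.fixture(scope="module")
def linear_table():
    return linear_theta_psa(weights=(300.0, 400.0), noise=50.0, n_iter=4000, seed=13)


class TestEvppi:
    def test_empty_subset_rejected(self, psa_small):
        with pytest.raises(ValueError):
            evppi(psa_small, [], wtp=20000.0)

    def test_informative_parameter_recovers_truth(self, linear_table):
        table, truths = linear_table
        res = evppi(table, ["theta_0"], wtp=20000.0, seed=0)
        assert res.method == "spline"
        assert res.evppi == pytest.approx(truths["theta_0"], rel=0.15)

    def test_noise_parameter_near_zero(self, linear_table):
        table, truths = linear_table
        table.df["param.noise_col"] = np.random.default_rng(5).normal(size=table.n_iter)
        res = evppi(table, ["noise_col"], wtp=20000.0, seed=0)
        assert res.evppi <= 0.05 * truths["evpi"] + 2 * res.se

    def test_full_subset_approaches_evpi(self, linear_table):
        table, truths = linear_table
        res = evppi(table, ["theta_0", "theta_1"], wtp=20000.0, seed=0, n_boot=10)
        assert res.method == "gp"
        evpi = evpi_per_person(table, 20000.0)
        assert res.evppi == pytest.approx(evpi, rel=0.15)

    def test_monotone_in_information(self, linear_table):
        """EVPPI of a subset never exceeds that of a superset (up to
        estimator noise)."""
        table, _ = linear_table
        single = evppi(table, ["theta_0"], wtp=20000.0, seed=0)
        both = evppi(table, ["theta_0", "theta_1"], wtp=20000.0, seed=0, n_boot=10)
        assert single.evppi <= both.evppi + 2 * (single.se + both.se)


class TestPopulationEvpi:
    def test_zero_counts(self):
        assert population_evpi(434.0, [0, 0, 0]) == 0.0

    def test_single_cohort_no_discount(self):
        assert population_evpi(434.0, [100_000], discount_annual=0.0) == pytest.approx(43.4e6)

    def test_discounting_shrinks_value(self):
        flat = population_evpi(434.0, [50_000] * 5, discount_annual=0.0)
        disc = population_evpi(434.0, [50_000] * 5, discount_annual=0.03)
        assert disc < flat

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            population_evpi(1.0, [-5])


def test_gaussian_evpi_closed_form_values():
    assert gaussian_evpi(0.0, 1000.0) == pytest.approx(1000.0 / np.sqrt(2 * np.pi), rel=1e-9)
    assert gaussian_evpi(1e6, 1.0) == pytest.approx(0.0, abs=1e-9)
    # symmetry: EVPI(m) == EVPI(-m)
    assert gaussian_evpi(-500.0, 1000.0) == pytest.approx(gaussian_evpi(500.0, 1000.0), rel=1e-12)
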