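"""Two-site cooperative binding: fractions, classification, global fit."""

import numpy as np
import pytest
from scipy import stats

from tweezfold.constructs import (
    PAPER_BINDING_MODEL,
    cnb_a,
    cnb_b,
    default_protocol,
    n3a_motif,
)
from tweezfold.errors import InvalidInputError, UnidentifiableModelError
from tweezfold.ripscan import RipEvent, detect_rips
from tweezfold.simulate import simulate_force_ramp, simulate_titration_counts
from tweezfold.titration import (
    BindingModel,
    LigandedState,
    SpeciesCounts,
    classify_trajectory,
    fit_global,
    log_likelihood,
    species_fractions,
)

CONC_GRID = np.geomspace(1.0, 150.0, 12)


def rip(force, dlc, direction="unfold", reversible=False):
    return RipEvent(
        cycle_id=0, direction=direction, rupture_force=force,
        delta_x=dlc * 0.55, delta_lc=dlc, loading_rate=6.0, time=1.0,
        reversible=reversible,
    )


class TestSpeciesFractions:
    def test_apo_limit(self):
        assert species_fractions(PAPER_BINDING_MODEL, 0.0) == (1.0, 0, 0, 0)

    def test_fitted_parameter_point(self):
        f = species_fractions(PAPER_BINDING_MODEL, 10.0)
        assert np.allclose(f, (0.230, 0.135, 0.230, 0.405), atol=1e-3)

    def test_independent_sites_factorize(self):
        m = BindingModel(k_a=20.0, k_b=20.0, gamma=1.0)
        for L in (1.0, 20.0, 80.0):
            f = species_fractions(m, L)
            theta = (L / 20.0) / (1 + L / 20.0)  # single-site occupancy
            assert f[0] == pytest.approx((1 - theta) ** 2, rel=1e-12)
            assert f[3] == pytest.approx(theta**2, rel=1e-12)

    def test_sum_and_monotonicity(self):
        grid = np.geomspace(0.01, 1e5, 200)
        prev = None
        for L in grid:
            f = np.array(species_fractions(PAPER_BINDING_MODEL, L))
            assert abs(f.sum() - 1.0) < 1e-12
            if prev is not None:
                assert f[3] >= prev[3]  # fully bound increases
                assert f[0] <= prev[0]  # apo decreases
            prev = f

    def test_thermodynamic_cycle_closure(self):
        m = PAPER_BINDING_MODEL
        ka2, kb2 = m.second_site_kds()
        # path B-first: K_B then K_A/γ; path A-first: K_A then K_B/γ
        assert m.k_b * ka2 == pytest.approx(m.k_a * kb2, rel=1e-12)

    def test_negative_concentration(self):
        with pytest.raises(InvalidInputError):
            species_fractions(PAPER_BINDING_MODEL, -1.0)


class TestClassifyTrajectory:
    def test_constructed_apo_cycle(self):
        # two rips at 7-9 pN with full-length contour changes
        state = classify_trajectory([rip(7.5, 45.0), rip(8.8, 50.0)])
        assert state is LigandedState.A0B0

    def test_constructed_hopping_cycle(self):
        events = [rip(11.2, 13.0, reversible=True), rip(12.0, 50.0),
                  rip(17.0, 30.0)]
        assert classify_trajectory(events) is LigandedState.A1B1

    def test_constructed_camp_cnba_cycle(self):
        events = [rip(10.5, 50.0), rip(16.0, 30.0)]
        assert classify_trajectory(events) is LigandedState.A1B0

    def test_empty_is_unclassified(self):
        assert classify_trajectory([]) is LigandedState.UNCLASSIFIED

    @pytest.mark.parametrize(
        "species,min_acc",
        [("A0B0", 0.75), ("A1B0", 0.8), ("A0B1", 0.65), ("A1B1", 0.8)],
    )
    def test_simulated_species_recovered(self, species, min_acc, protocol):
        domains = {
            "A0B0": [cnb_a("apo"), cnb_b("apo")],
            "A1B0": [cnb_a("camp"), cnb_b("apo")],
            "A0B1": [cnb_a("apo"), cnb_b("camp")],
            "A1B1": [n3a_motif(), cnb_a("camp"), cnb_b("camp")],
        }[species]
        seeds = {"A0B0": 101, "A1B0": 202, "A0B1": 303, "A1B1": 404}
        traces, _ = simulate_force_ramp(domains, protocol, 40,
                                        seed=seeds[species], noise_sd=1.0)
        correct = sum(
            classify_trajectory(detect_rips(tr)).value == species
            for tr in traces
        )
        assert correct / len(traces) >= min_acc


class TestFitGlobal:
    def test_plugin_consistency_at_large_n(self):
        """Counts set exactly to expected proportions recover the model to
        3 significant digits."""
        m = PAPER_BINDING_MODEL
        counts = np.vstack(
            [np.round(1e6 * np.array(species_fractions(m, L))).astype(int)
             for L in CONC_GRID]
        )
        fit = fit_global(SpeciesCounts(CONC_GRID, counts), n_boot=0)
        assert fit.k_a == pytest.approx(17.0, rel=1e-3)
        assert fit.k_b == pytest.approx(10.0, rel=1e-3)
        assert fit.gamma == pytest.approx(3.0, rel=1e-3)

    def test_ci_coverage_small_sample(self):
        hits = 0
        for r in range(10):
            counts = simulate_titration_counts(
                PAPER_BINDING_MODEL, CONC_GRID, 100, seed=300 + r
            )
            fit = fit_global(counts, seed=r, n_boot=300)
            hits += all(
                fit.ci[k][0] <= v <= fit.ci[k][1]
                for k, v in (("k_a", 17.0), ("k_b", 10.0), ("gamma", 3.0))
            )
        assert hits >= 8

    def test_likelihood_ratio_power_for_cooperativity(self):
        """Restricted γ=1 fits on γ=3 data: the LR statistic exceeds the
        95% χ²₁ critical value in most replicates at ~1200 molecules."""
        crit = stats.chi2.ppf(0.95, df=1)
        wins = 0
        n_rep = 20
        for r in range(n_rep):
            counts = simulate_titration_counts(
                PAPER_BINDING_MODEL, CONC_GRID, 100, seed=400 + r
            )
            full = fit_global(counts, seed=r, n_boot=0)
            restricted = fit_global(counts, seed=r, n_boot=0, fix_gamma=1.0)
            lr = 2 * (log_likelihood(full, counts)
                      - log_likelihood(restricted, counts))
            wins += lr > crit
        assert wins >= int(0.8 * n_rep)

    def test_single_species_unidentifiable(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[:, 0] = 100
        with pytest.raises(UnidentifiableModelError):
            fit_global(SpeciesCounts(np.array([1.0, 10.0, 50.0, 150.0]), counts))

    def test_narrow_concentration_range_rejected(self):
        counts = np.full((4, 4), 25)
        with pytest.raises(InvalidInputError):
            fit_global(SpeciesCounts(np.array([10.0, 11.0, 12.0, 13.0]), counts))

    def test_single_site_reduction_on_isolated_domain_data(self):
        """Isolated-domain titration (bound/unbound of one site only): the
        global fit reduces to the closed-form single-site Kd MLE."""
        rng = np.random.default_rng(5)
        kd = 30.0
        conc = np.geomspace(2, 500, 10)
        n = 400
        counts = np.zeros((10, 4), dtype=int)
        for i, L in enumerate(conc):
            bound = rng.binomial(n, L / (L + kd))
            counts[i] = (n - bound, 0, bound, 0)  # occupancy on one site
        start = BindingModel(k_a=1e5, k_b=30.0, gamma=1.0)
        fit = fit_global(SpeciesCounts(conc, counts), start=start, n_boot=0,
                         fix_gamma=1.0)
        from scipy.optimize import minimize_scalar

        def nll(log_kd):
            p = conc / (conc + np.exp(log_kd))
            return -np.sum(
                counts[:, 2] * np.log(p) + counts[:, 0] * np.log(1 - p)
            )

        kd_mle = np.exp(minimize_scalar(nll, bounds=(0, 8), method="bounded").x)
        assert fit.k_b == pytest.approx(kd_mle, rel=0.02)
        pred_two_site = [species_fractions(fit, L)[2] for L in conc]
        pred_single = conc / (conc + kd_mle)
        assert np.allclose(pred_two_site, pred_single, atol=0.02)
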