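"""Bell/DHS kinetics: histogram→lifetime transform, fits, reconstruction."""

import numpy as np
import pytest

from tweezfold.constants import kbt
from tweezfold.errors import InvalidInputError, ValidationError
from tweezfold.forcekinetics import (
    ROLE_REFOLD,
    ForceHistogram,
    KineticParams,
    LifetimeCurve,
    fit_lifetimes,
    histogram_to_lifetimes,
    reconstruct_force_distribution,
)
from tweezfold.simulate import sample_rupture_forces

from .conftest import analytic_density


def make_histogram(forces, bin_width, loading_rate):
    edges = np.arange(0.0, np.ceil(forces.max() / bin_width) * bin_width
                      + bin_width / 2, bin_width)
    cnt, _ = np.histogram(forces, edges)
    return ForceHistogram(
        bin_edges=edges,
        density=cnt / (forces.size * bin_width),
        counts=cnt,
        loading_rates=np.full(len(cnt), loading_rate),
    )


class TestKineticParams:
    def test_bell_force_dependence_signs(self):
        unfold = KineticParams(1e3, 5.0)
        refold = KineticParams(1.0, 6.0, role=ROLE_REFOLD)
        f = np.linspace(0, 20, 50)
        assert np.all(np.diff(unfold.lifetime(f)) < 0)
        assert np.all(np.diff(refold.lifetime(f)) > 0)

    def test_dhs_nu1_equals_bell(self):
        bell = KineticParams(1e3, 5.0)
        dhs1 = KineticParams(1e3, 5.0, dg_ddagger=15.0, nu=1.0)
        f = np.linspace(0, 15, 31)
        assert np.allclose(dhs1.lifetime(f), bell.lifetime(f), rtol=1e-12)

    def test_dhs_critical_force_domain_error(self):
        dhs = KineticParams(1e3, 5.0, dg_ddagger=10.0, nu=0.5)
        f_crit = 10.0 * kbt() / (0.5 * 5.0)
        with pytest.raises(InvalidInputError):
            dhs.lifetime(f_crit + 1.0)

    @pytest.mark.parametrize("bad", [{"tau0": -1.0}, {"dx_ddagger": 0.0},
                                     {"nu": 0.3}])
    def test_validation(self, bad):
        kwargs = {"tau0": 1.0, "dx_ddagger": 1.0}
        kwargs.update(bad)
        with pytest.raises(InvalidInputError):
            KineticParams(**kwargs)


class TestHistogramToLifetimes:
    def test_hand_worked_two_bin_example(self):
        # h = (0.6, 0.4)/pN over 1 pN bins at 1 pN/s
        hist = ForceHistogram(
            bin_edges=np.array([0.0, 1.0, 2.0]),
            density=np.array([0.6, 0.4]),
            counts=np.array([60, 40]),
            loading_rates=np.array([1.0, 1.0]),
        )
        curve = histogram_to_lifetimes(hist)
        assert curve.lifetimes == pytest.approx([0.7 / 0.6, 0.2 / 0.4])

    def test_single_bin_degenerate_case(self):
        hist = ForceHistogram(
            bin_edges=np.array([5.0, 6.0]),
            density=np.array([1.0]),
            counts=np.array([100]),
            loading_rates=np.array([2.0]),
        )
        curve = histogram_to_lifetimes(hist)
        # (ΔF/2)/Ḟ
        assert curve.lifetimes[0] == pytest.approx(0.5 / 2.0)

    def test_unnormalized_rejected(self):
        hist = ForceHistogram(
            bin_edges=np.array([0.0, 1.0, 2.0]),
            density=np.array([0.6, 0.6]),
            counts=np.array([60, 60]),
            loading_rates=np.array([1.0, 1.0]),
        )
        with pytest.raises(ValidationError):
            histogram_to_lifetimes(hist)

    def test_transform_matches_bell_in_validity_region(self, apo_kinetics):
        """τ(F) from a 1e5-event histogram tracks τ0·exp(−FΔx‡/kBT) in bins
        that are both well populated and not survival-starved."""
        fs = sample_rupture_forces(apo_kinetics, 1.0, 100_000, seed=2)
        curve = histogram_to_lifetimes(make_histogram(fs, 0.2, 1.0))
        h = curve.counts.astype(float)
        tail = np.concatenate([np.cumsum(h[::-1])[::-1][1:], [0.0]])
        survival_ratio = (h / 2 + tail) / h
        m = (curve.counts >= 500) & (survival_ratio >= 2.0)
        rel = curve.lifetimes[m] / apo_kinetics.lifetime(curve.bin_centers[m]) - 1
        # 5% systematic bound plus the per-bin counting-noise allowance
        tol = 0.05 + 3.0 / np.sqrt(curve.counts[m])
        assert np.all(np.abs(rel) < tol)
        assert np.median(np.abs(rel)) < 0.02


class TestFitLifetimes:
    def test_noiseless_bell_exact_recovery(self):
        kin = KineticParams(2.5e3, 4.0)
        f = np.linspace(4, 10, 10)
        curve = LifetimeCurve(f, kin.lifetime(f), np.full(10, 500),
                              np.full(10, 1.0))
        fit = fit_lifetimes(curve, n_boot=0, n_irls=0)
        assert fit.tau0 == pytest.approx(2.5e3, rel=1e-6)
        assert fit.dx_ddagger == pytest.approx(4.0, rel=1e-6)

    def test_refolding_role_sign(self):
        kin = KineticParams(1e-3, 6.0, role=ROLE_REFOLD)
        f = np.linspace(2, 8, 8)
        curve = LifetimeCurve(f, kin.lifetime(f), np.full(8, 200),
                              np.full(8, 1.0), role=ROLE_REFOLD)
        fit = fit_lifetimes(curve, n_boot=0, n_irls=0)
        assert fit.tau0 == pytest.approx(1e-3, rel=1e-6)
        assert fit.dx_ddagger == pytest.approx(6.0, rel=1e-6)

    def test_coverage_of_bootstrap_cis(self, apo_kinetics):
        """Truth inside the 95% bootstrap CI for both parameters in most
        seeded 1000-event replicates (coverage study, scaled to 30 reps)."""
        hits = 0
        n_rep = 30
        for r in range(n_rep):
            fs = sample_rupture_forces(apo_kinetics, 1.0, 1000, seed=50 + r)
            curve = histogram_to_lifetimes(make_histogram(fs, 0.25, 1.0))
            fit = fit_lifetimes(curve, n_boot=300, seed=r)
            ok = (
                fit.ci["tau0"][0] <= apo_kinetics.tau0 <= fit.ci["tau0"][1]
                and fit.ci["dx_ddagger"][0]
                <= apo_kinetics.dx_ddagger
                <= fit.ci["dx_ddagger"][1]
            )
            hits += ok
        assert hits >= int(0.8 * n_rep)

    def test_bell_fit_of_dhs_data_underestimates_tau0(self):
        """Model mismatch: a straight Bell line through curved ν=1/2 DHS
        lifetimes extrapolates to a too-small zero-force lifetime."""
        dhs = KineticParams(1e3, 5.0, dg_ddagger=20.0, nu=0.5)
        f = np.linspace(4, 10, 13)
        curve = LifetimeCurve(f, dhs.lifetime(f), np.full(13, 1000),
                              np.full(13, 1.0))
        bell = fit_lifetimes(curve, model="bell", n_boot=0, n_irls=0)
        assert dhs.tau0 - bell.tau0 > 0
        # while the matched DHS fit recovers the inputs
        refit = fit_lifetimes(curve, model="dhs", nu=0.5, n_boot=0, n_irls=0)
        assert refit.tau0 == pytest.approx(1e3, rel=1e-3)
        assert refit.dg_ddagger == pytest.approx(20.0, rel=1e-2)

    def test_too_few_bins(self):
        f = np.array([5.0, 6.0, 7.0])
        curve = LifetimeCurve(f, np.ones(3), np.full(3, 10), np.full(3, 1.0))
        with pytest.raises(InvalidInputError):
            fit_lifetimes(curve, n_boot=0)


class TestReconstruction:
    def test_normalization(self, apo_kinetics):
        grid = np.linspace(0.01, 25.0, 3000)
        p = reconstruct_force_distribution(apo_kinetics, 1.0, grid)
        assert np.trapezoid(p, grid) == pytest.approx(1.0, abs=1e-3)

    def test_mode_matches_analytic_bell_evans(self, apo_kinetics):
        kt = kbt()
        mode = (kt / 4.5) * np.log(1.0 * 4.5 * 1.3e3 / kt)
        assert mode == pytest.approx(6.5, abs=0.1)
        grid = np.linspace(0.01, 20.0, 4000)
        p = reconstruct_force_distribution(apo_kinetics, 1.0, grid)
        assert grid[np.argmax(p)] == pytest.approx(mode, abs=0.05)

    def test_matches_independent_quadrature_oracle(self, apo_kinetics):
        grid = np.linspace(2.0, 12.0, 21)
        p = reconstruct_force_distribution(apo_kinetics, 1.0, grid)
        oracle = analytic_density(apo_kinetics, 1.0, grid)
        assert np.allclose(p, oracle, rtol=1e-4)

    def test_closed_loop_recovers_parameters_within_3pct(self, apo_kinetics):
        """reconstruct → sample → transform → fit round trip."""
        fs = sample_rupture_forces(apo_kinetics, 1.0, 200_000, seed=9)
        curve = histogram_to_lifetimes(make_histogram(fs, 0.1, 1.0))
        fit = fit_lifetimes(curve, n_boot=0)
        assert fit.tau0 == pytest.approx(apo_kinetics.tau0, rel=0.03)
        assert fit.dx_ddagger == pytest.approx(apo_kinetics.dx_ddagger, rel=0.03)
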