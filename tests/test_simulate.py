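"""Kinetic Monte-Carlo simulators against analytic oracles."""

import numpy as np
import pytest
from scipy import stats

from tweezfold.constructs import (
    PAPER_BINDING_MODEL,
    bell,
    cnb_b,
    domain_from_delta_lc,
    kinetics_for_clamp,
)
from tweezfold.errors import InvalidInputError, InvalidProtocolError
from tweezfold.forcekinetics import ROLE_REFOLD, KineticParams
from tweezfold.simulate import (
    DomainSpec,
    PullingProtocol,
    sample_rupture_forces,
    sample_unfolding_times,
    simulate_force_clamp,
    simulate_force_ramp,
    simulate_titration_counts,
)
from tweezfold.titration import species_fractions
from tweezfold.wlc import WLCParams, frac_extension_at

from .conftest import analytic_density, bell_mean_rupture_force


def inert_domain(name="inert"):
    """A domain that never unfolds (infinite zero-force lifetime)."""
    return DomainSpec(
        name=name,
        n_residues=120,
        unfold_kinetics=KineticParams(np.inf, 4.5),
        refold_kinetics=KineticParams(1e-3, 6.0, role=ROLE_REFOLD),
        d_nc=3.0,
    )


class TestProtocolValidation:
    def test_negative_velocity_rejected(self):
        with pytest.raises(InvalidProtocolError):
            PullingProtocol(pull_velocity=-5.0)

    def test_min_above_max_rejected(self):
        with pytest.raises(InvalidProtocolError):
            PullingProtocol(min_force=30.0, max_force=10.0)

    def test_negative_noise_rejected(self, protocol):
        with pytest.raises(InvalidInputError):
            simulate_force_ramp([inert_domain()], protocol, 1, seed=0,
                                noise_sd=-1.0)


class TestForceRamp:
    def test_zero_hazard_gives_smooth_monotone_curves(self, protocol):
        traces, truth = simulate_force_ramp([inert_domain()], protocol, 3, seed=1)
        assert truth.events == []
        for tr in traces:
            s = tr.stretch()
            assert np.all(np.diff(s.force) > -1e-9)
            assert np.all(np.diff(s.extension) > -1e-9)

    def test_mean_rupture_force_matches_quadrature_oracle(self, apo_kinetics):
        fs = sample_rupture_forces(apo_kinetics, 1.0, 5000, seed=2)
        oracle = bell_mean_rupture_force(apo_kinetics, 1.0)
        se = fs.std(ddof=1) / np.sqrt(fs.size)
        assert abs(fs.mean() - oracle) < 2 * se

    def test_rupture_density_chi2_gof(self, apo_kinetics):
        """Sampled rupture forces follow p(F) = [Ḟτ]⁻¹ exp(−∫[Ḟτ]⁻¹).

        (χ² at p > 0.01 has a 1% intrinsic false-alarm rate; the p-value
        distribution over seeds was checked to be uniform.)
        """
        fs = sample_rupture_forces(apo_kinetics, 1.0, 5000, seed=7)
        lo, hi = np.quantile(fs, [0.005, 0.995])
        edges = np.linspace(lo, hi, 21)
        obs, _ = np.histogram(fs, edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = analytic_density(apo_kinetics, 1.0, centers)
        expected = dens * np.diff(edges) * fs.size
        expected *= obs.sum() / expected.sum()
        chi2 = np.sum((obs - expected) ** 2 / expected)
        p = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 0.01

    def test_constant_force_survival_is_exponential(self, apo_kinetics):
        times = sample_unfolding_times(apo_kinetics, 8.0, 5000, seed=4)
        tau = apo_kinetics.lifetime(8.0)
        ks = stats.kstest(times, "expon", args=(0, tau))
        assert ks.statistic < 0.02

    def test_seed_reproducibility_and_variation(self, protocol):
        dom = cnb_b("apo")
        t1, g1 = simulate_force_ramp([dom], protocol, 3, seed=11, noise_sd=1.0)
        t2, g2 = simulate_force_ramp([dom], protocol, 3, seed=11, noise_sd=1.0)
        t3, _ = simulate_force_ramp([dom], protocol, 3, seed=12, noise_sd=1.0)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.extension, b.extension)
            np.testing.assert_array_equal(a.force, b.force)
        assert [e.time for e in g1.events] == [e.time for e in g2.events]
        assert not np.array_equal(t1[0].extension, t3[0].extension)

    def test_trap_position_continuous_extension_jumps(self, protocol):
        """Total trap coordinate ext + F/k stays continuous through rips
        while the extension itself jumps."""
        dom = cnb_b("camp")
        traces, truth = simulate_force_ramp([dom], protocol, 5, seed=21)
        k = protocol.trap_stiffness
        v_dt = protocol.pull_velocity * protocol.dt
        found_jump = False
        for tr in traces:
            s = tr.stretch()
            x_trap = s.extension + s.force / k
            assert np.max(np.abs(np.diff(x_trap))) < 3 * v_dt
            if np.max(np.diff(s.extension)) > 5.0:
                found_jump = True
        assert found_jump

    def test_ground_truth_sidecar_roundtrip(self, protocol, tmp_path):
        import json

        dom = cnb_b("camp")
        _, truth = simulate_force_ramp([dom], protocol, 3, seed=44)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = json.loads(path.read_text())
        n_events = sum(len(v) for v in back["events_by_cycle"].values())
        assert n_events == len(truth.events)
        for cyc, evs in back["events_by_cycle"].items():
            assert len(evs) == len(truth.events_for_cycle(int(cyc)))

    def test_event_times_strictly_increasing_per_cycle(self, protocol):
        dom = cnb_b("camp")
        _, truth = simulate_force_ramp([dom], protocol, 10, seed=33)
        for cyc in range(10):
            times = [e.time for e in truth.events_for_cycle(cyc)]
            assert all(b > a for a, b in zip(times, times[1:]))


class TestForceClamp:
    def test_noiseless_telegraph_levels(self, wt_hopping_domain):
        trace, truth = simulate_force_clamp(
            wt_hopping_domain, 11.0, 60.0, 500.0, 0.0, seed=5
        )
        levels = np.unique(trace.extension)
        assert levels.size == 2
        xi = frac_extension_at(11.0, WLCParams(0.65))
        assert np.ptp(levels) == pytest.approx(9.5 * xi, rel=1e-9)
        assert len(truth.transition_times) > 20

    def test_dwell_means_match_rates(self):
        # 1/τ_F = 1/τ_U = 5/s over 200 s
        unfold, refold = kinetics_for_clamp(0.2, 0.2, clamp_force=10.0)
        dom = domain_from_delta_lc("sym", 10.0, unfold, refold)
        _, truth = simulate_force_clamp(dom, 10.0, 200.0, 1000.0, 0.0, seed=6)
        dwells = np.diff(truth.transition_times)
        assert dwells.mean() == pytest.approx(0.2, rel=0.1)

    def test_equal_lifetimes_give_half_occupancy(self):
        unfold, refold = kinetics_for_clamp(0.3, 0.3, clamp_force=11.0)
        dom = domain_from_delta_lc("sym", 10.0, unfold, refold)
        _, truth = simulate_force_clamp(dom, 11.0, 300.0, 500.0, 0.0, seed=7)
        frac_folded = np.mean(truth.state_path == 0)
        assert frac_folded == pytest.approx(0.5, abs=0.06)

    def test_negative_noise_rejected(self, wt_hopping_domain):
        with pytest.raises(InvalidInputError):
            simulate_force_clamp(wt_hopping_domain, 11.0, 10.0, 500.0, -1.0, 0)


class TestTitrationCounts:
    def test_apo_limit(self):
        counts = simulate_titration_counts(PAPER_BINDING_MODEL, [0.0], 500, 1)
        assert counts.counts[0, 0] == 500
        assert counts.counts[0, 1:].sum() == 0

    def test_saturation_limit(self):
        counts = simulate_titration_counts(PAPER_BINDING_MODEL, [1e6], 2000, 2)
        assert counts.counts[0, 3] / 2000 > 0.99

    def test_counts_match_partition_function(self):
        n = 100_000
        counts = simulate_titration_counts(PAPER_BINDING_MODEL, [10.0], n, 3)
        p = np.array(species_fractions(PAPER_BINDING_MODEL, 10.0))
        assert np.allclose(p, [0.230, 0.135, 0.230, 0.405], atol=1e-3)
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts.counts[0] - n * p) < 3 * se)

    def test_totals_conserved(self):
        counts = simulate_titration_counts(
            PAPER_BINDING_MODEL, np.geomspace(1, 150, 12), 100, 4
        )
        assert np.all(counts.totals == 100)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_titration_counts(PAPER_BINDING_MODEL, [-1.0], 10, 0)
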