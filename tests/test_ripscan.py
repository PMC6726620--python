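"""Rip detection, aggregation, and rupture-force histograms."""

import numpy as np
import pytest
from scipy import stats

from tweezfold.constructs import cnb_a, cnb_b, default_protocol, n3a_motif
from tweezfold.errors import (
    EmptyHistogramError,
    MissingGroupError,
    TooShortTraceError,
)
from tweezfold.forcekinetics import KineticParams, histogram_to_lifetimes
from tweezfold.ripscan import (
    DetectionConfig,
    RipEvent,
    aggregate,
    detect_rips,
    unfolding_histogram,
)
from tweezfold.simulate import (
    DomainSpec,
    sample_rupture_forces,
    simulate_force_ramp,
)
from tweezfold.forcekinetics import ROLE_REFOLD

from .conftest import analytic_density, bell_mean_rupture_force


def make_events(forces, delta_lc=30.0, loading_rate=1.0, direction="unfold"):
    return [
        RipEvent(
            cycle_id=i, direction=direction, rupture_force=float(f),
            delta_x=delta_lc * 0.6, delta_lc=delta_lc,
            loading_rate=loading_rate, time=float(i),
        )
        for i, f in enumerate(forces)
    ]


class TestDetectRips:
    def test_no_events_on_smooth_curve(self, protocol):
        dom = DomainSpec(
            "inert", 120,
            KineticParams(np.inf, 4.5),
            KineticParams(1e-3, 6.0, role=ROLE_REFOLD),
            d_nc=3.0,
        )
        traces, _ = simulate_force_ramp([dom], protocol, 2, seed=1, noise_sd=1.0)
        for tr in traces:
            assert detect_rips(tr) == []

    def test_single_rip_localized_and_measured(self, protocol):
        """One 30 nm domain, noiseless: one event, ΔLc within 1 nm, force
        within 0.2 pN of the generator's truth."""
        traces, truth = simulate_force_ramp(
            [cnb_a("camp")], protocol, 1, seed=3, noise_sd=0.0
        )
        events = [e for e in detect_rips(traces[0]) if e.direction == "unfold"]
        assert len(events) == 1
        true_ev = truth.events[0]
        assert events[0].rupture_force == pytest.approx(true_ev.force, abs=0.2)
        assert events[0].delta_lc == pytest.approx(30.0, abs=1.0)

    def test_recall_precision_on_large_rips(self, protocol):
        """>= 0.99 recall and precision for >= 10 nm rips at 1 nm noise."""
        traces, truth = simulate_force_ramp(
            [cnb_a("camp")], protocol, 150, seed=5, noise_sd=1.0
        )
        n_true = matched = n_det = 0
        for tr in traces:
            te = [e for e in truth.events_for_cycle(tr.cycle_id)
                  if e.direction == "unfold"]
            de = [e for e in detect_rips(tr)
                  if e.direction == "unfold" and e.delta_lc >= 10.0]
            n_true += len(te)
            n_det += len(de)
            for e in te:
                matched += any(abs(d.time - e.time) < 0.1 for d in de)
        assert matched / n_true >= 0.99
        assert matched / n_det >= 0.99

    def test_reversible_hopping_flagged_rip_not(self, protocol):
        """A trace with N3A hopping plus an irreversible rip: hopping events
        carry the reversible flag, the big rip does not."""
        domains = [n3a_motif(), cnb_a("camp")]
        traces, _ = simulate_force_ramp(domains, protocol, 30, seed=17,
                                        noise_sd=1.0)
        rev, big = [], []
        for tr in traces:
            for e in detect_rips(tr):
                if e.segment != "stretch":
                    continue
                if e.reversible:
                    rev.append(e)
                elif e.direction == "unfold" and e.delta_lc > 20:
                    big.append(e)
        assert len(rev) >= 5
        assert all(6.0 <= e.delta_lc <= 22.0 for e in rev)
        assert len(big) >= 25
        assert not any(e.reversible for e in big)

    def test_contour_conservation_against_truth(self, protocol):
        """Σ ΔLc of a cycle's unfold events ≈ the construct's unfolded
        contour (low noise, cycles where every domain unfolded once)."""
        domains = [cnb_a("camp"), cnb_b("camp")]
        total = sum(d.delta_lc for d in domains)
        traces, truth = simulate_force_ramp(domains, protocol, 25, seed=29,
                                            noise_sd=0.25)
        checked = 0
        for tr in traces:
            te = truth.events_for_cycle(tr.cycle_id)
            if sum(e.direction == "unfold" for e in te) != 2:
                continue
            de = [e for e in detect_rips(tr)
                  if e.direction == "unfold" and e.segment == "stretch"]
            if len(de) != 2:
                continue
            assert sum(e.delta_lc for e in de) == pytest.approx(total, rel=0.05)
            checked += 1
        assert checked >= 15

    def test_too_short_trace(self, protocol):
        from tweezfold.trace_io import ForceRampTrace

        tr = ForceRampTrace(
            np.arange(5) / 200.0, np.zeros(5), np.ones(5),
            np.zeros(5, np.int8),
        )
        with pytest.raises(TooShortTraceError):
            detect_rips(tr)


class TestAggregate:
    def test_single_event(self):
        stats_ = aggregate(make_events([10.0]), ["d1"])
        assert stats_[0].f_avg == 10.0
        assert stats_[0].f_sd == 0.0
        assert stats_[0].n == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        ev = make_events(rng.uniform(5, 15, 40))
        labels = ["a" if i % 2 else "b" for i in range(40)]
        s1 = aggregate(ev, labels)
        perm = rng.permutation(40)
        s2 = aggregate([ev[i] for i in perm], [labels[i] for i in perm])
        for a, b in zip(s1, s2):
            assert a.construct == b.construct and a.n == b.n
            assert a.f_avg == pytest.approx(b.f_avg, rel=1e-12)
            assert a.f_sd == pytest.approx(b.f_sd, rel=1e-12)

    def test_favg_matches_quadrature_oracle(self, apo_kinetics):
        fs = sample_rupture_forces(apo_kinetics, 1.0, 5000, seed=12)
        stats_ = aggregate(make_events(fs), lambda e: "dom")
        oracle = bell_mean_rupture_force(apo_kinetics, 1.0)
        se = fs.std(ddof=1) / np.sqrt(fs.size)
        assert abs(stats_[0].f_avg - oracle) < 2 * se

    def test_empty_raises(self):
        with pytest.raises(MissingGroupError):
            aggregate([], [])


class TestUnfoldingHistogram:
    def test_single_bin_normalization(self):
        hist = unfolding_histogram(make_events([10.1, 10.2, 10.3]), 1.0)
        occupied = hist.density > 0
        assert hist.density[occupied].sum() * hist.bin_width == pytest.approx(1.0)

    def test_bin_width_larger_than_range(self):
        hist = unfolding_histogram(make_events([8.0, 9.0, 10.0]), 20.0)
        assert (hist.density > 0).sum() == 1
        assert hist.density.sum() * hist.bin_width == pytest.approx(1.0)

    def test_chi2_against_analytic_density(self, apo_kinetics):
        fs = sample_rupture_forces(apo_kinetics, 1.0, 5000, seed=8)
        hist = unfolding_histogram(make_events(fs), 0.5)
        centers, obs = hist.bin_centers, hist.counts
        keep = obs >= 5
        expected = analytic_density(apo_kinetics, 1.0, centers[keep])
        expected = expected * hist.bin_width * fs.size
        expected *= obs[keep].sum() / expected.sum()
        chi2 = np.sum((obs[keep] - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=keep.sum() - 1) > 0.01

    def test_feeds_lifetime_transform(self, apo_kinetics):
        fs = sample_rupture_forces(apo_kinetics, 1.0, 20000, seed=4)
        hist = unfolding_histogram(make_events(fs), 0.25)
        curve = histogram_to_lifetimes(hist)
        assert np.all(curve.lifetimes > 0)

    def test_zero_events(self):
        with pytest.raises(EmptyHistogramError):
            unfolding_histogram([], 1.0)
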