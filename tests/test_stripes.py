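"""Stripe domains, boundary tracking, kinetics and aligned profiles."""

import numpy as np
import pandas as pd
import pytest

from stripedyn.stripes import (
    BoundaryTrack,
    StripeDomain,
    activation_kinetics,
    aligned_output_profile,
    assign_nuclei_to_stripes,
    boundary_track,
    define_mature_stripes,
    interstripe_distance,
    onset_delay,
    profile_boundaries_by_threshold,
    stripe2_expansion,
    summarize_window,
)
from stripedyn.traces import NormalizedTraces, SpatialProfile


def make_nt(el, dv, active, fluor=None):
    """NormalizedTraces with a given activity matrix (n_nuclei x n_t)."""
    el = np.asarray(el, dtype=float)
    dv = np.asarray(dv, dtype=float)
    active = np.asarray(active, dtype=bool)
    n, n_t = active.shape
    meta = pd.DataFrame({"nucleus_id": np.arange(n), "el_pct": el,
                         "dv_um": dv})
    if fluor is None:
        fluor = np.where(active, 10.0, 0.0)
    nt = NormalizedTraces(meta=meta, t_norm=np.linspace(0, 1, n_t),
                          fluor=fluor, nc14_duration_s=3000.0)
    nt.threshold = 1.0
    nt.active = active
    return nt


class TestDefineMatureStripes:
    def test_seven_well_separated_bands(self):
        el = np.concatenate([np.arange(5) + 10 * k for k in range(7)])
        active = np.ones((el.size, 3), dtype=bool)
        nt = make_nt(el, np.zeros(el.size), active)
        domains = define_mature_stripes(nt, gap_min_el=2.0)
        assert [d.stripe_id for d in domains] == list(range(1, 8))
        assert domains[0].mature_anterior == el.min()
        assert domains[-1].domain_end == 100.0
        # consecutive domains tile without overlap
        for a, b in zip(domains[:-1], domains[1:]):
            assert a.domain_end == b.domain_start

    def test_two_bands_only_last_runs_to_posterior_end(self):
        el = np.array([10.0, 11, 12, 40, 41, 42])
        nt = make_nt(el, np.zeros(6), np.ones((6, 2), dtype=bool))
        domains = define_mature_stripes(nt)
        assert len(domains) == 2
        assert domains[0].domain_end == 40.0
        assert domains[1].domain_end == 100.0

    def test_small_clusters_discarded(self):
        el = np.array([10.0, 11, 12, 50, 90, 91, 92.5])
        nt = make_nt(el, np.zeros(7), np.ones((7, 2), dtype=bool))
        domains = define_mature_stripes(nt, min_cluster=3)
        assert len(domains) == 2  # the singleton at 50 is dropped

    def test_no_active_nuclei_is_an_error(self):
        nt = make_nt([10.0, 20.0], [0, 0], np.zeros((2, 3), dtype=bool))
        with pytest.raises(ValueError, match="no mature stripes"):
            define_mature_stripes(nt)

    def test_matches_brute_force_gap_split(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            el = np.sort(rng.uniform(0, 100, n))
            active = np.ones((n, 2), dtype=bool)
            nt = make_nt(el, np.zeros(n), active)
            gap = float(rng.uniform(1, 10))
            # independent oracle: walk the sorted positions
            clusters, cur = [], [el[0]]
            for x in el[1:]:
                if x - cur[-1] > gap:
                    clusters.append(cur)
                    cur = [x]
                else:
                    cur.append(x)
            clusters.append(cur)
            clusters = [c for c in clusters if len(c) >= 3]
            if not clusters:
                with pytest.raises(ValueError):
                    define_mature_stripes(nt, gap_min_el=gap)
                continue
            domains = define_mature_stripes(nt, gap_min_el=gap)
            assert len(domains) == len(clusters)
            for d, c in zip(domains, clusters):
                assert d.mature_anterior == pytest.approx(c[0])
                assert d.mature_posterior == pytest.approx(c[-1])


class TestAssignNuclei:
    def _domains(self):
        return [
            StripeDomain(1, 30, 34, 30.0, 40.0),
            StripeDomain(2, 40, 44, 40.0, 100.0),
        ]

    def test_left_edge_belongs_to_domain(self):
        nt = make_nt([40.0], [0.0], np.ones((1, 2), dtype=bool))
        assign = assign_nuclei_to_stripes(self._domains(), nt)
        assert assign[0] == 2

    def test_anterior_of_first_stripe_unassigned(self):
        nt = make_nt([10.0], [0.0], np.ones((1, 2), dtype=bool))
        assert assign_nuclei_to_stripes(self._domains(), nt)[0] == 0

    def test_matches_interval_lookup_oracle(self, rng):
        domains = self._domains()
        el = rng.uniform(0, 100, 200)
        nt = make_nt(el, np.zeros(200), np.ones((200, 2), dtype=bool))
        assign = assign_nuclei_to_stripes(domains, nt)
        for x, a in zip(el, assign):
            if 30 <= x < 40:
                assert a == 1
            elif 40 <= x <= 100:
                assert a == 2
            else:
                assert a == 0


class TestBoundaryTrack:
    def test_rectangular_stripe(self):
        # 5 DV rows x positions 20..28, all active at all times
        el = np.tile(np.arange(20.0, 30.0, 2.0), 5)
        dv = np.repeat(np.arange(5.0), 5)
        active = np.ones((25, 4), dtype=bool)
        nt = make_nt(el, dv, active)
        dom = StripeDomain(1, 20, 28, 20.0, 100.0,
                           member_ids=np.arange(25))
        bt = boundary_track(nt, dom)
        assert np.allclose(bt.anterior, 20.0)
        assert np.allclose(bt.posterior, 28.0)
        assert np.allclose(bt.width_el, 8.0)
        assert np.allclose(bt.position, 24.0)

    def test_empty_sections_excluded_from_mean(self):
        # stripe active in 3 of 5 sections; mean over those 3 only
        el = np.tile(np.array([20.0, 30.0]), 5)
        dv = np.repeat(np.arange(5.0), 2)
        active = np.zeros((10, 2), dtype=bool)
        active[dv < 3] = True  # sections 0..2 active (rows with dv 0,1,2)
        nt = make_nt(el, dv, active)
        dom = StripeDomain(1, 20, 30, 20.0, 100.0, member_ids=np.arange(10))
        bt = boundary_track(nt, dom, dv_range=(-0.5, 4.5))
        assert np.allclose(bt.anterior, 20.0)
        assert np.allclose(bt.posterior, 30.0)

    def test_all_empty_time_is_nan(self):
        el = np.array([20.0, 25.0])
        active = np.array([[True, False], [True, False]])
        nt = make_nt(el, np.zeros(2), active)
        dom = StripeDomain(1, 20, 25, 20.0, 100.0, member_ids=np.arange(2))
        bt = boundary_track(nt, dom)
        assert np.isnan(bt.anterior[1]) and np.isnan(bt.width_el[1])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            n_t = int(rng.integers(2, 6))
            el = rng.uniform(0, 100, n)
            dv = rng.uniform(-50, 50, n)
            active = rng.random((n, n_t)) < 0.5
            nt = make_nt(el, dv, active)
            dom = StripeDomain(1, 0, 100, 0.0, 100.0,
                               member_ids=np.arange(n))
            n_sec = 5
            bt = boundary_track(nt, dom, n_sections=n_sec)
            edges = np.linspace(dv.min(), dv.max(), n_sec + 1)
            for j in range(n_t):
                ants, posts = [], []
                for s in range(n_sec):
                    lo, hi = edges[s], edges[s + 1]
                    rows = [i for i in range(n)
                            if (dv[i] >= lo and (dv[i] < hi or s == n_sec - 1)
                                and dv[i] <= hi and active[i, j])]
                    if rows:
                        ants.append(min(el[i] for i in rows))
                        posts.append(max(el[i] for i in rows))
                if ants:
                    assert bt.anterior[j] == pytest.approx(np.mean(ants))
                    assert bt.posterior[j] == pytest.approx(np.mean(posts))
                else:
                    assert np.isnan(bt.anterior[j])


class TestSummaries:
    def _track(self, width_fn, n_t=101):
        t = np.linspace(0, 1, n_t)
        ant = np.zeros(n_t)
        post = width_fn(t)
        return BoundaryTrack(1, t, np.tile(ant, (5, 1)), np.tile(post, (5, 1)),
                             ant, post)

    def test_constant_width_summary(self):
        bt = self._track(lambda t: np.full_like(t, 6.0))
        pos, wid = summarize_window(bt)
        assert wid == pytest.approx(6.0)
        assert pos == pytest.approx(3.0)

    def test_linear_ramp_means_midpoint(self):
        bt = self._track(lambda t: t)
        _, wid = summarize_window(bt, (0.80, 0.90))
        assert wid == pytest.approx(0.85, abs=1e-3)

    def test_matches_brute_force_mean(self, rng):
        t = np.linspace(0, 1, 100)
        post = rng.random(100) * 10
        bt = BoundaryTrack(1, t, np.zeros((5, 100)), np.tile(post, (5, 1)),
                           np.zeros(100), post)
        pos, wid = summarize_window(bt, (0.80, 0.90))
        sel = (t >= 0.80) & (t <= 0.90)
        assert wid == pytest.approx(post[sel].mean())
        assert pos == pytest.approx((post[sel] / 2).mean())

    def test_identical_cohorts_have_zero_expansion(self):
        bt = self._track(lambda t: np.full_like(t, 4.0))
        assert stripe2_expansion([bt], [bt]) == pytest.approx(0.0)

    def test_constant_offset_recovered(self):
        wt = self._track(lambda t: np.full_like(t, 4.0))
        het = self._track(lambda t: np.full_like(t, 5.5))
        assert stripe2_expansion([wt], [het],
                                 nuclei_per_el=2.0) == pytest.approx(3.0)


class TestKinetics:
    def test_all_active_from_start(self):
        nt = make_nt([10.0, 11, 12], np.zeros(3), np.ones((3, 10), dtype=bool))
        dom = StripeDomain(1, 10, 12, 10.0, 100.0, member_ids=np.arange(3))
        kc = activation_kinetics(nt, dom)
        assert kc.onset_time == 0.0
        assert np.allclose(kc.frac_active, 1.0)

    def test_step_activation_onset(self):
        n_t = 101
        active = np.zeros((4, n_t), dtype=bool)
        active[:, 50:] = True  # step at t = 0.5
        nt = make_nt([10.0, 11, 12, 13], np.zeros(4), active)
        dom = StripeDomain(1, 10, 13, 10.0, 100.0, member_ids=np.arange(4))
        kc = activation_kinetics(nt, dom)
        assert kc.onset_time == pytest.approx(0.5)

    def test_never_crossing_gives_nan_delay(self):
        nt = make_nt([10.0, 11, 12], np.zeros(3),
                     np.zeros((3, 10), dtype=bool))
        dom = StripeDomain(1, 10, 12, 10.0, 100.0, member_ids=np.arange(3))
        kc = activation_kinetics(nt, dom)
        assert np.isnan(kc.onset_time)
        assert np.isnan(onset_delay(kc, kc, 3000.0))

    def test_delay_in_minutes(self):
        n_t = 101
        a = np.zeros((3, n_t), dtype=bool)
        a[:, 25:] = True
        b = np.zeros((3, n_t), dtype=bool)
        b[:, 37:] = True  # 0.12 of NC14 later
        nt_a = make_nt([1.0, 2, 3], np.zeros(3), a)
        nt_b = make_nt([1.0, 2, 3], np.zeros(3), b)
        dom = StripeDomain(1, 1, 3, 1.0, 100.0, member_ids=np.arange(3))
        ka = activation_kinetics(nt_a, dom)
        kb = activation_kinetics(nt_b, dom)
        assert onset_delay(ka, kb, 3000.0) == pytest.approx(6.0)


class TestInterstripeDistance:
    def test_constant_center_separation(self):
        t = np.linspace(0, 1, 10)
        mk = lambda c: BoundaryTrack(1, t, np.zeros((5, 10)),
                                     np.zeros((5, 10)),
                                     np.full(10, c - 2.0), np.full(10, c + 2.0))
        d = interstripe_distance(mk(30.0), mk(50.0))
        assert np.allclose(d, 20.0)
        assert np.allclose(interstripe_distance(mk(30.0), mk(30.0)), 0.0)


class TestAlignedOutputProfile:
    def test_uniform_output_every_kept_bin_equal(self):
        el = np.linspace(40, 44, 50)
        out = np.full(50, 3.3)
        centers, mean, count = aligned_output_profile([(el, out)], min_n=10)
        assert len(centers) > 0
        assert np.allclose(mean, 3.3)

    def test_bins_under_min_n_excluded(self):
        el = np.concatenate([np.full(9, 40.2), np.full(12, 41.5)])
        out = np.ones(21)
        centers, mean, count = aligned_output_profile([(el, out)], min_n=10)
        # the 9-nucleus bin is dropped, the 12-nucleus bin kept
        assert len(centers) == 1
        assert count[0] == 12

    def test_alignment_to_anteriormost_nucleus(self):
        # two embryos with offset stripes but identical internal gradients
        el1 = np.linspace(40, 44, 30)
        el2 = np.linspace(47, 51, 30)
        slope = 2.0
        out1 = slope * (el1 - el1.min())
        out2 = slope * (el2 - el2.min())
        centers, mean, _ = aligned_output_profile([(el1, out1), (el2, out2)],
                                                  min_n=5)
        fit = np.polyfit(centers, mean, 1)
        assert fit[0] == pytest.approx(slope, rel=0.10)

    def test_empty_stripe_rejected(self):
        with pytest.raises(ValueError):
            aligned_output_profile([(np.array([]), np.array([]))])


class TestProfileBoundaries:
    def _profile(self, mean):
        edges = np.linspace(0, 100, 51)
        return SpatialProfile(edges, np.asarray(mean, dtype=float),
                              np.ones(50, dtype=int))

    def test_boxcar(self):
        mean = np.zeros(50)
        mean[30:41] = 5.0  # bins covering 60..82 %EL
        ant, post = profile_boundaries_by_threshold(self._profile(mean), 1.0)
        assert ant == 60.0 and post == 82.0

    def test_all_zero_is_undefined(self):
        ant, post = profile_boundaries_by_threshold(self._profile(np.zeros(50)),
                                                    1.0)
        assert np.isnan(ant) and np.isnan(post)

    def test_matches_scan_oracle(self, rng):
        for _ in range(100):
            mean = rng.random(50) * 10
            thr = float(rng.uniform(0, 10))
            ant, post = profile_boundaries_by_threshold(self._profile(mean),
                                                        thr)
            above = [i for i in range(50) if mean[i] > thr]
            if not above:
                assert np.isnan(ant)
            else:
                assert ant == above[0] * 2.0
                assert post == (above[-1] + 1) * 2.0
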