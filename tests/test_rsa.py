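"""Growth-engine tests, anchored by an independent enumeration oracle for
the fully deterministic (zero-variance, zero-tropism-noise) limit."""

import math
from collections import defaultdict

import numpy as np
import pytest

from splitroot import (ConfigurationError, GrowthParams, RootSystem,
                       activation_time, branch_sites, insert_branches,
                       run_ensemble, simulate, simulate_ensemble)


def enumerate_deterministic_lengths(params_by_order, duration):
    """Independent oracle: recursively enumerate every root and site under
    the deterministic growth rules and accumulate length per order."""
    lengths = defaultdict(float)
    counts = defaultdict(int)

    def visit(bn, t_birth):
        if t_birth > duration + 1e-12:
            return
        p = params_by_order[bn]
        lengths[bn] += min(p.r_mean * (duration - t_birth), p.lmax_mean)
        counts[bn] += 1
        if p.max_order > bn and (bn + 1) in params_by_order:
            zone = p.lmax_mean - p.la - p.lb
            if zone <= 0:
                return
            site = p.la
            while site + p.lb <= p.lmax_mean + 1e-12:
                visit(bn + 1, t_birth + (site + p.lb) / p.r_mean)
                site += p.ln_mean

    for _ in range(params_by_order[0].maxB):
        visit(0, 0.0)
    return dict(lengths), dict(counts)


class TestBranchSites:
    def test_enumeration_example(self):
        # length-10 parent, 1-cm zones, 2-cm interval: sites 1,3,5,7,9
        sites = branch_sites(lmax=10, la=1, lb=1, ln=2)
        assert list(sites) == [1, 3, 5, 7, 9]
        # the last site activates exactly at full length
        assert activation_time(9, lb=1, r=1.0, lmax=10) == pytest.approx(10)

    def test_no_branched_zone_means_no_sites(self):
        assert len(branch_sites(lmax=2.0, la=1.0, lb=1.0, ln=0.5)) == 0
        assert len(branch_sites(lmax=2.0, la=1.5, lb=1.0, ln=0.5)) == 0

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            branch_sites(lmax=10, la=1, lb=1, ln=0)

    def test_exponential_law_site_at_lmax_never_activates(self):
        assert activation_time(9, lb=1, r=1.0, lmax=10,
                               growth_law="exponential") == math.inf
        t = activation_time(4, lb=1, r=1.0, lmax=10,
                            growth_law="exponential")
        # length(t) = 10(1 - exp(-t/10)) must equal 5 at activation
        assert 10 * -math.expm1(-t / 10) == pytest.approx(5.0)


class TestInsertBranches:
    def test_full_grown_parent_emits_five_laterals(self, det_params, rng):
        system = simulate(det_params, 20.0, seed=0)
        parent = system.axes[0]
        laterals = insert_branches(parent, det_params, rng, length=10.0)
        assert len(laterals) == 5
        assert [round(a.insertion_arclength, 6) for a in laterals] == \
            [1, 3, 5, 7, 9]
        assert all(a.branching_number == 1 for a in laterals)

    def test_partial_parent_activates_only_passed_sites(self, det_params,
                                                        rng):
        system = simulate(det_params, 20.0, seed=0)
        parent = system.axes[0]
        # at length 5.5 the passed thresholds are 2 and 4 (sites 1 and 3)
        laterals = insert_branches(parent, det_params, rng, length=5.5)
        assert [a.insertion_arclength for a in laterals] == [1.0, 3.0]

    def test_short_parent_has_no_laterals(self, det_params, rng):
        system = simulate(det_params, 20.0, seed=0)
        laterals = insert_branches(system.axes[0], det_params, rng,
                                   length=0.5)  # still inside la
        assert laterals == []


class TestDeterministicLimit:
    def test_single_primary_length_is_capped_rate_times_time(self):
        p = {0: GrowthParams(branching_number=0, maxB=1, r_mean=1.0,
                             lmax_mean=10.0, theta_mean=0.0)}
        assert simulate(p, 5.0, seed=0).total_length() == pytest.approx(5.0)
        assert simulate(p, 20.0, seed=0).total_length() == pytest.approx(10.0)

    def test_primaries_only_total_length(self):
        p = {0: GrowthParams(branching_number=0, maxB=5, r_mean=1.0,
                             lmax_mean=100.0, theta_mean=0.0)}
        assert simulate(p, 10.0, seed=3).total_length() == pytest.approx(50.0)

    def test_total_length_matches_enumeration_oracle(self, det_params):
        system = simulate(det_params, 12.0, seed=0)
        expect_len, expect_n = enumerate_deterministic_lengths(det_params,
                                                               12.0)
        counts = system.counts_by_order()
        for bn in expect_len:
            assert counts[bn] == expect_n[bn]
            assert system.total_length(bn) == pytest.approx(
                expect_len[bn], rel=1e-6)

    def test_three_order_cascade_matches_oracle(self):
        params = {
            0: GrowthParams(branching_number=0, maxB=2, r_mean=1.3,
                            lmax_mean=9.0, la=0.7, lb=0.6, ln_mean=1.1,
                            theta_mean=0.0, max_order=2),
            1: GrowthParams(branching_number=1, r_mean=0.45, lmax_mean=2.0,
                            la=0.3, lb=0.25, ln_mean=0.7, theta_mean=50.0,
                            max_order=2),
            2: GrowthParams(branching_number=2, r_mean=0.2, lmax_mean=0.8,
                            theta_mean=60.0, max_order=2),
        }
        duration = 11.3
        system = simulate(params, duration, seed=5)
        expect_len, expect_n = enumerate_deterministic_lengths(params,
                                                               duration)
        counts = system.counts_by_order()
        for bn in sorted(expect_len):
            assert counts[bn] == expect_n[bn], f"count mismatch at bn {bn}"
            assert system.total_length(bn) == pytest.approx(
                expect_len[bn], rel=1e-6), f"length mismatch at bn {bn}"


class TestGrow:
    def test_zero_dt_leaves_system_unchanged(self, noisy_params):
        system = simulate(noisy_params, 6.0, seed=9)
        before = [(a.axis_id, a.length, a.polyline.copy())
                  for a in system.axes]
        system.grow(0.0)
        assert len(system.axes) == len(before)
        for (aid, length, poly), a in zip(before, system.axes):
            assert a.axis_id == aid
            assert a.length == length
            np.testing.assert_array_equal(a.polyline, poly)

    def test_negative_dt_rejected(self, noisy_params):
        with pytest.raises(ValueError):
            simulate(noisy_params, 1.0, seed=0).grow(-1.0)

    def test_incremental_growth_equals_single_call(self, noisy_params):
        a = simulate(noisy_params, 8.0, seed=21)
        b = RootSystem(noisy_params, seed=21)
        for _ in range(80):
            b.grow(0.1)
        assert len(a.axes) == len(b.axes)
        assert a.total_length() == pytest.approx(b.total_length(), rel=1e-9)

    def test_unknown_branching_number_is_configuration_error(self):
        p = {0: GrowthParams(branching_number=0, maxB=1, r_mean=1.0,
                             lmax_mean=10.0, la=1, lb=1, ln_mean=2,
                             max_order=1)}  # no order-1 params, but needed
        with pytest.raises(ConfigurationError):
            simulate(p, 20.0, seed=0)

    def test_lengths_monotone_in_time_and_capped(self, noisy_params):
        system = RootSystem(noisy_params, seed=2)
        prev = {}
        for _ in range(12):
            system.grow(1.0)
            for a in system.axes:
                assert a.length <= a.lmax + 1e-12
                if a.axis_id in prev:
                    assert a.length >= prev[a.axis_id] - 1e-12
                prev[a.axis_id] = a.length


class TestGeometry:
    def test_arc_length_matches_reported_length(self, noisy_params):
        system = simulate(noisy_params, 10.0, seed=4)
        for a in system.axes:
            arc = np.linalg.norm(np.diff(a.polyline, axis=0), axis=1).sum()
            assert arc == pytest.approx(a.length, rel=1e-6, abs=1e-9)

    def test_every_point_inside_box_and_compartment(self, noisy_params):
        for side in (1, -1):
            system = simulate(noisy_params, 10.0, seed=8, side=side)
            bx, by, bz = system.box_dims
            for a in system.axes:
                pts = a.polyline
                if side > 0:
                    assert pts[:, 0].min() >= -1e-9  # barrier plane
                else:
                    assert pts[:, 0].max() <= 1e-9
                assert np.abs(pts[:, 0]).max() <= bx / 2 + 1e-9
                assert np.abs(pts[:, 1]).max() <= by / 2 + 1e-9
                assert pts[:, 2].min() >= -1e-9
                assert pts[:, 2].max() <= bz + 1e-9

    def test_deep_system_reflects_at_bottom_conserving_arc_length(self):
        p = {0: GrowthParams(branching_number=0, maxB=1, r_mean=10.0,
                             lmax_mean=150.0, theta_mean=0.0)}
        system = simulate(p, 15.0, seed=0)
        a = system.axes[0]
        assert a.polyline[:, 2].max() <= system.box_dims[2] + 1e-9
        arc = np.linalg.norm(np.diff(a.polyline, axis=0), axis=1).sum()
        assert arc == pytest.approx(150.0, rel=1e-6)

    def test_every_axis_is_single_tipped_forest(self, noisy_params):
        system = simulate(noisy_params, 10.0, seed=6)
        ids = {a.axis_id for a in system.axes}
        for a in system.axes:
            if a.branching_number == 0:
                assert a.parent_id is None
            else:
                assert a.parent_id in ids
                parent = system.axes[a.parent_id]
                assert a.branching_number == parent.branching_number + 1
                assert a.insertion_arclength <= parent.length + 1e-9


class TestEnsemble:
    def test_same_seed_reproduces_identically(self, noisy_params):
        a = simulate_ensemble(noisy_params, 8.0, 5, seed=77)
        b = simulate_ensemble(noisy_params, 8.0, 5, seed=77)
        assert a.equals(b)

    def test_degenerate_single_replicate_matches_closed_form(self,
                                                             det_params):
        out = simulate_ensemble(det_params, 12.0, 1, seed=0)
        expect_len, _ = enumerate_deterministic_lengths(det_params, 12.0)
        for bn, length in expect_len.items():
            assert out.loc[bn, "mean_length_cm"] == pytest.approx(length)
            assert out.loc[bn, "sd_length_cm"] == 0.0

    def test_mean_primary_length_under_heading_noise(self):
        # arc length is preserved under tropism perturbation, so the mean
        # primary length before reaching lmax is exactly r*t
        p = {0: GrowthParams(branching_number=0, maxB=1, r_mean=1.0,
                             lmax_mean=50.0, theta_mean=20.0, theta_sd=5.0,
                             tropism_sigma=12.0)}
        out = simulate_ensemble(p, 10.0, 50, seed=13)
        assert out.loc[0, "mean_length_cm"] == pytest.approx(10.0, abs=1e-9)

    def test_zero_replicates_rejected(self, det_params):
        with pytest.raises(ValueError):
            simulate_ensemble(det_params, 5.0, 0, seed=0)
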