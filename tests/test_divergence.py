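import numpy as np
import pytest

from divscan import (
    SimulationConfig,
    bootstrap_ci,
    combine_group,
    expected_theta,
    mean_dxy,
    multilocus_theta,
    simulate_pair,
    site_components,
    site_dxy,
)
from divscan.divergence import SiteComponents, SiteDxy

from conftest import build_matrix, random_instance
from _oracles import dxy_oracle, wc_components_oracle


def components_from_pops(popA, popB):
    """Helper: run site_components on a single-site matrix."""
    G = build_matrix([list(popA) + list(popB)])
    a_ids = G.samples[: len(popA)]
    b_ids = G.samples[len(popA):]
    return site_components(G, a_ids, b_ids), site_dxy(G, a_ids, b_ids)


class TestBoundaryIdentities:
    def test_fixed_difference_theta_and_dxy_one(self):
        comp, dxy = components_from_pops([(0, 0), (0, 0)], [(1, 1), (1, 1)])
        assert comp.theta_per_site()[0] == pytest.approx(1.0, abs=0)
        assert dxy.dxy[0] == 1.0

    def test_shared_monomorphism_all_zero(self):
        comp, dxy = components_from_pops([(0, 0), (0, 0)], [(0, 0), (0, 0)])
        assert comp.a[0] == 0 and comp.b[0] == 0 and comp.c[0] == 0
        assert dxy.dxy[0] == 0.0

    def test_half_half_dxy(self):
        # x = y = (0.5, 0.5)
        comp, dxy = components_from_pops([(0, 0), (1, 1)], [(0, 1), (0, 1)])
        assert dxy.dxy[0] == pytest.approx(0.5, abs=0)

    def test_spec_worked_example(self):
        # popA {AA, Aa}, popB {aa, aa}: frozen oracle values
        comp, dxy = components_from_pops([(0, 0), (0, 1)], [(1, 1), (1, 1)])
        assert comp.a[0] == pytest.approx(0.5, rel=1e-12)
        assert comp.b[0] == pytest.approx(0.0, abs=1e-12)
        assert comp.c[0] == pytest.approx(0.25, rel=1e-12)
        assert comp.theta_per_site()[0] == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert dxy.dxy[0] == pytest.approx(0.75, rel=1e-12)

    def test_overlapping_pops_error(self):
        G = build_matrix([[(0, 0), (1, 1)]])
        with pytest.raises(ValueError):
            site_components(G, ["s0"], ["s0", "s1"])
        with pytest.raises(ValueError):
            site_dxy(G, ["s0"], ["s0", "s1"])

    def test_all_missing_population_undefined(self):
        comp, dxy = components_from_pops([(0, 0), (0, 1)], [None, None])
        assert not comp.defined[0]
        assert np.isnan(comp.a[0])
        assert not dxy.defined[0]


class TestOracleEquivalence:
    def test_random_small_instances(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(400):
            popA, popB, k = random_instance(rng)
            expected = wc_components_oracle([popA, popB])
            comp, dxy = components_from_pops(popA, popB)
            if expected is None:
                assert not comp.defined[0]
                continue
            checked += 1
            ea, eb, ec = expected
            assert comp.a[0] == pytest.approx(ea, rel=1e-12, abs=1e-12)
            assert comp.b[0] == pytest.approx(eb, rel=1e-12, abs=1e-12)
            assert comp.c[0] == pytest.approx(ec, rel=1e-12, abs=1e-12)
            ed = dxy_oracle(popA, popB)
            assert dxy.dxy[0] == pytest.approx(ed, rel=1e-12, abs=1e-12)
        assert checked > 200

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            popA, popB, _ = random_instance(rng)
            c1, d1 = components_from_pops(popA, popB)
            c2, d2 = components_from_pops(popB, popA)
            if not c1.defined[0]:
                assert not c2.defined[0]
                continue
            assert c1.a[0] == pytest.approx(c2.a[0], rel=1e-12, abs=1e-12)
            assert c1.den[0] == pytest.approx(c2.den[0], rel=1e-12, abs=1e-12)
            if d1.defined[0]:
                assert d1.dxy[0] == pytest.approx(d2.dxy[0], rel=1e-12, abs=1e-12)


def make_components(a, den, positions=None):
    a = np.asarray(a, dtype=float)
    den = np.asarray(den, dtype=float)
    n = len(a)
    if positions is None:
        positions = np.arange(1, n + 1) * 100
    return SiteComponents(
        contig="c",
        positions=np.asarray(positions, dtype=np.int64),
        a=a,
        b=den - a,
        c=np.zeros(n),
        defined=np.ones(n, dtype=bool),
        n_genotyped_a=np.full(n, 4),
        n_genotyped_b=np.full(n, 4),
    )


class TestCombiningRules:
    def test_ratio_of_sums_not_mean_of_ratios(self):
        # (a=1, den=2), (a=1, den=4): ratio-of-sums 2/6, mean-of-ratios 0.375
        comp = make_components([1.0, 1.0], [2.0, 4.0])
        est = multilocus_theta(comp)
        assert est.theta == pytest.approx(2.0 / 6.0, rel=1e-12)
        assert est.theta != pytest.approx(0.375, rel=1e-6)

    def test_monomorphic_sites_leave_theta_unchanged_but_count(self):
        one = make_components([0.5], [0.5])
        many = make_components([0.5] + [0.0] * 99, [0.5] + [0.0] * 99)
        e1, e2 = multilocus_theta(one), multilocus_theta(many)
        assert e1.theta == e2.theta == 1.0
        assert e2.n_positions == 100

    def test_zero_denominator_flagged(self):
        comp = make_components([0.0, 0.0], [0.0, 0.0])
        est = multilocus_theta(comp)
        assert np.isnan(est.theta) and not est.theta_defined
        assert est.n_positions == 2

    def test_mean_dxy(self):
        d = SiteDxy(
            "c",
            np.arange(1, 11) * 10,
            np.array([1.0] + [0.0] * 9),
            np.ones(10, dtype=bool),
        )
        assert mean_dxy(d) == pytest.approx(0.1)
        d.dxy[:] = 0.0
        assert mean_dxy(d) == 0.0

    def test_mean_dxy_decreases_with_monomorphic_sites_theta_invariant(self):
        comp = make_components([0.5], [0.5])
        comp_pad = make_components([0.5, 0.0], [0.5, 0.0])
        assert multilocus_theta(comp).theta == multilocus_theta(comp_pad).theta
        d1 = SiteDxy("c", np.array([10]), np.array([1.0]), np.array([True]))
        d2 = SiteDxy("c", np.array([10, 20]), np.array([1.0, 0.0]), np.array([True, True]))
        assert mean_dxy(d2) < mean_dxy(d1)

    def test_combine_group_single_is_identity(self):
        comp = make_components([1.0, 0.2], [2.0, 0.4])
        assert combine_group([comp]).theta == multilocus_theta(comp).theta

    def test_combine_group_homogeneous(self):
        comp = make_components([1.0, 0.2], [2.0, 0.4])
        assert combine_group([comp, comp]).theta == pytest.approx(
            multilocus_theta(comp).theta, rel=1e-12
        )

    def test_combine_group_equals_pooled_ratio_of_sums(self, rng):
        comps = []
        total_num = total_den = 0.0
        for _ in range(9):
            a = rng.uniform(-0.1, 1.0, 30)
            den = a + rng.uniform(0.0, 1.0, 30)
            comps.append(make_components(a, den))
            total_num += a.sum()
            total_den += den.sum()
        est = combine_group(comps)
        assert est.theta == pytest.approx(total_num / total_den, rel=1e-12)
        assert est.n_positions == 9 * 30

    def test_combine_group_dxy_is_mean_of_means(self):
        d1 = SiteDxy("c", np.array([10, 20]), np.array([0.2, 0.4]), np.ones(2, bool))
        d2 = SiteDxy("c", np.array([10]), np.array([0.9]), np.ones(1, bool))
        comp = make_components([0.1], [0.2])
        est = combine_group([comp, comp], [d1, d2])
        assert est.dxy_mean == pytest.approx((0.3 + 0.9) / 2)


class TestBootstrap:
    def test_degenerate_collapses_to_point(self):
        comp = make_components([0.25] * 20, [0.5] * 20)
        ci = bootstrap_ci(comp, "theta", n_reps=100, seed=1)
        assert ci.lower == ci.upper == pytest.approx(0.5)

    def test_same_seed_same_ci(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 100)
        comp = make_components(a, a + rng.uniform(0, 1, 100))
        c1 = bootstrap_ci(comp, "theta", n_reps=200, seed=42)
        c2 = bootstrap_ci(comp, "theta", n_reps=200, seed=42)
        assert (c1.lower, c1.upper) == (c2.lower, c2.upper)
        c3 = bootstrap_ci(comp, "theta", n_reps=200, seed=43)
        assert (c1.lower, c1.upper) != (c3.lower, c3.upper)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, 500)
        comp = make_components(a, a + rng.uniform(0, 1, 500))
        est = multilocus_theta(comp)
        ci = bootstrap_ci(comp, "theta", n_reps=500, seed=2)
        assert ci.lower <= est.theta <= ci.upper
        assert ci.lower < ci.upper

    def test_dxy_bootstrap(self):
        d = SiteDxy("c", np.arange(1, 101) * 10,
                    np.linspace(0, 1, 100), np.ones(100, dtype=bool))
        comp = make_components(np.zeros(100), np.ones(100))
        ci = bootstrap_ci(comp, "dxy", dxy=d, n_reps=300, seed=3)
        assert ci.lower < 0.5 < ci.upper

    def test_too_few_sites_errors(self):
        comp = make_components([0.1], [0.2])
        with pytest.raises(ValueError):
            bootstrap_ci(comp, "theta", n_reps=10, seed=0)


class TestEstimatorRecovery:
    def test_theta_recovers_F(self):
        # single moderate check here; the full F-grid sweep lives in the
        # acceptance suite
        cfg = SimulationConfig(
            n_per_pop=20, n_sites=5000, contig_length=100_000,
            F_bg=0.2, F_pk=0.2, seed=11,
        )
        G, _ = simulate_pair(cfg)
        comp = site_components(G, G.samples[:20], G.samples[20:])
        assert multilocus_theta(comp).theta == pytest.approx(0.2, abs=0.02)

    def test_theta_near_zero_at_tiny_F(self):
        cfg = SimulationConfig(
            n_per_pop=20, n_sites=5000, contig_length=100_000,
            F_bg=1e-6, F_pk=1e-6, seed=12,
        )
        G, _ = simulate_pair(cfg)
        comp = site_components(G, G.samples[:20], G.samples[20:])
        assert abs(multilocus_theta(comp).theta) < 0.01

    def test_mean_dxy_matches_truth_frequencies(self):
        cfg = SimulationConfig(
            n_per_pop=30, n_sites=3000, contig_length=50_000,
            F_bg=0.2, F_pk=0.2, seed=13,
        )
        G, truth = simulate_pair(cfg)
        dxy = site_dxy(G, G.samples[:30], G.samples[30:])
        got = mean_dxy(dxy)
        # expectation from the generating frequencies: E[1 - xy - (1-x)(1-y)]
        exp = np.mean(1 - truth.p_popA * truth.p_popB
                      - (1 - truth.p_popA) * (1 - truth.p_popB))
        assert got == pytest.approx(exp, abs=0.01)
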