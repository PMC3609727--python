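import math

import numpy as np
import pytest

import radrate as rr
from radrate.chronology import ConvergenceError, _PLProblem, pl_objective

# ---------------------------------------------------------------------
# pl_objective


def ages_of(tree):
    return {id(n): n.age for n in tree.preorder()}


class TestObjective:
    def test_one_branch_closed_form(self):
        # x = b*L = 1, r = 1, tau = 1: psi = 1*ln(1) - 1 = -1, no rate pairs
        tree = rr.Phylogram.from_newick("(A:0.001);")
        cfg = rr.PLConfig(seq_length=1000, smoothing=7.3)
        root, (tip,) = tree.root, tree.tips()
        ages = {id(root): 1.0, id(tip): 0.0}
        rates = {id(tip): 1.0}
        assert pl_objective(tree, ages, rates, cfg) == pytest.approx(-1.0)

    def test_equal_rates_zero_penalty(self):
        tree = rr.Phylogram.from_newick("((A:0.1,B:0.2):0.3,C:0.15);")
        cfg = rr.PLConfig(seq_length=100, smoothing=50.0)
        nodes = list(tree.preorder())
        root = nodes[0]
        internal = [n for n in nodes if n.parent is not None and not n.is_leaf][0]
        ages = {id(root): 10.0, id(internal): 4.0}
        for tip in tree.tips():
            ages[id(tip)] = 0.0
        r = 2.5
        rates = {id(n): r for n in nodes if n.parent is not None}
        expected = 0.0
        for n in nodes:
            if n.parent is None:
                continue
            tau = ages[id(n.parent)] - ages[id(n)]
            x = n.length * cfg.seq_length
            expected += x * math.log(r * tau) - r * tau
        assert pl_objective(tree, ages, rates, cfg) == pytest.approx(expected)

    def test_lambda_zero_termwise_oracle(self):
        # psi(lambda=0) equals the Poisson log-likelihood recomputed term by term
        rng = np.random.default_rng(4)
        tree = rr.Phylogram.from_newick(
            "(((A:0.02,B:0.05):0.01,C:0.07):0.03,(D:0.04,E:0.06):0.02);"
        )
        cfg = rr.PLConfig(seq_length=500, smoothing=0.0)
        nodes = list(tree.preorder())
        for trial in range(10):
            ages = {id(nodes[0]): 10.0}
            for n in nodes[1:]:
                if n.is_leaf:
                    ages[id(n)] = 0.0
            # feasible internal ages: fractions of the parent age
            for n in nodes[1:]:
                if not n.is_leaf:
                    ages[id(n)] = ages[id(n.parent)] * rng.uniform(0.2, 0.8)
            rates = {id(n): rng.uniform(0.5, 50) for n in nodes if n.parent is not None}
            oracle = sum(
                (n.length * cfg.seq_length) * math.log(rates[id(n)] * (ages[id(n.parent)] - ages[id(n)]))
                - rates[id(n)] * (ages[id(n.parent)] - ages[id(n)])
                for n in nodes
                if n.parent is not None
            )
            assert pl_objective(tree, ages, rates, cfg) == pytest.approx(oracle)

    def test_nonpositive_duration_rejected(self):
        tree = rr.Phylogram.from_newick("(A:0.1,B:0.1);")
        cfg = rr.PLConfig(seq_length=100)
        root = tree.root
        a, b = tree.tips()
        with pytest.raises(ValueError, match="duration"):
            pl_objective(
                tree, {id(root): 1.0, id(a): 2.0, id(b): 0.0},
                {id(a): 1.0, id(b): 1.0}, cfg,
            )
        with pytest.raises(ValueError, match="rate"):
            pl_objective(
                tree, {id(root): 1.0, id(a): 0.0, id(b): 0.0},
                {id(a): -1.0, id(b): 1.0}, cfg,
            )


# ---------------------------------------------------------------------
# estimation


def edge_nodes(tree):
    return [n for n in tree.preorder() if n.parent is not None]


class TestEstimation:
    def test_clock_tree_exact_recovery(self, clock_tree_4tip):
        # strict clock is the exact optimum: proportional ages, equal rates
        cfg = rr.PLConfig(seq_length=1000, smoothing=1.0, n_restarts=3, seed=0)
        est = rr.estimate_chronogram(
            clock_tree_4tip, rr.CalibrationSpec(25.0, 25.0, 25.0), cfg
        )
        by_tips = {
            frozenset(["A", "B"]): 12.5,   # depth 1.0 of 2.0
            frozenset(["C", "D"]): 18.75,  # depth 1.5 of 2.0
        }
        for node in est.preorder():
            if node.parent is None or node.is_leaf:
                continue
            tips = frozenset(
                t.label for t in est.tips() if _is_descendant(t, node)
            )
            assert node.age == pytest.approx(by_tips[tips], rel=1e-6)
        for node in edge_nodes(est):
            assert node.rate == pytest.approx(2.0 / 25.0, rel=1e-6)

    def test_lambda_zero_profile_optimum(self, three_taxon_tree):
        # with no penalty each branch can hit its Poisson maximum mu_j = x_j;
        # the age itself is unidentifiable, so check objective and fitted counts
        L = 1000
        cfg = rr.PLConfig(seq_length=L, smoothing=0.0, n_restarts=5, seed=0)
        est = rr.estimate_chronogram(
            three_taxon_tree, rr.CalibrationSpec(10.0, 10.0, 10.0), cfg
        )
        xs = [n.length * L for n in edge_nodes(three_taxon_tree)]
        psi_max = sum(x * math.log(x) - x for x in xs)
        assert est.objective == pytest.approx(psi_max, abs=1e-5)
        for orig, fit in zip(edge_nodes(three_taxon_tree), edge_nodes(est)):
            mu = fit.rate * L * (fit.parent.age - fit.age)
            assert mu == pytest.approx(orig.length * L, rel=1e-4)

    @pytest.mark.parametrize("lam", [1.0, 10.0])
    def test_grid_search_oracle_three_taxon(self, lam, three_taxon_tree):
        a, b, c, d = 0.05, 0.12, 0.06, 0.3
        T, L = 10.0, 1000
        cfg = rr.PLConfig(seq_length=L, smoothing=lam, n_restarts=5, seed=0)
        est = rr.estimate_chronogram(
            three_taxon_tree, rr.CalibrationSpec(T, T, T), cfg
        )
        t_opt = [n for n in edge_nodes(est) if not n.is_leaf][0].age
        r_opt = np.array([n.rate for n in edge_nodes(est)]) * L  # per-sequence

        psi_star, t_star, r_star, age_step, rate_step = _grid_oracle(
            a, b, c, d, T, L, lam
        )
        assert abs(t_opt - t_star) <= age_step + 1e-12
        assert np.all(np.abs(np.log(r_opt / r_star)) <= rate_step + 1e-12)
        # optimizer must not be beaten by the grid
        assert est.objective >= psi_star - 1e-6

    def test_scaling_identity_on_optimizer(self):
        # estimate at root 20 == estimate at root 25 rescaled by 0.8
        cfg = rr.SimConfig(
            birth_rate=1.0, target_n=12, rate_mean=0.01,
            rate_autocorr_sd=0.2, seq_length=1000, seed=42,
        )
        tree = rr.assign_rates(rr.simulate_tree(cfg), cfg)
        pl = rr.PLConfig(seq_length=1000, smoothing=1.0, n_restarts=5, seed=0)
        e25 = rr.estimate_chronogram(tree, rr.CalibrationSpec(25, 21.1, 29.3), pl)
        e20 = rr.estimate_chronogram(tree, rr.CalibrationSpec(20, 16.88, 23.44), pl)
        a25 = np.array([n.age for n in e25.preorder()])
        a20 = np.array([n.age for n in e20.preorder()])
        assert np.max(np.abs(a20 - 0.8 * a25)) < 1e-4
        r25 = np.array([n.rate for n in edge_nodes(e25)])
        r20 = np.array([n.rate for n in edge_nodes(e20)])
        np.testing.assert_allclose(r20, r25 * 25 / 20, rtol=1e-6)

    def test_objective_never_below_clock_start(self):
        cfg = rr.SimConfig(
            birth_rate=1.0, target_n=8, rate_mean=0.02,
            rate_autocorr_sd=0.5, seq_length=500, seed=9,
        )
        tree = rr.assign_rates(rr.simulate_tree(cfg), cfg)
        pl = rr.PLConfig(seq_length=500, smoothing=1.0, n_restarts=3, seed=0)
        prob = _PLProblem(tree, pl, 1e-6)
        f0, logr0 = prob.clock_start()
        psi_clock = -prob.neg_psi(np.concatenate([f0, logr0]))
        est = rr.estimate_chronogram(tree, rr.CalibrationSpec(10, 10, 10), pl)
        assert est.objective >= psi_clock - 1e-9

    def test_smoothing_shrinks_rate_variance(self):
        cfg = rr.SimConfig(
            birth_rate=1.0, target_n=10, rate_mean=0.01,
            rate_autocorr_sd=0.4, seq_length=800, seed=11,
        )
        tree = rr.assign_rates(rr.simulate_tree(cfg), cfg)
        calib = rr.CalibrationSpec(10.0, 10.0, 10.0)
        variances = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            pl = rr.PLConfig(seq_length=800, smoothing=lam, n_restarts=5, seed=0)
            est = rr.estimate_chronogram(tree, calib, pl)
            variances.append(np.var([n.rate for n in edge_nodes(est)]))
        for lo, hi in zip(variances[1:], variances[:-1]):
            assert lo <= hi * 1.05  # weakly decreasing, small optimizer slack

    def test_estimates_are_ultrametric(self):
        cfg = rr.SimConfig(
            birth_rate=1.0, target_n=9, rate_mean=0.01,
            rate_autocorr_sd=0.3, seq_length=700, seed=13,
        )
        tree = rr.assign_rates(rr.simulate_tree(cfg), cfg)
        pl = rr.PLConfig(seq_length=700, smoothing=1.0, n_restarts=3, seed=0)
        est = rr.estimate_chronogram(tree, rr.CalibrationSpec(25, 21.1, 29.3), pl)
        for tip in est.tips():
            total = 0.0
            node = tip
            while node.parent is not None:
                total += node.length
                node = node.parent
            assert total == pytest.approx(25.0, rel=1e-6)
        assert est.root_age == 25.0

    def test_determinism(self):
        cfg = rr.SimConfig(
            birth_rate=1.0, target_n=7, rate_mean=0.01,
            rate_autocorr_sd=0.3, seq_length=500, seed=21,
        )
        tree = rr.assign_rates(rr.simulate_tree(cfg), cfg)
        pl = rr.PLConfig(seq_length=500, smoothing=1.0, n_restarts=4, seed=5)
        e1 = rr.estimate_chronogram(tree, rr.CalibrationSpec(25, 21.1, 29.3), pl)
        e2 = rr.estimate_chronogram(tree, rr.CalibrationSpec(25, 21.1, 29.3), pl)
        assert e1.to_newick() == e2.to_newick()
        assert e1.objective == e2.objective

    def test_nonconvergence_carries_best_solution(self):
        cfg = rr.SimConfig(
            birth_rate=1.0, target_n=8, rate_mean=0.02,
            rate_autocorr_sd=0.5, seq_length=500, seed=3,
        )
        tree = rr.assign_rates(rr.simulate_tree(cfg), cfg)
        pl = rr.PLConfig(seq_length=500, smoothing=1.0, n_restarts=2, seed=0,
                         max_iter=1)
        with pytest.raises(ConvergenceError) as exc:
            rr.estimate_chronogram(tree, rr.CalibrationSpec(10, 10, 10), pl)
        assert isinstance(exc.value.best, rr.Chronogram)
        assert len(exc.value.trace) == 2

    def test_fewer_than_two_tips_rejected(self):
        tree = rr.Phylogram.from_newick("(A:0.5);")
        with pytest.raises(ValueError):
            rr.estimate_chronogram(
                tree, rr.CalibrationSpec(10, 10, 10), rr.PLConfig()
            )


def _is_descendant(tip, ancestor):
    node = tip
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def _grid_oracle(a, b, c, d, T, L, lam, age_step_frac=1e-3,
                 n_rate_grid=161, rate_span=100.0):
    """Brute-force reference for the 3-taxon tree ((A:a,B:b):c,C:d) at fixed
    root age T: 1-D grid over the free internal age (step 1e-3*T) crossed
    with per-coordinate descent over log-spaced rate grids. The objective is
    written out explicitly here, independent of the package internals.
    Returns (best psi, best age, best rates, age step, log rate step)."""
    x = np.array([c, a, b, d]) * L  # edge order: internal X, A, B, C

    def psi_rows(cand, tau):
        mu = cand * tau
        ll = np.sum(np.where(x > 0, x * np.log(mu), 0.0) - mu, axis=1)
        rho = cand * T
        m = (rho[:, 0] + rho[:, 3]) / 2
        phi = (
            (rho[:, 1] - rho[:, 0]) ** 2
            + (rho[:, 2] - rho[:, 0]) ** 2
            + ((rho[:, 0] - m) ** 2 + (rho[:, 3] - m) ** 2) / 2
        )
        return ll - lam * phi

    ages = np.arange(age_step_frac, 1.0, age_step_frac) * T
    log_steps = np.log(rate_span) * 2 / (n_rate_grid - 1)
    best = (-np.inf, None, None)
    for t in ages:
        tau = np.array([T - t, t, t, T])
        starts = [
            np.full(4, x.sum() / tau.sum()),
            np.where(x > 0, x / tau, x.sum() / tau.sum()),
        ]
        for r0 in starts:
            cur = r0.copy()
            val = psi_rows(cur[None, :], tau)[0]
            grids = [
                cur[k] * np.logspace(
                    -math.log10(rate_span), math.log10(rate_span), n_rate_grid
                )
                for k in range(4)
            ]
            for _ in range(60):
                improved = False
                scale = np.logspace(-1, 1, 81)
                cand = cur[None, :] * scale[:, None]
                vals = psi_rows(cand, tau)
                j = int(np.argmax(vals))
                if vals[j] > val + 1e-10:
                    val, cur, improved = vals[j], cand[j].copy(), True
                for k in range(4):
                    cand = np.repeat(cur[None, :], n_rate_grid, axis=0)
                    cand[:, k] = grids[k]
                    vals = psi_rows(cand, tau)
                    j = int(np.argmax(vals))
                    if vals[j] > val + 1e-10:
                        val, improved = vals[j], True
                        cur[k] = grids[k][j]
                if not improved:
                    break
            if val > best[0]:
                best = (val, t, cur.copy())
    return best[0], best[1], best[2], age_step_frac * T, log_steps


# ---------------------------------------------------------------------
# rescaling, CI propagation, crown ages


class TestRescaling:
    def test_study_age_ratio(self):
        # 2.56 Myr at root 25 -> 2.048 (prints as 2.05) at root 20
        assert 2.56 * 20 / 25 == pytest.approx(2.048)

    def test_rescale_chronogram(self):
        cfg = rr.SimConfig(birth_rate=1.0, target_n=6, seed=2)
        chrono = rr.simulate_tree(cfg)
        tree = rr.assign_rates(chrono, cfg)
        pl = rr.PLConfig(seq_length=1000, smoothing=1.0, n_restarts=2, seed=0)
        est = rr.estimate_chronogram(tree, rr.CalibrationSpec(25, 21.1, 29.3), pl)
        scaled = rr.rescale_chronogram(est, 20.0)
        for n1, n2 in zip(est.preorder(), scaled.preorder()):
            assert n2.age == pytest.approx(n1.age * 0.8)
            if n1.rate is not None:
                assert n2.rate == pytest.approx(n1.rate / 0.8)

    def test_identity_and_inverse(self):
        cfg = rr.SimConfig(birth_rate=1.0, target_n=5, seed=8)
        chrono = rr.simulate_tree(cfg)
        chrono25 = rr.rescale_chronogram(chrono, 25.0)
        same = rr.rescale_chronogram(chrono25, 25.0)
        back = rr.rescale_chronogram(rr.rescale_chronogram(chrono25, 20.0), 25.0)
        for a, b, c in zip(chrono25.preorder(), same.preorder(), back.preorder()):
            assert b.age == pytest.approx(a.age)
            assert c.age == pytest.approx(a.age)

    def test_rescale_invalid(self):
        cfg = rr.SimConfig(birth_rate=1.0, target_n=4, seed=1)
        with pytest.raises(ValueError):
            rr.rescale_chronogram(rr.simulate_tree(cfg), -1.0)


class TestCIPropagation:
    def test_study_rows(self, calib_study):
        lo, hi = rr.propagate_calibration_ci(1.22, calib_study)
        assert (round(lo, 2), round(hi, 2)) == (1.03, 1.43)
        lo, hi = rr.propagate_calibration_ci(0.64, calib_study)
        assert (round(lo, 2), round(hi, 2)) == (0.54, 0.75)

    def test_degenerate_interval(self):
        calib = rr.CalibrationSpec(25.0, 25.0, 25.0)
        assert rr.propagate_calibration_ci(3.7, calib) == (3.7, 3.7)

    def test_full_precision(self, calib_study):
        lo, hi = rr.propagate_calibration_ci(1.22, calib_study)
        assert lo == pytest.approx(1.22 * 21.1 / 25)
        assert hi == pytest.approx(1.22 * 29.3 / 25)

    def test_negative_age_rejected(self, calib_study):
        with pytest.raises(ValueError):
            rr.propagate_calibration_ci(-1.0, calib_study)

    def test_bad_calibration_rejected(self):
        with pytest.raises(ValueError):
            rr.CalibrationSpec(25.0, 26.0, 29.3)


class TestCrownAge:
    def test_all_tips_gives_root_age(self):
        cfg = rr.SimConfig(birth_rate=1.0, target_n=7, seed=4)
        chrono = rr.simulate_tree(cfg)
        clade = rr.CladeDefinition("all", set(chrono.tip_labels()), 7)
        assert rr.crown_age(chrono, clade) == chrono.root_age

    def test_cherry_closed_form(self, clock_tree_4tip):
        pl = rr.PLConfig(seq_length=1000, smoothing=1.0, n_restarts=2, seed=0)
        est = rr.estimate_chronogram(
            clock_tree_4tip, rr.CalibrationSpec(25.0, 25.0, 25.0), pl
        )
        clade = rr.CladeDefinition("ab", {"A", "B"}, 2)
        d, r = 1.0, 2.0 / 25.0  # tip branch length and clock rate
        assert rr.crown_age(est, clade) == pytest.approx(d / r, rel=1e-6)

    def test_single_tip_is_zero(self):
        cfg = rr.SimConfig(birth_rate=1.0, target_n=5, seed=6)
        chrono = rr.simulate_tree(cfg)
        clade = rr.CladeDefinition("one", {"t1"}, 1)
        assert rr.crown_age(chrono, clade) == 0.0

    def test_unknown_tip_error(self):
        cfg = rr.SimConfig(birth_rate=1.0, target_n=5, seed=6)
        chrono = rr.simulate_tree(cfg)
        with pytest.raises(KeyError, match="nope"):
            rr.crown_age(chrono, rr.CladeDefinition("bad", {"t1", "nope"}, 2))

    def test_matches_pairwise_mrca_oracle(self):
        import itertools
        import random

        rnd = random.Random(7)
        for seed in range(10):
            chrono = rr.simulate_tree(
                rr.SimConfig(birth_rate=1.0, target_n=9, seed=seed)
            )
            tips = chrono.tip_labels()
            chosen = rnd.sample(tips, rnd.randint(2, 6))
            clade = rr.CladeDefinition("c", set(chosen), len(chosen))
            # oracle: crown age = max over tip pairs of the pair MRCA age
            oracle = max(
                chrono.mrca([u, v]).age
                for u, v in itertools.combinations(chosen, 2)
            )
            assert rr.crown_age(chrono, clade) == pytest.approx(oracle)
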