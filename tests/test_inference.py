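"""Tests for the MCMC kernels and the full sampler."""

import numpy as np
import pytest
from scipy import stats

from attrtree.diagnostics import (
    geweke_zscores,
    monitored_stats,
    prior_forward_sample,
    regenerate_data,
)
from attrtree.inference import (
    McmcConfig,
    ModelHyper,
    ModelState,
    Trace,
    TraceEntry,
    joint_log_prob,
    mcmc_sweep,
    resample_assignments,
    resample_c,
    resample_theta,
    run_mcmc,
    select_map_sample,
)
from attrtree.model import (
    AttributeMatrix,
    NodeParams,
    NoiseModel,
    SparsityHyper,
    obs_log_likelihood,
    theta_log_prior,
)
from attrtree.nodes import ROOT
from attrtree.tssbp import (
    OccupancyCounts,
    StickState,
    TreeHyper,
    node_weight,
    stick_log_prior,
)


def make_state(theta_map, assignments, hyper=None, sticks_map=None):
    D = len(next(iter(theta_map.values())))
    hyper = hyper or ModelHyper.default(D)
    sticks = StickState()
    for n in theta_map:
        sticks.nu[n] = 0.5
        if n != ROOT:
            sticks.psi[n] = 0.5
    if sticks_map:
        for key, val in sticks_map.items():
            kind, node = key
            getattr(sticks, kind)[node] = val
    params = NodeParams({n: np.asarray(t, float) for n, t in theta_map.items()})
    return ModelState(
        sticks, params, OccupancyCounts.from_assignments(assignments),
        list(assignments), hyper,
    )


def empty_data(D):
    return AttributeMatrix(np.zeros((0, D), dtype=np.int8), [], [f"a{d}" for d in range(D)])


class TestJointLogProb:
    def test_empty_data_is_prior_only(self):
        state = make_state({ROOT: [0.2, 0.1]}, [])
        expected = stick_log_prior(state.sticks, state.hyper.tree) + theta_log_prior(
            state.params, state.hyper.sparsity
        )
        assert joint_log_prob(state, empty_data(2)) == pytest.approx(expected)

    def test_single_instance_additivity(self):
        x = np.array([1, 0], dtype=np.int8)
        data = AttributeMatrix(x[None, :], ["i1"], ["a", "b"])
        state0 = make_state({ROOT: [0.2, 0.1]}, [])
        state1 = make_state({ROOT: [0.2, 0.1]}, [ROOT])
        delta = joint_log_prob(state1, data) - joint_log_prob(state0, empty_data(2))
        expected = np.log(node_weight(state1.sticks, ROOT)) + obs_log_likelihood(
            x, ROOT, state1.params, state1.hyper.noise
        )
        assert delta == pytest.approx(expected)

    def test_instance_relabeling_invariance(self, rng):
        X = rng.integers(0, 2, (5, 3)).astype(np.int8)
        ids = [f"i{k}" for k in range(5)]
        data = AttributeMatrix(X, ids, ["a", "b", "c"])
        zs = [ROOT, (1,), ROOT, (1,), (1,)]
        state = make_state({ROOT: [0.2, 0.3, 0.4], (1,): [0.5, 0.1, 0.2]}, zs)
        lp = joint_log_prob(state, data)
        perm = rng.permutation(5)
        data2 = AttributeMatrix(X[perm], [ids[p] for p in perm], ["a", "b", "c"])
        state2 = make_state(
            {ROOT: [0.2, 0.3, 0.4], (1,): [0.5, 0.1, 0.2]}, [zs[p] for p in perm]
        )
        assert joint_log_prob(state2, data2) == pytest.approx(lp)

    def test_inconsistent_counts_error(self):
        state = make_state({ROOT: [0.2]}, [ROOT])
        state.counts.subtree_count[ROOT] = 5
        with pytest.raises(ValueError):
            joint_log_prob(state, AttributeMatrix(np.zeros((1, 1), np.int8), ["i"], ["a"]))


class TestResampleAssignments:
    def two_node_state(self, pi_root=0.5):
        # root and first child carry equal likelihoods; the child's stick
        # configuration absorbs all non-root mass
        sticks_map = {
            ("nu", ROOT): pi_root,
            ("psi", (1,)): 1 - 1e-12,
            ("nu", (1,)): 1 - 1e-12,
        }
        return make_state(
            {ROOT: [0.3], (1,): [1e-12]}, [ROOT], sticks_map=sticks_map
        )

    @pytest.mark.parametrize("pi_root", [0.5, 0.2])
    def test_equal_likelihood_assignment_follows_weights(self, pi_root):
        data = AttributeMatrix(np.array([[1]], dtype=np.int8), ["i1"], ["a"])
        rng = np.random.default_rng(0)
        n_root = 0
        reps = 4000
        for _ in range(reps):
            state = self.two_node_state(pi_root)
            resample_assignments(state, data, rng)
            if state.assignments[0] == ROOT:
                n_root += 1
        chi2 = stats.chisquare(
            [n_root, reps - n_root], [pi_root * reps, (1 - pi_root) * reps]
        )
        assert chi2.pvalue > 0.01

    def test_zero_likelihood_node_never_selected(self):
        # the child's theta is ~1 on a dimension observed as 0 with no
        # flip noise, so its likelihood is (numerically) zero
        sticks_map = {("nu", ROOT): 0.3, ("psi", (1,)): 0.9, ("nu", (1,)): 0.9}
        hyper = ModelHyper(
            TreeHyper(), SparsityHyper(D=1), NoiseModel(np.zeros(1))
        )
        data = AttributeMatrix(np.array([[0]], dtype=np.int8), ["i1"], ["a"])
        rng = np.random.default_rng(1)
        for _ in range(300):
            state = make_state(
                {ROOT: [0.2], (1,): [1.0 - 1e-12]}, [ROOT], hyper=hyper,
                sticks_map=sticks_map,
            )
            resample_assignments(state, data, rng)
            assert state.assignments[0] != (1,)

    def test_deterministic_given_seed(self):
        data = AttributeMatrix(np.array([[1], [0]], dtype=np.int8), ["i1", "i2"], ["a"])
        outs = []
        for _ in range(2):
            state = self.two_node_state()
            state.assignments = [ROOT, ROOT]
            state.counts = OccupancyCounts.from_assignments(state.assignments)
            resample_assignments(state, data, np.random.default_rng(42))
            outs.append(list(state.assignments))
        assert outs[0] == outs[1]


class TestResampleTheta:
    def test_zero_step_is_null_move(self):
        data = AttributeMatrix(np.array([[1, 0]], dtype=np.int8), ["i1"], ["a", "b"])
        state = make_state({ROOT: [0.3, 0.6]}, [ROOT])
        before = state.params.theta[ROOT].copy()
        resample_theta(state, data, np.random.default_rng(0), mh_step=0.0)
        assert np.array_equal(state.params.theta[ROOT], before)

    def test_matches_grid_conditional(self):
        # single root node, two independent dimensions: the MH chain's
        # marginal must match the exact conditional computed by
        # quadrature on a fine grid
        D = 2
        hyper = ModelHyper(
            TreeHyper(), SparsityHyper(D=D, a=4, b=4), NoiseModel.constant(D, 0.1)
        )
        rng = np.random.default_rng(7)
        X = (rng.random((12, D)) < [0.7, 0.2]).astype(np.int8)
        data = AttributeMatrix(X, [f"i{k}" for k in range(12)], ["a", "b"])
        state = make_state({ROOT: [0.5, 0.5]}, [ROOT] * 12, hyper=hyper)
        samples = []
        for it in range(30_000):
            resample_theta(state, data, rng, mh_step=0.6)
            if it % 60 == 59:  # heavy thinning: KS assumes independence
                samples.append(state.params.theta[ROOT].copy())
        samples = np.asarray(samples)

        grid = np.linspace(1e-4, 1 - 1e-4, 2000)
        sp = hyper.sparsity
        for d in range(D):
            n1 = X[:, d].sum()
            n0 = len(X) - n1
            ptil = grid * 0.9 + (1 - grid) * 0.1
            log_dens = (
                stats.beta.logpdf(grid, sp.root_alpha, sp.root_beta)
                + n1 * np.log(ptil)
                + n0 * np.log1p(-ptil)
            )
            dens = np.exp(log_dens - log_dens.max())
            cdf_vals = np.cumsum(dens)
            cdf_vals /= cdf_vals[-1]
            ks = stats.ks_1samp(
                samples[:, d], lambda q: np.interp(q, grid, cdf_vals)
            )
            assert ks.pvalue > 0.01, f"dimension {d}"


class TestResampleC:
    def test_uniform_posterior_without_edges(self):
        state = make_state({ROOT: [0.3]}, [ROOT])
        rng = np.random.default_rng(0)
        cs = []
        for _ in range(4000):
            resample_c(state, rng, c_step=25.0)
            cs.append(state.hyper.sparsity.c[0])
        cs = np.asarray(cs)
        lo, hi = state.hyper.sparsity.c_lower, state.hyper.sparsity.c_upper
        se = cs.std(ddof=1) / np.sqrt(len(cs) / 20)  # crude ESS discount
        assert abs(cs.mean() - (lo + hi) / 2) < 3 * se

    def test_degenerate_interval_is_constant(self):
        hyper = ModelHyper(
            TreeHyper(),
            SparsityHyper(D=1, c_lower=40.0, c_upper=40.0),
            NoiseModel.constant(1),
        )
        state = make_state({ROOT: [0.3], (1,): [0.31]}, [ROOT], hyper=hyper)
        resample_c(state, np.random.default_rng(0))
        assert state.hyper.sparsity.c[0] == 40.0

    def test_identical_children_match_grid_posterior(self):
        # theta_child = theta_parent increases the child density with c,
        # so the posterior over c drifts above the uniform prior mean;
        # the chain mean must match deterministic quadrature
        theta = [0.4]
        state = make_state(
            {ROOT: theta, (1,): theta, (1, 1): theta, (1, 1, 1): theta},
            [(1, 1, 1)],
        )
        rng = np.random.default_rng(3)
        cs = []
        for _ in range(6000):
            resample_c(state, rng, c_step=25.0)
            cs.append(state.hyper.sparsity.c[0])
        chain_mean = np.mean(cs[1000:])

        grid = np.linspace(20.0, 100.0, 4001)
        log_post = 3 * stats.beta.logpdf(0.4, grid * 0.4, grid * 0.6)
        w = np.exp(log_post - log_post.max())
        grid_mean = float((grid * w).sum() / w.sum())
        assert grid_mean > 60.0  # pulled above the prior mean
        assert abs(chain_mean - grid_mean) < 2.5


class TestRunMcmc:
    def small_data(self, n=40):
        from attrtree.synthetic import PlantedSpec, make_planted_model, simulate_dataset

        spec = PlantedSpec(children_per_level=[2], D=8, novel_per_node=3,
                           root_novel=2, N=n, omega=0.01, seed=6)
        model = make_planted_model(spec)
        data, assignments, cats = simulate_dataset(model)
        return data, assignments, cats

    def test_bitwise_reproducible(self):
        data, _, _ = self.small_data()
        cfg = McmcConfig(n_sweeps=40, burn_in=20, thin=5, seed=9, anneal_sweeps=10)
        t1 = run_mcmc(data, cfg, ModelHyper.default(data.D, 0.02))
        t2 = run_mcmc(data, cfg, ModelHyper.default(data.D, 0.02))
        assert t1.log_probs == t2.log_probs
        s1, s2 = t1.samples[-1].state, t2.samples[-1].state
        assert s1.assignments == s2.assignments
        assert s1.sticks.nu == s2.sticks.nu
        for n in s1.params.theta:
            assert np.array_equal(s1.params.theta[n], s2.params.theta[n])

    def test_state_audit_through_sweeps(self):
        data, _, _ = self.small_data()
        cfg = McmcConfig(n_sweeps=15, burn_in=5, thin=5, seed=2)
        run_mcmc(data, cfg, ModelHyper.default(data.D, 0.02), audit=True)

    def test_two_cluster_separation(self):
        # at this sample size the likelihood gain of separating the two
        # planted clusters dominates the parent-child coupling cost, so
        # the posterior (and the chain) must separate them
        data, _, cats = self.small_data(n=150)
        hits = 0
        for seed in range(5):
            cfg = McmcConfig(n_sweeps=300, burn_in=150, thin=10, seed=seed,
                             anneal_sweeps=100)
            trace = run_mcmc(data, cfg, ModelHyper.default(data.D, 0.02))
            state = select_map_sample(trace)
            by_cat = {}
            for z, c in zip(state.assignments, cats):
                by_cat.setdefault(c, []).append(z)
            modes = []
            for c, zs in by_cat.items():
                vals, counts = np.unique(
                    np.array([str(z) for z in zs]), return_counts=True
                )
                modes.append(vals[counts.argmax()])
            if len(set(modes)) == len(modes):
                hits += 1
        assert hits >= 4

    def test_dimension_mismatch_errors(self):
        data, _, _ = self.small_data()
        with pytest.raises(ValueError):
            run_mcmc(data, McmcConfig(n_sweeps=2), ModelHyper.default(data.D + 1))


class TestKernelInvariance:
    def test_full_sweep_preserves_prior_marginals(self):
        """Replicated prior-init chains keep every monitored statistic at
        its prior value when all kernels leave the joint invariant."""
        hyper = ModelHyper(
            TreeHyper(alpha0=1.0, lam=0.5, gamma=0.3),
            SparsityHyper(D=3),
            NoiseModel.constant(3, 0.1),
        )
        cfg = McmcConfig(n_sweeps=1, seed=0, mh_step=0.8, split_merge=3, c_step=30.0)
        rng = np.random.default_rng(21)
        R, T = 150, 8
        start, end = [], []
        for _ in range(R):
            state, data = prior_forward_sample(6, hyper, rng)
            start.append(monitored_stats(state, data))
            for _ in range(T):
                mcmc_sweep(state, data, cfg, rng)
                data = regenerate_data(state, rng)
            state.audit()
            end.append(monitored_stats(state, data))
        fwd = {k: np.array([s[k] for s in start]) for k in start[0]}
        chain = {k: np.array([s[k] for s in end]) for k in start[0]}
        z = {
            k: (fwd[k].mean() - chain[k].mean())
            / np.sqrt(fwd[k].var(ddof=1) / R + chain[k].var(ddof=1) / R + 1e-300)
            for k in fwd
        }
        bad = {k: v for k, v in z.items() if abs(v) > 4.0}
        assert not bad, f"marginal drift detected: {bad}"


class TestSplitMergeExactModel:
    def test_matches_quadrature_posterior(self):
        """On a two-instance model the posterior over tree structures is
        computable exactly (closed-form stick integrals, grid integrals
        over child parameters); a long split-merge-only chain must
        reproduce the class probabilities."""
        import math

        from scipy.special import betaln
        from scipy.stats import beta as beta_dist

        from attrtree.inference import split_merge_move
        from attrtree.model import sample_root_theta
        from attrtree.tssbp import sample_sticks

        a0t, lam, gam = 1.0, 0.5, 0.3
        alpha1 = a0t * lam
        D, omega_val, c_fix = 2, 0.1, 30.0
        hyper = ModelHyper(
            TreeHyper(a0t, lam, gam),
            SparsityHyper(D=D, a=10, b=5, c_lower=c_fix, c_upper=c_fix),
            NoiseModel.constant(D, omega_val),
        )
        X = np.array([[1, 0], [0, 1]], dtype=np.int8)
        data = AttributeMatrix(X, ["i0", "i1"], ["a", "b"])

        rng = np.random.default_rng(123)
        sticks = StickState()
        sample_sticks(sticks, hyper.tree, ROOT, rng)
        params = NodeParams({ROOT: sample_root_theta(hyper.sparsity, rng)})
        theta_r = params.theta[ROOT].copy()
        state = ModelState(
            sticks, params, OccupancyCounts.from_assignments([ROOT, ROOT]),
            [ROOT, ROOT], hyper.copy(),
        )

        # --- exact class weights conditional on the frozen theta_root ---
        g = np.linspace(1e-6, 1 - 1e-6, 3000)
        dg = g[1] - g[0]

        def lik(pact, x):
            pt = pact * (1 - omega_val) + (1 - pact) * omega_val
            return pt if x == 1 else 1 - pt

        def cpdf(d):
            return beta_dist.pdf(g, c_fix * theta_r[d], c_fix * (1 - theta_r[d]))

        def t_two_at_root(d):
            return lik(theta_r[d], X[0, d]) * lik(theta_r[d], X[1, d])

        def t_split(d, first_at_root):
            x_r = X[0, d] if first_at_root else X[1, d]
            x_c = X[1, d] if first_at_root else X[0, d]
            pact = 1 - (1 - theta_r[d]) * (1 - g)
            return lik(theta_r[d], x_r) * np.sum(cpdf(d) * lik(pact, x_c)) * dg

        def t_both_child(d):
            pact = 1 - (1 - theta_r[d]) * (1 - g)
            return np.sum(cpdf(d) * lik(pact, X[0, d]) * lik(pact, X[1, d])) * dg

        def t_two_children(d, one_first):
            x1 = X[0, d] if one_first else X[1, d]
            x2 = X[1, d] if one_first else X[0, d]
            pact = 1 - (1 - theta_r[d]) * (1 - g)
            return (np.sum(cpdf(d) * lik(pact, x1)) * dg) * (
                np.sum(cpdf(d) * lik(pact, x2)) * dg
            )

        def stick_terms(nu_pairs, psi_pairs):
            out = 0.0
            for n_stop, m_below, al in nu_pairs:
                out += betaln(1 + n_stop, al + m_below) - betaln(1, al)
            for n_here, n_tail in psi_pairs:
                out += betaln(1 + n_here, gam + n_tail) - betaln(1, gam)
            return out

        log_w = {
            "A": stick_terms([(2, 0, a0t)], [])
            + sum(math.log(t_two_at_root(d)) for d in range(D)),
            "B": stick_terms([(1, 1, a0t), (1, 0, alpha1)], [(1, 0)])
            + sum(math.log(t_split(d, True)) for d in range(D)),
            "B2": stick_terms([(1, 1, a0t), (1, 0, alpha1)], [(1, 0)])
            + sum(math.log(t_split(d, False)) for d in range(D)),
            "C": stick_terms([(0, 2, a0t), (2, 0, alpha1)], [(2, 0)])
            + sum(math.log(t_both_child(d)) for d in range(D)),
            "D": stick_terms(
                [(0, 2, a0t), (1, 0, alpha1), (1, 0, alpha1)], [(1, 1), (1, 0)]
            )
            + sum(math.log(t_two_children(d, True)) for d in range(D)),
            "D2": stick_terms(
                [(0, 2, a0t), (1, 0, alpha1), (1, 0, alpha1)], [(1, 1), (1, 0)]
            )
            + sum(math.log(t_two_children(d, False)) for d in range(D)),
        }
        mx = max(log_w.values())
        w = {k: math.exp(v - mx) for k, v in log_w.items()}
        tot = sum(w.values())

        def classify(st):
            z = tuple(st.assignments)
            nu = set(st.sticks.nu)
            psi = set(st.sticks.psi)
            if z == (ROOT, ROOT) and nu == {ROOT} and not psi:
                return "A"
            if nu == {ROOT, (1,)} and psi == {(1,)}:
                if z == (ROOT, (1,)):
                    return "B"
                if z == ((1,), ROOT):
                    return "B2"
                if z == ((1,), (1,)):
                    return "C"
            if nu == {ROOT, (1,), (2,)} and psi == {(1,), (2,)}:
                if z == ((1,), (2,)):
                    return "D"
                if z == ((2,), (1,)):
                    return "D2"
            return "rest"

        from collections import Counter

        counts = Counter()
        burn, total = 20_000, 220_000
        for t in range(total):
            split_merge_move(state, data, rng)
            if t >= burn and t % 5 == 0:
                counts[classify(state)] += 1
        n_main = sum(v for k, v in counts.items() if k != "rest")
        for k in w:
            assert abs(counts[k] / n_main - w[k] / tot) < 0.04, (
                k, counts[k] / n_main, w[k] / tot,
            )


class TestSelectMapSample:
    def entry(self, sweep, lp):
        state = make_state({ROOT: [0.5]}, [])
        return TraceEntry(sweep, lp, state)

    def test_single_sample(self):
        t = Trace(samples=[self.entry(1, -5.0)])
        assert select_map_sample(t) is t.samples[0].state

    def test_monotone_picks_last(self):
        t = Trace(samples=[self.entry(i, float(i)) for i in range(3)])
        assert select_map_sample(t) is t.samples[-1].state

    def test_tie_breaks_to_later_sweep(self):
        t = Trace(samples=[self.entry(1, -5.0), self.entry(2, -3.0), self.entry(3, -3.0)])
        assert select_map_sample(t) is t.samples[2].state

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError):
            select_map_sample(Trace())
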