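"""Cluster-based permutation testing and mixed-model condition effects."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from cardiostop.stats import (
    T_SENTINEL,
    build_adjacency,
    cluster_permutation_test,
    fit_condition_effect,
    paired_t_map,
)


def line_montage(n, spacing_cm=2.0):
    return pd.DataFrame(
        {"label": [f"ch{i}" for i in range(n)],
         "x_cm": np.arange(n) * spacing_cm, "y_cm": 0.0, "z_cm": 0.0}
    )


class TestAdjacency:
    def test_five_cm_rule(self):
        m = pd.DataFrame(
            {"label": ["a", "b", "c"], "x_cm": [0.0, 4.9, 10.0], "y_cm": 0.0, "z_cm": 0.0}
        )
        adj = build_adjacency(m, 5.0)
        assert "b" in adj.neighbors("a")
        assert "c" not in adj.neighbors("b")  # 5.1 cm apart

    def test_zero_threshold_empty(self):
        adj = build_adjacency(line_montage(4), 0.0)
        assert len(adj.edges) == 0

    def test_symmetric_no_self_edges(self, montage64):
        adj = build_adjacency(montage64, 5.0)
        assert np.all(adj.edges[:, 0] < adj.edges[:, 1])
        for a, b in adj.edges[:20]:
            assert adj.labels[a] in adj.neighbors(adj.labels[b])

    def test_missing_coordinate_rejected(self):
        m = line_montage(3)
        m.loc[1, "x_cm"] = np.nan
        with pytest.raises(ValueError):
            build_adjacency(m, 5.0)


class TestTMap:
    def test_identical_conditions_zero(self, rng):
        a = rng.standard_normal((6, 3, 10))
        t = paired_t_map(a, a.copy())
        assert np.allclose(t, 0.0)

    def test_matches_hand_formula(self, rng):
        d = np.array([1.0, 1.1, 0.9, 1.05])
        a = d[:, None, None] + np.zeros((4, 1, 1))
        b = np.zeros((4, 1, 1))
        t = paired_t_map(a, b)[0, 0]
        expect = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        assert t == pytest.approx(expect)

    def test_sign_flip_antisymmetry(self, rng):
        a = rng.standard_normal((5, 2, 8))
        b = rng.standard_normal((5, 2, 8))
        assert np.allclose(paired_t_map(a, b), -paired_t_map(b, a))

    def test_zero_variance_sentinel(self):
        a = np.ones((4, 1, 2))
        b = np.zeros((4, 1, 2))
        with pytest.warns(UserWarning):
            t = paired_t_map(a, b)
        assert np.all(t == T_SENTINEL)


def brute_force_max_stats(d_flat, tcrit):
    """Independent oracle: enumerate every sign assignment for a single
    channel; cluster suprathreshold same-sign t-values by temporal
    adjacency by direct scanning."""
    n = d_flat.shape[0]
    out = []
    for signs in itertools.product((1.0, -1.0), repeat=n):
        x = d_flat * np.asarray(signs)[:, None]
        m, sd = x.mean(0), x.std(0, ddof=1)
        t = np.where(sd == 0, np.sign(m) * T_SENTINEL, m / (sd / np.sqrt(n)))
        best = 0.0
        for sign in (1, -1):
            run = 0.0
            for v in np.append(t, np.nan):  # sentinel terminates final run
                if np.isfinite(v) and sign * v > tcrit:
                    run += v
                else:
                    best = max(best, abs(run))
                    run = 0.0
        out.append(best)
    return np.array(out)


class TestClusterPermutation:
    def test_no_clusters_when_identical(self, rng):
        a = rng.standard_normal((8, 3, 12))
        adj = build_adjacency(line_montage(3), 5.0)
        res = cluster_permutation_test(a, a.copy(), adj, n_permutations=300, rng=0)
        assert res.significant_clusters == []

    def test_exhaustive_matches_brute_force_enumeration(self, rng):
        """4 subjects, 1 channel, 2 samples, large uniform shift: the
        implementation's exact p equals a from-scratch enumeration of all
        16 sign assignments."""
        shift = 2.0
        d = shift + 0.3 * rng.standard_normal((4, 1, 2))
        a = d
        b = np.zeros_like(d)
        adj = build_adjacency(line_montage(1), 5.0)
        res = cluster_permutation_test(a, b, adj, n_permutations=1000, rng=1)
        assert res.exhaustive and res.n_permutations == 16
        tcrit = spstats.t.ppf(0.975, 3)
        null = brute_force_max_stats(d[:, 0, :], tcrit)
        obs = max(abs(c.summed_t) for c in res.clusters)
        assert obs == pytest.approx(null.max(), rel=1e-9)
        expect_p = np.mean(null >= obs - 1e-12)
        assert res.clusters[0].p_value == pytest.approx(expect_p)

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        d = 0.8 + 1.0 * rng.standard_normal((10, 2, 6))
        a, b = d, np.zeros_like(d)
        adj = build_adjacency(line_montage(2), 5.0)
        exact = cluster_permutation_test(a, b, adj, n_permutations=1024, rng=0)
        assert exact.exhaustive
        mc = cluster_permutation_test(a, b, adj, n_permutations=1000, rng=2)
        assert not mc.exhaustive
        p_e = exact.clusters[0].p_value
        p_m = mc.clusters[0].p_value
        tol = 3 * np.sqrt(max(p_e * (1 - p_e), 1e-4) / 1000) + 2 / 1000
        assert abs(p_m - p_e) <= tol

    def test_channel_reordering_invariance(self, rng):
        a = rng.standard_normal((7, 4, 10))
        b = rng.standard_normal((7, 4, 10))
        a[:, 1, 3:6] += 1.5
        m = line_montage(4)
        adj = build_adjacency(m, 5.0)
        res1 = cluster_permutation_test(a, b, adj, n_permutations=500, rng=3)
        perm = np.array([2, 0, 3, 1])
        m2 = m.iloc[perm].reset_index(drop=True)
        adj2 = build_adjacency(m2, 5.0)
        res2 = cluster_permutation_test(a[:, perm], b[:, perm], adj2,
                                        n_permutations=500, rng=3)
        sums1 = sorted(round(c.summed_t, 9) for c in res1.clusters)
        sums2 = sorted(round(c.summed_t, 9) for c in res2.clusters)
        assert sums1 == sums2

    def test_clusters_are_connected_and_same_sign(self, rng):
        a = rng.standard_normal((8, 4, 12))
        b = rng.standard_normal((8, 4, 12))
        a[:, :2, 4:8] += 1.2
        adj = build_adjacency(line_montage(4), 5.0)
        res = cluster_permutation_test(a, b, adj, n_permutations=300, rng=4)
        edge_set = {tuple(e) for e in adj.edges}
        for cl in res.clusters:
            members = {tuple(m) for m in cl.members}
            signs = {np.sign(res.t_obs[c, s]) for c, s in members}
            assert signs == {float(cl.sign)}
            if len(members) == 1:
                continue
            for c, s in members:  # every member touches another member
                nb = [(c, s - 1), (c, s + 1)] + [
                    (o, s) for o in range(4)
                    if (min(c, o), max(c, o)) in edge_set and o != c
                ]
                assert any(x in members for x in nb)

    def test_null_false_positive_rate_is_controlled(self, rng):
        """Quick validity check on a reduced null study (the full-size
        study runs in the acceptance suite)."""
        adj = build_adjacency(line_montage(4), 5.0)
        hits = 0
        n_data = 60
        for _ in range(n_data):
            a = rng.standard_normal((10, 4, 15))
            b = rng.standard_normal((10, 4, 15))
            res = cluster_permutation_test(a, b, adj, n_permutations=250, rng=rng)
            hits += bool(res.significant_clusters)
        assert hits / n_data <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_data) + 0.02


class TestConditionEffects:
    def _balanced(self, rng, n_sub=8, delta=None, sub_sd=0.0, noise=0.0):
        delta = delta if delta is not None else {"none": 0.0, "systole": 0.5, "diastole": -0.5}
        rows = []
        intercepts = rng.normal(0, sub_sd, n_sub)
        for s in range(n_sub):
            for cond, d in delta.items():
                rows.append((s, cond, 10.0 + intercepts[s] + d + rng.normal(0, noise)))
        return pd.DataFrame(rows, columns=["subject", "condition", "value"])

    def test_degenerate_model_equals_cell_means(self, rng):
        """Zero between-subject variance, balanced design: fixed effects
        coincide exactly with the empirical condition means."""
        df = self._balanced(rng, sub_sd=0.0, noise=0.3)
        est = fit_condition_effect(df, reference="none")
        assert not est.fallback
        cell = df.groupby("condition")["value"].mean()
        assert est.params.loc["Intercept", "estimate"] == pytest.approx(cell["none"], abs=1e-6)
        assert est.params.loc["condition[T.systole]", "estimate"] == pytest.approx(
            cell["systole"] - cell["none"], abs=1e-6
        )
        assert est.params.loc["condition[T.diastole]", "estimate"] == pytest.approx(
            cell["diastole"] - cell["none"], abs=1e-6
        )

    def test_effect_recovery_within_two_se(self):
        """Injected condition offset with subject intercept SD 1: the
        estimate lies within 2 SE of truth in >= 95% of replicates."""
        hits, n_rep = 0, 100
        for k in range(n_rep):
            rng = np.random.default_rng(500 + k)
            df = self._balanced(rng, n_sub=12, sub_sd=1.0, noise=0.5,
                                delta={"none": 0.0, "systole": 0.8, "diastole": 0.0})
            est = fit_condition_effect(df, reference="none")
            e = est.params.loc["condition[T.systole]"]
            hits += abs(e["estimate"] - 0.8) <= 2 * e["se"]
        assert hits / n_rep >= 0.95

    def test_interaction_slope_recovery(self):
        """SSD built as beta * P2 + condition offsets + subject intercepts:
        the slope's sign and magnitude are recovered."""
        beta = -0.4
        rng = np.random.default_rng(9)
        rows = []
        for s in range(20):
            u = rng.normal(0, 1.0)
            for cond, off in (("systole", 0.0), ("diastole", -1.0), ("none", 0.5)):
                for _ in range(5):
                    p2 = rng.normal(3.0, 1.5)
                    ssd = 300.0 + off + beta * p2 + u + rng.normal(0, 0.3)
                    rows.append((s, cond, p2, ssd))
        df = pd.DataFrame(rows, columns=["subject", "condition", "p2", "value"])
        est = fit_condition_effect(df, reference="none", covariates=["p2"])
        e = est.params.loc["p2"]
        assert np.sign(e["estimate"]) == np.sign(beta)
        assert abs(e["estimate"] - beta) <= 2 * e["se"] + 0.05
        assert est.random_intercept_var > 0.3

    def test_interaction_model_reports_both_aics(self, rng):
        df = self._balanced(rng, n_sub=10, sub_sd=0.5, noise=0.3)
        df["cov"] = rng.normal(size=len(df))
        est = fit_condition_effect(df, reference="none", covariates=["cov"],
                                   interaction_with="cov")
        assert est.aic_interaction is not None and np.isfinite(est.aic)

    def test_insufficient_design_rejected(self):
        df = pd.DataFrame({"subject": [0, 1], "condition": ["a", "a"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_condition_effect(df)
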