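import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mesreg.netinfer import (
    _R2_CLIP,
    _normal_scores,
    dpi_prune,
    edge_pvalues,
    filter_edges,
    infer_network,
    mutual_information,
)


def _matrix(rng, n_genes, n_samples, prefix="g"):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestMutualInformation:
    def test_closed_form_from_normal_score_correlation(self, rng):
        x = rng.normal(size=100)
        y = 0.8 * x + 0.6 * rng.normal(size=100)
        zx = stats.norm.ppf(stats.rankdata(x) / 101)
        zy = stats.norm.ppf(stats.rankdata(y) / 101)
        r = np.corrcoef(zx, zy)[0, 1]
        expected = -0.5 * np.log(1 - r**2)
        assert mutual_information(x, y) == pytest.approx(expected, rel=1e-10)

    def test_value_at_r_08(self):
        # any pair whose normal-score correlation is exactly 0.8 has
        # mi = -0.5*ln(0.36); verified on the closed form itself
        assert -0.5 * np.log(1 - 0.8**2) == pytest.approx(0.5108256, abs=1e-6)

    def test_monotone_transform_hits_clip_bound(self, rng):
        x = rng.normal(size=64)
        assert mutual_information(x, x**3) == pytest.approx(-0.5 * np.log1p(-_R2_CLIP))
        assert mutual_information(x, x**3) == mutual_information(x, x)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_monotone_invariance(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=30), r.normal(size=30)
        assert mutual_information(x, y) == mutual_information(y, x)
        assert mutual_information(np.exp(x), y) == pytest.approx(
            mutual_information(x, y), abs=1e-12
        )

    def test_constant_vector_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            mutual_information(np.ones(20), rng.normal(size=20))

    def test_histogram_estimator_orders_dependence(self, rng):
        x = rng.normal(size=500)
        dep = mutual_information(x, x + 0.2 * rng.normal(size=500), estimator="histogram")
        ind = mutual_information(x, rng.normal(size=500), estimator="histogram")
        assert dep > ind


class TestEdgePvalues:
    def test_null_pvalues_approximately_uniform(self, rng):
        vals = _matrix(rng, 100, 50)
        tab = edge_pvalues(vals, [f"g{i:03d}" for i in range(8)], n_perm=200, seed=3)
        ks = stats.kstest(tab["p"], "uniform").statistic
        assert ks < 0.05

    def test_planted_edge_attains_minimal_p(self, rng):
        vals = _matrix(rng, 60, 40)
        vals.loc["g030"] = vals.loc["g000"] + 0.05 * rng.normal(size=40)
        tab = edge_pvalues(vals, ["g000", "g001"], n_perm=200, seed=0)
        pool = 2 * 200 * (60 - 1)
        row = tab[(tab.regulator == "g000") & (tab.target == "g030")]
        assert row["p"].iloc[0] == pytest.approx(1 / (pool + 1))
        assert row["sign"].iloc[0] == 1

    def test_same_seed_gives_identical_table(self, rng):
        vals = _matrix(rng, 40, 30)
        t1 = edge_pvalues(vals, ["g000", "g001", "g002"], n_perm=150, seed=9)
        t2 = edge_pvalues(vals, ["g000", "g001", "g002"], n_perm=150, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_small_n_perm_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            edge_pvalues(_matrix(rng, 20, 20), ["g000"], n_perm=50)


class TestFilterEdges:
    def test_boundaries_and_random_table_match_brute_force(self, rng):
        tab = pd.DataFrame(
            {"regulator": "t", "target": [f"g{i}" for i in range(50)],
             "mi": rng.random(50), "sign": 1, "p": rng.random(50),
             "q": rng.random(50)}
        )
        assert filter_edges(tab.assign(q=1.0)).empty
        assert len(filter_edges(tab, alpha=1.0)) == (tab["q"] < 1.0).sum()
        kept = filter_edges(tab, alpha=0.3)
        assert set(kept["target"]) == set(tab.loc[tab["q"] < 0.3, "target"])


def _edge_frame(edges):
    rows = [{"regulator": a, "target": b, "mi": w, "sign": 1, "p": 0.0, "q": 0.0}
            for (a, b), w in edges.items()]
    return pd.DataFrame(rows)


def _brute_force_dpi(edges, tfs, tolerance=0.0):
    """Exhaustive triangle enumeration over undirected weights."""
    und = {}
    for (a, b), w in edges.items():
        und[frozenset((a, b))] = w
    nodes = set(itertools.chain.from_iterable(edges))
    marked = set()
    for t1, t2 in itertools.combinations(sorted(tfs), 2):
        if frozenset((t1, t2)) not in und:
            continue
        for g in nodes - {t1, t2}:
            tri = [frozenset((t1, t2)), frozenset((t1, g)), frozenset((t2, g))]
            if not all(e in und for e in tri):
                continue
            ws = sorted(tri, key=lambda e: und[e])
            if und[ws[0]] == und[ws[1]]:
                continue
            if und[ws[0]] < (1 - tolerance) * und[ws[1]]:
                marked.add(ws[0])
    return {frozenset(e) for e in edges if frozenset(e) not in marked}


class TestDpiPrune:
    def test_weakest_triangle_edge_removed(self):
        edges = {("T1", "T2"): 0.5, ("T2", "x"): 0.4, ("T1", "x"): 0.3}
        net = dpi_prune(_edge_frame(edges))
        kept = {(r, t) for r, t in zip(net.edges.regulator, net.edges.target)}
        assert ("T1", "x") not in kept and ("T2", "x") in kept and ("T1", "T2") in kept

    def test_tolerance_spares_the_weakest_edge(self):
        edges = {("T1", "T2"): 0.5, ("T2", "x"): 0.4, ("T1", "x"): 0.3}
        net = dpi_prune(_edge_frame(edges), tolerance=0.3)
        assert len(net.edges) == 3

    def test_tied_minimum_removes_nothing(self):
        edges = {("T1", "T2"): 0.5, ("T2", "x"): 0.3, ("T1", "x"): 0.3}
        assert len(dpi_prune(_edge_frame(edges)).edges) == 3

    def test_matches_exhaustive_enumeration_on_random_graphs(self, rng):
        tfs = [f"T{i}" for i in range(8)]
        targets = [f"x{i}" for i in range(15)]
        for _ in range(200):
            edges = {}
            for t1, t2 in itertools.combinations(tfs, 2):
                if rng.random() < 0.4:
                    edges[(t1, t2)] = float(rng.random())
            for t in tfs:
                for g in targets:
                    if rng.random() < 0.35:
                        edges[(t, g)] = float(rng.random())
            if not edges:
                continue
            net = dpi_prune(_edge_frame(edges))
            kept = {frozenset((r, t)) for r, t in zip(net.edges.regulator, net.edges.target)}
            assert kept == _brute_force_dpi(edges, tfs)

    def test_output_subset_and_idempotent(self, rng):
        tfs = [f"T{i}" for i in range(6)]
        edges = {}
        for t1, t2 in itertools.combinations(tfs, 2):
            edges[(t1, t2)] = float(rng.random())
        for t in tfs:
            for g in [f"x{i}" for i in range(10)]:
                if rng.random() < 0.5:
                    edges[(t, g)] = float(rng.random())
        once = dpi_prune(_edge_frame(edges))
        assert len(once.edges) <= len(edges)
        twice = dpi_prune(once.edges)
        pd.testing.assert_frame_equal(
            once.edges.reset_index(drop=True), twice.edges.reset_index(drop=True)
        )

    def test_protect_tf_tf_flag_keeps_tf_tf_edges(self):
        edges = {("T1", "T2"): 0.1, ("T2", "x"): 0.4, ("T1", "x"): 0.3}
        default = dpi_prune(_edge_frame(edges))
        kept = {(r, t) for r, t in zip(default.edges.regulator, default.edges.target)}
        assert ("T1", "T2") not in kept
        protected = dpi_prune(_edge_frame(edges), protect_tf_tf=True)
        kept2 = {(r, t) for r, t in zip(protected.edges.regulator, protected.edges.target)}
        assert ("T1", "T2") in kept2


class TestPlantedNetworkRecovery:
    def test_planted_regulons_recovered_with_correct_signs(self, rng):
        """10 TFs x 30 disjoint targets, effect 1, noise SD 1, n=120:
        >= 90% of planted edges survive q<0.05 + DPI and >= 95% of the
        recovered signs match, aggregated over 10 seeds."""
        recovered, total, sign_ok, sign_n = 0, 0, 0, 0
        for seed in range(10):
            r = np.random.default_rng(1000 + seed)
            n = 120
            tf_vals = r.normal(size=(10, n))
            rows, names, signs = [tf_vals], [f"T{i:02d}" for i in range(10)], {}
            for i in range(10):
                s = r.choice([1, -1], size=30)
                block = s[:, None] * tf_vals[i] + r.normal(size=(30, n))
                rows.append(block)
                for k in range(30):
                    names.append(f"x{i:02d}_{k:02d}")
                    signs[(f"T{i:02d}", f"x{i:02d}_{k:02d}")] = s[k]
            vals = pd.DataFrame(np.vstack(rows), index=names,
                                columns=[f"s{j}" for j in range(n)])
            net = infer_network(vals, [f"T{i:02d}" for i in range(10)],
                                n_perm=1000, seed=seed)
            kept = {(r_, t_): sg for r_, t_, sg in
                    zip(net.edges.regulator, net.edges.target, net.edges.sign)}
            total += len(signs)
            for e, s_true in signs.items():
                if e in kept:
                    recovered += 1
                    sign_n += 1
                    sign_ok += kept[e] == s_true
        assert recovered / total >= 0.90
        assert sign_ok / sign_n >= 0.95

    def test_bh_controls_false_edges_under_global_null(self, rng):
        fracs = []
        for seed in range(10):
            r = np.random.default_rng(2000 + seed)
            vals = pd.DataFrame(r.normal(size=(80, 40)),
                                index=[f"g{i:03d}" for i in range(80)],
                                columns=[f"s{j}" for j in range(40)])
            tab = edge_pvalues(vals, [f"g{i:03d}" for i in range(10)],
                               n_perm=200, seed=seed)
            fracs.append((tab["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05
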