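"""Pathway scoring and greedy correlation clustering tests."""

import numpy as np
import pandas as pd
import pytest

from csf_nathist.pathways import (PathwayDefinition, greedy_cluster,
                                  infer_directionality, read_gmt,
                                  score_pathways, write_gmt)


def oracle_greedy(absrho: pd.DataFrame, seed_t: float, mem_t: float):
    """Plain-python reference of the accretion rule, for cross-checking.

    Works directly on a precomputed |rho| matrix with explicit loops and
    sorting-based tie-breaks; returns cluster member lists in order.
    """
    pool = sorted(absrho.index)
    clusters = []
    while len(pool) >= 2:
        pairs = sorted(
            ((float(absrho.loc[a, b]), a, b)
             for i, a in enumerate(pool) for b in pool[i + 1:]),
            key=lambda t: (-t[0], t[1], t[2]))
        if pairs[0][0] < seed_t:
            break
        _, a, b = pairs[0]
        members, rest = [a, b], [c for c in pool if c not in (a, b)]
        while rest:
            ranked = sorted(
                ((min(float(absrho.loc[c, m]) for m in members), c)
                 for c in rest), key=lambda t: (-t[0], t[1]))
            if ranked[0][0] < mem_t:
                break
            members.append(ranked[0][1])
            rest.remove(ranked[0][1])
        clusters.append(members)
        pool = [c for c in pool if c not in members]
    return clusters


def _correlated_frame(rng, loadings, n=80, noise=0.5):
    """Columns built from shared factors: col = sum_k w_k f_k + eps."""
    k = max(len(w) for w in loadings.values())
    f = rng.normal(0, 1, (n, k))
    cols = {}
    for name, w in loadings.items():
        w = np.pad(np.asarray(w, dtype=float), (0, k - len(w)))
        cols[name] = f @ w + rng.normal(0, noise, n)
    return pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])


class TestDirectionality:
    def test_signs_from_outcome_anchor(self, rng):
        anchor = pd.Series(rng.normal(0, 1, 100),
                           index=[f"S{i}" for i in range(100)], name="GMSD")
        adj = pd.DataFrame({"up": anchor + rng.normal(0, 0.3, 100),
                            "down": -anchor + rng.normal(0, 0.3, 100)},
                           index=anchor.index)
        d = infer_directionality(adj, ["up", "down"], anchor)
        assert d == {"up": 1, "down": -1}

    def test_group_median_anchor(self, rng):
        idx = [f"S{i}" for i in range(60)]
        groups = pd.Series(["HC"] * 30 + ["MS"] * 30, index=idx)
        adj = pd.DataFrame({"raised": np.r_[rng.normal(0, 1, 30),
                                            rng.normal(2, 1, 30)]},
                           index=idx)
        d = infer_directionality(adj, ["raised"], groups,
                                 anchor_kind="groups")
        assert d == {"raised": 1}

    def test_constant_member_warns_and_defaults_positive(self, rng):
        anchor = pd.Series(rng.normal(0, 1, 20),
                           index=[f"S{i}" for i in range(20)])
        adj = pd.DataFrame({"flat": np.ones(20)}, index=anchor.index)
        with pytest.warns(UserWarning, match="constant"):
            d = infer_directionality(adj, ["flat"], anchor)
        assert d == {"flat": 1}


class TestScoring:
    def test_single_member_score_equals_member(self, rng):
        adj = pd.DataFrame({"a": rng.normal(0, 1, 30)},
                           index=[f"S{i}" for i in range(30)])
        d = PathwayDefinition("pw", ["a"], {"a": 1})
        scores = score_pathways(adj, [d])
        assert np.allclose(scores["pw"], adj["a"])

    def test_flipping_directionality_negates(self, rng):
        adj = pd.DataFrame(rng.normal(0, 1, (30, 3)),
                           columns=["a", "b", "c"],
                           index=[f"S{i}" for i in range(30)])
        plus = PathwayDefinition("p", ["a", "b", "c"],
                                 {"a": 1, "b": -1, "c": 1})
        minus = PathwayDefinition("m", ["a", "b", "c"],
                                  {"a": -1, "b": 1, "c": -1})
        scores = score_pathways(adj, [plus, minus])
        assert np.allclose(scores["p"], -scores["m"])

    def test_score_additive_over_partition(self, rng):
        adj = pd.DataFrame(rng.normal(0, 1, (20, 4)),
                           columns=list("abcd"),
                           index=[f"S{i}" for i in range(20)])
        dirs = {"a": 1, "b": -1, "c": 1, "d": -1}
        whole = PathwayDefinition("w", list("abcd"), dirs)
        part1 = PathwayDefinition("p1", ["a", "d"], dirs)
        part2 = PathwayDefinition("p2", ["b", "c"], dirs)
        s = score_pathways(adj, [whole, part1, part2])
        assert np.allclose(s["w"], s["p1"] + s["p2"])

    def test_pooled_pathway_beats_median_member(self, small_cohort,
                                                adjusted):
        """Summing direction-aligned members amplifies the anchor signal."""
        from scipy import stats
        _, samples, _, truth = small_cohort
        ms = [s for s in adjusted.values.index
              if samples.at[s, "diagnosis"] != "HC"]
        anchor = truth.latents.loc[ms, "latent_combiwise"].rename("GMSD")
        name, members = next(iter(truth.pathways.items()))
        members = [m for m in members if m in adjusted.values.columns]
        dirs = infer_directionality(adjusted.values.loc[ms], members, anchor)
        d = PathwayDefinition(name, members, dirs)
        score = score_pathways(adjusted.values.loc[ms], [d])[name]
        rho_score = abs(stats.spearmanr(score, anchor).statistic)
        rho_members = [abs(stats.spearmanr(adjusted.values.loc[ms, m],
                                           anchor).statistic)
                       for m in members]
        assert rho_score > np.median(rho_members)


class TestGreedyCluster:
    def test_single_strong_pair(self, rng):
        adj = _correlated_frame(rng, {
            "a": [1.0], "b": [1.0],
            "c": [0.0, 1.0], "d": [0.0, 0.0, 1.0]}, noise=0.3)
        out = greedy_cluster(adj, list(adj.columns))
        assert len(out) == 1
        assert sorted(out[0].members) == ["a", "b"]
        assert out[0].seed_rho >= 0.7

    def test_below_seed_threshold_yields_nothing(self, rng):
        adj = _correlated_frame(rng, {
            "a": [0.5], "b": [0.5], "c": [0.0, 1.0]}, noise=1.0)
        assert greedy_cluster(adj, list(adj.columns)) == []

    def test_candidate_failing_one_member_excluded(self):
        """C correlates with A but not B: complete-linkage keeps C out."""
        rng = np.random.default_rng(0)
        n = 400
        f = rng.normal(0, 1, n)
        ea, eb = rng.normal(0, 0.3, n), rng.normal(0, 0.3, n)
        a, b = f + ea, f + eb
        # c shares a's private noise: rho(c,a) moderate, rho(c,b) low
        c = 0.35 * f + 3.0 * ea + rng.normal(0, 0.5, n)
        adj = pd.DataFrame({"a": a, "b": b, "c": c},
                           index=[f"S{i}" for i in range(n)])
        rho = adj.corr(method="spearman").abs()
        assert rho.loc["c", "a"] > 0.4          # scenario sanity
        assert rho.loc["c", "b"] < 0.5
        out = greedy_cluster(adj, ["a", "b", "c"], member_thresh=0.5)
        expected = oracle_greedy(rho, 0.7, 0.5)
        assert [cl.members for cl in out] == expected

    def test_matches_oracle_on_random_structures(self, rng):
        for trial in range(40):
            k = int(rng.integers(4, 6))
            loadings = {chr(97 + j): rng.normal(0, 1, 2)
                        for j in range(k)}
            adj = _correlated_frame(rng, loadings, n=50,
                                    noise=float(rng.uniform(0.2, 1.5)))
            out = greedy_cluster(adj, list(adj.columns))
            rho = adj.corr(method="spearman").abs()
            assert [cl.members for cl in out] == oracle_greedy(rho, 0.7, 0.5)

    def test_input_order_invariance_and_disjointness(self, rng):
        loadings = {c: rng.normal(0, 1, 3) for c in "abcdefgh"}
        adj = _correlated_frame(rng, loadings, n=60, noise=0.4)
        base = greedy_cluster(adj, list("abcdefgh"))
        perm = greedy_cluster(adj, list("hgfedcba"))
        assert [c.members for c in base] == [c.members for c in perm]
        flat = [m for c in base for m in c.members]
        assert len(flat) == len(set(flat))

    def test_admission_time_complete_linkage(self, rng):
        loadings = {c: rng.normal(0, 1, 2) for c in "abcdef"}
        adj = _correlated_frame(rng, loadings, n=60, noise=0.3)
        rho = adj.corr(method="spearman").abs()
        for cl in greedy_cluster(adj, list("abcdef")):
            for i, m in enumerate(cl.members):
                if i < 2:
                    continue
                prior = cl.members[:i]
                assert min(rho.loc[m, p] for p in prior) >= 0.5


def test_gmt_roundtrip(tmp_path):
    pw = {"PW1": ["a", "b", "c"], "PW2": ["d", "e"]}
    path = tmp_path / "p.gmt"
    write_gmt(path, pw, descriptions={"PW1": "desc"})
    assert read_gmt(path) == pw
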