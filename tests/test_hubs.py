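"""Quantile activity, the permutation covariation test, BH correction,
signed-network hub detection and inflammation labelling."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

from gepatlas import AtlasConfig, generate_atlas
from gepatlas.hubs import (
    ActivityTensor,
    HubPartition,
    activity_quantiles,
    bh_adjust,
    build_signed_network,
    detect_hubs,
    edge_statistic,
    gep_inflammation_enrichment,
    label_inflammatory,
    permutation_null,
    permutation_p,
    signed_modularity,
    stratified_permutation,
)

CLIP = 1.0 - 1e-7


def _meta(samples, comps=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "compartment": comps if comps is not None else ["epithelial"] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )


def _activity(values, gep_ids, quantiles=(0.25, 0.5, 0.75, 0.95, 0.99)):
    values = np.asarray(values, dtype=float)
    n_s, n_g, n_q = values.shape
    counts = np.full((n_s, n_g), 100)
    return ActivityTensor(
        values=values,
        sample_ids=[f"s{i}" for i in range(n_s)],
        gep_ids=list(gep_ids),
        quantiles=tuple(quantiles),
        gep_compartments={g: "epithelial" for g in gep_ids},
        cell_counts=counts,
        low_cell_flag=np.zeros((n_s, n_g), bool),
    )


class TestActivityQuantiles:
    def test_interpolated_median_of_0_to_9(self):
        W = pd.DataFrame({"pEP01": np.arange(10.0)})
        W.index = [f"c{i}" for i in range(10)]
        act = activity_quantiles(
            W, _meta(["s1"] * 10), {"pEP01": "epithelial"}, quantiles=(0.5,)
        )
        assert act.values[0, 0, 0] == pytest.approx(4.5)

    def test_constant_usage_gives_constant_quantiles(self):
        W = pd.DataFrame({"pEP01": [3.0] * 12}, index=[f"c{i}" for i in range(12)])
        act = activity_quantiles(W, _meta(["s1"] * 12), {"pEP01": "epithelial"})
        np.testing.assert_allclose(act.values[0, 0], 3.0)

    def test_matches_linear_interpolation_oracle(self):
        # independent oracle: sort and interpolate at h = q * (n - 1)
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 1, size=37)
        W = pd.DataFrame({"pEP01": vals}, index=[f"c{i}" for i in range(37)])
        qs = (0.25, 0.5, 0.75, 0.95, 0.99)
        act = activity_quantiles(W, _meta(["s1"] * 37), {"pEP01": "epithelial"},
                                 quantiles=qs)
        srt = np.sort(vals)
        for qi, q in enumerate(qs):
            h = q * 36
            lo, frac = int(math.floor(h)), h - math.floor(h)
            expected = srt[lo] + frac * (srt[min(lo + 1, 36)] - srt[lo])
            assert act.values[0, 0, qi] == pytest.approx(expected, abs=1e-12)

    def test_quantiles_nondecreasing_in_q(self, usage_frame, locked_atlas):
        _, adata, _, truth = locked_atlas
        act = activity_quantiles(usage_frame, adata.obs, truth.gep_compartments)
        diffs = np.diff(act.values, axis=2)
        assert np.nanmin(diffs) >= 0

    def test_missing_compartment_recorded_as_nan_and_low_cell_flagged(self):
        W = pd.DataFrame(
            {"pEP01": [1.0, 2.0, 3.0], "pMY01": [0.5, 0.5, 4.0]},
            index=["c0", "c1", "c2"],
        )
        meta = _meta(["s1", "s1", "s2"], ["epithelial", "epithelial", "epithelial"])
        act = activity_quantiles(
            W, meta, {"pEP01": "epithelial", "pMY01": "myeloid"}, min_cells=10
        )
        assert np.isnan(act.values[:, 1, :]).all()  # no myeloid cells anywhere
        assert act.low_cell_flag[0, 0] and act.low_cell_flag[1, 0]


class TestEdgeStatistic:
    def test_perfect_proportionality_clips_to_finite_z(self):
        rng = np.random.default_rng(1)
        a = rng.gamma(2, 1, size=(8, 5))
        act = _activity(np.stack([a, 2 * a], axis=1), ["g1", "g2"])
        r, z = edge_statistic(act, "g1", "g2")
        np.testing.assert_allclose(r, 1.0)
        assert z == pytest.approx(np.arctanh(CLIP))

    def test_five_sample_hand_table(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        vals = np.stack(
            [np.tile(a[:, None], (1, 5)), np.tile(b[:, None], (1, 5))], axis=1
        )
        act = _activity(vals, ["g1", "g2"])
        r, z = edge_statistic(act, "g1", "g2")
        r_oracle = pearsonr(a, b).statistic
        np.testing.assert_allclose(r, r_oracle, atol=1e-12)
        assert z == pytest.approx(np.arctanh(r_oracle), abs=1e-12)

    def test_zero_variance_quantile_excluded_from_mean(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, size=(6, 5))
        b = a * 1.5
        b[:, 2] = 7.0  # constant at one quantile
        act = _activity(np.stack([a, b], axis=1), ["g1", "g2"])
        r, z = edge_statistic(act, "g1", "g2")
        assert np.isnan(r[2]) and np.isfinite(r[[0, 1, 3, 4]]).all()
        assert z == pytest.approx(
            np.mean(np.arctanh(np.clip(r[[0, 1, 3, 4]], -CLIP, CLIP)))
        )

    def test_requires_three_shared_samples(self):
        vals = np.full((4, 2, 5), np.nan)
        vals[:2] = 1.0
        act = _activity(vals, ["g1", "g2"])
        with pytest.raises(ValueError, match="3 shared samples"):
            edge_statistic(act, "g1", "g2")


class TestPermutationP:
    @pytest.mark.parametrize(
        "above, below, n_perm, expected",
        [
            (12, 9988, 10_000, 0.0024),  # 2 x min-count scaling
            (9988, 12, 10_000, 0.0024),
            (10_000, 10_000, 10_000, 1.0),  # statistic ties every permutation
            (0, 10_000, 10_000, 0.0002),  # floored at 2 / n_perm
            (500, 1500, 2000, 0.5),
        ],
    )
    def test_two_sided_min_count_formula(self, above, below, n_perm, expected):
        assert permutation_p(above, below, n_perm) == pytest.approx(expected)

    def test_never_zero_or_above_one(self):
        rng = np.random.default_rng(3)
        above = rng.integers(0, 1001, size=200)
        p = permutation_p(above, 1000 - above, 1000)
        assert (p > 0).all() and (p <= 1).all()


class TestStratifiedShuffle:
    def test_margins_preserved_exactly(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 6, size=200)
        strata = rng.integers(0, 3, size=200)
        perm = stratified_permutation(codes, strata, rng)
        for s in range(3):
            np.testing.assert_array_equal(
                np.bincount(codes[strata == s], minlength=6),
                np.bincount(perm[strata == s], minlength=6),
            )


class TestPermutationNull:
    def test_monte_carlo_p_within_binomial_ci_of_exhaustive_oracle(self):
        # 4 samples, one cell per compartment, the two GEPs in different
        # strata: the 4! x 4! within-stratum relabellings are exhaustively
        # enumerable, giving an exact two-sided permutation p
        a = np.array([0.5, 1.2, 2.0, 3.1])  # epithelial GEP, by sample
        b = np.array([1.1, 2.3, 3.4, 3.0])  # myeloid GEP, by sample
        W = pd.DataFrame(
            {"g1": np.r_[a, np.zeros(4)], "g2": np.r_[np.zeros(4), b]},
            index=[f"c{i}" for i in range(8)],
        )
        meta = _meta(
            ["s1", "s2", "s3", "s4"] * 2,
            ["epithelial"] * 4 + ["myeloid"] * 4,
        )
        comps = {"g1": "epithelial", "g2": "myeloid"}

        # exhaustive oracle, independent of the package machinery: with one
        # cell per sample every quantile equals the cell value, so the
        # statistic is atanh(pearson r) under each pair of relabellings
        def stat(x, y):
            return np.arctanh(np.clip(pearsonr(x, y).statistic, -CLIP, CLIP))

        true = stat(a, b)
        perms = [
            stat(a[list(p)], b[list(q)])
            for p in itertools.permutations(range(4))
            for q in itertools.permutations(range(4))
        ]
        above = sum(z >= true for z in perms)
        below = sum(z <= true for z in perms)
        pi = min(above, below) / len(perms)  # exact one-tail probability

        n_perm = 2000
        edges = permutation_null(W, meta, comps, n_perm=n_perm, seed=6, min_cells=1)
        p_mc = edges["p_value"].iloc[0]
        half_width = 2.576 * math.sqrt(pi * (1 - pi) / n_perm)
        assert abs(p_mc / 2 - pi) <= half_width + 1 / n_perm

    def test_null_p_values_are_superuniform(self):
        # no planted covariation: the fraction of small p-values stays near
        # the nominal level
        cfg = AtlasConfig(
            n_patients=15, samples_per_patient=2, cells_per_sample=20,
            n_genes=120, compartments=("epithelial",), k_true=6,
            within_hub_usage_correlation=0.0, sample_heterogeneity_sd=0.0,
            seed=21,
        )
        adata, _, truth = generate_atlas(cfg)
        W = pd.DataFrame(truth.W_true, index=adata.obs_names, columns=truth.gep_ids)
        edges = permutation_null(W, adata.obs, truth.gep_compartments,
                                 n_perm=400, seed=22)
        assert (edges["p_value"] <= 0.05).mean() <= 0.12

    def test_planted_hub_pairs_rank_first(self, locked_atlas, usage_frame):
        _, adata, _, truth = locked_atlas
        edges = permutation_null(usage_frame, adata.obs, truth.gep_compartments,
                                 n_perm=300, seed=7)
        hub = truth.hub_assignment_true
        same = edges.apply(lambda r: hub[r.gep_i] == hub[r.gep_j], axis=1)
        assert edges.loc[same, "z_mean_true"].median() > edges.loc[
            ~same, "z_mean_true"
        ].median()
        assert edges.loc[same, "r_adjusted"].mean() > 0.2

    def test_requires_minimum_permutations(self, usage_frame, locked_atlas):
        _, adata, _, truth = locked_atlas
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(usage_frame, adata.obs, truth.gep_compartments,
                             n_perm=10)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adj, sig = bh_adjust(np.array([0.05]), fdr=0.10)
        assert adj[0] == pytest.approx(0.05) and sig[0]

    def test_hand_computed_step_up(self):
        adj, _ = bh_adjust(np.array([0.01, 0.02, 0.04, 0.8]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.8], atol=1e-12)

    def test_equal_ps_map_to_themselves(self):
        adj, _ = bh_adjust(np.full(7, 0.3))
        np.testing.assert_allclose(adj, 0.3)

    def test_matches_reference_step_up_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            adj, _ = bh_adjust(p)
            m = p.size  # independent step-up implementation
            order = np.argsort(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(ranked, 1.0)
            np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_empty_and_invalid_inputs(self):
        adj, sig = bh_adjust(np.array([]))
        assert adj.size == 0 and sig.size == 0
        with pytest.raises(ValueError, match="p-values"):
            bh_adjust(np.array([0.0, 0.5]))


class TestSignedNetwork:
    def _edges(self, rows):
        df = pd.DataFrame(
            rows, columns=["gep_i", "gep_j", "z_mean_true", "significant"]
        )
        return df

    def test_no_significant_edges_gives_empty_graph(self):
        g = build_signed_network(self._edges([("a", "b", 0.5, False)]))
        assert g.number_of_edges() == 0

    def test_triangle_with_stored_weights(self):
        g = build_signed_network(
            self._edges(
                [("a", "b", 0.5, True), ("b", "c", 0.7, True), ("a", "c", 0.2, True)]
            )
        )
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3
        assert g["a"]["b"]["weight"] == pytest.approx(0.5)

    def test_negative_weights_preserved(self):
        g = build_signed_network(
            self._edges([("a", "b", -0.6, True), ("b", "c", 0.4, True)])
        )
        assert g["a"]["b"]["weight"] == pytest.approx(-0.6)


class TestDetectHubs:
    def _two_cliques(self):
        g = nx.Graph()
        for block, nodes in enumerate((list("abcd"), list("efgh"))):
            for u, v in itertools.combinations(nodes, 2):
                g.add_edge(u, v, weight=1.0)
        g.add_edge("a", "e", weight=-1.0)
        return g

    def test_two_positive_cliques_split_by_negative_bridge(self):
        part = detect_hubs(self._two_cliques(), seed=0)
        hubs = part.hubs()
        assert sorted(map(tuple, hubs.values())) == [
            tuple("abcd"), tuple("efgh"),
        ]

    def test_three_node_hub_never_split(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.1)
        g.add_edge("b", "c", weight=0.1)
        g.add_edge("a", "c", weight=-0.9)  # splitting would raise modularity
        part = detect_hubs(g, seed=0)
        sizes = sorted(len(v) for v in part.hubs().values())
        # the split rule applies only to hubs with MORE than three nodes, so
        # if the sweep put all three together they must stay together
        if sizes == [3]:
            assert len(part.hubs()) == 1

    def test_planted_three_hub_network_recovered(self):
        rng = np.random.default_rng(9)
        nodes = [f"n{i:02d}" for i in range(12)]
        truth = {n: i % 3 for i, n in enumerate(nodes)}
        g = nx.Graph()
        for u, v in itertools.combinations(nodes, 2):
            if truth[u] == truth[v]:
                g.add_edge(u, v, weight=0.8 + rng.normal(0, 0.05))
            else:
                g.add_edge(u, v, weight=-0.2 + rng.normal(0, 0.05))
        part = detect_hubs(g, seed=10)
        ari = adjusted_rand_score(
            [truth[n] for n in nodes], [part.assignment[n] for n in nodes]
        )
        assert ari == 1.0

    def test_invariant_to_node_relabelling(self):
        g = self._two_cliques()
        mapping = {n: f"x_{n}" for n in g.nodes}
        part1 = detect_hubs(g, seed=3)
        part2 = detect_hubs(nx.relabel_nodes(g, mapping), seed=3)
        blocks1 = sorted(sorted(v) for v in part1.hubs().values())
        blocks2 = sorted(sorted(n[2:] for n in v) for v in part2.hubs().values())
        assert blocks1 == blocks2

    def test_disconnected_components_handled(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("c", "d", weight=1.0)
        part = detect_hubs(g, seed=0)
        assert part.assignment["a"] == part.assignment["b"]
        assert part.assignment["c"] == part.assignment["d"]
        assert part.assignment["a"] != part.assignment["c"]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_hubs(nx.Graph(), seed=0)

    def test_signed_modularity_prefers_planted_partition(self):
        g = self._two_cliques()
        good = {n: 0 for n in "abcd"} | {n: 1 for n in "efgh"}
        bad = {n: i % 2 for i, n in enumerate("abcdefgh")}
        assert signed_modularity(g, good) > signed_modularity(g, bad)


@pytest.fixture(scope="module")
def enrichment():
    cfg = AtlasConfig(
        n_patients=20, samples_per_patient=2, cells_per_sample=25,
        n_genes=300, compartments=("epithelial", "myeloid"), k_true=10,
        inflammation_effect_geps=("pEP01", "pEP05", "pMY03"),
        inflammation_effect_size=1.2, seed=31,
    )
    adata, meta, truth = generate_atlas(cfg)
    W = pd.DataFrame(truth.W_true, index=adata.obs_names, columns=truth.gep_ids)
    act = activity_quantiles(W, adata.obs, truth.gep_compartments)
    return gep_inflammation_enrichment(act, meta), cfg


class TestInflammationEnrichment:
    def test_planted_effects_called_in_18_of_20_geps(self, enrichment):
        enr, cfg = enrichment
        affected = set(cfg.inflammation_effect_geps)
        correct = sum(
            bool(enr.loc[g, "significant"]) == (g in affected) for g in enr.index
        )
        assert correct >= 18

    def test_planted_shift_gives_positive_coefficient(self, enrichment):
        enr, cfg = enrichment
        assert (enr.loc[list(cfg.inflammation_effect_geps), "effect"] > 0).all()

    def test_constant_activity_untestable(self):
        vals = np.ones((8, 1, 5))
        act = _activity(vals, ["g1"])
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "patient_id": [f"p{i // 2}" for i in range(8)],
                "inflamed": [True, False] * 4,
                "age": 40, "sex": "F", "site": "AC",
                "disease_duration": 1.0, "treatment": "pre",
            }
        )
        enr = gep_inflammation_enrichment(act, meta)
        assert enr.loc["g1", "untestable"]
        assert not enr.loc["g1", "significant"]

    def test_requires_both_groups(self):
        act = _activity(np.ones((4, 1, 5)), ["g1"])
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(4)],
                "patient_id": ["p1", "p1", "p2", "p2"],
                "inflamed": [True] * 4,
            }
        )
        with pytest.raises(ValueError, match="noninflamed"):
            gep_inflammation_enrichment(act, meta)


def test_end_to_end_planted_inflammatory_hub_flagged():
    """Full synthetic run: the hub whose members all carry a planted
    inflammation shift is flagged inflammatory; the neutral hubs are not."""
    cfg = AtlasConfig(
        within_hub_usage_correlation=0.7,
        inflammation_effect_geps=("pEP01", "pEP04", "pMY01", "pMY04"),
        inflammation_effect_size=1.2, seed=1,
    )
    adata, meta, truth = generate_atlas(cfg)
    W = pd.DataFrame(truth.W_true, index=adata.obs_names, columns=truth.gep_ids)
    edges = permutation_null(W, adata.obs, truth.gep_compartments,
                             n_perm=500, seed=52)
    part = detect_hubs(build_signed_network(edges), seed=53)
    act = activity_quantiles(W, adata.obs, truth.gep_compartments)
    part = label_inflammatory(part, gep_inflammation_enrichment(act, meta))
    flagged = {h for h, f in part.inflammatory_flag.items() if f}
    hub_of = {h: set(m) for h, m in part.hubs().items()}
    planted = set(cfg.inflammation_effect_geps)
    assert len(flagged) == 1
    assert hub_of[flagged.pop()] == planted


class TestLabelInflammatory:
    def _enr(self, flags):
        return pd.DataFrame(
            {
                "significant": list(flags.values()),
                "effect": [1.0] * len(flags),
            },
            index=list(flags),
        )

    def test_half_is_not_inflammatory(self):
        part = HubPartition({g: 0 for g in "abcd"}, 0.0)
        enr = self._enr({"a": True, "b": True, "c": False, "d": False})
        assert label_inflammatory(part, enr).inflammatory_flag[0] is False

    def test_two_of_three_is_inflammatory(self):
        part = HubPartition({g: 0 for g in "abc"}, 0.0)
        enr = self._enr({"a": True, "b": True, "c": False})
        assert label_inflammatory(part, enr).inflammatory_flag[0] is True

    def test_negative_effects_do_not_count(self):
        part = HubPartition({g: 0 for g in "abc"}, 0.0)
        enr = self._enr({"a": True, "b": True, "c": False})
        enr["effect"] = [-1.0, 1.0, 1.0]
        assert label_inflammatory(part, enr).inflammatory_flag[0] is False

    def test_missing_enrichment_rejected(self):
        part = HubPartition({"a": 0, "b": 0}, 0.0)
        with pytest.raises(ValueError, match="without enrichment"):
            label_inflammatory(part, self._enr({"a": True}))
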