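"""Hubs of covarying gene expression programmes.

Per-sample GEP activity is summarised at five usage quantiles
(0.25, 0.5, 0.75, 0.95, 0.99). For every GEP pair, Pearson correlations
across samples are computed per quantile, Fisher-transformed, and averaged
into a single test statistic. Its null distribution comes from permuting
cells' sample labels (within each compartment, so cell-type composition is
held fixed); the two-sided p-value is twice the smaller tail count divided
by the number of permutations. After Benjamini-Hochberg correction
(FDR 10%), significant associations form a signed weighted network whose
communities — the hubs — are found by a resolution-swept signed-modularity
search with consensus thresholding and iterative splitting of large hubs.

An adjusted correlation (mean true r minus mean permuted r, on the
correlation scale) is reported per edge as an effect size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_QUANTILES",
    "ActivityTensor",
    "HubPartition",
    "activity_quantiles",
    "edge_statistic",
    "permutation_p",
    "permutation_null",
    "bh_adjust",
    "build_signed_network",
    "signed_modularity",
    "detect_hubs",
    "gep_inflammation_enrichment",
    "label_inflammatory",
]

DEFAULT_QUANTILES = (0.25, 0.5, 0.75, 0.95, 0.99)
_CLIP = 1.0 - 1e-7  # keeps atanh finite on degenerate perfect correlations


# ---------------------------------------------------------------------------
# activity summaries


@dataclass
class ActivityTensor:
    """Per-(sample, GEP, quantile) usage summaries.

    ``values`` is samples x GEPs x quantiles with NaN where a sample has no
    cells of the GEP's compartment; ``cell_counts`` records how many cells
    entered each (sample, GEP) summary and ``low_cell_flag`` marks entries
    built from fewer than the configured minimum.
    """

    values: np.ndarray
    sample_ids: list[str]
    gep_ids: list[str]
    quantiles: tuple[float, ...]
    gep_compartments: dict[str, str]
    cell_counts: np.ndarray
    low_cell_flag: np.ndarray

    def mean_activity(self) -> pd.DataFrame:
        """Mean of the quantile summaries per (sample, GEP) — the response
        used for inflammation-association testing."""
        return pd.DataFrame(
            self.values.mean(axis=2), index=self.sample_ids, columns=self.gep_ids
        )


def _quantiles_per_sample(
    usage: np.ndarray, codes: np.ndarray, n_samples: int, qs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical quantiles (linear interpolation) of each usage column within
    each sample. Returns (n_samples x k x n_q values, n_samples counts)."""
    k = usage.shape[1]
    out = np.full((n_samples, k, qs.size), np.nan)
    counts = np.zeros(n_samples, dtype=int)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    bounds = np.searchsorted(sorted_codes, np.arange(n_samples + 1))
    for s in range(n_samples):
        idx = order[bounds[s] : bounds[s + 1]]
        counts[s] = idx.size
        if idx.size:
            out[s] = np.quantile(usage[idx], qs, axis=0).T
    return out, counts


def activity_quantiles(
    W,
    cell_meta: pd.DataFrame,
    gep_compartments: dict[str, str],
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    min_cells: int = 10,
    sample_ids: list[str] | None = None,
) -> ActivityTensor:
    """Summarise per-cell GEP usage into per-sample activity quantiles.

    Each GEP's distribution is taken over the sample's cells belonging to
    that GEP's compartment only. ``W`` is a cells x GEPs DataFrame (or an
    array; then ``gep_compartments`` keys give the column order).
    """
    if isinstance(W, pd.DataFrame):
        gep_ids = list(W.columns)
        usage_all = W.to_numpy(dtype=float)
    else:
        gep_ids = list(gep_compartments)
        usage_all = np.asarray(W, dtype=float)
    if (usage_all < 0).any():
        raise ValueError("usage matrix must be non-negative")
    samples = cell_meta["sample_id"].astype(str).to_numpy()
    if sample_ids is None:
        sample_ids = list(pd.unique(samples))
    codes_all = pd.Index(sample_ids).get_indexer(samples)
    if (codes_all < 0).any():
        raise ValueError("cells reference sample ids missing from sample_ids")
    comps = cell_meta["compartment"].astype(str).to_numpy()
    qs = np.asarray(quantiles, dtype=float)

    n_s, n_g = len(sample_ids), len(gep_ids)
    values = np.full((n_s, n_g, qs.size), np.nan)
    cell_counts = np.zeros((n_s, n_g), dtype=int)
    for comp in pd.unique(comps):
        cols = [j for j, g in enumerate(gep_ids) if gep_compartments[g] == comp]
        if not cols:
            continue
        mask = comps == comp
        vals, counts = _quantiles_per_sample(
            usage_all[np.ix_(mask, cols)], codes_all[mask], n_s, qs
        )
        values[:, cols, :] = vals
        cell_counts[:, cols] = counts[:, None]
    missing = int(np.isnan(values[:, :, 0]).sum())
    if missing:
        logger.warning(
            "activity_quantiles: %d (sample, GEP) entries missing (no cells of "
            "the GEP's compartment in the sample)",
            missing,
        )
    return ActivityTensor(
        values=values,
        sample_ids=list(sample_ids),
        gep_ids=gep_ids,
        quantiles=tuple(qs.tolist()),
        gep_compartments=dict(gep_compartments),
        cell_counts=cell_counts,
        low_cell_flag=(cell_counts > 0) & (cell_counts < min_cells),
    )


# ---------------------------------------------------------------------------
# edge statistic


def _fisher_z_mean(r: np.ndarray) -> float:
    """Mean Fisher z over the non-NaN quantile correlations."""
    valid = ~np.isnan(r)
    if not valid.any():
        return float("nan")
    return float(np.mean(np.arctanh(np.clip(r[valid], -_CLIP, _CLIP))))


def edge_statistic(
    activity: ActivityTensor,
    gep_i: str,
    gep_j: str,
    samples: list[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Pearson r per quantile across samples for one GEP pair, and the mean
    Fisher-z statistic. Samples missing either activity are dropped; a
    zero-variance quantile yields NaN r and is excluded from the mean."""
    i = activity.gep_ids.index(gep_i)
    j = activity.gep_ids.index(gep_j)
    a = activity.values[:, i, :]
    b = activity.values[:, j, :]
    if samples is not None:
        rows = [activity.sample_ids.index(s) for s in samples]
        a, b = a[rows], b[rows]
    shared = ~(np.isnan(a[:, 0]) | np.isnan(b[:, 0]))
    if shared.sum() < 3:
        raise ValueError("need at least 3 shared samples with activity values")
    a, b = a[shared], b[shared]
    n_q = a.shape[1]
    r = np.full(n_q, np.nan)
    for q in range(n_q):
        x, y = a[:, q], b[:, q]
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning(
                "zero-variance activity at quantile %s for (%s, %s); excluded",
                activity.quantiles[q], gep_i, gep_j,
            )
            continue
        r[q] = np.corrcoef(x, y)[0, 1]
    return r, _fisher_z_mean(r)


# ---------------------------------------------------------------------------
# permutation test


def permutation_p(count_above: np.ndarray, count_below: np.ndarray, n_perm: int):
    """Two-sided permutation p-value: twice the smaller tail count over the
    number of permutations (ties counted on both sides), floored at
    ``2 / n_perm`` so no p-value is exactly zero, and capped at 1."""
    raw = 2 * np.minimum(count_above, count_below)
    return np.minimum(1.0, np.maximum(raw, 2) / n_perm)


def stratified_permutation(
    codes: np.ndarray, strata: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle sample codes within each stratum; per-stratum sample-size
    margins are preserved exactly."""
    out = codes.copy()
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        out[idx] = out[idx[rng.permutation(idx.size)]]
    return out


def _corr_z(A: np.ndarray) -> np.ndarray:
    """Mean-over-quantile Fisher-z correlation matrices.

    ``A`` is (..., samples, geps, quantiles); returns (..., geps, geps).
    Zero-variance (gep, quantile) columns are excluded from the mean per
    pair, matching :func:`edge_statistic`.
    """
    n_s = A.shape[-3]
    mean = A.mean(axis=-3, keepdims=True)
    sd = A.std(axis=-3, keepdims=True)
    ok = np.broadcast_to(sd > 0, A.shape)
    Z = np.where(ok, (A - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    # correlation per quantile: (..., q, g, g)
    r = np.einsum("...sgq,...shq->...qgh", Z, Z) / n_s
    valid = ok[..., 0, :, :]  # (..., g, q) variance indicator
    pair_valid = np.einsum("...gq,...hq->...qgh", valid, valid.astype(float))
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    z = np.where(pair_valid > 0, z, 0.0)
    denom = pair_valid.sum(axis=-3)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, z.sum(axis=-3) / denom, np.nan)


def permutation_null(
    W,
    cell_meta: pd.DataFrame,
    gep_compartments: dict[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    fdr: float = 0.10,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Permutation test of GEP-pair activity covariation.

    Cells' sample labels are shuffled ``n_perm`` times within each
    compartment stratum, the quantile summaries and the mean Fisher-z
    statistic are recomputed, and each pair's two-sided p-value is
    ``max(2 * min(#above, #below), 2) / n_perm`` where the counts include
    ties on both sides. BH adjustment at ``fdr`` and the adjusted
    correlation are included in the returned edge table.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    act = activity_quantiles(
        W, cell_meta, gep_compartments, quantiles=quantiles, min_cells=min_cells
    )
    gep_ids = act.gep_ids
    n_s, n_g, n_q = act.values.shape
    usage_all = (
        W.to_numpy(dtype=float) if isinstance(W, pd.DataFrame) else np.asarray(W, float)
    )
    samples = cell_meta["sample_id"].astype(str).to_numpy()
    codes_all = pd.Index(act.sample_ids).get_indexer(samples)
    comps = cell_meta["compartment"].astype(str).to_numpy()
    qs = np.asarray(quantiles, dtype=float)
    rng = np.random.default_rng(seed)

    comp_counts = (
        pd.DataFrame({"c": comps, "s": samples}).groupby("c")["s"].nunique()
    )
    thin = comp_counts[comp_counts < 2]
    if len(thin):
        logger.warning(
            "strata with < 2 samples; pairs in these compartments are untestable: %s",
            list(thin.index),
        )

    # permuted activity tensors, built compartment by compartment
    A_perm = np.full((n_perm, n_s, n_g, n_q), np.nan)
    for comp in pd.unique(comps):
        cols = [j for j, g in enumerate(gep_ids) if gep_compartments[g] == comp]
        mask = comps == comp
        usage = usage_all[np.ix_(mask, cols)]
        codes = codes_all[mask]
        for p in range(n_perm):
            perm_codes = codes[rng.permutation(codes.size)]
            vals, _ = _quantiles_per_sample(usage, perm_codes, n_s, qs)
            A_perm[p][:, cols, :] = vals

    z_true = _corr_z(act.values)
    z_perm = _corr_z(A_perm)  # n_perm x g x g

    # tail counts, two-sided, ties counted on both sides
    above = (z_perm >= z_true).sum(axis=0)
    below = (z_perm <= z_true).sum(axis=0)
    p = permutation_p(above, below, n_perm)

    # adjusted correlation on the r scale: mean true r minus mean permuted r
    def _mean_r(A):
        n_smp = A.shape[-3]
        mean = A.mean(axis=-3, keepdims=True)
        sd = A.std(axis=-3, keepdims=True)
        Z = np.where(sd > 0, (A - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        r = np.einsum("...sgq,...shq->...qgh", Z, Z) / n_smp
        return r.mean(axis=-3)

    r_true_mean = _mean_r(act.values)
    r_perm_mean = _mean_r(A_perm).mean(axis=0)
    r_adjusted = r_true_mean - r_perm_mean

    # per-quantile true correlations for reporting
    r_true_q = np.stack(
        [
            _mean_r(act.values[:, :, q : q + 1])
            for q in range(n_q)
        ],
        axis=0,
    )  # n_q x g x g

    testable = act.cell_counts.min(axis=0) > 0
    rows = []
    for i in range(n_g):
        for j in range(i + 1, n_g):
            row = {
                "gep_i": gep_ids[i],
                "gep_j": gep_ids[j],
                "z_mean_true": z_true[i, j],
                "z_mean_perm": z_perm[:, i, j].mean(),
                "p_value": p[i, j],
                "r_adjusted": r_adjusted[i, j],
                "testable": bool(testable[i] and testable[j]),
            }
            for qi, q in enumerate(quantiles):
                row[f"r_q{q}"] = r_true_q[qi, i, j]
            rows.append(row)
    edges = pd.DataFrame(rows)
    adj, sig = bh_adjust(edges["p_value"].to_numpy(), fdr=fdr)
    edges["p_adjusted"] = adj
    edges["significant"] = sig
    return edges


def bh_adjust(
    p_values: np.ndarray, fdr: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and the mask of
    discoveries at the given FDR."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p_values <= 0) | (p_values > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p_values, method="fdr_bh")
    return p_adj, p_adj <= fdr


# ---------------------------------------------------------------------------
# signed network and hub detection


def build_signed_network(edges: pd.DataFrame, significant_only: bool = True) -> nx.Graph:
    """Graph of significant GEP associations, edge weight = signed mean
    Fisher z of the true statistic. Negative associations are kept with
    negative weights."""
    g = nx.Graph()
    sub = edges[edges["significant"]] if significant_only else edges
    for rec in sub.itertuples(index=False):
        g.add_edge(rec.gep_i, rec.gep_j, weight=float(rec.z_mean_true))
    return g


@dataclass
class HubPartition:
    assignment: dict[str, int]
    modularity: float
    inflammatory_flag: dict[int, bool] = field(default_factory=dict)

    def hubs(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, h in self.assignment.items():
            out.setdefault(h, []).append(node)
        return {h: sorted(v) for h, v in out.items()}


def signed_modularity(graph: nx.Graph, assignment: dict[str, int]) -> float:
    """Signed modularity: the positive subgraph's modularity and the
    negative subgraph's modularity (each with its own configuration-model
    null strength) combined with weights proportional to their total edge
    strength, the negative part entering with a minus sign."""
    w_pos = w_neg = 0.0
    q_pos = q_neg = 0.0
    for sign in (+1, -1):
        sub = nx.Graph()
        sub.add_nodes_from(graph.nodes)
        for u, v, d in graph.edges(data=True):
            w = d["weight"] * sign
            if w > 0:
                sub.add_edge(u, v, weight=w)
        tot = sub.size(weight="weight")
        if tot == 0:
            continue
        comms: dict[int, set] = {}
        for node, h in assignment.items():
            comms.setdefault(h, set()).add(node)
        q = nx.algorithms.community.modularity(
            sub, comms.values(), weight="weight"
        )
        if sign > 0:
            w_pos, q_pos = tot, q
        else:
            w_neg, q_neg = tot, q
    denom = w_pos + w_neg
    if denom == 0:
        return 0.0
    return (w_pos * q_pos - w_neg * q_neg) / denom


def _signed_leiden(
    nodes: list[str],
    edges: list[tuple[str, str, float]],
    resolution: float,
    seed: int,
) -> dict[str, int]:
    """One signed-modularity Leiden run: positive and negative edge layers
    optimised jointly with layer weights (+1, -1)."""
    index = {n: i for i, n in enumerate(nodes)}
    g_pos = ig.Graph(n=len(nodes))
    g_neg = ig.Graph(n=len(nodes))
    pos_w, neg_w = [], []
    for u, v, w in edges:
        if w > 0:
            g_pos.add_edge(index[u], index[v])
            pos_w.append(w)
        elif w < 0:
            g_neg.add_edge(index[u], index[v])
            neg_w.append(-w)
    part_pos = la.RBConfigurationVertexPartition(
        g_pos, weights=pos_w or None, resolution_parameter=resolution
    )
    part_neg = la.RBConfigurationVertexPartition(
        g_neg, weights=neg_w or None, resolution_parameter=resolution
    )
    opt = la.Optimiser()
    opt.set_rng_seed(seed)
    opt.optimise_partition_multiplex([part_pos, part_neg], layer_weights=[1, -1])
    return {n: part_pos.membership[index[n]] for n in nodes}


def detect_hubs(
    graph: nx.Graph,
    resolution_range: tuple[float, float] = (0.001, 0.2),
    n_resolutions: int = 40,
    tau: float = 0.2,
    seed: int = 0,
) -> HubPartition:
    """Resolution-swept signed community detection with consensus and
    iterative splitting.

    A signed Leiden search runs at each of ``n_resolutions`` log-spaced
    resolutions; node pairs co-clustered in at least a ``tau`` fraction of
    the sweep are linked, and connected components of that consensus graph
    form the initial hubs. Hubs larger than three nodes are then
    recursively re-partitioned, each split kept only if it strictly
    improves total signed modularity. Deterministic given ``seed``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes)
    edges = [(u, v, float(d["weight"])) for u, v, d in graph.edges(data=True)]

    res_grid = np.logspace(
        np.log10(resolution_range[0]), np.log10(resolution_range[1]), n_resolutions
    )
    n = len(nodes)
    co = np.zeros((n, n))
    for ri, res in enumerate(res_grid):
        memb = _signed_leiden(nodes, edges, float(res), seed=seed + ri)
        lab = np.array([memb[x] for x in nodes])
        co += lab[:, None] == lab[None, :]
    co /= len(res_grid)

    consensus = nx.Graph()
    consensus.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if co[i, j] >= tau:
                consensus.add_edge(nodes[i], nodes[j])
    assignment: dict[str, int] = {}
    for hid, comp in enumerate(nx.connected_components(consensus)):
        for node in comp:
            assignment[node] = hid

    # iterative splitting of hubs with more than three nodes
    improved = True
    round_no = 0
    while improved:
        improved = False
        round_no += 1
        current_q = signed_modularity(graph, assignment)
        for hid, members in sorted(HubPartition(assignment, current_q).hubs().items()):
            if len(members) <= 3:
                continue
            sub_edges = [
                (u, v, w) for u, v, w in edges if u in members and v in members
            ]
            memb = _signed_leiden(
                sorted(members), sub_edges, resolution=1.0, seed=seed + 1000 * round_no + hid
            )
            if len(set(memb.values())) < 2:
                continue
            trial = dict(assignment)
            base = max(assignment.values()) + 1
            for node, sub_h in memb.items():
                trial[node] = base + sub_h
            if signed_modularity(graph, trial) > current_q + 1e-12:
                assignment = trial
                improved = True
                break

    # relabel hubs to consecutive ids ordered by sorted member lists
    hubs = HubPartition(assignment, 0.0).hubs()
    order = sorted(hubs, key=lambda h: hubs[h])
    remap = {old: new for new, old in enumerate(order)}
    assignment = {node: remap[h] for node, h in assignment.items()}
    return HubPartition(
        assignment=assignment, modularity=signed_modularity(graph, assignment)
    )


# ---------------------------------------------------------------------------
# inflammation enrichment and hub labelling


def gep_inflammation_enrichment(
    activity: ActivityTensor,
    sample_meta: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Association of per-sample mean GEP activity with inflammation status.

    Fits, per GEP, a linear mixed model of the mean quantile activity on
    inflammation status with age, sex, site, disease duration and treatment
    as fixed effects and a random intercept per patient; falls back to OLS
    with the same fixed effects when the mixed fit fails to converge.
    P-values (inflamed term) are BH-adjusted across GEPs.
    """
    meta = sample_meta.set_index("sample_id")
    infl = meta["inflamed"].astype(bool)
    if infl.sum() < 2 or (~infl).sum() < 2:
        raise ValueError("need >= 2 inflamed and >= 2 noninflamed samples")
    response = activity.mean_activity()

    covars = []
    for c, cat in [("age", False), ("sex", True), ("site", True),
                   ("disease_duration", False), ("treatment", True)]:
        if c in meta.columns and meta.loc[response.index, c].nunique() > 1:
            covars.append(f"C({c})" if cat else c)
    fixed = " + ".join(["inflamed_int"] + covars)

    rows = []
    for gep in response.columns:
        df = pd.DataFrame(
            {
                "y": response[gep],
                "inflamed_int": infl.loc[response.index].astype(int),
                "patient": meta.loc[response.index, "patient_id"],
            }
        )
        for c in ("age", "sex", "site", "disease_duration", "treatment"):
            if c in meta.columns:
                df[c] = meta.loc[response.index, c].values
        df = df.dropna(subset=["y"])
        if df["y"].nunique() <= 1:
            rows.append({"gep_id": gep, "effect": 0.0, "p_value": np.nan,
                         "untestable": True})
            continue
        formula = f"y ~ {fixed}"
        effect = p = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(formula, df, groups=df["patient"]).fit(reml=False)
            if np.isfinite(res.pvalues.get("inflamed_int", np.nan)):
                effect = float(res.params["inflamed_int"])
                p = float(res.pvalues["inflamed_int"])
        except Exception:  # singular / non-converged mixed fit
            pass
        if p is None:
            logger.warning("mixed model failed for %s; falling back to OLS", gep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.ols(formula, df).fit()
            effect = float(res.params["inflamed_int"])
            p = float(res.pvalues["inflamed_int"])
        rows.append({"gep_id": gep, "effect": effect, "p_value": p,
                     "untestable": False})
    out = pd.DataFrame(rows).set_index("gep_id")
    testable = ~out["untestable"] & out["p_value"].notna()
    out["p_adjusted"] = np.nan
    if testable.any():
        adj, _ = bh_adjust(out.loc[testable, "p_value"].to_numpy(), fdr=fdr)
        out.loc[testable, "p_adjusted"] = adj
    out["significant"] = (out["p_adjusted"] <= fdr).fillna(False)
    return out


def label_inflammatory(
    hubs: HubPartition, enrichment: pd.DataFrame
) -> HubPartition:
    """Flag a hub inflammatory iff strictly more than half of its member
    GEPs are significantly enriched with a positive inflammation effect."""
    missing = set(hubs.assignment) - set(enrichment.index)
    if missing:
        raise ValueError(f"hub members without enrichment results: {sorted(missing)}")
    enriched = enrichment["significant"] & (enrichment["effect"] > 0)
    flags = {}
    for hid, members in hubs.hubs().items():
        frac = enriched.loc[members].mean()
        flags[hid] = bool(frac > 0.5)
    hubs.inflammatory_flag = flags
    return hubs
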