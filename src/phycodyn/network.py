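"""Bipartite bacteria-eukaryote co-occurrence network inference.

Every pair of a dominant bacterial and a dominant eukaryotic taxon is scored
with an ensemble of four association measures over the shared sampling dates:
Pearson and Spearman correlation, Bray-Curtis dissimilarity, and symmetrised
Kullback-Leibler divergence on pseudocounted, renormalised profiles.
Per-method significance comes from sample-permutation nulls and stability from
bootstrap resampling (1000 iterations each by default, ReBoot style); an edge
is kept when at least ``min_methods`` methods agree on its direction at
p < alpha with a bootstrap interval clear of the null centre.  Positive
association (high correlation, low dissimilarity) is a co-occurrence edge,
negative a mutual-exclusion edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METHODS = ("pearson", "spearman", "braycurtis", "kl")
#: Methods where a LOW score means similarity (association sign is inverted).
DISSIMILARITY_METHODS = frozenset({"braycurtis", "kl"})


@dataclass
class EdgeCandidate:
    """One bacterium-eukaryote pair with per-method evidence."""

    bac: str
    euk: str
    scores: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    null_mean: dict = field(default_factory=dict)
    null_sd: dict = field(default_factory=dict)
    boot_interval: dict = field(default_factory=dict)
    boot_ok: dict = field(default_factory=dict)
    signs: dict = field(default_factory=dict)

    def supporting_methods(self, alpha: float = 0.05) -> list[str]:
        return [
            m
            for m in self.scores
            if self.p_values.get(m) is not None
            and self.p_values[m] < alpha
            and self.boot_ok.get(m, False)
        ]


@dataclass
class EdgeCandidateSet:
    """Aligned profile matrices plus the scored candidate pairs."""

    bac_profiles: pd.DataFrame
    euk_profiles: pd.DataFrame
    candidates: list[EdgeCandidate]
    pseudocount: float


@dataclass
class BipartiteNetwork:
    """Signed bacteria-eukaryote association graph."""

    graph: nx.Graph
    n_dropped_discordant: int = 0

    @property
    def co_occurrence_count(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] > 0)

    @property
    def mutual_exclusion_count(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] < 0)


@dataclass
class NetworkIndices:
    """The standard index set reported for bipartite co-occurrence networks."""

    n_nodes: int
    interaction: int
    co_occurrence: int
    mutual_exclusion: int
    density: float
    average_degree: float
    degree_heterogeneity: float
    degree_centralization: float
    modularity: float
    n_components: int
    diameter: int
    average_path_length: float


def _pseudocount_normalise(v: np.ndarray, pseudocount: float) -> np.ndarray:
    w = v + pseudocount
    return w / w.sum()


def kl_divergence(x: np.ndarray, y: np.ndarray, pseudocount: float = 1e-6) -> float:
    """Symmetrised Kullback-Leibler divergence between two abundance vectors.

    Both vectors are pseudocounted and renormalised to probability vectors
    first (raw zeros make KL undefined); the symmetrised form is
    0.5 * (KL(p||q) + KL(q||p)).
    """
    p = _pseudocount_normalise(np.asarray(x, dtype=float), pseudocount)
    q = _pseudocount_normalise(np.asarray(y, dtype=float), pseudocount)
    return float(0.5 * np.sum((p - q) * (np.log(p) - np.log(q))))


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.sum(x + y)
    return float(np.sum(np.abs(x - y)) / denom) if denom > 0 else np.nan


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.sum(Xc * Yc, axis=1)
    den = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(Yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _rowwise_braycurtis(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    denom = np.sum(X + Y, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sum(np.abs(X - Y), axis=1) / denom


def _rowwise_kl(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return 0.5 * np.sum((P - Q) * (np.log(P) - np.log(Q)), axis=1)


def _method_score(method: str, x: np.ndarray, y: np.ndarray, pseudocount: float) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "braycurtis":
        return _bray_curtis(x, y)
    if method == "kl":
        return kl_divergence(x, y, pseudocount)
    raise ValueError(f"unknown method {method!r}")


def score_edges(
    bac_profiles: pd.DataFrame,
    euk_profiles: pd.DataFrame,
    pseudocount: float = 1e-6,
) -> EdgeCandidateSet:
    """Score every bacterial x eukaryotic taxon pair with the method ensemble.

    Profiles are samples x taxa relative abundances of taxa already filtered
    at the dominance threshold; a pooled "other" column, if present, is
    excluded.  Requires >=5 shared samples.  Pairs involving a constant vector
    skip the correlation methods (undefined) with a log record.
    """
    bac = bac_profiles[[c for c in bac_profiles.columns if c != "other"]]
    euk = euk_profiles[[c for c in euk_profiles.columns if c != "other"]]
    shared = bac.index.intersection(euk.index)
    if len(shared) < 5:
        raise ValueError("need >=5 shared samples for network scoring")
    bac = bac.loc[shared]
    euk = euk.loc[shared]
    candidates = []
    for b in bac.columns:
        x = bac[b].values.astype(float)
        for e in euk.columns:
            y = euk[e].values.astype(float)
            cand = EdgeCandidate(bac=b, euk=e)
            constant = np.ptp(x) == 0 or np.ptp(y) == 0
            for m in METHODS:
                if constant and m in ("pearson", "spearman"):
                    logger.info("pair (%s, %s): constant vector, %s skipped", b, e, m)
                    continue
                cand.scores[m] = _method_score(m, x, y, pseudocount)
            candidates.append(cand)
    return EdgeCandidateSet(
        bac_profiles=bac, euk_profiles=euk, candidates=candidates, pseudocount=pseudocount
    )


def _null_scores(
    method: str, x: np.ndarray, y: np.ndarray, perm_idx: np.ndarray, pseudocount: float
) -> np.ndarray:
    """Scores of x against row-wise permutations of y."""
    B = perm_idx.shape[0]
    Yp = y[perm_idx]
    X = np.broadcast_to(x, (B, x.size))
    if method == "pearson":
        return _rowwise_pearson(X, Yp)
    if method == "spearman":
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        return _rowwise_pearson(np.broadcast_to(rx, (B, x.size)), ry[perm_idx])
    if method == "braycurtis":
        return _rowwise_braycurtis(X, Yp)
    if method == "kl":
        p = _pseudocount_normalise(x, pseudocount)
        q = _pseudocount_normalise(y, pseudocount)
        return _rowwise_kl(np.broadcast_to(p, (B, x.size)), q[perm_idx])
    raise ValueError(method)


def _boot_scores(
    method: str, x: np.ndarray, y: np.ndarray, boot_idx: np.ndarray, pseudocount: float
) -> np.ndarray:
    Xb = x[boot_idx]
    Yb = y[boot_idx]
    if method == "pearson":
        return _rowwise_pearson(Xb, Yb)
    if method == "spearman":
        return _rowwise_pearson(stats.rankdata(Xb, axis=1), stats.rankdata(Yb, axis=1))
    if method == "braycurtis":
        return _rowwise_braycurtis(Xb, Yb)
    if method == "kl":
        P = (Xb + pseudocount) / (Xb + pseudocount).sum(axis=1, keepdims=True)
        Q = (Yb + pseudocount) / (Yb + pseudocount).sum(axis=1, keepdims=True)
        return _rowwise_kl(P, Q)
    raise ValueError(method)


def reboot_significance(
    cands: EdgeCandidateSet,
    n_iter: int = 1000,
    seed: int | None = None,
) -> EdgeCandidateSet:
    """Permutation p-values and bootstrap stability intervals per method.

    The null for each method permutes one taxon's values across samples
    (``n_iter`` draws); the two-sided p-value is the fraction of null scores
    at least as far from the null mean as the observed score (add-one
    corrected).  Bootstrap resampling of samples (``n_iter`` draws) gives a
    95% percentile interval; a method only supports the edge when that
    interval does not cross the null centre.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    n = len(cands.bac_profiles)
    if n < 5:
        raise ValueError("too few samples for resampling (<5)")
    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_iter)])
    boot_idx = rng.integers(0, n, size=(n_iter, n))
    for cand in cands.candidates:
        x = cands.bac_profiles[cand.bac].values.astype(float)
        y = cands.euk_profiles[cand.euk].values.astype(float)
        for m, obs in cand.scores.items():
            null = _null_scores(m, x, y, perm_idx, cands.pseudocount)
            null = null[np.isfinite(null)]
            if null.size == 0 or not np.isfinite(obs):
                continue
            mu = float(null.mean())
            sd = float(null.std(ddof=0))
            dev = abs(obs - mu)
            p = (1 + int(np.sum(np.abs(null - mu) >= dev - 1e-12))) / (null.size + 1)
            boot = _boot_scores(m, x, y, boot_idx, cands.pseudocount)
            boot = boot[np.isfinite(boot)]
            if boot.size < n_iter // 2:
                continue
            lo, hi = np.percentile(boot, [2.5, 97.5])
            if m in DISSIMILARITY_METHODS:
                sign = 1 if obs < mu else -1
            else:
                sign = 1 if obs >= 0 else -1
            cand.p_values[m] = float(p)
            cand.null_mean[m] = mu
            cand.null_sd[m] = sd
            cand.boot_interval[m] = (float(lo), float(hi))
            cand.boot_ok[m] = not (lo <= mu <= hi)
            cand.signs[m] = sign
    return cands


def build_network(
    cands: EdgeCandidateSet,
    min_methods: int = 2,
    alpha: float = 0.05,
) -> BipartiteNetwork:
    """Merge per-method evidence into a signed bipartite graph.

    An edge is kept when >= ``min_methods`` methods pass (p < alpha and a
    stable bootstrap interval) with a concordant direction; discordant
    supported directions drop the edge (counted).  The edge score is the mean
    null-standardised deviation across supporting methods, signed so that
    positive means co-occurrence.
    """
    G = nx.Graph()
    for col in cands.bac_profiles.columns:
        G.add_node(col, domain="bacteria", mean_abundance=float(cands.bac_profiles[col].mean()))
    for col in cands.euk_profiles.columns:
        G.add_node(col, domain="eukaryote", mean_abundance=float(cands.euk_profiles[col].mean()))
    dropped = 0
    for cand in cands.candidates:
        support = cand.supporting_methods(alpha)
        if len(support) < min_methods:
            continue
        signs = {cand.signs[m] for m in support}
        if len(signs) > 1:
            dropped += 1
            logger.info("edge (%s, %s) dropped: discordant directions", cand.bac, cand.euk)
            continue
        sign = signs.pop()
        z_values = []
        for m in support:
            sd = cand.null_sd[m]
            z = (cand.scores[m] - cand.null_mean[m]) / sd if sd > 0 else 0.0
            if m in DISSIMILARITY_METHODS:
                z = -z
            z_values.append(z)
        G.add_edge(
            cand.bac,
            cand.euk,
            sign=sign,
            score=float(np.mean(z_values)),
            p=float(min(cand.p_values[m] for m in support)),
            methods=",".join(sorted(support)),
        )
    return BipartiteNetwork(graph=G, n_dropped_discordant=dropped)


def network_indices(net: BipartiteNetwork | nx.Graph) -> NetworkIndices:
    """The index set of a (bipartite) association network.

    density = 2E/(N(N-1)); average degree = 2E/N; heterogeneity = coefficient
    of variation of the degree distribution (population sd); centralization =
    sum(kmax - k_i) / ((N-1)(N-2)); modularity of the best greedy
    agglomerative partition; diameter and average path length on the largest
    connected component (disconnected pairs are ignored).
    """
    G = net.graph if isinstance(net, BipartiteNetwork) else net
    N = G.number_of_nodes()
    E = G.number_of_edges()
    if N == 0:
        raise ValueError("empty graph")
    degrees = np.array([d for _, d in G.degree()], dtype=float)
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std(ddof=0) / mean_deg) if mean_deg > 0 else float("nan")
    if N > 2:
        centralization = float((degrees.max() - degrees).sum() / ((N - 1) * (N - 2)))
    else:
        centralization = float("nan")
    if E > 0:
        communities = nx.community.greedy_modularity_communities(G)
        modularity = float(nx.community.modularity(G, communities))
    else:
        modularity = float("nan")
    components = list(nx.connected_components(G))
    largest = max(components, key=len)
    sub = G.subgraph(largest)
    if len(largest) > 1:
        diameter = int(nx.diameter(sub))
        apl = float(nx.average_shortest_path_length(sub))
    else:
        diameter = 0
        apl = float("nan")
    if isinstance(net, BipartiteNetwork):
        co = net.co_occurrence_count
        mx = net.mutual_exclusion_count
    else:
        co = sum(1 for _, _, d in G.edges(data=True) if d.get("sign", 1) > 0)
        mx = E - co
    return NetworkIndices(
        n_nodes=N,
        interaction=E,
        co_occurrence=co,
        mutual_exclusion=mx,
        density=float(nx.density(G)),
        average_degree=float(2 * E / N),
        degree_heterogeneity=heterogeneity,
        degree_centralization=centralization,
        modularity=modularity,
        n_components=len(components),
        diameter=diameter,
        average_path_length=apl,
    )


def edge_list(net: BipartiteNetwork) -> pd.DataFrame:
    """Tidy edge list (source, target, sign, score, p, methods)."""
    rows = [
        {"source": u, "target": v, "sign": d["sign"], "score": d["score"], "p": d["p"],
         "methods": d["methods"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "sign", "score", "p", "methods"])
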