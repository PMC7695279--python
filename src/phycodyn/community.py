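"""OTU-table statistics: dominance profiles, richness, Bray-Curtis clustering
with similarity-profile (SIMPROF) shift detection, and correlation screening.

The campaign question these routines answer is whether, and when, the
eukaryotic and bacterial communities of the two reactors changed
significantly, and which environmental covariates track the dominant taxa.
Dominant taxa are defined by relative-abundance thresholds (1% at species
level for eukaryotes, 10% at genus level for bacteria); community shifts are
detected by hierarchical (UPGMA) clustering of Bray-Curtis dissimilarities
combined with Clarke's similarity-profile permutation test; taxon-environment
association uses the tie-corrected Kendall tau-b against 7-day-preceding
covariate means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

RANK_PREFIX = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
}
RANK_ORDER = list(RANK_PREFIX)


@dataclass
class OtuTable:
    """Samples x OTUs counts with taxonomy lineages.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, rows = samples, columns = OTU ids.
    lineages : pandas.Series
        Rank-prefixed lineage string per OTU (``k__...;p__...;...``); missing
        ranks read as "unclassified".
    marker : str
        Amplicon marker, "16S" or "ITS".
    domains : pandas.Series, optional
        Domain label per OTU ("bacteria" | "eukaryote"); inferred from the
        marker when absent.
    sample_times : pandas.Series, optional
        Campaign day per sample, aligned to the physicochemical series.
    """

    counts: pd.DataFrame
    lineages: pd.Series
    marker: str = "16S"
    domains: pd.Series | None = None
    sample_times: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("sample ids must be unique")
        missing = self.counts.columns.difference(self.lineages.index)
        if len(missing):
            raise ValueError(f"OTUs without lineage: {list(missing)[:5]}")
        self.lineages = self.lineages.reindex(self.counts.columns)
        if self.domains is None:
            default = "bacteria" if self.marker == "16S" else "eukaryote"
            self.domains = pd.Series(default, index=self.counts.columns)
        else:
            self.domains = self.domains.reindex(self.counts.columns)

    def taxon_at_rank(self, rank: str) -> pd.Series:
        """Resolve each OTU's name at a taxonomic rank ("unclassified" fill)."""
        if rank == "otu":
            return pd.Series(self.counts.columns, index=self.counts.columns)
        prefix = RANK_PREFIX.get(rank)
        if prefix is None:
            raise ValueError(f"unknown rank {rank!r}")
        names = {}
        for otu, lin in self.lineages.items():
            name = "unclassified"
            for part in str(lin).split(";"):
                part = part.strip()
                if part.startswith(prefix + "__"):
                    val = part[len(prefix) + 2:].strip()
                    if val:
                        name = val
                    break
            names[otu] = name
        return pd.Series(names)


@dataclass
class AbundanceProfile:
    """Per-sample relative abundances of retained (dominant) taxa.

    ``data`` holds retained taxa plus a pooled residual column "other"; rows
    sum to 1 within floating tolerance.
    """

    data: pd.DataFrame
    rank: str
    threshold: float
    criterion: str = "max"

    @property
    def taxa(self) -> list[str]:
        return [c for c in self.data.columns if c != "other"]


@dataclass
class SharedPartition:
    """Dominant-OTU overlap between two reactors for one category."""

    total: int
    shared: int
    only_a: int
    only_b: int
    members_shared: set = field(default_factory=set)
    members_only_a: set = field(default_factory=set)
    members_only_b: set = field(default_factory=set)

    def __post_init__(self) -> None:
        assert self.shared + self.only_a + self.only_b == self.total


@dataclass
class SimprofNode:
    """One tested dendrogram node."""

    node_id: int
    n_leaves: int
    pi: float
    p_value: float
    significant: bool


@dataclass
class SimprofResult:
    """Dendrogram with similarity-profile tests and significant groups."""

    linkage_matrix: np.ndarray
    sample_ids: list
    nodes: list[SimprofNode]
    groups: list[list]

    def group_of(self) -> pd.Series:
        labels = {}
        for g, members in enumerate(self.groups):
            for m in members:
                labels[m] = g
        return pd.Series(labels).reindex(self.sample_ids)


@dataclass
class CorrelationScreen:
    """Kendall tau-b taxa x covariate screen with a significance mask."""

    tau: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    flagged_constant: list[tuple[str, str]] = field(default_factory=list)


def relative_abundance(
    table: OtuTable,
    rank: str = "otu",
    threshold: float = 0.01,
    criterion: str = "max",
) -> AbundanceProfile:
    """Normalise, aggregate to a rank, and keep the dominant taxa.

    Each sample is divided by its total count (classified + unclassified),
    OTUs are aggregated to ``rank`` by summing, and a taxon is retained when
    its relative abundance exceeds ``threshold`` in at least one sample
    (``criterion="max"``, default) or on campaign average (``"mean"``).  The
    residual is pooled into an "other" column so rows still sum to 1.
    """
    if table.counts.empty:
        raise ValueError("empty OTU table")
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total counts: {bad}")
    rel = table.counts.div(totals, axis=0)
    names = table.taxon_at_rank(rank)
    agg = rel.T.groupby(names).sum().T
    if criterion == "max":
        keep = agg.columns[(agg > threshold).any(axis=0)]
    elif criterion == "mean":
        keep = agg.columns[agg.mean(axis=0) > threshold]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    retained = agg[list(keep)]
    other = 1.0 - retained.sum(axis=1)
    data = retained.copy()
    data["other"] = other.clip(lower=0.0)
    return AbundanceProfile(data=data, rank=rank, threshold=threshold, criterion=criterion)


def richness(table: OtuTable) -> dict:
    """OTU richness: per-sample presence counts and the pooled total."""
    per_sample = (table.counts > 0).sum(axis=1)
    pooled = int(((table.counts > 0).any(axis=0)).sum())
    return {
        "per_sample": per_sample,
        "pooled": pooled,
        "mean": float(per_sample.mean()),
        "sd": float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0,
    }


def _dominant_set(table: OtuTable, threshold: float, match: str, rank: str) -> set:
    totals = table.counts.sum(axis=1)
    rel = table.counts.div(totals, axis=0)
    dominant_otus = set(rel.columns[(rel > threshold).any(axis=0)])
    if match == "id":
        return dominant_otus
    if match == "taxon":
        names = table.taxon_at_rank(rank)
        return {names[o] for o in dominant_otus if names[o] != "unclassified"}
    raise ValueError(f"unknown match mode {match!r}")


def shared_partition(
    table_a: OtuTable,
    table_b: OtuTable,
    threshold: float = 0.01,
    subset: set | None = None,
    match: str = "id",
    rank: str = "species",
) -> SharedPartition:
    """Partition dominant OTUs into shared / A-only / B-only sets.

    Dominance is relative abundance > ``threshold`` in at least one sample of
    the reactor.  Cross-reactor matching is by OTU id (default, requires a
    common clustering space) or by taxon name at ``rank``.  ``subset``
    restricts the id space (e.g. to microalgal OTUs).
    """
    set_a = _dominant_set(table_a, threshold, match, rank)
    set_b = _dominant_set(table_b, threshold, match, rank)
    if match == "id" and not (set_a | set_b):
        logger.warning("no dominant OTUs in either table")
    if subset is not None:
        set_a &= subset
        set_b &= subset
    shared = set_a & set_b
    only_a = set_a - set_b
    only_b = set_b - set_a
    return SharedPartition(
        total=len(shared | only_a | only_b),
        shared=len(shared),
        only_a=len(only_a),
        only_b=len(only_b),
        members_shared=shared,
        members_only_a=only_a,
        members_only_b=only_b,
    )


def bray_curtis_matrix(profiles: AbundanceProfile | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity among samples.

    BC(x, y) = 1 - 2 * sum(min(x_k, y_k)) / sum(x_k + y_k); symmetric with a
    zero diagonal and entries in [0, 1] for non-negative data.
    """
    data = profiles.data if isinstance(profiles, AbundanceProfile) else profiles
    if len(data) < 2:
        raise ValueError("need at least two samples")
    if (data.sum(axis=1) == 0).any():
        raise ValueError("sample with all-zero abundances")
    condensed = pdist(data.values, metric="braycurtis")
    return pd.DataFrame(squareform(condensed), index=data.index, columns=data.index)


def _sorted_profiles(data: np.ndarray) -> np.ndarray:
    """Sorted condensed Bray-Curtis dissimilarity profile of a data block."""
    return np.sort(pdist(data, metric="braycurtis"))


def simprof_test(
    data: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Clarke's similarity-profile permutation test on one group of samples.

    Under the null of no multivariate structure the values of each variable
    are exchangeable across samples.  The test statistic is
    pi = sum_k |d_(k) - mean_(k)| comparing the sorted observed Bray-Curtis
    profile with the mean sorted profile of variable-wise permutations; the
    p-value is the upper-tail fraction of a second permutation set.
    """
    if rng is None:
        rng = np.random.default_rng()
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("similarity profile needs >=3 samples")
    if data.shape[1] < 2:
        raise ValueError("similarity profile needs >=2 variables")
    if n_perm < 50:
        warnings.warn("n_perm < 50 gives a very coarse p-value", stacklevel=2)
    observed = _sorted_profiles(data)
    expected = np.zeros_like(observed)
    for _ in range(n_perm):
        expected += _sorted_profiles(rng.permuted(data, axis=0))
    expected /= n_perm
    pi_obs = float(np.abs(observed - expected).sum())
    exceed = 0
    for _ in range(n_perm):
        pi_k = float(np.abs(_sorted_profiles(rng.permuted(data, axis=0)) - expected).sum())
        if pi_k >= pi_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return pi_obs, p


def cluster_simprof(
    matrix: pd.DataFrame,
    profiles: AbundanceProfile | pd.DataFrame,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    method: str = "average",
) -> SimprofResult:
    """UPGMA clustering with recursive SIMPROF significance testing.

    The dendrogram is cut top-down: each node is tested with the
    similarity-profile statistic on the raw profiles of its leaves (the test
    permutes variables, not distances); recursion continues into the children
    of significant nodes and stops at non-significant ones, whose leaves form
    one homogeneous group.  Groups partition the samples.
    """
    data = profiles.data if isinstance(profiles, AbundanceProfile) else profiles
    data = data.loc[matrix.index]
    rng = np.random.default_rng(seed)
    condensed = squareform(matrix.values, checks=False)
    Z = linkage(condensed, method=method)
    tree = to_tree(Z)
    sample_ids = list(matrix.index)
    values = data.values

    nodes: list[SimprofNode] = []
    groups: list[list] = []

    def visit(node) -> None:
        leaves = node.pre_order(lambda leaf: leaf.id)
        if len(leaves) < 3:
            groups.append([sample_ids[i] for i in leaves])
            return
        pi, p = simprof_test(values[leaves], n_perm=n_perm, rng=rng)
        significant = p < alpha
        nodes.append(
            SimprofNode(
                node_id=node.id, n_leaves=len(leaves), pi=pi, p_value=p, significant=significant
            )
        )
        if significant:
            visit(node.left)
            visit(node.right)
        else:
            groups.append([sample_ids[i] for i in leaves])

    visit(tree)
    return SimprofResult(linkage_matrix=Z, sample_ids=sample_ids, nodes=nodes, groups=groups)


def dendrogram_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick serialisation of a scipy linkage dendrogram with branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def env_window_means(
    daily: pd.DataFrame,
    sampling_times: list[float] | np.ndarray,
    window: float = 7.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean covariates over the window preceding each sampling time.

    ``daily`` is indexed by campaign day.  For each sampling time t the mean
    over available days in (t - window, t] is returned, together with the
    number of contributing days (partial windows at campaign start are used
    as-is and visible through that count).
    """
    days = np.asarray(daily.index, dtype=float)
    rows, counts = {}, {}
    for t in sampling_times:
        in_window = (days > t - window) & (days <= t)
        if not in_window.any():
            raise ValueError(f"no daily covariates in the window preceding t={t}")
        block = daily.iloc[np.flatnonzero(in_window)]
        rows[t] = block.mean(axis=0)
        counts[t] = int(in_window.sum())
    means = pd.DataFrame(rows).T
    means.index.name = "t"
    return means, pd.Series(counts, name="n_days")


def kendall_screen(
    profiles: AbundanceProfile | pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> CorrelationScreen:
    """Kendall tau-b screening of taxa against environmental covariates.

    Computes the tie-corrected tau-b and its two-sided p for every
    taxon x covariate pair over the shared samples; cells with p >= alpha are
    masked.  Raw p-values are used by default, mirroring simple per-cell
    screening; ``bh_correct`` applies Benjamini-Hochberg across all cells.
    Constant vectors (tau undefined) are flagged, not silently dropped.
    """
    data = profiles.data if isinstance(profiles, AbundanceProfile) else profiles
    taxa_cols = [c for c in data.columns if c != "other"]
    shared = data.index.intersection(env.index)
    if len(shared) < 4:
        raise ValueError("need >=4 paired observations for the Kendall screen")
    X = data.loc[shared, taxa_cols]
    E = env.loc[shared]
    tau = pd.DataFrame(index=taxa_cols, columns=E.columns, dtype=float)
    pval = pd.DataFrame(index=taxa_cols, columns=E.columns, dtype=float)
    flagged = []
    for taxon in taxa_cols:
        x = X[taxon].values
        for cov in E.columns:
            y = E[cov].values
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                flagged.append((taxon, cov))
                tau.loc[taxon, cov] = np.nan
                pval.loc[taxon, cov] = np.nan
                continue
            res = stats.kendalltau(x, y, variant="b")
            tau.loc[taxon, cov] = res.statistic
            pval.loc[taxon, cov] = res.pvalue
    if bh_correct:
        flat = pval.values.ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            from statsmodels.stats.multitest import multipletests

            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        pval = pd.DataFrame(adj.reshape(pval.shape), index=pval.index, columns=pval.columns)
    significant = pval < alpha
    return CorrelationScreen(
        tau=tau, p=pval, significant=significant, alpha=alpha, flagged_constant=flagged
    )
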