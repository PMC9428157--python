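"""Alpha/beta diversity and host-range analysis of transconjugant pools.

Input is an OTU count table (OTUs x samples) for FACS-sorted transconjugant
communities, with rank-delimited taxonomy lineages and per-sample metadata.
All diversity statistics are implemented directly from their estimator
formulas (Mothur conventions: Shannon in nats, Simpson as the dominance sum
of squared proportions, ACE with a rare-abundance cutoff of 10), PCoA is
classical metric scaling of the Bray-Curtis matrix, and PERMANOVA p-values
come from seeded label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from plasmidfate.decay_kinetics import compare_groups

__all__ = [
    "RANKS",
    "OtuTable",
    "AlphaDiversity",
    "OrdinationResult",
    "PermanovaResult",
    "HostRangeSummary",
    "parse_lineage",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "pcoa",
    "permanova",
    "aggregate_taxonomy",
    "relative_abundance",
    "genus_presence_sets",
    "host_range_summary",
    "top_n_matrix",
    "compare_alpha_groups",
    "rarefy",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ``k__...;p__...;...;g__...`` lineage into rank -> name.

    Missing or empty ranks map to the empty string; ``norank``/``unclassified``
    placeholders are preserved verbatim.
    """
    out = {rank: "" for rank in RANKS}
    for part in lineage.split(";"):
        part = part.strip()
        for rank, prefix in zip(RANKS, _RANK_PREFIXES):
            if part.startswith(prefix):
                out[rank] = part[len(prefix):]
                break
    return out


@dataclass
class OtuTable:
    """OTU counts with taxonomy and sample metadata.

    ``counts``: integer DataFrame, rows = OTU ids, columns = sample ids.
    ``taxonomy``: otu_id -> rank-delimited lineage string.
    ``metadata``: DataFrame indexed by sample id with at least ``treatment``,
    ``phase``, ``replicate`` and a combined ``group`` column.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = self.counts
        if counts.empty:
            raise ValueError("OTU table has no counts")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("OTU counts must be integral")
            self.counts = counts = counts.round().astype(int)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("OTU counts must be non-negative")
        missing_tax = [o for o in counts.index if o not in self.taxonomy]
        if missing_tax:
            raise ValueError(f"OTUs without taxonomy: {missing_tax[:5]}")
        missing_meta = [s for s in counts.columns if s not in self.metadata.index]
        if missing_meta:
            raise ValueError(f"samples without metadata: {missing_meta[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(
            counts=self.counts[list(sample_ids)].copy(),
            taxonomy=self.taxonomy,
            metadata=self.metadata.loc[list(sample_ids)].copy(),
        )


@dataclass(frozen=True)
class AlphaDiversity:
    """Alpha-diversity indices for one sample.

    ``shannon`` is in nats; ``simpson`` is the dominance form (sum of squared
    proportions, lower = more diverse); ``goods_coverage`` is
    ``1 - singletons/reads``.
    """

    sobs: int
    chao1: float
    ace: float
    shannon: float
    simpson: float
    goods_coverage: float


def alpha_diversity(counts: Sequence[int], *, ace_rare_cutoff: int = 10) -> AlphaDiversity:
    """Compute Sobs, Chao1, ACE, Shannon, Simpson and Good's coverage.

    Chao1 uses the bias-corrected form ``Sobs + F1(F1-1)/(2(F2+1))``. ACE is
    the abundance-based coverage estimator with rare taxa defined as counts
    <= ``ace_rare_cutoff``; when the rare fraction is all singletons (ACE
    coverage zero) the Chao1 value is substituted.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("sample has no positive counts")
    n_reads = x.sum()
    sobs = int(x.size)
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    chao1 = sobs + f1 * (f1 - 1) / (2.0 * (f2 + 1))

    rare = x[x <= ace_rare_cutoff]
    abund = x[x > ace_rare_cutoff]
    s_rare, s_abund = rare.size, abund.size
    n_rare = rare.sum()
    if s_rare == 0:
        ace = float(sobs)
    else:
        c_ace = 1.0 - f1 / n_rare
        if c_ace <= 0:
            ace = chao1  # all rare taxa are singletons; ACE undefined
        else:
            ks = np.arange(1, ace_rare_cutoff + 1)
            fk = np.array([(x == k).sum() for k in ks], dtype=float)
            if n_rare > 1:
                gamma = (s_rare / c_ace) * (ks * (ks - 1) * fk).sum() / (
                    n_rare * (n_rare - 1)
                ) - 1.0
            else:
                gamma = 0.0
            gamma = max(gamma, 0.0)
            ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma

    p = x / n_reads
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p**2).sum())
    goods = 1.0 - f1 / n_reads
    return AlphaDiversity(
        sobs=sobs,
        chao1=float(chao1),
        ace=float(ace),
        shannon=shannon,
        simpson=simpson,
        goods_coverage=float(goods),
    )


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Alpha indices for every sample, one row per sample."""
    rows = {}
    for sid in table.sample_ids:
        a = alpha_diversity(table.counts[sid].to_numpy())
        rows[sid] = {
            "sobs": a.sobs, "chao1": a.chao1, "ace": a.ace,
            "shannon": a.shannon, "simpson": a.simpson,
            "goods_coverage": a.goods_coverage,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    ``d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``; symmetric, zero diagonal,
    entries in [0, 1]. Raises on a sample with zero total.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    if (totals <= 0).any():
        bad = list(counts.columns[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    n = arr.shape[1]
    dm = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(arr[:, i:i + 1] - arr[:, i:]).sum(axis=0)
        dm[i, i:] = diff / (totals[i] + totals[i:])
        dm[i:, i] = dm[i, i:]
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=counts.columns, columns=counts.columns)


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) coordinates and eigenvalue spectrum."""

    coordinates: pd.DataFrame  # samples x axes (PCo1, PCo2, ...)
    eigenvalues: np.ndarray  # full spectrum, descending, negatives included
    proportion_explained: np.ndarray  # per retained axis, vs positive sum


def pcoa(dissimilarity: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis by classical metric scaling.

    Double-centers ``-D^2/2``, eigendecomposes, and keeps axes with positive
    eigenvalues (coordinates scaled by sqrt(eigenvalue)). Negative
    eigenvalues — possible for non-Euclidean dissimilarities like
    Bray-Curtis — are reported in the spectrum, not corrected. Axis signs
    follow a deterministic convention: the largest-magnitude loading of each
    axis is made positive.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    n = d.shape[0]
    ids = list(dissimilarity.index) if isinstance(dissimilarity, pd.DataFrame) else list(range(n))
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if eigvals.size else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    keep = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvecs[:, :keep] * np.sqrt(eigvals[:keep]) if keep else np.zeros((n, 0))
    for ax in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, ax]))
        if coords[pivot, ax] < 0:
            coords[:, ax] *= -1
    pos_sum = eigvals[positive].sum()
    prop = eigvals[:keep] / pos_sum if pos_sum > 0 else np.zeros(keep)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix."""

    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_samples: int
    n_groups: int


def _permanova_f(sq_d: np.ndarray, labels: np.ndarray, n: int) -> tuple[float, float]:
    ss_total = sq_d[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = sq_d[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    a = np.unique(labels).size
    f = (ss_among / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dissimilarity: pd.DataFrame,
    grouping: Sequence[str] | pd.Series,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """PERMANOVA (Adonis): pseudo-F from squared-dissimilarity partitioning.

    p = (#{permuted F >= observed} + 1) / (n_permutations + 1), with label
    shuffles drawn from a generator seeded by ``seed``. Requires >= 2 groups,
    each non-empty, and >= 99 permutations.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if isinstance(grouping, pd.Series):
        if isinstance(dissimilarity, pd.DataFrame):
            grouping = grouping.reindex(dissimilarity.index)
            if grouping.isna().any():
                raise ValueError("grouping missing labels for some samples")
        grouping = grouping.to_numpy()
    labels = np.asarray(grouping)
    if labels.size != n:
        raise ValueError("grouping length must match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts == 0).any():
        raise ValueError("every group must be non-empty")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    sq_d = d**2
    f_obs, r2 = _permanova_f(sq_d, labels, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        f_perm, _ = _permanova_f(sq_d, perm, n)
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        n_samples=n,
        n_groups=int(uniq.size),
    )


def _effective_label(lineage: str, rank: str) -> str:
    """Taxon label at ``rank``, falling back to the nearest resolved
    ancestor's name when the rank is empty or a ``norank``/``unclassified``
    placeholder (mirrors family names standing in for unresolved genera)."""
    parsed = parse_lineage(lineage)
    idx = RANKS.index(rank)
    for r in RANKS[idx::-1]:
        name = parsed[r]
        if name and not name.lower().startswith(("norank", "unclassified", "uncultured")):
            return name
    return "unclassified"


def aggregate_taxonomy(table: OtuTable, rank: str) -> pd.DataFrame:
    """Sum OTU counts over taxa sharing the label at ``rank``.

    Per-sample totals are preserved; OTUs unresolved at ``rank`` are bucketed
    under the nearest resolved ancestor (or ``unclassified``).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = pd.Series(
        {otu: _effective_label(table.taxonomy[otu], rank) for otu in table.otu_ids}
    )
    agg = table.counts.groupby(labels.reindex(table.counts.index)).sum()
    agg.index.name = rank
    return agg


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-wise proportions; every sample column sums to 1."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(counts.columns[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts / totals


def genus_presence_sets(
    table: OtuTable,
    group_col: str = "group",
    *,
    rank: str = "genus",
    min_count: int = 1,
) -> dict[str, set[str]]:
    """Taxon presence sets per metadata group (taxon present in a group if
    any of the group's samples reaches ``min_count`` reads)."""
    agg = aggregate_taxonomy(table, rank)
    sets: dict[str, set[str]] = {}
    for group, sub in table.metadata.groupby(group_col, sort=True):
        cols = [s for s in sub.index if s in agg.columns]
        present = agg[cols].max(axis=1) >= min_count
        sets[str(group)] = set(agg.index[present])
    return sets


@dataclass
class HostRangeSummary:
    """Shared/unique/core taxon sets across groups of transconjugant pools."""

    sets: dict[str, set[str]]
    pairwise_shared: dict[tuple[str, str], int]
    unique: dict[str, int]
    core: set[str]
    shared_pct_of_union: float
    shared_pct_per_group: dict[str, float]


def host_range_summary(sets_by_group: Mapping[str, Iterable[str]]) -> HostRangeSummary:
    """Set algebra over per-group taxon presence sets.

    ``core`` is the intersection across all groups; ``unique`` counts taxa
    seen in exactly one group. The "shared percentage" is reported both as
    |core| / |union| and as |core| / |group| per group (the two plausible
    denominators).
    """
    groups = {g: set(s) for g, s in sets_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in groups.values()):
        raise ValueError("every group set must be non-empty")
    names = list(groups)
    core = set.intersection(*groups.values())
    union = set.union(*groups.values())
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = len(groups[a] & groups[b])
    unique = {
        g: len(groups[g] - set.union(*(groups[h] for h in names if h != g)))
        for g in names
    }
    return HostRangeSummary(
        sets=groups,
        pairwise_shared=pairwise,
        unique=unique,
        core=core,
        shared_pct_of_union=100.0 * len(core) / len(union),
        shared_pct_per_group={g: 100.0 * len(core) / len(s) for g, s in groups.items()},
    )


def top_n_matrix(aggregated: pd.DataFrame, n: int = 30) -> pd.DataFrame:
    """Relative abundances of the ``n`` most abundant taxa plus an ``Other`` row.

    Taxa are ranked by mean relative abundance across samples, ties broken
    lexicographically. If fewer than ``n`` taxa exist, all are returned
    (with an all-zero ``Other`` row for column-sum consistency).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rel = relative_abundance(aggregated)
    ranking = (
        rel.mean(axis=1)
        .to_frame("mean_rel")
        .assign(taxon=lambda df: df.index)
        .sort_values(["mean_rel", "taxon"], ascending=[False, True])
    )
    top = list(ranking.index[:n])
    rest = [t for t in rel.index if t not in top]
    out = rel.loc[top].copy()
    out.loc["Other"] = rel.loc[rest].sum(axis=0) if rest else 0.0
    return out


def compare_alpha_groups(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "duncan",
) -> tuple["pd.DataFrame", object]:
    """ANOVA + post-hoc letters for one alpha index across groups.

    Groups sharing a letter are not significantly different at p < 0.05.
    Letters are assigned to maximal cliques of the non-significance graph,
    ordered by descending group mean. Returns (letters frame, the underlying
    GroupComparison).
    """
    comparison = compare_groups(values_by_group, method=method)
    groups = comparison.groups
    graph = nx.Graph()
    graph.add_nodes_from(groups)
    for row in comparison.pairwise.itertuples():
        if row.p_adj >= 0.05:
            graph.add_edge(row.group_a, row.group_b)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(graph)),
        key=lambda c: -max(comparison.means[g] for g in c),
    )
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in clique:
            letters[g] += letter
    frame = pd.DataFrame({
        "group": groups,
        "mean": [comparison.means[g] for g in groups],
        "sd": [comparison.sds[g] for g in groups],
        "letters": [letters[g] for g in groups],
    })
    return frame, comparison


def rarefy(table: OtuTable, depth: int | None = None, seed: int | None = None) -> OtuTable:
    """Seeded subsampling of every sample to a common depth (default: the
    minimum sample total). Off by default in all pipelines; provided for
    parity with Mothur-style workflows."""
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if (totals < depth).any():
        raise ValueError("a sample has fewer reads than the rarefaction depth")
    out = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        reads = np.repeat(np.arange(col.size), col)
        pick = rng.choice(reads, size=depth, replace=False)
        out[sid] = np.bincount(pick, minlength=col.size)
    counts = pd.DataFrame(out, index=table.counts.index)
    return OtuTable(counts=counts, taxonomy=table.taxonomy, metadata=table.metadata.copy())
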