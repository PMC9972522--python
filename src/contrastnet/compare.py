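"""Downstream statistics for contrast subgraphs.

Covers the comparisons typically run once a contrast subgraph is in
hand: Mann–Whitney U tests on within-subgraph degree distributions in
the two source networks, Jaccard/Fisher overlap statistics between node
sets, hypergeometric over-representation analysis against GMT gene-set
collections with Benjamini–Hochberg correction, fold-change-based
upregulation calls, and mRNA–protein agreement summaries (per-gene
Pearson r, Cohen's d between groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, inf, sqrt
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graphs import WeightedNetwork

logger = logging.getLogger(__name__)

#: largest group size for which the Mann–Whitney p-value is computed exactly
_MWU_EXACT_MAX_GROUP = 20
#: largest number of enumerated arrangements for the tie-aware exact test
_MWU_ENUM_LIMIT = 500_000


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with a declared universe (GMT-style).

    Every computation first intersects each set (and the query) with the
    universe, so enrichment statistics are always conditioned on the
    genes actually observable in the experiment.
    """

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("gene set collection is empty")
        if not self.universe:
            raise ValueError("universe is empty")

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        frozen = {str(k): frozenset(map(str, v)) for k, v in sets.items()}
        if universe is None:
            uni: frozenset[str] = frozenset().union(*frozen.values())
        else:
            uni = frozenset(map(str, universe))
        return cls(sets=frozen, universe=uni)

    def restricted(self, name: str) -> frozenset[str]:
        return self.sets[name] & self.universe


@dataclass(frozen=True)
class EnrichmentResult:
    """One row of an over-representation table."""

    set_name: str
    overlap: int          # k: query genes in the set
    set_size: int         # K: set size within the universe
    query_size: int       # n: query size within the universe
    universe_size: int    # N
    p_value: float
    adjusted_p: float
    gene_ratio: float     # overlap / query size
    genes: tuple[str, ...]


def degree_distribution_test(
    s: Collection[str],
    net_a: WeightedNetwork,
    net_b: WeightedNetwork,
    induced: bool = True,
) -> tuple[pd.Series, pd.Series, float, float]:
    """Compare the degrees of a node set in two networks (Mann–Whitney U).

    By default degrees are weighted degrees within the subgraph induced
    by ``s`` — the quantity the contrast objective is about; with
    ``induced=False`` full-network degrees are used instead.  Returns
    (degrees_a, degrees_b, U, two-sided p); U counts wins of the first
    sample.  The p-value is exact (tie-aware) for small sets and a
    tie-corrected normal approximation with continuity correction
    otherwise.
    """
    s = sorted(set(s))
    if len(s) < 2:
        raise ValueError("degree comparison needs at least 2 nodes")
    missing = [n for n in s if n not in net_a or n not in net_b]
    if missing:
        raise KeyError(f"nodes absent from one of the networks: {missing[:5]}")

    def _degrees(net: WeightedNetwork) -> pd.Series:
        idx = net.indices(s)
        if induced:
            sub = net.weights[np.ix_(idx, idx)]
            vals = sub.sum(axis=1)
        else:
            vals = net.weights[idx].sum(axis=1)
        labels = [net.nodes[i] for i in idx]
        return pd.Series(vals, index=labels).loc[s]

    da, db = _degrees(net_a), _degrees(net_b)
    u, p = mann_whitney_u(da.values, db.values)
    return da, db, u, p


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test, exact for small samples.

    U is the number of (x, y) pairs with x > y, counting ties as 1/2.
    Routing: both groups ≤ 20 and no ties → exact recurrence; ties with a
    tractable number of arrangements → exact enumeration conditional on
    the observed tie structure; otherwise normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2)
    has_ties = len(np.unique(pooled)) < n + m
    small = n <= _MWU_EXACT_MAX_GROUP and m <= _MWU_EXACT_MAX_GROUP
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return u, float(res.pvalue)
    if small and has_ties and comb(n + m, n) <= _MWU_ENUM_LIMIT:
        return u, _mwu_exact_ties(ranks, n, m, u)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u, float(res.pvalue)


def _mwu_exact_ties(ranks: np.ndarray, n: int, m: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating group assignments of the ranks."""
    base = n * (n + 1) / 2
    mn = n * m
    lo = min(u_obs, mn - u_obs)
    eps = 1e-9
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - base
        if u <= lo + eps or u >= mn - lo - eps:
            count += 1
        total += 1
    return min(1.0, count / total)


def jaccard_index(s1: Collection[str], s2: Collection[str]) -> float:
    """|s1 ∩ s2| / |s1 ∪ s2|; undefined (error) when both sets are empty."""
    s1, s2 = set(s1), set(s2)
    union = s1 | s2
    if not union:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return len(s1 & s2) / len(union)


def fisher_overlap(
    s1: Collection[str],
    s2: Collection[str],
    universe: Collection[str],
    alternative: str = "greater",
) -> tuple[float, float, float]:
    """Fisher's exact test for the overlap of two sets within a universe.

    One-sided (enrichment) by default.  Returns (odds ratio, p, expected
    overlap |s1|·|s2|/N).  Both sets must be subsets of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    s1, s2 = set(s1), set(s2)
    for name, s in (("s1", s1), ("s2", s2)):
        extra = s - universe
        if extra:
            raise ValueError(f"{name} contains genes outside the universe: {sorted(extra)[:5]}")
    n = len(universe)
    k = len(s1 & s2)
    table = [[k, len(s1) - k], [len(s2) - k, n - len(s1) - len(s2) + k]]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    expected = len(s1) * len(s2) / n
    return float(odds), float(p), expected


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Collection[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Hypergeometric over-representation of a query set in a collection.

    The query and every gene set are intersected with the declared
    universe first.  Per set, p = P(X ≥ k) for X ~ Hypergeom(N, K, n);
    Benjamini–Hochberg adjustment is applied across all tested sets.
    Returns ``(significant, full_table)``, both sorted by adjusted p then
    raw p then set name; ``significant`` keeps adjusted p < threshold.
    """
    q = set(query) & collection.universe
    if not q:
        raise ValueError("query is empty after intersection with the universe")
    n_universe = len(collection.universe)
    names = sorted(collection.sets)
    rows = []
    for name in names:
        members = collection.restricted(name)
        hit = q & members
        k, big_k, n_q = len(hit), len(members), len(q)
        # upper tail P(X >= k); sf(k-1) == 1 when k == 0
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_q))
        rows.append((name, k, big_k, n_q, min(1.0, p), tuple(sorted(hit))))
    adj = benjamini_hochberg(np.array([r[4] for r in rows]))
    results = [
        EnrichmentResult(
            set_name=name, overlap=k, set_size=big_k, query_size=n_q,
            universe_size=n_universe, p_value=p, adjusted_p=float(a),
            gene_ratio=k / n_q, genes=genes,
        )
        for (name, k, big_k, n_q, p, genes), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.set_name))
    significant = [r for r in results if r.adjusted_p < fdr_threshold]
    return significant, results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "set_name": r.set_name, "overlap": r.overlap, "set_size": r.set_size,
            "query_size": r.query_size, "universe_size": r.universe_size,
            "gene_ratio": r.gene_ratio, "p_value": r.p_value,
            "adjusted_p": r.adjusted_p, "genes": ",".join(r.genes),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def upregulated_genes(
    tpm_a: pd.Series,
    tpm_b: pd.Series,
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
) -> frozenset[str]:
    """Genes upregulated in A vs B by log2 fold change on pseudocounted TPM.

    A gene is called up when log2(tpm_a + pc) − log2(tpm_b + pc) exceeds
    the threshold *strictly* (a fold change of exactly the threshold is
    excluded).  Swapping the arguments yields the downregulated mirror.
    """
    a = tpm_a.iloc[:, 0] if isinstance(tpm_a, pd.DataFrame) else tpm_a
    b = tpm_b.iloc[:, 0] if isinstance(tpm_b, pd.DataFrame) else tpm_b
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))[:5]
        only_b = sorted(set(b.index) - set(a.index))[:5]
        raise ValueError(
            f"gene labels differ between conditions (A-only: {only_a}, B-only: {only_b})"
        )
    b = b.loc[a.index]
    lfc = np.log2(a + pseudocount) - np.log2(b + pseudocount)
    return frozenset(lfc.index[lfc > lfc_threshold])


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised mean difference with pooled (Bessel-corrected) SD.

    A zero pooled SD with unequal means yields ±inf with a warning; with
    equal means the difference is 0 and d = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d needs at least 2 observations per group")
    diff = x.mean() - y.mean()
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if np.ptp(x) == 0 and np.ptp(y) == 0:  # constant groups; ignore fp residue
        pooled_var = 0.0
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        logger.warning("zero pooled SD with unequal means: Cohen's d is infinite")
        return inf if diff > 0 else -inf
    return float(diff / sqrt(pooled_var))


def expression_protein_agreement(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    groups: Mapping[str, Collection[str]] | None = None,
) -> tuple[pd.Series, dict[tuple[str, str], float]]:
    """Per-gene mRNA–protein Pearson correlation and group contrasts.

    Correlations are computed across the shared samples for each shared
    gene; genes with zero variance in either assay are excluded (count
    logged).  For every unordered pair of named groups, Cohen's d of the
    correlation values (first minus second, in sorted-name order) is
    returned.
    """
    genes = mrna.index.intersection(protein.index)
    samples = mrna.columns.intersection(protein.columns)
    if len(samples) < 3:
        raise ValueError("at least 3 shared samples are required")
    if len(genes) == 0:
        raise ValueError("no shared genes between the two matrices")
    a = mrna.loc[genes, samples].values.astype(float)
    b = protein.loc[genes, samples].values.astype(float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    corr = pd.Series(r, index=genes, name="pearson_r")
    n_dropped = int(corr.isna().sum())
    if n_dropped:
        logger.warning("excluded %d genes with zero-variance profiles", n_dropped)
        corr = corr.dropna()
    d_values: dict[tuple[str, str], float] = {}
    if groups:
        for g1, g2 in combinations(sorted(groups), 2):
            v1 = corr.loc[corr.index.intersection(list(groups[g1]))].values
            v2 = corr.loc[corr.index.intersection(list(groups[g2]))].values
            d_values[(g1, g2)] = cohens_d(v1, v2)
    return corr, d_values
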