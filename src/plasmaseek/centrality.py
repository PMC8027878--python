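"""Closeness centrality on the dual networks and the RCC importance statistic.

A gene's importance is summarized as the ratio of its closeness centrality
in the similarity network to its closeness in the dissimilarity network,
computed separately in the normal and tumor groups:

    RCC_N = CN_sim / CN_dis        RCC_P = CT_sim / CT_dis

Genes that matter shift their log2(RCC) between the two groups; a paired
Wilcoxon signed-rank test over a biomarker gene set quantifies that shift.

Closeness uses shortest paths with edge traversal length 1/weight (strong
edges are short) by default; the alternative of reading dissimilarity
weights directly as distances is available via ``distance_mode='direct'``.
Disconnected networks are handled with Wasserman-Faust component scaling:

    closeness(v) = [(m-1) / sum_u d(v,u)] * [(m-1) / (n-1)]

where m counts the nodes reachable from v (including v), so small components
are penalized and isolated nodes score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .cohort_io import CohortError, ExpressionCohort, PipelineConfig
from .network import DualNetworkPair, NetworkLayer, build_pair


@dataclass
class CentralityRccTable:
    """Per-gene closeness in all four networks plus RCC ratios."""

    frame: pd.DataFrame  # gene, CN_sim, CN_dis, CT_sim, CT_dis, RCC_N, RCC_P,
    #                      log2_RCC_N, log2_RCC_P, defined


@dataclass
class RccTestResult:
    genes_tested: int
    w_statistic: float
    p_value: float
    n_pairs: int
    n_dropped: int


def closeness(network: NetworkLayer, distance_mode: str = "inverse") -> np.ndarray:
    """Per-node closeness centrality of a weighted layer.

    ``distance_mode='inverse'`` treats weights as connection strengths
    (traversal length 1/weight); ``'direct'`` treats weights themselves as
    lengths, which only makes sense for the dissimilarity layer.
    """
    w = network.weights
    n = w.shape[0]
    if n == 1:
        return np.zeros(1)
    ii, jj = np.nonzero(w)
    if distance_mode == "inverse":
        lengths = 1.0 / w[ii, jj]
    elif distance_mode == "direct":
        lengths = w[ii, jj]
    else:
        raise CohortError("distance_mode must be 'inverse' or 'direct'")
    graph = csr_matrix((lengths, (ii, jj)), shape=(n, n))
    dist = dijkstra(graph, directed=False)
    out = np.zeros(n)
    for v in range(n):
        finite = np.isfinite(dist[v])
        m = int(finite.sum())  # includes v itself (d=0)
        if m <= 1:
            continue
        total = dist[v, finite].sum()
        if total <= 0:
            continue
        out[v] = ((m - 1) / total) * ((m - 1) / (n - 1))
    return out


def rcc(normal_pair: DualNetworkPair, tumor_pair: DualNetworkPair,
        distance_mode: str = "inverse") -> CentralityRccTable:
    """Closeness in all four networks and the RCC ratios per gene.

    Genes with a zero closeness in either dissimilarity network have an
    undefined ratio; they are flagged ``defined=False`` and excluded from
    downstream testing rather than imputed.
    """
    if normal_pair.similarity.genes != tumor_pair.similarity.genes:
        raise CohortError("normal and tumor pairs must share the gene set")
    genes = normal_pair.similarity.genes
    cn_sim = closeness(normal_pair.similarity, distance_mode)
    cn_dis = closeness(normal_pair.dissimilarity, distance_mode)
    ct_sim = closeness(tumor_pair.similarity, distance_mode)
    ct_dis = closeness(tumor_pair.dissimilarity, distance_mode)
    defined = (cn_dis > 0) & (ct_dis > 0) & (cn_sim > 0) & (ct_sim > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rcc_n = np.where(cn_dis > 0, cn_sim / cn_dis, np.nan)
        rcc_p = np.where(ct_dis > 0, ct_sim / ct_dis, np.nan)
        log_n = np.where(defined, np.log2(rcc_n), np.nan)
        log_p = np.where(defined, np.log2(rcc_p), np.nan)
    frame = pd.DataFrame(
        {
            "gene": genes,
            "CN_sim": cn_sim,
            "CN_dis": cn_dis,
            "CT_sim": ct_sim,
            "CT_dis": ct_dis,
            "RCC_N": rcc_n,
            "RCC_P": rcc_p,
            "log2_RCC_N": log_n,
            "log2_RCC_P": log_p,
            "defined": defined,
        }
    )
    return CentralityRccTable(frame=frame)


def wilcoxon_paired(log2_rcc_normal, log2_rcc_tumor) -> RccTestResult:
    """Two-sided paired Wilcoxon signed-rank test on per-gene log2(RCC).

    Pairs with an undefined value (NaN) and zero differences are dropped
    (standard Wilcoxon convention). The reported W is the sum of midranks of
    positive differences. The p-value is exact for small tie-free samples
    and uses the normal approximation with tie and continuity corrections
    otherwise.
    """
    x = np.asarray(log2_rcc_normal, dtype=float)
    y = np.asarray(log2_rcc_tumor, dtype=float)
    if x.shape != y.shape:
        raise CohortError("paired vectors must have equal length")
    total = x.size
    usable = np.isfinite(x) & np.isfinite(y)
    d = x[usable] - y[usable]
    nonzero = d[d != 0]
    n_pairs = nonzero.size
    n_dropped = total - n_pairs
    if n_pairs == 0:
        raise CohortError("all paired differences are zero or undefined; "
                          "RCC contrast untestable")
    if n_pairs < 3:
        raise CohortError(
            f"only {n_pairs} usable pair(s); need >= 3 for the signed-rank test"
        )
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    res = stats.wilcoxon(nonzero, alternative="two-sided", zero_method="wilcox",
                         correction=True, method="auto")
    return RccTestResult(
        genes_tested=total,
        w_statistic=w_plus,
        p_value=float(res.pvalue),
        n_pairs=n_pairs,
        n_dropped=n_dropped,
    )


def rcc_pipeline(
    cohort: ExpressionCohort,
    biomarker_genes: list[str],
    config: PipelineConfig,
) -> tuple[CentralityRccTable, RccTestResult]:
    """Dual networks for both groups, RCC for all genes, paired test on a panel."""
    missing = [g for g in biomarker_genes if g not in set(cohort.genes)]
    if missing:
        raise CohortError(f"biomarker gene(s) absent from cohort: {missing}")
    normal_pair = build_pair(cohort, "normal", config)
    tumor_pair = build_pair(cohort, "tumor", config)
    table = rcc(normal_pair, tumor_pair, config.distance_mode)
    sub = table.frame.set_index("gene").loc[biomarker_genes]
    test = wilcoxon_paired(sub["log2_RCC_N"].to_numpy(),
                           sub["log2_RCC_P"].to_numpy())
    return table, test
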