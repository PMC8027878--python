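"""Paired similarity/dissimilarity weighted co-expression networks.

For one sample group (tumor or normal), pairwise Pearson correlations r_ij
between gene expression profiles are mapped into two weighted adjacency
matrices,

    similarity_ij    = ((1 + r_ij) / 2) ** beta
    dissimilarity_ij = ((1 - r_ij) / 2) ** beta

with a common soft power beta >= 1 chosen per group so that the similarity
network's connectivity distribution best fits scale-free topology. Diagonal
entries (self-loops) are set to 0 and entries strictly below a hard
threshold (default 0.01) are removed. At beta = 1 the two weights sum to 1
entrywise, so the dissimilarity layer encodes negative co-expression — the
"distance" counterpart of the similarity layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import CohortError, ExpressionCohort, PipelineConfig


@dataclass
class CorrelationMatrix:
    genes: list[str]
    r: np.ndarray  # symmetric, unit diagonal, entries in [-1, 1]

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.r.shape != (n, n):
            raise CohortError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise CohortError("correlation matrix not symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise CohortError("correlation entries outside [-1, 1]")


@dataclass
class NetworkLayer:
    kind: str  # 'similarity' | 'dissimilarity'
    group: str  # 'normal' | 'tumor'
    genes: list[str]
    weights: np.ndarray
    beta: int
    hard_threshold: float

    def __post_init__(self) -> None:
        if self.kind not in ("similarity", "dissimilarity"):
            raise CohortError(f"unknown layer kind {self.kind!r}")
        n = len(self.genes)
        if self.weights.shape != (n, n):
            raise CohortError("weight matrix shape mismatch")


@dataclass
class DualNetworkPair:
    similarity: NetworkLayer
    dissimilarity: NetworkLayer
    group: str
    beta: int
    scale_free_r2: float

    def __post_init__(self) -> None:
        if self.similarity.genes != self.dissimilarity.genes:
            raise CohortError("layers of a pair must share the gene set")


@dataclass
class SoftPowerFit:
    beta_grid: tuple[int, ...]
    r2: list[float]  # signed scale-free fit index per beta
    usable: list[bool]  # both thresholded layers keep >= 50% non-isolated nodes
    chosen: int
    threshold: float
    passed: bool


# ---------------------------------------------------------------------------

def pearson_matrix(cohort: ExpressionCohort, group: str) -> CorrelationMatrix:
    """Pairwise Pearson correlation of gene profiles within one group.

    Zero-variance genes get r = 0 to every other gene (with a warning) so
    that they remain isolated nodes rather than being dropped — the gene set
    must stay identical across the four networks the RCC statistic compares.
    """
    x = cohort.group_values(group)
    if x.shape[1] < 3:
        raise CohortError(
            f"group {group!r} has {x.shape[1]} samples; need >= 3 for correlation"
        )
    sd = x.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) in group {group!r}; "
            "their correlations are set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.where(np.isfinite(r), r, 0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes=list(cohort.genes), r=r)


def transform(r, kind: str, beta: float):
    """Map correlation(s) to edge weight(s) in [0, 1].

    similarity = ((1+r)/2)**beta, dissimilarity = ((1-r)/2)**beta.
    """
    if beta < 1:
        raise CohortError("soft power beta must be >= 1")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise CohortError("correlation outside [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    if kind == "similarity":
        w = ((1.0 + r) / 2.0) ** beta
    elif kind == "dissimilarity":
        w = ((1.0 - r) / 2.0) ** beta
    else:
        raise CohortError(f"unknown transform kind {kind!r}")
    return w if w.ndim else float(w)


def scale_free_fit(weights: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit of a weighted network.

    Connectivity k_i is the sum of a node's edge weights (self excluded);
    see :func:`scale_free_index` for the fit itself.
    """
    w = np.asarray(weights, dtype=float)
    k = w.sum(axis=1) - np.diag(w)
    return scale_free_index(k, n_bins=n_bins)


def scale_free_index(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index of a connectivity vector.

    Connectivities are discretized into ``n_bins`` equal-width bins; the
    log10 of each non-empty bin's frequency (bin count / total) is regressed
    on the log10 of its mean connectivity. Returns -sign(slope) * R^2, so a
    decreasing power-law degree distribution scores +R^2 and an increasing
    one scores -R^2.
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < 2 or np.ptp(k) == 0:
        warnings.warn("all connectivities equal; scale-free fit undefined, using 0")
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        mean_k = members.mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_f.append(np.log10(members.size / k.size))
    if len(log_k) < 2:
        warnings.warn("fewer than 2 usable connectivity bins; fit index 0")
        return 0.0
    fit = stats.linregress(log_k, log_f)
    r2 = fit.rvalue ** 2
    return float(-np.sign(fit.slope) * r2) if fit.slope != 0 else 0.0


def _usable_after_threshold(r: np.ndarray, beta: int, hard_threshold: float) -> bool:
    """True when both thresholded layers keep >= 50% of nodes connected.

    Raising beta shrinks every weight, and past some point the hard
    threshold strips so many edges that closeness centrality — the sole
    consumer of these networks — degenerates to 0 for most genes. Such beta
    values are excluded from soft-power selection.
    """
    for kind in ("similarity", "dissimilarity"):
        w = transform(r, kind, beta)
        np.fill_diagonal(w, 0.0)
        degree = (w >= hard_threshold).sum(axis=1)
        if (degree >= 1).mean() < 0.5:
            return False
    return True


def select_soft_power(corr: CorrelationMatrix, config: PipelineConfig) -> SoftPowerFit:
    """Pick the smallest soft power meeting the scale-free fit threshold.

    The fit is evaluated on the similarity transform (diagonal excluded,
    pre-thresholding). Candidates whose hard-thresholded networks would be
    mostly edgeless are excluded; among the remaining candidates the
    smallest beta with signed R^2 >= threshold is chosen, falling back to
    the argmax (with a warning) when none passes. If no candidate at all is
    usable, the unconstrained rule applies.
    """
    grid = config.soft_power_grid
    r2s: list[float] = []
    usable: list[bool] = []
    for beta in grid:
        w = transform(corr.r, "similarity", beta)
        np.fill_diagonal(w, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2s.append(scale_free_fit(w))
        usable.append(_usable_after_threshold(corr.r, beta, config.hard_threshold))
    threshold = config.scale_free_r2_threshold
    pool = [(b, r2) for b, r2, ok in zip(grid, r2s, usable) if ok]
    if not pool:
        warnings.warn(
            "every candidate soft power empties the thresholded networks; "
            "selecting on the fit index alone"
        )
        pool = list(zip(grid, r2s))
    passing = [b for b, r2 in pool if r2 >= threshold]
    if passing:
        chosen, passed = passing[0], True
    else:
        best = max(pool, key=lambda t: t[1])
        chosen, passed = best[0], False
        warnings.warn(
            f"no soft power reaches scale-free R^2 {threshold}; using argmax "
            f"beta={chosen} (R^2={best[1]:.3f})"
        )
    return SoftPowerFit(beta_grid=tuple(grid), r2=r2s, usable=usable,
                        chosen=int(chosen), threshold=threshold, passed=passed)


def _layer(corr: CorrelationMatrix, kind: str, group: str, beta: int,
           hard_threshold: float) -> NetworkLayer:
    w = transform(corr.r, kind, beta)
    np.fill_diagonal(w, 0.0)
    w[w < hard_threshold] = 0.0
    return NetworkLayer(kind=kind, group=group, genes=list(corr.genes),
                        weights=w, beta=beta, hard_threshold=hard_threshold)


def build_pair(cohort: ExpressionCohort, group: str,
               config: PipelineConfig) -> DualNetworkPair:
    """Build the similarity/dissimilarity network pair for one group.

    Both layers share the soft power chosen on the similarity transform;
    self-loops are removed and weights strictly below the hard threshold are
    zeroed (edge absent).
    """
    corr = pearson_matrix(cohort, group)
    fit = select_soft_power(corr, config)
    sim = _layer(corr, "similarity", group, fit.chosen, config.hard_threshold)
    dis = _layer(corr, "dissimilarity", group, fit.chosen, config.hard_threshold)
    achieved = fit.r2[fit.beta_grid.index(fit.chosen)]
    return DualNetworkPair(similarity=sim, dissimilarity=dis, group=group,
                           beta=fit.chosen, scale_free_r2=achieved)


def write_layer(layer: NetworkLayer, path) -> None:
    """Serialize a layer as a weighted edge list TSV (upper triangle)."""
    import pandas as pd

    ii, jj = np.nonzero(np.triu(layer.weights, k=1))
    pd.DataFrame(
        {
            "gene_a": [layer.genes[i] for i in ii],
            "gene_b": [layer.genes[j] for j in jj],
            "weight": layer.weights[ii, jj],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
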