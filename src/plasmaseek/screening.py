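"""Rank-based tumor-vs-normal screening and expression-pattern classification.

Each gene is screened with a two-sided Mann-Whitney U test (all tumors vs all
normals) at raw alpha = 0.05 — no multiple-testing correction drives the
calls, matching the screening convention of plasma-biomarker mining studies;
a Benjamini-Hochberg q-value column is emitted for information. Deregulated
genes are then grouped by tumor stage and classified into pattern classes:

* ``leading_up`` / ``leading_down`` — the k most significant genes per
  direction;
* ``stage_specific`` — significantly shifted in exactly one stage relative
  to the other stages, which are mutually homogeneous;
* ``progressive_up`` / ``progressive_down`` — overall significant with stage
  medians shifting monotonically from stage I to IV and a significant
  ordered (Jonckheere-Terpstra style) trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import KNOWN_STAGES, CohortError, ExpressionCohort, PipelineConfig

PATTERNS = (
    "leading_up",
    "leading_down",
    "stage_specific",
    "progressive_up",
    "progressive_down",
    "not_significant",
)


@dataclass
class DifferentialTable:
    """Per-gene screening results, sorted ascending by p-value.

    ``frame`` columns: gene, U, p, q, direction, p_stage_I..p_stage_IV,
    stage_specific_stage, pattern.
    """

    frame: pd.DataFrame
    alpha: float
    stage_counts: dict[str, int]

    def significant(self, direction: str | None = None) -> pd.DataFrame:
        sig = self.frame[self.frame["p"] < self.alpha]
        if direction is not None:
            sig = sig[sig["direction"] == direction]
        return sig


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def mann_whitney(tumor_values, normal_values) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is the tumor-group statistic.

    Ties receive midranks. The p-value is exact for small tie-free samples
    (min group size <= 8) and uses the normal approximation with tie and
    continuity corrections otherwise. A pooled sample with zero variance
    (all observations identical) yields the central U and p = 1.
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size < 2 or n.size < 2:
        raise CohortError("each group needs at least 2 observations")
    if np.ptp(np.concatenate([t, n])) == 0:
        return t.size * n.size / 2.0, 1.0
    res = stats.mannwhitneyu(
        t, n, alternative="two-sided", method="auto", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _mwu_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Mann-Whitney over a (genes x n1) vs (genes x n2) pair."""
    res = stats.mannwhitneyu(
        a, b, axis=1, alternative="two-sided", method="auto", use_continuity=True
    )
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # constant rows (zero pooled variance) -> central U, p = 1
    flat = np.ptp(np.concatenate([a, b], axis=1), axis=1) == 0
    if np.any(flat):
        u[flat] = a.shape[1] * b.shape[1] / 2.0
        p[flat] = 1.0
    return u, np.clip(p, 0.0, 1.0)


def jonckheere_trend(groups: list[np.ndarray], alternative: str = "increasing"
                     ) -> tuple[float, float]:
    """Jonckheere-Terpstra test for an ordered alternative across groups.

    The statistic sums, over every ordered group pair (i < j), the number of
    observation pairs where the later group exceeds the earlier one (ties
    count 1/2). The one-sided p-value uses the normal approximation with a
    continuity correction; the variance is the tie-free form, adequate for
    continuous expression values.
    """
    if len(groups) < 2:
        raise CohortError("trend test needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    jt = 0.0
    for i in range(len(groups) - 1):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            gt = (b[:, None] > a[None, :]).sum()
            eq = (b[:, None] == a[None, :]).sum()
            jt += gt + 0.5 * eq
    ns = np.array([g.size for g in groups])
    n_tot = ns.sum()
    mean = (n_tot * n_tot - (ns * ns).sum()) / 4.0
    var = (
        n_tot * n_tot * (2 * n_tot + 3) - (ns * ns * (2 * ns + 3)).sum()
    ) / 72.0
    if var <= 0:
        return jt, 1.0
    if alternative == "increasing":
        z = (jt - mean - 0.5) / np.sqrt(var)
        p = stats.norm.sf(z)
    elif alternative == "decreasing":
        z = (jt - mean + 0.5) / np.sqrt(var)
        p = stats.norm.cdf(z)
    else:
        raise CohortError("alternative must be 'increasing' or 'decreasing'")
    return float(jt), float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen(cohort: ExpressionCohort, config: PipelineConfig) -> DifferentialTable:
    """Screen every gene tumor-vs-normal; attach per-stage tests and patterns."""
    tum = cohort.group_values("tumor")
    nor = cohort.group_values("normal")
    if tum.shape[1] < 2 or nor.shape[1] < 2:
        raise CohortError("screening needs >= 2 tumor and >= 2 normal samples")

    u, p = _mwu_rows(tum, nor)
    med_t = np.median(tum, axis=1)
    med_n = np.median(nor, axis=1)
    direction = np.where(
        p < config.alpha,
        np.where(med_t > med_n, "up", np.where(med_t < med_n, "down", "none")),
        "none",
    )
    q = multipletests(p, method="fdr_bh")[1]

    frame = pd.DataFrame(
        {"gene": cohort.genes, "U": u, "p": p, "q": q, "direction": direction}
    )

    stage_counts = cohort.stage_counts()
    for stage in KNOWN_STAGES:
        col = f"p_stage_{stage}"
        mask = cohort.stage_mask(stage)
        if mask.sum() >= 2:
            _, sp = _mwu_rows(cohort.values[:, mask], nor)
            frame[col] = sp
        else:
            frame[col] = np.nan

    frame["stage_specific_stage"] = ""
    frame["pattern"] = "not_significant"
    frame = frame.sort_values("p", kind="mergesort", ignore_index=True)

    table = DifferentialTable(frame=frame, alpha=config.alpha,
                              stage_counts=stage_counts)
    return classify_patterns(cohort, table, config)


def leading_genes(table: DifferentialTable, direction: str, k: int) -> list[str]:
    """The k most significant genes of the requested direction."""
    sig = table.significant(direction)
    genes = list(sig["gene"].iloc[:k])
    if len(genes) < k:
        warnings.warn(
            f"only {len(genes)} significant {direction}-regulated genes "
            f"available (requested {k})"
        )
    return genes


def _stage_arrays(cohort: ExpressionCohort) -> dict[str, np.ndarray]:
    """Per known stage: gene x sample submatrix of tumor samples."""
    return {
        s: cohort.values[:, cohort.stage_mask(s)]
        for s in KNOWN_STAGES
        if cohort.stage_mask(s).sum() > 0
    }


def stage_specific_genes(
    cohort: ExpressionCohort,
    table: DifferentialTable,
    config: PipelineConfig,
    direction: str = "up",
) -> dict[str, list[str]]:
    """Genes significantly shifted in one stage vs all other known stages.

    A gene is listed under stage s when the focal-vs-rest Mann-Whitney test
    is significant and the focal-stage median is higher (``direction='up'``)
    or lower (``'down'``). Unknown-stage tumors are excluded from both sides.
    """
    if direction not in ("up", "down"):
        raise CohortError("direction must be 'up' or 'down'")
    by_stage = _stage_arrays(cohort)
    out: dict[str, list[str]] = {}
    if not by_stage:
        warnings.warn("no tumors with known stage; stage-specific map empty")
        return out
    for stage, focal in by_stage.items():
        rest = [v for s, v in by_stage.items() if s != stage]
        if focal.shape[1] < 2 or sum(v.shape[1] for v in rest) < 2:
            warnings.warn(f"stage {stage}: too few tumors, skipped")
            continue
        rest_mat = np.concatenate(rest, axis=1)
        _, p = _mwu_rows(focal, rest_mat)
        med_f = np.median(focal, axis=1)
        med_r = np.median(rest_mat, axis=1)
        if direction == "up":
            hits = (p < config.alpha) & (med_f > med_r)
        else:
            hits = (p < config.alpha) & (med_f < med_r)
        ranked = sorted(np.flatnonzero(hits), key=lambda i: p[i])
        out[stage] = [cohort.genes[i] for i in ranked]
    return out


def progressive_genes(
    cohort: ExpressionCohort,
    table: DifferentialTable,
    config: PipelineConfig,
) -> tuple[list[str], list[str]]:
    """Genes with a monotone stage-wise expression trend.

    A gene is progressively upregulated when (a) it is overall significant
    with direction up, (b) its stage medians are nondecreasing from stage I
    to IV over stages with >= 2 tumors, and (c) the ordered trend test gives
    one-sided p < alpha. Progressively downregulated is the mirror.
    """
    by_stage = _stage_arrays(cohort)
    usable = {s: v for s, v in by_stage.items() if v.shape[1] >= 2}
    if len(usable) < 2:
        warnings.warn("fewer than two stages with >= 2 tumors; no trend testing")
        return [], []
    order = [s for s in KNOWN_STAGES if s in usable]
    sig = table.frame[table.frame["p"] < config.alpha]
    up_out, down_out = [], []
    gene_idx = {g: i for i, g in enumerate(cohort.genes)}
    for _, row in sig.iterrows():
        i = gene_idx[row["gene"]]
        groups = [usable[s][i] for s in order]
        medians = np.array([np.median(g) for g in groups])
        if row["direction"] == "up" and np.all(np.diff(medians) >= 0):
            _, p_tr = jonckheere_trend(groups, "increasing")
            if p_tr < config.alpha:
                up_out.append(row["gene"])
        elif row["direction"] == "down" and np.all(np.diff(medians) <= 0):
            _, p_tr = jonckheere_trend(groups, "decreasing")
            if p_tr < config.alpha:
                down_out.append(row["gene"])
    return up_out, down_out


def classify_patterns(
    cohort: ExpressionCohort,
    table: DifferentialTable,
    config: PipelineConfig,
) -> DifferentialTable:
    """Assign one pattern label per gene.

    Precedence: stage_specific, then progressive, then leading (the top-k
    remaining significant genes per direction), then not_significant. The
    stage-specific label additionally requires that the focal stage is the
    only stage significant in its direction and that the remaining stages
    are mutually homogeneous (Kruskal-Wallis p >= alpha) — this separates a
    single-stage spike from a stage-wise trend, which also elevates the
    focal-vs-rest contrast of the last stage.
    """
    frame = table.frame.copy()
    frame["pattern"] = "not_significant"
    frame["stage_specific_stage"] = ""
    gene_pos = {g: i for i, g in enumerate(cohort.genes)}

    by_stage = _stage_arrays(cohort)
    usable = {s: v for s, v in by_stage.items() if v.shape[1] >= 2}
    stage_hits_up = stage_specific_genes(cohort, table, config, "up") if usable else {}
    stage_hits_down = (
        stage_specific_genes(cohort, table, config, "down") if usable else {}
    )

    def _homogeneous_rest(gene: str, focal_stage: str) -> bool:
        rest = [usable[s][gene_pos[gene]] for s in usable if s != focal_stage]
        if len(rest) < 2:
            return True
        if np.ptp(np.concatenate(rest)) == 0:
            return True
        try:
            _, p_kw = stats.kruskal(*rest)
        except ValueError:  # all values identical
            return True
        return p_kw >= config.alpha

    stage_label: dict[str, str] = {}
    for hits, _dirn in ((stage_hits_up, "up"), (stage_hits_down, "down")):
        membership: dict[str, list[str]] = {}
        for stage, genes in hits.items():
            for g in genes:
                membership.setdefault(g, []).append(stage)
        for g, stages_of_g in membership.items():
            if len(stages_of_g) == 1 and _homogeneous_rest(g, stages_of_g[0]):
                if g not in stage_label:
                    stage_label[g] = stages_of_g[0]

    prog_up, prog_down = progressive_genes(cohort, table, config)
    prog_up = [g for g in prog_up if g not in stage_label]
    prog_down = [g for g in prog_down if g not in stage_label]

    taken = set(stage_label) | set(prog_up) | set(prog_down)
    frame_idx = frame.set_index("gene").index
    for g, s in stage_label.items():
        frame.loc[frame_idx.get_loc(g), "pattern"] = "stage_specific"
        frame.loc[frame_idx.get_loc(g), "stage_specific_stage"] = s
    for g in prog_up:
        frame.loc[frame_idx.get_loc(g), "pattern"] = "progressive_up"
    for g in prog_down:
        frame.loc[frame_idx.get_loc(g), "pattern"] = "progressive_down"

    tmp = DifferentialTable(frame=frame, alpha=table.alpha,
                            stage_counts=table.stage_counts)
    for dirn, label in (("up", "leading_up"), ("down", "leading_down")):
        sig = tmp.significant(dirn)
        remaining = [g for g in sig["gene"] if g not in taken]
        for g in remaining[: config.top_k]:
            frame.loc[frame_idx.get_loc(g), "pattern"] = label

    return DifferentialTable(frame=frame, alpha=table.alpha,
                             stage_counts=table.stage_counts)
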