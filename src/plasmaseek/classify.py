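"""Cross-validated linear-SVM evaluation of biomarker panels.

A candidate gene panel is evaluated as the feature set of a linear-kernel
support vector classifier separating tumor from normal samples, under
repeated stratified k-fold cross-validation (default 5 folds, 50 repeats).
Within each repeat, held-out decision scores are pooled across folds into a
single ROC curve/AUC; the panel's performance is the mean and SD of the
repeat AUCs, with a mean ROC curve obtained by vertical averaging on a
fixed 101-point false-positive-rate grid. Features are z-scored using
training-fold statistics only; the SVM uses C = 1 with no class weighting —
stratification alone handles the tumor/normal imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort_io import CohortError, ExpressionCohort, PipelineConfig

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class FeatureSet:
    """A labeled gene panel used as classifier features."""

    label: str  # 'upregulated' | 'downregulated' | 'random' | free-form
    genes: list[str]
    seed: int | None = None  # recorded for random draws

    def __post_init__(self) -> None:
        if not self.genes:
            raise CohortError("feature set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise CohortError("duplicate genes in feature set")


@dataclass
class RocSummary:
    label: str
    genes: list[str]
    mean_auc: float
    sd_auc: float
    auc_per_repeat: list[float]
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    n_repeats: int
    n_folds: int
    seed: int | None = None


def _pooled_roc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC and TPR interpolated on FPR_GRID from pooled held-out scores."""
    auc = roc_auc_score(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores)
    tpr_i = np.interp(FPR_GRID, fpr, tpr)
    tpr_i[0] = 0.0
    tpr_i[-1] = 1.0
    return float(auc), tpr_i


def evaluate_panel(
    cohort: ExpressionCohort,
    features: FeatureSet,
    config: PipelineConfig,
) -> RocSummary:
    """Repeated stratified-CV ROC/AUC of a gene panel.

    Repeat r uses split seed ``master_seed + r``; per fold a fresh
    StandardScaler + linear SVC are fit on the training samples only and the
    held-out decision values are pooled into that repeat's ROC curve.
    """
    missing = [g for g in features.genes if g not in set(cohort.genes)]
    if missing:
        raise CohortError(f"feature gene(s) absent from cohort: {missing}")
    sub = cohort.subset_genes(features.genes)
    x = sub.values.T  # samples x features
    y = sub.group_mask("tumor").astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise CohortError("both classes must be present")
    n_splits = config.cv_folds
    if min(y.sum(), y.size - y.sum()) < n_splits:
        raise CohortError(
            f"minority class has fewer samples than cv_folds={n_splits}"
        )

    aucs, tprs = [], []
    for r in range(1, config.cv_repeats + 1):
        seed = (config.master_seed + r) % (2**31)
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                  random_state=seed + 100_000 * attempt)
            splits = list(skf.split(x, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
                break
        scores = np.empty(y.size)
        for train, test in splits:
            scaler = StandardScaler().fit(x[train])
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(scaler.transform(x[train]), y[train])
            scores[test] = clf.decision_function(scaler.transform(x[test]))
        auc, tpr = _pooled_roc(scores, y)
        aucs.append(auc)
        tprs.append(tpr)

    aucs_arr = np.array(aucs)
    return RocSummary(
        label=features.label,
        genes=list(features.genes),
        mean_auc=float(aucs_arr.mean()),
        sd_auc=float(aucs_arr.std(ddof=1)) if len(aucs) > 1 else 0.0,
        auc_per_repeat=[float(a) for a in aucs],
        fpr_grid=FPR_GRID.copy(),
        mean_tpr=np.mean(tprs, axis=0),
        n_repeats=config.cv_repeats,
        n_folds=n_splits,
        seed=features.seed,
    )


def random_baseline(cohort: ExpressionCohort, config: PipelineConfig,
                    seed: int | None = None) -> RocSummary:
    """Evaluate a uniformly drawn random gene panel of the configured size."""
    if cohort.n_genes < config.random_gene_count:
        raise CohortError("cohort has fewer genes than random_gene_count")
    if seed is None:
        seed = (config.master_seed + 7919) % (2**31)
    rng = np.random.default_rng(seed)
    genes = [str(g) for g in rng.choice(cohort.genes,
                                        size=config.random_gene_count,
                                        replace=False)]
    return evaluate_panel(
        cohort, FeatureSet(label="random", genes=genes, seed=seed), config
    )


def compare_panels(summaries: list[RocSummary]) -> "pd.DataFrame":
    """Rank panels by mean AUC and flag superiority over the random baseline."""
    import pandas as pd

    if len(summaries) < 2:
        raise CohortError("need at least two summaries to compare")
    rows = [
        {
            "label": s.label,
            "mean_auc": s.mean_auc,
            "sd_auc": s.sd_auc,
            "n_genes": len(s.genes),
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows).sort_values(
        "mean_auc", ascending=False, kind="mergesort", ignore_index=True
    )
    baselines = [s.mean_auc for s in summaries if s.label == "random"]
    baseline = max(baselines) if baselines else None
    if baseline is None:
        df["beats_random"] = pd.NA
    else:
        df["beats_random"] = [
            (m > baseline) if lbl != "random" else pd.NA
            for m, lbl in zip(df["mean_auc"], df["label"])
        ]
    return df


def random_predictor_auc(
    n_samples: int = 200,
    n_repeats: int = 200,
    seed: int = 0,
    tumor_fraction: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Mean AUC of a predictor whose scores are independent of the labels.

    This is the diagonal-baseline check of the ROC machinery: scores drawn
    independently of class membership must average to AUC 0.5. Returns the
    mean and the per-repeat AUC values.
    """
    rng = np.random.default_rng(seed)
    n_tumor = int(round(n_samples * tumor_fraction))
    labels = np.array([1] * n_tumor + [0] * (n_samples - n_tumor))
    aucs = np.empty(n_repeats)
    for r in range(n_repeats):
        scores = rng.standard_normal(n_samples)
        aucs[r], _ = _pooled_roc(scores, labels)
    return float(aucs.mean()), aucs


def plot_mean_roc(summaries: list[RocSummary], path) -> None:
    """Overlay the mean ROC curves of several panels with the diagonal
    random-predictor baseline (AUC 0.5)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for s in summaries:
        ax.plot(s.fpr_grid, s.mean_tpr,
                label=f"{s.label} (AUC {s.mean_auc:.3f} ± {s.sd_auc:.3f})")
    ax.plot([0, 1], [0, 1], "b--", lw=1, label="random predictor (AUC 0.5)")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("mean ROC, repeated stratified 5-fold CV")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def auc_rank_estimate(scores, labels) -> float:
    """AUC via the rank-sum (Mann-Whitney) probability formulation.

    Serves as an internal cross-check of the ROC-integration AUC: the AUC
    equals P(score_tumor > score_normal) + 0.5 P(equal).
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = labels.sum()
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise CohortError("both classes required")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
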