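"""Cohort data model, file I/O and configuration.

The central container is :class:`ExpressionCohort`: a gene x sample matrix of
nonnegative normalized expression values (RSEM-normalized scale) together with
per-sample annotations (group: tumor/normal; tumor stage: I-IV or unknown).
All pipeline stages consume this object.

File formats
------------
* Expression matrix: TSV, first column header ``gene``, remaining headers are
  sample ids, one row per gene.
* Annotations: TSV with header ``sample_id<TAB>group<TAB>stage``.
* Gene panel: plain text, one symbol per line, ``#`` comments allowed.
* Config: flat YAML key/value file mirroring :class:`PipelineConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

GROUPS = ("tumor", "normal")
STAGES = ("I", "II", "III", "IV", "unknown")
KNOWN_STAGES = ("I", "II", "III", "IV")


class CohortError(ValueError):
    """Raised on malformed input files or invariant violations."""


def _normalize_stage(token: str) -> str:
    """Map a stage token to one of I/II/III/IV/unknown.

    Sub-stage suffixes (e.g. ``IIIa``, ``IVB``) collapse to the Roman-numeral
    prefix; matching is case-insensitive.
    """
    t = token.strip()
    if t.lower() in ("unknown", "na", "nan", ""):
        return "unknown"
    up = t.upper()
    for stage in ("IV", "III", "II", "I"):  # longest prefix first
        if up.startswith(stage):
            rest = up[len(stage):]
            if rest == "" or rest in ("A", "B", "C"):
                return stage
    raise CohortError(
        f"unrecognized stage token {token!r}; allowed: {', '.join(STAGES)} "
        "(sub-stages like 'IIa' are accepted)"
    )


@dataclass
class ExpressionCohort:
    """Gene x sample expression matrix plus per-sample annotations.

    Parameters
    ----------
    genes : list of str
        Ordered, unique gene symbols (rows).
    samples : list of str
        Ordered, unique sample ids (columns).
    values : ndarray of shape (n_genes, n_samples)
        Finite, nonnegative normalized expression.
    annotations : pandas.DataFrame or None
        Indexed by sample id with columns ``group`` and ``stage``. Normal
        samples must carry stage ``unknown`` (staging applies to tumors only).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise CohortError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        dup = pd.Index(self.genes)[pd.Index(self.genes).duplicated()]
        if len(dup):
            raise CohortError(f"duplicate gene symbol(s): {sorted(set(dup))}")
        dup = pd.Index(self.samples)[pd.Index(self.samples).duplicated()]
        if len(dup):
            raise CohortError(f"duplicate sample id(s): {sorted(set(dup))}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortError(
                f"non-finite value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise CohortError(
                f"negative expression value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if self.annotations is not None:
            self._validate_annotations(self.annotations)

    def _validate_annotations(self, anno: pd.DataFrame) -> None:
        missing = [s for s in self.samples if s not in anno.index]
        if missing:
            raise CohortError(f"samples missing annotation: {missing}")
        bad_group = anno.loc[~anno["group"].isin(GROUPS), "group"]
        if len(bad_group):
            raise CohortError(
                f"invalid group token(s) {sorted(set(bad_group))}; "
                f"allowed: {', '.join(GROUPS)}"
            )
        bad_stage = anno.loc[~anno["stage"].isin(STAGES), "stage"]
        if len(bad_stage):
            raise CohortError(
                f"invalid stage token(s) {sorted(set(bad_stage))}; "
                f"allowed: {', '.join(STAGES)}"
            )
        normals = anno[anno["group"] == "normal"]
        staged_normals = normals[normals["stage"] != "unknown"]
        if len(staged_normals):
            raise CohortError(
                "normal samples must have stage 'unknown': "
                f"{list(staged_normals.index)}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def _require_annotations(self) -> pd.DataFrame:
        if self.annotations is None:
            raise CohortError("cohort has no sample annotations attached")
        return self.annotations

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask over samples for ``group`` in ('tumor', 'normal')."""
        if group not in GROUPS:
            raise CohortError(f"unknown group {group!r}; allowed: {GROUPS}")
        anno = self._require_annotations()
        return np.array([anno.loc[s, "group"] == group for s in self.samples])

    def stage_mask(self, stage: str) -> np.ndarray:
        """Boolean mask for tumor samples of the given stage."""
        anno = self._require_annotations()
        return np.array(
            [
                anno.loc[s, "group"] == "tumor" and anno.loc[s, "stage"] == stage
                for s in self.samples
            ]
        )

    def group_values(self, group: str) -> np.ndarray:
        return self.values[:, self.group_mask(group)]

    def stage_counts(self) -> dict[str, int]:
        anno = self._require_annotations()
        tum = anno[anno["group"] == "tumor"]
        return {s: int((tum["stage"] == s).sum()) for s in STAGES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionCohort":
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise CohortError(f"genes absent from cohort: {missing}")
        rows = [idx[g] for g in genes]
        return ExpressionCohort(
            genes=list(genes),
            samples=list(self.samples),
            values=self.values[rows, :],
            annotations=self.annotations,
        )


@dataclass
class GenePanel:
    """Ordered set of gene symbols (e.g. the plasma-detectable proteome)."""

    symbols: list[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise CohortError("gene panel is empty")
        seen: set[str] = set()
        deduped = []
        for s in self.symbols:
            s = s.strip()
            if not s:
                continue
            if s not in seen:
                seen.add(s)
                deduped.append(s)
        self.symbols = deduped

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass
class PipelineConfig:
    """Tunable parameters shared across pipeline stages.

    alpha : two-sided significance level for all screening tests.
    top_k : number of leading genes per direction.
    soft_power_grid : candidate soft-threshold exponents for the network
        transforms.
    scale_free_r2_threshold : minimum signed R^2 of the scale-free topology
        fit for a soft power to be accepted.
    hard_threshold : edge weights strictly below this are removed.
    cv_folds / cv_repeats : stratified cross-validation geometry for the
        SVM panel evaluation.
    random_gene_count : size of the random-gene baseline feature set.
    distance_mode : 'inverse' (edge traversal length = 1/weight) or 'direct'
        (dissimilarity weights used as lengths unchanged).
    master_seed : seed from which all stochastic stages derive their streams.
    """

    alpha: float = 0.05
    top_k: int = 5
    soft_power_grid: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_threshold: float = 0.85
    hard_threshold: float = 0.01
    cv_folds: int = 5
    cv_repeats: int = 50
    random_gene_count: int = 5
    distance_mode: str = "inverse"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise CohortError(f"alpha must be in (0,1), got {self.alpha}")
        if self.top_k < 1:
            raise CohortError("top_k must be >= 1")
        if not 0 <= self.hard_threshold < 1:
            raise CohortError("hard_threshold must be in [0,1)")
        if self.cv_folds < 2:
            raise CohortError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise CohortError("cv_repeats must be >= 1")
        if not self.soft_power_grid:
            raise CohortError("soft_power_grid must be non-empty")
        if any(b < 1 for b in self.soft_power_grid):
            raise CohortError("soft powers must be >= 1")
        if self.distance_mode not in ("inverse", "direct"):
            raise CohortError("distance_mode must be 'inverse' or 'direct'")
        self.soft_power_grid = tuple(int(b) for b in self.soft_power_grid)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionCohort:
    """Read a TSV expression matrix (header ``gene`` + sample ids).

    Annotations are left unattached; see :func:`read_annotations`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CohortError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise CohortError(f"{path}: expected a gene column plus >=1 sample column")
    gene_col = df.columns[0]
    genes = [str(g).strip() for g in df[gene_col]]
    dup = pd.Index(genes)[pd.Index(genes).duplicated()]
    if len(dup):
        raise CohortError(f"{path}: duplicate gene symbol(s): {sorted(set(dup))}")
    samples = [str(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise CohortError(
            f"{path}: non-numeric value {body.iat[r, c]!r} at gene "
            f"{genes[r]!r}, sample {samples[c]!r}"
        )
    return ExpressionCohort(genes=genes, samples=samples, values=numeric.to_numpy(float))


def write_expression(cohort: ExpressionCohort, path: str | Path) -> None:
    df = cohort.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_annotations(path: str | Path, cohort: ExpressionCohort) -> ExpressionCohort:
    """Attach a sample annotation TSV (sample_id, group, stage) to a cohort.

    Annotated samples absent from the matrix are ignored with a warning;
    matrix samples without an annotation raise an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "stage"}
    if not required.issubset(df.columns):
        raise CohortError(
            f"{path}: annotation header must contain {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    df["sample_id"] = df["sample_id"].str.strip()
    groups = df["group"].str.strip().str.lower()
    bad = sorted(set(groups[~groups.isin(GROUPS)]))
    if bad:
        raise CohortError(
            f"{path}: invalid group token(s) {bad}; allowed: {', '.join(GROUPS)}"
        )
    stages = df["stage"].fillna("unknown").map(_normalize_stage)
    anno = pd.DataFrame(
        {"group": groups.to_numpy(), "stage": stages.to_numpy()},
        index=df["sample_id"],
    )
    extra = [s for s in anno.index if s not in set(cohort.samples)]
    if extra:
        warnings.warn(
            f"{len(extra)} annotated sample(s) absent from matrix, ignored: "
            f"{extra[:5]}{'...' if len(extra) > 5 else ''}"
        )
        anno = anno.drop(index=extra)
    out = replace(cohort, annotations=anno)
    return out


def write_annotations(cohort: ExpressionCohort, path: str | Path) -> None:
    anno = cohort._require_annotations()
    out = anno.loc[cohort.samples].reset_index()
    out.columns = ["sample_id", "group", "stage"]
    out.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> GenePanel:
    """Read a plain-text gene list (one symbol per line, # comments)."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    if not symbols:
        raise CohortError(f"{path}: no gene symbols found")
    return GenePanel(symbols=symbols)


def restrict_to_panel(
    cohort: ExpressionCohort, panel: GenePanel
) -> tuple[ExpressionCohort, list[str]]:
    """Restrict a cohort to the genes present in a panel.

    Returns the restricted cohort (original gene order preserved) and the
    list of panel symbols not found in the cohort. Matching is exact
    (case-sensitive) after whitespace trimming.
    """
    panel_set = set(panel.symbols)
    kept = [g for g in cohort.genes if g in panel_set]
    unmapped = [s for s in panel.symbols if s not in set(cohort.genes)]
    if not kept:
        raise CohortError("no panel gene is present in the cohort")
    return cohort.subset_genes(kept), unmapped


def read_config(path: str | Path) -> PipelineConfig:
    """Read a flat YAML key/value config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise CohortError(f"{path}: config must be a mapping")
    allowed = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise CohortError(f"{path}: unknown config key(s): {sorted(unknown)}")
    if "soft_power_grid" in raw:
        raw["soft_power_grid"] = tuple(raw["soft_power_grid"])
    return PipelineConfig(**raw)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
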