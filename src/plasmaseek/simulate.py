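"""Synthetic tumor/normal expression cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: an unbalanced tumor/normal cohort, stage labels with realistic
proportions, planted differential-expression patterns (global up/down,
stage-specific, progressively stage-trending), null genes, and
block-correlated gene modules driven by shared latent factors.

Generative model (per gene g, sample s), on the log2 scale:

    log2 x_gs = mu_g + sigma_g * (lambda * f_{m(g),s} + sqrt(1-lambda^2) * z_gs)
                + delta_gs

with f_{m,s} ~ N(0,1) a module factor shared by all genes of module m within
sample s, z_gs ~ N(0,1) idiosyncratic noise, and delta_gs the planted effect
in units of sigma_g (zero for normal samples and null genes). The emitted
value is 2**log2signal, so within-module pairs have Pearson correlation
lambda^2 on the log scale and every marginal has SD sigma_g.

Stage effects use stage indices I=1 .. IV=4: a ``stage_specific`` gene shifts
only its target stage by the full effect size; ``progressive`` genes shift
stage k tumors by effect_size * k/4. Tumors whose recorded stage is unknown
are assigned a latent stage for effect generation and then masked, mirroring
cohorts where staging is unrecorded rather than absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (
    KNOWN_STAGES,
    STAGES,
    CohortError,
    ExpressionCohort,
)

EFFECT_CLASSES = (
    "global_up",
    "global_down",
    "stage_specific",
    "progressive_up",
    "progressive_down",
    "null",
)

_STAGE_INDEX = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass(frozen=True)
class EffectSpec:
    """Planted differential-expression pattern for one gene.

    effect_size is expressed in units of the gene's own log2-scale SD, so a
    value of 1.5 shifts the affected tumors by 1.5 sigma.
    """

    gene: str
    klass: str
    effect_size: float = 0.0
    target_stage: str | None = None

    def __post_init__(self) -> None:
        if self.klass not in EFFECT_CLASSES:
            raise CohortError(f"unknown effect class {self.klass!r}")
        if self.effect_size < 0:
            raise CohortError("effect_size must be >= 0")
        if (self.effect_size == 0) != (self.klass == "null"):
            raise CohortError("effect_size must be 0 iff klass is 'null'")
        if (self.target_stage is not None) != (self.klass == "stage_specific"):
            raise CohortError("target_stage is set iff klass is 'stage_specific'")
        if self.target_stage is not None and self.target_stage not in _STAGE_INDEX:
            raise CohortError(f"target_stage must be one of {KNOWN_STAGES}")


@dataclass
class SimDesign:
    """Full specification of a synthetic cohort draw."""

    n_genes: int
    n_tumor: int
    n_normal: int
    stage_proportions: dict[str, float]
    effect_specs: list[EffectSpec] = field(default_factory=list)
    module_assignments: dict[str, int] = field(default_factory=dict)
    module_loading: float = 0.6
    baseline_log_mean_range: tuple[float, float] = (3.0, 12.0)
    baseline_log_sd_range: tuple[float, float] = (0.5, 1.5)
    rewire_tumor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise CohortError("need at least 2 tumor and 2 normal samples")
        if self.n_genes < 1:
            raise CohortError("n_genes must be >= 1")
        total = sum(self.stage_proportions.get(s, 0.0) for s in STAGES)
        if abs(total - 1.0) > 1e-9:
            raise CohortError(f"stage proportions must sum to 1, got {total}")
        if unknown := set(self.stage_proportions) - set(STAGES):
            raise CohortError(f"unknown stage key(s): {sorted(unknown)}")
        if not 0 <= self.module_loading < 1:
            raise CohortError("module_loading must be in [0, 1)")
        genes = self.gene_names()
        gene_set = set(genes)
        for spec in self.effect_specs:
            if spec.gene not in gene_set:
                raise CohortError(f"effect spec refers to unknown gene {spec.gene!r}")
        if len({s.gene for s in self.effect_specs}) != len(self.effect_specs):
            raise CohortError("multiple effect specs for the same gene")
        for g in self.module_assignments:
            if g not in gene_set:
                raise CohortError(f"module assignment for unknown gene {g!r}")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated cohort."""

    effects: dict[str, EffectSpec]
    stage_counts: dict[str, int]
    latent_stages: dict[str, str]
    module_assignments: dict[str, int]
    tumor_module_assignments: dict[str, int]

    def genes_of_class(self, klass: str) -> list[str]:
        return [g for g, spec in self.effects.items() if spec.klass == klass]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, spec in self.effects.items():
            rows.append(
                {
                    "gene": gene,
                    "klass": spec.klass,
                    "effect_size": spec.effect_size,
                    "target_stage": spec.target_stage or "",
                    "module": self.module_assignments.get(gene, -1),
                    "tumor_module": self.tumor_module_assignments.get(gene, -1),
                }
            )
        return pd.DataFrame(rows)


def _draw_stages(rng: np.random.Generator, design: SimDesign) -> tuple[list[str], list[str]]:
    """Draw (recorded, latent) stages for the tumor samples."""
    props = np.array([design.stage_proportions.get(s, 0.0) for s in STAGES])
    recorded = list(rng.choice(STAGES, size=design.n_tumor, p=props))
    known = np.array([design.stage_proportions.get(s, 0.0) for s in KNOWN_STAGES])
    if known.sum() <= 0:
        known = np.ones(4)
    known = known / known.sum()
    latent = [
        s if s != "unknown" else str(rng.choice(KNOWN_STAGES, p=known))
        for s in recorded
    ]
    return recorded, latent


def simulate_cohort(design: SimDesign) -> tuple[ExpressionCohort, SimTruth]:
    """Generate one cohort draw; fully deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    genes = design.gene_names()
    n_g = design.n_genes
    n_s = design.n_tumor + design.n_normal
    sample_ids = [f"T{i:04d}" for i in range(design.n_tumor)] + [
        f"N{i:04d}" for i in range(design.n_normal)
    ]
    is_tumor = np.array([True] * design.n_tumor + [False] * design.n_normal)

    recorded, latent = _draw_stages(rng, design)

    mu = rng.uniform(*design.baseline_log_mean_range, size=n_g)
    sigma = rng.uniform(*design.baseline_log_sd_range, size=n_g)

    # module factors: one standard-normal factor per (module, sample)
    lam = design.module_loading
    module_ids = sorted(set(design.module_assignments.values()))
    factors = {m: rng.standard_normal(n_s) for m in module_ids}

    tumor_modules = dict(design.module_assignments)
    if design.rewire_tumor and module_ids:
        # re-draw which genes belong to each tumor-group module: same module
        # sizes, members drawn uniformly from all genes
        sizes = {
            m: sum(1 for v in design.module_assignments.values() if v == m)
            for m in module_ids
        }
        pool = list(rng.permutation(genes))
        tumor_modules = {}
        pos = 0
        for m in module_ids:
            for g in pool[pos : pos + sizes[m]]:
                tumor_modules[g] = m
            pos += sizes[m]

    noise = rng.standard_normal((n_g, n_s))
    log2x = np.empty((n_g, n_s))
    effects = {spec.gene: spec for spec in design.effect_specs}
    stage_idx = np.array([_STAGE_INDEX[s] for s in latent])

    for i, g in enumerate(genes):
        struct = np.zeros(n_s)
        m_norm = design.module_assignments.get(g)
        m_tum = tumor_modules.get(g)
        if m_norm is not None or m_tum is not None:
            coef = np.sqrt(1.0 - lam * lam)
            for s in range(n_s):
                m = m_tum if is_tumor[s] else m_norm
                if m is None:
                    struct[s] = noise[i, s]
                else:
                    struct[s] = lam * factors[m][s] + coef * noise[i, s]
        else:
            struct = noise[i]
        row = mu[i] + sigma[i] * struct

        spec = effects.get(g, EffectSpec(gene=g, klass="null"))
        if spec.klass != "null":
            delta = np.zeros(n_s)
            tum = np.flatnonzero(is_tumor)
            if spec.klass == "global_up":
                delta[tum] = spec.effect_size
            elif spec.klass == "global_down":
                delta[tum] = -spec.effect_size
            elif spec.klass == "stage_specific":
                tgt = _STAGE_INDEX[spec.target_stage]
                delta[tum] = np.where(stage_idx == tgt, spec.effect_size, 0.0)
            elif spec.klass == "progressive_up":
                delta[tum] = spec.effect_size * stage_idx / 4.0
            elif spec.klass == "progressive_down":
                delta[tum] = -spec.effect_size * stage_idx / 4.0
            row = row + sigma[i] * delta
        log2x[i] = row

    values = np.clip(np.exp2(log2x), 0.0, None)

    anno = pd.DataFrame(
        {
            "group": ["tumor"] * design.n_tumor + ["normal"] * design.n_normal,
            "stage": recorded + ["unknown"] * design.n_normal,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = ExpressionCohort(
        genes=genes, samples=sample_ids, values=values, annotations=anno
    )
    full_effects = {
        g: effects.get(g, EffectSpec(gene=g, klass="null")) for g in genes
    }
    stage_counts = {s: recorded.count(s) for s in STAGES}
    truth = SimTruth(
        effects=full_effects,
        stage_counts=stage_counts,
        latent_stages=dict(zip(sample_ids[: design.n_tumor], latent)),
        module_assignments=dict(design.module_assignments),
        tumor_module_assignments=tumor_modules,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PRESETS = {
    "stomach_like": dict(
        n_tumor=415,
        n_normal=35,
        stage_proportions={
            "I": 0.137, "II": 0.296, "III": 0.407, "IV": 0.099, "unknown": 0.061,
        },
    ),
    "esophagus_like": dict(
        n_tumor=185,
        n_normal=11,
        stage_proportions={
            "I": 0.097, "II": 0.422, "III": 0.303, "IV": 0.049, "unknown": 0.129,
        },
    ),
}


def default_design(
    preset: str,
    seed: int = 0,
    *,
    n_genes: int = 500,
    effect_size: float = 1.5,
    rewire_tumor: bool = False,
) -> SimDesign:
    """Cohort design emulating the stomach or esophageal study layout.

    Both presets plant 5 genes per effect class (global up/down,
    stage-specific cycling over stages I-IV, progressive up/down) at the
    given effect size, plus 4 correlation modules of 20 genes with factor
    loading 0.6, in a 500-gene background.
    """
    if preset not in _PRESETS:
        raise CohortError(
            f"unknown preset {preset!r}; available: {sorted(_PRESETS)}"
        )
    base = _PRESETS[preset]
    genes = [f"G{i:04d}" for i in range(n_genes)]
    specs: list[EffectSpec] = []
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = genes[cursor : cursor + k]
        cursor += k
        return out

    for g in take(5):
        specs.append(EffectSpec(g, "global_up", effect_size))
    for g in take(5):
        specs.append(EffectSpec(g, "global_down", effect_size))
    for j, g in enumerate(take(5)):
        specs.append(
            EffectSpec(g, "stage_specific", effect_size,
                       target_stage=KNOWN_STAGES[j % 4])
        )
    for g in take(5):
        specs.append(EffectSpec(g, "progressive_up", effect_size))
    for g in take(5):
        specs.append(EffectSpec(g, "progressive_down", effect_size))

    # 4 modules of 20 genes each, drawn from the null background
    modules: dict[str, int] = {}
    for m in range(4):
        for g in take(20):
            modules[g] = m

    return SimDesign(
        n_genes=n_genes,
        effect_specs=specs,
        module_assignments=modules,
        module_loading=0.6,
        rewire_tumor=rewire_tumor,
        seed=seed,
        **base,
    )


def write_simulation(
    cohort: ExpressionCohort, truth: SimTruth, out_dir: str | Path
) -> dict[str, str]:
    """Write expression, annotations and truth TSVs; returns the paths."""
    from .cohort_io import write_annotations, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "annotations": str(out / "annotations.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_expression(cohort, paths["expression"])
    write_annotations(cohort, paths["annotations"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
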