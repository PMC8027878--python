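import numpy as np
import pandas as pd
import pytest

from plasmaseek import ExpressionCohort, PipelineConfig, SimDesign

EVEN_STAGES = {"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.2, "unknown": 0.05}
STOMACH_STAGES = {
    "I": 0.137, "II": 0.296, "III": 0.407, "IV": 0.099, "unknown": 0.061,
}


@pytest.fixture
def tiny_cohort() -> ExpressionCohort:
    """3 genes x 4 samples (2 tumor / 2 normal) with annotations."""
    anno = pd.DataFrame(
        {
            "group": ["tumor", "tumor", "normal", "normal"],
            "stage": ["I", "II", "unknown", "unknown"],
        },
        index=pd.Index(["T1", "T2", "N1", "N2"], name="sample_id"),
    )
    return ExpressionCohort(
        genes=["BIRC5", "APOC2", "CENPF"],
        samples=["T1", "T2", "N1", "N2"],
        values=np.array(
            [[10.0, 12.0, 1.0, 2.0], [5.0, 6.0, 5.5, 6.5], [0.0, 3.0, 2.0, 1.0]]
        ),
        annotations=anno,
    )


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def make_null_design(
    seed: int,
    n_genes: int = 200,
    n_tumor: int = 415,
    n_normal: int = 35,
    modules: bool = False,
    module_loading: float = 0.6,
    stage_proportions: dict | None = None,
) -> SimDesign:
    """An all-null cohort design, optionally with 4 correlation modules."""
    genes = [f"G{i:04d}" for i in range(n_genes)]
    mod = {}
    if modules:
        for m in range(4):
            for g in genes[m * 20 : (m + 1) * 20]:
                mod[g] = m
    return SimDesign(
        n_genes=n_genes,
        n_tumor=n_tumor,
        n_normal=n_normal,
        stage_proportions=stage_proportions or dict(STOMACH_STAGES),
        module_assignments=mod,
        module_loading=module_loading,
        seed=seed,
    )
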