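"""Screening-stage tests, anchored on an exhaustive rank-assignment oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from plasmaseek import (
    CohortError,
    EffectSpec,
    ExpressionCohort,
    PipelineConfig,
    SimDesign,
    default_design,
    jonckheere_trend,
    leading_genes,
    mann_whitney,
    progressive_genes,
    screen,
    simulate_cohort,
    stage_specific_genes,
)
from tests.conftest import EVEN_STAGES


def exact_mwu_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Independent of the implementation under test: for tie-free pooled data,
    every C(n1+n2, n1) assignment of the pooled ranks to the first group is
    equally likely under H0.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = x.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(pooled.size), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_matches_exhaustive_oracle_small_samples(self):
        """Exact agreement with rank enumeration for all sizes up to 6."""
        rng = np.random.default_rng(42)
        for n1 in range(2, 7):
            for n2 in range(2, 7):
                for _ in range(3):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                    u, p = mann_whitney(x, y)
                    u_ref, p_ref = exact_mwu_oracle(x, y)
                    assert u == u_ref
                    assert p == pytest.approx(p_ref, abs=1e-12)

    def test_separated_groups_frozen_example(self):
        u, p = mann_whitney([10, 11, 12], [1, 2, 3])
        assert u == 9
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_central(self):
        u, p = mann_whitney([1, 2], [1, 2])
        assert p == 1.0

    def test_complement_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n1, n2 = rng.integers(2, 10, size=2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            u_xy, _ = mann_whitney(x, y)
            u_yx, _ = mann_whitney(y, x)
            assert u_xy + u_yx == pytest.approx(n1 * n2)

    def test_small_group_rejected(self):
        with pytest.raises(CohortError):
            mann_whitney([1.0], [2.0, 3.0])

    def test_all_tied_pooled_data(self):
        u, p = mann_whitney([5, 5, 5], [5, 5])
        assert (u, p) == (3.0, 1.0)


class TestJonckheere:
    def test_statistic_is_sum_of_pairwise_u(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        groups = [rng.normal(size=n) for n in (4, 6, 5)]
        jt, _ = jonckheere_trend(groups)
        expected = sum(
            mannwhitneyu(groups[j], groups[i], alternative="two-sided").statistic
            for i in range(3)
            for j in range(i + 1, 3)
        )
        assert jt == pytest.approx(expected)

    def test_detects_increasing_trend(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc=mu, size=30) for mu in (0, 1, 2, 3)]
        _, p_inc = jonckheere_trend(groups, "increasing")
        _, p_dec = jonckheere_trend(groups, "decreasing")
        assert p_inc < 1e-6
        assert p_dec > 0.5

    def test_null_not_significant_usually(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            jonckheere_trend(
                [rng.normal(size=20) for _ in range(4)], "increasing"
            )[1] < 0.05
            for _ in range(100)
        )
        # one-sided alpha=0.05: 99% binomial interval roughly [0, 11]
        assert rejections <= 11


def _staged_cohort(stage_values: dict[str, list[float]],
                   normal_values: list[float],
                   extra_null_genes: int = 0,
                   seed: int = 0) -> ExpressionCohort:
    """Cohort with one focal gene given explicit per-stage tumor values."""
    rng = np.random.default_rng(seed)
    samples, groups, stages, row = [], [], [], []
    for stage, vals in stage_values.items():
        for v in vals:
            samples.append(f"T{len(samples)}")
            groups.append("tumor")
            stages.append(stage)
            row.append(v)
    for v in normal_values:
        samples.append(f"N{len(samples)}")
        groups.append("normal")
        stages.append("unknown")
        row.append(v)
    genes = ["FOCAL"] + [f"NULL{i}" for i in range(extra_null_genes)]
    values = [row] + [rng.uniform(1, 100, size=len(row)).tolist()
                      for _ in range(extra_null_genes)]
    anno = pd.DataFrame({"group": groups, "stage": stages},
                        index=pd.Index(samples, name="sample_id"))
    return ExpressionCohort(genes=genes, samples=samples,
                            values=np.array(values), annotations=anno)


class TestScreen:
    def test_planted_global_genes_lead(self):
        design = default_design("stomach_like", seed=7, effect_size=2.0)
        cohort, truth = simulate_cohort(design)
        table = screen(cohort, PipelineConfig())
        up = leading_genes(table, "up", 5)
        down = leading_genes(table, "down", 5)
        assert set(up) == set(truth.genes_of_class("global_up"))
        assert set(down) == set(truth.genes_of_class("global_down"))
        sig = table.frame.set_index("gene")
        for g in up:
            assert sig.loc[g, "direction"] == "up"
            assert sig.loc[g, "p"] < 0.05

    def test_table_sorted_by_p(self):
        design = default_design("stomach_like", seed=3, n_genes=60)
        cohort, _ = simulate_cohort(design)
        table = screen(cohort, PipelineConfig())
        assert table.frame["p"].is_monotonic_increasing

    def test_permutation_of_samples_is_irrelevant(self):
        design = default_design("stomach_like", seed=5, n_genes=40)
        cohort, _ = simulate_cohort(design)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n_samples)
        shuffled = ExpressionCohort(
            genes=cohort.genes,
            samples=[cohort.samples[i] for i in perm],
            values=cohort.values[:, perm],
            annotations=cohort.annotations,
        )
        t1 = screen(cohort, PipelineConfig())
        t2 = screen(shuffled, PipelineConfig())
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_constant_gene_inert(self):
        cohort = _staged_cohort(
            {"I": [5.0, 5.0], "II": [5.0, 5.0]}, [5.0, 5.0], extra_null_genes=2
        )
        table = screen(cohort, PipelineConfig())
        row = table.frame.set_index("gene").loc["FOCAL"]
        assert row["p"] == 1.0
        assert row["direction"] == "none"

    def test_no_normals_errors(self):
        design = default_design("stomach_like", seed=1, n_genes=30)
        cohort, _ = simulate_cohort(design)
        tumors_only = ExpressionCohort(
            genes=cohort.genes,
            samples=cohort.samples[:50],
            values=cohort.values[:, :50],
            annotations=cohort.annotations,
        )
        with pytest.raises(CohortError):
            screen(tumors_only, PipelineConfig())

    def test_leading_genes_empty_when_nothing_significant(self):
        frame = pd.DataFrame(
            {
                "gene": ["A", "B"],
                "U": [1.0, 2.0],
                "p": [0.4, 0.9],
                "q": [0.9, 0.9],
                "direction": ["none", "none"],
                "pattern": ["not_significant"] * 2,
            }
        )
        from plasmaseek.screening import DifferentialTable

        table = DifferentialTable(frame=frame, alpha=0.05, stage_counts={})
        with pytest.warns(UserWarning):
            assert leading_genes(table, "up", 5) == []


class TestPatternOps:
    def test_planted_stage_specific_listed_only_for_its_stage(self):
        vals = {
            "I": list(np.linspace(10, 12, 20)),
            "II": list(np.linspace(30, 36, 20)),
            "III": list(np.linspace(10, 12, 20)),
            "IV": list(np.linspace(10, 12, 20)),
        }
        cohort = _staged_cohort(vals, list(np.linspace(10, 12, 10)),
                                extra_null_genes=3)
        table = screen(cohort, PipelineConfig())
        hits = stage_specific_genes(cohort, table, PipelineConfig())
        assert "FOCAL" in hits.get("II", [])
        for stage in ("I", "III", "IV"):
            assert "FOCAL" not in hits.get(stage, [])

    def test_all_unknown_stages_gives_empty_map(self):
        cohort = _staged_cohort({"unknown": [1.0, 2.0, 3.0]}, [1.0, 2.0, 3.0],
                                extra_null_genes=1)
        table = screen(cohort, PipelineConfig())
        with pytest.warns(UserWarning):
            hits = stage_specific_genes(cohort, table, PipelineConfig())
        assert hits == {}

    def test_decreasing_medians_flag_progressive_down(self):
        vals = {
            "I": list(np.linspace(50, 52, 15)),
            "II": list(np.linspace(40, 42, 15)),
            "III": list(np.linspace(30, 32, 15)),
            "IV": list(np.linspace(20, 22, 15)),
        }
        cohort = _staged_cohort(vals, list(np.linspace(60, 62, 10)),
                                extra_null_genes=3)
        table = screen(cohort, PipelineConfig())
        up, down = progressive_genes(cohort, table, PipelineConfig())
        assert "FOCAL" in down
        assert "FOCAL" not in up
        assert (
            table.frame.set_index("gene").loc["FOCAL", "pattern"]
            == "progressive_down"
        )

    def test_flat_global_shift_not_progressive(self):
        vals = {s: list(np.linspace(30, 33, 15)) for s in
                ("I", "II", "III", "IV")}
        cohort = _staged_cohort(vals, list(np.linspace(10, 12, 10)),
                                extra_null_genes=3, seed=4)
        table = screen(cohort, PipelineConfig())
        up, down = progressive_genes(cohort, table, PipelineConfig())
        assert "FOCAL" not in up and "FOCAL" not in down

    def test_single_stage_cohort_no_trend(self):
        cohort = _staged_cohort({"II": [30.0, 31.0, 29.0, 33.0]},
                                [10.0, 11.0, 12.0], extra_null_genes=1)
        table = screen(cohort, PipelineConfig())
        with pytest.warns(UserWarning):
            up, down = progressive_genes(cohort, table, PipelineConfig())
        assert up == [] and down == []

    def test_pattern_vocabulary(self):
        design = default_design("stomach_like", seed=11, effect_size=2.0)
        cohort, _ = simulate_cohort(design)
        table = screen(cohort, PipelineConfig())
        from plasmaseek.screening import PATTERNS

        assert set(table.frame["pattern"]).issubset(set(PATTERNS))
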