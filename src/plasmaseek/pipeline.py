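"""End-to-end orchestration: simulate/load -> screen -> network -> RCC -> classify.

``run_all`` executes the full analysis from either a simulation preset or
user-supplied expression/annotation/panel files, wires the leading genes of
the screen into the RCC contrast and the SVM panel evaluation, and writes a
machine-readable run manifest listing every output, seed and warning.
``report`` renders a manifest into a human-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import rcc, wilcoxon_paired
from .classify import FeatureSet, compare_panels, evaluate_panel, random_baseline
from .cohort_io import (
    CohortError,
    ExpressionCohort,
    PipelineConfig,
    read_annotations,
    read_expression,
    read_panel,
    restrict_to_panel,
    write_config,
)
from .network import build_pair, write_layer
from .screening import leading_genes, progressive_genes, screen, stage_specific_genes
from .simulate import default_design, simulate_cohort, write_simulation

STAGE_ORDER = ("simulate", "screen", "network", "rcc", "classify")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    *,
    preset: str | None = None,
    expression: str | Path | None = None,
    annotations: str | Path | None = None,
    panel: str | Path | None = None,
) -> dict:
    """Run every pipeline stage in order and write a run manifest.

    Either ``preset`` (synthetic cohort) or ``expression`` + ``annotations``
    (real inputs, optionally restricted to a plasma ``panel``) must be given.
    Returns the manifest dict; the same content is written to
    ``<out_dir>/manifest.json``.
    """
    if (preset is None) == (expression is None):
        raise CohortError("provide exactly one of 'preset' or 'expression'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
        },
        "seeds": {"master": config.master_seed},
        "inputs": {},
        "outputs": {},
        "warnings": [],
        "stages_completed": [],
    }
    collected: list[str] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self._cm = _warnings.catch_warnings(record=True)
                self._log = self._cm.__enter__()
                _warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                for w in self._log:
                    collected.append(f"[{name}] {w.message}")
                self._cm.__exit__(exc_type, exc, tb)
                if exc_type is None:
                    manifest["stages_completed"].append(name)
                else:
                    manifest["failed_stage"] = name
                    manifest["warnings"] = collected
                    _dump_json(manifest, out / "manifest.partial.json")
                return False

        return _Ctx()

    # -- stage 1: obtain the cohort -------------------------------------
    with _stage("simulate"):
        if preset is not None:
            design = default_design(preset, seed=config.master_seed)
            cohort, truth = simulate_cohort(design)
            paths = write_simulation(cohort, truth, out / "simulated")
            manifest["outputs"]["simulate"] = paths
            manifest["seeds"]["simulate"] = design.seed
            manifest["inputs"]["preset"] = preset
        else:
            cohort = read_expression(expression)
            cohort = read_annotations(annotations, cohort)
            manifest["inputs"]["expression"] = str(expression)
            manifest["inputs"]["annotations"] = str(annotations)
            manifest["inputs"]["digests"] = {
                "expression": _digest(Path(expression)),
                "annotations": _digest(Path(annotations)),
            }
            if panel is not None:
                gene_panel = read_panel(panel)
                cohort, unmapped = restrict_to_panel(cohort, gene_panel)
                manifest["inputs"]["panel"] = str(panel)
                manifest["inputs"]["digests"]["panel"] = _digest(Path(panel))
                manifest["inputs"]["unmapped_panel_genes"] = unmapped

    # -- stage 2: differential screen ------------------------------------
    with _stage("screen"):
        table = screen(cohort, config)
        screen_tsv = out / "screen.tsv"
        table.frame.to_csv(screen_tsv, sep="\t", index=False,
                           float_format="%.10g")
        up = leading_genes(table, "up", config.top_k)
        down = leading_genes(table, "down", config.top_k)
        stage_map = stage_specific_genes(cohort, table, config)
        prog_up, prog_down = progressive_genes(cohort, table, config)
        summary = {
            "alpha": config.alpha,
            "n_significant": int((table.frame["p"] < config.alpha).sum()),
            "leading_up": up,
            "leading_down": down,
            "stage_specific": stage_map,
            "progressive_up": prog_up,
            "progressive_down": prog_down,
            "stage_counts": table.stage_counts,
        }
        screen_json = out / "screen_summary.json"
        _dump_json(summary, screen_json)
        manifest["outputs"]["screen"] = {
            "table": str(screen_tsv), "summary": str(screen_json),
        }

    # -- stage 3: dual networks ------------------------------------------
    with _stage("network"):
        pairs = {}
        net_out = {}
        for group in ("normal", "tumor"):
            pair = build_pair(cohort, group, config)
            pairs[group] = pair
            files = {}
            for layer in (pair.similarity, pair.dissimilarity):
                p = out / f"network_{group}_{layer.kind}.tsv"
                write_layer(layer, p)
                files[layer.kind] = str(p)
            side = out / f"network_{group}.json"
            _dump_json(
                {
                    "group": group,
                    "beta": pair.beta,
                    "scale_free_r2": pair.scale_free_r2,
                    "hard_threshold": config.hard_threshold,
                    "n_genes": len(pair.similarity.genes),
                },
                side,
            )
            files["sidecar"] = str(side)
            net_out[group] = files
        manifest["outputs"]["network"] = net_out

    # -- stage 4: RCC centrality -----------------------------------------
    with _stage("rcc"):
        biomarkers = up + down
        rcc_table = rcc(pairs["normal"], pairs["tumor"], config.distance_mode)
        rcc_tsv = out / "rcc.tsv"
        rcc_table.frame.to_csv(rcc_tsv, sep="\t", index=False,
                               float_format="%.10g")
        rcc_out = {"table": str(rcc_tsv)}
        if biomarkers:
            sub = rcc_table.frame.set_index("gene").loc[biomarkers]
            test = wilcoxon_paired(sub["log2_RCC_N"].to_numpy(),
                                   sub["log2_RCC_P"].to_numpy())
            test_json = out / "rcc_test.json"
            _dump_json(
                {
                    "biomarkers": biomarkers,
                    "W": test.w_statistic,
                    "p": test.p_value,
                    "n_pairs": test.n_pairs,
                    "n_dropped": test.n_dropped,
                },
                test_json,
            )
            rcc_out["test"] = str(test_json)
        else:
            collected.append("[rcc] no leading genes; paired test skipped")
        manifest["outputs"]["rcc"] = rcc_out

    # -- stage 5: SVM panel evaluation ------------------------------------
    with _stage("classify"):
        summaries = []
        if up:
            summaries.append(
                evaluate_panel(cohort, FeatureSet("upregulated", up), config)
            )
        if down:
            summaries.append(
                evaluate_panel(cohort, FeatureSet("downregulated", down), config)
            )
        baseline = random_baseline(cohort, config)
        summaries.append(baseline)
        manifest["seeds"]["random_panel"] = baseline.seed
        cls_out = {}
        panel_payload = []
        roc_frames = []
        for s in summaries:
            panel_payload.append(
                {
                    "label": s.label,
                    "genes": s.genes,
                    "mean_auc": s.mean_auc,
                    "sd_auc": s.sd_auc,
                    "n_repeats": s.n_repeats,
                    "n_folds": s.n_folds,
                }
            )
            roc_frames.append(
                pd.DataFrame(
                    {"label": s.label, "fpr": s.fpr_grid, "mean_tpr": s.mean_tpr}
                )
            )
        panels_json = out / "panels.json"
        _dump_json(panel_payload, panels_json)
        roc_tsv = out / "roc_curves.tsv"
        pd.concat(roc_frames, ignore_index=True).to_csv(
            roc_tsv, sep="\t", index=False, float_format="%.10g"
        )
        cls_out["panels"] = str(panels_json)
        cls_out["roc"] = str(roc_tsv)
        from .classify import plot_mean_roc

        roc_png = out / "roc_curves.png"
        plot_mean_roc(summaries, roc_png)
        cls_out["roc_plot"] = str(roc_png)
        if len(summaries) >= 2:
            cmp_tsv = out / "panel_comparison.tsv"
            compare_panels(summaries).to_csv(cmp_tsv, sep="\t", index=False,
                                             float_format="%.10g")
            cls_out["comparison"] = str(cmp_tsv)
        manifest["outputs"]["classify"] = cls_out

    manifest["warnings"] = collected
    config_path = out / "config_used.yaml"
    write_config(config, config_path)
    manifest["outputs"]["config"] = str(config_path)
    _dump_json(manifest, out / "manifest.json")
    manifest["manifest_path"] = str(out / "manifest.json")
    return manifest


def report(manifest: dict) -> str:
    """Render a completed run manifest as a plain-text summary."""
    missing = [s for s in ("screen", "network", "rcc") if s not in
               manifest.get("stages_completed", [])]
    if missing:
        raise CohortError(f"manifest incomplete; missing stage(s): {missing}")
    lines = ["plasmaseek run summary", "=" * 22, ""]

    lines.append("[cohort]")
    inputs = manifest.get("inputs", {})
    if "preset" in inputs:
        lines.append(f"  synthetic preset: {inputs['preset']}")
    else:
        lines.append(f"  expression: {inputs.get('expression')}")
    lines.append("")

    screen_summary = json.loads(
        Path(manifest["outputs"]["screen"]["summary"]).read_text()
    )
    lines.append("[differential screen]")
    lines.append(f"  significant genes (p < {screen_summary['alpha']}): "
                 f"{screen_summary['n_significant']}")
    lines.append(f"  leading upregulated:   {', '.join(screen_summary['leading_up']) or '-'}")
    lines.append(f"  leading downregulated: {', '.join(screen_summary['leading_down']) or '-'}")
    lines.append("")

    lines.append("[stage-specific genes]")
    stage_map = screen_summary["stage_specific"]
    if any(stage_map.values()):
        for stage, genes in stage_map.items():
            if genes:
                lines.append(f"  stage {stage}: {', '.join(genes)}")
    else:
        lines.append("  none detected")
    lines.append("")

    lines.append("[progressive genes]")
    lines.append(f"  up:   {', '.join(screen_summary['progressive_up']) or '-'}")
    lines.append(f"  down: {', '.join(screen_summary['progressive_down']) or '-'}")
    lines.append("")

    lines.append("[network / RCC]")
    for group in ("normal", "tumor"):
        side = json.loads(
            Path(manifest["outputs"]["network"][group]["sidecar"]).read_text()
        )
        lines.append(
            f"  {group}: beta={side['beta']}, scale-free R^2="
            f"{side['scale_free_r2']:.3f}"
        )
    rcc_out = manifest["outputs"]["rcc"]
    if "test" in rcc_out:
        test = json.loads(Path(rcc_out["test"]).read_text())
        lines.append(
            f"  paired Wilcoxon on log2(RCC): W={test['W']:.1f}, "
            f"p={test['p']:.3g} ({test['n_pairs']} pairs, "
            f"{test['n_dropped']} dropped)"
        )
    else:
        lines.append("  paired Wilcoxon: not run")
    lines.append("")

    lines.append("[panel classification]")
    if "classify" in manifest.get("stages_completed", []):
        panels = json.loads(
            Path(manifest["outputs"]["classify"]["panels"]).read_text()
        )
        for p in panels:
            lines.append(
                f"  {p['label']:<14} mean AUC = {p['mean_auc']:.4f} "
                f"(SD {p['sd_auc']:.4f}, {p['n_repeats']}x{p['n_folds']}-fold CV)"
            )
    else:
        lines.append("  not run")
    lines.append("")
    return "\n".join(lines)
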