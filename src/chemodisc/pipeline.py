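"""End-to-end orchestration: simulate/read -> preprocess -> explore -> split
-> select -> evaluate, with seeded reproducibility and on-disk artifacts.

A run writes a self-contained directory: the (replicate-level) dataset, the
exploratory summaries (PCA scores/loadings, dendrogram), the Kennard-Stone
split, one selection result per method, the evaluation reports and a
manifest snapshotting the configuration.  Re-running with the same config
and seed reproduces every artifact.

The single run seed is expanded into independent per-stage seeds with a
fixed splitting rule, so e.g. changing the GA settings never perturbs the
synthetic data.

Because the per-spectrum preprocessing stages (smoothing, baseline, min-max)
are row-local, they are applied to all rows once; mean-centering -- the only
cross-row stage -- is fitted globally for the exploratory view and refitted
on the training rows for the supervised stages, so the test partition never
leaks into the model.  Kennard-Stone distances are unchanged by either
centering (a common shift preserves pairwise distances).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import SpectralDataset, read_dataset, write_dataset, average_replicates
from .synthetic import generate_dataset, uv_default_config, ftir_default_config
from .preprocessing import PreprocessConfig, preprocess_dataset, mean_center
from .exploratory import pca, hca, two_group_separation
from .partitioning import stratified_split
from .selection import SPAConfig, GAConfig, spa_select, ga_select, fisher_weights
from .discriminant import evaluate_split

__all__ = ["RunConfig", "run_pipeline", "report_render", "BAND_ANNOTATIONS"]

# Tentative chemical assignments of the discriminant bands for the
# Lupinus/Mimosa extract problem (static lookup joined on nearest axis value).
BAND_ANNOTATIONS = {
    "uv": [
        (259.0, "Band II (Ring A) absorption of isoflavones",
         "genistein and derivatives (Lupinus)"),
        (284.0, "Band II absorption / phenolic B-ring",
         "hydroxyl/methoxyl substitution variation"),
        (358.0, "Band I (Ring B) absorption of flavonols",
         "flavones and flavonols, e.g. quercetin (Mimosa)"),
    ],
    "ftir": [
        (1658.0, "C=O stretching (Amide I)",
         "carbonyl groups of quinolizidine alkaloids (Lupinus)"),
        (1561.0, "N-H bending / C=C ring stretching",
         "aromatic and amide components"),
        (1105.0, "C-O stretching vibrations",
         "flavonoid glycosides and phenolic backbones (Mimosa)"),
    ],
}
ANNOTATION_TOL = {"uv": 3.0, "ftir": 6.0}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    modality: str = "uv"
    input_csv: str | None = None  # None -> simulate
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train_fraction: float = 2.0 / 3.0
    method: str = "both"  # spa | ga | both
    spa: SPAConfig = field(default_factory=SPAConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    # population/generation combinations to try for GA; best-cost flagged
    ga_combos: list = field(default_factory=lambda: [(100, 100), (200, 200), (300, 300)])
    average_replicates: bool = True
    hca_linkage: str = "average"
    seed: int = 0
    output_dir: str = "run"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "preprocess" in kwargs and isinstance(kwargs["preprocess"], dict):
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "spa" in kwargs and isinstance(kwargs["spa"], dict):
            kwargs["spa"] = SPAConfig(**kwargs["spa"])
        if "ga" in kwargs and isinstance(kwargs["ga"], dict):
            kwargs["ga"] = GAConfig(**kwargs["ga"])
        if "ga_combos" in kwargs:
            kwargs["ga_combos"] = [tuple(c) for c in kwargs["ga_combos"]]
        return cls(**kwargs)

    def stage_seeds(self) -> dict:
        """Fixed expansion of the run seed into per-stage seeds (< 2**31)."""
        state = np.random.SeedSequence(self.seed).generate_state(4, dtype=np.uint64)
        names = ("simulate", "ga", "spare1", "spare2")
        return {k: int(v % (2**31)) for k, v in zip(names, state)}


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    if hasattr(o, "__dict__"):
        return o.__dict__
    return str(o)


def _fom_block(report: dict) -> dict:
    out = {
        "cv": {
            "counts": report["cv"]["counts"].to_dict(),
            "fom": report["cv"]["fom"].to_dict(),
        },
        "test_absent": report.get("test_absent", False),
    }
    if report.get("test"):
        out["test"] = {
            "counts": report["test"]["counts"].to_dict(),
            "fom": report["test"]["fom"].to_dict(),
        }
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write artifacts; returns the manifest dict.

    Stage order: simulate/read, replicate averaging, per-spectrum
    preprocessing, exploratory PCA/HCA (globally centered), per-class
    Kennard-Stone split, variable selection (SPA and/or GA) on the
    train-centered matrix, LDA evaluation with LOO-CV and test figures.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    stage = "simulate"
    try:
        if cfg.input_csv:
            ds = read_dataset(cfg.input_csv, modality=cfg.modality)
            gt = None
        else:
            syn_cfg = (
                uv_default_config(seed=seeds["simulate"])
                if cfg.modality == "uv"
                else ftir_default_config(seed=seeds["simulate"])
            )
            ds, gt = generate_dataset(syn_cfg)
            write_dataset(ds, out / "dataset.csv")
            _json_dump(gt.to_dict(), out / "ground_truth.json")

        stage = "average"
        samples = average_replicates(ds) if cfg.average_replicates else ds

        stage = "preprocess"
        row_cfg = PreprocessConfig(
            sg_window=cfg.preprocess.sg_window,
            sg_polyorder=cfg.preprocess.sg_polyorder,
            baseline_mode=cfg.preprocess.baseline_mode,
            normalize=cfg.preprocess.normalize,
            center="none",
        )
        pre, _ = preprocess_dataset(samples, row_cfg)

        stage = "explore"
        X_global, _ = mean_center(pre.intensities)
        k = min(2, min(X_global.shape[0] - 1, X_global.shape[1]))
        pca_res = pca(X_global, k)
        dendro = hca(X_global, linkage=cfg.hca_linkage, leaf_labels=pre.sample_ids)
        purity = two_group_separation(dendro, pre.classes)
        pd.DataFrame(
            pca_res.scores,
            index=pre.sample_ids,
            columns=[f"PC{i+1}" for i in range(k)],
        ).to_csv(out / "pca_scores.csv")
        pd.DataFrame(
            pca_res.loadings,
            index=pre.axis,
            columns=[f"PC{i+1}" for i in range(k)],
        ).to_csv(out / "pca_loadings.csv")
        _json_dump(
            {
                "explained_variance_pct": pca_res.explained_variance_ratio.tolist(),
                "two_group_purity": purity,
                "hca_linkage": cfg.hca_linkage,
            },
            out / "exploratory.json",
        )
        (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        _json_dump(dendro.merge_table(), out / "dendrogram.json")

        stage = "split"
        split = stratified_split(pre, cfg.train_fraction)
        _json_dump(split.to_dict(), out / "split.json")

        stage = "supervised-centering"
        train_idx = np.asarray(split.train_indices)
        test_idx = np.asarray(split.test_indices)
        if cfg.preprocess.center == "global_mean":
            means = pre.intensities[train_idx].mean(axis=0)
            X = pre.intensities - means
        else:
            X = pre.intensities.copy()
        y = pre.class_vector()
        X_train, y_train = X[train_idx], y[train_idx]
        X_test, y_test = X[test_idx], y[test_idx]

        selections = {}
        if cfg.method in ("spa", "both"):
            stage = "select-spa"
            selections["spa"] = spa_select(X_train, y_train, cfg.spa)
        if cfg.method in ("ga", "both"):
            stage = "select-ga"
            combos = cfg.ga_combos if cfg.method == "both" else [
                (cfg.ga.population, cfg.ga.generations)
            ]
            ga_runs = []
            for pop_size, gens in combos:
                ga_cfg = GAConfig(
                    population=pop_size,
                    generations=gens,
                    mutation_rate=cfg.ga.mutation_rate,
                    crossover_rate=cfg.ga.crossover_rate,
                    max_vars=cfg.ga.max_vars,
                    elitism=cfg.ga.elitism,
                    seed=seeds["ga"],
                )
                ga_runs.append(((pop_size, gens), ga_select(X_train, y_train, ga_cfg)))
            best_combo, best_run = min(
                ga_runs, key=lambda kv: (kv[1].cost, kv[0][0] * kv[0][1])
            )
            best_run.extras["combos_tried"] = [list(c) for c, _ in ga_runs]
            best_run.extras["best_combo"] = list(best_combo)
            selections["ga"] = best_run

        stage = "evaluate"
        evaluation = {}
        for name, sel in selections.items():
            rep = evaluate_split(X_train, y_train, X_test, y_test, sel.selected_indices)
            fw = fisher_weights(X_train, y_train, sel.selected_indices)
            evaluation[name] = {
                "selection": sel.to_dict(axis=pre.axis),
                "fisher_weights": [
                    {**w, "axis_value": float(pre.axis[w["index"]])} for w in fw
                ],
                **_fom_block(rep),
                "scores": rep["scores"],
            }
            _json_dump(selections[name].to_dict(axis=pre.axis), out / f"selection_{name}.json")
            _json_dump(evaluation[name], out / f"evaluation_{name}.json")
            pd.DataFrame(rep["scores"]).to_csv(out / f"scores_{name}.csv", index=False)

        stage = "manifest"
        manifest = {
            "config": _config_snapshot(cfg),
            "stage_seeds": seeds,
            "versions": {
                "chemodisc": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
            },
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "artifacts": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
            "evaluation": {
                name: {kk: vv for kk, vv in block.items() if kk != "scores"}
                for name, block in evaluation.items()
            },
            "exploratory": {
                "explained_variance_pct": pca_res.explained_variance_ratio.tolist(),
                "two_group_purity": purity,
            },
        }
        _json_dump(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        partial = {"failed_stage": stage, "error": str(exc), "config": _config_snapshot(cfg)}
        _json_dump(partial, out / "manifest.partial.json")
        raise


def _config_snapshot(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["ga_combos"] = [list(c) for c in cfg.ga_combos]
    return d


def annotate_variable(axis_value: float, modality: str) -> dict:
    """Join one selected axis value to the nearest static band annotation."""
    tol = ANNOTATION_TOL.get(modality, 3.0)
    best = None
    for center, assignment, relevance in BAND_ANNOTATIONS.get(modality, []):
        d = abs(axis_value - center)
        if d <= tol and (best is None or d < best[0]):
            best = (d, assignment, relevance)
    if best is None:
        return {"axis_value": axis_value, "assignment": "unannotated", "relevance": ""}
    return {"axis_value": axis_value, "assignment": best[1], "relevance": best[2]}


def report_render(run_dir) -> str:
    """Render a markdown summary of a completed run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing artifact: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    modality = manifest["config"]["modality"]
    lines = [f"# Pipeline report ({modality})", ""]

    ev = manifest.get("exploratory", {})
    lines += ["## Exploratory", ""]
    evr = ev.get("explained_variance_pct", [])
    for i, v in enumerate(evr):
        lines.append(f"- PC{i+1} explained variance: {v:.2f}%")
    lines.append(f"- HCA two-group purity: {ev.get('two_group_purity', float('nan')):.3f}")
    lines.append("")

    unit = "nm" if modality == "uv" else "cm-1"
    for name, block in manifest.get("evaluation", {}).items():
        sel = block["selection"]
        lines += [f"## {name.upper()}-LDA", ""]
        lines.append(
            f"- selected variables ({len(sel['selected_indices'])}): "
            + ", ".join(f"{v:g} {unit}" for v in sel["selected_axis_values"])
        )
        lines.append(f"- selection cost (LOO error): {sel['cost']:.4f}")
        for fw in block.get("fisher_weights", []):
            w = "inf" if fw.get("infinite") else f"{fw['weight']:.3f}"
            lines.append(
                f"  - {fw['axis_value']:g} {unit}: Fisher weight {w}, "
                f"attributed to {fw['attributed_class']}"
            )
        cv = block["cv"]["fom"]
        lines.append(
            f"- cross-validation: SEN {cv['sensitivity']:.1f}% / "
            f"SPE {cv['specificity']:.1f}% / ACC {cv['accuracy']:.1f}%"
        )
        if block.get("test"):
            tf = block["test"]["fom"]
            lines.append(
                f"- test set: SEN {tf['sensitivity']:.1f}% / "
                f"SPE {tf['specificity']:.1f}% / ACC {tf['accuracy']:.1f}%"
            )
        else:
            lines.append("- test set: absent")
        lines += ["", "### Band annotations", ""]
        for v in sel["selected_axis_values"]:
            ann = annotate_variable(float(v), modality)
            lines.append(f"- {v:g} {unit}: {ann['assignment']}"
                         + (f" ({ann['relevance']})" if ann["relevance"] else ""))
        lines.append("")

    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
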