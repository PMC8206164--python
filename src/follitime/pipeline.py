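"""Pipeline orchestration: configuration, staged execution, run manifest.

Stages run in the order preprocess -> trajectory (PCA, k-means, contrasts,
per-cluster DE) -> smoothness filter -> SOM -> optional concordance, writing
every intermediate table under the configured output directory along with a
machine-readable manifest (parameters, seeds, row counts per stage).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, diffexpr, preprocess, smoothness, som_map, trajectory
from .concordance import StageMapping, run_concordance
from .matrix import ExpressionMatrix
from .smoothness import FilterThresholds
from .synthetic_data import ArchetypeSpec, generate_invivo_counterpart, generate_timecourse

__all__ = ["PipelineConfig", "run_pipeline", "simulate_fixture", "default_archetype_specs"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; defaults carry the standard thresholds."""

    expression: str = ""
    sample_meta: str = ""
    out_dir: str = "pipeline_out"
    comparator_expression: str | None = None
    comparator_meta: str | None = None
    intensity_threshold: float = 3.0
    sd_threshold: float = 0.3
    thr_pve: float = 0.6
    thr_c: float = 0.35
    thr_f: float = 2.0
    k: int = 6
    kmeans_restarts: int = 10
    kmeans_use_consensus: bool = True
    som_rows: int = 3
    som_cols: int = 3
    som_epochs: int = 30
    som_merge: bool = False
    som_merge_threshold: float = 0.95
    pca_components: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, require_inputs: bool = True) -> None:
        if require_inputs:
            for label, p in (("expression", self.expression), ("sample_meta", self.sample_meta)):
                if not p:
                    raise ValueError(f"config is missing required path: {label}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label} path does not exist: {p}")
            both = (self.comparator_expression is None) == (self.comparator_meta is None)
            if not both:
                raise ValueError("comparator_expression and comparator_meta must be given together")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write artifacts under ``config.out_dir``, return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                manifest["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 - stage tagging
                raise StageError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("preprocess")
    def _preprocess():
        m = ExpressionMatrix.read_tsv(config.expression, config.sample_meta)
        filtered, report = preprocess.filter_genes(
            m, config.intensity_threshold, config.sd_threshold
        )
        filtered.write_tsv(out / "filtered_expression.tsv", out / "filtered_meta.tsv")
        report.to_json(out / "filter_report.json")
        state["matrix"] = filtered
        return {"n_input": report.n_input, "n_retained": report.n_retained}

    @stage("pca")
    def _pca():
        res = trajectory.pca_samples(state["matrix"], n_components=config.pca_components)
        res.to_tsv(out / "pca_scores.tsv")
        pd.Series(
            res.explained_variance_ratio,
            index=res.scores.columns,
            name="variance_fraction",
        ).to_csv(out / "pca_variance.tsv", sep="\t", index_label="component")
        return {"variance_fractions": [float(v) for v in res.explained_variance_ratio]}

    @stage("cluster")
    def _cluster():
        traj = trajectory.consensus_profiles(state["matrix"])
        clusters = trajectory.kmeans_profiles(
            traj,
            k=config.k,
            seed=config.seed,
            n_restarts=config.kmeans_restarts,
            use_consensus=config.kmeans_use_consensus,
        )
        clusters.to_tsv(out / "clusters.tsv")
        clusters.centroids.to_csv(out / "cluster_centroids.tsv", sep="\t", index_label="cluster")
        state["traj"] = traj
        state["clusters"] = clusters
        sizes = clusters.assignments.value_counts().sort_index()
        return {"k": config.k, "inertia": clusters.inertia,
                "cluster_sizes": {int(k): int(v) for k, v in sizes.items()}}

    @stage("de")
    def _de():
        clusters = state["clusters"]
        spec_table = trajectory.contrasts_from_centroids(clusters)
        groups = trajectory.define_contrasts(clusters, spec_table, state["matrix"].sample_meta)
        info = {}
        for label, (high, low) in groups.items():
            members = clusters.members(label)
            sub = state["matrix"].subset_genes(members)
            table = diffexpr.run_de(sub, group_a=low, group_b=high)
            table.to_csv(out / f"de_cluster{label}.tsv", sep="\t", index_label="gene_id")
            info[str(label)] = {
                "n_genes": int(len(table)),
                "n_high_samples": len(high),
                "n_low_samples": len(low),
            }
        skipped = [str(l) for l, g in spec_table.items() if g.skip]
        return {"clusters_tested": info, "clusters_skipped": skipped}

    @stage("smoothness_filter")
    def _filter():
        scores = smoothness.compute_scores(state["traj"])
        thr = FilterThresholds(config.thr_pve, config.thr_c, config.thr_f)
        retained, counts = smoothness.apply_filter(scores, thr)
        scores.assign(retained=scores.index.isin(retained)).to_csv(
            out / "smoothness_scores.tsv", sep="\t", index_label="gene_id"
        )
        (out / "retained_genes.txt").write_text("\n".join(retained) + "\n")
        state["retained"] = retained
        return counts

    @stage("som")
    def _som():
        retained = state["retained"]
        if len(retained) == 0:
            return {"skipped": "no genes survived the smoothness filter"}
        stacked = state["traj"].stacked().loc[retained]
        feats = trajectory._standardize(stacked)
        model = som_map.train_som(
            feats,
            grid_rows=config.som_rows,
            grid_cols=config.som_cols,
            seed=config.seed,
            epochs=config.som_epochs,
        )
        model.to_tsv(out / "som_assignments.tsv")
        pd.DataFrame(model.codebooks, columns=feats.columns).to_csv(
            out / "som_codebooks.tsv", sep="\t", index_label="node"
        )
        result = {"n_genes": int(len(retained)),
                  "node_sizes": {int(k): int(v)
                                 for k, v in model.assignments.value_counts().sort_index().items()}}
        if config.som_merge:
            merged = som_map.merge_similar_nodes(model, feats, config.som_merge_threshold)
            _write_json(out / "som_merged_subsets.json", {str(k): v for k, v in merged.items()})
            result["n_merged_subsets"] = len(merged)
        return result

    if config.comparator_expression:

        @stage("concordance")
        def _concord():
            comparator = ExpressionMatrix.read_tsv(
                config.comparator_expression, config.comparator_meta
            )
            res = run_concordance(state["matrix"], comparator, StageMapping())
            res.to_json(out / "concordance.json")
            for name, tc in res.transitions.items():
                safe = name.replace("->", "_to_")
                pd.DataFrame(
                    {"t_invitro": tc.t_invitro, "t_comparator": tc.t_comparator}
                ).to_csv(out / f"tscores_{safe}.tsv", sep="\t", index_label="gene_id")
                (out / f"agreement_{safe}.txt").write_text("\n".join(tc.agreement) + "\n")
                (out / f"disagreement_{safe}.txt").write_text("\n".join(tc.disagreement) + "\n")
            return res.summary()

    _write_json(out / "manifest.json", manifest)
    return manifest


def default_archetype_specs(
    n_per_archetype: int = 60, amplitude: float = 2.0, noise_sd: float = 0.3
) -> list[ArchetypeSpec]:
    """One spec per archetype — a compact fixture exercising every pattern."""
    from .synthetic_data import ARCHETYPE_NAMES

    return [ArchetypeSpec(name, n_per_archetype, amplitude, noise_sd) for name in ARCHETYPE_NAMES]


def simulate_fixture(
    out_dir: str | Path,
    specs: list[ArchetypeSpec] | None = None,
    seed: int = 0,
    shared_sign_fraction: float = 0.8,
    reps_per_stage: int = 3,
    comparator_noise_sd: float = 0.3,
) -> dict:
    """Write a complete synthetic fixture: time course, comparator, truth ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = specs or default_archetype_specs()
    m, truth = generate_timecourse(specs, seed=seed)
    comp = generate_invivo_counterpart(
        truth,
        shared_sign_fraction=shared_sign_fraction,
        reps_per_stage=reps_per_stage,
        noise_sd=comparator_noise_sd,
        seed=seed + 1,
    )
    m.write_tsv(out / "expression.tsv", out / "sample_meta.tsv")
    comp.write_tsv(out / "comparator_expression.tsv", out / "comparator_meta.tsv")
    truth.to_json(out / "truth.json")
    inventory = {
        "n_genes": m.n_genes,
        "n_samples": m.n_samples,
        "n_comparator_samples": comp.n_samples,
        "seed": seed,
    }
    _write_json(out / "fixture_manifest.json", inventory)
    return inventory
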