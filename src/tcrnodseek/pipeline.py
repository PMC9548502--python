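"""End-to-end orchestration: cohort → diversity → enrichment → model → report.

A single YAML/JSON document configures every stage; one global seed fans out
to the simulation, the discovery/validation split, feature selection and the
GA.  Every intermediate artifact is written under the output directory and
listed, with its SHA-256 digest, in ``manifest.json``.  Manifests contain
only relative paths and no timestamps, so a rerun with the same config and
seed is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifier import GAConfig, ablate_tcr_features, predict, train
from .diversity import (
    DEFAULT_CLONE_TYPE_BINS,
    compare_groups,
    diversity_profile,
    profiles_to_frame,
)
from .enrichment import (
    build_sharing_index,
    find_common_motifs,
    group_exclusive_clones,
    select_enriched_sequences,
)
from .errors import ConfigError, PipelineStageError
from .features import assemble_features, rank_features, select_top_features
from .io import (
    read_clonotype_table,
    read_metadata,
    write_feature_table,
    write_metadata,
    write_repertoire,
)
from .metrics import roc_auc, stratified_evaluation
from .simulate import CohortSimConfig, simulate_cohort

logger = logging.getLogger(__name__)


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    coerced = dict(data)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run."""

    outdir: str = "tcrnodseek_run"
    seed: int = 0
    # either a simulation block or input paths
    simulation: CohortSimConfig | None = None
    repertoire_dir: str | None = None
    metadata_path: str | None = None
    # analysis parameters
    clone_type_bins: tuple[float, ...] = DEFAULT_CLONE_TYPE_BINS
    enrichment_group: str = "malignant"
    top_per_subject: int = 30
    top_pooled: int = 3000
    min_subjects: int = 2
    motif_min_length: int = 5
    motif_min_support: int = 5
    k_features: int = 3
    train_fraction: float = 0.6
    strata: tuple[str, ...] = ("ggn", "size_le_20", "size_le_10", "stage")
    ga: GAConfig = field(default_factory=GAConfig)
    run_ablation: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = _from_mapping(
                CohortSimConfig, data["simulation"], "simulation"
            )
        if "ga" in data and data["ga"] is not None and not isinstance(data["ga"], GAConfig):
            data["ga"] = _from_mapping(GAConfig, data["ga"], "ga")
        return _from_mapping(cls, data, "pipeline config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        have_paths = self.repertoire_dir is not None and self.metadata_path is not None
        if self.simulation is None and not have_paths:
            raise ConfigError(
                "config needs either a 'simulation' block or both "
                "'repertoire_dir' and 'metadata_path'"
            )
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")
        self.ga.validate()
        if self.simulation is not None:
            self.simulation.validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _split_cohort(metadata, train_fraction: float, seed: int):
    """Deterministic stratified discovery/validation split by label."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    discovery, validation = [], []
    for label in ("benign", "malignant"):
        ids = sorted(m.subject_id for m in metadata if m.label == label)
        n_train = int(round(train_fraction * len(ids)))
        perm = rng.permutation(len(ids))
        chosen = {ids[i] for i in perm[:n_train]}
        discovery += [s for s in ids if s in chosen]
        validation += [s for s in ids if s not in chosen]
    return sorted(discovery), sorted(validation)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, name: str, relpath: str):
        artifacts[name] = relpath
        manifest["stages"].setdefault(stage, {})[name] = {
            "path": relpath,
            "sha256": _sha256(outdir / relpath),
        }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, str(exc)) from exc
                logger.info("stage %s: done", name)
                return False

        return _Ctx()

    # ------------------------------------------------------------ ingest
    with stage("cohort"):
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            repertoires, metadata = simulate_cohort(sim)
            rep_dir = outdir / "repertoires"
            rep_dir.mkdir(exist_ok=True)
            for rep in repertoires:
                write_repertoire(rep, rep_dir / f"{rep.subject_id}.tsv")
            write_metadata(metadata, outdir / "metadata.tsv")
            for rep in repertoires:
                record("cohort", f"repertoire_{rep.subject_id}",
                       f"repertoires/{rep.subject_id}.tsv")
            record("cohort", "metadata", "metadata.tsv")
        else:
            metadata = read_metadata(config.metadata_path)
            repertoires = [
                read_clonotype_table(
                    Path(config.repertoire_dir) / f"{m.subject_id}.tsv",
                    subject_id=m.subject_id,
                )
                for m in metadata
            ]

    by_id = {m.subject_id: m for m in metadata}

    # --------------------------------------------------------- diversity
    with stage("diversity"):
        profiles = [
            diversity_profile(r, bins=config.clone_type_bins) for r in repertoires
        ]
        frame = profiles_to_frame(profiles)
        frame.insert(0, "label", [by_id[s].label for s in frame.index])
        write_feature_table(frame, outdir / "diversity_profiles.tsv")
        record("diversity", "profiles", "diversity_profiles.tsv")
        shannon_test = compare_groups(profiles, metadata, "shannon")
        _write_json(
            outdir / "diversity_comparison.json",
            {
                "feature": shannon_test.feature,
                "statistic": shannon_test.statistic,
                "p_value": shannon_test.p_value,
                "direction": shannon_test.direction,
                "test": shannon_test.test,
            },
        )
        record("diversity", "shannon_comparison", "diversity_comparison.json")

    # ------------------------------------------------------------- split
    discovery_ids, validation_ids = _split_cohort(
        metadata, config.train_fraction, config.seed
    )
    _write_json(
        outdir / "split.json",
        {"discovery": discovery_ids, "validation": validation_ids},
    )
    record("split", "split", "split.json")

    # -------------------------------------------------------- enrichment
    with stage("enrichment"):
        index = build_sharing_index(repertoires, metadata)
        exclusive, frac = group_exclusive_clones(index, config.enrichment_group)
        target_reps = [
            r for r in repertoires
            if by_id[r.subject_id].label == config.enrichment_group
            and r.subject_id in set(discovery_ids)
        ]
        enriched = select_enriched_sequences(
            target_reps,
            top_per_subject=config.top_per_subject,
            top_pooled=config.top_pooled,
            min_subjects=config.min_subjects,
        )
        motifs = (
            find_common_motifs(
                enriched,
                min_length=config.motif_min_length,
                min_support=config.motif_min_support,
            )
            if len(enriched)
            else []
        )
        enriched.provenance.to_csv(outdir / "enriched_sequences.tsv", sep="\t", index=False)
        record("enrichment", "enriched_sequences", "enriched_sequences.tsv")
        _write_json(
            outdir / "enrichment_summary.json",
            {
                "exclusive_group": config.enrichment_group,
                "n_exclusive_clones": len(exclusive),
                "exclusive_fraction": frac,
                "n_enriched_sequences": len(enriched),
                "top_motifs": [
                    {"motif": m.motif, "support": m.support, "length": m.length}
                    for m in motifs[:20]
                ],
            },
        )
        record("enrichment", "summary", "enrichment_summary.json")

    # -------------------------------------------- features and selection
    with stage("feature_selection"):
        table = assemble_features(profiles, metadata)
        write_feature_table(table, outdir / "feature_table.tsv")
        record("feature_selection", "feature_table", "feature_table.tsv")
        disc = table.loc[discovery_ids]
        ranking = rank_features(
            disc.drop(columns=["label"]),
            disc["label"].to_numpy(),
            random_state=config.seed,
        )
        selected = select_top_features(ranking, k=config.k_features)
        ranking.to_csv(outdir / "feature_ranking.tsv", sep="\t", index_label="feature")
        record("feature_selection", "ranking", "feature_ranking.tsv")
        _write_json(outdir / "selected_features.json", {"selected": selected})
        record("feature_selection", "selected", "selected_features.json")

    # --------------------------------------------------------- classifier
    with stage("train"):
        ga = dataclasses.replace(config.ga, seed=config.seed)
        model = train(disc, selected, ga)
        model.save(outdir / "model.json")
        record("train", "model", "model.json")

    # --------------------------------------------------------- evaluation
    with stage("evaluate"):
        reports = {}
        for split_name, ids in (("discovery", discovery_ids), ("validation", validation_ids)):
            part = table.loc[ids]
            pred = predict(model, part)
            report, waterfall = stratified_evaluation(
                pred["predicted_value"].to_numpy(),
                part["label"].to_numpy(),
                metadata,
                model.youden_cutoff_,
                subject_ids=ids,
                strata=config.strata,
            )
            reports[split_name] = report
            _write_json(outdir / f"evaluation_{split_name}.json", report.to_dict())
            record("evaluate", f"report_{split_name}", f"evaluation_{split_name}.json")
            waterfall.to_csv(outdir / f"waterfall_{split_name}.tsv", sep="\t", index=False)
            record("evaluate", f"waterfall_{split_name}", f"waterfall_{split_name}.tsv")
        if config.run_ablation:
            with_model, without_model = ablate_tcr_features(disc, selected, ga)
            val = table.loc[validation_ids]
            abl = {
                "with_tcr_auc": roc_auc(
                    with_model.predict_value(val), val["label"].to_numpy()
                ).auc,
                "without_tcr_auc": roc_auc(
                    without_model.predict_value(val), val["label"].to_numpy()
                ).auc,
            }
            _write_json(outdir / "ablation.json", abl)
            record("evaluate", "ablation", "ablation.json")

    manifest["artifacts"] = artifacts
    _write_json(outdir / "manifest.json", manifest)
    return manifest
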