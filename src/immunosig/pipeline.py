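"""End-to-end orchestration: simulate → preprocess → discover → combine →
evaluate → refine, with a reproducibility contract.

All randomness in a run derives from ``RunConfig.seed`` through named
children of a single :class:`numpy.random.SeedSequence` (spawned in a fixed
documented order), so identical configurations produce bitwise-identical
artifacts and digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .discovery import (elastic_net_frequency_select, gene_shaving_lists,
                        moderated_t_select, random_forest_select,
                        sparse_ipca_lists, sparse_pca_lists)
from .evaluate import pc1_weight_auc, signature_score
from .preprocess import preprocess, subject_table
from .refine import refine_signature, standard_comparisons
from .signatures import (SUPERVISED_PANELS, Panel, assemble_panel,
                         build_candidate_signatures, summary_table)
from .synthetic import (SignalSpec, choose_outlier_arrays, generate_design,
                        generate_peptide_library, simulate_abundances)

logger = logging.getLogger(__name__)

ALL_METHODS = ("spca", "sipca", "gs", "rl", "rf", "en")

#: Fixed spawn order of per-stage random streams under the master seed.
SEED_STREAMS = ("library", "design", "signal", "spca", "sipca", "gs",
                "rf", "en")


class PipelineStageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    library: dict = field(default_factory=lambda: {
        "n_analysis": 10_000, "n_control": 200, "length": 12})
    design: dict = field(default_factory=lambda: {
        "template": "paper_default", "params": None, "n_outlier_pairs": 0})
    signal: dict = field(default_factory=dict)     # SignalSpec overrides
    preprocess: dict = field(default_factory=lambda: {"min_concordance": 0.8})
    methods: list = field(default_factory=lambda: list(ALL_METHODS))
    spca: dict = field(default_factory=lambda: {"k_features": 100, "n_lists": 10})
    sipca: dict = field(default_factory=lambda: {"k_features": 100, "n_lists": 10})
    gs: dict = field(default_factory=lambda: {
        "n_lists": 10, "shave_fraction": 0.10, "n_permutations": 20,
        "max_cluster_size": None})
    rl: dict = field(default_factory=lambda: {"adj_p_threshold": 0.05})
    rf: dict = field(default_factory=lambda: {"n_trees": 1000,
                                              "gini_threshold": None})
    en: dict = field(default_factory=lambda: {
        "n_runs": 100, "n_case_drop": 2, "n_control_drop": 2,
        "freq_threshold": 0.10})
    panels: dict = field(default_factory=lambda: {"max_lists": 2,
                                                  "auc_tolerance": 0.02})
    refine: dict = field(default_factory=lambda: {
        "target": "CPS001", "alpha": 0.05, "adjust": None})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                default = getattr(base, f.name)
                if isinstance(default, dict) and isinstance(v, dict):
                    merged = dict(default)
                    merged.update(v)
                    v = merged
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Provenance, tables and summaries produced by one run."""

    config: dict
    seeds: dict
    stages: list = field(default_factory=list)
    digests: dict = field(default_factory=dict)
    qc_summary: dict = field(default_factory=dict)
    signature_summary: pd.DataFrame | None = None
    evaluation: pd.DataFrame | None = None
    refinement: dict = field(default_factory=dict)
    method_params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    # in-memory artifacts for library use
    signatures: dict = field(default_factory=dict)
    refined_signature: object = None
    planted_peptides: list = field(default_factory=list)
    processed_discovery: pd.DataFrame | None = None
    processed_validation: pd.DataFrame | None = None
    subjects: pd.DataFrame | None = None


def _stream_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(SEED_STREAMS))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(SEED_STREAMS, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage of the pipeline on synthetic data.

    Discovery selectors run on the discovery partition; all non-empty
    candidate signatures are evaluated on both partitions; the configured
    winner is refined through the four Welch comparisons.  When
    ``config.out_dir`` is set, every artifact is written and digested.
    """
    methods = [m for m in config.methods if m in ALL_METHODS]
    if not methods:
        raise PipelineStageError("discover", ValueError("no panels: every "
                                 "selector is disabled"))
    seeds = _stream_seeds(config.seed)
    report = RunReport(config=config.to_dict(), seeds=seeds)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    def save(name: str, writer, *args) -> None:
        if out_dir is None:
            return
        path = out_dir / name
        writer(*args, path)
        report.digests[name] = _sha256(path)

    def stage(name: str):
        logger.info("stage %s", name)
        report.stages.append(name)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            stage("simulate")
            library = generate_peptide_library(seed=seeds["library"],
                                               **config.library)
            manifest = generate_design(config.design.get("template",
                                                         "paper_default"),
                                       config.design.get("params"))
            outliers: tuple = ()
            n_out = int(config.design.get("n_outlier_pairs", 0) or 0)
            if n_out:
                outliers = tuple(choose_outlier_arrays(
                    manifest, n_out, seed=seeds["design"]))
            spec = SignalSpec(seed=seeds["signal"],
                              outlier_replicate_ids=outliers,
                              **config.signal)
            dataset = simulate_abundances(library, manifest, spec)
            report.planted_peptides = list(dataset.planted_peptides)
            save("library.tsv", pio.write_library, library)
            save("manifest.csv", pio.write_manifest, manifest)
            save("raw_matrix.tsv", pio.write_matrix, dataset.abundance)
            save("planted_peptides.txt", pio.write_id_list,
                 dataset.planted_peptides)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("simulate", exc) from exc

        try:
            stage("preprocess")
            processed, qc, _ = preprocess(
                dataset.abundance, manifest, library,
                min_concordance=config.preprocess.get("min_concordance", 0.8))
            subjects = subject_table(manifest)
            subjects = subjects.loc[[s for s in subjects.index
                                     if s in processed.values.columns]]
            disc = subjects.index[subjects["partition"] == "discovery"]
            val = subjects.index[subjects["partition"] == "validation"]
            x_disc = processed.values[list(disc)]
            x_val = processed.values[list(val)]
            labels_disc = subjects.loc[disc, "group"].tolist()
            labels_val = subjects.loc[val, "group"].tolist()
            report.qc_summary = {
                "n_arrays": int(len(manifest)),
                "n_merged_samples": int(processed.values.shape[1]),
                "n_discovery_samples": int(len(disc)),
                "n_validation_samples": int(len(val)),
                "removed_pair_subjects": list(processed.removed_pair_subjects),
                "removed_singletons": list(processed.removed_singletons)}
            report.processed_discovery = x_disc
            report.processed_validation = x_val
            report.subjects = subjects
            save("processed_matrix.tsv", pio.write_processed_matrix,
                 processed.values)
            save("replicate_qc.json", pio.write_qc_report, qc)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("preprocess", exc) from exc

        try:
            stage("discover")
            panels: dict[str, Panel] = {}
            panel_kw = dict(max_lists=config.panels.get("max_lists", 2),
                            auc_tolerance=config.panels.get("auc_tolerance",
                                                            0.02))
            if "spca" in methods:
                lists = sparse_pca_lists(x_disc, seed=seeds["spca"],
                                         **config.spca)
                panels["sPCA_panel"] = assemble_panel(
                    lists, x_disc, labels_disc, name="sPCA_panel", **panel_kw)
                for lst in lists:
                    save(f"list_{lst.name}.json", pio.write_panel, lst)
            if "sipca" in methods:
                lists = sparse_ipca_lists(x_disc, seed=seeds["sipca"],
                                          **config.sipca)
                panels["sIPCA_panel"] = assemble_panel(
                    lists, x_disc, labels_disc, name="sIPCA_panel", **panel_kw)
                for lst in lists:
                    save(f"list_{lst.name}.json", pio.write_panel, lst)
            if "gs" in methods:
                lists = gene_shaving_lists(x_disc, seed=seeds["gs"],
                                           **config.gs)
                panels["GS_panel"] = assemble_panel(
                    lists, x_disc, labels_disc, name="GS_panel", **panel_kw)
                for lst in lists:
                    save(f"list_{lst.name}.json", pio.write_panel, lst)
            if "rl" in methods:
                _, rl = moderated_t_select(x_disc, labels_disc, **config.rl)
                panels["RL_panel"] = assemble_panel([rl], name="RL_panel")
                report.method_params["RL"] = dict(rl.method_params)
                save("list_RL.json", pio.write_panel, rl)
            if "rf" in methods:
                rf = random_forest_select(x_disc, labels_disc,
                                          seed=seeds["rf"], **config.rf)
                panels["RF_panel"] = assemble_panel([rf], name="RF_panel")
                report.method_params["RF"] = dict(rf.method_params)
                save("list_RF.json", pio.write_panel, rf)
            if "en" in methods:
                en = elastic_net_frequency_select(x_disc, labels_disc,
                                                  seed=seeds["en"],
                                                  **config.en)
                panels["EN_panel"] = assemble_panel([en], name="EN_panel")
                report.method_params["EN"] = dict(en.method_params)
                save("list_EN.json", pio.write_panel, en)
            for name, panel in panels.items():
                save(f"panel_{name}.json", pio.write_panel, panel)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("discover", exc) from exc

        try:
            stage("combine")
            # disabled selectors contribute empty panels to the set algebra
            full_panels = {name: panels.get(name, Panel(name=name,
                                                        peptide_ids=[]))
                           for name in ("sPCA_panel", "sIPCA_panel",
                                        "GS_panel", *SUPERVISED_PANELS)}
            signatures = build_candidate_signatures(full_panels)
            report.signatures = signatures
            report.signature_summary = summary_table(signatures)
            for sig in signatures.values():
                save(f"signature_{sig.name}.json", pio.write_signature, sig)
                save(f"signature_{sig.name}.txt", pio.write_id_list,
                     sig.peptide_ids)
            if out_dir is not None:
                path = out_dir / "signature_summary.csv"
                report.signature_summary.to_csv(path, index=False)
                report.digests["signature_summary.csv"] = _sha256(path)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("combine", exc) from exc

        try:
            stage("evaluate")
            rows = []
            for sig in signatures.values():
                if not sig.carried:
                    continue
                if sig.excluded:
                    rows.append((sig.name, 0, np.nan, np.nan, True))
                    continue
                disc_auc = signature_score(x_disc, sig, labels_disc).auc
                val_auc = signature_score(x_val, sig, labels_val).auc
                rows.append((sig.name, len(sig), disc_auc, val_auc, False))
            evaluation = pd.DataFrame(rows, columns=[
                "signature", "size", "discovery_auc", "validation_auc",
                "excluded"])
            report.evaluation = evaluation
            if out_dir is not None:
                path = out_dir / "evaluation.csv"
                evaluation.to_csv(path, index=False, float_format="%.6g")
                report.digests["evaluation.csv"] = _sha256(path)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("evaluate", exc) from exc

        try:
            stage("refine")
            target = config.refine.get("target", "CPS001")
            sig = signatures.get(target)
            if sig is None or sig.excluded:
                candidates = evaluation[~evaluation["excluded"]]
                if candidates.empty:
                    raise ValueError("no non-empty signature to refine")
                target = candidates.sort_values(
                    "validation_auc", ascending=False)["signature"].iloc[0]
                sig = signatures[target]
            comparisons = standard_comparisons(x_disc, x_val, subjects)
            refined, refinement_report = refine_signature(
                sig, comparisons, alpha=config.refine.get("alpha", 0.05),
                adjust=config.refine.get("adjust"))
            report.refined_signature = refined
            summary = {"refined_from": target, "refined_name": refined.name,
                       "size": len(refined), "alpha": refinement_report.alpha}
            if not refined.excluded:
                res = signature_score(x_val, refined, labels_val)
                summary["validation_auc"] = res.auc
                summary["validation_pc1_weight_auc"] = pc1_weight_auc(
                    x_val, refined)
            if report.planted_peptides:
                planted = set(report.planted_peptides)
                kept = set(refined.peptide_ids)
                summary["planted_precision"] = (
                    len(kept & planted) / len(kept) if kept else np.nan)
                summary["planted_recall"] = len(kept & planted) / len(planted)
            report.refinement = summary
            save(f"signature_{refined.name}.json", pio.write_signature,
                 refined)
            save(f"signature_{refined.name}.txt", pio.write_id_list,
                 refined.peptide_ids)
            if out_dir is not None:
                path = out_dir / "refinement_report.csv"
                refinement_report.table.to_csv(path, float_format="%.6g")
                report.digests["refinement_report.csv"] = _sha256(path)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("refine", exc) from exc

        report.warnings = sorted({str(w.message) for w in caught})

    if out_dir is not None:
        payload = {
            "config": report.config, "seeds": report.seeds,
            "stages": report.stages, "digests": report.digests,
            "qc_summary": report.qc_summary,
            "signature_summary": report.signature_summary.to_dict("records"),
            "evaluation": json.loads(
                report.evaluation.to_json(orient="records")),
            "refinement": {k: (float(v) if isinstance(v, (int, float,
                                                          np.floating))
                               else v)
                           for k, v in report.refinement.items()},
            "warnings": report.warnings,
        }
        (out_dir / "run_report.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n")
    return report
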