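"""End-to-end pipeline orchestration.

Runs the stages in workflow order — alert screen, descriptor matrix and
variance filter, repeated CV with the permutation negative control,
attribution-based reduction to the SA-linked features, ROR ranking and
ranked top-N recall — from a single config, on synthetic or user data,
writing every artifact plus a checksummed manifest.

A single global seed is expanded into fixed per-stage substreams, so
toggling one stage never shifts another stage's randomness, and a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alerts import load_alert_dictionary, screen_alerts, write_screen_report
from .attribution import rank_features
from .chem_io import load_compounds, write_smiles_csv
from .descriptors import SA_DESCRIPTOR_CODES, assemble_matrix, import_matrix, variance_filter
from .disproportionality import ror_from_records, read_records_csv
from .sar import (
    CVConfig,
    Hyperparams,
    fit_full,
    permutation_control,
    recall_at_top_n,
    repeated_cv,
)
from .synthetic import (
    CohortSpec,
    DrugRorSpec,
    ReportTableSpec,
    generate_cohorts,
    generate_report_table,
)

logger = logging.getLogger(__name__)

_STAGE_KEYS = {
    "simulate": 11,
    "screen": 23,
    "descriptors": 37,
    "cv": 41,
    "permutation": 53,
    "select_features": 67,
    "ror": 79,
    "topn_recall": 97,
}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([global_seed, _STAGE_KEYS[stage]])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


@dataclass
class PipelineConfig:
    outdir: str = "qtalert_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "screen": True,
            "descriptors": True,
            "cv": True,
            "permutation": True,
            "select_features": True,
            "ror": True,
            "topn_recall": True,
        }
    )
    # input paths; None means "generate synthetically"
    pos_path: str | None = None
    neg_path: str | None = None
    dictionary_path: str | None = None
    records_path: str | None = None
    event_id: str = "QT_prolongation"
    screen_threshold: float = 0.20
    variance_threshold: float = 0.001
    cv: CVConfig = field(default_factory=lambda: CVConfig(n_iterations=20))
    model: Hyperparams = field(default_factory=Hyperparams)
    attribution_method: str = "shapley-sampling"
    top_k: int = 50
    topn_step: int = 50
    # synthetic-data shape (used only when paths are None)
    n_pos: int = 144
    n_neg: int = 95
    n_ranked_drugs: int = 150
    ranked_top_fraction: float = 1 / 3

    def __post_init__(self) -> None:
        if not 0 <= self.screen_threshold < 1:
            raise ValueError("screen_threshold must be in [0, 1)")
        if self.variance_threshold < 0:
            raise ValueError("variance_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cv_raw = raw.pop("cv", {})
        model_raw = raw.pop("model", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cv_raw:
            cfg.cv = CVConfig(**cv_raw)
        if model_raw:
            cfg.model = Hyperparams(**model_raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "qtalert_version": __version__,
        "seed": config.seed,
        "parameters": {
            "screen_threshold": config.screen_threshold,
            "variance_threshold": config.variance_threshold,
            "n_folds": config.cv.n_folds,
            "n_iterations": config.cv.n_iterations,
            "model_family": config.model.family,
        },
        "stages": {},
        "files": {},
    }
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    dictionary = load_alert_dictionary(config.dictionary_path)

    # --- inputs: load or simulate -----------------------------------------
    if config.pos_path and config.neg_path:
        pos = load_compounds(config.pos_path, "smiles-csv", "positive")
        neg = load_compounds(config.neg_path, "smiles-csv", "negative")
        screen_dictionary = dictionary
    else:
        spec = CohortSpec(
            n_pos=config.n_pos, n_neg=config.n_neg, seed=stage_seed(config.seed, "simulate")
        )
        screen_dictionary = [a for a in dictionary if a.name in spec.prevalences]
        synth = generate_cohorts(spec, screen_dictionary)
        pos, neg = synth.pos, synth.neg
        emit("cohort_positive.csv", lambda p: write_smiles_csv(pos, p))
        emit("cohort_negative.csv", lambda p: write_smiles_csv(neg, p))
        emit(
            "cohort_truth.tsv",
            lambda p: synth.realized.to_csv(p, sep="\t"),
        )
        manifest["stages"]["simulate"] = {
            "n_pos": pos.size,
            "n_neg": neg.size,
            "alerts_planted": len(spec.prevalences),
        }
    logger.info("inputs: %d positive, %d negative molecules", pos.size, neg.size)

    # --- alert screen ------------------------------------------------------
    if config.stages.get("screen", True):
        report = screen_alerts(pos, neg, screen_dictionary, config.screen_threshold)
        emit("screen_report.tsv", lambda p: write_screen_report(report, p))
        manifest["stages"]["screen"] = {
            "alerts_screened": len(report.rows),
            "alerts_retained": len(report.retained),
        }
        logger.info(
            "screen: %d alerts, %d retained at threshold %.2f",
            len(report.rows), len(report.retained), config.screen_threshold,
        )

    # --- descriptors -------------------------------------------------------
    matrix = None
    if config.stages.get("descriptors", True):
        matrix = assemble_matrix([pos, neg])
        n_before = len(matrix.codes)
        matrix = variance_filter(matrix, config.variance_threshold)
        emit("descriptor_matrix.csv", lambda p: matrix.to_csv(p))
        manifest["stages"]["descriptors"] = {
            "columns_in": n_before,
            "columns_surviving": len(matrix.codes),
        }
        logger.info(
            "descriptors: %d columns, %d survive the variance filter",
            n_before, len(matrix.codes),
        )

    # --- repeated CV and permutation control -------------------------------
    cv_cfg = dataclasses.replace(config.cv, seed=stage_seed(config.seed, "cv"))
    if config.stages.get("cv", True):
        if matrix is None:
            raise RuntimeError("cv stage requires the descriptors stage")
        summary = repeated_cv(matrix, cv_cfg, config.model)
        emit(
            f"cv_{config.model.family}.tsv",
            lambda p: summary.summary().to_csv(p, sep="\t"),
        )
        emit(
            f"cv_{config.model.family}_raw.csv",
            lambda p: summary.raw.to_csv(p, index_label="iteration"),
        )
        manifest["stages"]["cv"] = {
            "iterations": cv_cfg.n_iterations,
            "mean_bacc": float(summary.mean()["bacc"]),
        }
        logger.info("cv: mean bacc %.3f over %d iterations",
                    summary.mean()["bacc"], cv_cfg.n_iterations)

    if config.stages.get("permutation", True):
        if matrix is None:
            raise RuntimeError("permutation stage requires the descriptors stage")
        perm_cfg = dataclasses.replace(
            config.cv, seed=stage_seed(config.seed, "permutation")
        )
        perm = permutation_control(matrix, perm_cfg, config.model)
        emit("permutation_control.tsv", lambda p: perm.summary().to_csv(p, sep="\t"))
        manifest["stages"]["permutation"] = {
            "iterations": perm_cfg.n_iterations,
            "mean_bacc": float(perm.mean()["bacc"]),
            "mean_mcc": float(perm.mean()["mcc"]),
        }
        logger.info("permutation control: mean bacc %.3f", perm.mean()["bacc"])

    # --- attribution and reduced model -------------------------------------
    if config.stages.get("select_features", True):
        if matrix is None:
            raise RuntimeError("select_features stage requires the descriptors stage")
        fs_cfg = dataclasses.replace(
            config.cv, seed=stage_seed(config.seed, "select_features")
        )
        ranking = rank_features(matrix, fs_cfg, config.model, config.attribution_method)
        emit(
            "feature_ranking.tsv",
            lambda p: ranking.scores.rename("score").to_csv(p, sep="\t", index_label="code"),
        )
        selected = ranking.sa_linked(config.top_k) or ranking.top_k(
            min(10, len(matrix.codes))
        )
        reduced = repeated_cv(matrix.select(selected), fs_cfg, config.model)
        emit("reduced_cv.tsv", lambda p: reduced.summary().to_csv(p, sep="\t"))
        manifest["stages"]["select_features"] = {
            "method": ranking.method,
            "selected": selected,
            "reduced_mean_bacc": float(reduced.mean()["bacc"]),
        }
        logger.info("select-features: %d selected (%s)", len(selected), ranking.method)

    # --- ROR ranking and ranked recall -------------------------------------
    if config.stages.get("ror", True):
        ror_seed = stage_seed(config.seed, "ror")
        if config.records_path:
            records = read_records_csv(config.records_path)
            ranked_matrix = None
        else:
            records, ranked_matrix = _simulate_faers(config, ror_seed, screen_dictionary)
            emit("report_records.csv", lambda p: records.to_csv(p, index=False))
        ranked = ror_from_records(records, config.event_id)
        emit("ror_ranking.tsv", lambda p: ranked.to_frame().to_csv(p, sep="\t", index=False))
        manifest["stages"]["ror"] = {"drugs_ranked": len(ranked)}
        logger.info("ror: ranked %d drugs", len(ranked))

        if config.stages.get("topn_recall", True):
            if matrix is None:
                raise RuntimeError("topn_recall stage requires the descriptors stage")
            if ranked_matrix is None:
                raise RuntimeError(
                    "topn_recall on user data needs descriptor rows for the "
                    "ranked drugs; run the descriptors stage on them"
                )
            model = fit_full(matrix, config.model, seed=stage_seed(config.seed, "topn_recall"))
            curve = recall_at_top_n(
                model, ranked, ranked_matrix.select(matrix.codes), step=config.topn_step,
                threshold=config.cv.decision_threshold,
            )
            emit(
                "topn_recall.tsv",
                lambda p: pd.DataFrame(curve, columns=["n", "recall"]).to_csv(
                    p, sep="\t", index=False
                ),
            )
            manifest["stages"]["topn_recall"] = {
                "points": len(curve),
                "recall_first": curve[0][1],
                "recall_full": curve[-1][1],
            }
            logger.info(
                "topn-recall: %.3f at N=%d, %.3f over the full list",
                curve[0][1], curve[0][0], curve[-1][1],
            )

    for path in written:
        manifest["files"][path.name] = _sha256(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _simulate_faers(config: PipelineConfig, seed: int, dictionary):
    """Synthetic FAERS-like stage: ranked drugs whose top block carries
    the positive-cohort alert profile and whose tail does not, with
    planted RORs decreasing down the list."""
    n = config.n_ranked_drugs
    n_top = max(1, int(round(n * config.ranked_top_fraction)))
    n_tail = n - n_top
    spec = CohortSpec(n_pos=n_top, n_neg=n_tail, seed=seed)
    spec.prevalences = {
        k: v for k, v in spec.prevalences.items() if any(a.name == k for a in dictionary)
    }
    synth = generate_cohorts(spec, [a for a in dictionary if a.name in spec.prevalences])
    drug_ids = [f"drug_{i:04d}" for i in range(n)]
    # planted RORs decreasing from strong signal to none
    rors = np.geomspace(60.0, 1.2, n)
    table_spec = ReportTableSpec(
        drugs=[DrugRorSpec(d, float(r), 60) for d, r in zip(drug_ids, rors)],
        total_cases=60 * n + 20_000,
        background_rate=0.05,
        event_id=config.event_id,
        seed=seed,
    )
    records, _truth = generate_report_table(table_spec)

    # descriptor rows for the ranked drugs: top block from positive-profile
    # molecules, tail from negative-profile molecules
    mols = list(synth.pos) + list(synth.neg)
    ranked_matrix = assemble_matrix([_relabel(mols, drug_ids)])
    return records, ranked_matrix


def _relabel(records_list, ids):
    from .chem_io import CompoundCohort, MoleculeRecord

    out = [
        MoleculeRecord(id=i, name="", mol=r.mol, label="unknown")
        for i, r in zip(ids, records_list, strict=True)
    ]
    return CompoundCohort(out, "unlabeled")
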