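"""End-to-end orchestration: simulate (or load) → preprocess → PLS-DA
selection and validation → Bayesian relevance → joined overlap report.

A single global seed fans out to per-stage seeds by fixed offsets, so an
identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import plsda as mplsda
from .bayes import GibbsConfig, run_bayes
from .containers import PeakTable
from .errors import ConfigError, InputError
from .preprocess import DEFAULT_MISSING_THRESHOLD, preprocess_table
from .simulate import SimulationConfig, generate_dataset, inject_missingness

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets off the global seed
_SEED_PLSDA = 1_000
_SEED_VALIDATE = 2_000
_SEED_PERMUTE = 3_000
_SEED_GIBBS = 4_000


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str | Path = "run"
    simulation: SimulationConfig | None = None
    table_path: str | Path | None = None
    methods_path: str | Path | None = None
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD
    folds: int = 4
    tune_repeats: int = 100
    val_repeats: int = 10_000
    perm_repeats: int = 1_000
    max_ncomp: int | None = None
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        gibbs = raw.pop("gibbs", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if gibbs is not None:
            cfg.gibbs = GibbsConfig(**gibbs)
        return cfg

    def validate(self) -> None:
        if self.simulation is None and self.table_path is None:
            raise ConfigError("either a simulation config or a table_path is required")
        self.gibbs.validate()
        if self.simulation is not None:
            self.simulation.validate()


def overlap_report(bayes_table: pd.DataFrame, model: mplsda.PlsdaModel):
    """Join Bayesian relevance and PLS-DA selection per metabolite.

    Returns the joined table plus overlap counts (the intersection is a
    subset of both flag sets by construction).
    """
    universe = list(bayes_table["metabolite"])
    missing = set(model.retained_ids) - set(universe)
    if missing:
        raise InputError(
            f"PLS-selected metabolites absent from the Bayesian table: {sorted(missing)[:5]}"
        )
    selected = set(model.retained_ids)
    joined = bayes_table.copy()
    joined["pls_selected"] = joined["metabolite"].isin(selected)
    joined["both"] = joined["relevant"] & joined["pls_selected"]
    counts = {
        "n_bayes_relevant": int(joined["relevant"].sum()),
        "n_pls_selected": int(joined["pls_selected"].sum()),
        "n_overlap": int(joined["both"].sum()),
    }
    return joined, counts


@dataclass
class RunResult:
    out_dir: Path
    manifest: dict
    overlap_counts: dict
    joined: pd.DataFrame


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage, writing tables, reports and a manifest under
    ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("metabodisc").addHandler(handler)
    manifest: dict = {"seed": config.seed, "stages": []}

    def _stage(name: str, started: float, **info) -> None:
        manifest["stages"].append(
            {"stage": name, "wall_time_s": round(time.perf_counter() - started, 3), **info}
        )

    try:
        # -- input --------------------------------------------------------
        t0 = time.perf_counter()
        if config.simulation is not None:
            sim = config.simulation
            sim.seed = config.seed if sim.seed is None else sim.seed
            table, truth = generate_dataset(sim)
            table = inject_missingness(table, sim)
            mio.write_peak_table(table, out / "peak_table.tsv")
            mio.write_methods(table.method_of, out / "methods.tsv")
            mio.write_ground_truth(truth, out / "ground_truth.tsv")
            _stage("simulate", t0, n_samples=table.n_samples,
                   n_metabolites=table.n_metabolites)
        else:
            if config.methods_path is None:
                raise ConfigError("methods_path is required with table_path")
            table = mio.read_peak_table(config.table_path, config.methods_path)
            _stage("load", t0, table=str(config.table_path))

        # -- preprocess ---------------------------------------------------
        t0 = time.perf_counter()
        pre = preprocess_table(table, missing_threshold=config.missing_threshold)
        mio.write_transformed(pre.matrix, out / "transformed.tsv")
        (out / "preprocess_report.json").write_text(json.dumps(pre.report, indent=1))
        _stage("preprocess", t0, **pre.report)

        # -- PLS-DA -------------------------------------------------------
        t0 = time.perf_counter()
        y = pre.matrix.population.to_numpy()
        model, cv, trace = mplsda.iterative_selection(
            pre.matrix, y, seed=config.seed + _SEED_PLSDA, folds=config.folds,
            tune_repeats=config.tune_repeats, max_ncomp=config.max_ncomp,
        )
        report = mplsda.validate(
            model, pre.matrix, y, folds=config.folds,
            repeats=config.val_repeats, seed=config.seed + _SEED_VALIDATE,
        )
        perm = mplsda.permuted_validate(
            model, pre.matrix, y, folds=config.folds,
            repeats=config.perm_repeats, seed=config.seed + _SEED_PERMUTE,
        )
        model_summary = {
            "n_components": model.n_components,
            "retained_metabolites": model.retained_ids,
            "vip": dict(zip(model.retained_ids, map(float, model.vip))),
            "cv_ber": cv.best_ber,
        }
        (out / "plsda_model.json").write_text(json.dumps(model_summary, indent=1))
        pd.DataFrame(
            [{k: v for k, v in row.items() if k != "variables"} for row in trace]
        ).to_csv(out / "selection_trace.tsv", sep="\t", index=False)
        scores = pd.DataFrame(
            model.x_scores,
            index=pre.matrix.values.index,
            columns=[f"comp{i + 1}" for i in range(model.n_components)],
        )
        scores.to_csv(out / "plsda_scores.tsv", sep="\t", index_label="sample")
        validation = {
            "confusion_percent": report.confusion_percent.to_dict(),
            "accuracy": report.accuracy,
            "precision": report.precision,
            "permuted_confusion_percent": perm.confusion_percent.to_dict(),
            "permuted_tp_percent": perm.tp_percent,
        }
        (out / "validation.json").write_text(json.dumps(validation, indent=1))
        _stage("plsda", t0, n_selected=len(model.retained_ids),
               ber=cv.best_ber, accuracy=report.accuracy,
               permuted_tp_percent=perm.tp_percent)

        # -- Bayes --------------------------------------------------------
        t0 = time.perf_counter()
        gibbs = config.gibbs
        if gibbs.seed is None:
            gibbs.seed = config.seed + _SEED_GIBBS
        bayes_table = run_bayes(pre.matrix, config=gibbs, alpha=config.alpha)
        bayes_table.to_csv(out / "bayes_results.tsv", sep="\t", index=False)
        _stage("bayes", t0, n_relevant=int(bayes_table["relevant"].sum()))

        # -- overlap ------------------------------------------------------
        t0 = time.perf_counter()
        joined, counts = overlap_report(bayes_table, model)
        joined.to_csv(out / "final_table.tsv", sep="\t", index=False)
        _stage("overlap", t0, **counts)
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "input"
        logger.error("pipeline aborted after stage %r: %s", stage, exc)
        raise
    finally:
        logging.getLogger("metabodisc").removeHandler(handler)
        handler.close()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunResult(out_dir=out, manifest=manifest, overlap_counts=counts, joined=joined)
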