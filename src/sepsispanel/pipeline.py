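"""End-to-end orchestration: simulate → label → select → train → validate → report.

A single :class:`RunConfig` drives the whole analysis; every emitted table
carries the config hash and seed so a run is exactly reproducible.  Stages
log record counts in and out, and any stage failure aborts with the stage
name while preserving partial outputs.

Artifacts written to the output directory:

- ``cohort.csv`` (+ ``cohort.csv.spec.json``) — the simulated cohort, unless
  an input CSV was supplied
- ``exclusions.tsv`` — one row per excluded record with a machine-readable
  reason
- ``selection_path.tsv`` — per-k best subset, canonical correlation,
  enter/leave, forward-selection order
- ``model_k{k}.json`` / ``model_report.tsv`` — the trained panel classifier
  (weights ± SE over divisions, biomarker means/SDs)
- ``performance.tsv`` — mean ± SD of TPR/TNR/PPV/NPV/ACC for SSVM and LLR
- ``roc_k{k}.csv`` — vertically averaged ROC points (fpr, tpr_mean, tpr_sd)
- ``validation.jsonl`` — optional exhaustive every-combination sweep
- ``manifest.json`` — config, hash, seeds, stage counts
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

from .cohort import BIOMARKERS, default_cohort_spec, generate_cohort, write_cohort_csv
from .labeling import CriteriaThresholds, exclude_incomplete, make_labels
from .preprocess import standardize
from .selection import best_subsets
from .classifiers import repeated_evaluation
from .metrics import MEASURE_NAMES, average_roc, exhaustive_validation, univariate_pvalues

logger = logging.getLogger(__name__)

#: Columns a cohort CSV must provide.
MANDATORY_COLUMNS: tuple[str, ...] = (
    "eval_id", *BIOMARKERS, "anc", "abc", "it_ratio", "culture_positive",
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; no hidden defaults elsewhere."""

    # input: either a cohort CSV or simulation parameters
    input_csv: str | None = None
    n_pos: int = 300
    n_neg: int = 300
    cohort_seed: int = 0
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    k_range: tuple[int, ...] = tuple(range(1, 11))
    k_final: int = 5
    R: int = 100
    B: int = 1000
    scale: float = 1.0
    llr_lambda: float | None = None  # None → 5-fold CV per division
    eval_seed: int = 0
    outdir: str = "results"
    leakage_safe: bool = False
    cd64_outlier_cutoff: float | None = None
    stratified: bool = True
    run_validation: bool = False
    validation_R: int = 8
    validation_B: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = CriteriaThresholds(**raw["thresholds"])
        if "k_range" in raw:
            raw["k_range"] = tuple(int(k) for k in raw["k_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.to_dict()
        d["k_range"] = list(self.k_range)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # where results land is not an analysis parameter
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(self.input_csv)
        if self.k_final not in self.k_range:
            raise ValueError("k_final must be a member of k_range")


def read_cohort_csv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort CSV into typed records.

    Returns ``(records, malformed)``; rows with non-numeric biomarker or
    score-input values are collected in ``malformed`` with reasons
    (``parse:<column>``) rather than raising.  A missing mandatory column is
    an error naming it; unknown extra columns are accepted with a warning
    and ignored.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing mandatory column(s): "
                         f"{', '.join(missing)}")
    extra = [c for c in df.columns
             if c not in MANDATORY_COLUMNS and c != "true_group"]
    if extra:
        logger.warning("ignoring unknown columns: %s", ", ".join(extra))
        df = df.drop(columns=extra)
    bad_reasons: list[tuple[str, str]] = []
    bad_mask = np.zeros(len(df), dtype=bool)
    numeric_cols = [*BIOMARKERS, "anc", "abc", "it_ratio"]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna().to_numpy() & df[col].notna().to_numpy()
        for i in np.nonzero(bad & ~bad_mask)[0]:
            bad_reasons.append((str(df["eval_id"].iloc[i]), f"parse:{col}"))
        bad_mask |= bad
        df[col] = coerced
    df["culture_positive"] = df["culture_positive"].astype("boolean")
    malformed = pd.DataFrame(bad_reasons, columns=["eval_id", "reason"])
    return df.loc[~bad_mask].reset_index(drop=True), malformed


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") \
                    from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    counts: dict[str, int] = {}

    header = (f"# config_hash={chash} cohort_seed={config.cohort_seed} "
              f"eval_seed={config.eval_seed} "
              f"thresholds={json.dumps(config.thresholds.to_dict())}\n")

    def _write_tsv(df: pd.DataFrame, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    with _stage("simulate/load"):
        if config.input_csv is None:
            spec = default_cohort_spec(config.n_pos, config.n_neg,
                                       seed=config.cohort_seed)
            records = generate_cohort(spec)
            write_cohort_csv(records, outdir / "cohort.csv", spec)
            malformed = pd.DataFrame(columns=["eval_id", "reason"])
        else:
            records, malformed = read_cohort_csv(config.input_csv)
        counts["records_in"] = len(records) + len(malformed)

    with _stage("label"):
        kept, excluded = exclude_incomplete(
            records, cd64_outlier_cutoff=config.cd64_outlier_cutoff)
        exclusions = pd.concat([malformed, excluded], ignore_index=True)
        _write_tsv(exclusions, outdir / "exclusions.tsv")
        dataset = make_labels(kept, config.thresholds)
        counts["records_kept"] = len(kept)
        counts["records_excluded"] = len(exclusions)
        counts["n_septic"] = int((dataset.y == 1).sum())
        counts["n_nonseptic"] = int((dataset.y == -1).sum())

    with _stage("screen"):
        pvals = univariate_pvalues(dataset.X, dataset.y, dataset.names)
        _write_tsv(pvals, outdir / "univariate_pvalues.tsv")

    with _stage("select"):
        sm = standardize(dataset.X, names=dataset.names)
        path = best_subsets(sm.Xtilde, dataset.y, k_range=config.k_range,
                            names=dataset.names)
        _write_tsv(path.to_table(), outdir / "selection_path.tsv")
        selected = {sc.k: tuple(dataset.names[j] for j in sc.indices)
                    for sc in path.best}

    with _stage("train"):
        k = config.k_final
        panel = selected[k]
        summary = repeated_evaluation(
            dataset, feature_subset=panel, R=config.R, B=config.B,
            seed=config.eval_seed, scale=config.scale,
            leakage_safe=config.leakage_safe, collect_roc=True)
        idx = [dataset.names.index(b) for b in panel]
        model = {
            "names": list(panel),
            "w": summary.weights_mean.tolist(),
            "w_se": summary.weights_se.tolist(),
            "mu": sm.mu[idx].tolist(),
            "sigma": sm.sigma[idx].tolist(),
            "B": config.B, "R": config.R, "scale": config.scale,
            "seed": config.eval_seed, "config_hash": chash,
        }
        (outdir / f"model_k{k}.json").write_text(json.dumps(model, indent=2))
        report = pd.DataFrame({
            "biomarker": list(panel),
            "mean": sm.mu[idx], "sd": sm.sigma[idx],
            "weight": summary.weights_mean,
            "weight_se": summary.weights_se,
        })
        _write_tsv(report, outdir / "model_report.tsv")
        roc = average_roc(summary.roc_curves)
        roc_table = roc.to_table()
        roc_table.insert(0, "k", k)
        with open(outdir / f"roc_k{k}.csv", "w") as fh:
            fh.write(header)
            roc_table.to_csv(fh, index=False)
        counts["ssvm_fits"] = config.R * config.B

    with _stage("compare"):
        llr = repeated_evaluation(
            dataset, feature_subset=panel, R=config.R, B=1,
            seed=config.eval_seed, method="llr",
            llr_lambda=config.llr_lambda,
            leakage_safe=config.leakage_safe)
        perf = pd.DataFrame([summary.to_row(), llr.to_row()])
        _write_tsv(perf[["method", "subset", "R",
                         *MEASURE_NAMES,
                         *[f"{m}_sd" for m in MEASURE_NAMES]]],
                   outdir / "performance.tsv")

    if config.run_validation:
        with _stage("validate"):
            sweep = exhaustive_validation(
                dataset, config.k_range, config.validation_R,
                config.validation_B, config.eval_seed, scale=config.scale,
                selected=selected)
            with open(outdir / "validation.jsonl", "w") as fh:
                for rec in sweep.to_records():
                    fh.write(json.dumps(rec) + "\n")
            (outdir / "validation_ranks.json").write_text(
                json.dumps({str(k): v for k, v in sweep.ranks.items()},
                           indent=2))
            counts["validation_fits"] = sum(
                len(s) for s in sweep.per_k.values()
            ) * config.validation_R * config.validation_B

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seeds": {"cohort": config.cohort_seed, "eval": config.eval_seed},
        "counts": counts,
        "selected_panel": {str(k): list(v) for k, v in selected.items()},
        "performance": {
            "SSVM": {m: summary.mean[m] for m in MEASURE_NAMES},
            "LLR": {m: llr.mean[m] for m in MEASURE_NAMES},
        },
        "roc_auc_mean": roc.auc_mean,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
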