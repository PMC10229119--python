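"""I/O, configuration, and end-to-end orchestration.

The pipeline consumes (or simulates) a long voxel-coefficient table, runs the
cross-validated model comparison, and writes a reproducible artifact bundle:
``data.csv`` (when simulated), ``fits.csv``, ``evaluation.csv``,
``indices.csv``, ``stats.csv``, ``report.json`` and ``pipeline.log``.  The
same seed and configuration always produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .conditions import RAW_CONDITIONS
from .fitting import FitOptions
from .models import MODEL_IDS
from .synthetic_data import SimConfig

logger = logging.getLogger("voxnorm")

_SCHEMA = ("subject", "roi", "voxel", "half", "condition", "value")
_HALVES = ("odd", "even")


class PipelineError(RuntimeError):
    """A pipeline stage failed; see the failure manifest for details."""


def validate_voxel_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the long voxel table schema and completeness.

    Every (subject, roi, voxel, half) cell must contain each of the seven raw
    conditions exactly once, with finite numeric values; violations raise with
    the offending keys or row numbers.
    """
    missing_cols = [c for c in _SCHEMA if c not in df.columns]
    if missing_cols:
        raise ValueError(f"voxel table missing columns: {missing_cols}")
    if df.empty:
        raise ValueError("voxel table is empty")
    df = df.loc[:, list(_SCHEMA)].copy()
    bad_half = df.loc[~df["half"].isin(_HALVES)]
    if not bad_half.empty:
        raise ValueError(
            f"unknown half labels {sorted(bad_half['half'].unique())} "
            f"at rows {bad_half.index.tolist()[:10]}"
        )
    bad_cond = df.loc[~df["condition"].isin(RAW_CONDITIONS)]
    if not bad_cond.empty:
        raise ValueError(
            f"unknown condition labels {sorted(bad_cond['condition'].unique())} "
            f"at rows {bad_cond.index.tolist()[:10]}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad_val = df.loc[values.isna() | ~values.apply(pd.api.types.is_number)]
    if values.isna().any():
        raise ValueError(f"non-numeric values at rows {df.index[values.isna()].tolist()[:10]}")
    df["value"] = values.astype(float)
    if not pd.Series(values).map(lambda v: abs(v) < float("inf")).all():
        raise ValueError("non-finite values in voxel table")

    key_cols = ["subject", "roi", "voxel", "half", "condition"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].tolist()
        raise ValueError(f"duplicate rows for key {tuple(first)}")
    counts = df.groupby(["subject", "roi", "voxel", "half"], observed=True)["condition"].count()
    incomplete = counts[counts != len(RAW_CONDITIONS)]
    if not incomplete.empty:
        key = incomplete.index[0]
        present = set(
            df.set_index(["subject", "roi", "voxel", "half"]).loc[key, "condition"]
        )
        missing = sorted(set(RAW_CONDITIONS) - present)
        raise ValueError(f"voxel cell {key} missing conditions {missing}")
    halves = df.groupby(["subject", "roi", "voxel"], observed=True)["half"].nunique()
    if (halves != 2).any():
        key = halves[halves != 2].index[0]
        raise ValueError(f"voxel {key} lacks one of the odd/even halves")
    return df.reset_index(drop=True)


def read_voxel_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a voxel-coefficient CSV."""
    df = pd.read_csv(path)
    return validate_voxel_table(df)


def write_voxel_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, list(_SCHEMA)].to_csv(path, index=False)
    return path


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML."""

    input: str | None = None  # CSV path; mutually exclusive with simulate
    simulate: dict | None = None  # SimConfig fields
    kind: str = "normalizing"  # neuron kind when simulating
    models: tuple[str, ...] = MODEL_IDS
    fit: dict = field(default_factory=dict)  # FitOptions overrides
    output: str = "voxnorm_out"
    seed: int = 0
    log_level: str = "INFO"

    def fit_options(self) -> FitOptions:
        fit = dict(self.fit)
        if "fit_conditions" in fit and fit["fit_conditions"] is not None:
            fit["fit_conditions"] = tuple(fit["fit_conditions"])
        return FitOptions(seed=self.seed, **fit)

    def sim_config(self) -> SimConfig:
        base = dict(self.simulate or {})
        base.setdefault("seed", self.seed)
        return SimConfig.from_dict(base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stats_stage(evaluations: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Group-level rm-ANOVA of goodness of fit over model × ROI, if possible."""
    from .evaluation import summarize
    from .stats import rm_anova

    cell_means, _ = summarize(evaluations)
    n_subjects = cell_means["subject"].nunique()
    if n_subjects < 3:
        return pd.DataFrame(), (
            f"skipped: rm-ANOVA needs >= 3 subjects, dataset has {n_subjects}"
        )
    factors = [f for f in ("model", "roi") if cell_means[f].nunique() > 1]
    if not factors:
        return pd.DataFrame(), "skipped: no varying within-subject factor"
    table = rm_anova(cell_means, dv="gof", within=factors, subject="subject")
    return table, "ok"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate/load → fit → evaluate → indices → stats → report.

    Returns a manifest dict with artifact paths and stage counts.  A stage
    failure writes ``failure.json`` beside any artifacts already produced and
    raises :class:`PipelineError`.
    """
    from .comparison import VoxelModelComparison

    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    stage = "configure"
    try:
        logger.info("config digest %s, seed %d", config.digest(), config.seed)
        stage = "load-data"
        if config.input is not None:
            data = read_voxel_table(config.input)
            data_path = None
        else:
            from .synthetic_data import simulate_dataset

            sim = config.sim_config()
            logger.info(
                "simulating %s population: %s", config.kind,
                json.dumps(sim.to_dict(), sort_keys=True),
            )
            data = simulate_dataset(config.kind, sim, seed=config.seed)
            data_path = write_voxel_table(data, outdir / "data.csv")
        n_voxels = len(data[["subject", "roi", "voxel"]].drop_duplicates())
        logger.info("dataset: %d voxels, %d rows", n_voxels, len(data))

        stage = "fit-evaluate"
        comparison = VoxelModelComparison(
            data, models=config.models, fit_options=config.fit_options()
        )
        results = comparison.fit(seed=config.seed)
        paths = results.save(outdir)

        stage = "stats"
        stats_table, stats_status = _stats_stage(results.evaluations)
        stats_path = outdir / "stats.csv"
        stats_table.to_csv(stats_path, index=False)
        logger.info("stats stage: %s", stats_status)

        stage = "report"
        n_degenerate = int(results.evaluations["degenerate"].sum())
        manifest = {
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": _version(),
            "counts": {
                "voxels": n_voxels,
                "models": len(config.models),
                "evaluations": len(results.evaluations),
                "degenerate": n_degenerate,
            },
            "stats_status": stats_status,
            "artifacts": {
                **({"data": str(data_path)} if data_path else {}),
                **{k: str(v) for k, v in paths.items()},
                "stats": str(stats_path),
                "log": str(log_path),
            },
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %d evaluations", len(results.evaluations))
        return manifest
    except Exception as exc:
        failure = {"stage": stage, "error": str(exc), "type": type(exc).__name__}
        with open(outdir / "failure.json", "w") as fh:
            json.dump(failure, fh, indent=2)
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _version() -> str:
    from importlib.metadata import version, PackageNotFoundError

    try:
        return version("voxnorm")
    except PackageNotFoundError:
        return "unknown"
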