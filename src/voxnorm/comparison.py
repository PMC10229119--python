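"""Model-comparison facade: a Model object fitted to a voxel table.

:class:`VoxelModelComparison` is constructed from a long voxel-coefficient
table (subject, roi, voxel, half, condition, value) — real GLM coefficients or
the output of :mod:`voxnorm.synthetic_data` — and ``fit()`` runs the complete
per-voxel protocol for every requested response model: preference assignment,
canonicalization, split-half cross-validated constrained least squares,
held-out evaluation (goodness of fit, noise ceiling, NRD, AIC), and the two
attention indices.  The returned :class:`VoxelComparisonResults` carries the
tidy result tables and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .attention_metrics import asymmetry_index, model_data_gap, response_change_index
from .conditions import MODELED_CONDITIONS, RAW_CONDITIONS
from .evaluation import evaluate_crossval, summarize
from .fitting import CrossValResult, FitOptions, crossval_voxel
from .models import MODEL_IDS, MODEL_SPECS

_ALL_PARAM_NAMES: tuple[str, ...] = tuple(
    dict.fromkeys(n for m in MODEL_IDS for n in MODEL_SPECS[m].param_names)
)


class VoxelModelComparison:
    """Compare response models voxel by voxel on one dataset.

    Parameters
    ----------
    data
        Long table with columns subject, roi, voxel, half, condition, value;
        every (subject, roi, voxel, half) cell must contain exactly the seven
        raw conditions.
    models
        Model identifiers to fit (default: all six).
    fit_options
        Estimation and cross-validation settings.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        models: tuple[str, ...] = MODEL_IDS,
        fit_options: FitOptions | None = None,
    ) -> None:
        from .pipeline import validate_voxel_table

        self.data = validate_voxel_table(data)
        unknown = [m for m in models if m not in MODEL_SPECS]
        if unknown:
            raise ValueError(f"unknown models: {unknown}")
        self.models = tuple(models)
        self.fit_options = fit_options if fit_options is not None else FitOptions()

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        models: tuple[str, ...] = MODEL_IDS,
        fit_options: FitOptions | None = None,
    ) -> "VoxelModelComparison":
        from .pipeline import read_voxel_table

        return cls(read_voxel_table(path), models=models, fit_options=fit_options)

    @classmethod
    def from_simulation(
        cls,
        kind: str,
        sim_config=None,
        seed: int | None = None,
        models: tuple[str, ...] = MODEL_IDS,
        fit_options: FitOptions | None = None,
    ) -> "VoxelModelComparison":
        from .synthetic_data import SimConfig, simulate_dataset

        config = sim_config if sim_config is not None else SimConfig()
        return cls(
            simulate_dataset(kind, config, seed=seed), models=models, fit_options=fit_options
        )

    def _voxel_groups(self):
        keyed = self.data.set_index(["subject", "roi", "voxel", "half", "condition"])[
            "value"
        ]
        voxels = sorted(set(zip(self.data["subject"], self.data["roi"], self.data["voxel"])))
        for subject, roi, voxel in voxels:
            halves = {
                half: {c: float(keyed[(subject, roi, voxel, half, c)]) for c in RAW_CONDITIONS}
                for half in ("odd", "even")
            }
            yield (subject, roi, voxel), halves["odd"], halves["even"]

    def fit(self, seed: int | None = None) -> "VoxelComparisonResults":
        """Run the full cross-validated comparison; deterministic given seed."""
        base_seed = self.fit_options.seed if seed is None else int(seed)
        fit_rows, eval_rows, index_rows = [], [], []
        crossvals: dict[tuple, dict[str, CrossValResult]] = {}
        for i, (key, odd_raw, even_raw) in enumerate(self._voxel_groups()):
            subject, roi, voxel = key
            options = replace(self.fit_options, seed=(base_seed + 7919 * i) % (2**31))
            per_model: dict[str, CrossValResult] = {}
            for model_id in self.models:
                cv = crossval_voxel(odd_raw, even_raw, model_id, options, voxel=voxel)
                per_model[model_id] = cv
                for fold in cv.folds:
                    row = {
                        "subject": subject,
                        "roi": roi,
                        "voxel": voxel,
                        "model": model_id,
                        "train_half": fold.train_half,
                        "preference": fold.preference,
                        "train_sse": fold.fit.train_sse,
                        "converged": fold.fit.converged,
                    }
                    params = fold.fit.param_dict
                    for name in _ALL_PARAM_NAMES:
                        row[name] = params.get(name, np.nan)
                    fit_rows.append(row)
                record = evaluate_crossval(cv)
                eval_rows.append(
                    {
                        "subject": subject,
                        "roi": roi,
                        "voxel": voxel,
                        "model": model_id,
                        "gof": record.gof,
                        "noise_ceiling": record.noise_ceiling,
                        "nrd": record.nrd,
                        "aic": record.aic,
                        "rss_test": record.rss_test,
                        "n_obs": record.n_obs,
                        "k": record.k,
                        "degenerate": record.degenerate,
                    }
                )
            crossvals[key] = per_model
            index_rows.extend(self._voxel_indices(subject, roi, voxel, per_model))
        fits = pd.DataFrame(fit_rows)
        evaluations = pd.DataFrame(eval_rows)
        indices = pd.DataFrame(index_rows)
        return VoxelComparisonResults(
            model=self,
            seed=base_seed,
            fits=fits,
            evaluations=evaluations,
            indices=indices,
            crossvals=crossvals,
        )

    def _voxel_indices(self, subject, roi, voxel, per_model):
        """Observed and model-predicted attention indices for one voxel."""
        any_cv = per_model[self.models[0]]
        observed_avg = {
            c: 0.5 * (any_cv.folds[0].observed[c] + any_cv.folds[1].observed[c])
            for c in MODELED_CONDITIONS
        }
        data_rc = response_change_index(observed_avg)
        data_asym = asymmetry_index(observed_avg)
        rows = [
            {
                "subject": subject,
                "roi": roi,
                "voxel": voxel,
                "source": "data",
                "response_change": data_rc,
                "asymmetry": data_asym,
                "response_change_gap": np.nan,
                "asymmetry_gap": np.nan,
            }
        ]
        for model_id, cv in per_model.items():
            rc = response_change_index(cv.averaged_prediction)
            asym = asymmetry_index(cv.averaged_prediction)
            rows.append(
                {
                    "subject": subject,
                    "roi": roi,
                    "voxel": voxel,
                    "source": model_id,
                    "response_change": rc,
                    "asymmetry": asym,
                    "response_change_gap": model_data_gap(data_rc, rc),
                    "asymmetry_gap": model_data_gap(data_asym, asym),
                }
            )
        return rows


@dataclass
class VoxelComparisonResults:
    """Tidy result tables of a fitted :class:`VoxelModelComparison`."""

    model: VoxelModelComparison
    seed: int
    fits: pd.DataFrame
    evaluations: pd.DataFrame
    indices: pd.DataFrame
    crossvals: dict = field(repr=False, default_factory=dict)

    def roi_summary(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(subject × roi × model cell means, per-roi noise ceiling + SEM)."""
        return summarize(self.evaluations)

    def index_summary(self) -> pd.DataFrame:
        """Mean attention indices per roi × source (voxels pooled in subject)."""
        cols = ["response_change", "asymmetry", "response_change_gap", "asymmetry_gap"]
        return (
            self.indices.groupby(["subject", "roi", "source"], observed=True)[cols]
            .mean()
            .reset_index()
        )

    def summary(self) -> str:
        """Readable report: mean held-out fit per ROI and model, ceiling, indices."""
        cell_means, roi_ceiling = self.roi_summary()
        gof = (
            cell_means.groupby(["roi", "model"], observed=True)["gof"]
            .mean()
            .unstack("model")
            .reindex(columns=[m for m in self.model.models])
        )
        ceiling = roi_ceiling.set_index("roi")["noise_ceiling"]
        gof.insert(0, "noise_ceiling", ceiling)
        idx = (
            self.index_summary()
            .groupby(["roi", "source"], observed=True)[["response_change", "asymmetry"]]
            .mean()
            .unstack("source")
        )
        lines = [
            "Voxelwise model comparison (split-half cross-validated)",
            f"  voxels: {self.evaluations['voxel'].size // len(self.model.models)}"
            f"   models: {', '.join(self.model.models)}   seed: {self.seed}",
            "",
            "Mean held-out goodness of fit (r^2 over the 5 modeled conditions):",
            gof.round(4).to_string(),
            "",
            "Attention indices (mean per ROI; data vs cross-validated predictions):",
            idx.round(4).to_string(),
        ]
        return "\n".join(lines)

    def plot_roi_profile(self, roi: str, ax=None):
        """Mean observed vs predicted responses over the 5 modeled conditions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        obs = {c: [] for c in MODELED_CONDITIONS}
        preds = {m: {c: [] for c in MODELED_CONDITIONS} for m in self.model.models}
        for (subject, r, voxel), per_model in self.crossvals.items():
            if r != roi:
                continue
            cv0 = per_model[self.model.models[0]]
            for c in MODELED_CONDITIONS:
                obs[c].append(0.5 * (cv0.folds[0].observed[c] + cv0.folds[1].observed[c]))
                for m, cv in per_model.items():
                    preds[m][c].append(cv.averaged_prediction[c])
        x = np.arange(len(MODELED_CONDITIONS))
        ax.plot(x, [np.mean(obs[c]) for c in MODELED_CONDITIONS], "o-", color="navy",
                label="data", linewidth=2)
        for m in self.model.models:
            ax.plot(x, [np.mean(preds[m][c]) for c in MODELED_CONDITIONS], "--",
                    label=m, alpha=0.8)
        ax.set_xticks(x, MODELED_CONDITIONS)
        ax.set_ylabel("response (a.u.)")
        ax.set_title(f"{roi}: held-out predictions")
        ax.legend(fontsize=7)
        return ax

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write fits/evaluation/indices tables as CSV; return their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, table in (
            ("fits", self.fits),
            ("evaluation", self.evaluations),
            ("indices", self.indices),
        ):
            path = outdir / f"{name}.csv"
            table.to_csv(path, index=False)
            paths[name] = path
        return paths
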