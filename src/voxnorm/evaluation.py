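"""Held-out goodness of fit, noise ceiling, NRD, and AIC per voxel.

Goodness of fit is the squared Pearson correlation between held-out observed
and predicted responses over the five modeled conditions (Pat, PatN, PNat,
Nat, PN); the isolated ignored conditions P and N are excluded because the
linear models consume them as inputs.  The noise ceiling is the squared
split-half correlation of the observed profiles over the same conditions, an
upper bound on what any model can explain; NRD = ceiling − goodness of fit.
AIC = n·ln(RSS/n) + 2k + C penalizes the models' differing parameter counts
under a Gaussian-error assumption; the constant C cancels in ΔAIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import MODELED_CONDITIONS
from .fitting import CrossValResult
from .models import MODEL_SPECS


@dataclass(frozen=True)
class EvaluationRecord:
    """Per-voxel, per-model evaluation summary (fold-averaged)."""

    model_id: str
    gof: float
    noise_ceiling: float
    nrd: float
    aic: float
    rss_test: float
    n_obs: int
    k: int
    degenerate: bool


def r_squared(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation; 0 if either vector has zero variance.

    Note the metric is blind to sign and affine scaling: a perfectly
    anticorrelated prediction also scores 1.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size < 3:
        raise ValueError("need at least 3 conditions")
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        return 0.0
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


def is_degenerate(pred: np.ndarray, obs: np.ndarray) -> bool:
    """True when either vector has zero variance (r_squared convention 0)."""
    return bool(np.ptp(np.asarray(pred, float)) == 0.0 or np.ptp(np.asarray(obs, float)) == 0.0)


def noise_ceiling(odd_obs: np.ndarray, even_obs: np.ndarray) -> float:
    """Squared split-half correlation of the observed condition profiles."""
    return r_squared(np.asarray(odd_obs, float), np.asarray(even_obs, float))


def nrd(ceiling: float, gof: float) -> float:
    """Noise ceiling minus goodness of fit (may be negative per voxel)."""
    return float(ceiling) - float(gof)


def aic(rss: float, n: int, k: int, c: float = 0.0) -> float:
    """Akaike information criterion under Gaussian errors, up to a constant.

    rss = 0 (a perfect fit) returns -inf: the criterion is unbounded below.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0.0:
        return float("-inf")
    return n * float(np.log(rss / n)) + 2 * k + c


def delta_aic(aic_a: float, aic_b: float) -> float:
    """AIC difference a − b; the shared constant C cancels."""
    return aic_a - aic_b


def evaluate_crossval(cv: CrossValResult, aic_constant: float = 0.0) -> EvaluationRecord:
    """Fold-averaged evaluation of one voxel's cross-validated predictions.

    Goodness of fit, RSS, and AIC are computed per direction against that
    direction's held-out half (n = 5 conditions) and averaged; the noise
    ceiling compares the two observed halves in each direction's preference
    frame and is likewise averaged.
    """
    k = MODEL_SPECS[cv.model_id].k
    gofs, ceilings, rsses, aics, degenerate = [], [], [], [], False
    for fold in cv.folds:
        pred = np.array([fold.predicted[c] for c in MODELED_CONDITIONS])
        obs = np.array([fold.observed[c] for c in MODELED_CONDITIONS])
        train_obs = np.array([fold.train_profile[c] for c in MODELED_CONDITIONS])
        degenerate = degenerate or is_degenerate(pred, obs)
        gofs.append(r_squared(pred, obs))
        ceilings.append(noise_ceiling(train_obs, obs))
        rss = float(np.sum((obs - pred) ** 2))
        rsses.append(rss)
        aics.append(aic(rss, len(MODELED_CONDITIONS), k, aic_constant))
    gof = float(np.mean(gofs))
    ceiling = float(np.mean(ceilings))
    return EvaluationRecord(
        model_id=cv.model_id,
        gof=gof,
        noise_ceiling=ceiling,
        nrd=nrd(ceiling, gof),
        aic=float(np.mean(aics)),
        rss_test=float(np.mean(rsses)),
        n_obs=len(MODELED_CONDITIONS),
        k=k,
        degenerate=degenerate,
    )


def summarize(evaluations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-voxel evaluations for group-level statistics.

    Parameters
    ----------
    evaluations
        Long table with columns subject, roi, voxel, model, gof,
        noise_ceiling, nrd, aic, degenerate.

    Returns
    -------
    (cell_means, roi_ceiling)
        ``cell_means``: voxel-mean gof/nrd/aic per subject × roi × model,
        excluding degenerate voxels (their count is reported).
        ``roi_ceiling``: per-roi noise ceiling with across-subject SEM.
    """
    required = {"subject", "roi", "voxel", "model", "gof", "noise_ceiling", "degenerate"}
    missing = required - set(evaluations.columns)
    if missing:
        raise ValueError(f"evaluation table missing columns: {sorted(missing)}")
    valid = evaluations[~evaluations["degenerate"]]
    if valid.empty:
        raise ValueError("no non-degenerate voxels to summarize")
    metric_cols = [c for c in ("gof", "noise_ceiling", "nrd", "aic") if c in evaluations]
    grouped = valid.groupby(["subject", "roi", "model"], observed=True)
    cell_means = grouped[metric_cols].mean().reset_index()
    cell_means["n_voxels"] = grouped.size().to_numpy()
    n_degen = (
        evaluations[evaluations["degenerate"]]
        .groupby(["subject", "roi", "model"], observed=True)
        .size()
    )
    cell_means["n_degenerate"] = [
        int(n_degen.get(key, 0))
        for key in cell_means[["subject", "roi", "model"]].itertuples(index=False)
    ]

    subj_ceiling = (
        valid.groupby(["subject", "roi", "voxel"], observed=True)["noise_ceiling"]
        .mean()  # ceiling is model-independent; collapse duplicates across models
        .groupby(["subject", "roi"], observed=True)
        .mean()
        .reset_index()
    )
    roi_grp = subj_ceiling.groupby("roi", observed=True)["noise_ceiling"]
    roi_ceiling = roi_grp.agg(["mean", "sem", "count"]).reset_index()
    roi_ceiling.columns = ["roi", "noise_ceiling", "sem", "n_subjects"]
    return cell_means, roi_ceiling
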