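"""Per-voxel constrained least-squares fitting and split-half cross-validation.

Parameters are estimated per voxel by minimizing the sum of squared errors
between observed and predicted condition responses under the box constraints
declared in :mod:`voxnorm.models`, using multi-start trust-region least squares
(the normalization objective is non-convex, so each fit restarts from several
uniform draws within the bounds and keeps the best solution).

Cross-validation follows the split-half protocol: runs are divided into odd
and even halves; parameters estimated on one half predict the held-out half,
in both directions, and downstream comparisons use the average of the two
held-out predictions.  The voxel's category preference and the rp/rn inputs of
the linear models are taken from the training half of each fold, so nothing
predicting the test half originates in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .conditions import (
    CANONICAL_CONDITIONS,
    MODELED_CONDITIONS,
    CanonicalConditionProfile,
    assign_preference,
    canonicalize,
)
from .models import MODEL_SPECS, USES_ISOLATED_INPUTS, condition_arrays, predict_conditions

#: Restart counts below this arity use the reduced (convex-objective) default.
_LINEAR_ARITY = 2

from functools import lru_cache


@lru_cache(maxsize=None)
def _cached_arrays(conditions: tuple[str, ...]):
    return condition_arrays(conditions)


def _make_model_fns(model_id: str, conditions: tuple[str, ...], rp, rn):
    """Fast prediction and analytic-Jacobian closures for the optimizer.

    These duplicate :func:`voxnorm.models.predict_conditions` without its
    per-call validation; agreement between the two paths is property-tested.
    """
    cp, cn, att_p, att_n = _cached_arrays(conditions)
    afp = att_p.astype(float)
    afn = att_n.astype(float)

    if model_id == "normalization":

        def fun(x):
            l_p, l_n, sigma, beta = x
            g_p = np.where(att_p, beta, 1.0)
            g_n = np.where(att_n, beta, 1.0)
            return (g_p * cp * l_p + g_n * cn * l_n) / (g_p * cp + g_n * cn + sigma)

        def jac(x):
            l_p, l_n, sigma, beta = x
            g_p = np.where(att_p, beta, 1.0)
            g_n = np.where(att_n, beta, 1.0)
            num = g_p * cp * l_p + g_n * cn * l_n
            den = g_p * cp + g_n * cn + sigma
            dnum_db = afp * cp * l_p + afn * cn * l_n
            dden_db = afp * cp + afn * cn
            return np.stack(
                [
                    g_p * cp / den,
                    g_n * cn / den,
                    -num / den**2,
                    dnum_db / den - num * dden_db / den**2,
                ],
                axis=1,
            )

        return fun, jac

    rp = float(rp)
    rn = float(rn)

    if model_id in ("weighted_sum", "wa_ew"):
        scale = 1.0 if model_id == "weighted_sum" else 1.0 / (cp + cn)

        def fun(x):
            (beta,) = x
            g_p = np.where(att_p, beta, 1.0)
            g_n = np.where(att_n, beta, 1.0)
            return (g_p * cp * rp + g_n * cn * rn) * scale

        def jac(x):
            return ((afp * cp * rp + afn * cn * rn) * scale)[:, None]

        return fun, jac

    if model_id == "wa_uw":
        paired = cp + cn > 1

        def fun(x):
            alpha, beta = x
            g_p = np.where(att_p, beta, 1.0)
            g_n = np.where(att_n, beta, 1.0)
            return np.where(
                paired,
                g_p * alpha * rp + g_n * (1.0 - alpha) * rn,
                g_p * cp * rp + g_n * cn * rn,
            )

        def jac(x):
            alpha, beta = x
            g_p = np.where(att_p, beta, 1.0)
            g_n = np.where(att_n, beta, 1.0)
            d_alpha = np.where(paired, g_p * rp - g_n * rn, 0.0)
            d_beta = np.where(
                paired,
                afp * alpha * rp + afn * (1.0 - alpha) * rn,
                afp * cp * rp + afn * cn * rn,
            )
            return np.stack([d_alpha, d_beta], axis=1)

        return fun, jac

    # wa_uwub and wa_uwub_sat
    saturating = model_id == "wa_uwub_sat"

    def fun(x):
        alpha_p, alpha_n, beta_p, beta_n = x[:4]
        g_p = np.where(att_p, beta_p, 1.0)
        g_n = np.where(att_n, beta_n, 1.0)
        pred = g_p * cp * alpha_p * rp + g_n * cn * alpha_n * rn
        return np.minimum(pred, x[4]) if saturating else pred

    def jac(x):
        alpha_p, alpha_n, beta_p, beta_n = x[:4]
        g_p = np.where(att_p, beta_p, 1.0)
        g_n = np.where(att_n, beta_n, 1.0)
        cols = [
            g_p * cp * rp,
            g_n * cn * rn,
            afp * cp * alpha_p * rp,
            afn * cn * alpha_n * rn,
        ]
        if not saturating:
            return np.stack(cols, axis=1)
        pred = g_p * cp * alpha_p * rp + g_n * cn * alpha_n * rn
        unclipped = pred <= x[4]
        uf = unclipped.astype(float)
        return np.stack([c * uf for c in cols] + [1.0 - uf], axis=1)

    return fun, jac


@dataclass(frozen=True)
class FitOptions:
    """Options controlling per-voxel estimation and cross-validation."""

    n_restarts: int = 20  # multi-start count for the normalization model
    n_restarts_linear: int = 3  # for the 1-2 parameter (near-)convex models
    n_restarts_uwub: int = 12  # for the bilinear unconstrained-weights variants
    tolerance: float = 1e-10
    seed: int = 0
    #: conditions the SSE is taken over; None = the model's default
    #: (5 modeled conditions for WS/WA which consume P and N as inputs,
    #: all 7 for normalization, which predicts P and N itself).
    fit_conditions: tuple[str, ...] | None = None
    normalization_fit_all_conditions: bool = True
    #: where the linear models' rp/rn inputs come from when predicting the
    #: held-out half.
    rpn_source: str = "train"  # "train" | "test"
    #: assign voxel preference from the training half of each fold, or from
    #: the pooled mean of both halves.
    preference_scope: str = "fold"  # "fold" | "pooled"

    def restarts_for(self, model_id: str) -> int:
        if MODEL_SPECS[model_id].k <= _LINEAR_ARITY:
            return min(self.n_restarts, self.n_restarts_linear)
        if model_id.startswith("wa_uwub"):
            return min(self.n_restarts, self.n_restarts_uwub)
        return self.n_restarts

    def conditions_for(self, model_id: str) -> tuple[str, ...]:
        if self.fit_conditions is not None:
            return self.fit_conditions
        if model_id == "normalization" and self.normalization_fit_all_conditions:
            return CANONICAL_CONDITIONS
        return MODELED_CONDITIONS


@dataclass(frozen=True)
class FitResult:
    """Best constrained least-squares solution for one voxel and model."""

    model_id: str
    params: np.ndarray
    train_sse: float
    converged: bool
    n_restarts_used: int
    degenerate: bool = False

    @property
    def param_dict(self) -> dict[str, float]:
        names = MODEL_SPECS[self.model_id].param_names
        return dict(zip(names, self.params.tolist()))


@dataclass(frozen=True)
class FoldResult:
    """One cross-validation direction (train half -> test half)."""

    train_half: str
    test_half: str
    preference: str
    fit: FitResult
    predicted: dict[str, float]  # held-out predictions, modeled conditions
    observed: dict[str, float]  # held-out observations, modeled conditions
    train_profile: CanonicalConditionProfile
    test_profile: CanonicalConditionProfile


@dataclass(frozen=True)
class CrossValResult:
    """Both fold directions plus the condition-wise averaged prediction."""

    model_id: str
    folds: tuple[FoldResult, FoldResult]
    averaged_prediction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.averaged_prediction:
            avg = {
                c: 0.5 * (self.folds[0].predicted[c] + self.folds[1].predicted[c])
                for c in MODELED_CONDITIONS
            }
            object.__setattr__(self, "averaged_prediction", avg)


def _initial_points(spec, n_restarts: int, rng: np.random.Generator) -> np.ndarray:
    lower = np.array(spec.lower)
    upper = np.array(spec.upper)
    points = np.empty((n_restarts, spec.k))
    points[0] = 0.5 * (lower + upper)  # deterministic midpoint start
    if n_restarts > 1:
        points[1:] = rng.uniform(lower, upper, size=(n_restarts - 1, spec.k))
    return points


def fit_voxel(
    model_id: str,
    training_profile: CanonicalConditionProfile | Mapping[str, float],
    options: FitOptions = FitOptions(),
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit one model to one voxel's training-half condition profile.

    Returns the best of the multi-start solutions; a profile with zero
    variance over the fit conditions is flagged degenerate rather than
    raising.
    """
    spec = MODEL_SPECS[model_id]
    responses = (
        training_profile.responses
        if isinstance(training_profile, CanonicalConditionProfile)
        else training_profile
    )
    missing = [c for c in CANONICAL_CONDITIONS if c not in responses]
    if missing:
        raise ValueError(f"training profile missing conditions: {missing}")
    conditions = options.conditions_for(model_id)
    observed = np.array([responses[c] for c in conditions], dtype=float)
    rp = float(responses["P"]) if USES_ISOLATED_INPUTS[model_id] else None
    rn = float(responses["N"]) if USES_ISOLATED_INPUTS[model_id] else None
    degenerate = bool(np.ptp(observed) == 0.0)

    predict_fn, jac_fn = _make_model_fns(model_id, conditions, rp, rn)

    def residuals(x: np.ndarray) -> np.ndarray:
        return predict_fn(x) - observed

    def jacobian(x: np.ndarray) -> np.ndarray:
        return jac_fn(x)

    rng = np.random.default_rng(options.seed) if rng is None else rng
    n_restarts = options.restarts_for(model_id)
    starts = _initial_points(spec, n_restarts, rng)
    tol = options.tolerance

    best_x: np.ndarray | None = None
    best_sse = np.inf
    any_converged = False
    for x0 in starts:
        sol = least_squares(
            residuals,
            x0,
            jac=jacobian,
            bounds=(spec.lower, spec.upper),
            method="trf",
            xtol=tol,
            ftol=tol,
            gtol=tol,
        )
        sse = float(2.0 * sol.cost)
        any_converged = any_converged or bool(sol.success)
        if sol.success and sse < best_sse:
            best_sse = sse
            best_x = sol.x
    if best_x is None:  # every restart failed: keep the midpoint, flag it
        best_x = starts[0]
        best_sse = float(np.sum(residuals(best_x) ** 2))
    return FitResult(
        model_id=model_id,
        params=np.clip(best_x, spec.lower, spec.upper),
        train_sse=best_sse,
        converged=any_converged,
        n_restarts_used=n_restarts,
        degenerate=degenerate,
    )


def _fold(
    train_raw: Mapping[str, float],
    test_raw: Mapping[str, float],
    train_half: str,
    test_half: str,
    model_id: str,
    options: FitOptions,
    rng: np.random.Generator,
    voxel: str | None,
) -> FoldResult:
    if options.preference_scope == "pooled":
        b = 0.5 * (train_raw["B"] + test_raw["B"])
        h = 0.5 * (train_raw["H"] + test_raw["H"])
    else:
        b, h = train_raw["B"], train_raw["H"]
    preference = assign_preference(b, h, voxel=voxel)
    train_profile = canonicalize(train_raw, preference)
    test_profile = canonicalize(test_raw, preference)
    fit = fit_voxel(model_id, train_profile, options, rng)
    if USES_ISOLATED_INPUTS[model_id]:
        source = train_profile if options.rpn_source == "train" else test_profile
        rp, rn = source["P"], source["N"]
    else:
        rp = rn = None
    pred = predict_conditions(model_id, fit.params, MODELED_CONDITIONS, rp, rn)
    return FoldResult(
        train_half=train_half,
        test_half=test_half,
        preference=preference,
        fit=fit,
        predicted=dict(zip(MODELED_CONDITIONS, pred.tolist())),
        observed={c: test_profile[c] for c in MODELED_CONDITIONS},
        train_profile=train_profile,
        test_profile=test_profile,
    )


def crossval_voxel(
    odd_raw: Mapping[str, float],
    even_raw: Mapping[str, float],
    model_id: str,
    options: FitOptions = FitOptions(),
    voxel: str | None = None,
) -> CrossValResult:
    """Two-fold split-half cross-validation for one voxel and one model.

    Direction 1 trains on the odd half and predicts the even half; direction 2
    is mirrored; the averaged prediction map is their condition-wise mean.
    Deterministic given ``options.seed``.
    """
    for name, raw in (("odd", odd_raw), ("even", even_raw)):
        if raw is None:
            raise ValueError(f"missing {name} half")
    rng = np.random.default_rng(options.seed)
    fold1 = _fold(odd_raw, even_raw, "odd", "even", model_id, options, rng, voxel)
    fold2 = _fold(even_raw, odd_raw, "even", "odd", model_id, options, rng, voxel)
    return CrossValResult(model_id=model_id, folds=(fold1, fold2))
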