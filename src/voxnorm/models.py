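"""Forward predictions of the six voxel response models.

Every model predicts the response of one voxel to the seven canonical
conditions.  The weighted sum and weighted average families take the voxel's
isolated ignored responses ``rp`` and ``rn`` as inputs (they are data, not
parameters) and combine them linearly, with an attention gain multiplying the
attended stimulus's contribution:

* ``weighted_sum``      — paired response is rp + rn; one gain β.
* ``wa_ew``             — equal-weights average (rp + rn) / 2; one gain β.
* ``wa_uw``             — unequal weights α, 1 − α summing to 1; one gain β.
* ``wa_uwub``           — unconstrained weights αP, αN and separate gains
                          βP, βN; nests both models above.
* ``wa_uwub_sat``       — wa_uwub followed by a hard saturation min(·, s).

The normalization model instead estimates the excitatory drives LP, LN it
cannot observe and divides by the pooled activity plus a semi-saturation
constant σ; attention multiplies the attended stimulus's drive in numerator
and denominator alike:

    R = (gP·cP·LP + gN·cN·LN) / (gP·cP + gN·cN + σ)

with contrasts cP, cN ∈ {0, 1} flagging stimulus presence and the gain g equal
to β for the attended stimulus and 1 otherwise (both 1 under fixation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditions import (
    ATTENDED_STIMULUS,
    CANONICAL_CONDITIONS,
    CONTRASTS,
)

#: Model identifiers, in canonical reporting order.
MODEL_IDS: tuple[str, ...] = (
    "weighted_sum",
    "wa_ew",
    "wa_uw",
    "wa_uwub",
    "wa_uwub_sat",
    "normalization",
)


@dataclass(frozen=True)
class ModelSpec:
    """Parameter names and box bounds of one model."""

    model_id: str
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.param_names)

    def validate(self, params: np.ndarray) -> np.ndarray:
        x = np.asarray(params, dtype=float)
        if x.shape != (self.k,):
            raise ValueError(
                f"{self.model_id} expects {self.k} parameters "
                f"{self.param_names}, got shape {x.shape}"
            )
        return x


# β ≥ 1 and σ > 0, both < 10; |LP|, |LN| < 10.  The open lower bounds are
# closed at 1 and 1e-6 for the box-constrained solver.
_SIGMA_MIN = 1e-6

MODEL_SPECS: dict[str, ModelSpec] = {
    "weighted_sum": ModelSpec("weighted_sum", ("beta",), (1.0,), (10.0,)),
    "wa_ew": ModelSpec("wa_ew", ("beta",), (1.0,), (10.0,)),
    "wa_uw": ModelSpec("wa_uw", ("alpha", "beta"), (0.0, 1.0), (1.0, 10.0)),
    "wa_uwub": ModelSpec(
        "wa_uwub",
        ("alpha_p", "alpha_n", "beta_p", "beta_n"),
        (0.0, 0.0, 1.0, 1.0),
        (10.0, 10.0, 10.0, 10.0),
    ),
    "wa_uwub_sat": ModelSpec(
        "wa_uwub_sat",
        ("alpha_p", "alpha_n", "beta_p", "beta_n", "sat"),
        (0.0, 0.0, 1.0, 1.0, -10.0),
        (10.0, 10.0, 10.0, 10.0, 10.0),
    ),
    "normalization": ModelSpec(
        "normalization",
        ("l_p", "l_n", "sigma", "beta"),
        (-10.0, -10.0, _SIGMA_MIN, 1.0),
        (10.0, 10.0, 10.0, 10.0),
    ),
}

#: Whether a model consumes the isolated ignored responses rp, rn as inputs.
USES_ISOLATED_INPUTS: dict[str, bool] = {m: m != "normalization" for m in MODEL_IDS}


def condition_arrays(conditions: tuple[str, ...]) -> tuple[np.ndarray, ...]:
    """(cP, cN, attended-is-P, attended-is-N) arrays for a condition list."""
    cp = np.array([CONTRASTS[c][0] for c in conditions], dtype=float)
    cn = np.array([CONTRASTS[c][1] for c in conditions], dtype=float)
    att_p = np.array([ATTENDED_STIMULUS[c] == "preferred" for c in conditions])
    att_n = np.array([ATTENDED_STIMULUS[c] == "null" for c in conditions])
    return cp, cn, att_p, att_n


def predict_conditions(
    model_id: str,
    params: np.ndarray,
    conditions: tuple[str, ...],
    rp: float | None = None,
    rn: float | None = None,
) -> np.ndarray:
    """Predicted responses for an ordered list of canonical conditions."""
    spec = MODEL_SPECS.get(model_id)
    if spec is None:
        raise ValueError(f"unknown model {model_id!r}")
    x = spec.validate(params)
    unknown = [c for c in conditions if c not in ATTENDED_STIMULUS]
    if unknown:
        raise ValueError(f"unknown canonical conditions: {unknown}")
    cp, cn, att_p, att_n = condition_arrays(conditions)

    if model_id == "normalization":
        l_p, l_n, sigma, beta = x
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        g_p = np.where(att_p, beta, 1.0)
        g_n = np.where(att_n, beta, 1.0)
        num = g_p * cp * l_p + g_n * cn * l_n
        den = g_p * cp + g_n * cn + sigma
        return num / den

    if rp is None or rn is None:
        raise ValueError(f"{model_id} requires the isolated ignored responses rp and rn")
    rp = float(rp)
    rn = float(rn)

    if model_id == "weighted_sum":
        (beta,) = x
        g_p = np.where(att_p, beta, 1.0)
        g_n = np.where(att_n, beta, 1.0)
        return g_p * cp * rp + g_n * cn * rn

    if model_id == "wa_ew":
        (beta,) = x
        g_p = np.where(att_p, beta, 1.0)
        g_n = np.where(att_n, beta, 1.0)
        # paired response is the gained average; isolated attended is β·r
        return (g_p * cp * rp + g_n * cn * rn) / (cp + cn)

    if model_id == "wa_uw":
        alpha, beta = x
        g_p = np.where(att_p, beta, 1.0)
        g_n = np.where(att_n, beta, 1.0)
        paired = g_p * alpha * rp + g_n * (1.0 - alpha) * rn
        # weights apply only in clutter; an isolated stimulus keeps weight 1
        isolated = g_p * cp * rp + g_n * cn * rn
        return np.where(cp + cn > 1, paired, isolated)

    # the two UWUB variants share the unconstrained-weights core
    alpha_p, alpha_n, beta_p, beta_n = x[:4]
    g_p = np.where(att_p, beta_p, 1.0)
    g_n = np.where(att_n, beta_n, 1.0)
    pred = g_p * cp * alpha_p * rp + g_n * cn * alpha_n * rn
    if model_id == "wa_uwub_sat":
        pred = np.minimum(pred, x[4])
    return pred


def predict(
    model_id: str,
    params: np.ndarray,
    condition: str,
    rp: float | None = None,
    rn: float | None = None,
) -> float:
    """Predicted response of one model in one canonical condition."""
    return float(predict_conditions(model_id, params, (condition,), rp, rn)[0])


def predict_all_conditions(
    model_id: str,
    params: np.ndarray,
    rp: float | None = None,
    rn: float | None = None,
) -> dict[str, float]:
    """Complete 7-condition prediction map (rp/rn ignored by normalization)."""
    values = predict_conditions(model_id, params, CANONICAL_CONDITIONS, rp, rn)
    return dict(zip(CANONICAL_CONDITIONS, values.tolist()))
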