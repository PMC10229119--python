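"""Forward-model arithmetic, nesting relations, and limiting regimes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voxnorm.conditions import CANONICAL_CONDITIONS
from voxnorm.fitting import _make_model_fns
from voxnorm.models import (
    MODEL_IDS,
    MODEL_SPECS,
    predict,
    predict_all_conditions,
    predict_conditions,
)

PAIRED = ("PN", "PatN", "PNat")


@pytest.mark.parametrize(
    "model_id,params,condition,rp,rn,expected",
    [
        # weighted sum: paired = sum, attention gains one term
        ("weighted_sum", [1.5], "PatN", 2, 1, 4.0),
        ("weighted_sum", [1.5], "PNat", 2, 1, 3.5),
        ("weighted_sum", [1.0], "PN", 2, 1, 3.0),
        ("weighted_sum", [1.7], "PN", 2, 1, 3.0),
        ("weighted_sum", [2.0], "Pat", 3, 1, 6.0),
        # equal-weights average
        ("wa_ew", [2.0], "PatN", 2, 1, 2.5),
        ("wa_ew", [2.0], "PN", 2, 1, 1.5),
        ("wa_ew", [2.0], "Pat", 2, 1, 4.0),
        # unequal weights summing to one
        ("wa_uw", [0.75, 1.0], "PN", 2, 1, 1.75),
        ("wa_uw", [0.75, 2.0], "PatN", 2, 1, 3.25),
        ("wa_uw", [0.75, 2.0], "Pat", 2, 1, 4.0),
        # unconstrained weights and gains
        ("wa_uwub", [0.6, 0.5, 2.0, 1.5], "PatN", 2, 1, 2.9),
        ("wa_uwub", [0.6, 0.5, 2.0, 1.5], "PNat", 2, 1, 1.95),
        ("wa_uwub", [0.6, 0.5, 2.0, 1.5], "Pat", 2, 1, 2.4),
        # saturation clips the calculated response
        ("wa_uwub_sat", [0.6, 0.5, 2.0, 1.0, 2.0], "PatN", 2, 1, 2.0),
        ("wa_uwub_sat", [0.6, 0.5, 2.0, 1.0, 5.0], "PatN", 2, 1, 2.9),
        # divisive normalization
        ("normalization", [4, 2, 1.0, 1.0], "PN", None, None, 2.0),
        ("normalization", [4, 2, 0.5, 2.0], "PatN", None, None, 10 / 3.5),
        ("normalization", [4, 2, 1.0, 3.0], "Pat", None, None, 3.0),
        ("normalization", [4, 2, 1.0, 2.0], "PNat", None, None, 2.0),
    ],
)
def test_worked_prediction_examples(model_id, params, condition, rp, rn, expected):
    value = predict(model_id, np.asarray(params, float), condition, rp=rp, rn=rn)
    assert value == pytest.approx(expected, abs=1e-12)


def test_normalization_full_condition_map():
    preds = predict_all_conditions("normalization", np.array([4.0, 2.0, 1.0, 2.0]))
    # N is isolated and ignored: no gain anywhere, R = LN / (cN + sigma) = 1
    expected = {"Pat": 8 / 3, "PatN": 2.5, "PNat": 2.0, "Nat": 4 / 3, "P": 2.0, "PN": 2.0, "N": 1.0}
    assert preds == pytest.approx(expected)


@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_prediction_map_is_complete(model_id):
    params = 0.5 * (np.array(MODEL_SPECS[model_id].lower) + np.array(MODEL_SPECS[model_id].upper))
    preds = predict_all_conditions(model_id, params, rp=2.0, rn=1.0)
    assert set(preds) == set(CANONICAL_CONDITIONS)


def test_weighted_sum_without_attention_gain_is_plain_sum():
    preds = predict_all_conditions("weighted_sum", np.array([1.0]), rp=2.0, rn=0.7)
    assert preds["PN"] == preds["PatN"] == preds["PNat"] == pytest.approx(2.7)
    assert preds["Pat"] == preds["P"] == 2.0


def test_unknown_condition_and_arity_mismatch_raise():
    with pytest.raises(ValueError, match="unknown canonical"):
        predict("weighted_sum", np.array([1.0]), "XYZ", rp=1, rn=1)
    with pytest.raises(ValueError, match="parameters"):
        predict("normalization", np.array([1.0, 2.0]), "PN")
    with pytest.raises(ValueError, match="sigma"):
        predict("normalization", np.array([1.0, 0.5, 0.0, 1.0]), "PN")


def test_winner_take_all_limit_of_normalization():
    """As the attention gain grows, the attended-preferred paired response
    approaches the preferred drive (max-pooling regime)."""
    l_p, l_n, sigma = 6.0, 2.0, 0.5
    values = [
        predict("normalization", np.array([l_p, l_n, sigma, b]), "PatN")
        for b in (1.0, 2.0, 5.0, 20.0, 1e4)
    ]
    assert np.all(np.diff(values) > 0)  # monotone in beta while below LP
    assert values[-1] == pytest.approx(l_p, rel=1e-3)


def test_averaging_limit_of_normalization():
    """With no attention and vanishing semi-saturation, the paired response
    is the average of the drives."""
    value = predict("normalization", np.array([4.0, 2.0, 1e-9, 1.0]), "PN")
    assert value == pytest.approx(3.0, rel=1e-8)


@given(
    l_p=st.floats(0.5, 9.5),
    l_n=st.floats(0.1, 9.5),
    sigma=st.floats(0.05, 9.5),
    beta=st.floats(1.0, 9.5),
)
def test_normalization_response_change_closed_form(l_p, l_n, sigma, beta):
    params = np.array([l_p, l_n, sigma, beta])
    change = predict(params=params, model_id="normalization", condition="PatN") - predict(
        params=params, model_id="normalization", condition="PNat"
    )
    assert change == pytest.approx((beta - 1) * (l_p - l_n) / (beta + 1 + sigma), abs=1e-10)


@given(
    alpha=st.floats(0.0, 2.0),
    beta=st.floats(1.0, 9.0),
    rp=st.floats(-5, 5),
    rn=st.floats(-5, 5),
)
def test_uwub_nests_weighted_sum_and_equal_weights_average(alpha, beta, rp, rn):
    ws = predict_all_conditions("weighted_sum", np.array([beta]), rp=rp, rn=rn)
    uwub_ws = predict_all_conditions("wa_uwub", np.array([1.0, 1.0, beta, beta]), rp=rp, rn=rn)
    for c in CANONICAL_CONDITIONS:
        assert uwub_ws[c] == pytest.approx(ws[c], abs=1e-12)
    ew = predict_all_conditions("wa_ew", np.array([beta]), rp=rp, rn=rn)
    uwub_ew = predict_all_conditions("wa_uwub", np.array([0.5, 0.5, beta, beta]), rp=rp, rn=rn)
    for c in PAIRED:  # isolated attended conditions differ by design (β·r vs β·α·r)
        assert uwub_ew[c] == pytest.approx(ew[c], abs=1e-12)


@given(
    model_id=st.sampled_from(MODEL_IDS),
    u=st.tuples(*[st.floats(0.01, 0.99) for _ in range(5)]),
    rp=st.floats(-3, 3),
    rn=st.floats(-3, 3),
)
def test_fast_optimizer_path_matches_public_predictions(model_id, u, rp, rn):
    """The fitting module's closure predictions agree with predict_conditions."""
    spec = MODEL_SPECS[model_id]
    lower, upper = np.array(spec.lower), np.array(spec.upper)
    params = lower + np.array(u[: spec.k]) * (upper - lower)
    fast_fun, _ = _make_model_fns(model_id, CANONICAL_CONDITIONS, rp, rn)
    slow = predict_conditions(model_id, params, CANONICAL_CONDITIONS, rp, rn)
    np.testing.assert_allclose(fast_fun(params), slow, atol=1e-12)


# wa_uwub_sat is excluded: min(·, s) is non-differentiable at the clip point,
# so central differences can straddle the kink; it gets a fixed-point check.
@given(
    model_id=st.sampled_from([m for m in MODEL_IDS if m != "wa_uwub_sat"]),
    u=st.tuples(*[st.floats(0.05, 0.95) for _ in range(5)]),
)
def test_analytic_jacobian_matches_finite_differences(model_id, u):
    spec = MODEL_SPECS[model_id]
    lower, upper = np.array(spec.lower), np.array(spec.upper)
    params = lower + np.array(u[: spec.k]) * (upper - lower)
    fun, jac = _make_model_fns(model_id, CANONICAL_CONDITIONS, 2.0, 1.0)
    h = 1e-7
    numeric = np.stack(
        [
            (fun(params + h * e) - fun(params - h * e)) / (2 * h)
            for e in np.eye(spec.k)
        ],
        axis=1,
    )
    np.testing.assert_allclose(jac(params), numeric, atol=1e-5)


@pytest.mark.parametrize("sat", [0.45, 8.0])  # fully clipped / fully unclipped
def test_saturating_variant_jacobian_away_from_the_kink(sat):
    params = np.array([0.6, 0.5, 2.0, 1.5, sat])
    fun, jac = _make_model_fns("wa_uwub_sat", CANONICAL_CONDITIONS, 2.0, 1.0)
    h = 1e-7
    numeric = np.stack(
        [(fun(params + h * e) - fun(params - h * e)) / (2 * h) for e in np.eye(5)],
        axis=1,
    )
    np.testing.assert_allclose(jac(params), numeric, atol=1e-5)
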