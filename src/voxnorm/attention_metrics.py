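"""Attention effect sizes: response change, modulation asymmetry, model gaps.

Two indices summarize how attention reshapes the paired-stimulus response of
a voxel:

* response change — R(PatN) − R(PNat), the drop in activity when attention
  shifts from the preferred to the null stimulus while the stimuli stay fixed;
* asymmetry — (R(PNat) − R(Nat)) − (R(Pat) − R(PatN)), comparing how much the
  *unattended* stimulus moves the response when it is the preferred versus the
  null one.  Attending the preferred stimulus nearly removes the null
  stimulus's influence, but not vice versa, so this index is positive in data
  governed by divisive normalization.

Model-side indices are computed from the cross-validated, fold-averaged
prediction maps, never from refits, and compared with the data as a signed
gap (data − model).
"""

from __future__ import annotations

from typing import Mapping


def _require(responses: Mapping[str, float], conditions: tuple[str, ...]) -> None:
    missing = [c for c in conditions if c not in responses]
    if missing:
        raise ValueError(f"response map missing conditions: {missing}")


def response_change_index(responses: Mapping[str, float]) -> float:
    """R(PatN) − R(PNat): response drop when attention shifts P -> N."""
    _require(responses, ("PatN", "PNat"))
    return float(responses["PatN"]) - float(responses["PNat"])


def asymmetry_index(responses: Mapping[str, float]) -> float:
    """(R(PNat) − R(Nat)) − (R(Pat) − R(PatN)): modulation asymmetry."""
    _require(responses, ("PNat", "Nat", "Pat", "PatN"))
    return (float(responses["PNat"]) - float(responses["Nat"])) - (
        float(responses["Pat"]) - float(responses["PatN"])
    )


def model_data_gap(data_index: float, model_index: float) -> float:
    """Signed difference between an observed and a model-predicted index."""
    return float(data_index) - float(model_index)
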