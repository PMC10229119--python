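"""Condition vocabulary and the raw -> canonical (body/house -> preferred/null) mapping.

An experimental run has seven stimulus/attention conditions built from body (B)
and house (H) stimuli, with the superscript-"at" marking the attended category
(attention is on the fixation point otherwise).  Raw labels are spelled in ASCII
as ``Bat, BatH, BHat, Hat, B, H, BH``.  Because voxels differ in which category
they prefer, every analysis is carried out in a preference-referenced frame:
conditions are relabelled to ``Pat, PatN, PNat, Nat, P, PN, N`` where P is the
voxel's preferred category and N the null (non-preferred) one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: Raw condition labels (B = body, H = house, "at" suffix = attended stimulus).
RAW_CONDITIONS: tuple[str, ...] = ("Bat", "BatH", "BHat", "Hat", "B", "H", "BH")

#: Preference-referenced condition labels (P = preferred, N = null).
CANONICAL_CONDITIONS: tuple[str, ...] = ("Pat", "PatN", "PNat", "Nat", "P", "PN", "N")

#: The five conditions the models are evaluated on.  P and N are excluded
#: because the weighted sum/average models consume them as inputs.
MODELED_CONDITIONS: tuple[str, ...] = ("Pat", "PatN", "PNat", "Nat", "PN")

#: Which stimulus is attended in each canonical condition.
ATTENDED_STIMULUS: dict[str, str] = {
    "Pat": "preferred",
    "PatN": "preferred",
    "PNat": "null",
    "Nat": "null",
    "P": "fixation",
    "PN": "fixation",
    "N": "fixation",
}

#: Stimulus contrasts (cP, cN): 1 when the stimulus is on screen, else 0.
CONTRASTS: dict[str, tuple[int, int]] = {
    "Pat": (1, 0),
    "PatN": (1, 1),
    "PNat": (1, 1),
    "Nat": (0, 1),
    "P": (1, 0),
    "PN": (1, 1),
    "N": (0, 1),
}

#: raw -> canonical when the voxel prefers bodies.
BODY_PREFERENCE_MAP: dict[str, str] = {
    "Bat": "Pat",
    "BatH": "PatN",
    "BHat": "PNat",
    "Hat": "Nat",
    "B": "P",
    "H": "N",
    "BH": "PN",
}

#: raw -> canonical when the voxel prefers houses (mirror of the body map).
HOUSE_PREFERENCE_MAP: dict[str, str] = {
    "Bat": "Nat",
    "BatH": "PNat",
    "BHat": "PatN",
    "Hat": "Pat",
    "B": "N",
    "H": "P",
    "BH": "PN",
}

_PREFERENCE_MAPS = {"body": BODY_PREFERENCE_MAP, "house": HOUSE_PREFERENCE_MAP}


@dataclass(frozen=True)
class CanonicalConditionProfile:
    """The seven preference-referenced responses of one voxel in one data half."""

    responses: Mapping[str, float]
    preference: str  # "body" or "house", recorded for provenance

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_CONDITIONS if c not in self.responses]
        if missing:
            raise ValueError(f"profile is missing canonical conditions: {missing}")
        if self.preference not in ("body", "house"):
            raise ValueError(f"unknown preference {self.preference!r}")

    def __getitem__(self, condition: str) -> float:
        return float(self.responses[condition])

    def vector(self, conditions: tuple[str, ...] = CANONICAL_CONDITIONS) -> np.ndarray:
        return np.array([self.responses[c] for c in conditions], dtype=float)


def assign_preference(
    body_isolated_ignored: float,
    house_isolated_ignored: float,
    voxel: str | None = None,
) -> str:
    """Assign a voxel's preferred category from its isolated ignored responses.

    The category evoking the larger response while the participant attends the
    fixation point wins; exact ties break toward "body" with a warning.
    """
    if not (math.isfinite(body_isolated_ignored) and math.isfinite(house_isolated_ignored)):
        name = f" for voxel {voxel}" if voxel is not None else ""
        raise ValueError(
            f"non-finite isolated ignored responses{name}: "
            f"B={body_isolated_ignored}, H={house_isolated_ignored}"
        )
    if body_isolated_ignored == house_isolated_ignored:
        warnings.warn(
            f"tied isolated ignored responses{'' if voxel is None else ' for voxel ' + str(voxel)}"
            " — preference set to 'body'",
            stacklevel=2,
        )
        return "body"
    return "body" if body_isolated_ignored > house_isolated_ignored else "house"


def canonicalize(
    raw_responses: Mapping[str, float], preference: str
) -> CanonicalConditionProfile:
    """Relabel a voxel's raw-condition responses into the preference frame.

    Pure relabelling: values are untouched and the label mapping is a bijection,
    so the multiset of responses is conserved.
    """
    try:
        mapping = _PREFERENCE_MAPS[preference]
    except KeyError:
        raise ValueError(f"unknown preference {preference!r}") from None
    missing = [c for c in RAW_CONDITIONS if c not in raw_responses]
    if missing:
        raise ValueError(f"raw responses missing conditions: {missing}")
    canonical = {mapping[raw]: float(raw_responses[raw]) for raw in RAW_CONDITIONS}
    return CanonicalConditionProfile(responses=canonical, preference=preference)
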