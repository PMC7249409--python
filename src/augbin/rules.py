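"""Composite responder rules and deterministic responder classification.

A composite responder endpoint declares a patient a responder when a
dichotomised continuous criterion (e.g. "tumour diameter sum shrank by at
least 30% from baseline") AND a binary criterion (e.g. "no new lesions") are
both met.  This module represents such rules and classifies subjects exactly
as the standard binary analysis would — it is the shared ground truth for
both the binary comparator and the augmented analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .data import TrialData

__all__ = [
    "Direction",
    "Classification",
    "ComponentRule",
    "CompositeRule",
    "classify_responder",
    "classify_trial",
]


class Direction(str, Enum):
    """Which side of the threshold counts as meeting the criterion."""

    AT_LEAST = "at_least"
    AT_MOST = "at_most"


class Classification(str, Enum):
    RESPONDER = "responder"
    NON_RESPONDER = "non_responder"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ComponentRule:
    """Threshold rule on the continuous component.

    Comparison is inclusive: ``y == threshold`` meets the criterion for both
    directions, matching the >=/<= conventions of clinical responder
    definitions.

    Tumour shrinkage expressed as signed percent change from baseline is an
    ``at_most`` rule with threshold -30 (a -35% change IS a response); the
    direction is explicit configuration, never inferred from data, to avoid
    silent sign errors.
    """

    direction: Direction
    threshold: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        thr = float(self.threshold)
        if not math.isfinite(thr):
            raise ValueError(f"threshold must be finite, got {self.threshold!r}")
        object.__setattr__(self, "threshold", thr)

    def met(self, y):
        """Vectorised inclusive comparison; NaN propagates (neither met nor unmet)."""
        y = np.asarray(y, dtype=float)
        if self.direction is Direction.AT_LEAST:
            return y >= self.threshold
        return y <= self.threshold


@dataclass(frozen=True)
class CompositeRule:
    """Continuous criterion AND binary criterion define a responder.

    ``binary_required`` must be True: this implementation covers the
    single-continuous + single-binary composite.  "m of k" style rules
    (e.g. 20% improvement in at least three of five assessments) are not
    representable and are rejected at construction.
    """

    continuous_rule: ComponentRule
    binary_required: bool = True
    description: str = field(default="")

    def __post_init__(self) -> None:
        if isinstance(self.continuous_rule, (list, tuple, set)):
            raise ValueError(
                "multi-continuous composite rules (m-of-k definitions such as the "
                "ACR20 'three of five' item) are not supported; supply a single "
                "ComponentRule"
            )
        if not isinstance(self.continuous_rule, ComponentRule):
            raise TypeError("continuous_rule must be a ComponentRule")
        if not self.binary_required:
            raise ValueError(
                "binary_required must be True: the composite is defined as the "
                "continuous criterion AND the binary criterion"
            )


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_responder(y, b, rule: CompositeRule) -> Classification:
    """Classify one subject from continuous value ``y`` and binary value ``b``.

    Returns ``UNDETERMINED`` whenever any needed component is missing — even if
    an observed ``b = 0`` would already preclude response, a missing continuous
    value leaves the classification undetermined by convention.  Missingness
    never raises.
    """
    if _is_missing(y) or _is_missing(b):
        return Classification.UNDETERMINED
    b = int(b)
    if b not in (0, 1):
        raise ValueError(f"binary component must be 0 or 1, got {b!r}")
    cont_met = bool(rule.continuous_rule.met(y))
    if cont_met and b == 1:
        return Classification.RESPONDER
    return Classification.NON_RESPONDER


def classify_trial(data: "TrialData", rule: CompositeRule):
    """Classify every subject and tabulate counts per arm.

    Returns ``(classifications, counts)`` where ``classifications`` is a numpy
    object array (one :class:`Classification` per subject, in input order) and
    ``counts`` a DataFrame indexed by arm with columns
    ``responder / non_responder / undetermined / n``; counts sum to the arm
    sizes.
    """
    if data.n == 0:
        raise ValueError("cannot classify an empty trial")
    cls = np.array(
        [classify_responder(y, b, rule) for y, b in zip(data.y, data.b)],
        dtype=object,
    )
    counts = pd.DataFrame(
        {
            "responder": 0,
            "non_responder": 0,
            "undetermined": 0,
        },
        index=pd.Index(sorted(np.unique(data.z)), name="arm"),
    )
    for arm in counts.index:
        sub = cls[data.z == arm]
        # identity comparison: numpy's == would coerce the str-enum to a
        # plain string scalar and compare elementwise False
        for c in Classification:
            counts.loc[arm, c.value] = sum(x is c for x in sub)
    counts["n"] = counts.sum(axis=1)
    return cls, counts
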