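"""Training/validation set construction and endpoint discretization.

The validation set is drawn by sorting chemicals on the endpoint value and
taking every k-th one (k = 4 by default), which preserves the endpoint
distribution across the split. VDss is modeled on the natural-log scale.
Classification labels come from fixed cutpoints with a strict-greater "high"
convention; inequality-qualified values are labeled only when the qualifier
pins the class unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemreg import Endpoint, EndpointValue, Qualifier
from .errors import EmptyInputError, NonPositiveValueError, SchemeMismatchError

#: sentinel for a qualifier value that does not pin a single class
UNKNOWN = "UNKNOWN"

DEFAULT_SPLIT_K = 4


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    k: int
    offset: int


@dataclass(frozen=True)
class ClassScheme:
    """Cutpoints and labels for one endpoint.

    ``len(labels) == len(cutpoints) + 1``; a value belongs to class i when it
    exceeds exactly i cutpoints (values equal to a cutpoint fall in the lower
    class: "high" means strictly greater).
    """

    endpoint: Endpoint
    cutpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.labels) != len(self.cutpoints) + 1:
            raise ValueError("need len(cutpoints)+1 labels")

    def label_of(self, value: float) -> str:
        idx = sum(value > c for c in self.cutpoints)
        return self.labels[idx]


# the study's categorization schemes
F_BINARY = ClassScheme(Endpoint.F_PERCENT, (50.0,), ("low", "high"))
F_MULTICLASS = ClassScheme(Endpoint.F_PERCENT, (30.0, 60.0), ("low", "medium", "high"))
VDSS_BINARY = ClassScheme(Endpoint.VDSS_L_PER_KG, (1.0,), ("low", "high"))
VDSS_MULTICLASS = ClassScheme(
    Endpoint.VDSS_L_PER_KG, (0.6, 5.0), ("low", "medium", "high")
)
HALFLIFE_MULTICLASS = ClassScheme(
    Endpoint.HALFLIFE_H, (4.0, 24.0), ("low", "medium", "high")
)


def every_kth_split(values: dict[str, float], k: int = DEFAULT_SPLIT_K,
                    offset: int = 0) -> SplitAssignment:
    """Sorted every-k-th split: validation takes positions offset, offset+k, …

    Chemicals are sorted ascending by endpoint value (ties broken by id for
    determinism); with offset 0 and k = 4 one chemical in four — roughly 25 %
    — lands in the validation set, spanning the whole endpoint range.

    Raises
    ------
    EmptyInputError
        If ``values`` is empty.
    """
    if not values:
        raise EmptyInputError("no values to split")
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 <= offset < k:
        raise ValueError("offset must be in [0, k)")
    ordered = sorted(values, key=lambda i: (values[i], i))
    valid = tuple(ordered[offset::k])
    valid_set = set(valid)
    train = tuple(i for i in ordered if i not in valid_set)
    return SplitAssignment(train_ids=train, valid_ids=valid, k=k, offset=offset)


def ln_transform(values) -> np.ndarray:
    """Natural log of strictly positive endpoint values (VDss in L/kg)."""
    arr = np.asarray(values, dtype=float)
    if arr.size and np.min(arr) <= 0:
        raise NonPositiveValueError("ln transform requires strictly positive values")
    return np.log(arr)


def inverse_ln_transform(values) -> np.ndarray:
    return np.exp(np.asarray(values, dtype=float))


def discretize(value: EndpointValue, scheme: ClassScheme) -> str:
    """Map a measurement to a class label, honoring inequality qualifiers.

    EQ values map by interval membership. A "<"/">" value maps only when every
    endpoint value compatible with the qualifier falls in the same class
    (e.g. ">80" with cutpoints 30/60 is unambiguously high, while ">40" with
    cutpoint 50 straddles both classes and returns ``UNKNOWN``).
    """
    if value.endpoint is not scheme.endpoint:
        raise SchemeMismatchError(
            f"value endpoint {value.endpoint.value} != scheme {scheme.endpoint.value}"
        )
    cuts = scheme.cutpoints
    if value.qualifier is Qualifier.EQ:
        return scheme.label_of(value.value)
    if value.qualifier is Qualifier.GT:
        # possible class indices for x > v range from #{c <= v} to len(cuts)
        lo = sum(c <= value.value for c in cuts)
        hi = len(cuts)
    else:  # LT: indices range from 0 to #{c < v}
        lo = 0
        hi = sum(c < value.value for c in cuts)
    return scheme.labels[lo] if lo == hi else UNKNOWN


def build_class_set(measurements: dict[str, EndpointValue],
                    scheme: ClassScheme) -> dict[str, str]:
    """Labels for every chemical the scheme can classify (UNKNOWN dropped)."""
    out = {}
    for rid in sorted(measurements):
        label = discretize(measurements[rid], scheme)
        if label != UNKNOWN:
            out[rid] = label
    return out
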