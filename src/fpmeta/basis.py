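"""Fractional-polynomial (FP) bases and exposure preprocessing.

An FP of degree ``m`` models the log hazard contribution of a positive
exposure ``x`` as ``sum_k beta_k * h_k(x)`` where each basis function
``h_k`` is a power ``x**p_k`` with ``p_k`` drawn from the conventional
eight-element power set ``{-2, -1, -0.5, 0, 0.5, 1, 2, 3}``.  Two
conventions complete the family: ``x**0`` denotes ``log(x)``, and a
repeated power ``(p, p)`` contributes ``(x**p, x**p * log(x))`` — so the
repeated zero ``(0, 0)`` contributes ``(log x, (log x)**2)``.

This module provides the basis transform, enumeration of all candidate
power tuples up to dimension 2, reference-level contrast vectors, and the
pooled-sample winsorization used to tame extreme exposure values before
any powering is done.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, ValidationError

#: Permitted FP powers, in ascending order.  ``0`` denotes ``log(x)``.
POWER_SET: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPSpec:
    """Degree and ordered power tuple defining an FP basis.

    ``powers`` are stored sorted ascending; repeated values are allowed
    and trigger the log-multiplied column convention.  Degree 0 (empty
    power tuple) is permitted as an explicit "no exposure effect" model
    used by the degree-selection closed test; it is never produced by
    :func:`enumerate_fp_specs`.
    """

    powers: tuple[float, ...]
    degree: int = field(init=False)

    def __post_init__(self) -> None:
        powers = tuple(float(p) for p in self.powers)
        if any(p not in POWER_SET for p in powers):
            bad = [p for p in powers if p not in POWER_SET]
            raise ValidationError(
                f"powers {bad} not in permitted set {POWER_SET}"
            )
        if len(powers) > 2:
            raise ValidationError(f"FP degree {len(powers)} > 2 not supported")
        if tuple(sorted(powers)) != powers:
            powers = tuple(sorted(powers))
        object.__setattr__(self, "powers", powers)
        object.__setattr__(self, "degree", len(powers))

    def __iter__(self):
        return iter(self.powers)

    def __lt__(self, other):
        if not isinstance(other, FPSpec):
            return NotImplemented
        return (self.degree, self.powers) < (other.degree, other.powers)

    def __len__(self) -> int:
        return self.degree

    def label(self) -> str:
        if self.degree == 0:
            return "null"
        return "(" + ", ".join(f"{p:g}" for p in self.powers) + ")"


#: Degree-1 spec for a plain linear exposure effect.
LINEAR = FPSpec((1.0,))
#: Degree-0 spec for the no-exposure-effect model.
NULL = FPSpec(())


def _as_positive_array(x, name: str = "x") -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    bad = np.where(~(arr > 0.0) | ~np.isfinite(arr))[0]
    if bad.size:
        raise DomainError(
            f"{name} must be strictly positive and finite; offending index "
            f"{int(bad[0])} (value {arr[bad[0]]!r})"
        )
    return arr


def fp_transform(x, spec: FPSpec, scale: float = 1.0) -> np.ndarray:
    """Evaluate the FP basis at strictly positive ``x``.

    Parameters
    ----------
    x : array-like of positive reals
    spec : FPSpec
    scale : optional pre-scale factor applied as ``x / scale`` before
        powering (default 1: raw exposure, the convention for BMI-like
        exposures which are safely positive).

    Returns
    -------
    (n, m) ndarray; column ``k`` is the k-th basis function.  The columns
    follow the repeated-power recurrence ``h_k = x**p_k`` if
    ``p_k != p_{k-1}`` else ``h_{k-1} * log(x)``, with ``x**0 = log(x)``.
    """
    if not isinstance(spec, FPSpec):
        spec = FPSpec(tuple(spec))
    arr = _as_positive_array(x) / float(scale)
    logx = np.log(arr)
    cols = []
    prev_power: float | None = None
    for p in spec.powers:
        if prev_power is not None and p == prev_power:
            cols.append(cols[-1] * logx)
        elif p == 0.0:
            cols.append(logx.copy())
        else:
            cols.append(arr**p)
        prev_power = p
    if not cols:
        return np.empty((arr.shape[0], 0))
    return np.column_stack(cols)


def enumerate_fp_specs(dimension: int) -> list[FPSpec]:
    """All candidate FP specs up to the given dimension.

    ``dimension=1`` gives the 8 degree-1 specs; ``dimension=2`` adds the
    36 degree-2 specs (unordered pairs with repetition), for 44 total.
    Ordering is deterministic: degree 1 first, lexicographic within degree.
    """
    if dimension not in (1, 2):
        raise ValidationError(f"dimension must be 1 or 2, got {dimension!r}")
    specs = [FPSpec((p,)) for p in POWER_SET]
    if dimension == 2:
        specs += [
            FPSpec(pair)
            for pair in itertools.combinations_with_replacement(POWER_SET, 2)
        ]
    return specs


def contrast_vector(x: float, x0: float, spec: FPSpec) -> np.ndarray:
    """Contrast ``a(x) = basis(x) - basis(x0)`` as a length-m vector.

    ``a(x)^T beta`` is the log hazard ratio at ``x`` versus the reference
    ``x0``; ``a(x0)`` is exactly the zero vector.
    """
    return contrast_matrix(np.atleast_1d(float(x)), x0, spec)[0]


def contrast_matrix(grid, x0: float, spec: FPSpec) -> np.ndarray:
    """Row-wise contrast vectors for every grid value versus ``x0``."""
    b = fp_transform(grid, spec)
    b0 = fp_transform([x0], spec)
    return b - b0


def winsorize(x, lower_centile: float = 0.01, upper_centile: float = 0.99) -> np.ndarray:
    """Clamp a pooled vector at its lower/upper centiles.

    The centile is the order statistic at 1-based index ``ceil(q * n)``
    (no interpolation), which makes the operation bit-reproducible and
    idempotent.  Centiles are meant to be computed on the pooled
    (all-study) vector, so call this once on the concatenated exposures.
    """
    lower = float(lower_centile)
    upper = float(upper_centile)
    if not (0.0 <= lower < upper <= 1.0):
        raise ValidationError(
            f"centiles must satisfy 0 <= lower < upper <= 1, got "
            f"({lower}, {upper})"
        )
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot winsorize an empty vector")
    srt = np.sort(arr)
    n = arr.size
    lo_idx = max(math.ceil(lower * n), 1) - 1
    hi_idx = max(math.ceil(upper * n), 1) - 1
    return np.clip(arr, srt[lo_idx], srt[hi_idx])
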