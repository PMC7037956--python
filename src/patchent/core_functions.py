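"""Concave core functions that quantify the uncertainty of a discrete distribution.

Four strictly concave scalar functions are supported.  Applied element-wise to
the bin probabilities of a patch histogram and summed, each yields a scalar
uncertainty measure that is zero for a point-mass distribution and maximal for
the uniform distribution:

* ``SHANNON`` (M1): ``f(x) = -x ln x`` — classical Shannon entropy.
* ``LOG_FUZZY`` (M2): ``f(x) = -[x ln x + (1-x) ln(1-x)]`` — logarithmic fuzzy
  entropy; each bin contributes the entropy of the Bernoulli(x) split.
* ``EXP_FUZZY`` (M3): ``f(x) = x e^(1-x) + (1-x) e^x - 1`` — exponential fuzzy
  entropy.
* ``RATIONAL`` (M4): ``f(x) = x/(1+x) - x/2`` — a plain strictly concave
  rational function (not a fuzzy entropy).

All values are in nats (natural logarithm).  The conventions ``0 ln 0 := 0``
and ``(1-x) ln(1-x) := 0`` at ``x = 1`` are applied element-wise.

The maximum of the summed measure over all distributions with ``r`` bins (the
*variety degree*) has a closed form for each kind, exposed by
:func:`upper_bound`.  The gap ``Δ(r) = B2(r) - B1(r)`` between the logarithmic
fuzzy entropy bound and the Shannon bound is the extra quantification range the
fuzzy measure offers; it grows monotonically and converges to 1 nat.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoreFunctionKind",
    "ProbabilityVector",
    "BoundReport",
    "core_term",
    "measure",
    "upper_bound",
    "bound_gap",
    "check_strict_concavity",
    "bounds_table",
]

PROB_SUM_TOL = 1e-9


class CoreFunctionKind(enum.Enum):
    """The four concave core functions, by their conventional short tags."""

    SHANNON = "m1"
    LOG_FUZZY = "m2"
    EXP_FUZZY = "m3"
    RATIONAL = "m4"

    @classmethod
    def from_tag(cls, tag: "str | CoreFunctionKind") -> "CoreFunctionKind":
        if isinstance(tag, cls):
            return tag
        try:
            return cls(str(tag).lower())
        except ValueError:
            valid = ", ".join(k.value for k in cls)
            raise ValueError(f"unknown core function {tag!r}; expected one of {valid}")


@dataclass(frozen=True)
class ProbabilityVector:
    """A discrete probability distribution over ``r`` intensity bins.

    Raises ``ValueError`` on construction if any entry lies outside [0, 1] or
    the entries do not sum to 1 within ``1e-9``.  No silent renormalization is
    performed: an off-by-mass histogram is a bug upstream, not noise.
    """

    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("probability vector must be 1-D and non-empty")
        if np.any(p < 0) or np.any(p > 1):
            bad = p[(p < 0) | (p > 1)][0]
            raise ValueError(f"probability {bad!r} outside [0, 1]")
        s = float(p.sum())
        if abs(s - 1.0) > PROB_SUM_TOL:
            raise ValueError(f"probabilities sum to {s!r}, not 1 (tolerance {PROB_SUM_TOL})")
        object.__setattr__(self, "p", p)

    @property
    def r(self) -> int:
        """Variety degree: the number of bins."""
        return int(self.p.size)

    @classmethod
    def uniform(cls, r: int) -> "ProbabilityVector":
        return cls(np.full(r, 1.0 / r))

    @classmethod
    def delta(cls, r: int, index: int = 0) -> "ProbabilityVector":
        p = np.zeros(r)
        p[index] = 1.0
        return cls(p)


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x ln x with the 0 ln 0 := 0 convention, element-wise."""
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def core_term(kind: "CoreFunctionKind | str", p):
    """Evaluate the core function ``f_kind`` at probability ``p`` (nats).

    ``p`` may be a scalar or an array; values must lie in [0, 1].
    """
    kind = CoreFunctionKind.from_tag(kind)
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        bad = arr[(arr < 0) | (arr > 1)].flat[0]
        raise ValueError(f"probability {bad!r} outside [0, 1]")
    if kind is CoreFunctionKind.SHANNON:
        out = -_xlogx(arr)
    elif kind is CoreFunctionKind.LOG_FUZZY:
        out = -(_xlogx(arr) + _xlogx(1.0 - arr))
    elif kind is CoreFunctionKind.EXP_FUZZY:
        out = arr * np.exp(1.0 - arr) + (1.0 - arr) * np.exp(arr) - 1.0
    else:  # RATIONAL
        out = arr / (1.0 + arr) - arr / 2.0
    if np.isscalar(p):
        return float(out)
    return out


def measure(kind: "CoreFunctionKind | str", dist: "ProbabilityVector | np.ndarray") -> float:
    """Uncertainty of a distribution: ``Σ_i f_kind(p_i)`` in nats.

    Zero for a point mass, maximal (= ``upper_bound(kind, r)``) at uniform.
    """
    if not isinstance(dist, ProbabilityVector):
        dist = ProbabilityVector(np.asarray(dist, dtype=float))
    return float(np.sum(core_term(kind, dist.p)))


def upper_bound(kind: "CoreFunctionKind | str", r: int) -> float:
    """Closed-form maximum of ``measure(kind, ·)`` over ``r``-bin distributions.

    B1(r) = ln r
    B2(r) = ln r + (r-1) ln(r/(r-1))
    B3(r) = e^((r-1)/r) + (r-1) e^(1/r) - r
    B4(r) = r/(r+1) - 1/2

    All bounds are attained at the uniform distribution and vanish at r = 1.
    """
    kind = CoreFunctionKind.from_tag(kind)
    r = int(r)
    if r < 1:
        raise ValueError(f"variety degree r must be >= 1, got {r}")
    if kind is CoreFunctionKind.SHANNON:
        return math.log(r)
    if kind is CoreFunctionKind.LOG_FUZZY:
        return math.log(r) + bound_gap(r) if r >= 2 else 0.0
    if kind is CoreFunctionKind.EXP_FUZZY:
        return math.exp((r - 1) / r) + (r - 1) * math.exp(1.0 / r) - r
    return r / (r + 1.0) - 0.5


def bound_gap(r: int) -> float:
    """Δ(r) = B2(r) - B1(r) = (r-1) ln(r/(r-1)); strictly increasing, → 1.

    The extra quantification range of logarithmic fuzzy entropy over Shannon
    entropy, in nats.  Defined for r >= 2.
    """
    r = int(r)
    if r < 2:
        raise ValueError(f"bound gap requires r >= 2, got {r}")
    # (r-1) ln(r/(r-1)) = -(r-1) ln(1 - 1/r), via log1p for large r
    return -(r - 1) * math.log1p(-1.0 / r)


def check_strict_concavity(kind: "CoreFunctionKind | str", x1: float, x2: float, lam: float) -> bool:
    """True iff the strict Jensen inequality holds for the triple.

    ``f(λ x1 + (1-λ) x2) > λ f(x1) + (1-λ) f(x2)`` with ``x1 ≠ x2`` and
    ``λ ∈ (0, 1)``.
    """
    if x1 == x2:
        raise ValueError("strict concavity check requires x1 != x2")
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda must be in (0, 1), got {lam}")
    mid = core_term(kind, lam * x1 + (1.0 - lam) * x2)
    chord = lam * core_term(kind, x1) + (1.0 - lam) * core_term(kind, x2)
    return bool(mid > chord)


@dataclass(frozen=True)
class BoundReport:
    """Upper bounds of the four measures at one variety degree."""

    r: int
    b1: float
    b2: float
    b3: float
    b4: float
    gap: float

    @classmethod
    def at(cls, r: int) -> "BoundReport":
        return cls(
            r=r,
            b1=upper_bound(CoreFunctionKind.SHANNON, r),
            b2=upper_bound(CoreFunctionKind.LOG_FUZZY, r),
            b3=upper_bound(CoreFunctionKind.EXP_FUZZY, r),
            b4=upper_bound(CoreFunctionKind.RATIONAL, r),
            gap=bound_gap(r) if r >= 2 else 0.0,
        )


def bounds_table(r_min: int = 2, r_max: int = 1024) -> pd.DataFrame:
    """Tabulate B1..B4 and Δ(r) for r in [r_min, r_max] (columns r, B1..B4, gap)."""
    if not 1 <= r_min <= r_max:
        raise ValueError("need 1 <= r_min <= r_max")
    rows = [BoundReport.at(r) for r in range(r_min, r_max + 1)]
    return pd.DataFrame(
        {
            "r": [b.r for b in rows],
            "B1": [b.b1 for b in rows],
            "B2": [b.b2 for b in rows],
            "B3": [b.b3 for b in rows],
            "B4": [b.b4 for b in rows],
            "gap": [b.gap for b in rows],
        }
    )
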