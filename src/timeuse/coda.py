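"""Aitchison-geometry primitives for 24-hour time-use compositions.

A day divides into four mutually exclusive behaviours -- moderate-to-
vigorous physical activity (MVPA), light physical activity (LPA),
sedentary behaviour (SB) and sleep -- whose durations carry only
relative information once the day's total is fixed.  The natural sample
space is the simplex: compositions are re-scaled to a constant total
(the closure operation, 1440 min for a day), mapped to unconstrained
real coordinates with isometric log-ratio (ilr) transforms built from
pivot (sequential binary partition) bases, and summarised by geometric
(compositional) means.

Pairwise association *within* a composition cannot use ordinary Pearson
correlation (the constant-sum constraint forces spurious negative
correlations), so this module also provides symmetric balance
coordinates: for a highlighted pair of parts (i, j), two length-one
log-contrasts that are mirror images under i <-> j exchange and
orthogonal to each other.  The Pearson correlation of the pair of
coordinates measures the co-dominance of parts i and j relative to the
average of the remaining parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PART_NAMES",
    "DEFAULT_KAPPA",
    "CompositionError",
    "TimeUseComposition",
    "IlrCoordinates",
    "SymmetricBalancePair",
    "closure",
    "pivot_basis",
    "ilr_pivot",
    "ilr_inverse",
    "clr",
    "aitchison_distance",
    "compositional_mean",
    "symmetric_balance_coefficients",
    "symmetric_balance_coords",
    "cor_coda",
]

#: canonical part order used throughout the package
PART_NAMES = ("mvpa", "lpa", "sb", "sleep")

#: minutes in a day -- the default closure constant
DEFAULT_KAPPA = 1440.0

_GEOM_TOL = 1e-9


class CompositionError(ValueError):
    """Raised for invalid compositional input (zero/negative parts, bad kappa)."""


def _validate_positive(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise CompositionError("composition contains non-finite entries")
    if np.any(x <= 0):
        bad = np.argwhere(x <= 0).ravel().tolist()
        raise CompositionError(
            f"composition has zero or negative parts at positions {bad}; "
            "parts must be strictly positive (handle zeros upstream)"
        )


def closure(x, kappa: float = DEFAULT_KAPPA) -> np.ndarray:
    """Proportionally re-scale positive parts to sum to ``kappa``.

    Accepts a single composition (1-D) or a matrix of row compositions
    (2-D); rows are closed independently.  Scale invariant: ``closure(c*x)
    == closure(x)`` for any ``c > 0``.
    """
    if kappa <= 0 or not np.isfinite(kappa):
        raise CompositionError(f"closure constant must be positive, got {kappa}")
    arr = np.asarray(x, dtype=float)
    _validate_positive(arr)
    total = arr.sum(axis=-1, keepdims=True)
    return arr * (kappa / total)


@dataclass(frozen=True)
class TimeUseComposition:
    """A strictly positive D-part composition closed to ``kappa`` minutes."""

    parts: np.ndarray
    kappa: float = DEFAULT_KAPPA
    part_names: tuple = PART_NAMES

    def __post_init__(self):
        parts = np.asarray(self.parts, dtype=float)
        _validate_positive(parts)
        if len(self.part_names) != parts.shape[-1]:
            raise CompositionError("part_names length does not match parts")
        if abs(parts.sum() - self.kappa) > _GEOM_TOL * max(1.0, self.kappa):
            raise CompositionError(
                f"parts sum to {parts.sum():.6f}, expected kappa={self.kappa}; "
                "use TimeUseComposition.from_raw to close first"
            )
        object.__setattr__(self, "parts", parts)

    @classmethod
    def from_raw(cls, x, kappa: float = DEFAULT_KAPPA,
                 part_names: tuple = PART_NAMES) -> "TimeUseComposition":
        return cls(closure(x, kappa), kappa, part_names)

    def as_dict(self) -> dict:
        return dict(zip(self.part_names, self.parts))


@dataclass(frozen=True)
class IlrCoordinates:
    """D-1 real ilr coordinates plus the pivot-order identifier of their basis."""

    values: np.ndarray
    basis_id: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise CompositionError("ilr coordinates must be finite")
        object.__setattr__(self, "values", values)


def pivot_basis(D: int) -> np.ndarray:
    """Contrast matrix V (D x D-1) of the pivot ilr basis.

    Column i holds the clr coefficients of coordinate
    ``z_i = sqrt((D-i)/(D-i+1)) * ln(x_i / gmean(x_{i+1..D}))`` (1-based).
    Columns are orthonormal and sum to zero, so V'V = I.
    """
    if D < 2:
        raise CompositionError("need at least two parts for ilr coordinates")
    V = np.zeros((D, D - 1))
    for i in range(D - 1):
        r = D - i - 1
        c = np.sqrt(r / (r + 1.0))
        V[i, i] = c
        V[i + 1:, i] = -c / r
    return V


def _resolve_order(order, D: int, part_names=PART_NAMES):
    if order is None:
        return tuple(range(D))
    order = tuple(order)
    if all(isinstance(o, str) for o in order):
        order = tuple(part_names.index(o) for o in order)
    if sorted(order) != list(range(D)):
        raise CompositionError(f"order {order} is not a permutation of 0..{D - 1}")
    return order


def ilr_pivot(x, order=None, part_names=PART_NAMES):
    """Pivot ilr coordinates of composition(s) ``x``.

    ``order`` permutes the parts before the sequential binary partition;
    the first element becomes the first pivot.  Accepts a 1-D composition,
    a 2-D matrix of row compositions, or a :class:`TimeUseComposition`.
    Output is scale invariant in each row.
    """
    if isinstance(x, TimeUseComposition):
        part_names = x.part_names
        x = x.parts
    arr = np.asarray(x, dtype=float)
    _validate_positive(arr)
    D = arr.shape[-1]
    order = _resolve_order(order, D, part_names)
    V = pivot_basis(D)
    return np.log(arr[..., order]) @ V


def ilr_inverse(z, kappa: float = DEFAULT_KAPPA, order=None,
                part_names=PART_NAMES) -> np.ndarray:
    """Map ilr coordinates back to the unique composition with sum ``kappa``."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CompositionError("ilr coordinates must be finite")
    D = arr.shape[-1] + 1
    order = _resolve_order(order, D, part_names)
    V = pivot_basis(D)
    logx = arr @ V.T  # clr-scale log composition in permuted order
    # subtract the row max before exponentiating for overflow safety;
    # closure removes the common factor again
    x_perm = closure(np.exp(logx - logx.max(axis=-1, keepdims=True)), kappa)
    out = np.empty_like(x_perm)
    out[..., list(order)] = x_perm
    return out


def clr(x) -> np.ndarray:
    """Centred log-ratio transform (log parts minus row log geometric mean)."""
    arr = np.asarray(x, dtype=float)
    _validate_positive(arr)
    lx = np.log(arr)
    return lx - lx.mean(axis=-1, keepdims=True)


def aitchison_distance(x, y) -> float:
    """Aitchison distance: Euclidean distance between clr images."""
    return float(np.linalg.norm(clr(x) - clr(y)))


def compositional_mean(samples, kappa: float = DEFAULT_KAPPA) -> np.ndarray:
    """Per-part geometric mean of row compositions, then closure to ``kappa``.

    Equals ``ilr_inverse`` of the arithmetic mean of the samples' ilr
    coordinates; this is the centre of a compositional sample.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] == 0:
        raise CompositionError("compositional mean of an empty sample is undefined")
    _validate_positive(arr)
    return closure(np.exp(np.log(arr).mean(axis=0)), kappa)


@dataclass(frozen=True)
class SymmetricBalancePair:
    """Symmetric balance coordinates highlighting parts ``i`` and ``j``.

    ``z1`` loads +alpha on part i and beta on part j; ``z2`` swaps the
    two.  The clr coefficient vectors are zero-sum, unit-norm and
    mutually orthogonal, with alpha > 0 > beta.
    """

    alpha: float
    beta: float
    gamma: float
    i: int
    j: int
    z1: np.ndarray = field(repr=False)
    z2: np.ndarray = field(repr=False)


def symmetric_balance_coefficients(D: int):
    """Coefficients (alpha, beta, gamma) of the symmetric balance pair.

    The unique solution (up to the sign convention alpha > 0) of
    ``alpha + beta + (D-2) gamma = 0`` (zero sum),
    ``alpha^2 + beta^2 + (D-2) gamma^2 = 1`` (unit norm) and
    ``2 alpha beta + (D-2) gamma^2 = 0`` (pairwise orthogonality).
    Substituting the zero-sum identity reduces the system to a quadratic
    with discriminant exactly 1, giving the closed forms below.
    """
    if D < 3:
        raise CompositionError("symmetric balances require at least three parts")
    gamma = -1.0 / np.sqrt(D * (D - 2.0))
    s = np.sqrt((D - 2.0) / D)  # alpha + beta
    alpha = (s + 1.0) / 2.0
    beta = (s - 1.0) / 2.0
    return alpha, beta, gamma


def symmetric_balance_coords(X, i: int, j: int) -> SymmetricBalancePair:
    """Per-sample symmetric balance coordinate pair for parts ``i`` and ``j``."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    _validate_positive(arr)
    D = arr.shape[1]
    if i == j:
        raise CompositionError("symmetric balance needs two distinct parts")
    alpha, beta, gamma = symmetric_balance_coefficients(D)
    lx = np.log(arr)
    rest = lx.sum(axis=1) - lx[:, i] - lx[:, j]
    z1 = alpha * lx[:, i] + beta * lx[:, j] + gamma * rest
    z2 = beta * lx[:, i] + alpha * lx[:, j] + gamma * rest
    return SymmetricBalancePair(alpha, beta, gamma, i, j, z1, z2)


def cor_coda(X, i: int, j: int) -> float:
    """Dominance correlation of compositional parts ``i`` and ``j``.

    Pearson correlation of the two symmetric balance coordinates.
    Positive values mean the two parts rise together relative to the
    average of the remaining parts; negative values mean one dominates
    at the expense of the other.  Symmetric in (i, j) and invariant to
    per-sample rescaling.
    """
    # swapping i and j swaps z1 with z2, leaving the correlation
    # unchanged; canonicalize so the symmetry holds to the last bit
    i, j = (i, j) if i < j else (j, i)
    pair = symmetric_balance_coords(X, i, j)
    if pair.z1.shape[0] < 3:
        raise CompositionError("need at least three samples for a correlation")
    s1, s2 = pair.z1.std(), pair.z2.std()
    if s1 <= 0 or s2 <= 0:
        raise CompositionError(
            f"correlation undefined: zero variance in balance coordinates for parts ({i}, {j})"
        )
    return float(np.corrcoef(pair.z1, pair.z2)[0, 1])
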