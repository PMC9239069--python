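"""Aitchison-geometry foundations for compositional (relative-abundance) data.

A *composition* is a vector of D strictly positive parts carrying only
relative information: rescaling all parts by a common factor (closure) does
not change the object.  Analysis happens in log-ratio coordinates:

* CLR (centred log-ratio): ``v̂_i = ln v_i − mean_j ln v_j`` maps a
  composition onto the zero-sum hyperplane of R^D.
* ILR (isometric log-ratio): an orthonormal coordinate system on that
  hyperplane, defined by a contrast matrix Ψ whose D−1 rows are the CLR
  images of *balancing elements* — unit vectors encoding a log-contrast
  between a numerator group of r taxa and a denominator group of s taxa.

Both transforms are isometries, so distances, norms and inner products agree
between CLR and any ILR basis.  This module provides the typed containers
(:class:`Composition`, :class:`ClrVector`, :class:`IlrVector`,
:class:`ContrastBasis`, :class:`BalancingElement`, :class:`Balance`), the
transforms, sequential-binary-partition basis construction, and the count
pre-processing steps (prevalence filtering, multiplicative zero replacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio.stats.composition import closure as _skbio_closure

TOL = 1e-9

__all__ = [
    "Composition",
    "ClrVector",
    "IlrVector",
    "ContrastBasis",
    "BalancingElement",
    "Balance",
    "closure",
    "perturbation_between",
    "clr",
    "clr_inv",
    "ilr",
    "ilr_inv",
    "basis_from_partition",
    "pivot_basis",
    "balancing_coefficients",
    "zero_replace",
    "prevalence_filter",
]


def _as_labels(labels: Sequence[str] | None, d: int) -> tuple[str, ...]:
    if labels is None:
        return tuple(f"t{i + 1}" for i in range(d))
    labels = tuple(str(x) for x in labels)
    if len(labels) != d:
        raise ValueError(f"expected {d} labels, got {len(labels)}")
    if len(set(labels)) != d:
        raise ValueError("duplicate taxon labels")
    return labels


@dataclass(frozen=True)
class Composition:
    """A vector of D strictly positive parts, defined up to closure."""

    parts: np.ndarray
    labels: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        parts = np.asarray(self.parts, dtype=float)
        if parts.ndim != 1 or parts.size < 2:
            raise ValueError("a composition needs at least two parts")
        bad = np.flatnonzero(~(parts > 0))
        if bad.size:
            raise ValueError(f"non-positive part at index {bad[0]}")
        object.__setattr__(self, "parts", parts)
        object.__setattr__(self, "labels", _as_labels(self.labels, parts.size))

    @property
    def d(self) -> int:
        return self.parts.size

    def close(self, total: float = 1.0) -> "Composition":
        return closure(self.parts, total=total, labels=self.labels)


@dataclass(frozen=True)
class ClrVector:
    """CLR coordinates: a zero-sum vector of length D."""

    coords: np.ndarray
    labels: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 1 or coords.size < 2:
            raise ValueError("CLR vector needs at least two coordinates")
        if abs(coords.sum()) > TOL * max(1.0, np.abs(coords).max()):
            raise ValueError(
                f"CLR coordinates must sum to 0 (got {coords.sum():g})"
            )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", _as_labels(self.labels, coords.size))

    @property
    def d(self) -> int:
        return self.coords.size

    def norm(self) -> float:
        return float(np.linalg.norm(self.coords))


@dataclass(frozen=True)
class ContrastBasis:
    """An ILR contrast matrix Ψ ((D−1)×D) plus its node partitions.

    Row i is the CLR image of the balancing element of node i of a
    sequential binary partition; ``node_partitions[i]`` holds the
    (numerator, denominator) taxon-label sets of that node.
    """

    psi: np.ndarray
    node_partitions: tuple[tuple[frozenset, frozenset], ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=float)
        d = psi.shape[1]
        if psi.shape != (d - 1, d):
            raise ValueError(f"Ψ must be (D−1)×D, got {psi.shape}")
        gram = psi @ psi.T
        if not np.allclose(gram, np.eye(d - 1), atol=TOL):
            raise ValueError("Ψ rows are not orthonormal")
        if np.abs(psi.sum(axis=1)).max() > TOL:
            raise ValueError("Ψ rows must each sum to 0")
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "labels", _as_labels(self.labels, d))
        object.__setattr__(
            self,
            "node_partitions",
            tuple((frozenset(n), frozenset(dn)) for n, dn in self.node_partitions),
        )

    @property
    def d(self) -> int:
        return self.psi.shape[1]

    def elements(self) -> list["BalancingElement"]:
        return [
            BalancingElement(num, den, self.labels)
            for num, den in self.node_partitions
        ]

    def to_sign_table(self) -> pd.DataFrame:
        """Node table: +1 numerator, −1 denominator, 0 absent."""
        rows = []
        for num, den in self.node_partitions:
            rows.append([1 if t in num else (-1 if t in den else 0) for t in self.labels])
        return pd.DataFrame(
            rows,
            index=[f"b{i + 1}" for i in range(len(self.node_partitions))],
            columns=list(self.labels),
        )

    @classmethod
    def from_sign_table(cls, table: pd.DataFrame) -> "ContrastBasis":
        labels = tuple(table.columns)
        partitions = []
        for _, row in table.iterrows():
            num = frozenset(t for t in labels if row[t] > 0)
            den = frozenset(t for t in labels if row[t] < 0)
            partitions.append((num, den))
        return basis_from_partition(partitions, labels)


@dataclass(frozen=True)
class IlrVector:
    """ILR coordinates of length D−1 with respect to a contrast basis."""

    coords: np.ndarray
    basis: ContrastBasis

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (self.basis.d - 1,):
            raise ValueError(
                f"ILR vector must have length D−1={self.basis.d - 1}, got {coords.shape}"
            )
        object.__setattr__(self, "coords", coords)

    def norm(self) -> float:
        return float(np.linalg.norm(self.coords))


def balancing_coefficients(r: int, s: int) -> tuple[float, float]:
    """Closed-form CLR entries a+(r,s), a−(r,s) of a balancing element.

    ``a+ = √(rs/(r+s))/r`` on the r numerator taxa and
    ``a− = −√(rs/(r+s))/s`` on the s denominator taxa; together they give a
    zero-sum unit vector: r·a+ + s·a− = 0 and r·a+² + s·a−² = 1.
    """
    if r < 1 or s < 1:
        raise ValueError("numerator and denominator each need at least one taxon")
    root = math.sqrt(r * s / (r + s))
    return root / r, -root / s


@dataclass(frozen=True)
class BalancingElement:
    """A unit direction: log-contrast of numerator vs denominator taxa."""

    num: frozenset
    den: frozenset
    universe: tuple[str, ...]

    def __post_init__(self):
        num = frozenset(self.num)
        den = frozenset(self.den)
        universe = tuple(self.universe)
        uset = set(universe)
        if len(uset) != len(universe):
            raise ValueError("duplicate labels in universe")
        if num & den:
            raise ValueError("numerator and denominator overlap")
        if not num or not den:
            raise ValueError("numerator and denominator must be non-empty")
        if not (num | den) <= uset:
            raise ValueError("taxa outside the universe")
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)
        object.__setattr__(self, "universe", universe)

    @property
    def r(self) -> int:
        return len(self.num)

    @property
    def s(self) -> int:
        return len(self.den)

    @property
    def d(self) -> int:
        return len(self.universe)

    def clr(self) -> ClrVector:
        a_plus, a_minus = balancing_coefficients(self.r, self.s)
        coords = np.zeros(self.d)
        for i, t in enumerate(self.universe):
            if t in self.num:
                coords[i] = a_plus
            elif t in self.den:
                coords[i] = a_minus
        return ClrVector(coords, self.universe)

    def flipped(self) -> "BalancingElement":
        return BalancingElement(self.den, self.num, self.universe)

    def support(self) -> frozenset:
        return self.num | self.den

    def canonical(self) -> "BalancingElement":
        """Orientation with the lexicographically smallest supported taxon in num."""
        if min(self.num) <= min(self.den):
            return self
        return self.flipped()

    def same_direction(self, other: "BalancingElement") -> bool:
        """True if the two elements span the same axis (up to num↔den swap)."""
        return (self.num, self.den) in (
            (other.num, other.den),
            (other.den, other.num),
        )


@dataclass(frozen=True)
class Balance:
    """A balancing element scaled by a signed coefficient."""

    element: BalancingElement
    coefficient: float

    def clr(self) -> ClrVector:
        base = self.element.clr()
        return ClrVector(self.coefficient * base.coords, base.labels)

    def canonical(self) -> "Balance":
        """Positive-coefficient orientation (num↔den swap flips the sign)."""
        if self.coefficient < 0:
            return Balance(self.element.flipped(), -self.coefficient)
        if self.coefficient == 0:
            return Balance(self.element.canonical(), 0.0)
        return self


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def closure(parts, total: float = 1.0, labels: Sequence[str] | None = None) -> Composition:
    """Rescale positive parts to the given total (default 1)."""
    parts = np.asarray(parts, dtype=float)
    bad = np.flatnonzero(~(parts > 0))
    if bad.size:
        raise ValueError(f"non-positive part at index {bad[0]}")
    if total <= 0:
        raise ValueError("total must be positive")
    closed = _skbio_closure(parts) * total
    return Composition(closed, _as_labels(labels, parts.size))


def perturbation_between(sample1: Composition, sample2: Composition) -> Composition:
    """The compositional shift turning sample1 into sample2.

    Returns the closure of the component-wise ratio sample2/sample1 (the
    fold-change composition); identical samples give the uniform (zero)
    shift.
    """
    if sample1.labels != sample2.labels:
        raise ValueError("samples have mismatched labels")
    return closure(sample2.parts / sample1.parts, labels=sample1.labels)


def clr(v: Composition) -> ClrVector:
    logs = np.log(v.parts)
    return ClrVector(logs - logs.mean(), v.labels)


def clr_inv(v_hat: ClrVector) -> Composition:
    return closure(np.exp(v_hat.coords), labels=v_hat.labels)


def ilr(v_hat: ClrVector, basis: ContrastBasis) -> IlrVector:
    """v* = v̂ Ψᵀ."""
    if v_hat.d != basis.d:
        raise ValueError("dimension mismatch between CLR vector and basis")
    if v_hat.labels != basis.labels:
        raise ValueError("label mismatch between CLR vector and basis")
    return IlrVector(v_hat.coords @ basis.psi.T, basis)


def ilr_inv(v_star: IlrVector) -> ClrVector:
    """v̂ = v* Ψ."""
    return ClrVector(v_star.coords @ v_star.basis.psi, v_star.basis.labels)


def basis_from_partition(
    partitions: Iterable[tuple[Iterable, Iterable]],
    labels: Sequence[str],
) -> ContrastBasis:
    """Build Ψ from D−1 (numerator, denominator) node partitions.

    The partitions must form a sequential binary partition: jointly they must
    be pairwise tree-compatible (each pair of node supports disjoint or
    nested inside a single part) and cover a full binary tree over the
    taxa.
    """
    labels = tuple(labels)
    d = len(labels)
    parts = [(frozenset(n), frozenset(dn)) for n, dn in partitions]
    if len(parts) != d - 1:
        raise ValueError(f"need D−1={d - 1} node partitions, got {len(parts)}")
    rows = []
    for num, den in parts:
        rows.append(BalancingElement(num, den, labels).clr().coords)
    psi = np.vstack(rows)
    if not np.allclose(psi @ psi.T, np.eye(d - 1), atol=TOL):
        raise ValueError("partitions do not form a valid sequential binary partition")
    return ContrastBasis(psi, tuple(parts), labels)


def pivot_basis(labels: Sequence[str]) -> ContrastBasis:
    """Default pivot-style sequential binary partition over the label order.

    Node i contrasts taxon i against taxa i+1..D.  Any valid basis works for
    back-transformed results, so this serves as the default when none is
    supplied.
    """
    labels = tuple(labels)
    d = len(labels)
    partitions = [
        (frozenset([labels[i]]), frozenset(labels[i + 1:])) for i in range(d - 1)
    ]
    return basis_from_partition(partitions, labels)


# ---------------------------------------------------------------------------
# count pre-processing
# ---------------------------------------------------------------------------

def zero_replace(counts: pd.DataFrame, delta_fraction: float = 0.65) -> pd.DataFrame:
    """Deterministic multiplicative zero replacement, per sample (column).

    Each zero in a sample becomes ``delta_fraction`` times that sample's
    detection limit — 1/total for count data, the smallest positive
    proportion for an already-normalised table; the nonzero proportions are
    rescaled by ``1 − (replaced mass)`` so the sample still closes to 1.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    is_counts = np.allclose(mat, np.round(mat)) and mat.max() > 1
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        total = col.sum()
        if total <= 0:
            raise ValueError(f"sample {counts.columns[j]!r} has no positive counts")
        props = col / total
        zeros = props == 0
        if not zeros.any():
            out[:, j] = props
            continue
        limit = 1.0 / total if is_counts else props[~zeros].min()
        delta = delta_fraction * limit
        replaced = delta * zeros.sum()
        out[:, j] = np.where(zeros, delta, props * (1.0 - replaced))
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def prevalence_filter(
    counts: pd.DataFrame, min_reads: int = 2, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Keep taxa (rows) with ≥ min_reads in at least min_fraction of samples."""
    present = (counts.to_numpy() >= min_reads).mean(axis=1)
    keep = present >= min_fraction
    if not keep.any():
        raise ValueError(
            "prevalence filter removed every taxon; lower min_reads or min_fraction"
        )
    return counts.loc[keep]
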