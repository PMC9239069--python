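"""Nearest balance tree: a full ILR basis greedily fitted to one shift.

The first element is the nearest balance to the shift; each subsequent
element is the nearest to the shift among all balancing elements that can
share one binary tree with (and are therefore orthogonal to) everything
chosen so far.  After D−1 steps the elements form a complete sequential
binary partition, the projections of the shift on them reconstruct it
exactly, and the per-element impacts (squared projection / squared shift
norm) sum to one.

Tree compatibility is handled by *regions*: at any point the taxa form a
laminar family of groups (the numerators, denominators and supports of the
chosen elements).  A new element must live inside some open region — the
whole universe, or the numerator/denominator part of a chosen element — and
within that region it may only combine indivisible *units*: the maximal
chosen supports properly contained in the region plus the still-free taxa.
Replacing each unit by its summed CLR value with an integer weight reduces
the fixed-(r, s) search to choosing, per distinct weight, how many units go
to the numerator (taken greedily from the top when sorted by value) and how
many to the denominator (from the bottom); enumerating the weight
combinations that sum to each feasible (r, s) gives the exact optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .compo import Balance, BalancingElement, ClrVector, ContrastBasis, basis_from_partition
from .nearest import MIN_SHIFT_NORM, TIE_TOL, _element_key

__all__ = ["Unit", "BalanceTree", "nearest_balance_tree", "weight_partitions", "to_newick"]

DEFAULT_MAX_D = 30


@dataclass(frozen=True)
class Unit:
    """An indivisible block of taxa inside a region."""

    taxa: frozenset
    total: float  # sum of the shift's CLR values over the block

    @property
    def weight(self) -> int:
        return len(self.taxa)

    @property
    def mean(self) -> float:
        return self.total / self.weight


def _weight_classes(units: Sequence[Unit]):
    """Group units by weight; each class sorted by total descending (label asc)."""
    classes: dict[int, list[Unit]] = {}
    for u in units:
        classes.setdefault(u.weight, []).append(u)
    out = []
    for w in sorted(classes):
        out.append((w, sorted(classes[w], key=lambda u: (-u.total, min(u.taxa)))))
    return out


def _count_assignments(classes) -> Iterator[tuple[tuple[int, int], ...]]:
    """All per-class (numerator count, denominator count) assignments."""

    def rec(i, acc):
        if i == len(classes):
            yield tuple(acc)
            return
        _, members = classes[i]
        c = len(members)
        for a in range(c + 1):
            for b in range(c - a + 1):
                acc.append((a, b))
                yield from rec(i + 1, acc)
                acc.pop()

    yield from rec(0, [])


def _scan_units(units: Sequence[Unit]) -> Iterator[tuple[float, tuple, tuple]]:
    """Yield (inner product, num units, den units) for every count assignment.

    For fixed counts the optimum takes the top units per class for the
    numerator and the bottom ones for the denominator; flipped optima are
    covered by the swapped count assignment, so taking |inner| at selection
    covers every element realisable from the units.
    """
    classes = _weight_classes(units)
    for counts in _count_assignments(classes):
        r = s = 0
        num_sum = den_sum = 0.0
        num_units: list[Unit] = []
        den_units: list[Unit] = []
        for (w, members), (a, b) in zip(classes, counts):
            r += a * w
            s += b * w
            for u in members[:a]:
                num_sum += u.total
                num_units.append(u)
            if b:
                for u in members[len(members) - b:]:
                    den_sum += u.total
                    den_units.append(u)
        if r < 1 or s < 1:
            continue
        inner = math.sqrt(r * s / (r + s)) * (num_sum / r - den_sum / s)
        yield inner, tuple(num_units), tuple(den_units)


def weight_partitions(units: Sequence[Unit], r: int) -> Iterator[tuple[Unit, ...]]:
    """Candidate unit subsets of total weight exactly r.

    One candidate per feasible multiset of weights; within each weight class
    the units are taken greedily by descending mean (so the yielded subset
    maximises the weighted mean sum for its multiset).  Yields nothing when
    no combination of weights sums to r.
    """
    classes = _weight_classes(units)
    weights = [w for w, _ in classes]
    counts = [len(m) for _, m in classes]

    def rec(i, remaining, acc):
        if remaining == 0:
            subset = []
            for (w, members), a in zip(classes, acc):
                subset.extend(members[:a])
            # pad acc to full length implicitly: remaining classes take 0
            yield tuple(subset)
            return
        if i == len(classes):
            return
        max_a = min(counts[i], remaining // weights[i])
        for a in range(max_a + 1):
            yield from rec(i + 1, remaining - a * weights[i], acc + [a])

    seen_any = False
    for subset in rec(0, r, []):
        seen_any = True
        yield subset
    if not seen_any:
        return


@dataclass(frozen=True)
class BalanceTree:
    """D−1 mutually orthogonal balancing elements greedily fitted to a shift."""

    elements: tuple[BalancingElement, ...]
    coefficients: np.ndarray
    impacts: np.ndarray
    shift: ClrVector
    tied: bool
    block_history: tuple[tuple[frozenset, ...], ...]

    @property
    def d(self) -> int:
        return self.shift.d

    def balances(self) -> list[Balance]:
        return [Balance(e, c) for e, c in zip(self.elements, self.coefficients)]

    def basis(self) -> ContrastBasis:
        return basis_from_partition(
            [(e.num, e.den) for e in self.elements], self.shift.labels
        )

    def to_dict(self) -> dict:
        return {
            "balances": [
                {
                    "numerator": sorted(e.num),
                    "denominator": sorted(e.den),
                    "coefficient": float(c),
                    "impact": float(i),
                }
                for e, c, i in zip(self.elements, self.coefficients, self.impacts)
            ],
            "tied": self.tied,
        }


def _regions(universe: frozenset, chosen: Sequence[BalancingElement]):
    """Open regions and their units given the chosen elements."""
    supports = [e.support() for e in chosen]
    region_sets = [universe] + [e.num for e in chosen] + [e.den for e in chosen]
    out = []
    for region in region_sets:
        if len(region) < 2 or any(s == region for s in supports):
            continue
        inside = [s for s in supports if s < region]
        maximal = [
            s for s in inside if not any(s < t for t in inside if t is not s)
        ]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        units = [frozenset([t]) for t in region - covered] + maximal
        out.append((region, units))
    return out


def nearest_balance_tree(shift: ClrVector, max_d: int = DEFAULT_MAX_D) -> BalanceTree:
    """Greedy construction of the nearest balance tree for a CLR shift."""
    d = shift.d
    if d > max_d:
        raise ValueError(
            f"balance-tree search is combinatorial; D={d} exceeds the cap "
            f"max_d={max_d} (raise max_d to override)"
        )
    norm = shift.norm()
    if norm < MIN_SHIFT_NORM:
        raise ValueError("zero-norm shift: no direction to approximate")
    vmap = dict(zip(shift.labels, shift.coords))
    universe = frozenset(shift.labels)

    chosen: list[BalancingElement] = []
    coefs: list[float] = []
    history: list[tuple[frozenset, ...]] = []
    any_tie = False
    for _ in range(d - 1):
        candidates = []  # (inner, num taxa, den taxa, region units)
        for region, unit_sets in _regions(universe, chosen):
            units = [Unit(u, sum(vmap[t] for t in u)) for u in unit_sets]
            for inner, num_units, den_units in _scan_units(units):
                num = frozenset().union(*(u.taxa for u in num_units))
                den = frozenset().union(*(u.taxa for u in den_units))
                candidates.append((inner, num, den, tuple(unit_sets)))
        best_abs = max(abs(c[0]) for c in candidates)
        tied = [c for c in candidates if abs(c[0]) >= best_abs - TIE_TOL]
        tied.sort(key=lambda c: _element_key(c[1], c[2]))
        inner, num, den, units_used = tied[0]
        if best_abs > 1e-10:
            axes = {(n, dn) if (min(n) <= min(dn)) else (dn, n) for _, n, dn, _ in tied}
            if len(axes) > 1:
                any_tie = True
        element = BalancingElement(num, den, shift.labels)
        coef = float(shift.coords @ element.clr().coords)
        if coef < 0:
            element = element.flipped()
            coef = -coef
        chosen.append(element)
        coefs.append(coef)
        history.append(units_used)

    coefs_arr = np.asarray(coefs)
    impacts = coefs_arr**2 / norm**2
    return BalanceTree(
        elements=tuple(chosen),
        coefficients=coefs_arr,
        impacts=impacts,
        shift=shift,
        tied=any_tie,
        block_history=tuple(history),
    )


def to_newick(tree: BalanceTree, with_impacts: bool = False) -> str:
    """Render the balance tree as a binary newick string.

    Leaves are taxon labels; each internal node is labelled ``b<k>`` with k
    the discovery index of its balance (optionally suffixed with the
    impact).
    """
    universe = frozenset(tree.shift.labels)
    by_support = {e.support(): i for i, e in enumerate(tree.elements)}
    if universe not in by_support:
        raise ValueError("incomplete tree: no root element spans all taxa")

    def render(group: frozenset) -> str:
        if len(group) == 1:
            return next(iter(group))
        i = by_support.get(group)
        if i is None:
            raise ValueError("incomplete tree: unsplit internal group")
        e = tree.elements[i]
        label = f"b{i + 1}"
        if with_impacts:
            label += f"|{tree.impacts[i]:.4g}"
        return f"({render(e.num)},{render(e.den)}){label}"

    return render(universe) + ";"
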