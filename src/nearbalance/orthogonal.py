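"""Second orthogonal balance: the best element sharing a tree with a first one.

Two balancing elements can appear as nodes of one sequential binary
partition only if one of three relations holds between their supports
(numerator ∪ denominator):

* **case A** — the second element lives entirely inside the first's
  numerator or denominator;
* **case B** — the first element's whole support sits inside one side of
  the second (the second node is an ancestor);
* **case C** — the supports are disjoint.

Any such pair is orthogonal in CLR.  Given a first element and a target CLR
vector w, :func:`second_balance` maximises ⟨ŵ, ê₂⟩ over the five resulting
candidate searches (A within num, A within den, C outside, B with the first
element's block forced into the numerator or the denominator), each solved
by the same sorted-scan trick as the nearest-balance search.
"""

from __future__ import annotations

import math

import numpy as np

from .compo import BalancingElement, ClrVector
from .nearest import (
    MIN_SHIFT_NORM,
    TIE_TOL,
    NearestBalanceResult,
    _element_key,
    _result_from_element,
)

__all__ = ["second_balance", "case_b_search", "compatible_with"]


def _sorted_by_value(labels, values):
    """Labels ordered by value descending, label ascending (stable)."""
    idx = np.lexsort((np.asarray(labels), -np.asarray(values)))
    return [labels[i] for i in idx], np.asarray(values)[idx]


def _scan_support(labels, values):
    """Yield (inner, num, den) for the best element at each (r, s) within a support."""
    if len(labels) < 2:
        return
    slab, sval = _sorted_by_value(labels, values)
    d = len(slab)
    prefix = np.concatenate(([0.0], np.cumsum(sval)))
    for total in range(2, d + 1):
        for r in range(1, total):
            s = total - r
            inner = math.sqrt(r * s / (r + s)) * (
                prefix[r] / r - (prefix[d] - prefix[d - s]) / s
            )
            yield inner, tuple(slab[:r]), tuple(slab[d - s:])


def case_b_search(first: BalancingElement, w: ClrVector, side: str):
    """Best ancestor element with the first element's support forced into one side.

    Orders the taxa outside the first element by their ŵ component
    (descending), keeps the first element's taxa together as a block at the
    start (side="num") or end (side="den") of the list, and scans the valid
    (r, s) range.  Returns a list of (inner, num, den) candidates, empty
    when no taxon lies outside the first element.
    """
    if side not in ("num", "den"):
        raise ValueError("side must be 'num' or 'den'")
    wmap = dict(zip(w.labels, w.coords))
    block = sorted(first.support())
    others = [t for t in w.labels if t not in first.support()]
    if not others:
        return []
    olab, oval = _sorted_by_value(others, [wmap[t] for t in others])
    block_sum = sum(wmap[t] for t in block)
    b = len(block)
    m = len(olab)
    prefix = np.concatenate(([0.0], np.cumsum(oval)))
    out = []
    for k in range(0, m):  # extras joining the block's side
        for s in range(1, m - k + 1):  # taxa on the opposite side
            if side == "num":
                # num = block + k best others, den = s worst others
                r = b + k
                num_sum = block_sum + prefix[k]
                den_sum = prefix[m] - prefix[m - s]
                inner = math.sqrt(r * s / (r + s)) * (num_sum / r - den_sum / s)
                num = tuple(block) + tuple(olab[:k])
                den = tuple(olab[m - s:])
            else:
                # den = block + k worst others, num = s best others
                r_den = b + k
                den_sum = block_sum + (prefix[m] - prefix[m - k])
                num_sum = prefix[s]
                inner = math.sqrt(s * r_den / (s + r_den)) * (
                    num_sum / s - den_sum / r_den
                )
                num = tuple(olab[:s])
                den = tuple(block) + tuple(olab[m - k:])
            out.append((inner, num, den))
    return out


def compatible_with(first: BalancingElement, other: BalancingElement) -> bool:
    """True if the two elements can be nodes of one binary tree (cases A/B/C)."""
    s1, s2 = first.support(), other.support()
    return (
        not (s1 & s2)
        or s2 <= first.num
        or s2 <= first.den
        or s1 <= other.num
        or s1 <= other.den
    )


def second_balance(first: BalancingElement, w: ClrVector) -> NearestBalanceResult:
    """Nearest element to ŵ among those tree-compatible with (hence orthogonal
    to) a given first element.

    The winner maximises |⟨ŵ, ê₂⟩| over the case A/B/C candidates; ties
    break toward smaller support, then smaller numerator, then lexicographic
    taxon sets.  When ŵ is orthogonal to every candidate (e.g. w = ê₁), the
    tie-break winner is returned with coefficient 0.
    """
    if first.d < 3:
        raise ValueError("no second balance exists for D < 3")
    if w.labels != first.universe:
        raise ValueError("w and the first element use different taxon universes")
    if w.norm() < MIN_SHIFT_NORM:
        raise ValueError("zero-norm vector: no direction to approximate")
    wmap = dict(zip(w.labels, w.coords))
    outside = [t for t in w.labels if t not in first.support()]

    candidates = []  # (inner, num, den, case)
    for name, group in (("A-num", sorted(first.num)), ("A-den", sorted(first.den))):
        for inner, num, den in _scan_support(group, [wmap[t] for t in group]):
            candidates.append((inner, num, den, name))
    for inner, num, den in _scan_support(outside, [wmap[t] for t in outside]):
        candidates.append((inner, num, den, "C"))
    for side in ("num", "den"):
        for inner, num, den in case_b_search(first, w, side):
            candidates.append((inner, num, den, f"B-{side}"))

    if not candidates:
        raise ValueError("no tree-compatible second element exists")

    best_inner = max(abs(c[0]) for c in candidates)
    tied = [c for c in candidates if abs(c[0]) >= best_inner - TIE_TOL]
    tied.sort(key=lambda c: _element_key(c[1], c[2]))
    inner, num, den, case = tied[0]
    ties = [
        (frozenset(n), frozenset(d))
        for _, n, d, _ in tied[1:]
        if not (frozenset(n) == frozenset(num) and frozenset(d) == frozenset(den))
        and not (frozenset(n) == frozenset(den) and frozenset(d) == frozenset(num))
    ]
    return _result_from_element(w, num, den, ties=tuple(ties), case=case)
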