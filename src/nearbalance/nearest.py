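"""Nearest-balance search: the best single-balance approximation of a shift.

Given a composition shift in CLR coordinates, find the balancing element
with maximal cosine to it.  Because a balancing element is constant on its
numerator and denominator groups, the best element at fixed group sizes
(r, s) takes the r largest and the s smallest CLR components; a scan over
all (r, s) with r+s ≤ D then yields the global optimum in O(D log D + D²)
instead of a search over all ~3^D/2 elements.  The projection of the shift
onto the winning element is the *nearest balance*; its squared share of the
shift's squared norm is the *impact*.

:func:`brute_force_nearest` enumerates every element outright and serves as
the independent oracle for small D.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compo import Balance, BalancingElement, ClrVector

MIN_SHIFT_NORM = 1e-12
TIE_TOL = 1e-12

__all__ = [
    "NearestBalanceResult",
    "nearest_balance",
    "cosine_for_sizes",
    "brute_force_nearest",
]


@dataclass(frozen=True)
class NearestBalanceResult:
    """Outcome of a nearest-balance search.

    ``cosine`` is the achieved maximum (≥ 0 by the sign convention that the
    numerator holds the increasing taxa); ``impact`` = cosine²;
    ``distance`` is the residual ‖b* − v*‖, so distance² + ‖b*‖² = ‖v*‖².
    """

    balance: Balance
    cosine: float
    distance: float
    impact: float
    ties: tuple = ()
    candidate_table: pd.DataFrame | None = None
    case: str | None = None

    @property
    def tied(self) -> bool:
        return len(self.ties) > 0

    def to_dict(self) -> dict:
        el = self.balance.element
        out = {
            "numerator": sorted(el.num),
            "denominator": sorted(el.den),
            "coefficient": self.balance.coefficient,
            "cosine": self.cosine,
            "impact": self.impact,
            "distance": self.distance,
            "ties": [
                {"numerator": sorted(n), "denominator": sorted(d)} for n, d in self.ties
            ],
        }
        if self.case is not None:
            out["case"] = self.case
        return out


def _element_key(num, den):
    """Deterministic tie-break key: parsimony first, then lexicographic sets."""
    return (len(num) + len(den), len(num), tuple(sorted(num)), tuple(sorted(den)))


def _result_from_element(
    shift: ClrVector,
    num,
    den,
    ties=(),
    candidate_table=None,
    case=None,
) -> NearestBalanceResult:
    element = BalancingElement(
        frozenset(map(str, num)), frozenset(map(str, den)), shift.labels
    )
    e = element.clr().coords
    coef = float(shift.coords @ e)
    if coef < 0:
        element = element.flipped()
        e = -e
        coef = -coef
    norm = shift.norm()
    cosine = min(coef / norm, 1.0)
    distance = float(np.linalg.norm(shift.coords - coef * e))
    return NearestBalanceResult(
        balance=Balance(element, coef),
        cosine=cosine,
        distance=distance,
        impact=cosine**2,
        ties=tuple(ties),
        candidate_table=candidate_table,
        case=case,
    )


def cosine_for_sizes(sorted_coords: np.ndarray, r: int, s: int) -> float:
    """Best achievable cosine at group sizes (r, s) for descending CLR coords.

    Equals √(rs/(r+s))·[(mean of top r) − (mean of bottom s)]/‖v̂‖.
    """
    v = np.asarray(sorted_coords, dtype=float)
    d = v.size
    if r < 1 or s < 1 or r + s > d:
        raise ValueError(f"invalid group sizes r={r}, s={s} for D={d}")
    norm = float(np.linalg.norm(v))
    if norm < MIN_SHIFT_NORM:
        raise ValueError("zero-norm vector has no direction to approximate")
    root = math.sqrt(r * s / (r + s))
    return root * (v[:r].mean() - v[d - s:].mean()) / norm


def nearest_balance(
    shift: ClrVector, keep_candidate_table: bool = False
) -> NearestBalanceResult:
    """Find the balancing element with maximal cosine to a CLR shift.

    Sorts the CLR components descending (stable on value, then label) and
    scans all (r, s); ties within ``TIE_TOL`` of the maximum are broken
    toward smaller r+s, then smaller r, then lexicographic taxon sets, and
    reported in ``ties``.
    """
    v = shift.coords
    d = v.size
    norm = shift.norm()
    if norm < MIN_SHIFT_NORM:
        raise ValueError("zero-norm shift: no direction to approximate")
    labels = np.asarray(shift.labels)
    order = np.lexsort((labels, -v))  # value descending, label ascending
    sv = v[order]
    prefix = np.concatenate(([0.0], np.cumsum(sv)))

    # all (r, s) pairs, listed in (r+s, r) order so ties break toward parsimony
    totals = np.repeat(np.arange(2, d + 1), np.arange(1, d))
    rr = np.concatenate([np.arange(1, t) for t in range(2, d + 1)])
    ss = totals - rr
    cos_all = (
        np.sqrt(rr * ss / (rr + ss))
        * (prefix[rr] / rr - (prefix[d] - prefix[d - ss]) / ss)
        / norm
    )
    best_cos = cos_all.max()
    tied_idx = np.flatnonzero(cos_all >= best_cos - TIE_TOL)
    r, s = int(rr[tied_idx[0]]), int(ss[tied_idx[0]])

    num = labels[order[:r]]
    den = labels[order[d - s:]]
    ties = []
    for k in tied_idx[1:]:
        tr, ts = int(rr[k]), int(ss[k])
        ties.append(
            (
                frozenset(map(str, labels[order[:tr]])),
                frozenset(map(str, labels[order[d - ts:]])),
            )
        )
    # equal CLR values straddling a cut make group membership non-unique
    if (r < d and abs(sv[r - 1] - sv[r]) <= TIE_TOL) or (
        s < d and abs(sv[d - s] - sv[d - s - 1]) <= TIE_TOL
    ):
        warnings.warn(
            "tied CLR components straddle a group boundary; balance membership "
            "is not unique",
            stacklevel=2,
        )
        ties.append((frozenset(map(str, num)), frozenset(map(str, den))))
    table = (
        pd.DataFrame({"r": rr, "s": ss, "cosine": cos_all})
        if keep_candidate_table
        else None
    )
    return _result_from_element(shift, num, den, ties=ties, candidate_table=table)


def enumerate_elements(labels, max_d: int = 12):
    """Yield every balancing element over the labels, one per sign pair."""
    labels = tuple(labels)
    d = len(labels)
    if d > max_d:
        raise ValueError(
            f"exhaustive enumeration guarded at D≤{max_d} (got D={d}); "
            "use nearest_balance for larger problems"
        )
    for assign in itertools.product((1, -1, 0), repeat=d):
        if 1 not in assign or -1 not in assign:
            continue
        if assign > tuple(-a for a in assign):  # deduplicate sign-symmetric pair
            continue
        num = frozenset(l for l, a in zip(labels, assign) if a == 1)
        den = frozenset(l for l, a in zip(labels, assign) if a == -1)
        yield BalancingElement(num, den, labels)


@functools.lru_cache(maxsize=8)
def _element_matrix(labels: tuple):
    """All balancing elements over the labels plus their stacked CLR vectors."""
    elements = list(enumerate_elements(labels))
    matrix = np.vstack([el.clr().coords for el in elements])
    return elements, matrix


def brute_force_nearest(shift: ClrVector, max_d: int = 12) -> NearestBalanceResult:
    """Exhaustive oracle: global cosine maximiser over all balancing elements."""
    norm = shift.norm()
    if norm < MIN_SHIFT_NORM:
        raise ValueError("zero-norm shift: no direction to approximate")
    if shift.d > max_d:
        raise ValueError(
            f"exhaustive enumeration guarded at D≤{max_d} (got D={shift.d}); "
            "use nearest_balance for larger problems"
        )
    elements, matrix = _element_matrix(tuple(shift.labels))
    cos = np.abs(matrix @ shift.coords) / norm
    best_cos = cos.max()
    tied_idx = np.flatnonzero(cos >= best_cos - TIE_TOL)
    ranked = sorted(
        tied_idx, key=lambda i: _element_key(elements[i].num, elements[i].den)
    )
    best = elements[ranked[0]]
    ties = [(elements[i].num, elements[i].den) for i in ranked[1:]]
    return _result_from_element(shift, best.num, best.den, ties=ties)
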