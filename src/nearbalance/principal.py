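"""Principal balance analysis via nearest balances.

Principal components of ILR-transformed data are directions of maximal
variance but are hard to read in terms of taxa.  Approximating PC1 by its
nearest balancing element, and PC2 by the best element tree-compatible with
(hence orthogonal to) the first, yields two interpretable log-contrasts
whose explained variance can be compared with the PCs themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compo import Balance, BalancingElement, ClrVector, ContrastBasis
from .nearest import nearest_balance
from .orthogonal import second_balance
from .tree import BalanceTree, nearest_balance_tree

__all__ = ["pca_in_ilr", "principal_balances", "principal_balance_tree", "PrincipalBalancesResult"]


def pca_in_ilr(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA of an N × (D−1) ILR data matrix.

    Returns (directions, variances): unit-norm component directions as rows,
    ordered by non-increasing variance.  The sign of each direction is fixed
    by making its largest-magnitude loading positive so downstream balance
    numerators are reproducible.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    Xc = X - X.mean(axis=0)
    total = float((Xc**2).sum()) / (n - 1)
    if total < 1e-14:
        raise ValueError("constant data: no variance to decompose")
    cov = Xc.T @ Xc / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    dirs = vecs[:, order].T
    for i in range(dirs.shape[0]):
        j = np.argmax(np.abs(dirs[i]))
        if dirs[i, j] < 0:
            dirs[i] = -dirs[i]
    return dirs, vals


@dataclass(frozen=True)
class PrincipalBalancesResult:
    """Two orthogonal balances approximating the first two PCs."""

    b1: Balance
    b2: Balance
    explained: tuple[float, float]  # variance share of each balance
    pc_variance_shares: tuple[float, float]
    case_b2: str | None

    def to_dict(self) -> dict:
        def bal(b, share):
            return {
                "numerator": sorted(b.element.num),
                "denominator": sorted(b.element.den),
                "explained": float(share),
            }

        return {
            "b1": bal(self.b1, self.explained[0]),
            "b2": bal(self.b2, self.explained[1]),
            "explained_sum": float(sum(self.explained)),
            "pc_variance_shares": [float(v) for v in self.pc_variance_shares],
        }


def _explained_share(data: np.ndarray, element: BalancingElement, basis: ContrastBasis) -> float:
    e_ilr = element.clr().coords @ basis.psi.T
    e_ilr = e_ilr / np.linalg.norm(e_ilr)
    X = np.atleast_2d(np.asarray(data, float))
    Xc = X - X.mean(axis=0)
    proj = Xc @ e_ilr
    return float((proj**2).sum() / (Xc**2).sum())


def principal_balances(data: np.ndarray, basis: ContrastBasis) -> PrincipalBalancesResult:
    """Nearest balance to PC1 and best orthogonal balance for PC2.

    ``data`` holds ILR coordinates in the given basis.  The explained share
    of a balance is the variance of the data projected on its element over
    the total variance; by the Rayleigh bound it cannot exceed the matching
    PC's share.
    """
    if basis.d < 3:
        raise ValueError("principal balances need at least 3 taxa")
    dirs, vals = pca_in_ilr(data)
    total = vals.sum()
    pc1_clr = ClrVector(dirs[0] @ basis.psi, basis.labels)
    nb1 = nearest_balance(pc1_clr)
    pc2_clr = ClrVector(dirs[1] @ basis.psi, basis.labels)
    nb2 = second_balance(nb1.balance.element, pc2_clr)
    return PrincipalBalancesResult(
        b1=nb1.balance,
        b2=nb2.balance,
        explained=(
            _explained_share(data, nb1.balance.element, basis),
            _explained_share(data, nb2.balance.element, basis),
        ),
        pc_variance_shares=(float(vals[0] / total), float(vals[1] / total)),
        case_b2=nb2.case,
    )


def principal_balance_tree(data: np.ndarray, basis: ContrastBasis, max_d: int = 30) -> BalanceTree:
    """Variant: full nearest-balance tree fitted to the PC1 direction."""
    dirs, _ = pca_in_ilr(data)
    pc1_clr = ClrVector(dirs[0] @ basis.psi, basis.labels)
    return nearest_balance_tree(pc1_clr, max_d=max_d)
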