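"""Single-balance multivariate linear regression in ILR coordinates.

The ordinary model regresses the ILR coordinates of a composition on a
scalar predictor x and covariates z (including an implicit intercept):

    y*_i ~ N(x_i v* + A z_i, σ² I)

The single-balance variant constrains the predictor coefficient to be a
balance vector b* — a unit change of the predictor then moves the
composition along a single log-contrast between two taxon groups.  The
least-squares solution factorises: fit the unconstrained OLS, replace the
predictor coefficient v*_ls by its nearest balance β_ls, and refit the
covariate coefficients as A_ls = (Y − x β_lsᵀ) projected onto the covariate
space.  This module provides that fit both as plain functions
(:func:`fit_ols`, :func:`fit_single_balance`, :func:`r_squared`,
:func:`balance_impact`, :func:`orthogonal_complement_test`,
:func:`classify_by_balance`) and as a statsmodels-style model
(:class:`SingleBalanceRegression` → :class:`SingleBalanceResults`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .compo import (
    Balance,
    ClrVector,
    Composition,
    ContrastBasis,
    clr,
    closure,
    ilr,
    pivot_basis,
)
from .nearest import nearest_balance

__all__ = [
    "RegressionDesign",
    "OlsFit",
    "SingleBalanceFit",
    "fit_ols",
    "fit_single_balance",
    "r_squared",
    "balance_impact",
    "orthogonal_complement_test",
    "classify_by_balance",
    "SingleBalanceRegression",
    "SingleBalanceResults",
]

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class RegressionDesign:
    """Samples × ILR-coordinates response with predictor and covariates.

    ``Z`` always carries the intercept as its first column; use
    :meth:`build` to assemble a design from user-supplied covariates
    (without the intercept).
    """

    Y: np.ndarray  # N × (D−1)
    x: np.ndarray  # N
    Z: np.ndarray  # N × (K+1), first column constant 1
    basis: ContrastBasis
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self):
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        x = np.asarray(self.x, dtype=float).ravel()
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        n = Y.shape[0]
        if x.size != n or Z.shape[0] != n:
            raise ValueError("Y, x and Z must have one row per sample")
        if Y.shape[1] != self.basis.d - 1:
            raise ValueError("Y must have D−1 ILR coordinates per sample")
        if Z.shape[1] and not np.allclose(Z[:, 0], 1.0):
            raise ValueError("first column of Z must be the constant intercept")
        if n <= Z.shape[1]:
            raise ValueError("need more samples than covariates")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "Z", Z)
        names = tuple(self.covariate_names) or tuple(
            f"z{k}" for k in range(1, Z.shape[1])
        )
        object.__setattr__(self, "covariate_names", names)
        self._check_rank()

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def design_matrix(self) -> np.ndarray:
        return np.column_stack([self.x, self.Z])

    @property
    def column_names(self) -> tuple[str, ...]:
        head = ("x", "intercept") if self.Z.shape[1] else ("x",)
        return (*head, *self.covariate_names)

    def _check_rank(self):
        X = self.design_matrix
        if np.linalg.matrix_rank(X, tol=_RANK_TOL) < X.shape[1]:
            bad = []
            for j in range(X.shape[1]):
                others = np.delete(X, j, axis=1)
                resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
                if np.linalg.norm(resid) < _RANK_TOL * max(1, np.linalg.norm(X[:, j])):
                    bad.append(self.column_names[j])
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    @classmethod
    def build(
        cls,
        Y: np.ndarray,
        x: np.ndarray,
        basis: ContrastBasis,
        covariates: np.ndarray | None = None,
        covariate_names: Sequence[str] = (),
        include_intercept: bool = True,
    ) -> "RegressionDesign":
        """Assemble a design; the intercept is implicit unless disabled.

        Disable it only for the pure mean-shift model (x ≡ 1, no
        covariates), where the predictor itself plays the constant role.
        """
        n = np.asarray(x).size
        Z = np.ones((n, 1)) if include_intercept else np.empty((n, 0))
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != n:
                cov = cov.T
            Z = np.column_stack([Z, cov])
        return cls(Y, x, Z, basis, tuple(covariate_names))


@dataclass(frozen=True)
class OlsFit:
    """Unconstrained least squares: predictor coefficient and covariate matrix."""

    v_star: np.ndarray  # (D−1,) ILR coefficient of the predictor
    covariate_coefficients: np.ndarray  # (K+1) × (D−1)
    sigma2: float
    rss: float


@dataclass(frozen=True)
class SingleBalanceFit:
    """Least-squares single-balance fit (balance + refitted covariates)."""

    balance: Balance
    element_ilr: np.ndarray  # unit direction of the element in the design basis
    beta_ilr: np.ndarray  # balance vector β_ls in ILR coordinates
    covariate_coefficients: np.ndarray  # (K+1) × (D−1)
    sigma2: float
    rss: float
    r_squared: float
    impact: float
    ties: tuple
    ols: OlsFit
    basis: ContrastBasis

    @property
    def tied(self) -> bool:
        return len(self.ties) > 0


def fit_ols(design: RegressionDesign) -> OlsFit:
    """Ordinary multivariate least squares of Y on [x, intercept, covariates]."""
    X = design.design_matrix
    B, *_ = np.linalg.lstsq(X, design.Y, rcond=None)
    resid = design.Y - X @ B
    rss = float((resid**2).sum())
    dof = (design.n - X.shape[1]) * design.Y.shape[1]
    return OlsFit(
        v_star=B[0],
        covariate_coefficients=B[1:],
        sigma2=rss / dof,
        rss=rss,
    )


def _train_r_squared(design: RegressionDesign, rss: float) -> float:
    centred = design.Y - design.Y.mean(axis=0)
    total = float((centred**2).sum())
    if total <= 0:
        raise ValueError("zero total variance in responses")
    return 1.0 - rss / total


def fit_single_balance(design: RegressionDesign) -> SingleBalanceFit:
    """Constrain the predictor coefficient to its nearest balance and refit.

    Implements the least-squares factorisation: β_ls is the nearest balance
    to the OLS coefficient v*_ls and the covariate matrix is re-estimated
    from the residual Y − x β_lsᵀ.
    """
    ols = fit_ols(design)
    basis = design.basis
    if np.linalg.norm(ols.v_star) < 1e-12:
        raise ValueError("no predictor-associated shift: OLS coefficient is zero")
    clr_coef = ClrVector(ols.v_star @ basis.psi, basis.labels)
    nb = nearest_balance(clr_coef)
    element_ilr = nb.balance.element.clr().coords @ basis.psi.T
    beta_ilr = nb.balance.coefficient * element_ilr
    resid = design.Y - np.outer(design.x, beta_ilr)
    A, *_ = np.linalg.lstsq(design.Z, resid, rcond=None)
    final_resid = resid - design.Z @ A
    rss = float((final_resid**2).sum())
    dof = (design.n - design.design_matrix.shape[1]) * design.Y.shape[1]
    return SingleBalanceFit(
        balance=nb.balance,
        element_ilr=element_ilr,
        beta_ilr=beta_ilr,
        covariate_coefficients=A,
        sigma2=rss / dof,
        rss=rss,
        r_squared=_train_r_squared(design, rss),
        impact=nb.impact,
        ties=nb.ties,
        ols=ols,
        basis=basis,
    )


def _predict(fit: SingleBalanceFit, x: np.ndarray, Z: np.ndarray) -> np.ndarray:
    return np.outer(np.asarray(x, float).ravel(), fit.beta_ilr) + Z @ fit.covariate_coefficients


def r_squared(
    fit: SingleBalanceFit,
    Y: np.ndarray,
    x: np.ndarray,
    Z: np.ndarray | None = None,
    recenter: bool = False,
) -> float:
    """Proportion of variance explained: 1 − MSE / total variance.

    Works on held-out data (may be negative).  With ``recenter`` the
    observed responses are shifted so their mean matches the predicted
    mean, correcting for a systematic location offset between datasets.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    if Z is None:
        Z = np.ones((n, 1))
    pred = _predict(fit, x, Z)
    if recenter:
        Y = Y - (Y.mean(axis=0) - pred.mean(axis=0))
    centred = Y - Y.mean(axis=0)
    total = float((centred**2).sum())
    if total <= 0:
        raise ValueError("zero total variance in responses")
    mse_part = float(((Y - pred) ** 2).sum())
    return 1.0 - mse_part / total


def balance_impact(fit: SingleBalanceFit) -> float:
    """Share ‖β_ls‖²/‖v*_ls‖² of the predictor shift captured by the balance."""
    return fit.impact


def orthogonal_complement_test(
    design: RegressionDesign,
    fit: SingleBalanceFit,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Permutation pseudo-F test for predictor effects outside the balance.

    Projects the responses onto the (D−2)-dimensional complement of the
    fitted balancing element and tests the predictor there with a
    Freedman–Lane residual-permutation pseudo-F.  A high p-value means the
    single balance captures essentially all predictor-associated change.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    x = design.x
    uniq = np.unique(x)
    if uniq.size == 2:
        counts = [(x == u).sum() for u in uniq]
        if min(counts) < 3:
            raise ValueError("too few samples per group for a permutation test")
    e = fit.element_ilr / np.linalg.norm(fit.element_ilr)
    P = np.eye(design.Y.shape[1]) - np.outer(e, e)
    Yc = design.Y @ P

    Z = design.Z
    X_full = design.design_matrix
    coef_red, *_ = np.linalg.lstsq(Z, Yc, rcond=None)
    fitted_red = Z @ coef_red
    resid_red = Yc - fitted_red
    rss_red = float((resid_red**2).sum())
    p_full = X_full.shape[1]

    def pseudo_f(Ymat):
        B, *_ = np.linalg.lstsq(X_full, Ymat, rcond=None)
        rss_f = float(((Ymat - X_full @ B) ** 2).sum())
        rss_r = float(((Ymat - Z @ np.linalg.lstsq(Z, Ymat, rcond=None)[0]) ** 2).sum())
        return (rss_r - rss_f) / (rss_f / (design.n - p_full))

    f_obs = pseudo_f(Yc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(design.n)
        y_perm = fitted_red + resid_red[perm]
        if pseudo_f(y_perm) >= f_obs:
            count += 1
    p_value = (1 + count) / (1 + n_permutations)
    return {"pseudo_f": f_obs, "p_value": p_value, "n_permutations": n_permutations}


def classify_by_balance(
    fit: SingleBalanceFit,
    new_samples: np.ndarray,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, float | None]:
    """Score samples by their projection on the fitted balancing element.

    Returns (scores, AUC); the AUC (rank statistic against the binary
    labels) is None when labels are not supplied.
    """
    scores = np.atleast_2d(np.asarray(new_samples, float)) @ (
        fit.element_ilr / np.linalg.norm(fit.element_ilr)
    )
    auc = None
    if labels is not None:
        labels = np.asarray(labels).ravel()
        if np.unique(labels).size < 2:
            raise ValueError("AUC needs both classes present")
        auc = float(roc_auc_score(labels, scores))
    return scores, auc


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class SingleBalanceRegression:
    """Model object for single-balance regression.

    Parameters
    ----------
    endog : ndarray, N × (D−1)
        ILR coordinates of the compositions, one row per sample.
    exog : ndarray, length N
        Scalar predictor (binary group indicator or continuous).
    basis : ContrastBasis
        The ILR basis the coordinates refer to.  The fitted balance is
        basis-invariant after back-transform to CLR.
    covariates : ndarray, optional
        N × K covariate matrix *without* the intercept, which is implicit.
    """

    def __init__(self, endog, exog, basis, covariates=None, covariate_names=()):
        self.design = RegressionDesign.build(
            endog, exog, basis, covariates, covariate_names
        )

    @classmethod
    def from_compositions(
        cls,
        table: pd.DataFrame,
        exog,
        covariates=None,
        covariate_names=(),
        basis: ContrastBasis | None = None,
    ) -> "SingleBalanceRegression":
        """Build from a taxa × samples table of positive proportions/counts."""
        labels = tuple(table.index)
        if basis is None:
            basis = pivot_basis(labels)
        mat = table.to_numpy(dtype=float)
        rows = []
        for j in range(mat.shape[1]):
            comp = closure(mat[:, j], labels=labels)
            rows.append(ilr(clr(comp), basis).coords)
        return cls(np.vstack(rows), exog, basis, covariates, covariate_names)

    def fit(self) -> "SingleBalanceResults":
        return SingleBalanceResults(self.design, fit_single_balance(self.design))


class SingleBalanceResults:
    """Fitted single-balance regression with diagnostics."""

    def __init__(self, design: RegressionDesign, fit: SingleBalanceFit):
        self.design = design
        self._fit = fit

    # -- estimates ---------------------------------------------------------
    @property
    def balance(self) -> Balance:
        return self._fit.balance

    @property
    def ols_coefficient(self) -> np.ndarray:
        return self._fit.ols.v_star

    @property
    def covariate_coefficients(self) -> np.ndarray:
        return self._fit.covariate_coefficients

    @property
    def sigma2(self) -> float:
        return self._fit.sigma2

    @property
    def impact(self) -> float:
        return self._fit.impact

    @property
    def rsquared(self) -> float:
        return self._fit.r_squared

    @property
    def tied(self) -> bool:
        return self._fit.tied

    # -- diagnostics -------------------------------------------------------
    def rsquared_on(self, Y, x, Z=None, recenter=False) -> float:
        return r_squared(self._fit, Y, x, Z, recenter=recenter)

    def orthogonal_complement_test(self, n_permutations=999, seed=None) -> dict:
        return orthogonal_complement_test(
            self.design, self._fit, n_permutations, seed
        )

    def classify(self, new_samples, labels=None):
        return classify_by_balance(self._fit, new_samples, labels)

    def summary(self) -> str:
        el = self.balance.element
        lines = [
            "Single-balance regression",
            "=" * 60,
            f"samples: {self.design.n}    taxa: {self.design.basis.d}    "
            f"covariates: {self.design.Z.shape[1] - 1}",
            f"numerator   ({el.r}): " + ", ".join(sorted(el.num)),
            f"denominator ({el.s}): " + ", ".join(sorted(el.den)),
            f"coefficient: {self.balance.coefficient:.6g}",
            f"impact of balance on OLS shift: {self.impact:.4f}",
            f"train R^2: {self.rsquared:.4f}    sigma^2: {self.sigma2:.6g}",
        ]
        if self.tied:
            lines.append("warning: nearest-balance search was tied")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        el = self.balance.element
        return {
            "numerator": sorted(el.num),
            "denominator": sorted(el.den),
            "coefficient": float(self.balance.coefficient),
            "impact": float(self.impact),
            "r_squared": float(self.rsquared),
            "sigma2": float(self.sigma2),
            "tied": self.tied,
        }
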