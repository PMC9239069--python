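"""Synthetic data generators for exercising the nearest-balance machinery.

Two protocols are emulated:

* **Noise stability** — start from the balancing elements of a
  hierarchically-clustered ILR basis over a log-normal compositional
  dataset; perturb each element with Gaussian noise drawn in the subspace
  orthogonal to it (and to the closure constraint), rescaled to a fixed
  fraction of the element's unit length; ask whether the nearest-balance
  search recovers the original taxon categorisation.

* **Case-control cohort** — two groups whose ILR means differ by a planted
  single-balance shift, with isotropic Gaussian noise; used for parameter
  recovery and classification benchmarks.  The default noise level is
  parameterised by the noise-to-shift ratio — the expected relative error
  of the estimated regression coefficient, sd ≈ σ√(2(D−1)/n)/‖shift‖ for
  two groups of n samples.

All generators are deterministic under a fixed seed and return the ground
truth needed for scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .compo import (
    BalancingElement,
    ClrVector,
    ContrastBasis,
    basis_from_partition,
)

__all__ = [
    "NoiseSimConfig",
    "CaseControlSimConfig",
    "DisturbedElement",
    "CaseControlData",
    "simulate_base_composition",
    "simulate_disturbed_elements",
    "taxon_accuracy",
    "simulate_case_control",
]


@dataclass(frozen=True)
class NoiseSimConfig:
    """Settings for the noise-stability protocol."""

    noise_fractions: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30)
    replicates: int = 20
    seed: int | None = None

    def __post_init__(self):
        if any(not (0 < f < 1) for f in self.noise_fractions):
            raise ValueError("noise fractions must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class CaseControlSimConfig:
    """Settings for the two-group cohort protocol.

    ``num``/``den`` define the planted balance (defaults: the first ~D/6
    taxa against the next ~D/3); ``sigma2`` is the isotropic ILR noise
    variance, by default derived from a 4% noise-to-shift ratio at the
    given sample size.
    """

    d: int = 30
    n_per_group: int = 1000
    num: tuple[str, ...] = ()
    den: tuple[str, ...] = ()
    coefficient: float = 1.0
    sigma2: float | None = None
    noise_to_shift: float = 0.04
    seed: int | None = None

    def __post_init__(self):
        if self.d < 3:
            raise ValueError("need at least 3 taxa")
        labels = self.labels
        if not self.num and not self.den:
            r = max(1, round(self.d / 6))
            s = max(1, round(self.d / 3))
            object.__setattr__(self, "num", labels[:r])
            object.__setattr__(self, "den", labels[r:r + s])
        if self.sigma2 is None:
            sd = (
                self.noise_to_shift
                * abs(self.coefficient)
                / math.sqrt(2 * (self.d - 1) / self.n_per_group)
            )
            object.__setattr__(self, "sigma2", sd**2)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        self.element  # validates the planted balance

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"t{i + 1}" for i in range(self.d))

    @property
    def element(self) -> BalancingElement:
        return BalancingElement(frozenset(self.num), frozenset(self.den), self.labels)


def simulate_base_composition(
    d: int, n: int = 200, seed: int | None = None
) -> tuple[pd.DataFrame, ContrastBasis]:
    """Log-normal compositional dataset plus a hierarchically-clustered basis.

    Log-abundances are Gaussian with heterogeneous per-taxon variances; the
    sequential binary partition is built by complete-linkage clustering of
    the pairwise log-ratio variation matrix, mimicking principal-balance
    style bases built on real cohorts.
    """
    if d < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    labels = tuple(f"t{i + 1}" for i in range(d))
    mu = rng.normal(0.0, 1.5, size=d)
    sigma = rng.uniform(0.5, 2.0, size=d)
    logs = mu[:, None] + sigma[:, None] * rng.standard_normal((d, n))
    props = np.exp(logs)
    props /= props.sum(axis=0, keepdims=True)

    # pairwise log-ratio variation matrix
    var_logs = logs  # log proportions differ from logs by a per-sample constant
    centered = var_logs - var_logs.mean(axis=1, keepdims=True)
    sq = (centered**2).mean(axis=1)
    cross = centered @ centered.T / n
    variation = sq[:, None] + sq[None, :] - 2 * cross
    np.fill_diagonal(variation, 0.0)
    variation = np.maximum(variation, 0.0)

    link = linkage(squareform(variation, checks=False), method="complete")
    sets = [frozenset([labels[i]]) for i in range(d)]
    partitions = []
    for a, b, *_ in link:
        left, right = sets[int(a)], sets[int(b)]
        partitions.append((left, right))
        sets.append(left | right)
    basis = basis_from_partition(partitions, labels)
    table = pd.DataFrame(props, index=labels, columns=[f"s{j + 1}" for j in range(n)])
    return table, basis


@dataclass(frozen=True)
class DisturbedElement:
    """A balancing element plus one noisy observation of it."""

    element: BalancingElement
    fraction: float
    replicate: int
    vector: ClrVector  # element + orthogonal noise of relative length `fraction`


def simulate_disturbed_elements(
    basis: ContrastBasis, config: NoiseSimConfig
) -> list[DisturbedElement]:
    """Perturb every basis element with orthogonal noise of fixed relative size.

    The noise is Gaussian in the subspace orthogonal to both the element and
    the closure constraint, rescaled so its norm is exactly
    ``fraction`` × 1 (the element has unit length).
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for element in basis.elements():
        e = element.clr().coords
        for f in config.noise_fractions:
            for rep in range(config.replicates):
                g = rng.standard_normal(e.size)
                g -= g.mean()  # stay in the zero-sum hyperplane
                g -= (g @ e) * e  # orthogonal to the element
                g *= f / np.linalg.norm(g)
                out.append(
                    DisturbedElement(
                        element=element,
                        fraction=f,
                        replicate=rep,
                        vector=ClrVector(e + g, basis.labels),
                    )
                )
    return out


def taxon_accuracy(true_element: BalancingElement, found_element: BalancingElement) -> float:
    """Fraction of taxa whose num/den/excluded category matches, up to sign.

    A global num↔den swap of the found element counts as a perfect match
    (the axis is the same).
    """
    if true_element.universe != found_element.universe:
        raise ValueError("elements use different taxon universes")

    def cats(el):
        return np.array(
            [1 if t in el.num else (-1 if t in el.den else 0) for t in el.universe]
        )

    a = cats(true_element)
    b = cats(found_element)
    return float(max((a == b).mean(), (a == -b).mean()))


@dataclass(frozen=True)
class CaseControlData:
    """Simulated two-group cohort with its ground truth."""

    Y: np.ndarray  # (2n) × (D−1) ILR coordinates
    x: np.ndarray  # group indicator 0/1
    basis: ContrastBasis
    element: BalancingElement
    coefficient: float
    sigma2: float
    baseline: np.ndarray  # group-0 ILR mean


def simulate_case_control(
    config: CaseControlSimConfig,
    baseline: np.ndarray | None = None,
) -> CaseControlData:
    """Two groups whose ILR means differ by the planted single-balance shift.

    Group 0 sits at the baseline (origin — the uniform composition — unless
    given); group 1 at baseline + coefficient × element.  Noise is isotropic
    Gaussian in ILR coordinates with variance ``config.sigma2``.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.labels
    from .compo import pivot_basis

    basis = pivot_basis(labels)
    element = config.element
    e_ilr = element.clr().coords @ basis.psi.T
    if baseline is None:
        baseline = np.zeros(config.d - 1)
    baseline = np.asarray(baseline, dtype=float)
    n = config.n_per_group
    x = np.concatenate([np.zeros(n), np.ones(n)])
    means = baseline[None, :] + np.outer(x, config.coefficient * e_ilr)
    Y = means + math.sqrt(config.sigma2) * rng.standard_normal((2 * n, config.d - 1))
    return CaseControlData(
        Y=Y,
        x=x,
        basis=basis,
        element=element,
        coefficient=config.coefficient,
        sigma2=config.sigma2,
        baseline=baseline,
    )
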