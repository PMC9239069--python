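# Methods

## Geometry and conventions

All analysis happens in Aitchison geometry. A composition of D strictly
positive parts is mapped to the zero-sum hyperplane of R^D by the centred
log-ratio (CLR) transform; an ILR basis is an orthonormal coordinate system
on that hyperplane given by a contrast matrix Ψ whose rows are the CLR
images of the balancing elements of a sequential binary partition (SBP).
Both transforms are isometries, so every search in this package is phrased
in CLR and is invariant to the ILR basis a caller happens to use; tests
verify basis invariance of the regression and principal-balance results to
1e-8.

Conventions chosen once and used everywhere:

* Count tables are taxa × samples; all group operations use taxon labels,
  never positions.
* A balance is reported with a non-negative coefficient; the numerator is
  the side the shift increases. When the coefficient is exactly zero the
  orientation is fixed by putting the lexicographically smallest supported
  taxon in the numerator.
* Orthonormality, zero-sum and round-trip checks use an absolute tolerance
  of 1e-9. Shifts with norm below 1e-12 are rejected ("no direction to
  approximate") rather than resolved arbitrarily.
* The default ILR basis, when a caller supplies none, is the pivot SBP over
  the label order; any valid basis gives the same back-transformed results.

## Nearest balance (single shift)

The cosine between a CLR shift v̂ and a balancing element with groups of
sizes (r, s) is maximised, at fixed sizes, by the r largest and s smallest
components of v̂. The search therefore sorts once (stable: value
descending, then label — so equal values order deterministically) and scans
all (r, s) with r+s ≤ D using prefix sums: O(D log D + D²) total, vectorised
over the (r, s) grid.

Tie handling: all (r, s) whose cosine is within 1e-12 of the maximum are
collected; the scan enumerates pairs in (r+s, r) order, so the first —
smallest support, then smallest numerator — wins, and the alternatives are
reported in the result's `ties` field. Equal CLR values straddling a
winning group boundary would make membership non-unique; the search detects
this and warns (with the parsimony tie-break the situation essentially
coincides with an exact cosine tie and is reported there too). The
exhaustive oracle `brute_force_nearest` (guarded at D ≤ 12) enumerates all
(3^D − 2^(D+1) + 1)/2 sign-deduplicated elements and applies the same
tie-break key; equivalence with the fast search is asserted over hundreds
of random shifts in the test suite.

`distance` is computed from the explicit residual v̂ − ⟨v̂, ê⟩ê, not from
√(‖v̂‖² − coef²), which cancels catastrophically near perfect fits.

## Second orthogonal balance

Two balancing elements can be nodes of one binary tree iff their supports
are disjoint (case C), one support lies inside a single part of the other
(case A), or vice versa (case B); each relation implies CLR orthogonality.
Given a first element and a target vector w, five restricted searches cover
every compatible element: the sorted scan inside the first's numerator,
inside its denominator, among the outside taxa, and two "ancestor" scans in
which the first element's full support enters the numerator or the
denominator as an indivisible block (the block's summed ŵ value enters the
group sum with its full multiplicity). The ancestor scans include the case
where the numerator (or denominator) is exactly the block — such elements
are valid strict ancestors and the exhaustive oracle confirms they can win.
The winner maximises |⟨ŵ, ê⟩|; sign is restored afterwards. When w is
orthogonal to every candidate (e.g. w equals the first element itself) the
tie-break winner is returned with coefficient zero rather than failing, so
pipelines that feed arbitrary PCA axes keep working.

## Nearest balance tree

The greedy tree search keeps, after k chosen elements, a laminar family of
taxon groups. A new element must live inside an *open region* — the whole
universe or the numerator/denominator part of a chosen element, provided no
chosen element splits that region already — and may only combine that
region's *units*: the maximal chosen supports properly inside it plus its
free taxa. Replacing each unit by its summed CLR value with an integer
weight reduces the search to choosing, per distinct weight, how many units
enter the numerator (taken greedily from the top of the weight class sorted
by value) and how many the denominator (from the bottom); enumerating all
per-class count assignments covers every feasible (r, s) exactly, and the
swapped assignment covers the flipped orientation. Each step's winner is
the global argmax over regions under the same tie-break as the single
search; a tie at any step is recorded on the result, since a tied greedy
choice can propagate.

After D−1 steps the elements form a complete SBP: they are mutually
orthogonal, the projections reconstruct the shift exactly, and the impacts
(squared projections over the squared shift norm) sum to one — all asserted
at 1e-9. The default dimension cap is D ≤ 30 (the weight-combination
enumeration is combinatorial in the block structure); callers can override
`max_d` knowingly. Newick export finds the root element (support =
universe) and recurses; internal nodes carry the balance's discovery index
and optionally its impact.

## Single-balance regression

The model is y*_i ~ N(x_i b* + A z_i, σ² I) with b* constrained to be a
balance vector and the intercept always an implicit covariate. The
least-squares solution factorises: fit unconstrained OLS, take the nearest
balance β to the predictor coefficient v*_ls, then refit the covariate
matrix on Y − x βᵀ. The test suite verifies the factorisation against
exhaustive enumeration (every element with its implied covariate matrix)
on random small designs, including the mean-shift special case (x ≡ 1
without intercept, where the OLS coefficient is the sample mean) and the
single-predictor intercept identity a = ȳ − x̄ β.

Reported metrics: R² = 1 − MSE/total variance, computable on held-out data
(optionally re-centred to absorb a systematic location offset between
datasets); impact = ‖β‖²/‖v*_ls‖²; σ² estimated from the residual sum of
squares over (N − p)(D − 1) degrees of freedom.

The test for predictor effects outside the fitted balance projects the
responses onto the (D−2)-dimensional complement of the balancing element
and runs a permutation pseudo-F (Freedman–Lane: residuals of the
covariate-only model are permuted and re-added to its fitted values) with
a seeded generator; 999 permutations by default, at least 99 enforced.
A permutation test was chosen over parametric MANOVA because it is
distribution-free, needs no choice of statistic (Pillai/Wilks), and is
valid at small N; the cost is that p-values are granular at 1/(B+1).
Note the complement is taken around the *estimated* balance, so under a
true single-balance alternative the test is very slightly anticonservative
when the balance itself is misestimated; calibration is verified by
simulation at the noise levels where recovery is reliable.

Classification scores are projections on the fitted element; AUC is the
rank statistic (Mann–Whitney) over the true labels.

## Principal balances

PCA runs on the ILR covariance by eigendecomposition; each component's sign
is fixed by making its largest-magnitude loading positive so balance
numerators are reproducible. The two-balance construction (nearest balance
to PC1, best tree-compatible balance to PC2) is the primary variant because
exactly two balances are what the analysis reports; a full
nearest-balance-tree on PC1 is available as `principal_balance_tree` for
callers who want a complete coordinate system, without optimality claims
beyond the greedy construction. A balance's explained share is the variance
of the data projected on its element over the total variance; the Rayleigh
bound (share ≤ matching PC's share) is asserted in tests.

## Synthetic data

The noise-stability generator draws log-normal compositions with
heterogeneous per-taxon log-variances (means N(0, 1.5²), standard
deviations U(0.5, 2) — a caricature of the broad abundance ranges of stool
microbiomes), builds an SBP by complete-linkage clustering of the pairwise
log-ratio variation matrix, and perturbs each basis element with Gaussian
noise projected into the subspace orthogonal to both the element and the
closure constraint, rescaled so the noise norm is exactly the requested
fraction of the element's unit length. Defaults: fractions
{5, 10, 20, 30}%, 20 replicates per element. What this does *not* emulate:
read-count sampling noise, zero inflation, or the taxon correlation
structure of a real cohort — so passing recovery rates show the geometry of
the search is stable to orthogonal perturbations, not that any particular
real dataset is this clean.

The case-control generator plants a single-balance mean difference between
two groups with isotropic Gaussian ILR noise. Defaults: D = 30 taxa, 1000
samples per group, coefficient 1, and noise parameterised by a 4%
noise-to-shift ratio — the expected relative error of the estimated
coefficient, sd ≈ σ√(2(D−1)/n)/‖shift‖ — matching the regime where a
two-group design of this size estimates the shift to a few percent. The
baseline (group-0) mean defaults to the ILR origin, i.e. the uniform
composition; a real cohort's fitted baseline cannot be reproduced without
that cohort, and the recovery metrics depend only on the shift and the
noise, not the baseline. The categorisation accuracy metric counts taxa
whose three-way assignment (numerator/denominator/excluded) matches the
planted element, treating a global num↔den swap as a perfect match.

## Zero replacement and filtering

Zeros are replaced deterministically and multiplicatively, per sample: each
zero becomes δ = 0.65 × the sample's detection limit (1/total for count
data, the smallest positive proportion for an already-normalised table) and
the nonzero proportions are scaled by 1 − (replaced mass) so the sample
still closes to 1. A Bayesian-multiplicative imputation would randomise
results and add a dependency for no benefit at this package's scale; δ is
configurable. Prevalence filtering keeps taxa with ≥ min_reads in at least
min_fraction of samples (defaults 2 reads, 5%) and refuses to remove every
taxon.

## Problem sizes used in the checks

The standing test suite runs the exhaustive oracles at D ≤ 8 (hundreds of
random shifts), the regression theorem suite on 100 random designs with
D ≤ 6, N ≤ 40 and 0–2 covariates, the noise-stability check at D = 44 and
D = 117 with 20 replicates per element at 10% noise, and parameter recovery
on 20 seeded cohorts of 2 × 1000 samples — sizes chosen so the whole suite
completes in a few seconds while still covering the paper-scale dimensions
of the stability claim.

## Known limitations

* Greedy tree construction is not globally optimal, and a tie at any step
  can propagate; ties are detected and flagged, not resolved by lookahead.
* The tree-compatibility constraint for the second balance is exactly
  "same binary tree"; unconstrained orthogonal pairs are not searched.
* The permutation test's complement is built around the estimated balance
  (see above).
* Weighted taxa and sparsity-penalised balance selection are out of scope.
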