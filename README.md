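# nearbalance

Nearest-balance interpretation of compositional shifts — microbiome
relative-abundance data first and foremost, but any composition works.

## The problem

Sequencing yields *compositions*: vectors of D taxon abundances informative
only up to proportions. Correct analysis happens in log-ratio coordinates —
the centred log-ratio `clr(v)_i = ln v_i − (1/D) Σ_j ln v_j` or any
isometric log-ratio (ILR) basis `v* = v̂ Ψᵀ` built from a sequential binary
partition of the taxa. Models fitted in those coordinates return vectors
(a regression coefficient, a PCA axis, a difference of group means) that
are hard to read: every taxon loads on every coordinate.

A *balance* is the interpretable special case: a log-contrast between the
geometric means of a numerator group of r taxa and a denominator group of
s taxa, with unit direction (the *balancing element*)

    ê_i = +√(rs/(r+s))/r  (numerator taxa),
          −√(rs/(r+s))/s  (denominator taxa),
          0               (everything else).

`nearbalance` finds, for any CLR/ILR vector v̂, the balancing element with
maximal cosine to it and the projection b* = ⟨v̂, ê⟩ ê — the least-squares
single-balance approximation of the shift, with *impact* ‖b*‖²/‖v̂‖², the
share of the shift it captures. Because a balancing element is constant on
each of its two groups, the optimum at fixed (r, s) uses the r largest and
s smallest CLR components, so a sort plus an O(D²) scan replaces a search
over all ~3^D/2 elements.

On top of that single search the package provides:

* **second orthogonal balance** — the best element tree-compatible with a
  given first one (for joint interpretation of two directions, e.g. two
  principal components);
* **nearest balance tree** — a full orthonormal ILR basis (D−1 balances)
  greedily fitted to one shift, with per-balance impacts summing to 1;
* **single-balance regression** — multivariate OLS in ILR coordinates whose
  predictor coefficient is constrained to a balance; the least-squares
  solution is the nearest balance to the unconstrained coefficient with the
  covariate matrix refitted, plus R², impact, a permutation pseudo-F test
  on the orthogonal complement, and single-balance classification (AUC);
* **principal balances** — nearest balance to PC1 and best orthogonal
  balance to PC2, with variance shares;
* **simulators** — noise-stability and planted-balance case-control
  generators with ground truth, used by the test suite and the acceptance
  script;
* a **CLI** (`nearbalance shift|tree|regress|pca|simulate|filter`) over
  TSV/CSV count tables with prevalence filtering and multiplicative zero
  replacement built in.

## Worked example

The coffee recipe: cup 2 is cup 1 with a triple portion of milk
(espresso/milk/syrup 50/40/10 → 50/120/10).

```bash
$ nearbalance shift --counts coffee.tsv --sample1 cup1 --sample2 cup2 --min-prevalence 0
{
  "numerator": ["milk"],
  "denominator": ["espresso", "syrup"],
  "coefficient": 0.8970131774626956,
  "cosine": 0.9999999999999999,
  "impact": 0.9999999999999998,
  ...
}
```

Cosine 1: the whole shift is exactly a change in the milk-vs-rest balance;
the coefficient 0.897 = √(2/3)·ln 3 is its size in Aitchison geometry.

An 8-taxon CLR shift and its full balance tree:

```python
import numpy as np
from nearbalance import ClrVector, nearest_balance, nearest_balance_tree, to_newick

v = ClrVector(np.array([-0.1, -0.8, -0.1, -0.3, 0.1, 0.9, -0.6, 0.9]))
res = nearest_balance(v)
# numerator {t6, t8}, denominator {t2, t4, t7}
# cosine=0.970614  impact=0.942092  coefficient=1.6067

tree = nearest_balance_tree(v)
# impacts: [0.9421 0.0456 0.0097 0.0019 0.0006 0.  0. ]   (sum = 1)
print(to_newick(tree))
# (((t6,t8)b7,((t4,t2)b2,t7)b5)b1,(t5,(t1,t3)b6)b3)b4;
```

The single balance t6,t8 vs t2,t4,t7 captures 94.2% of the shift; the
remaining 5.8% decomposes along six further orthogonal balances.

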