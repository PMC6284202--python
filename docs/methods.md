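# Methods

## Model

The indicator model is a K-class mixture of product-multinomials: class
proportions `π` (length K) and, per item j with C_j categories, a K × C_j
table `θ_jk` of conditional response probabilities; items are independent
given class (local independence). At an interior node of a tree the same
model is fitted to the *full* sample with case weights equal to the
posterior probability of belonging to that node, maximizing the weighted
log-likelihood `Σ_i w_i log Σ_k π_k Π_j θ_jk(y_ij)`. Weights enter the EM
updates linearly, so duplicating a case while halving its weight changes
nothing — this weight linearity is what makes proportional assignment exact
at every depth.

## Estimation

`em_fit` runs EM from `n_starts = 16` random soft assignments (Dirichlet(1)
rows) and keeps the best solution. The M-step is the closed-form weighted
update of `π` and `θ`; the E-step is Bayes' rule in log space. Convergence
is declared when the relative log-likelihood change drops below
`tol = 1e-8` (cap `max_iter = 1000`); nonconvergence is flagged on the
result, not fatal. Response probabilities are floored at
`prob_floor = 1e-6` and renormalized after every M-step so no observed
pattern ever reaches probability zero; with ten binary items the worst-case
per-case log-probability is ≈ −138, far from underflow in log space.

Internally EM collapses the data to unique response patterns with summed
weights. The likelihood, the M-step statistics, and per-pattern posteriors
are identical under this reformulation, so it is exact — not an
approximation — and typically 3–6× faster at survey-like sizes; posteriors
are expanded back to all N cases on return.

Seeds: a single master seed spawns per-start seed sequences; per-node seeds
in the tree are derived from the master seed and the node's path label, so
an identical configuration reproduces an identical tree bit for bit.

## Tree construction

The root is tested for a split into `root_K` classes (default 2); each
accepted child is then tested breadth-first for a binary split (`k_split`
overridable). A split is accepted when the criterion (BIC by default; AIC
optional) of the k-class model at the node is lower than the one-class
model's. The BIC penalty uses `log(N)` with N the root sample size, which is
the printed-formula convention; `ic_mode="node"` substitutes the node's
effective size, the statistically natural alternative for nested models on
weighted subsets. Children are ordered by size descending — exact ties
broken by lexicographic comparison of the class parameter profile — and
labeled by path (`"1"`, `"21"`, …). Nodes below 1 % of the total weight
(`min_split_fraction`) or with fewer effective cases than candidate
parameters are not split; `max_depth = 10` caps growth. Every case is
carried at every node; weight conservation (children sum to the parent,
leaves sum to one per case) holds to 1e-10 and is asserted in the tests.

## Root sizing by relative improvement

`RI_{K,K+1} = (m_{K+1} − m_K)/(m_2 − m_1)` with m the log-likelihood, or the
negated differences for BIC/AIC so that improvement is positive. The
denominator must be strictly positive or the measure is undefined (error).
The measure is invariant to positive affine rescaling of m, and `RI_{1,2}`
is 1 by construction. The claimed upper bound of 1 is not mathematically
guaranteed; values above 1 are reported with a warning rather than clamped.
The default threshold is 0.10; the full RI table is always reported because
the choice is judgment-aided, and display rounding (3 decimals for RI,
integers for BIC/AIC) never feeds back into computation. Automatic nonbinary
sizing is exposed for the root only; deeper nonbinary splits are available
manually via `k_split`.

## Top-2 ranking model

Per item j and class k, effects-coded logits `β_jk` (summing to zero over
the A_j alternatives) define utilities `τ = exp(β)`; the ordered pair
probability is `τ_a1/Σ_a τ_a · τ_a2/Σ_{a≠a1} τ_a`, with utilities shared
between the first and second choice (hard-coded; it is the model's defining
assumption). Free parameters: `(K−1) + K·Σ_j (A_j−1)`.

EM alternates posterior class memberships with an inner M-step that, for
each class and item, maximizes the posterior-weighted pair log-likelihood
over the A_j − 1 free logits. The inner objective depends on the data only
through the weighted count of each ordered pair, is concave (both stages are
conditional-logit likelihoods), and is solved by BFGS with the analytic
gradient to `inner_tol = 1e-9` (on the count-normalized scale), warm-started
from the previous iteration. The effects-coding constraint is enforced by
the parameterization itself, so it holds exactly at every step. The same
pattern-collapsing trick applies (unique (first, second) profiles).

## Synthetic data

`simulate_lc` draws class labels from the class sizes and responses
independently per item given class; `simulate_ranking` draws the first
choice from the full choice set and the second from the remainder. Built-in
configurations (10 binary items, n = 1,000, equal class sizes):

* **A** — classes at 0.8 everywhere; 0.3/0.1; 0.1/0.3 (mirror pair around
  0.2 on all ten items).
* **B** — 0.8 everywhere; 0.2 everywhere; 0.8 on items 1–5, 0.2 on 6–10.
* **C** — high pair 0.96/0.64 on items 1–5 (0.8 on 6–10), low pair
  0.36/0.04 on items 6–10 (0.2 on 1–5): macro-cluster means 0.8 and 0.2,
  within-pair differences on disjoint subsets.

Only the qualitative structure of these configurations is prescribed;
the exact constants are this package's own, chosen once so that (i) every
stated structural constraint holds, and (ii) the intended tree behavior is
actually realized at n = 1,000 under BIC — the similar pair in A and both
pairs in C are separable at the second level (an exact KL calculation puts
each within-pair split gain comfortably above the 11-parameter BIC bar of
≈ 38 nats), while leaving RI_{2,3} well below the 0.10 threshold for A and
C and far above it for B. The generator emulates exact local independence,
exact class proportions, and no missing data; real survey data violate all
three (residual associations, unbalanced classes, item nonresponse), so
passing tests demonstrate correct recovery under the model's own
assumptions, not robustness to misspecification.

The study runner (`run_ri_study`) defaults to 20 replications — desk scale;
pass `n_replications=100` for the full design — fitting K = 1..Kmax per
replication and recording RI_{2,3} (and RI_{3,4} when Kmax ≥ 4) with
per-replication seeds spawned from a master seed.

## Numerical and interface choices

* 1-based category codes in files, 0-based indexing internally.
* Missing cells are rejected at read time with the row and column named;
  the model does not handle missingness.
* A K = 1 fit is closed-form (weighted marginals); K exceeding the number
  of distinct observed patterns triggers a boundary warning.
* `FitResult` records the log-likelihood trajectory of the winning start;
  EM monotonicity is tested against it.
* Tree exports: JSON (label, size, criterion values, class profiles per
  node; exact float round trip) and Graphviz DOT text.
* The CLI writes a manifest (config, seeds, versions) with every run.

## Limitations

Local-dependence models, covariates, ordinal restrictions, and modal/random
assignment are out of scope. Full rankings beyond the top two are not
supported. Nonbinary splits below the root require a manual `k_split`.
BIC-gated growth inherits BIC's conservatism: weak but real subclasses near
the penalty boundary are found in a majority, not all, of replications at
n = 1,000.
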