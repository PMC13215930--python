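# Methods

## Scope and model

The package implements a two-phase "structure analysis → weight
calculation" workflow for risk-factor systems: questionnaire psychometrics
condense raw Likert items into common factors; Interpretive Structural
Modeling (ISM) turns expert pairwise influence judgments over those factors
into a multi-level hierarchy; the Analytic Network Process (ANP) turns the
resulting influence network plus Saaty pairwise comparisons into global
factor weights. A bundled 18-factor preschool drowning-risk system
(factors classified by Haddon dimension) serves as the worked example, and
synthetic generators cover every input the workflow needs.

## Psychometrics

* **Correlations.** Likert scores are treated as numeric and correlated
  with Pearson's r (polychoric correlation is out of scope). Items with
  zero variance are rejected by name; missing responses are rejected unless
  listwise deletion is requested — the workflow assumes complete valid
  questionnaires.
* **Cronbach's α** uses sample variances with the n−1 denominator
  throughout. With population variances α differs in roughly the fourth
  decimal at small n; one convention is fixed and documented rather than
  exposed as an option.
* **KMO** computes anti-image partial correlations from the inverse
  correlation matrix. The identity matrix gives 0/0; the package returns 0
  with a warning, "no sampling adequacy" being the natural limit. A
  numerically singular matrix raises, advising a diagonal ridge
  (`ridge=1e-8`) that is off by default.
* **Factor extraction** is principal components on the correlation matrix;
  loadings are eigenvectors scaled by √eigenvalue. The eigenvalue > 1
  retention rule is strict (an eigenvalue of exactly 1, as in an identity
  correlation, is excluded). Variance-contribution columns come from the
  unrotated eigenvalues (100·λⱼ/p with prefix-sum cumulative), matching the
  usual "initial eigenvalues" reporting layout. Extraction can be run on
  any item subset's correlation matrix, so per-dimension tables (one
  eigenvalue block per Haddon dimension) and whole-questionnaire runs use
  the same entry point.
* **Varimax** is Kaiser's pairwise algorithm with the closed-form rotation
  angle φ = ¼·atan2(D − 2AB/p, C − (A²−B²)/p) per factor pair, swept until
  no pair moves. The planar rotations are orthogonal, so communalities are
  preserved to machine precision and the criterion never decreases; the
  closed form also handles the exact-45° starting point that defeats
  gradient-style varimax iterations. Loadings are presented columns-sorted
  by explained sum of squares with each column's largest loading positive.

## ISM

* **Coding.** V/A/X/O relation codes map to adjacency entries
  (V: aᵢⱼ=1; A: aⱼᵢ=1; X: both; O: neither); unlisted pairs default to O
  and the diagonal is 0. A pair coded twice is an error — conflicting
  expert codings cannot be reconciled mechanically.
* **Closure** is Boolean squaring of (A+I) to its fixed point, the
  (A+I)^k = (A+I)^{k+1} contract; Warshall's algorithm would be an
  equivalent implementation. Closure is idempotent and elementwise ≥ A+I;
  tests check it against networkx's transitive closure on random digraphs.
* **Level semantics.** The extraction rule R(Fᵢ)∩Q(Fᵢ)=R(Fᵢ) places sinks
  (consequence factors) in level 1, so the hierarchy reads surface → root.
  Some ISM literature numbers levels from the root end; this package does
  not.
* **Non-closed input.** A reachability matrix supplied directly (e.g.
  reconstructed from a published reachable-set table) may fail the closure
  check. `partition_levels` processes it as given with a warning —
  published tables are sometimes not perfectly closed yet still yield their
  published hierarchy under the extraction rule — and `reclose=True`
  re-closes first. For the bundled example the partition is identical
  either way. A non-closed matrix can also make extraction stall; that
  raises with the stuck factor set rather than looping.
* **Digraph.** The exported hierarchy uses the transitive reduction of the
  strict reachability relation (edge kept iff no one-step bypass exists),
  which is the unique minimal edge set for a closed acyclic relation; ties
  are broken by ascending factor index, and cyclic relations are rejected
  since their reduction is not unique. DOT output groups each level with
  `rank=same`.
* **Factor ids** are 1-based ("F1"…) in every file and table; positional
  indexing is confined to the implementation.

## Bundled example tables

The bundled tables are verbatim transcriptions (range notation like
"9–15" is expanded on load; hyphen and en-dash both accepted; a SHA-256
checksum guards the transcription). They carry three internal
inconsistencies that the package flags rather than corrects:

1. the reachable sets are not transitively closed — e.g. R(F15) omits
   F4/F5 though both are reachable through F13, and R(F16) omits F3 though
   F2 is listed; `check_closure` lists all 17 violating triples;
2. the hierarchy table lists 17 of the 18 factors: F8 appears in every
   other table but in no hierarchy row. The extraction rule necessarily
   places F8 in level 3 (once levels 1–2 remove F4, F5 and F13, its
   reachable and antecedent sets are both {F8});
3. the printed antecedent set of F2 is {F1, F2}, while the printed
   reachable set of F16 contains F2 — no 0/1 matrix satisfies both, and
   the matrix reconstructed from the reachable column gives
   Q(F2) = {F1, F2, F16}.

The test suite asserts the computed results exactly and pins each
discrepancy exactly, so a change in either the code or the transcription
fails loudly.

## ANP

* **Orientation.** Entry (i, j) of the supermatrix is positive iff factor
  j influences factor i: column j distributes j's influence over its
  targets. This is the orientation under which factors that nothing
  influences (empty antecedent sets — F1, F8, F15, F16 in the example)
  have structurally zero rows and therefore global weight exactly 0
  regardless of judgment values, matching the zero weights reported for
  exactly those factors. The classical Saaty "dependence" orientation
  (column j holds priorities of j's influencers) is available via
  `orientation="dependence"`; under it the sinks become the absorbing
  elements instead.
* **Sinks.** Factors influencing nothing get an absorbing diagonal 1;
  leaving their columns zero would break column stochasticity and with it
  the limit contract.
* **Priorities** come from the principal right eigenvector (dense
  eigendecomposition; power iteration is the test oracle), normalized to
  sum 1. Reciprocity is validated to 1e-6 relative tolerance.
* **Consistency.** CI = (λmax−m)/(m−1), CR = CI/RI with Saaty's
  RI(1..10) = 0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49 and
  CR ≡ 0 for m ≤ 2. When a network criterion compares more than 10
  elements (the bundled network's F15 and F16 compare 11 and 14), the
  pipeline gates such matrices using RI(10) — a lower bound of the (in m
  increasing) random index — which over-estimates CR and therefore only
  tightens the CR < 0.1 gate; `consistency()` itself raises for m > 10
  unless this fallback is requested explicitly.
* **Cluster weighting** scales block (r, c) of W₀ by a_rc and renormalizes
  every column; the renormalization is required for column stochasticity
  and is applied always. Column c of the cluster matrix is a priority
  vector over exactly the clusters structurally linked in column-cluster c
  of W₀ (including the diagonal block created by absorbing sinks); a
  uniform 1/k fallback stands in when no cluster judgments are supplied.
* **Limit.** Repeated squaring with the fixed-point test
  max|P·W − P| < 1e-10 and a cap of 200 squarings; non-convergent
  (periodic or reducible) chains fall back to the Cesàro average of 32
  consecutive powers after a burn-in of W⁶⁴, flagged `method="cesaro"`.
  The fixed-point test deliberately multiplies by W once more rather than
  comparing successive squarings, which would falsely accept period-2
  chains. When the method is "power" the limit satisfies
  ‖W∞·W − W∞‖_max < 1e-8.
* **Weights.** If all limit columns agree to 1e-6 any column is the weight
  vector; otherwise the row mean is renormalized (the reducible case).
  Ranks are competition-style, ties sharing the smaller rank.
* **A structural caveat.** On an acyclic influence network with absorbing
  sinks the pure power limit concentrates *all* mass on the sinks: every
  transient (mid-level) factor gets weight 0, not just the roots. Published
  ANP analyses that report positive weights for mid-level factors must
  therefore use either inner-dependence loops beyond plain reachability or
  a different synthesis than the raw power limit. The package does not
  guess which: it exposes both limit methods, records which was used in
  every result, and accepts arbitrary extra network edges so
  inner-dependence variants can be expressed explicitly. Consequently the
  bundled example reproduces the *structural* facts of its source tables
  (hierarchy, zero weights of the four root factors, ranking of surface
  factors) but not the exact published mid-level weights, whose expert
  judgment matrices were never published in any case.
* The symbol "A" traditionally denotes both the ISM adjacency matrix and
  the ANP cluster weight matrix; the code names them `adjacency` and
  `cluster_matrix`.

## Synthetic generators

* **Responses.** Latent factors are standard normal, items are
  Σλ·factor + noise, z-scaled, mapped to mean 3 / SD 1, rounded half-up
  and clipped to [1, 5]. Defaults (15 items, 3 factors, loading 0.7,
  noise SD 0.5, 500 respondents) give a clean simple structure whose
  recovery (mean Tucker congruence > 0.9 over 20 seeds) the suite checks.
  The generator emulates the coarsening a 5-point scale applies to a
  continuum; it does not emulate response styles (acquiescence, central
  tendency), item difficulty differences, or respondent demographics — so
  passing recovery tests show the estimator chain works on well-behaved
  discretized data, not that any real questionnaire has this structure.
* **Judgments.** p_ij = (wᵢ/wⱼ)·exp(εᵢⱼ) with antisymmetric normal ε, so
  reciprocity is exact for every noise level; δ=0 is perfectly consistent
  (CR = 0, priorities recover w). Optional rounding snaps the upper
  triangle to the nearest admissible 1-9 scale value. At δ=0.1 and m=4 the
  median CR over seeds stays under the 0.1 gate.
* **DAGs.** A random permutation fixes a topological order; forward pairs
  get edges with the requested density — acyclic by construction.
* All generators are pure functions of their spec, seed included.

## Problem sizes and numerics

The bundled system has 18 factors; the property batteries use random
digraphs up to n=12 (200 instances) and n≤6 (1000 instances against a
path oracle), 50 judgment seeds for the structural-zero law, and 20
response-generation seeds at n=500 for loading recovery — sizes chosen so
the entire suite and the acceptance script each run in well under a minute
on one CPU. Tolerances: closure and partitions are exact integer
computations; eigenvector quantities are asserted at 1e-9; supermatrix
stochasticity at 1e-9; the limit fixed point at 1e-10 with idempotence
verified at 1e-8.

## Known limitations

* Pearson-only correlations understate association for coarse Likert data;
  polychoric EFA, confirmatory factor analysis and factor-score estimation
  are out of scope, as is automatic factor naming (a human judgment).
* MICMAC driving/dependence analysis and fuzzy/grey ISM or interval ANP
  variants are not implemented.
* The CR gate for comparison sets larger than 10 elements relies on the
  RI(10) lower-bound argument above; exact random indices for large m are
  not tabulated here.
* Exact reproduction of the example study's published global weights is
  impossible in principle from the published record (the expert judgment
  matrices are not public) and structurally out of reach of a pure power
  limit, as discussed under ANP.
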