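# Methods

## Model

The package implements the fuzzy Analytic Network Process: priorities for a
goal are derived from pairwise comparison judgments over a network of
clusters and elements that may depend on each other (inner dependence within
a cluster, outer dependence across clusters), rather than a strict
hierarchy. Judgment uncertainty is carried by triangular fuzzy numbers
(TFNs) `(l, m, u)`, `0 < l ≤ m ≤ u`, with the usual approximate arithmetic:
componentwise multiplication and addition, reciprocal `(1/u, 1/m, 1/l)`,
componentwise geometric mean. The crisp case `l = m = u` is supported
throughout, and every fuzzy operation degenerates to its crisp counterpart
there — a property the tests rely on.

Pipeline, per comparison question ("compare the elements of cluster C with
regard to node s"):

1. each expert's reciprocal TFN matrix is validated structurally (unit
   diagonal, reciprocity within tolerance);
2. the panel is aggregated cell-wise by geometric mean (equal expert
   weights). Geometric aggregation commutes with the reciprocal, so the
   aggregate is reciprocal to floating precision — arithmetic averaging
   would not be;
3. fuzzy weights by Buckley's geometric-mean method,
   `w̃_i = r_i ⊗ (Σ_k r_k)^(-1)` with `r_i` the row geometric mean and the
   sum inverted bounds-reversed; defuzzification by the Liou–Wang total
   integral at optimism `α` (default 0.5, i.e. `(l+2m+u)/4`), then
   normalization and ranking (ties broken stably by input order);
4. consistency gating: Saaty's `CR = CI/RI(n)`, `CI = (λ_max − n)/(n−1)`,
   computed on two crisp surrogates of the fuzzy matrix — the modal-value
   matrix (CRm) and the matrix of `sqrt(l·u)` (CRg). A run aborts when any
   CRm ≥ 0.1 unless forced. `λ_max` comes from power iteration
   (tolerance 1e-10, cap 10,000 iterations, uniform start), estimated as
   the mean Rayleigh ratio; matrices of order ≤ 2 have CR = 0 by
   definition;
5. supermatrix synthesis: local vectors are stacked block-wise (the column
   of element `e` holds, in the rows of cluster C, the priorities of C's
   elements with regard to `e`), blocks are scaled by cluster weights and
   each nonzero column renormalized to 1, and the weighted matrix is raised
   to powers until it stops changing. The limit column, restricted to
   element rows and renormalized, gives overall priorities; cluster
   priorities are their sums, within-cluster weights the renormalized
   blocks.

### Alternative derivation routes

Chang's extent analysis is implemented (synthetic extents
`S_i = (Σ_j a_ij) ⊗ (Σ_ij a_ij)^(-1)`, pairwise possibility degrees
`V(S_i ≥ S_j)`, weights from the normalized minima) but is not the default:
on the bundled worked-example matrix it assigns an exact zero to
Efficiency, because the Efficiency extent lies strictly below the other
two — extent analysis is a ranking device that can zero out elements whose
extents do not overlap, and it provably cannot have produced the bundled
example's strictly positive printed weights. The package keeps it for
comparison and records degenerate outcomes instead of failing the recovery
harness. The classic crisp principal eigenvector is the third route.

## Numerical choices

- **Limit computation.** Repeated squaring with convergence tolerance 1e-9
  and a cap of 64 squarings (mathematically equivalent to raising to any
  large power, deterministic stopping). Two non-generic cases are explicit:
  *nilpotent* chains — a hierarchy whose sinks keep zero columns loses all
  mass under squaring, so the last nonzero power is returned; its goal
  column holds exactly the accumulated top-down weight products, matching
  the classic hierarchy result. *Periodic* chains — when the squaring fixed
  point is not a one-step limit, the Cesàro average over the detected cycle
  is returned (e.g. the 2-cycle `[[0,1],[1,0]]` averages to uniform).
- **Sink policy.** Zero columns (elements with no outgoing influence) stay
  zero by default; `sink_policy="uniform"` replaces them with uniform
  columns for compatibility with tools that keep the chain fully
  stochastic. The two conventions answer different questions (absorbed
  top-down mass vs. a recurrent chain) and give different limits on
  hierarchies; the default preserves the hierarchy answer.
- **Aggregation is not re-symmetrized.** Reciprocity of the aggregate is a
  mathematical consequence of geometric aggregation and is *tested*, not
  enforced, so the property check is meaningful (residuals are at the
  1e-16 level).
- **Floating comparisons** use absolute tolerance 1e-9 unless stated: all
  quantities are O(1) ratios or weights.
- **Random index table**: Saaty's classic values
  (n = 3 → 0.58 … 10 → 1.49), configurable per call; an order outside the
  table is a configuration error, not a silent fallback.

## The 9-point fuzzy scale

Score `s` maps to `(max(s−δ, 1), s, min(s+δ, 9))` with `(1,1,1)` pinned and
δ = 1 by default; reciprocal scores map to the fuzzy reciprocal, making the
scale reciprocal-consistent by construction. The exact fuzzification used
for the bundled aggregate is not recoverable from its source, so the common
unit-spread convention is the default and δ is configurable everywhere
(including `scale_delta` for crisp-score CSV input and `fuzz_delta` in the
generator).

## The bundled worked example

The fixture is a 3×3 fuzzy aggregate comparison of three allocation
paradigms (Efficiency, Equity and Access, Effectiveness). Its printed
entries are rounded to 3 decimals, which is why reciprocity validation of
the fixture uses tolerance 5e-3 (the worst mirrored pair deviates by
4.1e-3, consistent with rounding entries of magnitude ≈ 3). The Buckley +
total-integral (α = 0.5) route reproduces the printed certain weights
(0.168, 0.428, 0.413) and normal weights (0.166, 0.424, 0.409) to all three
printed decimals — this reconstruction is what fixes α = 0.5 as the
default. The package computes CRm ≈ 0.017 and CRg ≈ 0.020 for this matrix;
the source's footnoted values (0.021, 0.063) cannot be reconciled with any
λ_max-based CR of the printed aggregate and may summarize per-expert
matrices that are not available, so the package reports its own values and
does not hard-match those two numbers. The reported final element weights
shipped in `reference_final_weights.csv` depend on elicited supermatrices
that are likewise unavailable; they are reference data for comparison, not
recomputation targets.

The bundled network config (3 clusters, 8 indicators, goal) marks its edge
list as a reconstruction: only the Efficiency → Equity-and-Access arrow is
documented explicitly in the source model; goal edges and inner dependence
are inferred. Structural tests treat it as one plausible topology, not as
ground truth.

## Synthetic panel generator

The generator emulates the study design behind the worked example — a panel of
14 respondents answering pairwise questionnaires on the 9-point scale — with
a known ground truth so the pipeline can be tested by parameter recovery:

- start from the perfectly consistent matrix `a_ij = w_i/w_j` (CR = 0);
- multiply each upper-triangle judgment by `exp(ε)`, `ε ~ N(0, σ²)` — the
  standard lognormal random-judgment model behind the CR framework —
  and complete the lower triangle by exact reciprocity; optionally snap to
  the nearest admissible 9-point value in log space;
- fuzzify each crisp judgment with spread δ (default 1, matching the
  elicitation scale).

Defaults: 14 experts, σ = 0.2 (moderate disagreement: individual 3×3
matrices then pass the CR gate essentially always, as elicited panels that
survive screening do), δ = 1. One root seed spawns per-expert child seeds,
so panels are bit-reproducible. What the generator does **not** emulate:
systematic expert bias, correlated opinions or consensus dynamics,
incomplete questionnaires, and panel heterogeneity — passing recovery tests
therefore shows the *pipeline* is correct under the stated noise model, not
that elicited judgments are well described by it.

Monte-Carlo test sizes (hundreds of replicates of 3×3 panels, 1,000 random
panels for the reciprocity property, ≤ 6×6 matrices for the Markov oracle)
were chosen so the full suite runs in a few seconds while keeping
Monte-Carlo error far below the effect sizes being asserted.

## Known limitations

- Trapezoidal and interval type-2 fuzzy numbers are out of scope; only the
  two defuzzifiers (total integral, centroid) are provided.
- Missing judgments are an error: there is no incomplete-matrix completion
  procedure.
- Consistency is assessed on crisp surrogates of the fuzzy matrix; fuzzy
  λ_max or interval eigenvector methods are not implemented.
- The cluster matrix defaults to equal weights over influenced clusters
  when no cluster-level comparison (`"<source> -> @clusters"` question) is
  supplied.
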