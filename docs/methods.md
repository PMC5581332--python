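# Methods

## Model

The corpus is modelled as a 3-mode sparse tensor `X ∈ R^{m×n×p}` over
terms × genes × TFs. Cell (i, j, k) holds `log2(1 + f_ijk)`, where
`f_ijk` counts occurrences of term i in the concatenated titles+abstracts
of the citations shared by gene j and TF k. The log weighting discounts
high-frequency common terms in favour of specific delineators; it maps
counts 0, 1, 3 to 0, 1, 2.

The rank-k non-negative PARAFAC (CP) model approximates
`X ≈ Σ_r λ_r (a_r ∘ b_r ∘ c_r)` with elementwise non-negative factor
matrices A (m×k), B (n×k), C (p×k). Non-negativity is what makes the
components directly interpretable: the high-magnitude entries of a column
triple are read as one transcriptional module. The underlying assumptions
are that module structure is approximately additive in the weighted-count
domain and that a gene–TF functional relationship expresses itself as
correlated term usage across the pair documents.

## Solver

* **Objective.** Frobenius-norm reconstruction error; reported as
  fit = 1 − ‖X − X̂‖_F / ‖X‖_F.
* **Updates.** Per sweep, A, B, C are updated in succession with the
  multiplicative rule `F ← F ⊙ (X_(mode) Z) ⊘ (F ZᵀZ + ε)`, Z the
  Khatri–Rao product of the other two factors. `X_(mode) Z` is evaluated
  as a sparse MTTKRP (scatter-add over nonzeros, O(nnz·k)); `ZᵀZ` via the
  Gram–Hadamard identity `(U⊙V)ᵀ(U⊙V) = UᵀU ∗ VᵀV`. The update preserves
  non-negativity and zeros exactly, and in practice the fit is monotone
  (the test suite asserts no decrease beyond 1e−6 per sweep).
* **ε = 1e−9** stabilizes the denominator against underflow. It biases a
  fixed point by a relative O(ε) amount, far below all test tolerances.
* **Initialization.** Absolute values of the k leading left singular
  vectors of each mode's unfolding, computed via the eigendecomposition of
  the mode Gram matrix `X_(mode) X_(mode)ᵀ` (mathematically the same left
  singular vectors without forming the m×np matrix). This makes runs
  deterministic. Entries below 1e−12 are floored at 1e−12 so the
  multiplicative updates are not permanently zero-locked by round-off.
  When k exceeds the numerical rank of an unfolding (singular values below
  1e−8 of the largest), the remaining columns are seeded uniform(0,1)
  noise — the only randomness in the solver, governed by `random_state`.
* **Convergence.** Stop when the absolute change in fit between sweeps
  drops below `tol` (default 1e−4), or after `max_iter` sweeps (default
  100, a guard against pathological inputs). Stopping on fit change is the
  standard CP-ALS convention; note it halts on plateaus, not only at
  optima.
* **Normalization.** Once at convergence (not per sweep), each factor
  column is scaled to unit 2-norm and the product of the three norms
  stored in λ; components are sorted by λ descending, ties kept in
  original order. All-zero columns keep λ = 0. Reconstruction is invariant
  under this renormalization.
* **Matricization conventions.** 0-based; mode-1 is m×(n·p) with column
  k·n+j (gene fastest), mode-2 is n×(m·p) with column k·m+i, mode-3 is
  p×(m·n) with column j·m+i. These are exactly the orderings under which
  `X_(1) = A diag(λ)(C⊙B)ᵀ` and its mode-2/3 analogues hold; the identity
  is asserted to 1e−10 in the tests.

Degenerate symmetric inputs deserve a note: if two planted components are
exactly exchangeable (identical sizes and intensities), the leading
singular subspace is degenerate, the initializer mixes the components, and
the multiplicative updates can stall on a symmetric saddle. Real corpora
are never exchangeable; the synthetic generator avoids the degeneracy by
giving blocks distinct intensities (below).

## Module extraction

Per component and mode the scores are sorted descending (ties broken
lexicographically by label) and truncated to an upper bound: 300 terms,
184 genes, 21 TFs by default — the gene/TF maxima observed across curated
pathway collections and an abstract-length cap for terms; all three are
overridable. On the truncated list the normalized entropy
`E = −Σ p_i log p_i / log n` (p_i the score shares; base-independent) is
computed and the number of significant entities is
`s = max(1, |{p_i > E/n}|)`. Under this reading a uniform list collapses
to s = 1, which matches the filter's purpose of isolating dominant
entries; the alternative reading with threshold `1/(n·E)` is available
via `rule="inverse"`. A component with an all-zero mode column yields a
placeholder entity and is flagged degenerate.

## Evaluation statistics

* **Enrichment**: upper-tail hypergeometric probability of the overlap
  between a module's pooled genes+TFs and a category, with the tensor's
  gene+TF label set as the default universe. Raw p ≤ 0.05 defines
  enrichment; no multiple-testing correction by default (a
  Benjamini–Hochberg flag exists in the library but is off to keep the
  statistic comparable with the raw-p convention).
* **Term AUC**: Mann–Whitney AUC of the ranked term list with the
  tokenized category names+descriptions as positives, midrank (0.5) for
  ties. Undefined (None, with a warning) when the ranking lacks positives
  or negatives. Descriptions are tokenized with the identical corpus
  tokenizer and stop list so both rankings live in one vocabulary.
* **Precision**: |module ∩ gold| / |module| over pooled genes+TFs.
  Significance versus chance uses a right-tailed Welch's t-test between
  module precisions and the precisions of random gene–TF sets with the
  same gene/TF counts (200 per module), or the fixed 8-gene + 2-TF null
  (the median module size), 1,000 replicates.
* **Redundancy / diversity**: pairwise Jaccard between module member
  sets; per-run diversity is the fraction of the tensor's entities of
  each type covered by the union of a run's modules (defined for k ≥ 2
  only; the cross-run union is reported separately by the evaluation
  summary).
* **Category prediction**: guilt-by-association proposes a module's
  unannotated members for each category enriched in it; term mapping
  ranks non-enriched categories by the overlap between the module's
  significant terms and the category's tokenized description.

## Synthetic data

`PlantedModel` plants blocks (term subset × gene subset × TF subset,
positive intensity). Two emitters exist:

* `synth_tensor` — block cells get `intensity · (1 + U(−noise, noise))`,
  plus background entries at a fraction `noise_rate` of all cells with
  small uniform values. With noise 0 a single block is an exact rank-1
  tensor and b disjoint blocks give CP-rank ≤ b.
* `synth_corpus` — every within-block (gene, TF) pair shares 2 citations
  whose bag-of-words texts draw from the block's 30-term lexicon with
  probability 1 − noise, and from filler/stop words otherwise (60 words
  per abstract); a fraction `noise_rate` of cross-block pairs share one
  filler-only citation. The gold-standard GMT's categories are the planted
  blocks. Defaults: 2–5 blocks of 10 genes and 2 TFs, noise 0.1 — module
  sizes chosen to match the median module observed downstream (8 genes,
  2 TFs is the extraction median) and a noise level at which recovery is
  imperfect-but-dominant, i.e. a non-trivial test.

Block intensities in the convenience constructor follow a decreasing
geometric profile (`intensity · 0.8^b`): real modules differ in literature
volume, the planted components acquire a well-defined λ order, and the
exact-exchangeability degeneracy described above cannot arise.

What the generator does **not** emulate: natural-language structure,
skewed gene citation-count distributions, polysemous terms shared across
modules, and overlapping module membership. Passing recovery tests
therefore demonstrates the correctness of the pipeline's mechanics and its
behaviour under idealized block structure plus uniform noise — not
performance on real MEDLINE text.

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, so the tensor and corpus emitters are
independently reproducible.

## Problem sizes and defaults

The test and reference runs use desk-scale instances: a 200×100×20 tensor
(~24k nonzeros) for the full 16-rank schedule `1, 2, 3, 5, 10, 15, 20,
25, 30, 50, 100, 200, 300, 500, 700, 900` (whose component count totals
2,861), a 50×40×10 planted rank-3 tensor for solver convergence, and a
2-block corpus (20 genes, 4 TFs, 80 terms) for end-to-end recovery. For
ranks ≥ 50 on the sweep the iteration cap is lowered to 2 sweeps: the
module-count arithmetic is independent of convergence, and overcomplete
ranks (k far above the tensor's dimensions) are exploratory
decompositions, not converged fits.

## Known limitations

* Multiplicative updates converge slowly near non-orthogonal optima; for
  dense tensors with strongly collinear components hundreds of sweeps may
  be needed to push the fit above 0.99 (the solver tests use a raised
  `max_iter` for that fixture). HALS/ANLS-style solvers are out of scope.
* The stopping rule can halt on saddle plateaus of symmetric inputs.
* Tensor rank estimation is not attempted; the rank schedule is
  exploratory by design.
* The evaluation operates on whatever GMT it is given; it does not fetch
  or version curated pathway/ontology resources.
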