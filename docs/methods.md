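# Methods

## Model

`rbpknn` treats motif inference for an uncharacterized RNA-binding protein
(RBP) as K-nearest-neighbors regression in homolog space. The assumption is
perfect co-evolution: an RBP's binding preference diverges in step with its
amino-acid sequence, so nearby homologs' motifs are unbiased, noisy
observations of the query's motif. Under that assumption the
similarity-weighted average

PWM_x(i,j) = Σ_p w^p PWM^p(i,j) / Σ_p w^p

over the K nearest homologs is a shrinkage estimator: small K tracks a close
neighbor faithfully, large K averages away per-neighbor noise at the cost of
bias toward the family consensus. Cross-validation over K resolves the
trade-off per query; when the query has no binding data at all, K defaults
to 7, an empirical average of cross-validated K values in benchmarking. Cell
weights are the raw similarities in [0, 1] — no kernel or exponent — so the
estimate is a convex combination of neighbor PWMs and probability columns
stay normalized.

### Sequence similarity

Pairwise similarity is global-alignment percent identity: identical aligned
positions divided by full alignment length, gap columns included, computed
with BLOSUM62 and affine gaps (open 10, extend 0.5 — ClustalW-like
defaults) via Biopython's pairwise aligner. The denominator choice makes the
measure symmetric and bounded. The first optimal alignment is taken, and
neighbor ties are broken by ascending identifier, so rankings are
deterministic. Externally computed similarity matrices (e.g. from an MSA)
can be injected through `SimilarityMatrix` / the TSV reader instead.

### Scan scoring

A sequence s is scored as
y = (1/|s|) Σ_{t=0..|s|−k} f(Π_l PWM[index(s_{t+l}), l]),
f(a) = arcsinh(a) for a > 1, else 0.

Two numerical consequences drive the API:

* the gate only passes window products above 1, which is possible only on
  the background-ratio scale (probability / 0.25). Probability-scale
  products of k factors ≤ 1 would make y identically zero, so
  `score_sequence` rejects probability-scale PWMs unless asked to convert.
* normalization is by sequence length |s|, not the window count |s|−k+1,
  implemented exactly as stated; for fixed-length probe sets the two differ
  by a constant factor and leave correlations and rankings unchanged.

Windows overlapping an unknown base (N) are given product 0 and are thus
removed by the gate — a conservative choice. RNA is single-stranded, so no
reverse-complement scan is performed. T is read as U everywhere.

### Mirror-tree co-evolution test

Co-evolution is the Pearson correlation between the off-diagonal upper
triangles of two matrices over the same proteins: sequence similarity and
motif similarity. Motif similarity between two equal-width PWMs is the
Pearson correlation of their flattened 4 × k matrices mapped to [0, 1] via
(r+1)/2; since all library PWMs share width 7 by construction, no offset
search is needed. The metric is pluggable (any callable PWM × PWM → [0, 1]).

Significance: the default test permutes the motif-to-protein assignment
(jointly permuting rows and columns of the motif matrix), recomputes the
statistic, and reports the add-one estimator
p = (1 + #{permuted ≥ observed}) / (1 + n_perm), which never returns 0 and
is exact under exchangeability. The parametric one-sided Student-t on the
correlation (df = n_pairs − 2) treats the n(n−1)/2 matrix entries as
independent, which they are not; it is anti-conservative and reported as a
secondary diagnostic only.

### k-mer table conversion

For logistic k-mer models, φ_m = Π_l PWM[index(m_l), l] for every k-mer m,
stored densely in lexicographic order (A < C < G < U). The products are taken
on the PWM's own scale, verbatim; for probability-scale input the table is a
product measure and sums to 1 exactly (a conservation check used in the
tests). The table freezes at construction: downstream trainers may update
the bias b and their own parameters, and `freeze_contract_check` audits —
bitwise — that φ never moved across a training step. A width guard at k ≤ 10
caps the table at ~10⁶ entries.

## Evaluation harness

* Intensities are clamped at the empirical 99.95th percentile before use.
  The cap is the order statistic at floor(q·(n−1)) rather than the
  interpolated (type-7) value: both cap exactly the same set of values
  (no datum lies strictly between consecutive order statistics), but the
  order-statistic cap makes clamping exactly idempotent, whereas an
  interpolated cap drifts downward every time it is recomputed on clamped
  data.
* Probe sets split ~50/50 into sets A and B by a seeded permutation; the
  k-mer-coverage-balanced split used in array design is not reproduced.
  Clamping is applied per experiment, before splitting.
* Continuous predictions are scored by Pearson correlation, binary
  bound/unbound labels by ROC AUC (midrank/Mann–Whitney, tie-safe, via
  scikit-learn). Methods are compared by paired Student t-tests across
  experiments, with multiple test sets of one RBP first collapsed to their
  mean.
* K selection uses 2-fold cross-validation: fold assignment is a seeded
  permutation; each candidate K's PWM (inferred from homologs only) scores
  each held-out fold, fold PCCs are averaged, and ties in the argmax go to
  the smallest K. Folds with constant scores yield undefined correlations
  and drop that candidate.

## Synthetic data generator

The generator provides seeded, fully in-memory study conditions emulating a
curated in vitro motif library plus an intensity assay.

Family: one ancestral protein (150 aa, a typical RNA-binding-region-scale
construct) and one ancestral PWM with sharp Dirichlet(0.15) columns (one
dominant base per position, ~8–12 bits over 7 positions, like motifs derived
from top-bound probes). Each of n members diverges independently with a
member-specific depth u ~ U(0,1):

* sequence: per-site substitution probability d = u · mutation_rate
  (default 0.5), substitutions drawn uniformly over the other 19 residues,
  so pairwise identities span roughly 0.5–1.0 as in a real homolog family;
* motif: redrawn from a Dirichlet centered on (1−m)·ancestral + m·uniform
  with concentration 8 / max(m, 10⁻³), where the noise magnitude is
  m = (1−c)·e + c·d, c = coevo_strength, and e ~ U(0, mutation_rate) is an
  independent draw. At c = 1 motif noise is proportional to sequence
  divergence (the KNN model's ideal); at c = 0 the two are independent (the
  mirror-tree null). m = 0 returns the ancestral PWM exactly, and m near 1
  gives near-uniform columns.

Probes: uniform-random RNA (default 2000 probes of 35 nt, inside the
30–41 nt range of array designs); the first half receives one motif
instance sampled column-wise from the PWM at a random offset (label 1);
intensity = scan score + Gaussian noise (default sd 0.1).

What the generator does not emulate: array probe design (k-mer coverage
balancing), position/flanking biases, multiple motif occurrences per probe,
heteroscedastic intensity noise, domain architecture (every member is one
"RRM/FL" protein), and real phylogenetic tree structure (star phylogeny,
not nested clades). Passing tests therefore demonstrate the estimator's
statistical behavior under its own assumptions — co-evolution strength,
noise level, neighborhood structure — not performance on any real assay.

## Numerical choices and degenerate inputs

* PWMs carry an explicit scale; probability columns must sum to 1 and
  background-ratio columns average to 1 (tolerance 1e-9). File readers snap
  rounded columns back onto the exact invariant.
* PFM → PWM: pseudocount 1 added to every count, columns normalized; wider
  matrices keep the contiguous max-information 7-column window (ties →
  leftmost; the window is chosen on pseudocount-free frequencies so the
  choice is invariant to uniform count scaling); narrower matrices are
  padded with uniform columns, extra column on the right. Information is
  log₂ against the uniform background.
* K = 1 inference returns the neighbor's PWM bit-exactly (the single
  normalized weight is exactly 1.0).
* Zero-variance inputs (flat PWMs, constant scores, identical paired
  metrics) raise `DegenerateError` rather than returning NaN; all-zero
  top-K weights likewise.
* |r| = 1 in the parametric test returns p = 0 (positive) or 1 (negative)
  rather than an infinite t statistic.

## Problem sizes

The test suite and the acceptance script run everything at desk scale: 20
replicate families of 16–20 proteins, 1000–2000 probes per experiment,
1000 permutations per test, 200–500 replicates for calibration rates. These
sizes give Monte Carlo error comfortably inside the asserted bands while
keeping a full run in the low tens of seconds to a few minutes on one CPU.

## Known limitations

* The homolog pool is not automatically restricted to one domain family or
  construct type; `filter_records` exposes the curation predicates but the
  caller decides (the benchmarking protocol implies same-family pools
  without mandating them).
* The mirror-tree test does not correct for shared speciation history; a
  stratified or user-supplied shuffle can be run through the permutation
  machinery, but no species-tree projection is built in.
* Motif averaging is cell-by-cell at a fixed width — no offset/alignment
  search between neighbor PWMs and no variable-width motifs.
* The k-mer table module guarantees the frozen-φ contract for downstream
  sequence-and-structure trainers but deliberately contains no trainer, no
  structure-context parameters, and no intensity regression of its own.
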