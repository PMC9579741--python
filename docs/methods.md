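# Methods

## Composition profiles

A library is summarised by an L × 5 table of base counts (A, C, G, T, N)
over the first L = 50 positions of read1, tabulated from a uniform
subsample of k = 100,000 reads drawn in a single pass with reservoir
sampling (Algorithm R, seeded, bit-reproducible). Reads shorter than L
contribute only up to their length, so the per-position totals equal the
number of sampled reads covering that position. Lowercase bases are
uppercased; anything outside {A, C, G, T} counts as N.

For modelling, counts become percentages per position with N excluded
from the denominator, so each position's A/C/G/T block sums to 100 and a
profile flattens to a 200-dimensional feature vector
(`pos1_A … pos50_T`). Positions are 0-based internally and labelled
1–50 in all files and plots. A position covered by no sampled read
(every read shorter) yields NaN percentages; when a database is
assembled these rows are imputed with the database-wide mean composition
at that position (with a warning), and queries are imputed with the
fitted model's stored feature means. Strict mode errors instead. This
keeps short-read libraries usable without silently fabricating
per-sample signal.

## Reference database and inclusion rules

The training set is a table of labelled feature vectors. Before
fitting, three rules are applied: samples labelled `OTHER`
(case-insensitive) are excluded; library types with fewer than 25
samples are dropped; types with more than 500 samples are reduced to
exactly 500 by seeded uniform subsampling without replacement (the rule
could equally be first-N; uniform subsampling avoids ordering artefacts
in the source table). Filtering is idempotent, logged per type
(before/after counts), and the log is persisted in a JSON sidecar next
to the database TSV.

## Embedding

The S × 200 matrix is embedded into 2-D with UMAP, Euclidean metric,
`n_neighbors = 15`, `min_dist = 8`. umap-learn requires
`min_dist ≤ spread`; `spread = 10` is the smallest round value that
makes this parameterisation valid, and both are exposed as
configuration. The embedding seed defaults to 42 and is stored in the
model file; with a fixed seed both fitting and projection are exactly
reproducible. Queries are placed by the fitted transform
(out-of-sample projection), never by refitting with the query included:
the map a library is judged against must not move with the library.

Each query is projected in its own transform call. umap-learn optimises
a batch of new points jointly, so batching queries would let them
influence each other's coordinates; per-query projection guarantees
`predict(A ++ B) = predict(A) ++ predict(B)`.

One caveat: the stochastic-gradient optimiser consumes per-row random
streams, so permuting the database rows does not permute the fitted
coordinates exactly even at a fixed seed. The recovered cluster
structure is row-order independent (tested via k-NN label purity after
permutation); exact coordinate equivariance is not claimed.

## Tiles and the type-percentage map

The embedding's bounding box, padded by 2% per side, is split into a
24 × 24 grid (the tile count is a resolution-versus-sparsity trade-off at a
few hundred reference samples and is configurable as `--tiles NX NY`).
Binning is half-open, `[edge_i, edge_{i+1})`, with the top and right
edges closed, so every in-box point maps to exactly one tile. The
per-tile percentage of type t divides the tile count by the type's
database total before normalising:

    percent[τ, t] = 100 · (n[τ,t]/N_t) / Σ_u (n[τ,u]/N_u)

which makes the map invariant to per-type database size (duplicating
every sample of one type changes nothing) — the property that lets
maps built under the 500-sample cap be read across types of very
different abundance. Empty tiles carry all-zero percentages; a query
landing in one (or off the padded box) is assigned the nearest occupied
tile by center distance (ties broken row-major) and flagged
`fallback_used` in the report.

The type-level self-consistency matrix averages, over all samples of a
type, the percentage vector of each sample's own tile; rows sum to 100,
and a high diagonal means the type occupies tiles specific to it. It is
a map-specificity summary, not a held-out classifier evaluation.

## Synthetic signatures

The generator emulates five protocol fingerprints as L × 4
row-stochastic positional base-probability matrices:

| signature  | construction | defaults |
|------------|--------------|----------|
| `genomic`  | flat rows at the genome GC: A = T = (1−gc)/2, C = G = gc/2 | gc = 41% (human), 42% (mouse) |
| `bisulfite`| C reduced to a residual, deficit added to T | residual 0.02 |
| `atac`     | genomic + zero-sum perturbation, amplitude a·d^p over positions 1–12, baseline after | a = 0.15, d = 0.7 |
| `chiapet`  | fixed 9-mer linker dominating positions 17–25 | dominant-base probability 0.88 |
| `rnaseq`   | genomic + milder start perturbation over positions 1–10, shape distinct from `atac` | a = 0.10, d = 0.8 |

The perturbations are unit-norm zero-sum direction vectors over
(A, C, G, T) cycled along the read, so rows stay stochastic and the bias
"wiggles" as real tagmentation/priming bias does. Amplitudes were fixed
once at the 5–15 percentage-point deviations routinely visible in
per-base-content QC plots of real ATAC-seq and RNA-seq libraries; they
are stylised encodings of the mechanisms, not fits to any dataset.

Database samples add per-sample variability by Dirichlet-perturbing
each row (concentration 2000, i.e. ~1 percentage-point s.d. per
feature) before drawing multinomial counts at 100,000 reads. FASTQ
simulation draws each read's bases independently per position from the
signature rows (positions beyond L reuse the last row) with constant
dummy qualities.

What this emulates — and does not. The generator reproduces the
*positional composition marginals* of each protocol with realistic
between-sample jitter. It does not model genome sequence, mappability,
quality scores, adapter read-through, sub-protocol structure (WGBS vs
RRBS vs PBAT), or the partial overlap of real RNA-seq flavours.
Synthetic types are therefore cleanly separable by construction, and the
recovery statistics (k-NN purity, confusion diagonal, held-out top-1
≈ 99–100%) demonstrate that the pipeline is correct and lossless, not
that real libraries separate this well; on public data some types
(e.g. ncRNA-seq vs miRNA-seq) genuinely co-occupy tiles.

## Numerical choices and degenerate inputs

- Percentage rows are exact to 1e-9; round trips of profiles (integer
  counts) and databases (float features via pandas shortest-repr) are
  lossless.
- Reservoir sampling, capping, jitter, multinomial draws and the
  embedding all take explicit integer seeds; every output records the
  seeds used.
- A degenerate bounding box (all coordinates identical) is an error; a
  zero span on one axis only gets a fixed 0.5 pad.
- Tile ties at interior edges go to the upper tile (half-open
  convention); nearest-occupied-tile ties go to the lowest row-major
  index.
- Batch prediction skips (with a logged error) profiles whose length
  does not match the model and continues with the rest.

## Problem sizes

The shipped tests and the acceptance script run the study conditions at
desk scale: a five-type reference database of 50 samples per type
(100,000 simulated reads each), 10 held-out queries per type, and one
250,000-read × 150 bp simulated FASTQ for the extractor checks. A full
acceptance run takes well under a minute of compute beyond the one-off
numba JIT warm-up.
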