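# libtype

Library-type quality control for sequencing data, from per-position base
composition alone.

## The problem

Before any mapping, a FASTQ file already carries a strong fingerprint of
how its library was prepared: at each read position one can count the
fraction of reads carrying A, C, G or T. A plain genomic library (or a
ChIP-seq library, most of whose reads come from non-enriched genome)
shows four flat lines at the organism's GC content. Bisulfite conversion
turns unmethylated C into T, collapsing the C curve to a few percent
along the whole read. Tn5 tagmentation (ATAC-seq) imprints a positional
bias over the first ~12 positions; ChIA-PET linkers impose a nearly
fixed sequence in the middle of the read; random priming perturbs the
start of RNA-seq reads. Checking a freshly sequenced library against the
composition expected for its protocol catches sample swaps and
preparation irregularities before any time is spent on alignment.

`libtype` turns this into an automated check:

1. **Extract** — stream a FASTQ file (read1 of paired-end data),
   reservoir-sample 100,000 reads, and tabulate base counts at the first
   50 positions.
2. **Build** — take a labelled collection of such profiles, apply
   inclusion rules (drop the `OTHER` label, drop types with fewer than
   25 samples, cap over-represented types at 500), and embed the
   S × 200 matrix of per-position A/C/G/T percentages into 2-D with
   UMAP (`n_neighbors = 15`, `min_dist = 8`, `spread = 10`) — the
   *reference map*. The map is split into a 24 × 24 grid of tiles, and
   each tile τ gets imbalance-corrected library-type percentages

   $$P(\tau, t) = 100\cdot\frac{n_{\tau t}/N_t}{\sum_u n_{\tau u}/N_u},$$

   where $n_{\tau t}$ is the number of type-$t$ samples in the tile and
   $N_t$ the type's database total. Dividing by $N_t$ makes the
   percentages invariant to how many samples of each type the database
   happens to hold.
3. **Query** — project a test library onto the fixed map
   (out-of-sample UMAP transform, never a refit), find its tile, and
   report $P(\tau, t)$ for every library type: "the percentage of each
   library type found in this library's map tile". This is a similarity
   readout, not a calibrated classifier — a surprising mix is a red
   flag to investigate, not a verdict.

Because the public composition collections such maps are normally built
from cannot be redistributed here, the package ships a first-class
synthetic generator (`libtype simulate`) that emulates five protocol
signatures — `genomic`, `bisulfite`, `atac`, `chiapet`, `rnaseq` — as
positional base-probability models, and can emit both labelled profile
databases and raw FASTQ files from them.

## Worked example

Build a reference map from a simulated database and query a library of
undisclosed origin against it:

```bash
libtype simulate --db db.tsv --n-per-type 50 --seed 0
libtype build db.tsv --out reference
libtype simulate --fastq-type bisulfite --fastq-out mystery.fastq --reads 100000 --seed 9
libtype query mystery.fastq --model reference/model.joblib --grid reference/grid.json --out qc
```

The query step prints

```
INFO libtype: mystery -> tile (14, 2), top type bisulfite (100.0%)
INFO libtype: wrote 7 output files to qc
```

and `qc/predictions.tsv` contains

```
sample_id  x       y        tile_x  tile_y  fallback_used  atac  bisulfite  chiapet  genomic  rnaseq
mystery    12.932  -50.612  14      2       False          0.0   100.0      0.0      0.0      0.0
```

meaning the test library landed at map coordinates (12.9, −50.6), in
tile (14, 2), a tile occupied exclusively by bisulfite-type libraries —
the library's composition is fully consistent with a bisulfite
preparation. `fallback_used` would be `True` had the query landed in an
empty tile and been assigned the nearest occupied one (a low-confidence
answer). The directory also holds the reference-map scatter, per-type
tile probability maps and a query × type heatmap as SVG and PNG.

The same pipeline is available as a library API
(`profile_fastq`, `filter_database`, `fit_reference_map`, `build_grid`,
`predict`, `render_report`); see the module docstrings.

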