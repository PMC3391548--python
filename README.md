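# pyroqc

Quality-score refinement and diversity analysis for SSU rRNA amplicon
pyroreads (454-style), with a built-in seeded read simulator so every
pipeline stage is testable without external data.

## What it does

- **seqio** — reads/writes FASTA + paired `.qual` (whitespace-separated
  integer Phred scores, the native 454 convention) and Phred+33 FASTQ,
  with transparent gzip. Quality values outside 0–40 are rejected, not
  clipped.
- **refine** — the refinement pipeline in fixed stage order
  *length → quality → ambiguous (N) → primer*:
  - length trimming to `floor(mean − sample sd)` of the raw lengths
    (reads shorter are removed, survivors truncated from the 5′ end);
  - quality filtering in *fraction* mode (keep a read iff at most a
    given fraction of bases have Q strictly below the cutoff, e.g.
    Q27 with a 15% allowance) or *end-trim* mode (truncate at the first
    sub-threshold base, then length-filter);
  - removal of reads with ambiguous bases or 5′ primer mismatches
    (IUPAC-degenerate, zero mismatches tolerated, optional stripping);
  - a `RemovalLedger` accounting for every read at the earliest failing
    stage (conservation: raw = removed + remaining).
- **otu_cluster** — pairwise alignment distances (mismatches + internal
  gap columns over aligned columns, terminal overhangs excluded) and
  deterministic complete-linkage clustering cut at a distance threshold
  (0.03 = 97% similarity). Ties are broken by lexicographically smallest
  member id, so the partition is independent of input order.
- **diversity** — analytic (hypergeometric) rarefaction, Chao1 with a
  95% log-normal confidence interval, Shannon H (natural log) and
  Pielou's evenness.
- **bias** — pre/post-filter taxon fraction comparison with R² against
  the identity line y = x, and attribution of removed reads to their
  pre-filter clusters.
- **homopoly** — maximal homopolymer run detection and tabulation by
  base and length bin (4, 5, 6, 7, 8, >8).
- **simdata** — seeded mock-community simulator: divergent templates
  carrying a concrete primer realization, reads with declining quality,
  isolated low-Q spikes, Phred-linked substitutions (P = 10^(−Q/10)),
  homopolymer ±1 length errors, and a configurable fraction of globally
  degraded reads; full per-read ground truth.
- **pipeline / CLI** — grid orchestration across filter conditions
  (two no-Q baselines plus the cutoff × fraction cross product) with
  TSV/JSON reports.

## CLI

```sh
# simulate a community with ground truth
pyroqc simulate --seed 7 --n-templates 10 --n-reads 500 --frac-bad-reads 0.2 \
    --out-prefix sim

# refine at Q27 with a 15% allowance
pyroqc refine --fasta sim.fasta --qual sim.qual \
    --q-cutoff 27 --fraction 0.15 --out-prefix refined

# cluster at 97% similarity and estimate diversity
pyroqc cluster --fasta refined.fasta --qual refined.qual --out otus.tsv
pyroqc diversity --otu-table otus.tsv --out diversity.tsv

# homopolymer table
pyroqc homopoly --fasta sim.fasta --qual sim.qual --out homopolymers.tsv

# the full condition grid with summary tables
pyroqc grid --fasta sim.fasta --qual sim.qual --out-dir results/ \
    --bias-condition Q27_15pct
```

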