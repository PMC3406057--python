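# pooledseq

Simulation and accuracy assessment of pooled-sequencing (Pool-seq) allele
frequency estimation.

Pool-seq estimates population allele frequencies from the read fractions of
a single library made from many pooled individuals. This package provides a
tested pipeline to ask how accurate those estimates are:

- **`synthetic_data`** — generate panels of homozygous (isogenic) strains
  from a configurable site frequency spectrum, draw per-strain DNA
  contribution weights (symmetric Dirichlet, or exactly equal), and simulate
  pooled read counts with truncated-Poisson or empirical depth models and
  optional per-read sequencing error.
- **`pool_freq`** — turn read counts into frequency estimates behind a
  minimum-depth filter (default 10x), merge libraries at the read level,
  and intersect site sets across libraries.
- **`accuracy`** — Lin's concordance correlation coefficient, the squared
  relative-error statistic, frequency-binned resampling (20 bins of 5%,
  50 sites per bin, 1,000 sites per replicate, 100 replicates), and the
  binomial-expectation simulation giving the best-case accuracy at observed
  depths; estimate-vs-truth and replicate-vs-replicate comparison modes.
- **`contributions`** — estimate each strain's DNA share in a pool from the
  pooled frequencies of its private SNPs (mean ± 2 SD over resampling
  replicates).
- **`discovery`** — a transparent binomial-test SNP caller and false
  positive / false negative rates by folded-frequency bin, against either a
  source population or only the pooled strains.
- **`experiment` / `cli`** — orchestrated library families (small pool,
  replicate pairs, read-merged larger pools) and a strains-pooled vs
  concordance sweep.

## CLI

All subcommands take `--seed` and write a JSON run log (parameters, version,
timings) next to their outputs.

```bash
# strain panel -> pooled counts -> accuracy report
pooledseq simulate-panel --strains 92 --sites 100000 --seed 1 --out panel.tsv
pooledseq simulate-pool  --panel panel.tsv --depth 40 --concentration 20 \
                         --seed 2 --out pool.tsv
pooledseq evaluate-accuracy --counts pool.tsv --panel panel.tsv \
                            --seed 3 --out accuracy.tsv

# replicate mode: pass a second library with --counts2
pooledseq evaluate-accuracy --counts b1.tsv --counts2 b2.tsv --panel panel.tsv \
                            --seed 3 --out replicate.tsv

# per-strain DNA shares from private SNPs
pooledseq estimate-contributions --panel panel.tsv --counts pool.tsv \
                                 --seed 4 --out contributions.tsv

# SNP discovery error rates by folded-frequency bin
pooledseq assess-discovery --panel panel.tsv --counts pool.tsv \
                           --out discovery.tsv

# the full library family (22/42/50/92-strain pools, merges, replicate pair)
pooledseq run-experiment --seed 1 --out runs/default
```

`run-experiment` accepts a YAML config (`--config`); a resolved copy of the
configuration is written next to the outputs for provenance. Counts can be
written as TSV or PoPoolation-style sync (`--format sync`).

## File formats

- panel TSV: `site_id, truth_freq, strain_1..strain_N` (0/1 genotypes)
- counts TSV: `site_id, nonref, depth, library_id`
- sync: `chrom, pos, ref, A:T:C:G:N:del` per library
- minimal VCF reader (AD allelic depths, biallelic records, needs pysam)
  and writer for called sites
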