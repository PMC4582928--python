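# divscan

Relative (θ̂ / F_ST) and absolute (d_xy) genomic divergence scans for
multi-sample diploid genotype data from hybrid zones, with:

- **Weir–Cockerham variance components** per site (two populations,
  unequal sample sizes, observed heterozygosity, any number of alleles),
  combined across sites and comparisons as a ratio of sums;
- **absolute divergence** d_xy per site from sample allele frequencies,
  combined as a mean;
- a **75% per-taxon genotyping filter** applied per comparison pair;
- **sliding-window scans** (15-kb windows, 5-kb steps, ≥20% coverage by
  default) that aggregate exactly to region-level estimates;
- **bootstrap baselines**: background divergence from intervals unlinked
  to the focal locus, with percentile CIs from 1000 position resamples;
- **divergence decay** with recombination distance from the center of a
  functional interval (constant-rate 1430 cM / 400 Mb map, 0.01-cM bins,
  loess smoothing for presentation);
- the **comparison design** of a five-hybrid-zone study: four
  within-species parapatric pairs, one between-species pair, and
  allopatric groups of exactly 9 / 6 / 3 race pairs;
- a **Balding–Nichols synthetic data generator** with a configurable
  divergence peak, so every stage has a closed-form recovery target.

## CLI

```bash
# simulate a two-population dataset with a divergence peak
divscan simulate --out sim.vcf --truth truth.tsv --seed 1

# validate inputs and report sample/region counts
divscan load --vcf sim.vcf --samples samples.tsv --regions regions.tsv

# full pipeline: filter, per-site tables, windows, baseline + CI, decay
divscan all --config run.yaml

# individual stages
divscan scan --config run.yaml
divscan baseline --config run.yaml
divscan decay --config run.yaml --bin-cm 0.01 --span 0.3
```

`run.yaml` holds `RunConfig` keys (`vcf`, `samples`, `regions`, `outdir`,
`window_size`, `window_step`, `min_coverage`, `missing_threshold`,
`bootstrap_reps`, `ci_level`, `bin_cM`, `map_length_cM`, `genome_size_mb`,
`comparisons`, `seed`); CLI flags override the file.  `comparisons: auto`
enumerates the parapatric pairs from the sample table; otherwise list
explicit `{id, taxonA, taxonB}` entries.  Every output directory gets a
`config.json` echo, a `run.log`, per-site/window/baseline/decay TSV
tables and a plain-text report; reruns with the same config and seed are
byte-identical.

### Input formats

- **VCF v4.x** genotypes (uncompressed or indexed); indels are dropped at
  read time, multiallelic SNP records are kept with all alleles,
  half-calls count as missing.
- **samples.tsv**: `sample_id  taxon  hybrid_zone  phenotype_class  role`
  (phenotype_class ∈ postman/rayed/himera/outgroup).
- **regions.tsv**: `name  contig  start  end  flags` with 1-based
  inclusive coordinates and flags from
  {color_locus, functional, unlinked}.

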