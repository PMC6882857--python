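# phasekit

Statistical haplotype phasing for multi-sample diploid genotype panels.

The engine samples each individual's haplotype pair from a diploid
Li–Stephens model run over a compact *genotype graph* (segments of at most
three heterozygous genotypes, merged and pruned as the MCMC converges).
The conditioning haplotypes are selected with a positional Burrows–Wheeler
transform (PBWT): the arrays are interrogated every eight variants for the
`P` nearest long-prefix matches, and the reports over a 2 Mb sliding window
are collapsed into a small, data-adaptive set of `K` distinct haplotypes.
The MCMC runs a fixed schedule of burn-in, pruning and main iterations
(default `5b,1p,1b,1p,1b,1p,5m`, i.e. 15 iterations with 3 pruning stages);
main-iteration transition posteriors are averaged into the final solution.

Additional layers of phase information are integrated:

* **Reference panels** — phased haplotypes appended to the PBWT so the
  conditioning set can copy from them.
* **Haplotype scaffolds** — pre-phased heterozygous genotypes enforced as
  hard constraints (inconsistent graph configurations are pruned).
* **Phase sets** (VCF `FORMAT/PS`, from read-backed haplotype assembly) —
  probabilistic constraints with a configurable error rate
  (default 1e-4); the scaffold always has priority over reads.
* **IBD2 protection** — a tri-allelic PBWT-style genotype-match scan flags
  individual pairs sharing both haplotypes across a whole window; such
  pairs never condition on each other.

A synthetic-data module (`phasekit.evalsim`) generates mosaic founder
populations with known truth, trios, planted phase sets/scaffolds, and the
switch-error metrics, so the whole tool is testable offline.

## CLI

```sh
phasekit --input unphased.vcf --output phased.vcf \
         --map genetic_map.txt --seed 1 \
         [--region chr:start-end] [--reference ref.vcf] \
         [--scaffold scaffold.vcf] [--use-ps 0.0001] \
         [--pbwt-depth 4] [--pbwt-modulo 8] [--window 2000000] \
         [--mcmc-iterations 5b,1p,1b,1p,1b,1p,5m] [--ne 15000] [--log run.log]
```

Input is plain or gzipped VCF with `GT` (and optionally `PS`); 5%
missingness QC is applied to variants, then individuals.  Output is a
phased VCF with a per-genotype phasing-certainty field (`PP`).  Runs are
deterministic for a given seed.

## Library sketch

| module           | contents                                                         |
|------------------|------------------------------------------------------------------|
| `io_formats`     | VCF/scaffold/genetic-map readers, QC, panel intersection, writer |
| `pbwt`           | prefix/divergence/locator arrays, neighbour queries, IBD2 scan, PBWT-guided initialization |
| `genotype_graph` | segmentation, scaffold pruning, phase-set weighting, merging     |
| `lsm`            | diploid Li–Stephens forward–backward, sampling, final solve      |
| `engine`         | windows, MCMC schedule, per-individual updates, ligation         |
| `evalsim`        | mosaic simulator, trio phasing, switch-error metrics, fixtures   |

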