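# trild

Three-locus (third-order) linkage disequilibrium for biallelic SNPs:

- **`trild.ld_core`** — canonical parameterization of a three-locus system:
  conversion between the 8 haplotype frequencies and (allele frequencies,
  pairwise LD, third-order LD), exact admissible bounds of the third-order
  coefficient, range-based normalization, and the third-order proportion
  `beta = |d123| / (|d123| + |d12| + |d13| + |d23|)`.
- **`trild.admixture`** — LD generated by crossing two populations: a
  closed-form decomposition of the cross plus an independent
  haplotype-mixing route, and the nine reference scenarios.
- **`trild.recombination`** — deterministic one-generation recursion of the
  haplotype frequencies under random mating without interference, and
  multi-generation decay trajectories.
- **`trild.em_estimator`** — EM estimation of the 8 haplotype frequencies
  (hence all LD parameters) from unphased joint-genotype counts, the
  multinomial log-likelihood, and a full-vs-allele-frequencies
  likelihood-ratio test (chi-square, 4 df, asymptotic).
- **`trild.io_scan`** — PLINK `.ped`/`.map` and VCF input, MAF/call-rate
  filters, and three scan designs over SNP triplets (consecutive,
  inter-chromosomal, all-triplets-in-window) with per-triplet records and a
  distance–LD summary.
- **`trild.synth`** — seeded synthetic data: HWE triplet genotypes,
  Wright–Fisher drift with recombination, admixed cohorts, and multi-SNP
  panels drawn from founder haplotype pools (small pools give strong
  multi-locus LD; per-interval founder switching gives distance-decaying LD).

Conventions: allele "1" is the first-listed allele of the input (first
allele seen in a `.ped`, REF in VCF); genotype codes are 1 = hom "1",
2 = hom "2", 3 = het, 0 = missing. All LD signs are orientation-dependent;
relabeling alleles at one locus flips the sign of the third-order
coefficient and of the two pairwise coefficients involving that locus.

## CLI

```sh
# cross two populations (file with two lines: f1 f2 f3 d12 d13 d23 d123)
trild admix parents.txt --tau 0.5

# recombination break-up from a haplotype-frequency file (8 labeled lines)
trild decay --c12 0.01 --c23 0.01 --generations 100 --start haps.txt

# EM fit of one triplet from a count table (g1 g2 g3 count) or call matrix
trild estimate --counts counts.tsv

# synthetic panel, then genome scans
trild simulate --samples 300 --chroms 18 --snps-per-chrom 50 --seed 1 --out panel
trild scan --ped panel --mode consecutive --out scan.tsv
trild scan --ped panel --mode inter --seed 2 --out inter.tsv
trild scan --ped panel --mode window --chromosome chr1 --window 40 --out win.tsv
```

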