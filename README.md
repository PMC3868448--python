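# navdup

Duplication-aware genotyping analyses for a two-site voltage-gated
sodium-channel (kdr) locus in *Aedes aegypti*.

Allele-specific PCR reports the *presence* of each variant, not its dosage,
so a tandem gene duplication that pairs a wild-type and a mutant copy on one
chromosome is typed as an ordinary heterozygote. `navdup` implements the
chain of inferences that exposes such a duplication from standard assay
outputs:

- **`locus_model`** — haplotypes (1011 allele + intron-20 class + 1016
  allele), single/duplicated chromosome units, diploid genotypes, Mendelian
  gamete distributions, and the presence/absence masking operator that maps
  genotypes to observable molecular phenotypes.
- **`hwe_analysis`** — haplotype-frequency estimation (gene counting, with
  an EM fallback for non-uniquely-decodable unit sets) and a multinomial
  chi-square Hardy–Weinberg fit test on six-category phenotype tables.
  Duplication signatures: missing mutant homozygotes, heterozygote excess.
- **`cross_analysis`** — expected F1/F2 offspring distributions under the
  competing parental constitutions (plain heterozygote vs. duplication
  homo-/heterozygote), with exact two-sided Fisher tests of observed vs.
  expected counts and star significance codes.
- **`clone_typing`** — per-specimen haplotype profiles from sequenced clones
  (CSV calls, or FASTA plus a YAML diagnostic-rule config); specimens with
  three haplotypes are flagged as duplication evidence.
- **`copy_number`** — TaqMan comparative-CT arithmetic: per-replicate ΔCT,
  per-assay means, ΔΔCT against a calibrator lineage, and diploid copy
  number `cn_ref · 2^(−μ[ΔΔCT])`.
- **`synthetic_data`** — seeded generators for all four input kinds
  (random-union populations, crosses, clone reads with error, qPCR plates).
- **`datasets`** — the bundled published inputs (survey table, 40 clone
  profiles, cross outcomes, qPCR per-assay means) used by the CLI fixtures
  and the acceptance report.

## CLI

Every analysis writes a full-precision CSV plus a human-readable markdown
table; simulators write the exact CSV dialects the analyses consume.

```sh
# export a bundled dataset, then analyse it
navdup datasets survey --output survey.csv
navdup hwe --input survey.csv --output hwe_report.csv

navdup datasets crosses-f1 --output crosses.csv
navdup cross --input crosses.csv --output verdicts.csv

navdup datasets clones --output clones.csv
navdup clones --input clones.csv --output profiles.csv

navdup datasets qpcr-means --output means.csv
navdup cnv --input means.csv --means --output cnv.csv

# simulate then analyse (deterministic given --seed)
navdup simulate population --preset survey:Fortaleza,R --n 200 --seed 1 --output sim.csv
navdup hwe --input sim.csv --output sim_report.csv
navdup simulate qpcr --copies 'Rock=2,EE=10,Hyb=6' --noise-sd 0.05 --seed 1 --output wells.csv
navdup cnv --input wells.csv --output sim_cnv.csv
```

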