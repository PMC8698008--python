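# haplodeficit

A reverse genetic screen for deleterious recessive haplotypes in pedigreed,
SNP-genotyped populations. The package scans phased genotypes with sliding
marker windows, flags haplotypes whose homozygotes are significantly
depleted (an exact Hardy-Weinberg deficit test with Benjamini-Yekutieli
FDR correction), merges significant windows into candidate regions extended
by 2 Mb, and links each region to protein-changing variants in a sequenced
carrier panel via r² between diplotype state and genotype dosage. A
gene-drop simulator with plantable recessive-lethal haplotypes makes the
whole pipeline testable without proprietary breeding data.

## Modules

| Module | Purpose |
| --- | --- |
| `haplodeficit.simdata` | Gene-drop simulator (Haldane crossovers, 1 cM/Mb), embedded lethal haplotypes with configurable penetrance, sequenced carrier panel, exports to phased VCF / TSV |
| `haplodeficit.genodata` | VCF + pedigree loading, QC (animal call rate ≥ 0.8, SNP call rate ≥ 0.99, MAF ≥ 0.01), trio & parent-grandparent (pgp) cohort construction, Mendelian trio phaser |
| `haplodeficit.hapscan` | Sliding-window haplotype enumeration, exact one-sided HWE deficit test, BY correction, deficient-homozygosity regions with per-animal diplotypes |
| `haplodeficit.linkvar` | Protein-changing consequence filter (14 SO terms), diplotype-vs-dosage r², candidate screening, codon / frameshift helpers |
| `haplodeficit.cli` | `haplodeficit simulate | scan | link | all` with YAML config and run manifests |

## Command line

```bash
# simulate a demo population with one embryonic-lethal haplotype
haplodeficit simulate --config config.yaml --seed 1 --out sim/

# QC + cohorts + scan; writes qc_report.tsv, regions.tsv, manifest
haplodeficit scan --config config.yaml --vcf sim/genotypes.vcf \
    --pedigree sim/pedigree.tsv --mode trio --out scan/

# candidate variants in the extended regions (r² = 1 by default)
haplodeficit link --config config.yaml --vcf sim/genotypes.vcf \
    --regions scan/regions.tsv --panel-vcf sim/panel.vcf --out link/

# or everything in one go
haplodeficit all --config config.yaml --seed 1 --out run/
```

Exit codes: 0 success, 1 usage error, 2 data error. A sample config:

```yaml
simulate:
  n_chromosomes: 1
  markers_per_chromosome: 160
  chromosome_length_bp: 16000000
  n_founders: 200
  n_generations: 1
  matings_per_generation: 450
  offspring_per_mating: 4
  n_ancestral_haplotypes: 25
  lethal_loci:
    - {chromosome: 0, center_marker: 80, span_markers: 90,
       target_carrier_frequency: 0.085, penetrance: 1.0,
       linked_variant_offset_bp: 12345}
scan:
  window_size: 50
  alpha: 0.05
  cohort_mode: trio     # trio | pgp | both
  expected_mode: hwe    # hwe | transmission
link:
  r2_threshold: 1.0
  n_carriers: 4
  n_background_variants: 15
```

## File formats

* **Genotypes**: VCF 4.2, biallelic SNPs, phased GT (`0|1`); unphased
  heterozygotes (`0/1`) are accepted and resolved by the trio phaser where
  parental genotypes force the phase.
* **Pedigree**: TSV with header `animal_id sire_id dam_id sex`
  (`0` = unknown parent; sex 1 male, 2 female, 0 unknown).
* **Marker map**: TSV `marker_id chrom pos_bp` (1-based positions).
* **Truth** (simulator output): TSV `locus_id chrom start_marker end_marker
  start_bp end_bp allele_string variant_pos penetrance target_frequency`.
* **Panel**: VCF with a SnpEff-style `ANN` INFO field, or a sidecar TSV
  `chrom pos ref alt gene transcript consequence c_dot`.
* **Region report**: TSV with columns `region_id approach chrom start_bp
  end_bp length_mb observed expected deficiency_pct freq p p_adj ...` plus
  the top window's marker ids and haplotype so the link stage can rebuild
  diplotypes.

## Statistical notes

* The exact deficit test conditions on the focal-haplotype allele count
  `n_A = 2·n_AA + n_AB` within the tested cohort; configurations with the
  same `n` and `n_A` are weighted ∝ `n!·2^n_AB / (n_AA!·n_AB!·n_BB!)` and
  the one-sided p-value is `P(homozygotes ≤ observed)`. Computation is in
  log space and exact for any cohort size.
* BY adjustment uses the step-up rule with the harmonic factor
  `c(m) = Σ 1/k`, valid under arbitrary dependence between window tests;
  the correction family is all (window, haplotype) tests of one cohort run.
* Haplotype frequencies and Hardy-Weinberg expectations (`E = n·q²`) are
  computed on all analyzed animals with complete window data; the cohort
  structure determines which offspring enter the exact test. A
  `transmission` mode instead accumulates per-offspring homozygosity
  probabilities from ancestor diplotypes.
* Deficiency is `100·(E − O)/E`; a haplotype never seen homozygous scores
  exactly 100%.

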