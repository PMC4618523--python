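# bsacross

Bulk-segregant mapping of higher-order cryptic genetic interactions in the
BY × 3S yeast cross.

## The problem

In a cross between the lab strain BY4716 ("BY") and a derivative of the
clinical isolate 322134S ("3S"), colony morphology on ethanol medium is
normally smooth. A spontaneous truncation of *IRA2* (ira2Δ2933), a negative
regulator of the Ras pathway, acts as a *phenotypic capacitor*: in specific
recombinants it uncovers cryptic variants at six genes — *END3*, *FLO8*,
*MGA1*, *MSS11*, *SFL1*, *TRR1* — that have no visible effect on their own.
The rough phenotype appears only in segregants carrying one of two specific
multi-locus allele combinations together with the lesion:

* **five-way**: *END3*^BY *FLO8*^3S ira2Δ2933 *MSS11*^BY *TRR1*^3S
* **six-way**: *END3*^3S *FLO8*^3S ira2Δ2933 *MGA1*^BY *MSS11*^BY *SFL1*^BY

Deleting the transcriptional repressor *SFL1* acts as a second capacitor:
in a BY × 3S *sfl1*Δ cross, rough segregants carry *END3*^BY *FLO8*^3S
*MSS11*^BY *TRR1*^3S.

`bsacross` implements, end to end, the genetics and the mapping statistic
used to dissect this system:

1. **Cross simulation** — haploid segregants over dense biallelic SNP maps
   (36,756 SNPs on 16 chromosomes at full scale), meiosis under the Haldane
   (no-interference) model, backcross pedigrees ((BY×3S)×3S)×BY and
   ((BY×3S)×3S)×3S, and engineered lesions (ira2Δ2933, *sfl1*Δ) that
   segregate like alleles.
2. **Trait rules** — penetrance rules mapping allele combinations plus a
   capacitor background to SMOOTH / BUMPY / ROUGH, with exhaustive
   enumeration as a built-in oracle.
3. **Pooled sequencing** — equimolar pools of phenotype-selected
   segregants, Poisson depth, symmetric miscall errors.
4. **Locus mapping** — per-SNP 3S-allele frequency f = n₃ₛ/(n₃ₛ+n_BY),
   running windows of 10 SNPs (step 1), loci called where window means
   reach ≥ 95% (3S-fixed), ≤ 5% (BY-fixed), or where a segregating
   engineered lesion is fixed (MUTANT), with intervals delimited to the
   smallest region spanned by qualifying windows.
5. **Exact class expectations** — e.g. that five-way rough segregants
   should arise exactly twice as often as six-way ones, because the
   five-way genotype constrains one fewer freely segregating locus:
   P₅/P₆ = (1/2)⁴ / (1/2)⁵ = 2.

It is aimed at quantitative/statistical geneticists who want a testable,
data-free model of BSA-seq locus recovery under higher-order epistasis,
and it doubles as an analysis tool: real per-SNP allele-count tables (TSV)
or a samtools mpileup stream plus a SNP list can be fed straight into the
mapper.

## Worked example

Exact interaction-class expectations in the BY × 3S ira2Δ2933 cross:

```text
$ bsacross expect --scheme byx3s-ira2mut
scheme  BYx3S_IRA2MUT
P(FIVE_WAY)     0.03125
P(SIX_WAY)      0.015625
P(OTHER)        0.953125
P(FIVE_WAY|ROUGH)       0.666667
P(SIX_WAY|ROUGH)        0.333333
P(OTHER|ROUGH)  0
P(ROUGH)        0.046875
five_to_six_ratio       2
```

Reading: among all segregants, 1/32 carry the five-way genotype and 1/64
the six-way one (ratio 2); 3/64 of segregants are rough, and among rough
ones two thirds are five-way.

Simulate a BY × 3S *sfl1*Δ cross, pool 44 rough segregants, sequence at
100×, and map:

```text
$ bsacross simulate-pools --scheme byx3s-sfl1del --pool-size 44 --seed 4 --out-dir demo
$ bsacross map-loci --counts demo/counts.tsv --map demo/markers.tsv --out-prefix demo/loci
$ cat demo/loci.tsv
# bsacross 0.1.0
# window_snps=10
# fix_threshold=0.95
# coordinates=1-based inclusive
chrom   start_bp  end_bp  fixed_allele  mean_freq  n_markers  pool  genes
IV      42913     80805   3S            0.981133   117        pool  TRR1
V       19        30767   3S            0.984091   96         pool  FLO8
XIII    53        38721   BY            0.988698   124        pool  MSS11
XIV     17010     42272   BY            0.973022   78         pool  END3
```

The four called loci are exactly the four genes the *sfl1*Δ rough rule
constrains: *TRR1* and *FLO8* fixed for the 3S allele, *MSS11* and *END3*
fixed for BY. A BED6 file (0-based half-open) is written alongside.

The same pipeline is available as a library (`bsacross.simulate_cross`,
`bsacross.map_backcross_pools`, …); see `docs/methods.md` for the model
details and `examples/` for a rule-set YAML.

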