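# Methods

## Genetic model

A segregant is a haploid mosaic of the two parental genomes (BY, 3S) over
an ordered biallelic SNP map. Meiosis follows the Haldane model: per
chromosome, the number of crossovers is Poisson-distributed in the genetic
length (Morgans), crossover positions are uniform on the genetic map, and
the gamete alternates between parental strands from a fair random start.
There is no crossover interference, gene conversion, or aneuploidy.
Genetic positions derive from physical positions at a constant density
(default 0.4 cM/kb, a typical genome-wide yeast figure; configurable).

Engineered lesions — the spontaneous ira2Δ2933 truncation and the *sfl1*Δ
deletion — are modelled as states attached to their gene's marker and are
transmitted with whichever strand the gamete inherits there, i.e. they
segregate exactly like alleles. In the ira2Δ2933 cross the lesion rides
the 3S copy of *IRA2*, matching how it arose.

Cross schemes cover the study designs: BY × 3S wild type, BY × 3S with
ira2Δ2933 on the 3S founder, BY × 3S with *SFL1* deleted in both founders
(so the deletion does not segregate), and the two backcrosses of a
recombinant founder segregant to BY or 3S. In a backcross, markers where
the founder matches the recurrent parent are monomorphic and carry no
mapping information.

An optional viability hook models allele-dependent survival during spore
isolation (`simulate_cross(..., viability_bias={gene: {origin: p}})`).
There is evidence for a BY-favouring viability locus linked to *END3* in
the real system, but its strength is unquantified, so no bias is applied
by default and no result here depends on it.

## Trait rules

Phenotype is assigned by an ordered list of penetrance rules; each rule
names a capacitor background (ira2Δ2933, sfl1Δ, or none), required
parental origins at causal genes, a phenotype (ROUGH or BUMPY), and a
penetrance in [0, 1]. The first matching rule fires with probability equal
to its penetrance; anything else is SMOOTH. The default set holds the
three characterised interactions (five-way, six-way, sfl1Δ; see README) at
penetrance 1. The default rules are mutually exclusive (the five- and
six-way genotypes differ at *END3*), so rule order does not matter for
them; this is tested. A brute-force enumerator over all 2⁶ cryptic-gene
combinations per background serves as an independent oracle for the
classifier: 6 rough combinations under ira2Δ2933 (4 five-way, 2 six-way),
4 under sfl1Δ.

The BUMPY class is representable but ships with no default rule — no
genotype is established for it. The single exceptional rough *sfl1*Δ
genotype (*TRR1*^BY instead of ^3S) is not in the default set either,
since several explanations are possible for one individual; an optional
low-penetrance version is provided in `examples/rules_with_sfl1_exception.yaml`.

## Pooling and sequencing

Selected segregants are pooled exactly equimolar (the wet protocol mixes
equimolar stationary cultures), so the true pooled 3S frequency at a
marker is the fraction of pooled haploids with 3S origin there. Optional
per-strain abundance noise (gamma-distributed weights with a chosen CV)
defaults to off. Sequencing is emulated per marker: depth ~
Poisson(mean coverage); each read reports the true pooled allele with
probability 1 − e and otherwise one of the three other bases uniformly, so
BY↔3S cross-contamination occurs at e/3 and 2e/3 of errors land in an
`other` tally that the frequency estimator excludes from its denominator.
The default e = 0.005 is a nominal figure; the real data's error rate was
not reported, only that small deviations from fixation traced to
sequencing/mapping errors. Engineered lesions get a separate mutant-read
count at their marker (binomial in the site's depth), the pooled analogue
of detecting a deletion directly from alignments — this is what keeps
ira2Δ2933 mappable in the 3S backcross, where the surrounding SNPs do not
segregate.

## Locus mapping

Per-SNP 3S frequency: f = n₃ₛ / (n₃ₛ + n_BY); markers with fewer
informative reads than `min_depth` (default 1) are missing. Windows hold
`window_snps` = 10 consecutive informative markers on one chromosome, step
one marker ("running windows"); missing or masked markers are skipped, not
interpolated. A window qualifies where its mean is ≥ 0.95 (3S) or ≤ 0.05
(BY); maximal runs of qualifying windows become locus calls, delimited to
the span from the first to the last member marker of their windows.
Threshold comparisons are inclusive. A segregating engineered lesion whose
mutant fraction reaches the threshold converts the covering call to
MUTANT, or is emitted as a single-marker MUTANT call where no SNP window
covers it.

Two non-obvious choices deserve explanation:

**Shoulder merging (`merge_gap_cm`, default 10 cM).** Around a truly fixed
site the expected frequency at a linked marker decays as 1 − r (Haldane),
crossing 95% near 5 cM and 90% near 11 cM. With pools of tens of
segregants the realized pooled frequency is a slowly-mixing random walk
around that expectation (sampling SD ≈ 0.03–0.06), so window means
repeatedly cross the threshold throughout the belt where the expectation
sits within ~2 SD of it. Without merging, one locus fragments into several
same-sign runs separated by brief dips. Runs of the same sign closer than
`merge_gap_cm` are therefore one locus. The default equals the ~10 cM
excursion belt implied by the noise analysis; it is far smaller than any
inter-locus distance in the study system at real genome scale.

**Backcross report keyed by causal-site overlap.** Reciprocal backcross
pools are mapped independently (each masked to the markers segregating in
that cross) and merged into one report with one row per causal site
covered by a call in either pool — the interval is the intersection when
both pools call it. Calls covering no causal site are appended with an
empty gene field. On scaled maps (below) two jointly-required linked loci
can leave no sub-threshold valley between them, so run separation alone
cannot split them; keying by site reports each locus with its own row, as
reciprocal-cross bookkeeping does in practice.

BY-fixation is only meaningful at markers segregating in the analysed
cross; the mapper takes the founder genotype (known in simulation) or a
user-supplied marker mask (`map-loci --mask`) to exclude uninformative
markers, and a non-segregating engineered lesion (e.g. *sfl1*Δ carried by
both parents) is likewise excluded from MUTANT calling.

## Exact expectations

Genotype-class probabilities (five-way, six-way, other; overall and
conditional on rough) are computed by exact enumeration over causal-site
allele combinations weighted by per-locus transmission probabilities (0.5
segregating, 0/1 fixed), at most 2⁸ states — no Monte Carlo, hence no
sampling error in the 2:1 expectation. The enumeration treats causal
sites as unlinked, which holds on the real genome (the closest pair,
*IRA2*–*SFL1*, lies ~166 cM apart); on strongly scaled maps that pair
becomes linked and simulated six-way counts fall below the unlinked
expectation — a map-compression artefact the tests sidestep by relocating
*SFL1* when checking Monte-Carlo convergence.

## Scaled maps and what the simulations show

Full-scale simulations use 36,756 SNPs over the real chromosome lengths.
The end-to-end mapping tests and the acceptance script use 2,000-marker
maps whose chromosome lengths are shrunk proportionally, preserving the
real per-marker spacing (~330 bp, ~0.13 cM): a 10-SNP window then spans
the same genetic distance as in the real data, so fixation signals at
causal sites behave identically at a fraction of the cost. The price is
compressed inter-locus distances on the same chromosome, which is what the
causal-site-keyed report absorbs.

Study-design constants used throughout: backcross rough pools of 63 (BY
backcross, END3^3S-genotyped) and 88 (3S backcross) segregants; an *sfl1*Δ
rough pool of 44; 100× mean coverage (the real pools ran at 73× and 122×);
window 10 / threshold 95%. Null controls use unselected pools of 100.

The generator emulates segregant genotypes, selection, and pooled counts.
It does not simulate reads, mapping bias, library artefacts, structural
variation, or the unquantified viability bias — so passing tests show that
the mapping statistic recovers rule-constrained loci under Mendelian
segregation and sequencing noise, not that it is robust to alignment
artefacts; and observed cohort skews that depend on unmodelled selection
(e.g. a 20:1 five-way:six-way count among small rough cohorts) are outside
what this package reproduces.

## Numerical notes

All randomness flows through a single `numpy.random.Generator` per run;
identical seeds give byte-identical outputs. Pooled frequencies for
equimolar pools are computed as exact means so fixed markers are exactly
0 or 1. Counts at a marker always satisfy n_BY + n₃ₛ + n_other = depth
(validated at construction). Coordinates are 1-based inclusive everywhere
except BED exports (0-based half-open). Degenerate inputs: zero-depth
markers become missing; chromosomes with fewer informative markers than
the window size yield no windows; an empty pool is an error.
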