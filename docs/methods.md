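# Methods

## Setting and model

The package analyses a clonal design: one parental fibroblast line and
several iPS-cell lines derived from it, all exome-sequenced and jointly
genotyped so that every sample has a call (GT, AD, GQ) at every candidate
site, with site-level annotations QUAL, QD, MQ, FS and HaplotypeScore.
Upstream read processing and the joint caller are outside the package's
boundary: the input is the multi-sample VCF, plus structural-alteration
intervals from SNP-array analysis (BED), effect labels from an annotation
engine (TSV), per-telomere fluorescence intensities (TSV) and passage
metadata.

## The stringent filter

A record is eliminated for a focal sample when any clause of

    QUAL < 400 || QD < 2.0 || MQ < 40.0 || FS > 60.0
    || HaplotypeScore > 13.0 || GQ <= 60

holds. All clauses except GQ are strict, so boundary values (QUAL = 400,
QD = 2.0, MQ = 40.0, FS = 60.0, HaplotypeScore = 13.0) pass while GQ = 60
fails; the verdict lists every clause that fired, not just the first.
The GQ clause is evaluated on the focal sample only — whether it was
originally applied to all samples at a site is unknowable from the record
of the method, and the focal-sample reading is the less destructive one.

The allelic-depth rules depend on the genotype class. "Within twofold"
and "no less than 32-fold" are fold-ratios, not arithmetic differences:
the explicit (1, ≥ 16) and (0, ≥ 8) carve-outs of the homozygous rule are
exceptions for a degenerate denominator, which only a ratio rule needs.
Both boundary readings are inclusive (het 8/16 passes; hom 64/2 passes).
For the homozygous rule the genotype allele's depth is compared against
the **maximum** depth among all other alleles — the most conservative
possible contaminant at a multi-allelic site. A 0/0 genotype at a variant
site is evaluated by the same homozygous rule as 1/1. The comparisons are
implemented in integer arithmetic (`max ≤ 2·min`, `a ≥ 32·b`) so no
floating-point edge case can flip a boundary.

Missingness is a first-class state: a record lacking any required
annotation (or GT/AD for the focal sample) is eliminated with a
`MISSING_FIELD` verdict rather than being defaulted — the stringent
reading — with a `permissive_missing` switch that skips absent clauses
instead, for call sets annotated by other pipelines.

## Somatic selection and the exclusion accounting

A site counts as a de novo SNV of a derived line when (i) the derived
sample passes the full filter, (ii) the parental sample passes it too
(switchable via `require_parental_pass`; requiring both is the default
because a noisy parental call cannot certify reference homozygosity),
(iii) the parental genotype is 0/0, and (iv) the derived genotype carries
an allele absent from it. Requiring parental 0/0 — rather than "genotypes
differ" — keeps loss-of-heterozygosity genotype changes out of the
substitution count; those are handled by the structural channel.

SNVs overlapping a structural interval are removed and attributed to that
interval's label (left-most interval wins if several overlap); the VCF's
1-based position `p` overlaps the 0-based half-open interval `[s, e)` iff
`s < p ≤ e`, the single coordinate bridge in the package. The manual
exclusion list is an explicit TSV of (chrom, pos, sample) so the
hand-curation step is reproducible and auditable: entries that match
nothing raise warnings, never errors. The accounting object enforces
`final = called − Σ region − manual ≥ 0` at construction.

Outputs are ordered by karyotype chromosome order then position, making
every stage deterministic.

## Mutation profile

Each SNV's effect labels collapse to one category by fixed precedence
(coding > splice site > UTR > intron > up/downstream > non-coding exon >
intergenic); the table is printed in `profiles.CATEGORY_PRECEDENCE` and
deliberately does not replicate any annotation engine's internal ranking.
The spectrum is exported both as the 12 ordered ref→alt classes and the 6
pyrimidine-collapsed classes, since figure conventions differ; Ti/Tv
counts A↔G and C↔T changes as transitions and reports ∞ when no
transversion was observed. Spectrum and tallies can be computed pooled or
per line — both groupings are available because the published pooling is
not recoverable from the text.

The substitution rate per population doubling (PD) is
`Σ counts / (Σ passages × pd_per_passage)`. The PD-per-passage value is a
required assumption with default **3.70**: with 167 SNVs over 94 summed
passages the rate is `167/(94·p)`, and `p ≈ 3.70` is the value that
back-solves the published 0.48 substitutions/PD. It is a documented
assumption, not a measurement; the rate scales as `1/p`, and 3–4
doublings per passage is the plausible range for clump-passaged human
iPS cultures.

## Q-FISH telomere length

Per spread, the median of all telomere signals (p- and q-arms of every
chromosome) is the robust location summary; per sample, the mean of
per-spread medians. Length is calibrated against a control line measured
in the same batch, with control length 6.91 kbp (TIG-1 fibroblasts at 34
population doublings) as the default anchor:

    ratio  = round(sample TFI / control TFI, 3)
    length = round(ratio × control kbp, 2)

The ratio is rounded to 3 decimals **before** scaling. This is the
arithmetic of the reference table the package reproduces: for the
ATiPS-262 measurement (16495/8671) the unrounded product is 13.145 kbp,
which would print as 13.15, whereas the table's 13.14 follows from
1.902 × 6.91. The unrounded ratio is kept on the result object
(`raw_ratio`) for statistical work. Control pairing is part of the input
schema — the three control batches have different TFIs — and is never
inferred. No background subtraction or image processing is modelled;
intensity tables are the input boundary.

## Culture metrics

Reprogramming efficiency is `100 × colonies / cells plated`. The fold
comparison between two lines assumes comparable plating; for the
published 0.5% control value the plated-cell denominator is not recorded,
so the comparison is reproduced under the assumption of identical
plating. Survival after irradiation expresses each replicate count as a
percentage of the matched non-irradiated control mean (controls are 100%
by construction, per clone before pooling), reported as mean ± SD over
replicates; the statistic is scale-invariant to counting units.

## Synthetic data

The generator emulates the study design: a parent plus four derived lines
(default names ATiPS-262/-263/-264/-024, passages 17/27/25/25), candidate
sites at ~90× mean depth (Poisson, floored at 16), inherited background
variants shared by all samples, planted de novo SNVs per line, structural
regions holding a stated number of those SNVs, and an ambiguous subset
destined for the exclusion list. Each derived line owns one artificial
chromosome sized to hold its regions, so pooled region exclusion affects
exactly the intended line — a property of the synthetic genome, not of
real data. All randomness flows from one named NumPy generator per call;
the seed is recorded in emitted VCF headers, and identical configs are
byte-identical.

Allelic depths: with `ad_noise = 0` the depth split is the deterministic
expectation (⌈d/2⌉/⌊d/2⌋ for het, (d, 0) for hom), which makes
planted-truth recovery exact and seed-robust; with `ad_noise > 0` depths
are drawn binomially with a contamination fraction, so borderline
failures occur at realistic rates. Ambiguous calls are given
boundary-legal depths (8, 16 — exactly twofold), mimicking calls that
survive the filter yet deserve manual exclusion; the mechanism behind the
real ambiguous calls is unrecorded, so this is a modelling choice.
Site-quality annotations are drawn from documented parametric stand-ins
(uniform pass/fail windows per clause) with configurable per-clause
failure fractions; the study's true QD/MQ/FS/HaplotypeScore distributions
are unknown.

`scenario_paper(seed)` fixes the study-scale instance: 212 candidates
split 84/49/36/43 across the lines, of which 2 lie in a 23,314-kb CNLOH
and 37 in a 3,586-kb deletion (line 262), 1 in a 234-kb deletion (line
024), and 2/1/1/1 are ambiguous — so the pipeline necessarily ends at 167
split 43/48/35/41. The counts are invariant to the seed; the seed moves
positions, alleles and annotation values only. Q-FISH fixtures are
lognormal intensity tables (σ = 0.45, 92 signals/spread — two telomeres
per chromosome arm of a 46-chromosome spread, the scored number being
configurable since the true count per spread is unrecorded) whose medians
target the measured TFI ratios.

What passing tests on this synthetic data do **not** show: robustness to
mapping artifacts, systematic strand bias, contamination between samples,
or structural events co-occurring with point mutations on shared
chromosomes — none of which the generator models.

## Numerical and testing notes

- Filter comparisons are exact (integers; float thresholds representable
  in float32, so VCF round-trips cannot flip a clause).
- Verification is dual-route throughout: the filter engine and the
  interval exclusion are checked against independently written
  brute-force evaluators on ~10³ random records; generators are checked
  by planted-truth recovery (exact with noise off; within 3 binomial SDs
  at n = 1000 for spectrum/category mixes; within 3 SE over 20 seeds for
  the Q-FISH ratio).
- Problem sizes in the test suite (10²–10³ records, 20 seeds) keep the
  full suite under a few seconds while leaving the binomial/SE tolerances
  meaningful.
- Known limitations: no BAM/FASTQ simulation (the called VCF is the
  boundary); no CNV/LOH detection (regions are consumed, not computed);
  no re-annotation; the per-PD rate is conditional on the PD-per-passage
  assumption above.
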