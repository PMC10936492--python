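# Methods

## Data model and coordinate conventions

Genotypes are held as a samples × variants × 2 array of allele indices
(0 = reference, 1 = effect/alternate, −1 = missing) with a per-call phase
flag; coordinates are 1-based VCF convention throughout. Multi-allelic VCF
records are split into biallelic variants at read time: the k-th alternate
becomes its own variant, a call equal to k maps to allele index 1 and any
other non-missing allele to 0, which conserves total alternate dosage across
the split records; rsIDs of split records gain an allele suffix. Missing
genotypes are never imputed — every operation states its own missing-data
rule — and effect alleles from annotation tables are matched to ref/alt by
uppercase string equality only; strand flips are never auto-resolved because
silently flipping corrupts direction classification.

The verdict-table schema carries an optional `gene` column in addition to
(chrom, pos, ref, alt, tool…): the disruption analysis needs a gene label
for each predicted-deleterious variant, and annotating raw variants against
gene models is outside this package's scope, so the label travels with the
verdict input.

## Frequencies and population comparison

Allele frequency divides the effect-allele count by the number of
non-missing chromosomes; carrier frequency divides carrier individuals by
individuals with complete calls. The two are deliberately kept as distinct
quantities (under HWE, carrier = 1 − (1 − p)²) because population reports
often print both as "% of the population"; the flag logic downstream always
states which one it uses.

Star-allele (haplotype) frequencies require phased calls at every defining
site; each of the 2n haplotypes is assigned to the first definition, in
definition-file order, whose required alleles all match, so definition files
should order suballeles from most to least specific. Unassigned haplotypes
are pooled as reference/other.

Fisher's exact test is two-sided by the minimum-likelihood rule (the sum of
all conditional table probabilities not exceeding the observed one) — stated
explicitly because two-sided conventions differ. Counts derived from a
frequency use round(af · n_chromosomes), applied identically everywhere.
The FDR family defaults to every variant × population-pair comparison
computed in one invocation (a figure-wide correction); a per-population-pair
family is available. q-values come from the Benjamini–Hochberg step-up and
are checked in the tests against the closed-form formula and, for the test
itself, against exhaustive hypergeometric enumeration on all 2×2 tables with
grand total ≤ 30.

## LD pruning

r² is the squared Pearson correlation of 0/1/2 genotype dosages (composite
LD), computed on pairwise-complete samples, so unphased cohorts are
supported; on phased data it tracks haplotype D²/(p₁q₁p₂q₂) closely and the
tests assert agreement within ±0.02. Pruning is greedy first-kept-wins in
genomic position order (ties broken by allele strings): deterministic by
construction, which we prioritized over mimicking any particular tool's
undocumented internal ordering. Monomorphic or data-poor pairs have
undefined LD and are treated as r² = 0 (they never force a drop);
cross-chromosome pairs are never compared. Pruning may be run on the
combined panel (default) or per population.

## Direction classification and burden

Phenotype strings are normalized to a five-term vocabulary (increased/
decreased response, increased/decreased toxicity, other); the normalization
table is extensible, and dosage/PK phenotypes (e.g. "decreased clearance")
map to *other* because their clinical sign is drug-dependent. Efficacy terms
dominate: an annotation with both efficacy and toxicity terms is signed by
the efficacy term. Toxicity-only annotations are kept and signed by toxicity
(decreased toxicity = positive); an `efficacy_only` switch restricts to
efficacy terms. Direction refers to the annotation's stated effect allele,
not the population minor allele, which is unstable under resampling. The
classifier always partitions its input: every annotation is positive,
negative, or excluded with a rationale code.

Burden counts sum effect-allele dosages per individual over the pruned
panel, separately for positive and negative directions within each drug
class; a variant annotated for several drugs of one class counts once per
class, and may count in several classes. Missing calls contribute 0 and are
tallied; samples exceeding 20% panel missingness are flagged, not dropped.
Location tests: Kruskal–Wallis omnibus across populations (p = 1 by
convention when all values are identical), and a two-sided rank-sum test of
the reference population against each other population — exact enumeration
for groups of ≤ 50 without ties, otherwise the normal approximation with
midranks, tie-corrected variance and continuity correction. Pairwise
p-values are reported unadjusted (no pairwise correction is imposed), with
a BH-adjusted column emitted alongside.

## Deleteriousness consensus and disruption

A variant is consensus-deleterious when ≥ 2 tools (configurable) call it
deleterious, missing verdicts counting as neither; an all-missing row is
indeterminate and raises rather than defaulting. The common filter keeps
consensus calls with effect AF strictly above 1% (strict inequality: "over
1%"). A gene's disruption frequency aggregates its qualifying variants by
maximum AF (conservative, matches per-variant reporting); the optional
combined mode 1 − ∏(1 − afᵢ) approximates the any-disrupting-allele
frequency under independence. Per (drug, role) the report gives the
disrupted fraction of role-genes with complete (= 1) and partial (≥ 0.5)
flags; a role with zero genes is omitted, never counted as disrupted; the
three roles are evaluated independently with no cross-role combination
rule. Disruption prevalence enters the flag logic as allele frequency;
carrier frequency can be computed alongside from genotypes and the two are
never interchanged.

## Interactions and DDGI rules

Overlap fractions use the co-medication category's gene set as denominator
(the "X% of PPI genes are also NIAD genes" reading). The drug–gene network
is bipartite; a gene's degree is its number of incident drugs, and a drug's
share score is the fraction of its genes shared with at least one drug of a
different category — the simplest faithful reading of a "proportion of
shared PGx genes" score, documented here because other readings exist.
Inhibitor joins emit one (victim, perpetrator, enzyme) row whenever the
perpetrator inhibits an enzyme in the victim's enzyme-role set, excluding
self-pairs; strength tiers (strong/moderate/weak, by AUC fold-change or
clearance-decrease bands) are carried through but never alter DDGI
categories.

The DDGI classifier is pathway-topology-based (no quantitative AUC
modelling). With the victim's pathway table (enzyme → contribution
fraction, summing to ≤ 1), a perpetrator action set, and a genetic
phenotype (PM/IM = reduced, NM = normal, UM = increased activity;
transporter decreased/normal), the rules in precedence order are:
category 1 when the perpetrator pushes the phenotype gene's own pathway in
the same direction as the phenotype; category 3 when it pushes that pathway
in the opposite direction; category 2 when it pushes a *different* pathway
of the same victim in the phenotype's direction; none otherwise (normal
phenotypes, or phenotype genes outside the victim's pathway set). Induction
is supported as the mirror image of inhibition so category 3 is symmetric.
A `major_threshold` (default 0.5) on the contribution fraction labels
pathways major/minor in the rationale text without affecting the category.

## Synthetic cohorts

The generator emulates multi-population diploid cohorts under HWE: each
individual is two independent haplotypes; unlinked sites are Bernoulli(af)
per haplotype. LD blocks are drawn at the haplotype level by a first-order
chain — the first member is Bernoulli(af), and each next member is drawn
conditional on the previous with P(1|1) = p₂ + r·√(p₂q₂q₁/p₁), which hits
the target pairwise correlation r while preserving marginal frequencies.
Feasibility of r is checked against the Fréchet bounds on the 2×2 haplotype
table; infeasible requests raise with the feasible range rather than
clamping, so a misconfigured test cannot silently pass. Haplotypes are
paired into phased diploids. One global seed drives a named (hashed)
sub-stream per population and per table, so adding a population never
perturbs another's draws and equal seeds reproduce cohorts byte-for-byte.

The matched annotation suite assigns each variant a synthetic drug (spread
round-robin over the eight NIAD classes), a direction (negative with
probability `direction_mix`), an evidence level in {3, 4} — mirroring the
observation that NIAD annotations in curated sources carry no level-1/2
evidence — and per-tool verdicts that match the variant's true
deleteriousness with probability `agreement` per tool. Ground truth
(directions, true AFs, deleterious set, per-gene disruption status) is
emitted for recovery tests.

What the generator does *not* emulate: realistic site-frequency spectra,
linkage beyond first-order blocks, genotyping error, relatedness,
population substructure within a labelled population, and indel/star-allele
complexity beyond explicit definitions. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to artifacts of real sequencing data.

## Problem sizes and numerical choices

Default test and demonstration scales were chosen to make the statistics
well-conditioned while staying desk-sized: cohort-scale recovery runs use
1029 individuals (the reference Indian whole-genome cohort size) for allele
frequencies and 100 000 for the carrier-rate closed-form check; null
calibrations use 1000 replicates; power checks use 500 individuals per
group and 20 seeds; LD-pruning validation uses panels of up to 200 variants
with exhaustive pairwise verification; the end-to-end pipeline demonstration
uses 2 populations × 1000 individuals × 500 variants. Tolerances follow the
underlying sampling distributions (e.g. ±3 binomial standard errors for
realized frequencies, ±0.05 for realized haplotype correlation at 2000
haplotypes).

Degenerate inputs are handled explicitly: zero non-missing calls raise an
undefined-frequency error; monomorphic variants raise for point LD queries
but are treated as unlinked inside pruning; identical-constant groups yield
p = 1 for rank-based tests; 0/0 odds ratios are NaN and x/0 are infinite.

## Known limitations

Burden counts are unweighted allele counts: population-specific effect sizes
for these variants are not available, so no effect-weighted polygenic score
is attempted, and imbalance is a descriptive contrast, not a calibrated
response predictor. Star-allele calling is first-match over explicit
definitions on phased data only (no EM phasing). DDGI predictions are
qualitative rule classifications over pathway topology; they rank candidate
interactions but do not estimate exposure changes.
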