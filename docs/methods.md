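# Methods

## Problem setting

Noninvasive genetic surveys identify individual animals from DNA in
field-collected scats. Fecal DNA is dilute, degraded and contaminated, so
three error modes dominate every PCR: wholesale amplification failure,
allelic dropout (one allele of a heterozygote fails to amplify, so it looks
homozygous), and false alleles (spurious fragments, typically near real
allele sizes). The pipeline's design is shaped entirely by these errors:
replication, conservative aggregation rules, explicit ambiguity, and a
probabilistic bound on coincidental genotype identity.

## Assay calling

Each diagnostic assay (carnivore-generic cytochrome-*b*, species-specific
cytochrome-*b*, Y-chromosomal AMELY for sex) is run in triplicate with a
positive and a no-template negative control. A replicate with a failed
control is discarded before any aggregation — a contaminated negative
control invalidates a band, a failed positive control invalidates its
absence.

The decision rule requires at least `min_positive = 2` band-positive valid
replicates for POSITIVE (or MALE), and at least `min_valid = 2` valid
replicates, none positive beyond threshold, for NEGATIVE (or FEMALE);
everything thinner is INVALID (UNKNOWN). The 2-of-3 threshold guards
symmetrically against single-replicate contamination and single-replicate
dropout; the counts are parameters, not constants, because deeper
replication designs exist. A sex call is only interpretable when the
species assay is POSITIVE: absence of a Y band means "female" only when the
template demonstrably amplifies.

Survey tallies keep INVALID as a first-class outcome (tallied separately,
never forced into the species × carnivore 2×2), and percentages are
computed on the survey's natural denominators: assay positives out of all
collected samples, genotyping success and individual counts out of
species-positive samples.

## Consensus genotyping (multiple-tubes)

Each sample × locus is amplified in `n_replicates = 3` reactions; each
replicate scores a set of 0–2 alleles (0 = failure). An allele is
*confirmed* at `min_support = 2` sightings. The call logic:

| observation pattern | call |
|---|---|
| two confirmed alleles | OK heterozygote (confirmed pair outvotes one-off strays) |
| one confirmed, nothing else seen | OK homozygote |
| one confirmed + unconfirmed extras | AMBIGUOUS, candidates = all observed |
| ≥ 3 confirmed | AMBIGUOUS (mixed template cannot be resolved here) |
| nothing confirmed, something seen | AMBIGUOUS |
| no amplification anywhere | MISSING |

Three or more alleles in a *single* replicate is an error (scoring fault or
mixed sample), not a call. When nothing is confirmed and only one allele was
ever seen, the AMBIGUOUS candidate set is a singleton — the information is
kept rather than demoted to MISSING, and downstream treatment is identical
(ambiguous loci are never compared or counted).

AMBIGUOUS calls are preserved through every output table in slash notation
(`101/103`) rather than being resolved, because the downstream statistics
depend on knowing which cells were uncertain: per-locus sample sizes in the
diversity table are only reproducible when ambiguous genotypes are excluded,
not guessed.

A sample counts as "successfully genotyped" when typed (OK or AMBIGUOUS) at
`min_typed_loci` panel loci, default one less than the panel size. The
default admits composites with a single entirely failed locus: the remaining
loci still individualise, and surveys report such samples as genotyped. The
threshold is exposed because stricter designs may demand completeness.

## Individual matching

Two composites are compared only at loci where **both** carry OK calls;
AMBIGUOUS and MISSING are never compared. Any disagreement (unordered
allele-pair inequality — dropout is handled upstream as AMBIGUOUS, never by
partial matching here) is a MISMATCH. A MATCH additionally requires
`min_shared = 4` of 6 co-typed loci; pairs with fewer comparable loci are
UNRESOLVED and never merged. The default errs toward splitting — the output
is a *minimum* number of individuals present — because the sibling
probability of identity at only 3–4 informative loci of moderate diversity
is of order 0.1, too weak to assert identity.

Clustering is greedy in input order: a sample joins the first cluster whose
*every* member it matches, guaranteeing all within-cluster pairs are
MATCHes; the result is deterministic given input order. A post-hoc audit
over all pairs reports (a) UNRESOLVED pairs and (b) non-transitive MATCH
triples (A≈B, B≈C, A≉C), which can arise when different pairs are compared
on different locus subsets; clusters stand by the first-link rule but the
conflicts are surfaced for review. When the MATCH relation is transitive
the partition (hence the cluster count) is order-invariant.

Cluster sex is the members' unanimous assay call; any MALE/FEMALE conflict
forces UNKNOWN with a warning, since it flags either a false merge or an
assay error. For each multi-member cluster, the package reports the product
of per-locus PID(sib) over the loci its members were actually compared on:
a conservative upper bound on the probability that the "same individual"
conclusion is a coincidence between close relatives.

## Frequencies, diversity, probability of identity

Allele frequencies are estimated from the *unique* individuals (duplicate
scats collapsed first), each contributing two allele copies per locus;
AMBIGUOUS and MISSING genotypes are excluded per locus, so N varies across
loci. With pᵢ the frequency of allele i and N the contributing individuals:

- Ne = 1/Σpᵢ², He = 1 − Σpᵢ² (so He = 1 − 1/Ne identically, asserted in
  tests to 1e-12), UHe = 2N/(2N−1)·He, Ho = heterozygote count / N;
- PID(unrelated) = 2(Σpᵢ²)² − Σpᵢ⁴, the probability two unrelated HWE
  individuals share a genotype, verified against exhaustive genotype
  enumeration (Σ_g P(g)²);
- PID(sib) = 0.25 + 0.5Σpᵢ² + 0.5(Σpᵢ²)² − 0.25Σpᵢ⁴, verified against a
  Mendelian sibling-pair Monte-Carlo simulation (3-standard-error
  agreement at 200,000 pairs per frequency vector).

Panel-wide PIDs are products across loci (loci assumed independent —
the panel was chosen on separate chromosomes). All arithmetic runs at
full floating precision; presentation rounding (Ne to 1 decimal, the
heterozygosities to 3) happens only in the report table. Overall Ho/He are
unweighted across-locus means of the unrounded per-locus values.

On the packaged survey fixtures the pipeline computes panel-wide
PID(unrelated) ≈ 1.050 × 10⁻⁴ and PID(sib) ≈ 0.0179, whereas the original
report of this survey printed 0.00014 and 0.0182. The printed values are
not exactly recoverable under any documented handling of the ambiguous
cells and the duplicate sample; the package reports its own computed values
and flags the discrepancy rather than tuning to match. The tests therefore
hold these totals to order-of-magnitude agreement (factor 1.5) while
holding every *per-locus* quantity, and the diversity table itself, to the
printed precision.

## Survey fixtures

The packaged genotype table and sex-call table are the survey's published
per-sample data, in the external CSV dialect. The replicate-level assay
sheet for all 71 collected scats is reconstructed programmatically from the
published category counts; per-sample identifiers outside the 10 genotyped
scats, and the site split of the non-genotyped categories, are synthetic
placeholders consistent with the published totals. The join between the
genotype table and the sex table uses the unique region-and-order-consistent
mapping, which reproduces the published per-region sex tallies exactly.

## Primer screen

The species-diagnostic screen scans every k-mer window (default k = 20) of
the target sequence in a multi-species alignment. A window qualifies only
against **every** off-target simultaneously: forward primers by ≥ 2
mismatches within the 3′-terminal window (default 5 bases — the alignment
does not define "3′-end", so the window is a parameter; 5 is standard
allele-specific-PCR practice), reverse primers by ≥ 5 mismatches anywhere
in the primer ("more than 4"), counted over the whole primer because the
criterion's scope is otherwise underdetermined; both thresholds are
parameters and both are enforced jointly (the unused one defaults to 0).
Reverse-strand primers are the reverse complement of the window, so their
3′ terminus maps to the window's left edge; complementing both strands
preserves mismatches, so counting happens on the given strand. A gap or N
in the *target* window disqualifies it (the primer could not be
synthesised); in an off-target, a gap counts as a mismatch and an N as a
match (no mismatch can be claimed against an unknown base). Coordinates
are 0-based half-open alignment columns; amplicon length is the ungapped
target span from forward-primer start to reverse-primer end inclusive.

## Synthetic surveys

The simulator draws per-locus allele frequencies from a symmetric Dirichlet
and multilocus genotypes independently per individual under HWE — exactly
the model the statistics assume. Defaults emulate the packaged survey:

| parameter | default | basis |
|---|---|---|
| n_individuals | 9 | individuals recovered in the survey |
| sex_ratio | 1/3 | 3 of 9 males |
| panel | 6 loci, allele counts (6,4,4,3,4,2) | the survey's Na column |
| freq_concentration | 2.0 | expected UHe ≈ 0.62, matching the survey mean |
| scats_per_individual | 2.1 | 19 species-positive scats / 9 individuals |
| offtarget_fraction | 0.73 | 52 of 71 collected scats non-target |
| offtarget_carnivore_prob | 0.577 | 30 of 52 from other carnivores |
| dropout_rate | 0.2 / allele / replicate | typical felid scat-DNA range |
| failure_rate | 0.15 / replicate | typical felid scat-DNA range |
| false_allele_rate | 0.05 / replicate | typical felid scat-DNA range |
| n_replicates | 3 | triplicate design |

The collected-scat count is Poisson(n_individuals × scats_per_individual)
for target scats, each attributed to a uniformly random individual, plus an
independent Poisson off-target stream at rate f/(1−f) times the target
rate, so each collected scat is off-target with probability f. Template
quality is shared across assays within a replicate (replicate i of the
carnivore and species assays fails together), which makes species-positive
⇒ carnivore-positive structural, matching the nested-target design. Males
yield the Y band per replicate with probability (1−dropout) on amplifiable
template; females never do. False alleles are drawn uniformly from the
locus's allele set ± 2 bp, deliberately adjacent to real alleles to stress
exact-match clustering; when a replicate already shows two alleles the
spurious peak displaces a random real one (a miscall), keeping observations
at ≤ 2 alleles.

Determinism: every operation derives its generator from the seed
(population and scat streams use distinct child seeds), so identical seeds
give byte-identical output, including the truth JSON.

`recovery_experiment` runs the full pipeline per simulated survey and
compares the recovered individual count against the *detected* truth — the
individuals that contributed at least one species-positive scat — since an
unsampled individual is unknowable to any method. Only identifiable
clusters (consensus OK at ≥ min_shared loci) count as recovered; thinner
clusters are tallied separately as unidentifiable, so heavy dropout
undercounts rather than spuriously inflating the total. Reported metrics:
bias and RMSE of the count, exact-recovery rate, false-merge rate (a
cluster mixing two true individuals), false-split rate (one individual
spread over clusters), and the error of the across-locus mean UHe versus
the truth He of the drawn frequencies.

Validation checks computed by the test suite, at the problem sizes the
package uses: error-free surveys at 10 individuals / ~30 scats are
recovered exactly in ≥ 99% of 1,000 runs (the analytic ceiling is chance
identity: the expected full-panel PID(unrelated) under the default
Dirichlet panel is ≈ 5 × 10⁻⁵, about 2 expected collisions per 1,000 runs
across 45 pairs); the heterozygote deficit of raw single replicates under
dropout d matches (1−d)/(1+d) among amplified replicates; and the
probability that a true heterozygote survives consensus is
[P(Bin(3, 1−d) ≥ 2)]².

## What the simulator does and does not show

It emulates HWE, locus independence, no null alleles, no stutter, spatially
unstructured scat deposition, and error rates independent of sample age and
locus. Passing recovery tests therefore demonstrates the pipeline's logic
is sound under the model the statistics assume — not that real surveys with
population structure, related individuals, null alleles or locus-specific
failure behave as well. Known systematic effect, measured here: under
genotyping error the ambiguity-exclusion rule removes heterozygous loci
preferentially (a dropout event sends a heterozygote to AMBIGUOUS more
often than a homozygote), so the estimated mean UHe from recovered
individuals runs slightly low (≈ −0.01 at the default error rates); the
unbiasedness test is framed on error-free surveys, which isolate the
sampling property.

## Degenerate inputs and numerical conventions

Statistics at a locus with no OK genotypes are flagged undefined, never
zero-filled. PID requires frequencies summing to 1 within 1e-9. Empty
replicate lists, empty surveys for clustering, k exceeding alignment
length, inverted primer pairs, and >2 alleles in a replicate are errors,
not silent defaults. The empty product convention applies to match support
(a cluster compared at zero loci has support probability 1, i.e. no
evidence). Allele identity is exact integer equality on fragment size —
no binning tolerance — matching integer-called panels.
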