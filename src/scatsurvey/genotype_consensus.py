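"""Consensus microsatellite genotypes from replicate PCR observations.

Fecal DNA is dilute and degraded, so single PCRs are unreliable: a
heterozygote's allele can drop out (making it look homozygous), spurious
alleles can appear, and whole reactions can fail.  The multiple-tubes
approach amplifies every sample x locus several times (three here) and
only accepts an allele once it recurs.  An allele is *confirmed* when seen
in at least ``min_support`` replicates (default 2 of 3); the consensus
call is then:

* two confirmed alleles -> OK heterozygote (confirmed alleles outvote any
  unconfirmed strays);
* one confirmed allele and nothing else ever seen -> OK homozygote;
* one confirmed plus unconfirmed extras -> AMBIGUOUS (possible dropout),
  candidates = everything observed;
* three or more confirmed alleles -> AMBIGUOUS (mixed template or scoring
  fault upstream cannot be resolved here);
* nothing confirmed but something seen -> AMBIGUOUS;
* no amplification in any replicate -> MISSING.

AMBIGUOUS calls keep their candidate sets and are rendered downstream in
slash notation (``101/103``) rather than being forced to a genotype;
population statistics exclude them per locus.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

from .survey_io import (
    DEFAULT_LOCI,
    GenotypeRow,
    GenotypeTable,
    LocusGenotype,
    SampleRecord,
    Status,
    logger,
)


def consensus_locus(
    observations: Sequence[frozenset[int] | set[int]],
    locus: str = "",
    min_support: int = 2,
) -> LocusGenotype:
    """Collapse replicate allele observations at one locus into one call.

    Each observation is the allele set scored in one PCR replicate: empty
    (amplification failure), one allele (apparent homozygote or dropout) or
    two.  More than two alleles in a single replicate signals a scoring
    fault or a mixed sample and is an error.
    """
    if not observations:
        raise ValueError("consensus_locus requires at least one replicate")
    counts: Counter[int] = Counter()
    for obs in observations:
        if len(obs) > 2:
            raise ValueError(
                f"{locus}: replicate with {len(obs)} alleles "
                "(scoring fault or mixed sample)"
            )
        for allele in obs:
            counts[allele] += 1
    if not counts:
        return LocusGenotype(locus, Status.MISSING)
    support = dict(counts)
    confirmed = sorted(a for a, n in counts.items() if n >= min_support)
    unconfirmed = sorted(a for a, n in counts.items() if n < min_support)
    if len(confirmed) == 2:
        return LocusGenotype(
            locus, Status.OK, alleles=(confirmed[0], confirmed[1]), support=support
        )
    if len(confirmed) == 1 and not unconfirmed:
        a = confirmed[0]
        return LocusGenotype(locus, Status.OK, alleles=(a, a), support=support)
    return LocusGenotype(
        locus, Status.AMBIGUOUS, candidates=frozenset(counts), support=support
    )


def consensus_sample(
    sample: SampleRecord,
    loci: Sequence[str] = DEFAULT_LOCI,
    min_support: int = 2,
) -> dict[str, LocusGenotype]:
    """Per-locus consensus for one sample over the whole panel.

    Loci with no replicate data at all come back MISSING, so the composite
    always covers the full panel.
    """
    composite: dict[str, LocusGenotype] = {}
    for locus in loci:
        reps = sample.genotype_replicates.get(locus, [])
        if not reps:
            composite[locus] = LocusGenotype(locus, Status.MISSING)
        else:
            composite[locus] = consensus_locus(reps, locus, min_support)
    return composite


def is_complete(composite: Mapping[str, LocusGenotype]) -> bool:
    """True when every panel locus has an unambiguous OK call."""
    return all(gt.status is Status.OK for gt in composite.values())


def n_typed_loci(composite: Mapping[str, LocusGenotype]) -> int:
    """Number of loci scored at all (OK or AMBIGUOUS)."""
    return sum(1 for gt in composite.values() if gt.is_typed)


def consensus_table(
    samples: Sequence[SampleRecord],
    loci: Sequence[str] = DEFAULT_LOCI,
    min_support: int = 2,
) -> GenotypeTable:
    """Consensus composites for a batch of samples as a GenotypeTable."""
    rows = [
        GenotypeRow(
            sample_id=s.sample_id,
            site=s.site,
            region=s.region,
            year=s.year or 0,
            genotypes=consensus_sample(s, loci, min_support),
        )
        for s in samples
    ]
    return GenotypeTable(rows=rows, loci=tuple(loci))


def genotyping_success_rate(
    composites: Iterable[Mapping[str, LocusGenotype]],
    loci: Sequence[str] = DEFAULT_LOCI,
    min_typed_loci: int | None = None,
) -> float:
    """Fraction of samples counted as successfully genotyped.

    A sample counts as a genotyping success when it is typed (OK or
    AMBIGUOUS — unresolved candidate sets still carry identification
    information) at ``min_typed_loci`` or more panel loci.  The default,
    one less than the panel size, admits composites with at most one
    entirely untyped locus: surveys report samples with a single failed
    locus as genotyped, since the remaining loci still individualise.
    Returns 0.0 for an empty batch.
    """
    if min_typed_loci is None:
        min_typed_loci = len(loci) - 1
    composites = list(composites)
    if not composites:
        return 0.0
    n_success = sum(1 for c in composites if n_typed_loci(c) >= min_typed_loci)
    logger.info(
        "genotyping success: %d/%d samples typed at >=%d of %d loci",
        n_success, len(composites), min_typed_loci, len(loci),
    )
    return n_success / len(composites)
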