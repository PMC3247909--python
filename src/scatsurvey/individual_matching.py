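"""Individual identification by composite-genotype matching.

Scats sharing a multilocus genotype are taken to come from one animal.
Comparison is deliberately conservative with low-quality data: only loci
where *both* samples carry an unambiguous OK call are compared (AMBIGUOUS
candidate sets and MISSING loci never are), any disagreement at a compared
locus is a MISMATCH, and a MATCH additionally requires at least
``min_shared`` co-typed loci (default 4 of 6) so that two mostly-untyped
samples are never merged on thin evidence — those pairs are UNRESOLVED and
kept as separate putative individuals, which errs toward reporting a
minimum count of distinct animals.

The chance that a match is coincidental is quantified afterwards with the
sibling probability of identity accumulated over the loci actually
compared (:func:`match_support`) — siblings being the worst realistic
case for shared genotypes in a small population.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .survey_io import GenotypeRow, LocusGenotype, Status, logger
from .assay_calls import Sex


class MatchResult(enum.Enum):
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    UNRESOLVED = "UNRESOLVED"


def compared_loci(
    a: Mapping[str, LocusGenotype], b: Mapping[str, LocusGenotype]
) -> list[str]:
    """Loci carrying an OK call in both composites (the comparable set)."""
    shared_panel = set(a) & set(b)
    if not shared_panel:
        raise ValueError("composites share no loci — disjoint panels")
    return sorted(
        locus
        for locus in shared_panel
        if a[locus].status is Status.OK and b[locus].status is Status.OK
    )


def genotypes_match(
    a: Mapping[str, LocusGenotype],
    b: Mapping[str, LocusGenotype],
    min_shared: int = 4,
) -> MatchResult:
    """Compare two composite genotypes on their co-typed OK loci.

    MISMATCH as soon as any compared locus carries different unordered
    allele pairs; MATCH when all compared loci agree and at least
    ``min_shared`` were comparable; UNRESOLVED otherwise.
    """
    loci = compared_loci(a, b)
    for locus in loci:
        if a[locus].unordered() != b[locus].unordered():
            return MatchResult.MISMATCH
    if len(loci) >= min_shared:
        return MatchResult.MATCH
    return MatchResult.UNRESOLVED


@dataclass
class IndividualCluster:
    """Samples attributed to one individual animal."""

    individual_id: int
    member_samples: list[str]
    consensus_composite: dict[str, LocusGenotype]
    sex: Sex = Sex.UNKNOWN
    sites: set[tuple[str, str, int]] = field(default_factory=set)
    # Loci carrying an OK call in every member: the loci the members were
    # actually compared on when the cluster formed.
    compared: frozenset[str] = frozenset()

    @property
    def n_members(self) -> int:
        return len(self.member_samples)


@dataclass
class ClusteringResult:
    clusters: list[IndividualCluster]
    conflicts: list[tuple[str, str, str]]
    unresolved_pairs: list[tuple[str, str]]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def transitive(self) -> bool:
        return not self.conflicts


def _merge_composites(
    rows: Sequence[GenotypeRow], loci: Sequence[str]
) -> dict[str, LocusGenotype]:
    """Most-informative call per locus across a cluster's members.

    Members can only disagree where at least one is AMBIGUOUS or MISSING
    (OK calls were compared during matching), so preference order
    OK > AMBIGUOUS > MISSING with first occurrence breaking ties is exact.
    """
    rank = {Status.OK: 0, Status.AMBIGUOUS: 1, Status.MISSING: 2}
    merged: dict[str, LocusGenotype] = {}
    for locus in loci:
        merged[locus] = min(
            (row.genotypes[locus] for row in rows), key=lambda g: rank[g.status]
        )
    return merged


def cluster_individuals(
    rows: Sequence[GenotypeRow], min_shared: int = 4
) -> ClusteringResult:
    """Greedy agglomeration of samples into individuals by genotype identity.

    Samples are taken in input order; each joins the first existing cluster
    to whose *every* member it MATCHes, otherwise it seeds a new cluster —
    deterministic given input order, and guaranteeing every within-cluster
    pair is a MATCH.  A post-hoc audit flags non-transitive MATCH triples
    (A matches B, B matches C, A does not match C): clusters stand by the
    first-link rule but the conflicts are reported.  UNRESOLVED pairs
    (too few co-typed loci) are never merged and are listed for review.
    """
    if not rows:
        raise ValueError("cluster_individuals requires at least one composite")
    loci = sorted(rows[0].genotypes)
    member_rows: list[list[GenotypeRow]] = []
    for row in rows:
        placed = False
        for members in member_rows:
            if all(
                genotypes_match(row.genotypes, m.genotypes, min_shared)
                is MatchResult.MATCH
                for m in members
            ):
                members.append(row)
                placed = True
                break
        if not placed:
            member_rows.append([row])

    # Post-hoc audits over all sample pairs.
    conflicts: list[tuple[str, str, str]] = []
    unresolved: list[tuple[str, str]] = []
    assignment = {
        row.sample_id: ci for ci, members in enumerate(member_rows) for row in members
    }
    for a, b in combinations(rows, 2):
        result = genotypes_match(a.genotypes, b.genotypes, min_shared)
        if result is MatchResult.UNRESOLVED:
            unresolved.append((a.sample_id, b.sample_id))
        elif result is MatchResult.MATCH and assignment[a.sample_id] != assignment[b.sample_id]:
            conflicts.append(
                (a.sample_id, b.sample_id, "MATCH split across clusters")
            )

    clusters = [
        IndividualCluster(
            individual_id=i + 1,
            member_samples=[r.sample_id for r in members],
            consensus_composite=_merge_composites(members, loci),
            sites={(r.site, r.region, r.year) for r in members},
            compared=frozenset(
                locus
                for locus in loci
                if all(r.genotypes[locus].status is Status.OK for r in members)
            ),
        )
        for i, members in enumerate(member_rows)
    ]
    logger.info(
        "clustered %d samples into %d individuals (%d unresolved pairs, %d conflicts)",
        len(rows), len(clusters), len(unresolved), len(conflicts),
    )
    if conflicts:
        logger.warning("non-transitive MATCH relation: %s", conflicts)
    return ClusteringResult(
        clusters=clusters, conflicts=conflicts, unresolved_pairs=unresolved
    )


def attach_sex(
    clusters: Sequence[IndividualCluster], sample_sex: Mapping[str, Sex]
) -> list[IndividualCluster]:
    """Attach per-sample sex calls to clusters (in place; returns clusters).

    A cluster's sex is its members' unanimous call; members disagreeing on
    MALE vs FEMALE force UNKNOWN with a warning (a merged-cluster red
    flag).  Members without a call, or called UNKNOWN, are ignored for
    unanimity.
    """
    for cluster in clusters:
        calls = {
            sample_sex[sid]
            for sid in cluster.member_samples
            if sid in sample_sex and sample_sex[sid] is not Sex.UNKNOWN
        }
        if len(calls) == 1:
            cluster.sex = calls.pop()
        elif len(calls) > 1:
            cluster.sex = Sex.UNKNOWN
            logger.warning(
                "individual %d: conflicting sex calls among members %s",
                cluster.individual_id, cluster.member_samples,
            )
        else:
            cluster.sex = Sex.UNKNOWN
    return list(clusters)


def sex_tally(clusters: Sequence[IndividualCluster]) -> dict[str, int]:
    tally = {sex.value: 0 for sex in Sex}
    for cluster in clusters:
        tally[cluster.sex.value] += 1
    return tally


def match_support(
    clusters: Sequence[IndividualCluster],
    pid_sib_per_locus: Mapping[str, float],
) -> dict[int, float]:
    """Chance-identity probability for every multi-member cluster.

    For each cluster with two or more members, the product of the per-locus
    sibling probabilities of identity over the loci its members were
    actually compared on (OK in all members) — the conservative probability
    that a full sibling would share the observed composite by chance.  An
    empty comparable set yields the empty product, 1.
    """
    out: dict[int, float] = {}
    for cluster in clusters:
        if cluster.n_members < 2:
            continue
        support = 1.0
        for locus in sorted(cluster.compared):
            if locus not in pid_sib_per_locus:
                raise KeyError(f"locus {locus} compared but absent from PID map")
            support *= pid_sib_per_locus[locus]
        out[cluster.individual_id] = support
    return out
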