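"""Allele frequencies and diversity statistics from unique individuals.

With no independent population sample available, allele frequencies are
estimated from the unique composite genotypes recovered by the survey
itself: duplicate scats are collapsed to one genotype per individual
first, and at each locus only unambiguous OK genotypes contribute (an
AMBIGUOUS candidate set carries no defensible allele count, so the locus's
N shrinks instead).  Each contributing individual adds two allele copies.

Per-locus summaries follow the standard codominant-marker definitions:

* ``Na``  observed number of alleles,
* ``Ne = 1 / sum(p_i^2)``  effective number of alleles,
* ``Ho``  observed heterozygosity (heterozygous individuals / N),
* ``He = 1 - sum(p_i^2)``  expected (Nei) heterozygosity,
* ``UHe = 2N/(2N-1) * He``  its small-sample unbiased correction,

and the probabilities that two individuals share a genotype by chance,

* ``PID_u  = 2 (sum p_i^2)^2 - sum p_i^4``  for unrelated individuals,
* ``PID_sib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4``
  for full siblings (the conservative bound),

both multiplied across loci for the panel-wide values.  All arithmetic is
done at full floating precision; rounding (Ne to 1 decimal, the rest to 3)
happens only in the presentation table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .survey_io import LocusGenotype, Status, logger
from .individual_matching import IndividualCluster

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class LocusFrequencies:
    """Allele frequencies at one locus over unique individuals."""

    locus: str
    n_individuals: int
    counts: Mapping[int, int]

    @property
    def freqs(self) -> dict[int, float]:
        total = 2 * self.n_individuals
        return {a: c / total for a, c in self.counts.items()}

    @property
    def empty(self) -> bool:
        return self.n_individuals == 0


@dataclass
class AlleleFrequencyTable:
    loci: dict[str, LocusFrequencies]

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.loci[locus]

    def flagged_empty(self) -> list[str]:
        return [name for name, lf in self.loci.items() if lf.empty]


@dataclass(frozen=True)
class LocusStats:
    locus: str
    n: int
    na: int
    ne: float
    ho: float
    he: float
    uhe: float
    pid_u: float
    pid_sib: float


def allele_frequencies(
    clusters: Sequence[IndividualCluster], loci: Sequence[str]
) -> AlleleFrequencyTable:
    """Per-locus allele counts over unique individuals.

    Only OK genotypes contribute; AMBIGUOUS and MISSING loci are excluded
    entirely (the individual simply does not count toward that locus's N).
    A locus nobody was typed at is kept, empty, and flagged in the log.
    """
    table: dict[str, LocusFrequencies] = {}
    for locus in loci:
        counts: dict[int, int] = {}
        n = 0
        for cluster in clusters:
            gt = cluster.consensus_composite.get(locus)
            if gt is None or gt.status is not Status.OK:
                continue
            n += 1
            for allele in gt.alleles:  # type: ignore[union-attr]
                counts[allele] = counts.get(allele, 0) + 1
        if n == 0:
            logger.warning("locus %s: no OK genotypes among unique individuals", locus)
        table[locus] = LocusFrequencies(locus=locus, n_individuals=n, counts=counts)
    return AlleleFrequencyTable(loci=table)


def _check_normalised(freqs: Mapping[int, float]) -> None:
    total = sum(freqs.values())
    if abs(total - 1.0) > _NORM_TOL:
        raise ValueError(f"allele frequencies sum to {total}, not 1")


def pid_locus(freqs: Mapping[int, float]) -> tuple[float, float]:
    """(PID-unrelated, PID-sibling) for one locus from its frequencies."""
    _check_normalised(freqs)
    s2 = sum(p * p for p in freqs.values())
    s4 = sum(p ** 4 for p in freqs.values())
    pid_u = 2.0 * s2 * s2 - s4
    pid_sib = 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4
    return pid_u, pid_sib


def locus_stats(
    locus: str,
    freqs: Mapping[int, float],
    n: int,
    genotypes: Sequence[LocusGenotype],
) -> LocusStats:
    """All per-locus summary statistics from frequencies plus OK genotypes.

    ``genotypes`` are the N contributing OK calls (needed for Ho, which is
    a property of genotypes, not of allele frequencies).
    """
    if n < 1:
        raise ValueError(f"{locus}: stats undefined at N=0")
    if len(genotypes) != n:
        raise ValueError(f"{locus}: {len(genotypes)} genotypes but N={n}")
    _check_normalised(freqs)
    s2 = sum(p * p for p in freqs.values())
    he = 1.0 - s2
    uhe = he * (2 * n) / (2 * n - 1)
    ho = sum(1 for g in genotypes if g.is_heterozygous) / n
    pid_u, pid_sib = pid_locus(freqs)
    return LocusStats(
        locus=locus,
        n=n,
        na=len(freqs),
        ne=1.0 / s2,
        ho=ho,
        he=he,
        uhe=uhe,
        pid_u=pid_u,
        pid_sib=pid_sib,
    )


def stats_from_clusters(
    clusters: Sequence[IndividualCluster], loci: Sequence[str]
) -> list[LocusStats]:
    """Convenience: frequencies then stats for every non-empty panel locus."""
    freq_table = allele_frequencies(clusters, loci)
    out: list[LocusStats] = []
    for locus in loci:
        lf = freq_table[locus]
        if lf.empty:
            continue
        genotypes = [
            c.consensus_composite[locus]
            for c in clusters
            if locus in c.consensus_composite
            and c.consensus_composite[locus].status is Status.OK
        ]
        out.append(locus_stats(locus, lf.freqs, lf.n_individuals, genotypes))
    return out


def cumulative_pid(per_locus: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Panel-wide (PID-unrelated, PID-sibling): products across loci.

    Order-invariant and non-increasing as loci are added (every factor is
    at most 1).
    """
    if not per_locus:
        raise ValueError("cumulative_pid requires at least one locus")
    pid_u = 1.0
    pid_sib = 1.0
    for u, s in per_locus:
        pid_u *= u
        pid_sib *= s
    return pid_u, pid_sib


def summary_table(
    stats: Sequence[LocusStats], include_pid: bool = False
) -> pd.DataFrame:
    """Presentation table: one row per locus plus unweighted overall means.

    Ne is rounded to 1 decimal, the heterozygosities to 3, only here; the
    overall row holds the unweighted across-locus means of the *unrounded*
    per-locus values, rounded last.
    """
    if not stats:
        raise ValueError("summary_table requires at least one locus")
    rows = []
    for s in stats:
        row = {
            "Locus": s.locus,
            "N": s.n,
            "Na": s.na,
            "Ne": round(s.ne, 1),
            "Ho": round(s.ho, 3),
            "He": round(s.he, 3),
            "UHe": round(s.uhe, 3),
        }
        if include_pid:
            row["PID_u"] = s.pid_u
            row["PID_sib"] = s.pid_sib
        rows.append(row)
    mean_ho = sum(s.ho for s in stats) / len(stats)
    mean_he = sum(s.he for s in stats) / len(stats)
    mean_uhe = sum(s.uhe for s in stats) / len(stats)
    overall = {
        "Locus": "Overall",
        "N": "",
        "Na": "",
        "Ne": "",
        "Ho": round(mean_ho, 3),
        "He": round(mean_he, 3),
        "UHe": round(mean_uhe, 3),
    }
    if include_pid:
        pid_u, pid_sib = cumulative_pid([(s.pid_u, s.pid_sib) for s in stats])
        overall["PID_u"] = pid_u
        overall["PID_sib"] = pid_sib
    rows.append(overall)
    return pd.DataFrame(rows)
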