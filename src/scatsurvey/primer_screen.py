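"""Species-diagnostic primer site screening on a multi-species alignment.

To build a species-specific PCR assay from a mitochondrial alignment
(target species plus every plausible off-target: sympatric carnivores,
prey, human), a candidate annealing window is diagnostic when the target
sequence differs from *every* off-target either near the primer's 3'
terminus (allele-specific discrimination: polymerase extension is most
sensitive to terminal mismatches) or by enough mismatches overall.  The
forward-primer criterion used here is >= 2 mismatches within the terminal
5 bases; the reverse-primer criterion is > 4 mismatches over the whole
primer, counted on the reverse complement whose 3' end maps to the left
edge of the alignment window.

Coordinates are 0-based half-open on alignment columns; amplicon lengths
are reported on the ungapped target sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import AlignIO

from .survey_io import SurveyFormatError, logger

Strand = Literal["forward", "reverse"]

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class AlignedSpeciesSet:
    """A multi-species alignment with one designated target sequence."""

    target_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if self.target_id not in self.sequences:
            raise KeyError(f"target {self.target_id!r} absent from alignment")
        if len(self.sequences) < 2:
            raise ValueError("need the target plus at least one off-target")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must share one length")
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"{name}: unexpected characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[self.target_id])

    @property
    def target(self) -> str:
        return self.sequences[self.target_id].upper()

    def offtargets(self) -> dict[str, str]:
        return {
            k: v.upper() for k, v in self.sequences.items() if k != self.target_id
        }

    def reverse_complement(self) -> "AlignedSpeciesSet":
        return AlignedSpeciesSet(
            target_id=self.target_id,
            sequences={
                k: v.upper().translate(_COMPLEMENT)[::-1]
                for k, v in self.sequences.items()
            },
        )


def read_alignment(path: str | Path, target_id: str) -> AlignedSpeciesSet:
    """Load an aligned FASTA into an :class:`AlignedSpeciesSet`."""
    aln = AlignIO.read(str(path), "fasta")
    sequences = {rec.id: str(rec.seq).upper() for rec in aln}
    if target_id not in sequences:
        raise SurveyFormatError(f"target {target_id!r} not in {path}")
    return AlignedSpeciesSet(target_id=target_id, sequences=sequences)


@dataclass(frozen=True)
class PrimerSite:
    """A candidate diagnostic annealing window.

    ``min_3prime_mismatches`` / ``min_total_mismatches`` are minima over all
    off-target species, i.e. the discrimination against the *worst* one.
    """

    start: int
    strand: Strand
    k: int
    min_3prime_mismatches: int
    min_total_mismatches: int


def _mismatch(target_base: str, other_base: str) -> bool:
    # A gap in the off-target is a mismatch (no pairing partner); an N is
    # treated as a match because a mismatch cannot be claimed against an
    # unknown base.
    if other_base == "N":
        return False
    return target_base != other_base


def _window_counts(
    target: str, other: str, start: int, k: int, window3: int, strand: Strand
) -> tuple[int, int]:
    """(3'-window mismatches, total mismatches) for one off-target window."""
    total = 0
    three_prime = 0
    # Forward primer reads left->right: 3' terminus is the window's right
    # edge.  A reverse primer is the reverse complement, so its 3' terminus
    # sits at the window's left edge; complementing both strands preserves
    # mismatch positions, so counting on the given strand suffices.
    if strand == "forward":
        three_range = range(start + k - window3, start + k)
    else:
        three_range = range(start, start + window3)
    three = set(three_range)
    for col in range(start, start + k):
        if _mismatch(target[col], other[col]):
            total += 1
            if col in three:
                three_prime += 1
    return three_prime, total


def scan_diagnostic_sites(
    aln: AlignedSpeciesSet,
    k: int = 20,
    window3: int = 5,
    min3: int | None = None,
    min_total: int | None = None,
    strand: Strand = "forward",
) -> list[PrimerSite]:
    """Scan every alignment window for species-diagnostic primer sites.

    A window qualifies when, versus *every* off-target species, it shows at
    least ``min3`` mismatches within the 3'-terminal ``window3`` bases and
    at least ``min_total`` mismatches anywhere in the window.  The strand
    sets the 3' geometry (right edge for forward primers, left edge for
    reverse primers, whose sequence is the reverse complement) and, when a
    threshold is left unset, the conventional criterion for that strand:
    forward primers discriminate at the 3' terminus (``min3=2``,
    ``min_total=0``), reverse primers by overall divergence (``min3=0``,
    ``min_total=5``).  Windows containing a gap or N in the *target* are
    disqualified (the primer could not be synthesised from them).
    """
    if k > aln.length:
        raise ValueError(f"primer length {k} exceeds alignment length {aln.length}")
    if not 0 < window3 <= k:
        raise ValueError("window3 must be in 1..k")
    if min3 is None:
        min3 = 2 if strand == "forward" else 0
    if min_total is None:
        min_total = 0 if strand == "forward" else 5
    target = aln.target
    others = aln.offtargets()
    sites: list[PrimerSite] = []
    for start in range(aln.length - k + 1):
        window = target[start : start + k]
        if "-" in window or "N" in window:
            continue
        min_three = None
        min_tot = None
        ok = True
        for other in others.values():
            three, total = _window_counts(target, other, start, k, window3, strand)
            min_three = three if min_three is None else min(min_three, three)
            min_tot = total if min_tot is None else min(min_tot, total)
            if three < min3 or total < min_total:
                ok = False
                break
        if ok:
            sites.append(
                PrimerSite(
                    start=start,
                    strand=strand,
                    k=k,
                    min_3prime_mismatches=min_three,  # type: ignore[arg-type]
                    min_total_mismatches=min_tot,  # type: ignore[arg-type]
                )
            )
    logger.info(
        "primer scan (%s strand, k=%d): %d/%d windows diagnostic",
        strand, k, len(sites), aln.length - k + 1,
    )
    return sites


def amplicon_for_pair(
    aln: AlignedSpeciesSet, fwd: PrimerSite, rev: PrimerSite
) -> int:
    """Ungapped target length of the product of a forward/reverse pair.

    Measured primer-start to primer-end inclusive, the convention in which
    a 20-mer pair flanking 110 target bases yields a 150 bp amplicon.
    """
    if fwd.strand != "forward" or rev.strand != "reverse":
        raise ValueError("expected a (forward, reverse) primer pair")
    fwd_end = fwd.start + fwd.k
    rev_end = rev.start + rev.k
    if rev.start < fwd_end:
        raise ValueError("reverse primer overlaps or precedes the forward primer")
    target = aln.target
    return sum(1 for c in target[fwd.start : rev_end] if c != "-")


def write_site_report(
    aln: AlignedSpeciesSet, sites: Iterable[PrimerSite], path: str | Path
) -> None:
    """CSV report: one row per site with its per-species mismatch profile."""
    others = aln.offtargets()
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["start", "strand", "k", "min_3prime_mismatches", "min_total_mismatches"]
        header += [f"{sp}_total_mismatches" for sp in others]
        writer.writerow(header)
        for site in sites:
            row = [
                site.start, site.strand, site.k,
                site.min_3prime_mismatches, site.min_total_mismatches,
            ]
            for other in others.values():
                _, total = _window_counts(
                    aln.target, other, site.start, site.k, site.k, site.strand
                )
                row.append(total)
            writer.writerow(row)
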