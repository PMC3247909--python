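"""Replicate-level presence/absence PCR call logic.

The survey screens each scat with three diagnostic PCR assays, each run in
triplicate with a known positive control and a no-template negative
control: a carnivore-generic cytochrome-b amplicon (DNA quality gate), a
snow-leopard-specific cytochrome-b amplicon (species identification), and a
Y-chromosome AMELY amplicon (sex: a band means male, reproducible absence
in amplifiable DNA means female).

A replicate whose positive control failed (no band where one was expected)
or whose negative control failed (contamination) is discarded before
calling.  The default decision rule requires at least two concordant valid
replicates, guarding symmetrically against single-replicate contamination
and single-replicate dropout; the threshold is explicit configuration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .survey_io import SampleRecord, logger

CARNIVORE_ASSAY = "carnivore"
SPECIES_ASSAY = "species"
SEX_ASSAY = "sex"


@dataclass(frozen=True)
class ReplicateOutcome:
    """One PCR replicate: band seen or not, plus control validity."""

    band_present: bool
    positive_control_ok: bool = True
    negative_control_ok: bool = True

    @property
    def valid(self) -> bool:
        return self.positive_control_ok and self.negative_control_ok


class Call(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    INVALID = "INVALID"


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class AssayCall:
    call: Call
    n_valid_replicates: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_positive > self.n_valid_replicates:
            raise ValueError("n_positive cannot exceed n_valid_replicates")


class UninterpretableAssayError(ValueError):
    """Raised when a sex call is requested without a positive species call."""


def call_assay(
    replicates: Sequence[ReplicateOutcome],
    min_valid: int = 2,
    min_positive: int = 2,
) -> AssayCall:
    """Aggregate replicate outcomes into one presence/absence call.

    Control-failed replicates are excluded entirely.  POSITIVE requires at
    least ``min_positive`` band-positive valid replicates; NEGATIVE requires
    at least ``min_valid`` valid replicates with fewer positives than that;
    anything thinner is INVALID (not enough evidence either way).
    """
    if not replicates:
        raise ValueError("call_assay requires at least one replicate")
    valid = [r for r in replicates if r.valid]
    n_valid = len(valid)
    n_pos = sum(r.band_present for r in valid)
    if n_pos >= min_positive:
        call = Call.POSITIVE
    elif n_valid >= min_valid:
        call = Call.NEGATIVE
    else:
        call = Call.INVALID
    return AssayCall(call=call, n_valid_replicates=n_valid, n_positive=n_pos)


def call_sex(
    replicates: Sequence[ReplicateOutcome],
    species_call: Call = Call.POSITIVE,
    min_valid: int = 2,
    min_positive: int = 2,
) -> Sex:
    """Call sex from Y-chromosome assay replicates.

    Absence of the Y amplicon is only evidence of a female when the sample
    is confirmed target species with amplifiable DNA, so the species call
    must be POSITIVE.  MALE needs >= ``min_positive`` valid positive
    replicates; FEMALE needs >= ``min_valid`` valid replicates, all
    negative; the mixed case (single band: dropout and contamination are
    indistinguishable) is UNKNOWN.
    """
    if species_call is not Call.POSITIVE:
        raise UninterpretableAssayError(
            "sex assay is uninterpretable without a positive species call"
        )
    if not replicates:
        raise ValueError("call_sex requires at least one replicate")
    valid = [r for r in replicates if r.valid]
    n_pos = sum(r.band_present for r in valid)
    if n_pos >= min_positive:
        return Sex.MALE
    if len(valid) >= min_valid and n_pos == 0:
        return Sex.FEMALE
    return Sex.UNKNOWN


def sample_calls(
    sample: SampleRecord, min_valid: int = 2, min_positive: int = 2
) -> dict[str, AssayCall]:
    """Carnivore/species (and, where interpretable, sex) calls for a sample."""
    out: dict[str, AssayCall] = {}
    for assay in (CARNIVORE_ASSAY, SPECIES_ASSAY):
        reps = sample.assay_replicates.get(assay, [])
        if reps:
            out[assay] = call_assay(reps, min_valid, min_positive)
    return out


@dataclass
class CongruenceTable:
    """2x2 species-call x carnivore-call counts with marginals.

    ``congruence`` is the fraction of species-positive samples that are
    also carnivore-positive (1.0 when the species target nests within the
    carnivore target and template quality is shared); None when there are
    no species-positive samples to assess.
    """

    species_pos_carn_pos: int
    species_pos_carn_neg: int
    species_neg_carn_pos: int
    species_neg_carn_neg: int
    n_invalid: int

    @property
    def total(self) -> int:
        return (
            self.species_pos_carn_pos
            + self.species_pos_carn_neg
            + self.species_neg_carn_pos
            + self.species_neg_carn_neg
        )

    @property
    def congruence(self) -> float | None:
        n_species_pos = self.species_pos_carn_pos + self.species_pos_carn_neg
        if n_species_pos == 0:
            return None
        return self.species_pos_carn_pos / n_species_pos

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "carnivore_positive": [
                    self.species_pos_carn_pos, self.species_neg_carn_pos,
                ],
                "carnivore_negative": [
                    self.species_pos_carn_neg, self.species_neg_carn_neg,
                ],
            },
            index=["species_positive", "species_negative"],
        )
        frame["total"] = frame.sum(axis=1)
        frame.loc["total"] = frame.sum(axis=0)
        return frame


def congruence_table(
    samples: Iterable[SampleRecord], min_valid: int = 2, min_positive: int = 2
) -> CongruenceTable:
    """Cross-tabulate species vs carnivore assay calls over a survey.

    Samples with an INVALID call in either assay are tallied separately in
    ``n_invalid`` rather than forced into the 2x2.  An entirely untested
    assay (no replicates at all, e.g. field blanks) counts as NEGATIVE for
    tallying, mirroring survey bookkeeping where no amplification was ever
    observed.
    """
    cells = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    n_invalid = 0
    for sample in samples:
        calls = {}
        for assay in (SPECIES_ASSAY, CARNIVORE_ASSAY):
            reps = sample.assay_replicates.get(assay, [])
            calls[assay] = (
                call_assay(reps, min_valid, min_positive).call
                if reps
                else Call.NEGATIVE
            )
        if Call.INVALID in calls.values():
            n_invalid += 1
            continue
        key = (
            calls[SPECIES_ASSAY] is Call.POSITIVE,
            calls[CARNIVORE_ASSAY] is Call.POSITIVE,
        )
        cells[key] += 1
    return CongruenceTable(
        species_pos_carn_pos=cells[(True, True)],
        species_pos_carn_neg=cells[(True, False)],
        species_neg_carn_pos=cells[(False, True)],
        species_neg_carn_neg=cells[(False, False)],
        n_invalid=n_invalid,
    )


@dataclass
class SurveySummary:
    """Stage-by-stage survey attrition tallies.

    Percentages use the survey's natural denominators: assay positives out
    of everything collected, genotyping success out of species-positives,
    and individuals out of species-positives.
    """

    n_collected: int
    n_carnivore_positive: int
    n_species_positive: int
    n_genotyped: int | None = None
    n_individuals: int | None = None

    @property
    def pct_carnivore_positive(self) -> float | None:
        return _pct(self.n_carnivore_positive, self.n_collected)

    @property
    def pct_species_positive_of_collected(self) -> float | None:
        return _pct(self.n_species_positive, self.n_collected)

    @property
    def pct_species_positive_of_carnivore(self) -> float | None:
        return _pct(self.n_species_positive, self.n_carnivore_positive)

    @property
    def pct_genotyped(self) -> float | None:
        if self.n_genotyped is None:
            return None
        return _pct(self.n_genotyped, self.n_species_positive)

    @property
    def pct_individuals(self) -> float | None:
        if self.n_individuals is None:
            return None
        return _pct(self.n_individuals, self.n_species_positive)

    def to_dict(self) -> dict:
        return {
            "n_collected": self.n_collected,
            "n_carnivore_positive": self.n_carnivore_positive,
            "n_species_positive": self.n_species_positive,
            "n_genotyped": self.n_genotyped,
            "n_individuals": self.n_individuals,
            "pct_carnivore_positive": self.pct_carnivore_positive,
            "pct_species_positive_of_collected": self.pct_species_positive_of_collected,
            "pct_species_positive_of_carnivore": self.pct_species_positive_of_carnivore,
            "pct_genotyped": self.pct_genotyped,
            "pct_individuals": self.pct_individuals,
        }


def _pct(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def survey_summary(
    samples: Sequence[SampleRecord],
    n_genotyped: int | None = None,
    n_individuals: int | None = None,
    min_valid: int = 2,
    min_positive: int = 2,
) -> SurveySummary:
    """Tally the survey funnel: collected -> carnivore+ -> species+ -> ...

    ``n_collected`` counts every sample handed in, INVALID calls included
    (the field tally is the honest denominator).  Genotyping and individual
    counts come from downstream modules and are attached when provided.
    """
    table = congruence_table(samples, min_valid, min_positive)
    summary = SurveySummary(
        n_collected=len(samples),
        n_carnivore_positive=table.species_pos_carn_pos + table.species_neg_carn_pos,
        n_species_positive=table.species_pos_carn_pos + table.species_pos_carn_neg,
        n_genotyped=n_genotyped,
        n_individuals=n_individuals,
    )
    logger.info(
        "survey summary: %d collected, %d carnivore+, %d species+",
        summary.n_collected,
        summary.n_carnivore_positive,
        summary.n_species_positive,
    )
    return summary
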