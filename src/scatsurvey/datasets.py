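"""Packaged study fixtures: the published survey's printed data.

The genotype table (10 samples x 6 loci, slash-ambiguity and missing cells
included verbatim) and the per-sample sex calls ship as CSV in the
package's external dialect, so loading them exercises the same readers
users run on their own data.  The replicate-level assay sheet for all 71
collected scats is reconstructed programmatically from the published 2x2
counts (19 species+carnivore positive / 30 carnivore-only / 22 neither)
and per-region species-positive tallies; sample identifiers beyond the 10
published ones, and the site split of the non-genotyped samples, are
synthetic — only the tallies are data.

Region spelling follows the genotype table ("Gunsa"); the running text's
"Ghunsa" refers to the same region.
"""

from __future__ import annotations

from importlib.resources import as_file, files

import pandas as pd

from .survey_io import GenotypeTable, SampleRecord, read_genotype_table
from .assay_calls import (
    CARNIVORE_ASSAY,
    SEX_ASSAY,
    SPECIES_ASSAY,
    ReplicateOutcome,
    Sex,
)

_DATA = files("scatsurvey.data")

#: sample ids of the 10 successfully genotyped scats, in table order
GENOTYPED_SAMPLE_IDS: tuple[str, ...] = (
    "SL49", "SL54", "SL55", "SL57", "SL64",
    "SL42", "SL28", "SL34", "SL25", "SL3",
)

#: the 9 species-positive scats that failed full genotyping (synthetic ids;
#: regions fill the published per-region species-positive tallies:
#: 4 Shey + 5 Dho in SPNP, 8 Gunsa + 2 Yagma in KCA)
UNGENOTYPED_SPECIES_POSITIVE: tuple[tuple[str, str, str], ...] = (
    ("SL65", "SPNP", "Dho"),
    ("SL66", "SPNP", "Dho"),
    ("SL67", "SPNP", "Dho"),
    ("SL68", "SPNP", "Dho"),
    ("SL10", "KCA", "Gunsa"),
    ("SL11", "KCA", "Gunsa"),
    ("SL12", "KCA", "Gunsa"),
    ("SL13", "KCA", "Gunsa"),
    ("SL14", "KCA", "Gunsa"),
)


def load_genotype_table() -> GenotypeTable:
    """The published 10-sample genotype table in the two-column dialect."""
    with as_file(_DATA / "survey_genotypes.csv") as path:
        return read_genotype_table(path)


def load_sex_calls() -> dict[str, Sex]:
    """Per-sample sex-assay calls for the 10 genotyped scats."""
    with as_file(_DATA / "survey_sex_calls.csv") as path:
        frame = pd.read_csv(path)
    return {rec.sample_id: Sex[rec.sex] for rec in frame.itertuples()}


def _triplicate(band: bool) -> list[ReplicateOutcome]:
    return [ReplicateOutcome(band_present=band) for _ in range(3)]


def survey_samples() -> list[SampleRecord]:
    """All 71 collected scats with replicate-level assay outcomes.

    Band patterns are uniform within each published category (positives
    amplified in all three replicates, negatives in none, controls clean):
    the printed tables record only the per-sample calls, so the replicate
    sheet is the simplest one consistent with them.
    """
    sex_calls = load_sex_calls()
    samples: list[SampleRecord] = []

    for row in load_genotype_table().rows:
        sample = SampleRecord(
            sample_id=row.sample_id, site=row.site, region=row.region, year=row.year
        )
        sample.assay_replicates[CARNIVORE_ASSAY] = _triplicate(True)
        sample.assay_replicates[SPECIES_ASSAY] = _triplicate(True)
        sample.assay_replicates[SEX_ASSAY] = _triplicate(
            sex_calls[row.sample_id] is Sex.MALE
        )
        samples.append(sample)

    for sid, site, region in UNGENOTYPED_SPECIES_POSITIVE:
        sample = SampleRecord(sample_id=sid, site=site, region=region, year=2008)
        sample.assay_replicates[CARNIVORE_ASSAY] = _triplicate(True)
        sample.assay_replicates[SPECIES_ASSAY] = _triplicate(True)
        samples.append(sample)

    # 30 carnivore-positive / species-negative; 22 negative in both.
    # Site split chosen to reproduce the collected totals (23 SPNP, 48 KCA).
    carnivore_only = [("SPNP", 9), ("KCA", 21)]
    negatives = [("SPNP", 5), ("KCA", 17)]
    i = 0
    for site, count in carnivore_only:
        for _ in range(count):
            i += 1
            sample = SampleRecord(sample_id=f"CN{i:02d}", site=site, year=2008)
            sample.assay_replicates[CARNIVORE_ASSAY] = _triplicate(True)
            sample.assay_replicates[SPECIES_ASSAY] = _triplicate(False)
            samples.append(sample)
    i = 0
    for site, count in negatives:
        for _ in range(count):
            i += 1
            sample = SampleRecord(sample_id=f"NG{i:02d}", site=site, year=2008)
            sample.assay_replicates[CARNIVORE_ASSAY] = _triplicate(False)
            sample.assay_replicates[SPECIES_ASSAY] = _triplicate(False)
            samples.append(sample)
    return samples


def species_positive_composites() -> list[dict]:
    """Composites for all 19 species-positive scats.

    The 10 genotyped samples carry their table genotypes; the 9 samples
    that failed genotyping contribute all-MISSING composites, so success
    rates computed over this list use the species-positive denominator.
    """
    from .survey_io import LocusGenotype, Status

    table = load_genotype_table()
    composites = [row.genotypes for row in table.rows]
    for _ in UNGENOTYPED_SPECIES_POSITIVE:
        composites.append(
            {locus: LocusGenotype(locus, Status.MISSING) for locus in table.loci}
        )
    return composites
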