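"""Readers and writers for noninvasive scat-survey data.

This module holds the core record types shared by the whole pipeline
(:class:`SampleRecord`, :class:`GenotypeTable`, :class:`LocusGenotype`) and
the file dialects they travel in:

* genotype tables with two allele columns per microsatellite locus, where a
  cell may be a plain fragment size in bp (``96``), a slash-separated
  candidate set recording an unresolved call (``101/103``), or a missing
  token (``-``);
* replicate-level sample sheets carrying per-PCR band/control outcomes for
  the carnivore, species and sex assays;
* replicate genotype sheets (one row per sample x locus x PCR replicate);
* a GenAlEx-style two-column codominant export (missing code ``0``).

Parsing is strict and dialect-driven: the delimiter, missing token and
slash token are explicit configuration, never sniffed, and allele identity
is exact integer equality on fragment size.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("scatsurvey")

# Default marker panel (six polymorphic felid microsatellites).
DEFAULT_LOCI: tuple[str, ...] = (
    "PUN124",
    "PUN229",
    "PUN935",
    "PUN1157",
    "PUN132",
    "PUN894",
)


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


class SurveyFormatError(ValueError):
    """Malformed survey input (bad allele token, duplicate id, bad header)."""


class Status(enum.Enum):
    """Quality of a single-locus consensus call."""

    OK = "OK"
    AMBIGUOUS = "AMBIGUOUS"
    MISSING = "MISSING"


@dataclass(frozen=True)
class LocusGenotype:
    """One sample x one locus call.

    ``alleles`` is the confirmed unordered allele pair (fragment sizes, bp)
    when ``status`` is OK; ``candidates`` is the unresolved candidate set
    when AMBIGUOUS; MISSING carries neither.  ``support`` optionally records
    per-allele replicate counts when the call came from consensus building.
    """

    locus: str
    status: Status
    alleles: tuple[int, int] | None = None
    candidates: frozenset[int] = frozenset()
    support: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status is Status.OK:
            if self.alleles is None or len(self.alleles) != 2:
                raise ValueError(f"{self.locus}: OK call requires an allele pair")
            if any(a <= 0 for a in self.alleles):
                raise ValueError(f"{self.locus}: allele sizes must be positive")
        elif self.status is Status.AMBIGUOUS:
            if not self.candidates:
                raise ValueError(f"{self.locus}: AMBIGUOUS call requires candidates")
        elif self.alleles is not None:
            raise ValueError(f"{self.locus}: MISSING call carries no alleles")

    @property
    def is_typed(self) -> bool:
        """True when the locus was scored at all (OK or AMBIGUOUS)."""
        return self.status is not Status.MISSING

    def unordered(self) -> frozenset[int] | None:
        """Allele pair as a multiset-insensitive key (OK calls only)."""
        if self.status is not Status.OK:
            return None
        return frozenset(self.alleles)  # type: ignore[arg-type]

    @property
    def is_heterozygous(self) -> bool | None:
        if self.status is not Status.OK:
            return None
        return self.alleles[0] != self.alleles[1]  # type: ignore[index]


@dataclass
class SampleRecord:
    """One collected scat sample and everything measured on it."""

    sample_id: str
    site: str = ""
    region: str = ""
    year: int | None = None
    assay_replicates: dict[str, list] = field(default_factory=dict)
    genotype_replicates: dict[str, list[frozenset[int]]] = field(default_factory=dict)


@dataclass
class GenotypeRow:
    """One genotype-table row: a sample with a call for every panel locus."""

    sample_id: str
    site: str
    region: str
    year: int
    genotypes: dict[str, LocusGenotype]


@dataclass
class GenotypeTable:
    rows: list[GenotypeRow]
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.sample_id in seen:
                raise SurveyFormatError(f"duplicate sample_id {row.sample_id!r}")
            seen.add(row.sample_id)
            for locus in self.loci:
                if locus not in row.genotypes:
                    row.genotypes[locus] = LocusGenotype(locus, Status.MISSING)

    def __len__(self) -> int:
        return len(self.rows)

    def status_counts(self) -> pd.DataFrame:
        """Per-locus tally of OK / AMBIGUOUS / MISSING calls."""
        data = {
            locus: {
                s.value: sum(1 for r in self.rows if r.genotypes[locus].status is s)
                for s in Status
            }
            for locus in self.loci
        }
        return pd.DataFrame(data).T


@dataclass(frozen=True)
class TableDialect:
    """Explicit genotype-table dialect; nothing is sniffed."""

    delimiter: str = ","
    missing: str = "-"
    slash: str = "/"
    year_range: tuple[int, int] = (1950, 2100)


DEFAULT_DIALECT = TableDialect()

_META_COLUMNS = ("sample_id", "site", "region", "year")


def _parse_allele_token(
    token: str, dialect: TableDialect, where: str
) -> frozenset[int]:
    """One cell -> candidate allele set; raises naming the offending cell."""
    parts = token.split(dialect.slash)
    out: set[int] = set()
    for part in parts:
        part = part.strip()
        try:
            value = int(part)
        except ValueError:
            raise SurveyFormatError(
                f"malformed allele token {token!r} at {where}"
            ) from None
        if value <= 0:
            raise SurveyFormatError(f"non-positive allele {value} at {where}")
        out.add(value)
    return frozenset(out)


def parse_cell_pair(
    first: str, second: str, locus: str, dialect: TableDialect = DEFAULT_DIALECT,
    where: str = "?",
) -> LocusGenotype:
    """Interpret the two allele columns of one locus for one sample.

    A missing token (or empty cell) in either column makes the locus
    MISSING.  A slash in either column makes it AMBIGUOUS with the union of
    both columns' candidates; two plain integers make an OK call, including
    homozygotes written as the same size twice.
    """
    t1, t2 = first.strip(), second.strip()
    if t1 in ("", dialect.missing) or t2 in ("", dialect.missing):
        return LocusGenotype(locus, Status.MISSING)
    c1 = _parse_allele_token(t1, dialect, where)
    c2 = _parse_allele_token(t2, dialect, where)
    if len(c1) == 1 and len(c2) == 1:
        return LocusGenotype(locus, Status.OK, alleles=(min(c1), min(c2)))
    return LocusGenotype(locus, Status.AMBIGUOUS, candidates=c1 | c2)


def _loci_from_header(header: Sequence[str]) -> tuple[str, ...]:
    loci: list[str] = []
    for name in header:
        if name in _META_COLUMNS:
            continue
        if name.endswith("_1"):
            loci.append(name[:-2])
        elif name.endswith("_2"):
            if name[:-2] not in loci:
                raise SurveyFormatError(f"column {name!r} lacks its _1 partner")
        else:
            raise SurveyFormatError(f"unrecognised column {name!r}")
    if not loci:
        raise SurveyFormatError("no locus columns found")
    return tuple(loci)


def read_genotype_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> GenotypeTable:
    """Read a two-column-per-locus genotype table.

    Expected header: ``sample_id,site,region,year`` followed by
    ``<locus>_1,<locus>_2`` pairs.  Cells follow the dialect's missing and
    slash conventions.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep=dialect.delimiter, dtype=str, keep_default_na=False
    )
    loci = _loci_from_header(list(frame.columns))
    lo, hi = dialect.year_range
    rows: list[GenotypeRow] = []
    for idx, rec in frame.iterrows():
        where_base = f"{path.name}:row {idx + 2}"
        try:
            year = int(rec["year"])
        except (KeyError, ValueError):
            raise SurveyFormatError(f"bad year at {where_base}") from None
        if not lo <= year <= hi:
            raise SurveyFormatError(f"year {year} outside {lo}-{hi} at {where_base}")
        genotypes = {
            locus: parse_cell_pair(
                rec[f"{locus}_1"], rec[f"{locus}_2"], locus, dialect,
                where=f"{where_base}, {locus}",
            )
            for locus in loci
        }
        rows.append(
            GenotypeRow(
                sample_id=rec["sample_id"].strip(),
                site=rec.get("site", "").strip(),
                region=rec.get("region", "").strip(),
                year=year,
                genotypes=genotypes,
            )
        )
    table = GenotypeTable(rows=rows, loci=loci)
    logger.info("read %d samples x %d loci from %s", len(rows), len(loci), path)
    return table


def _render_cell_pair(gt: LocusGenotype, dialect: TableDialect) -> tuple[str, str]:
    if gt.status is Status.OK:
        a, b = gt.alleles  # type: ignore[misc]
        return str(a), str(b)
    if gt.status is Status.AMBIGUOUS:
        token = dialect.slash.join(str(a) for a in sorted(gt.candidates))
        return token, token
    return dialect.missing, dialect.missing


def write_genotype_table(
    table: GenotypeTable, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Write a table back out in the same dialect (round-trips OK cells)."""
    path = Path(path)
    header = list(_META_COLUMNS) + [
        f"{locus}_{i}" for locus in table.loci for i in (1, 2)
    ]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(header)
        for row in table.rows:
            cells = [row.sample_id, row.site, row.region, str(row.year)]
            for locus in table.loci:
                cells.extend(_render_cell_pair(row.genotypes[locus], dialect))
            writer.writerow(cells)


def write_genalex_table(table: GenotypeTable, path: str | Path) -> None:
    """Export a GenAlEx-style codominant table.

    Two numeric allele columns per locus; MISSING and AMBIGUOUS cells are
    emitted as the missing code ``0`` (GenAlEx has no ambiguity notation).
    The site column doubles as the population label.
    """
    path = Path(path)
    header = ["sample_id", "pop"] + [
        f"{locus}_{i}" for locus in table.loci for i in (1, 2)
    ]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in table.rows:
            cells: list[str] = [row.sample_id, row.site]
            for locus in table.loci:
                gt = row.genotypes[locus]
                if gt.status is Status.OK:
                    cells.extend(str(a) for a in gt.alleles)  # type: ignore[union-attr]
                else:
                    cells.extend(("0", "0"))
            writer.writerow(cells)
    logger.info("wrote GenAlEx-style table (%d rows) to %s", len(table.rows), path)


# ---------------------------------------------------------------------------
# Replicate-level sheets
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = (
    "sample_id", "site", "region", "year", "assay", "replicate",
    "band", "positive_control_ok", "negative_control_ok",
)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a replicate-level assay sheet into SampleRecords.

    One row per sample x assay x PCR replicate with 0/1 flags for the band
    and both controls.  Rows for one sample may be scattered; they are
    grouped by ``sample_id`` preserving first-appearance order.
    """
    from .assay_calls import ReplicateOutcome  # deferred: avoids import cycle

    frame = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(frame.columns)
    if missing:
        raise SurveyFormatError(f"sample sheet lacks columns {sorted(missing)}")
    records: dict[str, SampleRecord] = {}
    for _, rec in frame.iterrows():
        sid = rec["sample_id"].strip()
        sample = records.get(sid)
        if sample is None:
            sample = SampleRecord(
                sample_id=sid,
                site=rec["site"].strip(),
                region=rec["region"].strip(),
                year=int(rec["year"]) if rec["year"].strip() else None,
            )
            records[sid] = sample
        outcome = ReplicateOutcome(
            band_present=_as_bool(rec["band"]),
            positive_control_ok=_as_bool(rec["positive_control_ok"]),
            negative_control_ok=_as_bool(rec["negative_control_ok"]),
        )
        sample.assay_replicates.setdefault(rec["assay"].strip(), []).append(outcome)
    logger.info("read %d samples from sample sheet %s", len(records), path)
    return list(records.values())


def write_sample_sheet(samples: Iterable[SampleRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for sample in samples:
            for assay, reps in sample.assay_replicates.items():
                for i, rep in enumerate(reps, start=1):
                    writer.writerow(
                        [
                            sample.sample_id, sample.site, sample.region,
                            "" if sample.year is None else sample.year,
                            assay, i,
                            int(rep.band_present),
                            int(rep.positive_control_ok),
                            int(rep.negative_control_ok),
                        ]
                    )


REPLICATE_SHEET_COLUMNS = (
    "sample_id", "locus", "replicate", "allele1", "allele2",
)


def read_replicate_genotypes(
    path: str | Path,
) -> dict[str, dict[str, list[frozenset[int]]]]:
    """Read a replicate genotype sheet.

    One row per sample x locus x replicate; blank allele cells mean the
    allele (or the whole reaction) did not amplify, so a fully blank row is
    an amplification failure (empty observation set).
    """
    frame = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = set(REPLICATE_SHEET_COLUMNS) - set(frame.columns)
    if missing:
        raise SurveyFormatError(f"replicate sheet lacks columns {sorted(missing)}")
    out: dict[str, dict[str, list[frozenset[int]]]] = {}
    for idx, rec in frame.iterrows():
        obs: set[int] = set()
        for col in ("allele1", "allele2"):
            token = rec[col].strip()
            if token:
                try:
                    obs.add(int(token))
                except ValueError:
                    raise SurveyFormatError(
                        f"malformed allele {token!r} at row {idx + 2}, {col}"
                    ) from None
        out.setdefault(rec["sample_id"].strip(), {}).setdefault(
            rec["locus"].strip(), []
        ).append(frozenset(obs))
    return out


def write_replicate_genotypes(
    observations: Mapping[str, Mapping[str, Sequence[frozenset[int]]]],
    path: str | Path,
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPLICATE_SHEET_COLUMNS)
        for sid, by_locus in observations.items():
            for locus, reps in by_locus.items():
                for i, obs in enumerate(reps, start=1):
                    alleles = sorted(obs)
                    a1 = str(alleles[0]) if len(alleles) >= 1 else ""
                    a2 = str(alleles[1]) if len(alleles) >= 2 else ""
                    writer.writerow([sid, locus, i, a1, a2])


def _as_bool(token: str) -> bool:
    token = token.strip().lower()
    if token in ("1", "true", "yes", "y"):
        return True
    if token in ("0", "false", "no", "n", ""):
        return False
    raise SurveyFormatError(f"cannot interpret boolean token {token!r}")
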