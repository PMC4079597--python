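"""Specimen records: FASTA + metadata reading, validation, and filters.

A specimen record couples one aligned COI barcode sequence with its
taxonomic labels (binomial species name, optional subspecies epithet,
genus) and a geographic region code.  Region codes follow the convention
of Australian barcode surveys: state codes (QLD, NSW, NT, WA, SA, VIC, CT)
plus broad-scope codes for records from outside the continent
(EM = Eastern Malesia, Pi = Pacific islands, WM = Western Malesia,
SEA = continental Southeast Asia, OW = other Old World regions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Region codes understood without a warning.
AUSTRALIAN_REGIONS = frozenset({"QLD", "NSW", "NT", "WA", "SA", "VIC", "CT"})
SCOPE_REGIONS = frozenset({"EM", "Pi", "WM", "SEA", "OW"})
KNOWN_REGIONS = AUSTRALIAN_REGIONS | SCOPE_REGIONS

GAP_CHARS = frozenset("-.")
MISSING_CHARS = frozenset("Nn?")

METADATA_COLUMNS = [
    "sample_id",
    "process_id",
    "species",
    "subspecies",
    "genus",
    "region",
    "lat",
    "lon",
]


class SpecimenError(ValueError):
    """Raised for malformed or inconsistent specimen input."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcode sequence with its taxonomic and geographic labels."""

    sample_id: str
    species: str
    sequence: str
    process_id: str = ""
    subspecies: str | None = None
    genus: str = ""
    region: str = "unknown"
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise SpecimenError("sample_id must be non-empty")
        if not self.genus and self.species:
            object.__setattr__(self, "genus", self.species.split()[0])

    @property
    def trinomial(self) -> str:
        if self.subspecies:
            return f"{self.species} {self.subspecies}"
        return self.species

    @property
    def unaligned_length(self) -> int:
        """Informative sites: everything except gaps and N.

        IUPAC ambiguity codes count — they are real base calls.
        """
        skip = GAP_CHARS | MISSING_CHARS
        return sum(1 for c in self.sequence if c not in skip)


@dataclass
class SpecimenTable:
    """An ordered, validated collection of specimen records."""

    records: list[SpecimenRecord]
    scope_name: str = "dataset"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = []
        for r in self.records:
            if r.sample_id in seen:
                dupes.append(r.sample_id)
            seen.add(r.sample_id)
        if dupes:
            raise SpecimenError(f"duplicate sample_id values: {sorted(set(dupes))}")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            offenders = sorted(
                {r.sample_id for r in self.records if len(r.sequence) != max(lengths)}
            )
            raise SpecimenError(
                "aligned sequence lengths differ "
                f"(found {sorted(lengths)}); offending ids include {offenders[:10]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    def species_of(self) -> dict[str, str]:
        return {r.sample_id: r.species for r in self.records}

    def genus_of(self) -> dict[str, str]:
        return {r.sample_id: r.genus for r in self.records}

    def region_of(self) -> dict[str, str]:
        return {r.sample_id: r.region for r in self.records}

    def subset(self, ids: Iterable[str], scope_name: str | None = None) -> "SpecimenTable":
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise SpecimenError(f"unknown sample_ids: {sorted(unknown)}")
        return SpecimenTable(
            [r for r in self.records if r.sample_id in wanted],
            scope_name=scope_name or self.scope_name,
        )

    def restrict_to_regions(self, regions: Iterable[str], scope_name: str) -> "SpecimenTable":
        regions = set(regions)
        return SpecimenTable(
            [r for r in self.records if r.region in regions], scope_name=scope_name
        )


def _parse_header_dialect(header: str) -> dict[str, str]:
    """Pipe-delimited header: sample_id|species|subspecies-or-empty|region."""
    parts = header.split("|")
    if len(parts) != 4:
        raise SpecimenError(
            f"header {header!r} does not match sample_id|species|subspecies|region"
        )
    sample_id, species, subspecies, region = (p.strip() for p in parts)
    return {
        "sample_id": sample_id,
        "species": species,
        "subspecies": subspecies or None,
        "region": region,
    }


def _check_region(region: str, sample_id: str) -> str:
    if region and region not in KNOWN_REGIONS:
        warnings.warn(
            f"unknown region code {region!r} for {sample_id}; set to 'unknown'",
            stacklevel=3,
        )
        return "unknown"
    return region or "unknown"


def read_metadata(metadata_source: str | Path) -> pd.DataFrame:
    """Read the UTF-8 TSV metadata table (header row required)."""
    meta = pd.read_csv(metadata_source, sep="\t", dtype=str).fillna("")
    missing = {"sample_id", "species"} - set(meta.columns)
    if missing:
        raise SpecimenError(f"metadata table lacks required columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise SpecimenError(f"duplicate sample_id in metadata: {dupes}")
    return meta


def read_specimens(
    fasta_source: str | Path,
    metadata_source: str | Path | None = None,
    scope_name: str = "dataset",
) -> SpecimenTable:
    """Read specimens from FASTA, joining metadata on ``sample_id``.

    Without a metadata table, FASTA headers must carry the pipe-delimited
    dialect ``sample_id|species|subspecies-or-empty|region``.

    Raises :class:`SpecimenError` listing every FASTA entry that has no
    metadata row, and on duplicate ids or unequal aligned lengths.
    """
    entries = list(SeqIO.parse(str(fasta_source), "fasta"))
    if not entries:
        raise SpecimenError(f"no FASTA entries in {fasta_source}")

    records: list[SpecimenRecord] = []
    if metadata_source is None:
        for e in entries:
            fields = _parse_header_dialect(e.description)
            fields["region"] = _check_region(fields["region"], fields["sample_id"])
            records.append(SpecimenRecord(sequence=str(e.seq).upper(), **fields))
    else:
        meta = read_metadata(metadata_source)
        rows: Mapping[str, dict] = {
            row["sample_id"]: row for row in meta.to_dict("records")
        }
        orphans = [e.id for e in entries if e.id not in rows]
        if orphans:
            raise SpecimenError(
                f"FASTA entries with no metadata row: {sorted(orphans)}"
            )
        for e in entries:
            row = rows[e.id]
            lat = float(row["lat"]) if row.get("lat") else None
            lon = float(row["lon"]) if row.get("lon") else None
            records.append(
                SpecimenRecord(
                    sample_id=e.id,
                    process_id=row.get("process_id", ""),
                    species=row["species"],
                    subspecies=row.get("subspecies") or None,
                    genus=row.get("genus", ""),
                    region=_check_region(row.get("region", ""), e.id),
                    lat=lat,
                    lon=lon,
                    sequence=str(e.seq).upper(),
                )
            )
    return SpecimenTable(records, scope_name=scope_name)


def write_specimens(
    table: SpecimenTable, fasta_dest: str | Path, metadata_dest: str | Path
) -> None:
    """Write a specimen table back out as FASTA + metadata TSV."""
    with open(fasta_dest, "w") as fh:
        for r in table:
            fh.write(f">{r.sample_id}\n{r.sequence}\n")
    rows = [
        {
            "sample_id": r.sample_id,
            "process_id": r.process_id,
            "species": r.species,
            "subspecies": r.subspecies or "",
            "genus": r.genus,
            "region": r.region,
            "lat": "" if r.lat is None else r.lat,
            "lon": "" if r.lon is None else r.lon,
        }
        for r in table
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_dest, sep="\t", index=False
    )


def filter_by_length(table: SpecimenTable, min_unaligned_length: int = 500) -> SpecimenTable:
    """Keep records strictly longer than the cutoff in informative sites.

    The cutoff is on unaligned length — non-gap, non-N characters —
    mirroring the standard "longer than 500 bp" barcode-quality filter.
    """
    if min_unaligned_length < 0:
        raise ValueError("min_unaligned_length must be >= 0")
    kept = [r for r in table if r.unaligned_length > min_unaligned_length]
    removed = len(table) - len(kept)
    if removed:
        logger.info("length filter removed %d of %d records", removed, len(table))
    if not kept:
        raise SpecimenError("no records survive length filter")
    return SpecimenTable(kept, scope_name=table.scope_name)
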