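"""Decision rules for barcode-based species delimitation.

A taxon is flagged as a candidate split when its maximum intraspecific
divergence exceeds the threshold (default 2%) AND its specimens fall
into two or more reciprocally monophyletic clusters separated by more
than the threshold; it is flagged a candidate lump when its nearest
heterospecific neighbour lies below the threshold.  The threshold is an
operational trigger for in-depth study, not a species concept.

Candidate splits are resolved against independent evidence: Confirmed
Candidate Species (CCS) when morphology or a nuclear marker supports the
distinction; Deep Conspecific Lineage (DCL) when both lines of evidence
are explicitly negative; unresolved otherwise.  Lump candidates carry no
CCS/DCL resolution — they are reported with their partner taxa, since
their causes (misidentification, synonymy, introgression) need
case-by-case work.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .clusters import ClusterPartition, is_reciprocally_monophyletic
from .distance import DistanceMatrix
from .gapstats import SpeciesGapStats

logger = logging.getLogger(__name__)

COHESIVE = "cohesive"
SPLIT = "split-candidate"
LUMP = "lump-candidate"
SPLIT_AND_LUMP = "split-and-lump"

CCS = "CCS"
DCL = "DCL"
UNRESOLVED = "unresolved"
NOT_APPLICABLE = "not-applicable"

_TRISTATE = ("yes", "no", "unknown")


@dataclass(frozen=True)
class EvidenceRecord:
    """Independent evidence for a candidate split of one taxon."""

    taxon: str
    morphology_distinct: str = "unknown"
    nuclear_diagnostic: str = "unknown"
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("morphology_distinct", "nuclear_diagnostic"):
            v = getattr(self, name)
            if v not in _TRISTATE:
                raise ValueError(f"{name} must be one of {_TRISTATE}, got {v!r}")


@dataclass
class TaxonDelimitation:
    """Delimitation outcome for one taxon."""

    taxon: str
    status: str
    partition: ClusterPartition | None = None
    delta: float | None = None
    delta_sp: float | None = None
    nn_taxon: str | None = None
    lump_partners: list[str] = field(default_factory=list)
    resolution: str = NOT_APPLICABLE
    watch: bool = False

    @property
    def is_split(self) -> bool:
        return self.status in (SPLIT, SPLIT_AND_LUMP)

    @property
    def is_lump(self) -> bool:
        return self.status in (LUMP, SPLIT_AND_LUMP)


@dataclass
class DelimitationReport:
    """Per-taxon delimitation statuses at one scope and threshold."""

    scope: str
    threshold_pct: float
    entries: dict[str, TaxonDelimitation]

    def __iter__(self):
        return iter(self.entries.values())

    def __getitem__(self, taxon: str) -> TaxonDelimitation:
        return self.entries[taxon]

    def taxa_with_status(self, status: str) -> list[str]:
        return sorted(t for t, e in self.entries.items() if e.status == status)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in sorted(self.entries.values(), key=lambda x: x.taxon):
            p = e.partition
            rows.append(
                {
                    "taxon": e.taxon,
                    "scope": self.scope,
                    "status": e.status,
                    "resolution": e.resolution,
                    "delta": "N/A" if e.delta is None else f"{e.delta:.2f}",
                    "delta_sp": "N/A" if e.delta_sp is None else f"{e.delta_sp:.2f}",
                    "nn_taxon": e.nn_taxon or "N/A",
                    "n_clusters": p.n_groups if p else 1,
                    "cluster_sizes": ";".join(str(len(g)) for g in p.groups)
                    if p
                    else "",
                    "min_between_cluster_pct": f"{p.between_min_pct:.2f}"
                    if p and p.between_min_pct is not None
                    else "N/A",
                    "lump_partners": ";".join(e.lump_partners),
                    "watch": e.watch,
                    "threshold_pct": self.threshold_pct,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, destination: str | Path) -> None:
        self.to_frame().to_csv(destination, sep="\t", index=False)


def flag_candidates(
    stats: Iterable[SpeciesGapStats],
    partitions: Mapping[str, ClusterPartition],
    threshold_pct: float = 2.0,
    min_interspecific: pd.DataFrame | None = None,
    watch_min_pct: float = 1.0,
    scope: str = "dataset",
) -> DelimitationReport:
    """Assign cohesive / split-candidate / lump-candidate statuses.

    Split: delta > threshold AND the taxon's partition qualifies
    (>= 2 monophyletic clusters more than the threshold apart).
    Lump: delta_sp < threshold.  Both: split-and-lump.  Strict
    inequalities on both sides.  ``min_interspecific`` (taxon x taxon
    minimum distances) extends lump partners beyond the single nearest
    neighbour.  Taxa with near-threshold intraspecific divergence
    (delta in [watch_min_pct, threshold]) that do not qualify as splits
    are marked on a report-only watch list — shallow clusters worth a
    look when they match an existing taxonomic division.
    """
    stats = list(stats)
    stat_taxa = {s.taxon for s in stats}
    part_taxa = set(partitions)
    if not part_taxa <= stat_taxa:
        raise ValueError(
            f"partitions cover taxa missing from stats: {sorted(part_taxa - stat_taxa)}"
        )
    entries: dict[str, TaxonDelimitation] = {}
    for st in stats:
        part = partitions.get(st.taxon)
        split = (
            st.delta is not None
            and st.delta > threshold_pct
            and part is not None
            and part.qualifies
        )
        lump = st.delta_sp is not None and st.delta_sp < threshold_pct
        if split and lump:
            status = SPLIT_AND_LUMP
        elif split:
            status = SPLIT
        elif lump:
            status = LUMP
        else:
            status = COHESIVE
        partners: list[str] = []
        if lump:
            if min_interspecific is not None and st.taxon in min_interspecific.index:
                row = min_interspecific.loc[st.taxon]
                partners = sorted(row.index[(row < threshold_pct).fillna(False)])
            elif st.nn_taxon is not None:
                partners = [st.nn_taxon]
        watch = (
            not split
            and st.delta is not None
            and watch_min_pct <= st.delta <= threshold_pct
        )
        entries[st.taxon] = TaxonDelimitation(
            taxon=st.taxon,
            status=status,
            partition=part,
            delta=st.delta,
            delta_sp=st.delta_sp,
            nn_taxon=st.nn_taxon,
            lump_partners=partners,
            watch=watch,
        )
    return DelimitationReport(scope=scope, threshold_pct=threshold_pct, entries=entries)


def resolve_candidate(entry: TaxonDelimitation, evidence: EvidenceRecord) -> str:
    """CCS/DCL resolution of a candidate split from independent evidence.

    One positive line of evidence (morphology or nuclear) confirms the
    candidate (CCS); two explicit negatives demote it to a deep
    conspecific lineage (DCL); anything else stays unresolved.
    """
    if not entry.is_split:
        warnings.warn(
            f"resolve_candidate called on non-split taxon {entry.taxon!r}",
            stacklevel=2,
        )
        entry.resolution = NOT_APPLICABLE
        return NOT_APPLICABLE
    m, g = evidence.morphology_distinct, evidence.nuclear_diagnostic
    if m == "yes" or g == "yes":
        res = CCS
    elif m == "no" and g == "no":
        res = DCL
    else:
        res = UNRESOLVED
    entry.resolution = res
    return res


def apply_evidence(
    report: DelimitationReport, evidence: Mapping[str, EvidenceRecord]
) -> DelimitationReport:
    """Resolve every split candidate that has an evidence record."""
    for entry in report:
        if entry.is_split:
            ev = evidence.get(entry.taxon)
            entry.resolution = (
                resolve_candidate(entry, ev) if ev is not None else UNRESOLVED
            )
    return report


def read_evidence(source: str | Path) -> dict[str, EvidenceRecord]:
    """Read the evidence TSV (taxon, morphology_distinct, nuclear_diagnostic, notes)."""
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("unknown")
    out = {}
    for row in df.to_dict("records"):
        out[row["taxon"]] = EvidenceRecord(
            taxon=row["taxon"],
            morphology_distinct=row.get("morphology_distinct", "unknown"),
            nuclear_diagnostic=row.get("nuclear_diagnostic", "unknown"),
            notes=row.get("notes", "") if row.get("notes") != "unknown" else "",
        )
    return out


def subspecies_congruence(
    tree: dendropy.Tree,
    matrix: DistanceMatrix,
    trinomials: Mapping[str, tuple[str, str | None]],
) -> pd.DataFrame:
    """Audit named subspecies against genetic clusters.

    ``trinomials`` maps sample_id -> (species, subspecies-or-None).  For
    every species with >= 2 labelled subspecies, each subspecies is
    tested for reciprocal monophyly and the minimum pairwise distance
    between every subspecies pair is reported.  A species is "congruent"
    when all its subspecies are monophyletic.  Species with a single
    subspecies label are skipped with a note.
    """
    by_species: dict[str, dict[str, list[str]]] = {}
    for sid, (species, subsp) in trinomials.items():
        if subsp:
            by_species.setdefault(species, {}).setdefault(subsp, []).append(sid)

    rows = []
    pct = matrix.percent
    if not any(len(subs) >= 2 for subs in by_species.values()):
        raise ValueError("no species with >= 2 labelled subspecies")
    for species in sorted(by_species):
        subs = by_species[species]
        if len(subs) < 2:
            logger.info("species %s has a single subspecies label; skipped", species)
            continue
        mono = {
            name: is_reciprocally_monophyletic(tree, ids)
            for name, ids in sorted(subs.items())
        }
        names = sorted(subs)
        for a_i, a in enumerate(names):
            ia = [matrix.index_of(s) for s in subs[a]]
            for b in names[a_i + 1:]:
                ib = [matrix.index_of(s) for s in subs[b]]
                block = pct[np.ix_(ia, ib)]
                block = block[np.isfinite(block)]
                rows.append(
                    {
                        "species": species,
                        "subspecies_a": a,
                        "subspecies_b": b,
                        "monophyletic_a": mono[a],
                        "monophyletic_b": mono[b],
                        "min_between_pct": float(block.min()) if block.size else None,
                        "congruent_species": all(mono.values()),
                    }
                )
    return pd.DataFrame(rows)
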