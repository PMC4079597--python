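"""Diagnostic nucleotide positions between two specimen groups.

Given a second (typically nuclear, e.g. 28S rDNA D2) alignment and a
two-way grouping of specimens — usually the two barcode clusters of a
candidate split — a position is diagnostic when the groups are fixed for
non-overlapping states there.  Coordinates are 1-based on the provided
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

BASES = set("ACGT")


@dataclass
class DiagnosticSite:
    position: int  # 1-based
    group1_states: frozenset[str]
    group2_states: frozenset[str]


@dataclass
class DiagnosticSiteReport:
    sites: list[DiagnosticSite]
    n_usable_sites: int
    n_unusable_sites: int

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]


def diagnostic_sites(
    alignment: Mapping[str, str],
    grouping: Mapping[str, int],
    allow_missing_fraction: float = 0.0,
) -> DiagnosticSiteReport:
    """Find fixed, non-overlapping differences between two groups.

    ``alignment`` maps sample_id to aligned sequence; ``grouping`` maps
    sample_id to group 1 or 2.  A column is usable when, in each group,
    the fraction of records without an unambiguous base (gap, N,
    ambiguity code) is at most ``allow_missing_fraction`` and at least
    one base remains; it is diagnostic when within-group states are
    uniform and the two groups' states differ.  The strict default
    (``allow_missing_fraction = 0``) means "diagnostic substitution" in
    the classical sense: a fixed difference with no missing data.
    """
    if not 0.0 <= allow_missing_fraction <= 1.0:
        raise ValueError("allow_missing_fraction must be in [0, 1]")
    g1 = [sid for sid, g in grouping.items() if g == 1]
    g2 = [sid for sid, g in grouping.items() if g == 2]
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    missing = [sid for sid in grouping if sid not in alignment]
    if missing:
        raise KeyError(f"grouped ids absent from alignment: {sorted(missing)}")
    seqs1 = [alignment[s].upper() for s in g1]
    seqs2 = [alignment[s].upper() for s in g2]
    lengths = {len(s) for s in seqs1 + seqs2}
    if len(lengths) != 1:
        raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
    (length,) = lengths

    sites: list[DiagnosticSite] = []
    usable = unusable = 0
    for col in range(length):
        col1 = [s[col] for s in seqs1]
        col2 = [s[col] for s in seqs2]
        ok = True
        states: list[frozenset[str]] = []
        for colvals in (col1, col2):
            present = [c for c in colvals if c in BASES]
            n_missing = len(colvals) - len(present)
            if not present or n_missing / len(colvals) > allow_missing_fraction:
                ok = False
                break
            states.append(frozenset(present))
        if not ok:
            unusable += 1
            continue
        usable += 1
        s1, s2 = states
        if len(s1) == 1 and len(s2) == 1 and not (s1 & s2):
            sites.append(
                DiagnosticSite(
                    position=col + 1, group1_states=s1, group2_states=s2
                )
            )
    return DiagnosticSiteReport(
        sites=sites, n_usable_sites=usable, n_unusable_sites=unusable
    )


def read_grouping(source) -> dict[str, int]:
    """Read a grouping TSV (sample_id, group) with groups coded 1/2."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t", dtype=str)
    out = {}
    for row in df.to_dict("records"):
        g = int(row["group"])
        if g not in (1, 2):
            raise ValueError(f"group must be 1 or 2, got {g}")
        out[row["sample_id"]] = g
    return out
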