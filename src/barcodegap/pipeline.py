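"""Estimator-style interfaces composing the delimitation pipeline.

`K2PDistance` (a transformer), `NeighborJoining` and
`BarcodeGapDelimiter` follow scikit-learn conventions — ``fit`` /
``transform``, ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore — so they compose with sklearn tooling.  The
underlying per-operation functions live in the topical modules
(:mod:`.distance`, :mod:`.nj`, :mod:`.clusters`, :mod:`.gapstats`,
:mod:`.delimit`).

`analyze` orchestrates the two runs a barcode survey performs: one
restricted to the focal region (Australia by default) and one on the
full dataset, merging per-taxon statistics into a single checklist-style
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import clusters, delimit, gapstats
from .distance import DEFAULT_MIN_OVERLAP, DistanceMatrix, distance_matrix
from .nj import build_nj
from .records import AUSTRALIAN_REGIONS, SpecimenTable, filter_by_length


class K2PDistance(TransformerMixin, BaseEstimator):
    """Pairwise K2P distance matrix as a scikit-learn transformer.

    Parameters
    ----------
    min_overlap : int
        Minimum jointly comparable sites per pair; pairs below it are NaN.
    percent : bool
        Return distances x100 (percent) rather than substitutions/site.
    """

    def __init__(self, min_overlap: int = DEFAULT_MIN_OVERLAP, percent: bool = True):
        self.min_overlap = min_overlap
        self.percent = percent

    def fit(self, X, y=None):
        self._validate(X)
        self.n_sequences_in_ = len(X)
        return self

    def transform(self, X) -> np.ndarray:
        """Square distance matrix over sequences (NaN = undefined pair)."""
        table = self._as_table(X)
        dm = distance_matrix(
            table, min_overlap=self.min_overlap, max_undefined_fraction=1.0
        )
        return dm.percent if self.percent else dm.values.copy()

    @staticmethod
    def _validate(X) -> None:
        if len(X) < 2:
            raise ValueError("need at least 2 sequences")

    @staticmethod
    def _as_table(X) -> SpecimenTable:
        if isinstance(X, SpecimenTable):
            return X
        from .records import SpecimenRecord

        return SpecimenTable(
            [
                SpecimenRecord(sample_id=f"x{i}", species="unlabelled", sequence=s)
                for i, s in enumerate(X)
            ]
        )


class NeighborJoining(BaseEstimator):
    """Neighbour-joining tree estimator over a precomputed distance matrix.

    ``fit`` accepts a :class:`DistanceMatrix` or a square ndarray (taken
    at face value in whatever units it carries) and exposes the tree as
    ``tree_`` (a dendropy tree) with tip ids in ``ids_``.
    """

    def fit(self, X, y=None):
        if isinstance(X, DistanceMatrix):
            dm = X
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != X.shape[1]:
                raise ValueError("X must be a square distance matrix")
            dm = DistanceMatrix(
                ids=[f"t{i}" for i in range(X.shape[0])],
                values=X,
                defined_mask=np.isfinite(X),
            )
        self.tree_ = build_nj(dm)
        self.ids_ = list(dm.ids)
        return self


class BarcodeGapDelimiter(BaseEstimator):
    """Full barcode-gap delimitation of a specimen table.

    ``fit`` runs length filtering, K2P distances, neighbour joining,
    per-taxon gap statistics, threshold clustering and the split/lump
    decision rules; ``fit_predict`` returns an integer cluster label per
    retained specimen (taxon x divergent-cluster granularity).

    Parameters
    ----------
    min_length : int
        Length-filter cutoff (strict, unaligned informative sites).
    min_overlap : int
        Minimum comparable sites for a defined pairwise distance.
    threshold_pct : float
        Operational divergence threshold (percent) for both the split
        and the lump rule.
    scope : iterable of str or None
        Region codes to restrict the analysis to (None = all records).
    sd_mode : str
        "pair" or "sem" dispersion for the per-taxon sd.
    watch_min_pct : float
        Lower bound of the report-only watch band below the threshold.
    """

    def __init__(
        self,
        min_length: int = 500,
        min_overlap: int = DEFAULT_MIN_OVERLAP,
        threshold_pct: float = 2.0,
        scope: Iterable[str] | None = None,
        sd_mode: str = "pair",
        watch_min_pct: float = 1.0,
    ):
        self.min_length = min_length
        self.min_overlap = min_overlap
        self.threshold_pct = threshold_pct
        self.scope = scope
        self.sd_mode = sd_mode
        self.watch_min_pct = watch_min_pct

    def fit(self, X: SpecimenTable, y=None, evidence: Mapping | None = None):
        if not isinstance(X, SpecimenTable):
            raise TypeError("X must be a SpecimenTable")
        table = X
        if self.scope is not None:
            table = table.restrict_to_regions(self.scope, scope_name="scoped")
            if not len(table):
                raise ValueError("scope selects no records")
        table = filter_by_length(table, self.min_length)
        dm = distance_matrix(table, min_overlap=self.min_overlap)
        if not dm.fully_defined:
            dm = dm.drop_undefined()
            table = table.subset(dm.ids)
        self.table_ = table
        self.matrix_ = dm
        self.tree_ = build_nj(dm)

        labels = table.species_of()
        self.stats_ = gapstats.intraspecific_stats(
            dm, labels, scope=table.scope_name, sd_mode=self.sd_mode
        )
        taxa = {labels[i] for i in dm.ids}
        self.nn_ = (
            gapstats.nearest_neighbour(dm, labels) if len(taxa) > 1 else {}
        )
        for st in self.stats_:
            if st.taxon in self.nn_:
                st.delta_sp, st.nn_taxon = self.nn_[st.taxon]
        self.min_interspecific_ = (
            gapstats.min_interspecific(dm, labels) if len(taxa) > 1 else None
        )
        self.partitions_ = {}
        for taxon in sorted(taxa):
            members = [i for i in dm.ids if labels[i] == taxon]
            part = clusters.split_clusters(
                dm, self.tree_, members,
                threshold_pct=self.threshold_pct, taxon=taxon,
            )
            if part.n_groups >= 2 and not part.qualifies:
                # the criterion is existential: look for a coarser
                # single-linkage cut whose groups are all monophyletic
                better = clusters.qualifying_partition(
                    dm, self.tree_, members,
                    threshold_pct=self.threshold_pct, taxon=taxon,
                )
                if better is not None:
                    part = better
            self.partitions_[taxon] = part
        self.report_ = delimit.flag_candidates(
            self.stats_,
            self.partitions_,
            threshold_pct=self.threshold_pct,
            min_interspecific=self.min_interspecific_,
            watch_min_pct=self.watch_min_pct,
            scope=table.scope_name,
        )
        if evidence is not None:
            delimit.apply_evidence(self.report_, evidence)
        self.statuses_ = {e.taxon: e.status for e in self.report_}

        cluster_key: dict[tuple[str, int], int] = {}
        labels_out = np.empty(len(table), dtype=int)
        for pos, sid in enumerate(table.ids):
            part = self.partitions_[labels[sid]]
            g = next(i for i, grp in enumerate(part.groups) if sid in grp)
            key = (labels[sid], g)
            cluster_key.setdefault(key, len(cluster_key))
            labels_out[pos] = cluster_key[key]
        self.labels_ = labels_out
        return self

    def fit_predict(self, X: SpecimenTable, y=None, **fit_kwargs) -> np.ndarray:
        return self.fit(X, y, **fit_kwargs).labels_


@dataclass
class AnalysisResult:
    """Outputs of the two-scope survey analysis."""

    regional: BarcodeGapDelimiter | None
    full: BarcodeGapDelimiter
    table1: pd.DataFrame
    subspecies: pd.DataFrame | None


def checklist_table(
    table: SpecimenTable,
    regional: BarcodeGapDelimiter | None,
    full: BarcodeGapDelimiter,
) -> pd.DataFrame:
    """Checklist-style per-taxon table merging both scopes.

    Columns mirror a barcode-survey summary table: N, per-region counts,
    regional-scope deltaA/dA/sdA, full-scope deltaG/dG/sdG, delta_sp and
    nearest neighbour (all percent, 2 decimals, N/A when undefined).
    """
    regions = sorted({r.region for r in table})
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for r in table:
        counts.setdefault(r.species, {}).setdefault(r.region, 0)
        counts[r.species][r.region] += 1
        totals[r.species] = totals.get(r.species, 0) + 1

    reg_stats = {s.taxon: s for s in (regional.stats_ if regional else [])}
    full_stats = {s.taxon: s for s in full.stats_}
    rows = []
    for taxon in sorted(totals):
        fs = full_stats.get(taxon)
        rs = reg_stats.get(taxon)
        render = lambda st, attr: (
            "N/A" if st is None or getattr(st, attr) is None
            else f"{getattr(st, attr):.2f}"
        )
        row = {"taxon": taxon, "N": totals[taxon]}
        for region in regions:
            row[f"n_{region}"] = counts[taxon].get(region, 0)
        row.update(
            {
                "deltaA": render(rs, "delta"),
                "dA": render(rs, "d_mean"),
                "sdA": render(rs, "sd"),
                "deltaG": render(fs, "delta"),
                "dG": render(fs, "d_mean"),
                "sdG": render(fs, "sd"),
                "delta_sp": render(fs, "delta_sp"),
                "nn_taxon": fs.nn_taxon if fs and fs.nn_taxon else "N/A",
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def analyze(
    table: SpecimenTable,
    regional_regions: Iterable[str] = AUSTRALIAN_REGIONS,
    min_length: int = 500,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    threshold_pct: float = 2.0,
    evidence: Mapping | None = None,
    sd_mode: str = "pair",
    watch_min_pct: float = 1.0,
) -> AnalysisResult:
    """Run the survey's two analyses: regional scope and full dataset.

    The full-dataset delimiter drives the split/lump report (its delta
    is the global Dmax and its delta_sp the nearest-neighbour distance);
    the regional run contributes the within-region columns of the
    checklist table.  The regional run is skipped (None) when fewer than
    two in-region records survive, or when no record carries a regional
    code.
    """
    params = dict(
        min_length=min_length,
        min_overlap=min_overlap,
        threshold_pct=threshold_pct,
        sd_mode=sd_mode,
        watch_min_pct=watch_min_pct,
    )
    full = BarcodeGapDelimiter(**params).fit(table, evidence=evidence)

    regional_regions = set(regional_regions)
    n_regional = sum(1 for r in table if r.region in regional_regions)
    regional = None
    if n_regional >= 2:
        try:
            regional = BarcodeGapDelimiter(
                scope=regional_regions, **params
            ).fit(table, evidence=evidence)
        except ValueError:
            regional = None

    table1 = checklist_table(full.table_, regional, full)

    subspecies = None
    trinomials = {
        r.sample_id: (r.species, r.subspecies)
        for r in full.table_
    }
    n_poly = {}
    for sid, (sp, ssp) in trinomials.items():
        if ssp:
            n_poly.setdefault(sp, set()).add(ssp)
    if any(len(v) >= 2 for v in n_poly.values()):
        subspecies = delimit.subspecies_congruence(
            full.tree_, full.matrix_, trinomials
        )
    return AnalysisResult(
        regional=regional, full=full, table1=table1, subspecies=subspecies
    )
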