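"""Per-taxon barcode-gap statistics at a named geographic scope.

For each taxon with N >= 2 specimens in scope:

* delta — maximum intraspecific K2P distance (the per-species "Dmax";
  deltaA at a within-country scope, deltaG at the global scope),
* d_mean — mean intraspecific distance over all N(N-1)/2 pairs,
* sd — dispersion of those pairwise distances (population formula by
  default; a standard-error-of-the-mean mode is available),
* delta_sp — distance to the nearest heterospecific neighbour, with the
  neighbouring taxon's name.

All statistics are reported on the percent scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class SpeciesGapStats:
    """Barcode-gap summary for one taxon at one scope (percent scale)."""

    taxon: str
    scope: str
    n: int
    delta: float | None = None
    d_mean: float | None = None
    sd: float | None = None
    delta_sp: float | None = None
    nn_taxon: str | None = None

    def render(self, x: float | None) -> str:
        return "N/A" if x is None else f"{x:.2f}"


def _pair_values(pct: np.ndarray, idx: list[int]) -> np.ndarray:
    """Defined pairwise distances among a set of row/col indices."""
    block = pct[np.ix_(idx, idx)]
    vals = block[np.triu_indices(len(idx), k=1)]
    return vals[np.isfinite(vals)]


def intraspecific_stats(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    scope_filter: Callable[[str], bool] | None = None,
    scope: str = "dataset",
    sd_mode: str = "pair",
) -> list[SpeciesGapStats]:
    """delta / d_mean / sd per taxon over specimens passing the scope filter.

    ``scope_filter`` takes a sample_id and returns whether it is in scope
    (None = everything).  Taxa entirely out of scope are omitted; taxa
    with a single in-scope specimen are emitted with undefined (None)
    statistics.  ``sd_mode`` is "pair" (population sd over the pairwise
    distances) or "sem" (standard error of their mean).
    """
    if sd_mode not in ("pair", "sem"):
        raise ValueError("sd_mode must be 'pair' or 'sem'")
    unlabelled = [i for i in matrix.ids if i not in labels]
    if unlabelled:
        raise KeyError(f"ids without a taxon label: {sorted(unlabelled)}")

    in_scope = [
        i for i in matrix.ids if scope_filter is None or scope_filter(i)
    ]
    if not in_scope:
        raise ValueError("scope filter selects no records")
    pct = matrix.percent
    by_taxon: dict[str, list[int]] = {}
    for sid in in_scope:
        by_taxon.setdefault(labels[sid], []).append(matrix.index_of(sid))

    out: list[SpeciesGapStats] = []
    for taxon in sorted(by_taxon):
        idx = by_taxon[taxon]
        st = SpeciesGapStats(taxon=taxon, scope=scope, n=len(idx))
        if len(idx) >= 2:
            vals = _pair_values(pct, idx)
            if vals.size:
                st.delta = float(vals.max())
                st.d_mean = float(vals.mean())
                spread = float(vals.std(ddof=0))
                st.sd = (
                    spread if sd_mode == "pair"
                    else spread / math.sqrt(vals.size)
                )
        out.append(st)
    return out


def nearest_neighbour(
    matrix: DistanceMatrix, labels: Mapping[str, str]
) -> dict[str, tuple[float, str]]:
    """Distance to the nearest heterospecific neighbour per taxon.

    Returns ``{taxon: (delta_sp_percent, nn_taxon)}`` where delta_sp is
    the minimum distance over all (member, heterospecific) pairs.  Ties
    are broken alphabetically on the neighbour name and logged.
    """
    taxa = sorted(set(labels[i] for i in matrix.ids))
    if len(taxa) < 2:
        raise ValueError("nearest-neighbour analysis needs >= 2 taxa")
    pct = matrix.percent
    lab_arr = np.array([labels[i] for i in matrix.ids])
    result: dict[str, tuple[float, str]] = {}
    for taxon in taxa:
        own = np.flatnonzero(lab_arr == taxon)
        other = np.flatnonzero(lab_arr != taxon)
        block = pct[np.ix_(own, other)]
        finite = np.isfinite(block)
        if not finite.any():
            continue
        dmin = float(block[finite].min())
        # all heterospecific taxa attaining the minimum (within fp exactness)
        hit_cols = np.unique(np.nonzero(finite & (block == dmin))[1])
        candidates = sorted(set(lab_arr[other][hit_cols]))
        if len(candidates) > 1:
            logger.info(
                "nearest-neighbour tie for %s at %.4f%%: %s (alphabetical pick)",
                taxon, dmin, candidates,
            )
        result[taxon] = (dmin, candidates[0])
    return result


def min_interspecific(
    matrix: DistanceMatrix, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Taxon x taxon matrix of minimum between-taxon distances (percent)."""
    taxa = sorted(set(labels[i] for i in matrix.ids))
    pct = matrix.percent
    lab_arr = np.array([labels[i] for i in matrix.ids])
    out = pd.DataFrame(np.nan, index=taxa, columns=taxa)
    for a_i, a in enumerate(taxa):
        ia = np.flatnonzero(lab_arr == a)
        for b in taxa[a_i + 1:]:
            ib = np.flatnonzero(lab_arr == b)
            block = pct[np.ix_(ia, ib)]
            block = block[np.isfinite(block)]
            if block.size:
                out.loc[a, b] = out.loc[b, a] = float(block.min())
    return out


def genus_species_means(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    genera: Mapping[str, str],
    weighting: str = "pair",
) -> dict[str, float | None]:
    """Grand mean within-species and within-genus (congeneric,
    heterospecific) K2P distances, percent scale.

    ``weighting`` is "pair" (grand mean over all qualifying pairs, the
    default) or "taxon" (mean of per-taxon/per-genus means).  Returns a
    dict with keys within_species_mean/sd and within_genus_mean/sd; a
    value is None when no qualifying pair exists.
    """
    if weighting not in ("pair", "taxon"):
        raise ValueError("weighting must be 'pair' or 'taxon'")
    pct = matrix.percent
    n = len(matrix)
    sp = np.array([labels[i] for i in matrix.ids])
    gn = np.array([genera[i] for i in matrix.ids])

    iu = np.triu_indices(n, k=1)
    vals = pct[iu]
    ok = np.isfinite(vals)
    same_sp = (sp[iu[0]] == sp[iu[1]]) & ok
    same_gn = (gn[iu[0]] == gn[iu[1]]) & (sp[iu[0]] != sp[iu[1]]) & ok

    def summary(mask: np.ndarray, groups: np.ndarray) -> tuple[float | None, float | None]:
        v = vals[mask]
        if v.size == 0:
            return None, None
        if weighting == "pair":
            return float(v.mean()), float(v.std(ddof=0))
        keys = groups[mask]
        per_group = pd.Series(v).groupby(pd.Series(keys)).mean().to_numpy()
        return float(per_group.mean()), float(per_group.std(ddof=0))

    sp_groups = sp[iu[0]]
    gn_groups = gn[iu[0]]
    ws_mean, ws_sd = summary(same_sp, sp_groups)
    wg_mean, wg_sd = summary(same_gn, gn_groups)
    if ws_mean is None:
        logger.info("no conspecific pairs: within-species mean undefined")
    if wg_mean is None:
        logger.info(
            "no congeneric heterospecific pairs: within-genus mean undefined"
        )
    return {
        "within_species_mean": ws_mean,
        "within_species_sd": ws_sd,
        "within_genus_mean": wg_mean,
        "within_genus_sd": wg_sd,
    }


def stats_table(
    stats: list[SpeciesGapStats],
    nn: Mapping[str, tuple[float, str]] | None = None,
) -> pd.DataFrame:
    """Tabulate gap statistics (one row per taxon, percent, 2 decimals)."""
    rows = []
    for st in stats:
        pair = nn.get(st.taxon) if nn else None
        rows.append(
            {
                "taxon": st.taxon,
                "scope": st.scope,
                "N": st.n,
                "delta": st.render(st.delta),
                "d_mean": st.render(st.d_mean),
                "sd": st.render(st.sd),
                "delta_sp": st.render(pair[0]) if pair else "N/A",
                "nn_taxon": pair[1] if pair else "N/A",
            }
        )
    return pd.DataFrame(rows)
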