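"""Kimura two-parameter (K2P) pairwise distances.

The K2P model corrects observed differences for multiple hits while
distinguishing transitions (A<->G, C<->T) from transversions.  With P and
Q the transition and transversion proportions over jointly comparable
sites,

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

in expected substitutions per site.  Distances are stored internally as
proportions and rendered as percentages (x100) in reports.

Missing data are handled by pairwise deletion: a site contributes to a
pair only when both sequences carry an unambiguous base (A, C, G or T)
there.  Gaps, N and IUPAC ambiguity codes are skipped for that pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import SpecimenTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 300

# base codes: 0..3 = A, G, C, T (purines first so code // 2 gives the
# purine/pyrimidine class); 255 = not comparable
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class SaturationError(ValueError):
    """K2P log argument fell to or below zero: distance undefined."""


class UndefinedPairError(ValueError):
    """Pair has too few comparable sites for a defined distance."""


@dataclass(frozen=True)
class PairwiseDistance:
    """K2P distance between two aligned sequences.

    Attributes
    ----------
    d : float
        Distance in substitutions/site (proportion scale).
    P, Q : float
        Transition and transversion proportions over comparable sites.
    n_sites : int
        Number of jointly comparable sites.
    """

    d: float
    P: float
    Q: float
    n_sites: int

    @property
    def percent(self) -> float:
        return 100.0 * self.d


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A,G,C,T -> 0..3; other -> 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pq(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    comp = (a != 255) & (b != 255)
    n = int(comp.sum())
    if n == 0:
        return 0, 0, 0
    ac, bc = a[comp], b[comp]
    diff = ac != bc
    same_class = (ac >> 1) == (bc >> 1)
    ts = int((diff & same_class).sum())
    tv = int((diff & ~same_class).sum())
    return ts, tv, n


def k2p_from_counts(transitions: int, transversions: int, n_sites: int) -> float:
    """K2P distance from transition/transversion counts (proportion scale)."""
    P = transitions / n_sites
    Q = transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f} leave no defined K2P distance"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p(
    seq_a: str, seq_b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> PairwiseDistance:
    """K2P distance between two aligned sequences with pairwise deletion.

    Raises
    ------
    UndefinedPairError
        Fewer than ``min_overlap`` jointly comparable sites.
    SaturationError
        Observed divergence beyond the model's domain
        (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    ts, tv, n = _pq(encode(seq_a), encode(seq_b))
    if n < min_overlap:
        raise UndefinedPairError(
            f"only {n} comparable sites (< min_overlap={min_overlap})"
        )
    d = k2p_from_counts(ts, tv, n)
    return PairwiseDistance(d=d, P=ts / n, Q=tv / n, n_sites=n)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distance matrix with comparability bookkeeping.

    ``values`` holds proportions (substitutions/site); undefined cells are
    NaN with ``defined_mask`` False.  The diagonal is exactly zero and
    always defined.
    """

    ids: list[str]
    values: np.ndarray
    defined_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.defined_mask.shape != (n, n):
            raise ValueError("matrix shapes do not match id count")
        defined = self.defined_mask
        v = self.values
        if not np.allclose(np.diag(v), 0.0) or not np.diag(defined).all():
            raise ValueError("diagonal must be zero and defined")
        finite = defined & np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite], rtol=1e-9, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.values

    @property
    def fully_defined(self) -> bool:
        return bool(self.defined_mask.all())

    def index_of(self, sample_id: str) -> int:
        try:
            return self.ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def get(self, id_a: str, id_b: str) -> float:
        """Distance (proportion) between two ids; NaN when undefined."""
        return float(self.values[self.index_of(id_a), self.index_of(id_b)])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)].copy(),
            defined_mask=self.defined_mask[np.ix_(idx, idx)].copy(),
        )

    def drop_undefined(self) -> "DistanceMatrix":
        """Greedily drop records until every remaining pair is defined."""
        mask = self.defined_mask.copy()
        keep = np.ones(len(self.ids), dtype=bool)
        while True:
            undef_counts = (~mask[np.ix_(keep, keep)]).sum(axis=1)
            if undef_counts.sum() == 0:
                break
            worst_local = int(np.argmax(undef_counts))
            worst = np.flatnonzero(keep)[worst_local]
            keep[worst] = False
        kept_ids = [i for i, k in zip(self.ids, keep) if k]
        if len(kept_ids) < len(self.ids):
            logger.info(
                "dropped %d records with undefined pairs",
                len(self.ids) - len(kept_ids),
            )
        return self.submatrix(kept_ids)

    def to_tsv(self, destination: str | Path) -> None:
        """Dump the lower triangle as TSV (percent, 4 decimals)."""
        with open(destination, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = []
                for j in range(i):
                    if self.defined_mask[i, j]:
                        cells.append(f"{100.0 * self.values[i, j]:.4f}")
                    else:
                        cells.append("NA")
                fh.write(sid + ("\t" if cells else "") + "\t".join(cells) + "\n")


def distance_matrix(
    table: SpecimenTable,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_undefined_fraction: float = 0.5,
) -> DistanceMatrix:
    """All-pairs K2P distance matrix over a specimen table.

    Undefined pairs (too little overlap, or saturation) are masked, never
    silently zeroed.  More than ``max_undefined_fraction`` undefined pairs
    is treated as a data problem and raised.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    codes = [encode(s) for s in table.sequences]
    n = len(codes)
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    n_undef = 0
    for i in range(n):
        for j in range(i + 1, n):
            ts, tv, ns = _pq(codes[i], codes[j])
            ok = ns >= min_overlap
            if ok:
                try:
                    d = k2p_from_counts(ts, tv, ns)
                except SaturationError as exc:
                    logger.warning(
                        "pair (%s, %s) undefined: %s",
                        table.ids[i], table.ids[j], exc,
                    )
                    ok = False
            else:
                logger.warning(
                    "pair (%s, %s) undefined: %d comparable sites < %d",
                    table.ids[i], table.ids[j], ns, min_overlap,
                )
            if ok:
                values[i, j] = values[j, i] = d
            else:
                values[i, j] = values[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
                n_undef += 1
    n_pairs = n * (n - 1) // 2
    if n_pairs and n_undef / n_pairs > max_undefined_fraction:
        raise ValueError(
            f"{n_undef}/{n_pairs} pairs undefined (> {max_undefined_fraction:.0%}); "
            "check alignment quality, sequence lengths and min_overlap"
        )
    return DistanceMatrix(ids=list(table.ids), values=values, defined_mask=defined)
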