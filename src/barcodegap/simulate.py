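"""Synthetic COI barcode datasets with known ground truth.

The generator emulates the statistical structure that barcode-gap
delimitation assumes: tight within-species clusters (expected pairwise
K2P distance ~0.1-1%), well-separated species (2-10%), optional planted
cryptic splits (one species containing two divergent clusters), planted
lumps (two names emitted from a single cluster), and a stated fraction
of records shortened below the length-filter cutoff.

Sequences evolve under the K2P substitution process itself — sites
mutate independently with transition/transversion rates in ratio kappa
and equal base frequencies — so the distance estimator downstream is
inverting exactly the process that generated the data.  Within-species
genealogy is a star: every specimen hangs off its species (or
sub-cluster) root at half the target intraspecific divergence, giving
direct control of expected pairwise distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import SpecimenRecord, SpecimenTable

_BASES = np.array(list("AGCT"))  # codes 0..3; transition partner = code ^ 1
_CODE_LOOKUP = {"A": 0, "G": 1, "C": 2, "T": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Controls for one synthetic barcode dataset.

    Divergences are target expected pairwise K2P distances in percent.
    ``planted_splits`` entries are (species_index, split_divergence_pct,
    group1_fraction); ``planted_lumps`` lists species indices whose
    single cluster is emitted under two species names.  ``seed`` fixes
    the output byte-for-byte.
    """

    n_species: int = 8
    specimens_per_species: int | tuple[int, int] = 8
    seq_length: int = 658
    kappa: float = 4.0
    intra_divergence: float = 0.5
    inter_divergence: float = 8.0
    planted_splits: tuple[tuple[int, float, float], ...] = ()
    planted_lumps: tuple[int, ...] = ()
    short_record_fraction: float = 0.0
    short_length: int = 450
    species_per_genus: int = 2
    regions: tuple[str, ...] = ("QLD", "NSW", "NT")
    foreign_region: str = "EM"
    foreign_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 < self.intra_divergence < self.inter_divergence:
            raise ValueError(
                "need 0 < intra_divergence < inter_divergence "
                f"(got {self.intra_divergence} vs {self.inter_divergence})"
            )
        for frac_name in ("short_record_fraction", "foreign_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1]")
        split_idx = set()
        for idx, pct, frac in self.planted_splits:
            if not 0 <= idx < self.n_species:
                raise ValueError(f"planted split index {idx} out of range")
            if pct <= self.intra_divergence:
                raise ValueError(
                    f"split divergence {pct}% must exceed intra_divergence "
                    f"{self.intra_divergence}%"
                )
            if not 0.0 < frac < 1.0:
                raise ValueError("split group fraction must be in (0, 1)")
            split_idx.add(idx)
        for idx in self.planted_lumps:
            if not 0 <= idx < self.n_species:
                raise ValueError(f"planted lump index {idx} out of range")
            if idx in split_idx:
                raise ValueError(f"species {idx} cannot be both split and lump")

    def to_flat_file(self, destination: str | Path) -> None:
        """Dump the configuration as a flat key=value file."""
        lines = []
        for key, value in self.__dict__.items():
            lines.append(f"{key}={value!r}")
        Path(destination).write_text("\n".join(lines) + "\n")


@dataclass
class TruthTable:
    """Planted ground truth for a simulated dataset.

    ``specimens`` has one row per emitted record (sample_id,
    species = emitted name, true_cluster, region, short_record);
    ``species_status`` maps each emitted species name to its planted
    status ("cohesive" | "split" | "lump") with the planted divergence
    and, for lumps, the partner name.
    """

    specimens: pd.DataFrame
    species_status: dict[str, dict]

    def expected_statuses(self) -> dict[str, str]:
        """Planted statuses in the delimitation report's vocabulary."""
        mapping = {
            "cohesive": "cohesive",
            "split": "split-candidate",
            "lump": "lump-candidate",
        }
        return {
            name: mapping[info["status"]]
            for name, info in self.species_status.items()
        }

    def to_tsv(self, destination: str | Path) -> None:
        self.specimens.to_csv(destination, sep="\t", index=False)


def _k2p_category_probs(branch_length: float, kappa: float) -> tuple[float, float]:
    """(p_transition, p_each_transversion) after time = branch_length.

    Rates are normalized so branch_length is the expected number of
    substitutions per site: alpha = kappa/(kappa+2), beta = 1/(kappa+2).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * branch_length)
    e2 = math.exp(-2.0 * (alpha + beta) * branch_length)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-random sequence over A, C, G, T."""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def evolve_sequence(
    parent: str, branch_length: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence along one branch under the K2P process.

    Each site mutates independently using the closed-form K2P
    substitution probabilities for time ``branch_length`` (expected
    substitutions/site, proportion scale).
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    codes = np.array([_CODE_LOOKUP.get(c, -1) for c in parent], dtype=np.int64)
    if (codes < 0).any():
        bad = sorted({c for c in parent if c not in "ACGT"})
        raise ValueError(f"parent sequence must be over ACGT; found {bad}")
    p_ts, p_tv = _k2p_category_probs(branch_length, kappa)
    u = rng.random(len(codes))
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)
    out[ts] = codes[ts] ^ 1  # A<->G, C<->T
    other_class_base = 2 * (1 - (codes >> 1))  # first base of the other class
    out[tv1] = other_class_base[tv1]
    out[tv2] = other_class_base[tv2] + 1
    return "".join(_BASES[out])


def simulate_dataset(config: SimulationConfig) -> tuple[SpecimenTable, TruthTable]:
    """Generate a specimen table plus its ground truth.

    Star-like design: species roots radiate from a common ancestor at
    half the target between-species divergence; specimens radiate from
    their species (or planted sub-cluster) root at half the target
    within-species divergence.  Planted splits place two sub-roots
    (split - intra)/2 apart on each side of the species root so the
    expected between-subcluster distance is the configured split
    divergence once tip branches are added.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    intra = config.intra_divergence / 100.0
    inter = config.inter_divergence / 100.0
    ancestor = random_sequence(L, rng)

    splits = {idx: (pct, frac) for idx, pct, frac in config.planted_splits}
    lumps = set(config.planted_lumps)

    records: list[SpecimenRecord] = []
    truth_rows: list[dict] = []
    species_status: dict[str, dict] = {}

    for sp in range(config.n_species):
        genus = f"Genus{sp // config.species_per_genus + 1}"
        name = f"{genus} species{sp + 1}"
        root = evolve_sequence(ancestor, inter / 2.0, config.kappa, rng)

        if isinstance(config.specimens_per_species, tuple):
            lo, hi = config.specimens_per_species
            n_spec = int(rng.integers(lo, hi + 1))
        else:
            n_spec = config.specimens_per_species

        if sp in splits:
            pct, frac = splits[sp]
            gap = (pct - config.intra_divergence) / 100.0
            sub1 = evolve_sequence(root, gap / 2.0, config.kappa, rng)
            sub2 = evolve_sequence(root, gap / 2.0, config.kappa, rng)
            n1 = min(max(int(round(frac * n_spec)), 1), n_spec - 1)
            parents = [(sub1, "a")] * n1 + [(sub2, "b")] * (n_spec - n1)
            species_status[name] = {
                "status": "split",
                "divergence_pct": pct,
                "partner": None,
            }
            names = [name] * n_spec
        elif sp in lumps:
            partner = f"{genus} species{sp + 1}bis"
            parents = [(root, "a")] * n_spec
            half = n_spec // 2
            names = [name] * (n_spec - half) + [partner] * half
            for nm, other in ((name, partner), (partner, name)):
                species_status[nm] = {
                    "status": "lump",
                    "divergence_pct": config.intra_divergence,
                    "partner": other,
                }
        else:
            parents = [(root, "a")] * n_spec
            names = [name] * n_spec
            species_status[name] = {
                "status": "cohesive",
                "divergence_pct": config.intra_divergence,
                "partner": None,
            }

        for k, ((parent_seq, cluster), emitted) in enumerate(zip(parents, names)):
            seq = evolve_sequence(parent_seq, intra / 2.0, config.kappa, rng)
            if config.foreign_fraction and rng.random() < config.foreign_fraction:
                region = config.foreign_region
            else:
                region = str(rng.choice(list(config.regions)))
            sid = f"SIM{sp:02d}-{k:03d}"
            records.append(
                SpecimenRecord(
                    sample_id=sid,
                    process_id=f"PRC{sp:02d}{k:03d}",
                    species=emitted,
                    genus=genus,
                    region=region,
                    sequence=seq,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "species": emitted,
                    "true_species": name,
                    "true_cluster": f"{name}|{cluster}",
                    "region": region,
                    "short_record": False,
                }
            )

    # shorten a stated fraction of records below the length cutoff
    n_short = int(round(config.short_record_fraction * len(records)))
    if n_short:
        short_idx = rng.choice(len(records), size=n_short, replace=False)
        for i in short_idx:
            r = records[i]
            seq = r.sequence[: config.short_length] + "-" * (L - config.short_length)
            records[i] = SpecimenRecord(
                sample_id=r.sample_id,
                process_id=r.process_id,
                species=r.species,
                genus=r.genus,
                region=r.region,
                sequence=seq,
            )
            truth_rows[i]["short_record"] = True

    table = SpecimenTable(records, scope_name="simulated")
    truth = TruthTable(
        specimens=pd.DataFrame(truth_rows), species_status=species_status
    )
    return table, truth
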