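"""Split/lump flagging, CCS/DCL resolution, subspecies congruence."""

import numpy as np
import pytest

from barcodegap import (
    ClusterPartition,
    EvidenceRecord,
    SpeciesGapStats,
    flag_candidates,
    resolve_candidate,
    subspecies_congruence,
)
from barcodegap.delimit import (
    CCS,
    COHESIVE,
    DCL,
    LUMP,
    NOT_APPLICABLE,
    SPLIT,
    SPLIT_AND_LUMP,
    UNRESOLVED,
    apply_evidence,
)


def stats_for(taxon, delta, delta_sp, n=10, nn="Other taxon"):
    return SpeciesGapStats(
        taxon=taxon, scope="test", n=n, delta=delta,
        d_mean=None if delta is None else delta / 2,
        sd=0.0, delta_sp=delta_sp, nn_taxon=None if delta_sp is None else nn,
    )


def qualifying_partition(taxon, between_min, n_groups=2, mono=True):
    groups = [[f"{taxon}-{g}-{i}" for i in range(3)] for g in range(n_groups)]
    return ClusterPartition(
        taxon=taxon,
        groups=groups,
        monophyletic=[mono] * n_groups,
        threshold_pct=2.0,
        between_min_pct=between_min if n_groups > 1 else None,
        between_max_pct=between_min if n_groups > 1 else None,
    )


class TestFlagCandidates:
    def test_deep_split_with_monophyletic_clusters(self):
        """A 6.4%-divergent species in two monophyletic clusters is a
        split candidate; a shallow well-separated one is cohesive; one
        1.19% from its neighbour is a lump candidate."""
        stats = [
            stats_for("Acosmeryx-like deep", 6.4, 7.0),
            stats_for("Cohesive shallow", 0.5, 7.2),
            stats_for("Close pair member", 1.0, 1.19),
        ]
        parts = {
            "Acosmeryx-like deep": qualifying_partition("Acosmeryx-like deep", 6.4),
            "Cohesive shallow": qualifying_partition("Cohesive shallow", None, 1),
            "Close pair member": qualifying_partition("Close pair member", None, 1),
        }
        report = flag_candidates(stats, parts, threshold_pct=2.0)
        assert report["Acosmeryx-like deep"].status == SPLIT
        assert report["Cohesive shallow"].status == COHESIVE
        assert report["Close pair member"].status == LUMP
        assert report["Close pair member"].lump_partners == ["Other taxon"]

    def test_split_requires_qualifying_partition(self):
        """delta above threshold alone is not enough: the clusters must
        be monophyletic and separated by more than the threshold."""
        stats = [stats_for("Deep but tangled", 6.0, 8.0)]
        parts = {
            "Deep but tangled": qualifying_partition(
                "Deep but tangled", 6.0, mono=False
            )
        }
        report = flag_candidates(stats, parts, threshold_pct=2.0)
        assert report["Deep but tangled"].status == COHESIVE

    def test_strict_threshold_boundaries(self):
        stats = [
            stats_for("At delta boundary", 2.0, 8.0),
            stats_for("At deltasp boundary", 0.5, 2.0),
        ]
        parts = {s.taxon: qualifying_partition(s.taxon, 6.0) for s in stats}
        report = flag_candidates(stats, parts, threshold_pct=2.0)
        assert report["At delta boundary"].status == COHESIVE  # needs > 2
        assert report["At deltasp boundary"].status == COHESIVE  # needs < 2

    def test_split_and_lump_combined(self):
        stats = [stats_for("Both ways", 5.0, 1.0)]
        parts = {"Both ways": qualifying_partition("Both ways", 5.0)}
        report = flag_candidates(stats, parts)
        assert report["Both ways"].status == SPLIT_AND_LUMP
        entry = report["Both ways"]
        assert entry.is_split and entry.is_lump

    def test_undefined_stats_cohesive(self):
        stats = [stats_for("Singleton", None, 8.0, n=1)]
        report = flag_candidates(stats, {})
        assert report["Singleton"].status == COHESIVE

    def test_watch_list_band(self):
        stats = [
            stats_for("Near threshold", 1.4, 8.0),
            stats_for("Below watch band", 0.4, 8.0),
        ]
        report = flag_candidates(stats, {}, watch_min_pct=1.0)
        assert report["Near threshold"].watch
        assert not report["Below watch band"].watch

    def test_mismatched_taxa_error(self):
        with pytest.raises(ValueError, match="missing from stats"):
            flag_candidates(
                [stats_for("Taxon a", 0.5, 5.0)],
                {"Taxon b": qualifying_partition("Taxon b", 6.0)},
            )

    def test_threshold_monotonicity(self):
        """Lowering the threshold never removes a split flag and never
        adds a lump flag."""
        stats = [
            stats_for("Deep one", 5.0, 8.0),
            stats_for("Mid one", 2.5, 8.0),
            stats_for("Close one", 0.4, 3.0),
        ]
        parts = {
            "Deep one": qualifying_partition("Deep one", 5.0),
            "Mid one": qualifying_partition("Mid one", 2.5),
            "Close one": qualifying_partition("Close one", None, 1),
        }
        prev_splits, prev_lumps = None, None
        for threshold in (4.0, 3.0, 2.0, 1.0):
            for p in parts.values():
                p.threshold_pct = threshold
            report = flag_candidates(stats, parts, threshold_pct=threshold)
            splits = {e.taxon for e in report if e.is_split}
            lumps = {e.taxon for e in report if e.is_lump}
            if prev_splits is not None:
                assert splits >= prev_splits
                assert lumps <= prev_lumps
            prev_splits, prev_lumps = splits, lumps


class TestResolveCandidate:
    @pytest.mark.parametrize(
        "morph,nuclear,expected",
        [
            ("yes", "yes", CCS),
            ("yes", "no", CCS),
            ("yes", "unknown", CCS),
            ("no", "yes", CCS),
            ("unknown", "yes", CCS),
            ("no", "no", DCL),
            ("no", "unknown", UNRESOLVED),
            ("unknown", "no", UNRESOLVED),
            ("unknown", "unknown", UNRESOLVED),
        ],
    )
    def test_resolution_truth_table(self, morph, nuclear, expected):
        stats = [stats_for("Candidate", 9.7, 8.0)]
        parts = {"Candidate": qualifying_partition("Candidate", 9.7)}
        report = flag_candidates(stats, parts)
        ev = EvidenceRecord(
            taxon="Candidate", morphology_distinct=morph,
            nuclear_diagnostic=nuclear,
        )
        assert resolve_candidate(report["Candidate"], ev) == expected
        # pure function: same inputs -> same output
        assert resolve_candidate(report["Candidate"], ev) == expected

    def test_cohesive_taxon_not_applicable_with_warning(self):
        stats = [stats_for("Stable", 0.3, 6.0)]
        report = flag_candidates(stats, {})
        ev = EvidenceRecord(taxon="Stable", morphology_distinct="yes")
        with pytest.warns(UserWarning, match="non-split"):
            assert resolve_candidate(report["Stable"], ev) == NOT_APPLICABLE

    def test_apply_evidence_resolves_only_splits(self):
        stats = [
            stats_for("Morph-backed split", 9.7, 8.0),
            stats_for("Evidence-free split", 2.2, 8.0),
            stats_for("Plain lump", 0.5, 1.2),
        ]
        parts = {
            "Morph-backed split": qualifying_partition("Morph-backed split", 9.7),
            "Evidence-free split": qualifying_partition("Evidence-free split", 2.2),
            "Plain lump": qualifying_partition("Plain lump", None, 1),
        }
        report = flag_candidates(stats, parts)
        apply_evidence(
            report,
            {
                "Morph-backed split": EvidenceRecord(
                    taxon="Morph-backed split", morphology_distinct="yes"
                ),
                "Evidence-free split": EvidenceRecord(
                    taxon="Evidence-free split",
                    morphology_distinct="no",
                    nuclear_diagnostic="no",
                ),
            },
        )
        assert report["Morph-backed split"].resolution == CCS
        assert report["Evidence-free split"].resolution == DCL
        assert report["Plain lump"].resolution == NOT_APPLICABLE

    def test_invalid_evidence_value_rejected(self):
        with pytest.raises(ValueError, match="morphology_distinct"):
            EvidenceRecord(taxon="X", morphology_distinct="maybe")


class TestSubspeciesCongruence:
    def test_planted_divergent_subspecies(self):
        """Two subspecies simulated as 3%-separated clusters are both
        monophyletic with min distance near the planted value."""
        from barcodegap import SimulationConfig, build_nj, distance_matrix, simulate_dataset
        from barcodegap.records import SpecimenRecord, SpecimenTable

        cfg = SimulationConfig(
            n_species=3, specimens_per_species=6,
            planted_splits=((0, 3.0, 0.5),), intra_divergence=0.3,
            seed=9,
        )
        table, truth = simulate_dataset(cfg)
        # relabel the split species' two true clusters as subspecies
        clusters = dict(
            zip(truth.specimens["sample_id"], truth.specimens["true_cluster"])
        )
        records = []
        for r in table:
            sub = None
            if clusters[r.sample_id].endswith("|a"):
                sub = "north"
            elif clusters[r.sample_id].endswith("|b"):
                sub = "south"
            if r.species != "Genus1 species1":
                sub = None
            records.append(
                SpecimenRecord(
                    sample_id=r.sample_id, species=r.species,
                    subspecies=sub, genus=r.genus, region=r.region,
                    sequence=r.sequence,
                )
            )
        table = SpecimenTable(records)
        dm = distance_matrix(table)
        tree = build_nj(dm)
        trinomials = {
            r.sample_id: (r.species, r.subspecies) for r in table
        }
        df = subspecies_congruence(tree, dm, trinomials)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["monophyletic_a"] and row["monophyletic_b"]
        assert row["congruent_species"]
        # oracle: brute-force min over between-subspecies pairs
        ids_a = [s for s, (sp, ss) in trinomials.items() if ss == "north"]
        ids_b = [s for s, (sp, ss) in trinomials.items() if ss == "south"]
        expected = min(
            100.0 * dm.get(a, b) for a in ids_a for b in ids_b
        )
        assert row["min_between_pct"] == pytest.approx(expected, abs=1e-12)
        assert 1.5 < row["min_between_pct"] < 6.0  # near the planted 3%

    def test_intermixed_subspecies_not_monophyletic(self):
        """Subspecies labels scattered over one tight cluster fail
        reciprocal monophyly."""
        from barcodegap import build_nj
        from test_clusters import dm_from_array

        ids = [f"S{i}" for i in range(6)]
        rng = np.random.default_rng(3)
        pct = rng.uniform(0.1, 0.5, size=(6, 6))
        pct = (pct + pct.T) / 2
        np.fill_diagonal(pct, 0)
        # two distant outgroup-ish tips to give the tree structure
        pct[4, :4] = pct[:4, 4] = 5.0
        pct[5, :] = pct[:, 5] = 8.0
        pct[4, 5] = pct[5, 4] = 6.0
        np.fill_diagonal(pct, 0)
        dm = dm_from_array(pct / 100.0, ids)
        tree = build_nj(dm)
        trinomials = {
            "S0": ("Genus alpha", "east"),
            "S1": ("Genus alpha", "west"),
            "S2": ("Genus alpha", "east"),
            "S3": ("Genus alpha", "west"),
            "S4": ("Genus beta", None),
            "S5": ("Genus gamma", None),
        }
        df = subspecies_congruence(tree, dm, trinomials)
        row = df.iloc[0]
        assert not (row["monophyletic_a"] and row["monophyletic_b"])
        assert not row["congruent_species"]

    def test_no_polytypic_species_raises(self):
        from barcodegap import build_nj
        from test_clusters import dm_from_array

        dm = dm_from_array(np.array([[0, 0.02], [0.02, 0]]), ["A", "B"])
        tree = build_nj(dm)
        with pytest.raises(ValueError, match="subspecies"):
            subspecies_congruence(
                tree, dm, {"A": ("G a", None), "B": ("G b", None)}
            )
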