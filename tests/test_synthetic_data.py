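import math

import numpy as np
import pytest

from barcodegap.distances import count_site_patterns, k2p_distance
from barcodegap.haplotypes import GapMode, collapse_haplotypes
from barcodegap.io_model import build_dataset, read_metadata, subset_dataset
from barcodegap.synthetic_data import (
    CladeConfig,
    ConfigError,
    LocusConfig,
    SimulationConfig,
    default_config,
    evolve_alignment,
    simulate_bundle,
    simulate_species_tree,
)


def two_species_config(rate, length, kappa=3.0, seed=0):
    """Two singleton clades: path length between the species is exactly 2
    (unit-height tree), so expected divergence is 2 * rate."""
    return SimulationConfig(
        clades=(CladeConfig("A", 1), CladeConfig("B", 1)),
        loci=(LocusConfig("L", length, rate, kappa),),
        intraspecific_depth=0.0,
        gap_rate=0.0,
        missing_rate=0.0,
        seed=seed,
    )


class TestSpeciesTree:
    def test_two_clades_of_two_form_cherries(self):
        cfg = SimulationConfig(
            clades=(CladeConfig("A", 2), CladeConfig("B", 2)),
            loci=(LocusConfig("L", 100, 0.01),),
            seed=1,
        )
        truth = simulate_species_tree(cfg)
        assert sorted(truth.species) == ["A_sp01", "A_sp02", "B_sp01", "B_sp02"]
        assert truth.clade_path("A_sp01") == ("Viburnum", "A")
        # within-clade paths are shallower than between-clade paths
        assert truth.path_length("A_sp01", "A_sp02") \
            < truth.path_length("A_sp01", "B_sp01")

    def test_same_seed_gives_identical_tree(self):
        cfg = default_config(seed=5)
        t1 = simulate_species_tree(cfg)
        t2 = simulate_species_tree(cfg)
        assert t1.tree.as_string(schema="newick") == t2.tree.as_string(schema="newick")
        assert t1.path_lengths == t2.path_lengths

    def test_unit_height_ultrametric(self):
        cfg = SimulationConfig(
            clades=(CladeConfig("A", 20), CladeConfig("B", 30)),
            loci=(LocusConfig("L", 100, 0.01),),
            seed=3,
        )
        truth = simulate_species_tree(cfg)
        depths = [
            leaf.distance_from_root() for leaf in truth.tree.leaf_node_iter()
        ]
        assert max(depths) - min(depths) < 1e-9
        assert max(depths) == pytest.approx(1.0)

    def test_regions_follow_clades(self):
        cfg = default_config(seed=1)
        truth = simulate_species_tree(cfg)
        assert truth.region_of["Succodontotinus_sp01"] == "Japan"
        assert truth.region_of["Lantana_sp01"] is None

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(clades=(), loci=(LocusConfig("L", 10, 0.1),))
        with pytest.raises(ConfigError):
            CladeConfig("A", 0)
        with pytest.raises(ConfigError):
            LocusConfig("L", 100, 0.01, kappa=0.0)
        with pytest.raises(ConfigError):
            LocusConfig("L", 0, 0.01)


class TestEvolve:
    def test_rate_zero_keeps_all_sequences_identical(self):
        cfg = SimulationConfig(
            clades=(CladeConfig("A", 4), CladeConfig("B", 4)),
            loci=(LocusConfig("L", 200, 0.0),),
            seed=2,
        )
        truth = simulate_species_tree(cfg)
        recs = evolve_alignment(truth, cfg.loci[0])
        assert len({r.residues for r in recs}) == 1

    def test_mean_recovery_at_moderate_divergence(self):
        # expected divergence 0.05; 60 replicates x 5000 sites
        dists = []
        for seed in range(60):
            cfg = two_species_config(rate=0.025, length=5000, seed=seed)
            truth = simulate_species_tree(cfg)
            a, b = evolve_alignment(truth, cfg.loci[0])
            dists.append(k2p_distance(count_site_patterns(a.residues, b.residues)))
        dists = np.array(dists)
        se = dists.std(ddof=1) / math.sqrt(len(dists))
        assert abs(dists.mean() - 0.05) < 3 * se

    def test_large_kappa_suppresses_transversions(self):
        cfg = two_species_config(rate=0.01, length=4000, kappa=1e6, seed=4)
        truth = simulate_species_tree(cfg)
        a, b = evolve_alignment(truth, cfg.loci[0])
        counts = count_site_patterns(a.residues, b.residues)
        assert counts.n_transversions == 0
        assert counts.n_transitions > 0

    def test_deterministic_under_seed(self):
        cfg = two_species_config(rate=0.02, length=500, seed=9)
        truth = simulate_species_tree(cfg)
        r1 = evolve_alignment(truth, cfg.loci[0])
        r2 = evolve_alignment(truth, cfg.loci[0])
        assert [r.residues for r in r1] == [r.residues for r in r2]


class TestAccessionsAndNoise:
    def test_zero_intraspecific_depth_collapses_conspecifics(self):
        cfg = SimulationConfig(
            clades=(CladeConfig("A", 4), CladeConfig("B", 4)),
            loci=(LocusConfig("L", 300, 0.02),),
            intraspecific_depth=0.0,
            multi_accession_fraction=1.0,
            gap_rate=0.02,
            missing_rate=0.02,
            seed=6,
        )
        aln, truth = simulate_bundle(cfg)
        ds = build_dataset(aln, ["L"])
        part = collapse_haplotypes(ds, GapMode.GAP_AS_MISSING)
        for sp in truth.species:
            accs = [a for a in ds.accessions if aln.metadata.species_of(a) == sp]
            assert len({part.cluster_of(a) for a in accs}) == 1

    def test_no_noise_makes_gap_modes_agree(self):
        cfg = SimulationConfig(
            clades=(CladeConfig("A", 6),),
            loci=(LocusConfig("L", 300, 0.03),),
            gap_rate=0.0,
            missing_rate=0.0,
            seed=8,
        )
        aln, _ = simulate_bundle(cfg)
        ds = build_dataset(aln, ["L"])
        assert collapse_haplotypes(ds, GapMode.GAP_AS_MISSING).n_unique \
            == collapse_haplotypes(ds, GapMode.GAP_AS_FIFTH_STATE).n_unique

    def test_gapped_simulation_fifth_state_at_least_missing(self, small_sim):
        _, aln, _ = small_sim
        for locus in ("slow", "fast"):
            ds = build_dataset(aln, [locus])
            assert collapse_haplotypes(ds, GapMode.GAP_AS_FIFTH_STATE).n_unique \
                >= collapse_haplotypes(ds, GapMode.GAP_AS_MISSING).n_unique

    def test_one_representative_per_species(self, small_sim):
        _, aln, truth = small_sim
        reps = aln.metadata.representatives()
        assert set(reps) == set(truth.species)

    def test_expected_divergence_matches_rate_times_path(self, small_sim):
        cfg, _, truth = small_sim
        a, b = truth.species[0], truth.species[-1]
        assert truth.expected_divergence(a, b, "fast") == pytest.approx(
            0.04 * truth.path_length(a, b))


class TestBundleOutput:
    def test_bundle_files_written_and_readable(self, tmp_path):
        cfg = SimulationConfig(
            clades=(CladeConfig("A", 3, region="X"), CladeConfig("B", 3)),
            loci=(LocusConfig("L1", 120, 0.01), LocusConfig("L2", 80, 0.03)),
            seed=12,
        )
        aln, truth = simulate_bundle(cfg, out_dir=tmp_path)
        assert (tmp_path / "L1.fasta").exists()
        assert (tmp_path / "tree.newick").exists()
        meta = read_metadata(tmp_path / "metadata.tsv")
        assert set(meta.accessions()) == set(aln.metadata.accessions())
        truth_lines = (tmp_path / "truth.tsv").read_text().splitlines()
        assert truth_lines[0].split("\t") == [
            "speciesA", "speciesB", "locus", "expected_divergence"]
        assert len(truth_lines) == 1 + 15 * 2  # C(6,2) pairs x 2 loci

    def test_same_seed_identical_bundle_bytes(self, tmp_path):
        cfg = SimulationConfig(
            clades=(CladeConfig("A", 3), CladeConfig("B", 3)),
            loci=(LocusConfig("L1", 100, 0.02),),
            seed=13,
        )
        simulate_bundle(cfg, out_dir=tmp_path / "r1")
        simulate_bundle(cfg, out_dir=tmp_path / "r2")
        for name in ("L1.fasta", "metadata.tsv", "tree.newick", "truth.tsv"):
            assert (tmp_path / "r1" / name).read_bytes() \
                == (tmp_path / "r2" / name).read_bytes()
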