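import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest

from florachip.errors import ConfigError, PlacementError
from florachip.motifs import (
    MOTIF_A_CONSENSUS,
    MOTIF_B_CONSENSUS,
    pwm_from_consensus,
    scan,
)
from florachip.synthio import (
    SimConfig,
    generate_bundle,
    generate_de_tables,
    generate_gene_models,
    generate_genome,
    plant_sites_and_motifs,
    simulate_fragments,
    write_bundle,
)


def dir_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*")) if p.is_file()
    }


class TestConfig:
    @pytest.mark.parametrize(
        "field, value",
        [("chrom_len", 0), ("n_genes", 0), ("subset_frac_B", 1.5),
         ("amp_ratio_B", 0.0), ("background_rate", -1), ("frag_len", 100_000)],
    )
    def test_invalid_values_name_the_field(self, field, value):
        cfg = dataclasses.replace(SimConfig(), **{field: value})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=5, n_sites_A=12)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SimConfig.from_yaml(p) == cfg


class TestGenome:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(seed=1, n_chrom=2, chrom_len=20_000)
        g1 = generate_genome(cfg, np.random.default_rng(cfg.seed))
        g2 = generate_genome(cfg, np.random.default_rng(cfg.seed))
        assert g1 == g2
        assert set(g1) == {"chr1", "chr2"}
        assert all(len(s) == 20_000 for s in g1.values())

    def test_different_seeds_differ_widely(self):
        cfg1 = SimConfig(seed=1, n_chrom=1, chrom_len=20_000)
        g1 = generate_genome(cfg1, np.random.default_rng(1))
        g2 = generate_genome(cfg1, np.random.default_rng(2))
        a = np.frombuffer(bytes(g1["chr1"]), dtype=np.uint8)
        b = np.frombuffer(bytes(g2["chr1"]), dtype=np.uint8)
        assert (a != b).mean() > 0.4

    def test_zero_length_rejected(self):
        with pytest.raises(ConfigError, match="chrom_len"):
            generate_genome(SimConfig(chrom_len=0), np.random.default_rng(0))


class TestGeneModels:
    def test_count_and_non_overlap(self):
        cfg = SimConfig(seed=3, n_genes=100)
        rng = np.random.default_rng(3)
        genome = generate_genome(cfg, rng)
        genes = generate_gene_models(cfg, genome, rng)
        assert len(genes) == 100
        by_chrom = {}
        for g in genes:
            assert g.end - g.start >= 500
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_impossible_packing_raises(self):
        cfg = dataclasses.replace(SimConfig(), n_chrom=1, chrom_len=10_000,
                                  n_genes=10**6, frag_len=100)
        genome = {"chr1": bytearray(b"A" * 10_000)}
        with pytest.raises(PlacementError):
            generate_gene_models(cfg, genome, np.random.default_rng(0))


class TestPlantedSites:
    def test_subset_structure(self, default_bundle):
        sites = default_bundle.sites
        assert len(sites) == 50
        b = [s for s in sites if s.is_b]
        assert len(b) == round(50 * 0.2)
        assert set((s.chrom, s.center) for s in b) <= set(
            (s.chrom, s.center) for s in sites)

    def test_full_subset_fraction_makes_sets_identical(self):
        cfg = SimConfig(seed=4, subset_frac_B=1.0)
        bundle = generate_bundle(cfg)
        assert all(s.is_b for s in bundle.sites)

    def test_embedded_instances_scan_back_at_offset_two(self, default_bundle):
        motif_a = pwm_from_consensus(MOTIF_A_CONSENSUS, motif_id="a")
        motif_b = pwm_from_consensus(MOTIF_B_CONSENSUS, motif_id="b")
        checked = 0
        for site in default_bundle.sites[:12]:
            seq = bytes(
                default_bundle.genome[site.chrom][site.center - 40:site.center + 40]
            ).decode()
            hits_a = scan({"w": seq}, motif_a, 1e-4)
            hits_b = scan({"w": seq}, motif_b, 1e-4)
            assert hits_a and hits_b
            best_a = min(hits_a, key=lambda h: h.p_value)
            best_b = min(hits_b, key=lambda h: h.p_value)
            assert best_a.strand == best_b.strand == site.strand
            d = best_a.start - best_b.start
            assert (d if site.strand == "+" else -d) == 2
            checked += 1
        assert checked == 12

    def test_site_spacing_respected(self, default_bundle):
        cfg = default_bundle.cfg
        by_chrom = {}
        for s in default_bundle.sites:
            by_chrom.setdefault(s.chrom, []).append(s.center)
        for centers in by_chrom.values():
            centers.sort()
            assert all(b - a >= cfg.min_site_spacing
                       for a, b in zip(centers, centers[1:]))


class TestFragments:
    def test_background_free_limit(self):
        cfg = SimConfig(seed=9, background_rate=0.0, amp_A=20)
        bundle = generate_bundle(cfg)
        for df in bundle.fragments["untagged"]:
            assert len(df) == 0
        sites = bundle.sites
        for df in bundle.fragments["tagged_A"]:
            for row in df.itertuples():
                assert any(
                    s.chrom == row.chrom
                    and abs((row.start + cfg.frag_len // 2) - s.center)
                    <= 4 * cfg.frag_len
                    for s in sites
                )

    def test_mean_fragment_count_matches_poisson_expectation(self, default_bundle):
        cfg = default_bundle.cfg
        sizes = default_bundle.chrom_sizes
        expectation = (
            sum(sizes.values()) / 1000 * cfg.background_rate
            + len(default_bundle.sites) * cfg.amp_A
        )
        counts = []
        for seed in range(100):
            frames = simulate_fragments(
                cfg, sizes, default_bundle.sites, np.random.default_rng(seed)
            )
            counts.extend(len(df) for df in frames["tagged_A"])
        counts = np.array(counts)
        se = np.sqrt(expectation / len(counts))
        assert abs(counts.mean() - expectation) <= 3 * se

    def test_b_occupancy_is_half_of_a(self, default_bundle):
        cfg = default_bundle.cfg
        sizes = default_bundle.chrom_sizes
        b_sites = [s for s in default_bundle.sites if s.is_b]

        def center_depth(frames, sites):
            depth = 0
            for df in frames:
                for s in sites:
                    sub = df[(df.chrom == s.chrom) & (df.start <= s.center)
                             & (df.end > s.center)]
                    depth += len(sub)
            return depth

        ratios = []
        for seed in range(50):
            frames = simulate_fragments(
                cfg, sizes, default_bundle.sites, np.random.default_rng(seed)
            )
            a = center_depth(frames["tagged_A"], b_sites)
            b = center_depth(frames["tagged_B"], b_sites)
            ratios.append(b / a)
        assert np.mean(ratios) == pytest.approx(cfg.amp_ratio_B, rel=0.2)


class TestDETables:
    def test_full_overlap_puts_every_bound_gene_in_both_tables(self):
        cfg = SimConfig(seed=11, de_overlap_frac=1.0)
        bundle = generate_bundle(cfg)
        bound = set(bundle.b_bound_genes())
        for df in bundle.de_tables.values():
            assert bound <= set(df.gene_id)

    def test_zero_overlap_excludes_bound_genes(self):
        cfg = SimConfig(seed=11, de_overlap_frac=0.0)
        bundle = generate_bundle(cfg)
        bound = set(bundle.b_bound_genes())
        for df in bundle.de_tables.values():
            assert not (bound & set(df.gene_id))

    def test_opposite_sign_fraction_matches_configured_rate(self):
        # pooled over seeds the opposite-sign share of genes present in both
        # tables should approach the configured 15/29 within binomial noise
        opposite = shared = 0
        for seed in range(20):
            bundle = generate_bundle(SimConfig(seed=seed, de_overlap_frac=1.0))
            loss = dict(zip(bundle.de_tables["loss_mutant"].gene_id,
                            bundle.de_tables["loss_mutant"].log2fc))
            ind = dict(zip(bundle.de_tables["induction"].gene_id,
                           bundle.de_tables["induction"].log2fc))
            bound = bundle.b_bound_genes()
            for g in bound:
                if g in loss and g in ind:
                    shared += 1
                    opposite += loss[g] * ind[g] < 0
        p = 15 / 29
        se = np.sqrt(p * (1 - p) / shared)
        assert abs(opposite / shared - p) <= 4 * se


class TestBundleSerialization:
    def test_byte_identical_under_same_config(self, tmp_path):
        cfg = SimConfig(seed=21, n_chrom=1, chrom_len=100_000, n_genes=30,
                        n_sites_A=10)
        write_bundle(generate_bundle(cfg), tmp_path / "one")
        write_bundle(generate_bundle(cfg), tmp_path / "two")
        assert dir_digest(tmp_path / "one") == dir_digest(tmp_path / "two")

    def test_expected_files_written(self, tmp_path, default_bundle):
        paths = write_bundle(default_bundle, tmp_path)
        for key in ("genome", "genes", "sites_A", "sites_B", "terms",
                    "motifs", "de_loss_mutant", "de_induction", "config"):
            assert paths[key].exists(), key
        fasta = paths["genome"].read_text()
        assert fasta.startswith(">chr1")
        n_reps = default_bundle.cfg.n_replicates
        frag_files = [k for k in paths if k.startswith("fragments/")]
        assert len(frag_files) == 3 * n_reps
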