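"""Tests for the synthetic-data generators and the fixture bundle."""

import numpy as np
import pandas as pd
import pytest

from dimotif import (
    DiMotifConfig,
    SimConfig,
    Sequence,
    enumerate_configs,
    make_fixture_bundle,
    read_bedgraph,
    read_fasta,
    read_feature_starts,
    scan_dimotifs,
    simulate_de_tables,
    simulate_occupancy,
    simulate_promoters,
    simulate_tpm,
)
from dimotif.geneset_classify import CONTRAST_NAMES
from dimotif.synthetic import ClassMotifSpec, config_from_dict, asdict_config


class TestSimConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(class_proportions={"background": 0.5})

    def test_inconsistent_effects_rejected(self):
        bad = SimConfig.__new__(SimConfig)  # bypass to build kwargs easily
        effects = SimConfig().effects
        effects["kar4_dependent"]["kar4_t60_vs_wt_t60"] = 0.0  # no longer dep
        with pytest.raises(ValueError, match="classify"):
            SimConfig(effects=effects)

    def test_round_trip_through_dict(self):
        cfg = SimConfig(n_genes=40, seed=3)
        again = config_from_dict(asdict_config(cfg))
        assert again == cfg


class TestSimulatePromoters:
    def test_plant_then_rescan_identity(self, small_sim):
        genome = small_sim["genome"]["chr_sim"]
        truth = small_sim["truth"]
        cfg = small_sim["config"]
        configs = enumerate_configs(20)
        planted = truth[truth["class"] != "background"]
        for gene, row in planted.iterrows():
            start = int(row["prom_start"])
            seq = Sequence(gene, genome[start:start + cfg.promoter_len])
            ms = scan_dimotifs(seq, configs)
            assert any(
                m.config == DiMotifConfig(row["orientation"], int(row["spacing"]))
                and m.strand == row["strand"]
                and (m.m1, m.m2) == (int(row["m1"]), int(row["m2"]))
                for m in ms
            ), f"planted motif not recovered for {gene}"

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_genes=30, seed=5)
        g1, _, t1, _ = simulate_promoters(cfg)
        g2, _, t2, _ = simulate_promoters(cfg)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        g1, _, _, _ = simulate_promoters(SimConfig(n_genes=30, seed=5))
        g2, _, _, _ = simulate_promoters(SimConfig(n_genes=30, seed=6))
        assert g1 != g2

    def test_class_counts_match_proportions(self, small_sim):
        counts = small_sim["truth"]["class"].value_counts()
        assert (counts == 20).all()  # 80 genes, 4 equal classes

    def test_promoter_too_short_rejected(self):
        spec = {"kar4_only": ClassMotifSpec("TT", 3, ((0, 0),))}
        with pytest.raises(ValueError, match="too short"):
            SimConfig(promoter_len=15, motif_specs={**spec})


class TestSimulateOccupancy:
    def test_zero_noise_matches_deterministic_formula(self):
        cfg = SimConfig(n_genes=40, occ_sigma=0.0, seed=2)
        _, _, truth, _ = simulate_promoters(cfg)
        truth, _, _, _ = simulate_occupancy(truth, cfg)
        planted = truth[truth["class"] != "background"]
        want = cfg.occ_base * np.exp(
            -cfg.occ_lambda * (planted["m1"] + planted["m2"])
        )
        assert planted["occ_wt"].to_numpy() == pytest.approx(want.to_numpy())

    def test_lambda_zero_removes_mismatch_dependence(self):
        cfg = SimConfig(n_genes=40, occ_sigma=0.0, occ_lambda=0.0, seed=2)
        _, _, truth, _ = simulate_promoters(cfg)
        truth, _, _, _ = simulate_occupancy(truth, cfg)
        planted = truth[truth["class"] != "background"]
        assert planted["occ_wt"].nunique() == 1

    def test_rpm_recovery_from_tags(self, small_sim):
        from dimotif import GenomicRegion, occupancy_rpm

        tracks = small_sim["tracks"]
        plus, minus = tracks[("wt", "+")], tracks[("wt", "-")]
        scale = sum(
            float((t["value"] * (t["end"] - t["start"])).sum())
            for t in (plus, minus)
        ) / 1e6
        assert scale == pytest.approx(1.0)
        for site in small_sim["sites"][:20]:
            region = GenomicRegion("chr_sim", site.point - 120,
                                   site.point + 121, site.region_id)
            rpm = occupancy_rpm([plus, minus], region, scale)
            assert rpm == pytest.approx(site.occupancy_rpm, rel=0.01)

    def test_genotype_penalty_direction(self, small_sim):
        truth = small_sim["truth"]
        dep = truth.loc[truth["class"] == "kar4_dependent", "occ_kar4"].mean()
        ind = truth.loc[truth["class"] == "kar4_independent", "occ_kar4"].mean()
        only = truth.loc[truth["class"] == "kar4_only"]
        assert dep < ind
        # penalty 0.5 means kar4-delta-only sites GAIN occupancy without Kar4
        assert (only["occ_kar4"] > only["occ_wt"]).all()


class TestSimulateDETables:
    def test_zero_noise_gives_exact_padj(self):
        cfg = SimConfig(n_genes=40, lfc_sigma=0.0, seed=4)
        _, _, truth, _ = simulate_promoters(cfg)
        cs = simulate_de_tables(truth, cfg)
        wt = cs.wt_t60_vs_t0.set_index("gene")
        planted = truth[truth["class"].isin(
            ["kar4_independent", "kar4_dependent"])].index
        assert (wt.loc[planted, "padj"] == 0.0).all()
        background = truth[truth["class"] == "background"].index
        assert (wt.loc[background, "padj"] == 1.0).all()

    def test_noise_accuracy_degrades_gracefully(self):
        accs = []
        for sigma in (0.0, 0.6):
            cfg = SimConfig(n_genes=200, lfc_sigma=sigma, seed=9)
            _, _, truth, _ = simulate_promoters(cfg)
            cs = simulate_de_tables(truth, cfg)
            from dimotif import classify_genesets

            labels = classify_genesets(cs, exclude=())
            expected = truth["class"].map({
                "kar4_independent": "pheromone_up_kar4_independent",
                "kar4_dependent": "pheromone_up_kar4_dependent",
                "kar4_only": "kar4_only_up",
                "background": "all_other",
            })
            accs.append((labels["label"].loc[expected.index] == expected).mean())
        assert accs[0] == 1.0
        assert accs[1] < accs[0]

    def test_tpm_table_consistent_with_effects(self):
        cfg = SimConfig(n_genes=40, lfc_sigma=0.0, seed=4)
        _, _, truth, _ = simulate_promoters(cfg)
        tpm = simulate_tpm(truth, cfg)
        ind = truth[truth["class"] == "kar4_independent"].index[0]
        ratio = np.log2(tpm.loc[ind, "wt_t60_r1"] / tpm.loc[ind, "wt_t0_r1"])
        assert ratio == pytest.approx(2.0)


class TestFixtureBundle:
    def test_bundle_loads_through_every_reader(self, tmp_path):
        import warnings

        cfg = SimConfig(n_genes=24, seed=13)
        make_fixture_bundle(tmp_path / "b", seed=13, config=cfg)
        b = tmp_path / "b"
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            genome = read_fasta(b / "genome.fa")
            feats = read_feature_starts(b / "features.gff3")
            tags = read_bedgraph(b / "tags_wt_plus.bedgraph")
        assert len(genome) == 1
        assert sum(f.feature_type == "gene" for f in feats) == 24
        assert sum(f.feature_type == "LTR" for f in feats) == 3
        assert (tags["value"] > 0).all()
        for name in CONTRAST_NAMES:
            df = pd.read_csv(b / f"contrast_{name}.tsv", sep="\t")
            assert set(df.columns) == {"gene", "lfc", "padj"}

    def test_same_seed_stable_outputs(self, tmp_path):
        cfg = SimConfig(n_genes=16, seed=21)
        make_fixture_bundle(tmp_path / "a", seed=21, config=cfg)
        make_fixture_bundle(tmp_path / "b", seed=21, config=cfg)
        for name in ("genome.fa", "truth.tsv", "sites.bed",
                     "contrast_wt_t60_vs_t0.tsv"):
            assert (tmp_path / "a" / name).read_text() == \
                (tmp_path / "b" / name).read_text()
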