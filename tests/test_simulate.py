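import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from koaudit.core import ValidationError
from koaudit.simulate import (
    SimulationConfig,
    scenario_config,
    simulate_all,
    simulate_annotation,
    simulate_counts,
    simulate_methylation,
    simulate_variants,
)

TINY = dict(
    n_chromosomes=1,
    chrom_length=10_000_000,
    region_start=2_000_000,
    region_end=5_000_000,
    signature_size=10,
    family_size=2,
)


def tiny_config(**kw):
    base = dict(TINY, n_genes=100, n_cis_deregulated=10, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_region_outside_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="region"):
            tiny_config(region_end=20_000_000)

    def test_region_rate_must_exceed_background(self):
        with pytest.raises(ValidationError, match="exceed"):
            tiny_config(snp_background_rate=5.0, snp_region_rate=5.0)

    def test_unknown_scenario(self):
        with pytest.raises(ValidationError, match="unknown scenario"):
            scenario_config("bogus")


class TestAnnotation:
    def test_packing(self):
        ann = simulate_annotation(tiny_config())
        g = ann.genes.sort_values(["chrom", "start"])
        assert len(g) == 100
        assert (g["start"] < g["end"]).all()
        same = g["chrom"].values[1:] == g["chrom"].values[:-1]
        assert (g["start"].values[1:] >= g["end"].values[:-1])[same].all()

    def test_overfull_genome_fatal(self):
        with pytest.raises(ValidationError, match="cannot pack"):
            simulate_annotation(
                tiny_config(n_genes=5000, chrom_length=10_000_000,
                            region_start=0, region_end=10_000_000,
                            n_cis_deregulated=0)
            )

    def test_deterministic(self):
        a = simulate_annotation(tiny_config())
        b = simulate_annotation(tiny_config())
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.elements, b.elements)

    def test_zero_genes(self):
        ann = simulate_annotation(
            tiny_config(n_genes=0, n_cis_deregulated=0, family_size=0,
                        signature_size=0)
        )
        assert len(ann.genes) == 0

    def test_tss_symmetric_and_element_classes(self):
        cfg = tiny_config()
        ann = simulate_annotation(cfg)
        tss = ann.elements_of_class("TSS")
        assert (tss["end"] - tss["start"] == 2 * cfg.tss_halfwidth).all()
        g = ann.genes.iloc[0]
        mid = g["start"] if g["strand"] == "+" else g["end"] - 1
        row = tss[(tss["start"] <= mid) & (tss["end"] > mid)].iloc[0]
        assert row["start"] == mid - cfg.tss_halfwidth
        assert set(ann.elements["element_class"]) == {"TSS", "EXN", "INT",
                                                      "ING"}


class TestCounts:
    def test_poisson_limit_variance(self):
        cfg = tiny_config(n_genes=2000, chrom_length=60_000_000,
                          region_start=2_000_000, region_end=30_000_000,
                          dispersion=0.0, n_cis_deregulated=0,
                          libsize_range=(1.0, 1.0), samples_per_group=(4, 4))
        ann = simulate_annotation(cfg)
        cm, truth = simulate_counts(cfg, ann)
        assert truth.beta == {}
        m = cm.counts.mean(axis=1)
        v = cm.counts.var(axis=1, ddof=1)
        # pooled variance/mean ratio ~ 1 in the Poisson limit
        assert v.sum() / m.sum() == pytest.approx(1.0, abs=0.05)

    def test_nb_variance_mean_relation(self):
        phi = 0.2
        cfg = tiny_config(n_genes=2000, chrom_length=60_000_000,
                          region_start=2_000_000, region_end=30_000_000,
                          dispersion=phi, n_cis_deregulated=0,
                          libsize_range=(1.0, 1.0), samples_per_group=(8, 8))
        ann = simulate_annotation(cfg)
        cm, _ = simulate_counts(cfg, ann)
        m = cm.counts.mean(axis=1)
        v = cm.counts.var(axis=1, ddof=1)
        phi_hat = np.sum(v - m) / np.sum(m**2)
        assert phi_hat == pytest.approx(phi, rel=0.2)

    def test_signature_offset_recovered(self):
        cfg = tiny_config(
            n_genes=2000, chrom_length=60_000_000,
            region_start=2_000_000, region_end=30_000_000,
            n_cis_deregulated=0, signature_size=300,
            signature_shifts={"CON": 0.0, "LZS": 1.0, "DZS": 0.0,
                              "NVS": 0.0, "CBS": 0.0},
            samples_per_group=(4, 4), dispersion=0.05,
        )
        ann = simulate_annotation(cfg)
        cm, truth = simulate_counts(cfg, ann)
        gene_idx = {g: i for i, g in enumerate(cm.genes)}
        idx1 = cm.group_indices("ctrl")
        idx2 = cm.group_indices("ko")
        rows = [gene_idx[g] for g in truth.signature_members["LZS"]]
        m1 = cm.counts[rows][:, idx1].mean(axis=1)
        m2 = cm.counts[rows][:, idx2].mean(axis=1)
        observed = np.mean(np.log2(m2 + 0.5) - np.log2(m1 + 0.5))
        assert observed == pytest.approx(1.0, abs=0.1)

    def test_cis_bookkeeping(self, small_gc_config, small_gc_annotation,
                             small_gc_data):
        cfg = small_gc_config
        _, truth = small_gc_data
        sig_members = {
            g for members in truth.signature_members.values() for g in members
        }
        cis = {
            g: b for g, b in truth.beta.items()
            if g not in sig_members and not g.startswith(cfg.family_prefix)
        }
        assert len(cis) == cfg.n_cis_deregulated
        coords = small_gc_annotation.genes.set_index("gene")
        for gene in cis:
            row = coords.loc[gene]
            assert row["chrom"] == cfg.region_chrom
            assert row["start"] < cfg.region_end
            assert row["end"] > cfg.region_start
        signs = np.sign(list(cis.values()))
        assert (signs > 0).any() and (signs < 0).any()

    def test_non_de_means_equal_between_groups(self, small_gc_data):
        cm, truth = small_gc_data
        null_rows = [i for i, g in enumerate(cm.genes) if g not in truth.beta]
        idx1 = cm.group_indices("ctrl")
        idx2 = cm.group_indices("ko")
        s = np.asarray(truth.size_factors)
        norm = cm.counts / s  # undo library-size factors with the truth
        m1 = norm[null_rows][:, idx1].mean()
        m2 = norm[null_rows][:, idx2].mean()
        assert m2 / m1 == pytest.approx(1.0, abs=0.05)


class TestVariants:
    def test_degenerate_rates_all_in_region(self):
        cfg = tiny_config(snp_background_rate=0.0, snp_region_rate=10.0)
        ann = simulate_annotation(cfg)
        vt = simulate_variants(cfg, ann)
        pos0 = vt.records["pos"] - 1
        assert (pos0 >= cfg.region_start).all()
        assert (pos0 < cfg.region_end).all()
        assert (vt.records["strain"] == cfg.strain).all()

    def test_poisson_expectation(self):
        cfg = tiny_config(
            chrom_length=30_000_000, region_start=5_000_000,
            region_end=25_000_000, snp_background_rate=0.0,
            snp_region_rate=10.0,
        )
        ann = simulate_annotation(cfg)
        vt = simulate_variants(cfg, ann)
        expected = 10.0 * 20_000_000 / 50_000  # 4000
        assert len(vt) == pytest.approx(expected, abs=4 * np.sqrt(expected))

    def test_deterministic(self):
        cfg = tiny_config()
        ann = simulate_annotation(cfg)
        a = simulate_variants(cfg, ann)
        b = simulate_variants(cfg, ann)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_coding_flag_matches_exons(self):
        cfg = tiny_config()
        ann = simulate_annotation(cfg)
        vt = simulate_variants(cfg, ann)
        exons = ann.elements_of_class("EXN")
        for row in vt.records.head(50).itertuples(index=False):
            pos0 = row.pos - 1
            in_exon = (
                (exons["chrom"] == row.chrom)
                & (exons["start"] <= pos0)
                & (pos0 < exons["end"])
            ).any()
            assert bool(row.coding) == bool(in_exon)


class TestMethylation:
    def test_null_exchangeable_means(self):
        cfg = tiny_config(n_genes=400)
        ann = simulate_annotation(cfg)
        a, b = simulate_methylation(cfg, ann)
        for cls in ("TSS", "EXN", "INT", "ING"):
            la, lb = a.loads_of_class(cls), b.loads_of_class(cls)
            assert np.mean(lb) / np.mean(la) == pytest.approx(1.0, abs=0.25)

    def test_injection_factor_recovered(self):
        cfg = tiny_config(n_genes=500, meth_element_sigma=0.3)
        ann = simulate_annotation(cfg)
        a, b = simulate_methylation(cfg, ann,
                                    inject_demethylation={"EXN": 0.5})
        ratio = np.mean(b.loads_of_class("EXN")) / np.mean(
            a.loads_of_class("EXN")
        )
        assert ratio == pytest.approx(0.5, abs=0.08)
        ratio_tss = np.mean(b.loads_of_class("TSS")) / np.mean(
            a.loads_of_class("TSS")
        )
        assert ratio_tss == pytest.approx(1.0, abs=0.2)

    def test_identity_factor_equals_no_injection(self):
        cfg = tiny_config()
        ann = simulate_annotation(cfg)
        a1, b1 = simulate_methylation(cfg, ann)
        a2, b2 = simulate_methylation(cfg, ann,
                                      inject_demethylation={"EXN": 1.0})
        pd.testing.assert_frame_equal(a1.elements, a2.elements)
        pd.testing.assert_frame_equal(b1.elements, b2.elements)


class TestEmission:
    def test_fixed_seed_fixes_every_byte(self, tmp_path):
        cfg = tiny_config()
        p1 = simulate_all(cfg, tmp_path / "one")
        p2 = simulate_all(cfg, tmp_path / "two")
        for key in p1:
            b1 = Path(p1[key]).read_bytes() if Path(p1[key]).is_file() else None
            b2 = Path(p2[key]).read_bytes() if Path(p2[key]).is_file() else None
            assert b1 == b2, f"{key} differs between identically-seeded runs"

    def test_ground_truth_consistent_with_files(self, tmp_path):
        cfg = tiny_config()
        paths = simulate_all(cfg, tmp_path)
        truth = json.loads(Path(paths["ground_truth"]).read_text())
        counts = pd.read_csv(paths["counts_tsv"], sep="\t", index_col=0)
        assert set(truth["beta"]).issubset(set(counts.index))
        sets_dir = Path(paths["sets_dir"])
        for label, members in truth["signature_members"].items():
            on_disk = (sets_dir / f"{label}.txt").read_text().split()
            assert on_disk == members
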