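import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import exact_hypergeom_upper
from zdep.enrichment import sea_enrichment
from zdep.regions import compute_gene_regions
from zdep.simulate import (
    CapacityError,
    SimulationConfig,
    expected_chip_mean,
    generate_annotation,
    generate_chip_coverage,
    generate_rna_counts,
    generate_term_annotation,
    simulate_bundle,
    write_fixture_bundle,
)
from zdep.io import write_gff3


class TestSimulationConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_proportions=(0.5, 0.5, 0.5))

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            SimulationConfig(n_genes=1000, n_chromosomes=1, chrom_length=100_000)

    def test_bad_coupling_rule(self):
        with pytest.raises(ValueError, match="coupling_rule"):
            SimulationConfig(coupling_rule={"up": "sideways"})

    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert cfg.chrom_names == ["chr1", "chr2"]


class TestGenerateAnnotation:
    def test_empty_case(self):
        genes, truth = generate_annotation(SimulationConfig(n_genes=0))
        assert genes == [] and truth.empty

    def test_geometry_constraints(self, default_config):
        genes, _ = generate_annotation(default_config)
        by_chrom = {}
        for g in genes:
            assert 1000 <= g.length <= 5000
            assert g.start >= 1000
            assert g.end <= default_config.chrom_length - 1000
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 >= e1, "genes overlap"

    def test_class_counts_within_binomial_envelope(self):
        cfg = SimulationConfig(n_genes=300, class_proportions=(0.5, 0.33, 0.17),
                               n_chromosomes=2, chrom_length=1_200_000, seed=4)
        _, truth = generate_annotation(cfg)
        counts = truth["planted_class"].value_counts()
        for cls, p in zip(("k1_broad", "k2_tss", "k3_depleted"), (0.5, 0.33, 0.17)):
            lo = stats.binom.ppf(0.005, 300, p)
            hi = stats.binom.ppf(0.995, 300, p)
            assert lo <= counts.get(cls, 0) <= hi

    def test_every_gene_in_truth_once(self, bundle):
        assert len(bundle.truth) == len(bundle.genes)
        assert not bundle.truth.index.duplicated().any()
        assert [g.gene_id for g in bundle.genes] == list(bundle.truth.index)

    def test_coupling_rule_respected(self, bundle):
        truth = bundle.truth
        assert (truth.loc[truth["planted_de"] == "up",
                          "planted_h2az_change"] == "gb_down").all()
        assert (truth.loc[truth["planted_de"] == "down",
                          "planted_h2az_change"] == "gb_up").all()
        assert (truth.loc[truth["planted_de"] == "null",
                          "planted_h2az_change"] == "none").all()

    def test_same_seed_identical_gff_bytes(self, tmp_path, default_config):
        files = []
        for name in ("a.gff3", "b.gff3"):
            genes, _ = generate_annotation(default_config)
            write_gff3(genes, tmp_path / name,
                       chrom_sizes=default_config.chrom_sizes)
            files.append((tmp_path / name).read_bytes())
        assert files[0] == files[1]


class TestChipCoverage:
    def test_unknown_condition_rejected(self, bundle, default_config):
        with pytest.raises(ValueError, match="condition"):
            generate_chip_coverage(bundle.genes, bundle.truth, default_config,
                                   "drought", "chip")

    def test_unknown_role_rejected(self, bundle, default_config):
        with pytest.raises(ValueError, match="role"):
            generate_chip_coverage(bundle.genes, bundle.truth, default_config,
                                   "control", "mock")

    def test_all_depleted_never_exceeds_background(self):
        cfg = SimulationConfig(n_genes=50, n_chromosomes=1,
                               class_proportions=(0.0, 0.0, 1.0), seed=2)
        genes, truth = generate_annotation(cfg)
        mu = expected_chip_mean(genes, truth, cfg, "control")
        for vec in mu.values():
            assert np.all(vec <= cfg.background_level + 1e-12)

    def test_no_effect_means_identical_expectations(self):
        cfg = SimulationConfig(n_genes=60, n_chromosomes=1, seed=3,
                               redistribution_effect=0.0, coupling_rule=None)
        genes, truth = generate_annotation(cfg)
        mu_c = expected_chip_mean(genes, truth, cfg, "control")
        mu_s = expected_chip_mean(genes, truth, cfg, "stress")
        for chrom in mu_c:
            np.testing.assert_allclose(mu_c[chrom], mu_s[chrom], rtol=1e-12)

    def test_observed_difference_within_poisson_envelope(self):
        cfg = SimulationConfig(n_genes=60, n_chromosomes=1, seed=3,
                               redistribution_effect=0.0, coupling_rule=None)
        genes, truth = generate_annotation(cfg)
        a = generate_chip_coverage(genes, truth, cfg, "control", "chip", 1)
        b = generate_chip_coverage(genes, truth, cfg, "stress", "chip", 1)
        mu = expected_chip_mean(genes, truth, cfg, "control")["chr1"]
        diff = (a.counts["chr1"] - b.counts["chr1"]).mean()
        se = np.sqrt(2 * mu.mean() / mu.size)
        assert abs(diff) <= 4 * se

    def test_k2_peak_position(self):
        cfg = SimulationConfig(n_genes=1, n_chromosomes=1, seed=0,
                               class_proportions=(0.0, 1.0, 0.0))
        genes, truth = generate_annotation(cfg)
        # relocate the gene so its TSS sits at exactly 10,000 on + strand
        from zdep.io import GeneModel

        g = genes[0]
        gene = GeneModel(g.gene_id, g.chrom, 10_000, 10_000 + g.length, "+", g.biotype)
        mu = expected_chip_mean([gene], truth, cfg, "control")["chr1"]
        peak_bp = int(np.argmax(mu)) * 200 + 100
        assert 9_750 <= peak_bp < 10_500

    def test_replicate_changes_stream_only(self, bundle, default_config):
        r1 = generate_chip_coverage(bundle.genes, bundle.truth, default_config,
                                    "control", "chip", 1)
        r1_again = generate_chip_coverage(bundle.genes, bundle.truth,
                                          default_config, "control", "chip", 1)
        r2 = generate_chip_coverage(bundle.genes, bundle.truth, default_config,
                                    "control", "chip", 2)
        assert all(np.array_equal(r1.counts[c], r1_again.counts[c])
                   for c in r1.counts)
        assert any(not np.array_equal(r1.counts[c], r2.counts[c])
                   for c in r1.counts)

    def test_input_uniform_at_background(self, bundle, default_config):
        inp = bundle.tracks["control_input_r1"]
        for vec in inp.counts.values():
            assert abs(vec.mean() - default_config.background_level) < 0.2

    def test_mean_structure_of_k2_genes(self, bundle, default_config):
        """Average observed counts at the TSS windows of >= 50 k2 genes
        reproduce the expected kernel within Monte-Carlo error."""
        truth, genes = bundle.truth, bundle.genes
        mu = expected_chip_mean(genes, truth, default_config, "control")
        track = bundle.tracks["control_chip_r1"]
        k2 = [g for g in genes
              if truth.loc[g.gene_id, "planted_class"] == "k2_tss"]
        assert len(k2) >= 50
        obs, exp = [], []
        for g in k2:
            tss = g.start if g.strand == "+" else g.end - 1
            w = tss // 200
            obs.append(track.counts[g.chrom][w])
            exp.append(mu[g.chrom][w])
        obs, exp = np.array(obs), np.array(exp)
        se = np.sqrt(exp.sum()) / len(k2)
        assert abs(obs.mean() - exp.mean()) <= 3 * se

    def test_redistribution_moves_signal(self, bundle, default_config):
        """Stress lowers expected TSS-region signal and raises GB signal."""
        cfg = default_config
        truth, genes = bundle.truth, bundle.genes
        mu_c = expected_chip_mean(genes, truth, cfg, "control")
        mu_s = expected_chip_mean(genes, truth, cfg, "stress")
        tss_c = tss_s = gb_c = gb_s = 0.0
        for g in genes:
            if truth.loc[g.gene_id, "planted_h2az_change"] != "none":
                continue
            r = compute_gene_regions(g, cfg.chrom_length)
            for (lo, hi), acc in ((r.tss_region, "tss"), (r.gb_region, "gb")):
                w0, w1 = lo // 200, max(hi // 200, lo // 200 + 1)
                c = mu_c[g.chrom][w0:w1].sum()
                s = mu_s[g.chrom][w0:w1].sum()
                if acc == "tss":
                    tss_c, tss_s = tss_c + c, tss_s + s
                else:
                    gb_c, gb_s = gb_c + c, gb_s + s
        assert tss_s < tss_c
        assert gb_s > gb_c


class TestRnaCounts:
    def test_requires_two_replicates(self, bundle):
        cfg = SimulationConfig(n_replicates=1)
        with pytest.raises(ValueError, match="replicates"):
            generate_rna_counts(bundle.genes, bundle.truth, cfg)

    def test_planted_zero_genes_all_zero(self, bundle):
        zero = bundle.truth.index[bundle.truth["planted_zero"]]
        assert len(zero) > 0
        assert (bundle.expr.counts.loc[zero] == 0).all().all()

    def test_baselines_span_four_orders(self, bundle):
        nz = bundle.expr.counts[(bundle.expr.counts > 0).all(axis=1)]
        means = nz.mean(axis=1)
        assert means.max() / max(means.min(), 0.5) >= 1e3

    def test_planted_fold_change_recovered_in_means(self, bundle):
        counts = bundle.expr.counts
        truth = bundle.truth
        ctrl = counts[[c for c in counts if c.startswith("control")]].mean(axis=1)
        strs = counts[[c for c in counts if c.startswith("stress")]].mean(axis=1)
        up = truth.index[(truth["planted_de"] == "up") & (ctrl > 50)]
        assert len(up) >= 5
        ratios = (strs[up] / ctrl[up])
        # lfc 2 -> ratio 4; average over genes well within NB noise
        assert 3.0 <= ratios.mean() <= 5.3

    def test_determinism(self, bundle, default_config):
        again = generate_rna_counts(bundle.genes, bundle.truth, default_config)
        pd.testing.assert_frame_equal(again.counts, bundle.expr.counts)

    def test_null_lfc_type_i(self):
        from zdep.expression import de_test

        cfg = SimulationConfig(n_genes=400, lfc_magnitude=0.0, de_fraction=0.2,
                               zero_expr_fraction=0.0, seed=13)
        genes, truth = generate_annotation(cfg)
        expr = generate_rna_counts(genes, truth, cfg)
        groups = dict(expr.samples["condition"])
        res = de_test(expr.counts, groups)
        assert (res["p_value"] < 0.05).mean() <= 0.09


class TestTermAnnotation:
    def test_empty_term_set(self, bundle):
        cfg = SimulationConfig(n_terms=0)
        truth = bundle.truth.copy()
        assert generate_term_annotation(truth, cfg) == {}

    def test_planted_enrichment_detected(self, bundle):
        truth = bundle.truth
        k1 = set(truth.index[truth["planted_class"] == "k1_broad"])
        bg = list(truth.index)
        res = sea_enrichment(k1, bundle.terms, bg)
        top = res.iloc[0]
        assert top["term_id"] == "T001" and top["significant"]

    def test_odds_ratio_one_is_null(self):
        cfg = SimulationConfig(term_odds_ratio=1.0, seed=21)
        genes, truth = generate_annotation(cfg)
        terms = generate_term_annotation(truth, cfg)
        k1 = set(truth.index[truth["planted_class"] == "k1_broad"])
        res = sea_enrichment(k1, terms, list(truth.index))
        assert not res["significant"].any()

    def test_term_covering_exactly_k1_hits_closed_form(self, bundle):
        truth = bundle.truth
        k1 = set(truth.index[truth["planted_class"] == "k1_broad"])
        bg = list(truth.index)
        res = sea_enrichment(k1, {"TX": k1}, bg)
        expected = exact_hypergeom_upper(len(k1), len(bg), len(k1), len(k1))
        assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_truth_records_memberships(self, bundle):
        row = bundle.truth["planted_terms"]
        listed = {g for g, s in row.items() if s}
        from_terms = set().union(*bundle.terms.values())
        assert listed == from_terms


class TestBundleDeterminism:
    def _digest(self, outdir: Path) -> dict:
        return {
            p.relative_to(outdir).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.rglob("*")) if p.is_file()
        }

    def test_fixture_bundle_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_genes=40, n_chromosomes=1,
                               chrom_length=400_000, seed=9)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        write_fixture_bundle(simulate_bundle(cfg), d1)
        write_fixture_bundle(simulate_bundle(cfg), d2)
        assert self._digest(d1) == self._digest(d2)

    def test_seed_changes_bundle(self, tmp_path):
        a = SimulationConfig(n_genes=40, n_chromosomes=1,
                             chrom_length=400_000, seed=9)
        b = SimulationConfig(n_genes=40, n_chromosomes=1,
                             chrom_length=400_000, seed=10)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        write_fixture_bundle(simulate_bundle(a), d1)
        write_fixture_bundle(simulate_bundle(b), d2)
        assert self._digest(d1) != self._digest(d2)

    def test_round_trip_through_io(self, tmp_path, bundle, default_config):
        from zdep.io import read_bedgraph, read_counts_tsv, read_gff3

        out = tmp_path / "bundle"
        write_fixture_bundle(bundle, out)
        genes = read_gff3(out / "annotation.gff3")
        assert genes == bundle.genes
        track = read_bedgraph(out / "coverage/control_chip_r1.bedgraph", 200,
                              chrom_sizes=default_config.chrom_sizes)
        for chrom, vec in bundle.tracks["control_chip_r1"].counts.items():
            np.testing.assert_allclose(track.counts[chrom], vec)
        counts = read_counts_tsv(out / "rna_counts.tsv")
        pd.testing.assert_frame_equal(counts, bundle.expr.counts)
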