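"""Generator properties: determinism, feasibility checks, planted structure,
and statistical fidelity of the simulated methylomes and expression."""

import numpy as np
import pandas as pd
import pytest

from dupmeth import io as dio
from dupmeth.simulate import (
    GENETIC_CODE,
    SimulationConfig,
    generate_annotation,
    generate_cds_pairs,
    mutate_codons,
    plant_duplicates,
    simulate_expression,
    simulate_methylomes,
)

from conftest import small_config


class TestAnnotation:
    def test_empty_genome_gives_valid_header_only_gff(self, tmp_path):
        cfg = SimulationConfig(n_chromosomes=1, genes_per_chromosome=0,
                               category_counts={}, frac_te=0.0)
        catalog = generate_annotation(cfg)
        assert len(catalog) == 0
        path = tmp_path / "empty.gff3"
        dio.write_gff3(catalog, path)
        assert path.read_text() == "##gff-version 3\n"

    def test_same_seed_gives_byte_identical_gff(self, tmp_path):
        paths = []
        for run in range(2):
            catalog = generate_annotation(small_config())
            p = tmp_path / f"run{run}.gff3"
            dio.write_gff3(catalog, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_genes_nonoverlapping_with_sequential_ranks(self):
        cfg = SimulationConfig(n_chromosomes=2, genes_per_chromosome=50,
                               category_counts={}, frac_te=0.0)
        catalog = generate_annotation(cfg)
        assert len(catalog) == 100
        for _, sub in catalog.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert list(sub["rank"]) == list(range(1, 51))
            # pairwise interval scan: each gene starts after the previous ends
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()

    def test_infeasible_config_raises(self):
        cfg = SimulationConfig(n_chromosomes=1, genes_per_chromosome=10,
                               category_counts={"tandem": 20})
        with pytest.raises(ValueError, match="non-TE genes"):
            cfg.validate()


class TestPlanting:
    def test_no_categories_gives_empty_truth_and_decoy_only_hits(self):
        cfg = small_config(category_counts={}, n_decoy_hits=50)
        catalog = generate_annotation(cfg)
        truth, hits = plant_duplicates(catalog, cfg)
        assert truth.pairs.empty
        assert len(hits) == 50
        assert (hits["evalue"] > 1e-10).all()

    def test_tandem_pairs_are_rank_adjacent_same_chromosome(self, study):
        truth, catalog = study["truth"], study["catalog"]
        g = catalog.genes
        tandem = truth.pairs[truth.pairs["category"] == "tandem"]
        assert len(tandem) == study["config"].category_counts["tandem"]
        for r in tandem.itertuples():
            assert g.at[r.gene_a, "chrom"] == g.at[r.gene_b, "chrom"]
            assert abs(g.at[r.gene_a, "rank"] - g.at[r.gene_b, "rank"]) == 1

    def test_proximal_gap_within_bounds_and_transposed_cross_chromosome(self, study):
        g = study["catalog"].genes
        cfg = study["config"]
        prox = study["truth"].pairs.query("category == 'proximal'")
        for r in prox.itertuples():
            assert g.at[r.gene_a, "chrom"] == g.at[r.gene_b, "chrom"]
            gap = abs(g.at[r.gene_a, "rank"] - g.at[r.gene_b, "rank"])
            assert 2 <= gap <= cfg.proximal_max_gap
        trans = study["truth"].pairs.query("category == 'transposed'")
        for r in trans.itertuples():
            assert g.at[r.gene_a, "chrom"] != g.at[r.gene_b, "chrom"]

    def test_genes_used_by_at_most_one_pair(self, study):
        pairs = study["truth"].pairs
        used = pd.concat([pairs["gene_a"], pairs["gene_b"]])
        assert not used.duplicated().any()

    def test_planted_pairs_have_subthreshold_hits(self, study):
        hits = study["hits"]
        best = {}
        for q, s, e in zip(hits["qseqid"], hits["sseqid"], hits["evalue"]):
            key = tuple(sorted((q, s)))
            best[key] = min(best.get(key, 1.0), e)
        for r in study["truth"].pairs.itertuples():
            assert best[(r.gene_a, r.gene_b)] < 1e-10


class TestMethylomes:
    def test_retention_one_preserves_cg_levels(self):
        cfg = small_config(cg_retention_mutant=1.0)
        catalog = generate_annotation(cfg)
        truth, _ = plant_duplicates(catalog, cfg)
        simulate_methylomes(truth, catalog, cfg)
        meth = truth.gene_meth
        assert np.allclose(meth["cg_wt"], meth["cg_mut"])

    def test_retention_zero_gives_no_methylated_cg_reads(self):
        cfg = small_config(cg_retention_mutant=0.0)
        catalog = generate_annotation(cfg)
        truth, _ = plant_duplicates(catalog, cfg)
        _, cx_mut = simulate_methylomes(truth, catalog, cfg)
        cg = cx_mut[cx_mut["context"] == "CG"]
        assert (cg["count_methylated"] == 0).all()

    def test_mutant_body_level_matches_binomial_expectation(self):
        """One gene, known WT level 0.8 and retention 0.09 -> the pooled
        mutant estimate lands within 3 SE of 0.072."""
        cfg = SimulationConfig(
            n_chromosomes=2, genes_per_chromosome=1, frac_te=0.0,
            category_counts={}, sites_per_gene={"CG": 200, "CHG": 1, "CHH": 1},
            mean_coverage=20.0, frac_bm_genes=1.0, seed=11,
        )
        catalog = generate_annotation(cfg)
        truth, _ = plant_duplicates(catalog, cfg)
        from dupmeth.simulate import _assign_true_levels
        _assign_true_levels(truth, catalog, cfg)
        truth.gene_meth["cg_wt"] = 0.8
        truth.gene_meth["cg_mut"] = 0.8 * cfg.cg_retention_mutant
        _, cx_mut = simulate_methylomes(truth, catalog, cfg)
        cg = cx_mut[cx_mut["context"] == "CG"]
        total = (cg["count_methylated"] + cg["count_unmethylated"]).sum()
        level = cg["count_methylated"].sum() / total
        p = 0.8 * cfg.cg_retention_mutant
        se = np.sqrt(p * (1 - p) / total)
        assert abs(level - p) < 3 * se

    def test_chg_chh_levels_identical_across_genotypes(self, study):
        meth = study["truth"].gene_meth
        assert (meth["chg_wt"] == meth["chg_mut"]).all()
        assert (meth["chh_wt"] == meth["chh_mut"]).all()

    def test_conservation_methylated_reads_bounded_by_coverage(self, study):
        for key in ("cx_wt", "cx_mut"):
            cx = study[key]
            assert (cx["count_methylated"] >= 0).all()
            assert (cx["count_unmethylated"] >= 0).all()

    def test_same_seed_identical_reports(self, sim_config, study):
        cfg = small_config()
        catalog = generate_annotation(cfg)
        truth, _ = plant_duplicates(catalog, cfg)
        cx_wt, _ = simulate_methylomes(truth, catalog, cfg)
        pd.testing.assert_frame_equal(cx_wt, study["cx_wt"])


class TestExpression:
    def test_zero_coupling_leaves_means_unchanged(self):
        cfg = small_config(bcgm_expression_coupling=0.0, expression_noise_sd=0.0)
        catalog = generate_annotation(cfg)
        truth, _ = plant_duplicates(catalog, cfg)
        simulate_expression(truth, catalog, cfg)
        ge = truth.gene_expr
        assert np.allclose(ge["wt_mean_fpkm"], ge["mut_mean_fpkm"])

    def test_fpkm_invariant_to_library_size_at_fixed_fractions(self, study):
        """FPKM = count / (kb * millions of reads): scaling counts and
        library together leaves FPKM unchanged."""
        expr = study["expr"]
        scale = (expr["gene_length"] / 1e3) * (expr["library_size"] / 1e6)
        recomputed = expr["count"] / scale
        assert np.allclose(recomputed, expr["fpkm"])
        doubled = (expr["count"] * 2) / (scale * 2)
        assert np.allclose(doubled, expr["fpkm"])

    def test_roles_match_wt_means(self, study):
        ge = study["truth"].gene_expr
        for r in study["truth"].pairs.itertuples():
            fa, fb = ge.at[r.gene_a, "wt_mean_fpkm"], ge.at[r.gene_b, "wt_mean_fpkm"]
            ra, rb = ge.at[r.gene_a, "role"], ge.at[r.gene_b, "role"]
            assert {ra, rb} == {"higher", "lower"}
            assert (fa >= fb) == (ra == "higher")


class TestCdsPairs:
    def test_zero_substitutions_gives_identical_sequences(self):
        rng = np.random.default_rng(0)
        ancestor = ["ATG", "GCT", "CGA", "TTA"]
        assert mutate_codons(ancestor, 0, 0, rng) == ancestor

    def test_planted_counts_classify_correctly_step_by_step(self):
        rng = np.random.default_rng(3)
        ancestor = ["CTT"] * 50
        derived = mutate_codons(ancestor, 10, 0, rng)
        # all substitutions synonymous: translations identical
        t_a = "".join(GENETIC_CODE[c] for c in ancestor)
        t_b = "".join(GENETIC_CODE[c] for c in derived)
        assert t_a == t_b
        assert sum(a != b for a, b in zip(ancestor, derived)) > 0

    def test_impossible_request_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="exceed available"):
            mutate_codons(["ATG"], 100, 0, rng)

    def test_no_stops_and_length_preserved(self, study):
        for pair_id, seqs in study["cds"].items():
            for seq in seqs.values():
                assert len(seq) % 3 == 0
                codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
                assert all(GENETIC_CODE[c] != "*" for c in codons)

    def test_truth_records_realized_counts(self, study):
        ct = study["truth"].cds_truth
        assert len(ct) == len(study["truth"].pairs)
        assert (ct["syn_subs"] >= 0).all() and (ct["nonsyn_subs"] >= 0).all()
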