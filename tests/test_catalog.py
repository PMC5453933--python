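"""Candidate filtering, collinear-block chaining (vs an exhaustive oracle),
and duplicate-origin classification rules."""

import numpy as np
import pandas as pd
import pytest

from dupmeth.catalog import (
    GeneCatalog,
    classify_duplicates,
    detect_collinear_blocks,
    filter_candidates,
)

from oracles import longest_chain_brute


def make_catalog(n_per_chrom, n_chrom=2, te=()):
    rows = []
    for c in range(1, n_chrom + 1):
        for r in range(1, n_per_chrom + 1):
            gid = f"g{c}_{r}"
            rows.append({
                "gene_id": gid, "chrom": f"chr{c}", "start": r * 1000,
                "end": r * 1000 + 500, "strand": "+", "rank": r,
                "is_te": gid in te,
            })
    return GeneCatalog(pd.DataFrame(rows).set_index("gene_id"))


def hits_frame(records):
    """records: (q, s, evalue[, bitscore])"""
    rows = []
    for rec in records:
        q, s, e = rec[0], rec[1], rec[2]
        bs = rec[3] if len(rec) > 3 else 500.0
        rows.append({"qseqid": q, "sseqid": s, "evalue": e, "bitscore": bs})
    return pd.DataFrame(rows)


class TestFilterCandidates:
    def test_single_good_hit_kept(self):
        cat = make_catalog(5)
        out = filter_candidates(hits_frame([("g1_1", "g1_2", 1e-20)]), cat)
        assert list(map(tuple, out[["gene_a", "gene_b"]].to_numpy())) == [("g1_1", "g1_2")]

    def test_evalue_threshold_is_strict(self):
        cat = make_catalog(5)
        out = filter_candidates(hits_frame([("g1_1", "g1_2", 1e-10)]), cat)
        assert out.empty
        out = filter_candidates(hits_frame([("g1_1", "g1_2", 0.999e-10)]), cat)
        assert len(out) == 1

    def test_self_hits_and_te_genes_removed(self):
        cat = make_catalog(5, te=("g1_3",))
        out = filter_candidates(hits_frame([
            ("g1_1", "g1_1", 1e-50), ("g1_1", "g1_3", 1e-50), ("g1_3", "g1_2", 1e-50),
        ]), cat)
        assert out.empty

    def test_unknown_gene_raises_with_offender(self):
        cat = make_catalog(3)
        with pytest.raises(ValueError, match="ghost"):
            filter_candidates(hits_frame([("g1_1", "ghost", 1e-50)]), cat)

    def test_top_k_matches_brute_force_sort(self):
        """7 subjects with distinct e-values: only the 5 smallest survive."""
        cat = make_catalog(10)
        rng = np.random.default_rng(5)
        evs = 10.0 ** rng.uniform(-60, -20, size=7)
        recs = [("g1_1", f"g1_{i + 2}", e) for i, e in enumerate(evs)]
        out = filter_candidates(hits_frame(recs), cat, top_k=5)
        expected_subjects = {
            f"g1_{i + 2}" for i in np.argsort(evs)[:5]
        }
        got = set(out["gene_a"]).union(out["gene_b"]) - {"g1_1"}
        assert got == expected_subjects

    def test_pairs_symmetrized_and_deduplicated(self):
        cat = make_catalog(5)
        out = filter_candidates(hits_frame([
            ("g1_1", "g1_2", 1e-50), ("g1_2", "g1_1", 1e-40),
        ]), cat)
        assert len(out) == 1
        assert out.at[0, "evalue"] == 1e-50


def anchors_to_candidates(anchors):
    """anchors: list of (rank_on_chr1, rank_on_chr2)."""
    return pd.DataFrame(
        [{"gene_a": f"g1_{r1}", "gene_b": f"g2_{r2}"} for r1, r2 in anchors]
    )


class TestCollinearBlocks:
    def test_perfect_diagonal_one_block_same_orientation(self):
        cat = make_catalog(10)
        cands = anchors_to_candidates([(i, i) for i in range(1, 7)])
        blocks = detect_collinear_blocks(cands, cat)
        assert len(blocks) == 1
        assert blocks[0].score == 6
        assert blocks[0].orientation == "same"

    def test_antidiagonal_one_block_inverted(self):
        cat = make_catalog(10)
        cands = anchors_to_candidates([(i, 7 - i) for i in range(1, 7)])
        blocks = detect_collinear_blocks(cands, cat)
        assert len(blocks) == 1
        assert blocks[0].score == 6
        assert blocks[0].orientation == "inverted"

    def test_gap_bound_splits_chain(self):
        cat = make_catalog(100)
        cands = anchors_to_candidates(
            [(i, i) for i in range(1, 6)] + [(i, i) for i in range(50, 55)]
        )
        blocks = detect_collinear_blocks(cands, cat, min_block_anchors=5, max_rank_gap=25)
        assert sorted(b.score for b in blocks) == [5, 5]

    def test_planted_chain_in_noise_recovered_exactly(self):
        rng = np.random.default_rng(42)
        planted = []
        r1, r2 = 5, 8
        for _ in range(8):
            planted.append((r1, r2))
            r1 += int(rng.integers(1, 4))
            r2 += int(rng.integers(1, 4))
        noise, used1, used2 = [], {r for r, _ in planted}, {r for _, r in planted}
        while len(noise) < 30:
            a, b = int(rng.integers(1, 90)), int(rng.integers(1, 90))
            if a in used1 or b in used2:
                continue
            used1.add(a)
            used2.add(b)
            # keep noise anchors isolated so only the planted chain survives
            if any(abs(a - x) <= 3 and abs(b - y) <= 3 for x, y in noise + planted):
                continue
            noise.append((a, b))
        cat = make_catalog(100)
        blocks = detect_collinear_blocks(
            anchors_to_candidates(planted + noise), cat,
            min_block_anchors=5, max_rank_gap=3,
        )
        assert len(blocks) == 1
        got = {(int(a.split("_")[1]), int(b.split("_")[1]))
               for a, b in blocks[0].anchors}
        assert got == set(planted)

    @pytest.mark.parametrize("seed", range(12))
    def test_best_chain_length_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        anchors = set()
        while len(anchors) < n:
            anchors.add((int(rng.integers(1, 30)), int(rng.integers(1, 30))))
        anchors = sorted(anchors)
        # ranks on chr1 must be unique for a chain (strict monotonicity);
        # the oracle enumerates subsets so duplicates are handled the same way
        cat = make_catalog(30)
        max_gap = 6
        blocks = detect_collinear_blocks(
            anchors_to_candidates(anchors), cat,
            min_block_anchors=1, max_rank_gap=max_gap,
        )
        best_impl = max((b.score for b in blocks), default=0)
        best_oracle = longest_chain_brute(anchors, max_gap)
        assert best_impl == best_oracle


class TestClassification:
    def make_setup(self):
        cat = make_catalog(40)
        # one clean cross-chromosome block
        block_anchors = [(i, i + 3) for i in range(1, 7)]
        cands = anchors_to_candidates(block_anchors)
        extra = pd.DataFrame([
            {"gene_a": "g1_20", "gene_b": "g1_21"},   # tandem
            {"gene_a": "g1_25", "gene_b": "g1_30"},   # proximal (gap 5)
            {"gene_a": "g1_8", "gene_b": "g1_19"},    # gap 11 -> transposed
            {"gene_a": "g1_35", "gene_b": "g2_35"},   # cross-chrom singleton
        ])
        cands = pd.concat([cands, extra], ignore_index=True)
        blocks = detect_collinear_blocks(cands, cat)
        return cat, cands, blocks

    def test_rule_table(self):
        cat, cands, blocks = self.make_setup()
        out = classify_duplicates(cands, blocks, cat)
        by_pair = {(a, b): c for a, b, c in
                   zip(out["gene_a"], out["gene_b"], out["category"])}
        assert by_pair[("g1_1", "g2_4")] == "WGD"
        assert by_pair[("g1_20", "g1_21")] == "tandem"
        assert by_pair[("g1_25", "g1_30")] == "proximal"
        assert by_pair[("g1_8", "g1_19")] == "transposed"  # gap > proximal_max_gap
        assert by_pair[("g1_35", "g2_35")] == "transposed"

    def test_block_anchor_precedence_over_tandem(self):
        """A rank-adjacent pair that is also a block anchor stays WGD."""
        cat = make_catalog(20)
        anchors = [(i, i) for i in range(1, 7)]
        cands = anchors_to_candidates(anchors)
        blocks = detect_collinear_blocks(cands, cat)
        out = classify_duplicates(cands, blocks, cat)
        assert (out["category"] == "WGD").all()

    def test_every_pair_gets_exactly_one_category(self):
        cat, cands, blocks = self.make_setup()
        out = classify_duplicates(cands, blocks, cat)
        assert len(out) == len(cands)
        assert out["category"].isin(["WGD", "tandem", "proximal", "transposed"]).all()

    def test_classification_symmetric_in_gene_order(self):
        cat, cands, blocks = self.make_setup()
        flipped = cands.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        a = classify_duplicates(cands, blocks, cat)
        b = classify_duplicates(flipped, blocks, cat)
        key_a = {frozenset((r.gene_a, r.gene_b)): r.category for r in a.itertuples()}
        key_b = {frozenset((r.gene_a, r.gene_b)): r.category for r in b.itertuples()}
        assert key_a == key_b

    def test_missing_gene_raises(self):
        cat = make_catalog(5)
        cands = pd.DataFrame([{"gene_a": "g1_1", "gene_b": "nope"}])
        with pytest.raises(ValueError, match="absent"):
            classify_duplicates(cands, [], cat)


class TestRecoveryOnSyntheticStudy:
    def test_all_planted_categories_recovered(self, study):
        catalog, truth, hits = study["catalog"], study["truth"], study["hits"]
        cands = filter_candidates(hits, catalog)
        blocks = detect_collinear_blocks(cands, catalog)
        out = classify_duplicates(cands, blocks, catalog)
        got = {(a, b): c for a, b, c in
               zip(out["gene_a"], out["gene_b"], out["category"])}
        for r in truth.pairs.itertuples():
            assert got.get((r.gene_a, r.gene_b)) == r.category
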