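"""Body-level aggregation, site/gene-level binomial calls, the pair
context-class partition, Fisher differential methylation, and the
between-copy divergence metric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupmeth.catalog import GeneCatalog
from dupmeth.methylation import (
    BackgroundRates,
    annotate_sites,
    bcgm_divergence,
    call_methylated_sites,
    classify_body_methylation,
    compute_background,
    compute_body_levels,
    pair_bcgm_reduction,
    partition_pairs,
)
from dupmeth.methylation import test_differential_methylation as diff_meth_test

from oracles import binom_lower_tail, binom_upper_tail, fisher_2x2_brute


def one_gene_catalog(start=100, end=1000):
    df = pd.DataFrame([{
        "gene_id": "G1", "chrom": "chr1", "start": start, "end": end,
        "strand": "+", "rank": 1, "is_te": False,
    }]).set_index("gene_id")
    return GeneCatalog(df)


def calls(rows):
    """rows: (pos, meth, unmeth, context)"""
    return pd.DataFrame([
        {"chrom": "chr1", "pos": p, "strand": "+", "count_methylated": m,
         "count_unmethylated": u, "context": c, "trinucleotide": "CGA"}
        for p, m, u, c in rows
    ])


class TestBodyLevels:
    def test_single_site_level(self):
        cat = one_gene_catalog()
        prof = compute_body_levels(calls([(150, 10, 10, "CG")]), cat)
        assert prof.loc[("G1", "CG"), "body_level"] == pytest.approx(0.5)

    def test_low_coverage_site_excluded(self):
        cat = one_gene_catalog()
        prof = compute_body_levels(calls([(150, 2, 1, "CG")]), cat, min_reads=4)
        assert prof.empty

    def test_hand_sum_over_three_sites(self):
        cat = one_gene_catalog()
        prof = compute_body_levels(
            calls([(150, 8, 2, "CG"), (200, 0, 10, "CG"), (300, 5, 5, "CG")]), cat
        )
        row = prof.loc[("G1", "CG")]
        assert row["n_covered_sites"] == 3
        assert row["body_level"] == pytest.approx(13 / 30)

    def test_sites_outside_gene_body_ignored(self):
        cat = one_gene_catalog(start=100, end=1000)
        prof = compute_body_levels(calls([(50, 10, 0, "CG"), (1500, 10, 0, "CG")]), cat)
        assert prof.empty

    def test_aggregation_conserves_reads(self):
        cat = one_gene_catalog()
        rows = [(100 + i * 7, i % 5, (i * 3) % 7, "CG") for i in range(40)]
        df = calls(rows)
        prof = compute_body_levels(df, cat, min_reads=1)
        total = df["count_methylated"] + df["count_unmethylated"]
        kept = df[total >= 1]
        assert prof.loc[("G1", "CG"), "total_reads"] == (
            kept["count_methylated"] + kept["count_unmethylated"]).sum()

    def test_scale_invariance_of_level(self):
        cat = one_gene_catalog()
        base = calls([(150, 3, 5, "CG"), (200, 7, 1, "CG")])
        scaled = base.copy()
        scaled[["count_methylated", "count_unmethylated"]] *= 10
        l1 = compute_body_levels(base, cat).loc[("G1", "CG"), "body_level"]
        l2 = compute_body_levels(scaled, cat).loc[("G1", "CG"), "body_level"]
        assert l1 == pytest.approx(l2)


class TestSiteCalls:
    def test_zero_methylated_not_called(self):
        out = call_methylated_sites(calls([(1, 0, 20, "CG")]))
        assert not out["site_methylated"].iloc[0]

    def test_fully_methylated_called(self):
        out = call_methylated_sites(calls([(1, 20, 0, "CG")]))
        assert out["site_methylated"].iloc[0]

    def test_invalid_error_rate_rejected(self):
        with pytest.raises(ValueError):
            call_methylated_sites(calls([(1, 1, 1, "CG")]), error_rate=0.0)

    @pytest.mark.parametrize("k,n", [(2, 10), (1, 10), (3, 25), (0, 4)])
    def test_flag_matches_exact_tail_summation(self, k, n):
        out = call_methylated_sites(
            calls([(1, k, n - k, "CG")]), error_rate=0.005, alpha=0.01
        )
        expected = binom_upper_tail(k, n, 0.005) < 0.01
        assert bool(out["site_methylated"].iloc[0]) == expected


class TestBackground:
    def _flags(self, flags):
        df = calls([(100 + i, 1, 1, "CG") for i in range(len(flags))])
        df["gene_id"] = "G1"
        df["site_methylated"] = flags
        return df

    def test_all_methylated_rate_one(self):
        rates = compute_background(self._flags([True] * 5), one_gene_catalog())
        assert rates.rate("CG") == 1.0

    def test_arithmetic(self):
        rates = compute_background(
            self._flags([True] * 30 + [False] * 90), one_gene_catalog()
        )
        assert rates.rate("CG") == pytest.approx(0.25)
        assert rates.covered_sites["CG"] == 120

    def test_te_genes_excluded_and_empty_context_nan(self):
        df = self._flags([True] * 4)
        cat_te = GeneCatalog(pd.DataFrame([{
            "gene_id": "G1", "chrom": "chr1", "start": 100, "end": 1000,
            "strand": "+", "rank": 1, "is_te": True,
        }]).set_index("gene_id"))
        rates = compute_background(df, cat_te)
        assert np.isnan(rates.rate("CG"))


class TestBodyMethylationCall:
    def _status(self, k, n, p_bg, mode="not_lower", alpha=0.05):
        df = calls([(100 + i, 1, 1, "CG") for i in range(n)])
        df["gene_id"] = "G1"
        df["site_methylated"] = [True] * k + [False] * (n - k)
        rates = BackgroundRates({"CG": p_bg, "CHG": np.nan, "CHH": np.nan}, {})
        return classify_body_methylation(df, rates, alpha=alpha, mode=mode)

    def test_high_level_gene_is_body_methylated(self):
        # k=15 of n=20 at background 0.3: lower tail ~ 1
        out = self._status(15, 20, 0.3)
        assert bool(out.loc[("G1", "CG"), "body_methylated"])
        assert out.loc[("G1", "CG"), "p"] == pytest.approx(
            binom_lower_tail(15, 20, 0.3))

    def test_zero_methylated_gene_rejected(self):
        # closed form: lower tail at k=0 is 0.7^50 ~ 1.8e-8
        out = self._status(0, 50, 0.3)
        assert out.loc[("G1", "CG"), "p"] == pytest.approx(0.7 ** 50)
        assert not bool(out.loc[("G1", "CG"), "body_methylated"])

    def test_too_few_sites_gives_no_status(self):
        out = self._status(2, 4, 0.3)
        assert out.empty

    def test_enrichment_mode_flips_the_rule(self):
        out = self._status(15, 20, 0.3, mode="enriched")
        assert bool(out.loc[("G1", "CG"), "body_methylated"])
        assert out.loc[("G1", "CG"), "p"] == pytest.approx(
            binom_upper_tail(15, 20, 0.3))
        out = self._status(6, 20, 0.3, mode="enriched")
        assert not bool(out.loc[("G1", "CG"), "body_methylated"])


def status_frame(entries):
    """entries: {gene: (bcgm, bchgm, bchhm)}"""
    rows = []
    for gene, (cg, chg, chh) in entries.items():
        for ctx, flag in (("CG", cg), ("CHG", chg), ("CHH", chh)):
            rows.append({"gene_id": gene, "context": ctx, "n_sites": 10,
                         "n_methylated": 5, "p": 0.5, "q": 0.5,
                         "body_methylated": flag})
    return pd.DataFrame(rows).set_index(["gene_id", "context"])


class TestPartition:
    def pairs(self):
        return pd.DataFrame([{"pair_id": "P0", "gene_a": "A", "gene_b": "B",
                              "category": "WGD"}])

    def test_cg_only(self):
        st_ = status_frame({"A": (True, False, False), "B": (False, False, False)})
        out = partition_pairs(self.pairs(), st_)
        assert out["meth_class"].iloc[0] == "CG_only"

    def test_all_context(self):
        st_ = status_frame({"A": (True, True, False), "B": (False, False, False)})
        out = partition_pairs(self.pairs(), st_)
        assert out["meth_class"].iloc[0] == "all_context"

    def test_unmethylated(self):
        st_ = status_frame({"A": (False, False, False), "B": (False, True, False)})
        out = partition_pairs(self.pairs(), st_)
        assert out["meth_class"].iloc[0] == "unmethylated"

    def test_missing_copy_excluded(self):
        st_ = status_frame({"A": (True, False, False)})
        out = partition_pairs(self.pairs(), st_)
        assert out["meth_class"].iloc[0] == "excluded"


class TestDifferentialMethylation:
    def _profiles(self, m, u):
        idx = pd.MultiIndex.from_tuples([("G1", "CG")], names=["gene_id", "context"])
        return pd.DataFrame({
            "n_covered_sites": [10], "total_meth_reads": [m],
            "total_reads": [m + u],
            "body_level": [m / (m + u)],
        }, index=idx)

    def test_strong_loss_detected(self):
        out = diff_meth_test(
            self._profiles(50, 50), self._profiles(5, 95))
        assert out.loc["G1", "q"] < 0.05
        assert out.loc["G1", "direction"] == "loss"
        expected = fisher_2x2_brute(50, 50, 5, 95)
        assert out.loc["G1", "p"] == pytest.approx(expected, rel=1e-6)

    def test_identical_tables_p_one(self):
        out = diff_meth_test(
            self._profiles(30, 70), self._profiles(30, 70))
        assert out.loc["G1", "p"] == pytest.approx(1.0)
        assert out.loc["G1", "direction"] == "none"

    def test_pair_reduction_flag_requires_loss_in_one_copy(self):
        pairs = pd.DataFrame([
            {"pair_id": "P0", "gene_a": "A", "gene_b": "B"},
            {"pair_id": "P1", "gene_a": "C", "gene_b": "D"},
        ])
        dm = pd.DataFrame({
            "direction": ["loss", "none", "none", "gain"],
        }, index=["A", "B", "C", "D"])
        flags = pair_bcgm_reduction(pairs, dm)
        assert flags.tolist() == [True, False]


class TestDivergence:
    def _profiles(self, la, lb):
        idx = pd.MultiIndex.from_tuples(
            [("A", "CG"), ("B", "CG")], names=["gene_id", "context"])
        return pd.DataFrame({
            "n_covered_sites": [10, 10], "total_meth_reads": [1, 1],
            "total_reads": [10, 10], "body_level": [la, lb],
        }, index=idx)

    def pairs(self):
        return pd.DataFrame([{"pair_id": "P0", "gene_a": "A", "gene_b": "B"}])

    def test_equal_levels_zero(self):
        d = bcgm_divergence(self.pairs(), self._profiles(0.8, 0.8))
        assert d.iloc[0] == pytest.approx(0.0)

    def test_arithmetic(self):
        d = bcgm_divergence(self.pairs(), self._profiles(0.9, 0.2))
        assert d.iloc[0] == pytest.approx(0.7)

    def test_missing_level_gives_nan(self):
        prof = self._profiles(0.9, 0.2).drop(("B", "CG"))
        d = bcgm_divergence(self.pairs(), prof)
        assert np.isnan(d.iloc[0])

    @given(la=st.floats(0, 1), lb=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_bounded_zero_iff_equal(self, la, lb):
        p = self.pairs()
        d_ab = bcgm_divergence(p, self._profiles(la, lb)).iloc[0]
        d_ba = bcgm_divergence(p, self._profiles(lb, la)).iloc[0]
        assert d_ab == pytest.approx(d_ba)
        assert 0.0 <= d_ab <= 1.0
        assert (d_ab == 0.0) == (la == lb)


class TestAnnotateSites:
    def test_gene_assignment_and_outside_drop(self, study):
        ann = annotate_sites(study["cx_wt"].head(500), study["catalog"])
        g = study["catalog"].genes
        for r in ann.head(50).itertuples():
            row = g.loc[r.gene_id]
            assert row["start"] <= r.pos <= row["end"]
            assert row["chrom"] == r.chrom
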