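"""Allele-resolved Fisher tests, BH correction and concordance rules."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncexport import mutation as mut


def read_row(read_id, fraction, overlapped, carried):
    return {
        "read_id": read_id,
        "fraction": fraction,
        "gene_id": "g1",
        "overlapped_mutations": ",".join(overlapped),
        "carried_mutations": ",".join(carried),
    }


class TestCountAlleles:
    def test_multi_mutation_reads_discarded(self):
        reads = pd.DataFrame(
            [
                read_row("r1", "nuc", ["m1", "m2"], ["m1", "m2"]),
                read_row("r2", "nuc", ["m1"], ["m1"]),
            ]
        )
        counts, discarded = mut.count_alleles(reads)
        assert discarded == 1
        rec = counts.set_index("mutation_id").loc["m1"]
        assert rec["n_mut_nuc"] == 1 and rec["n_ref_nuc"] == 0

    def test_reference_read_increments_ref_cell(self):
        reads = pd.DataFrame([read_row("r1", "nuc", ["m1"], [])])
        counts, _ = mut.count_alleles(reads)
        assert counts.iloc[0]["n_ref_nuc"] == 1

    def test_cell_sums_conserve_retained_reads(self, rng):
        rows = []
        for i in range(300):
            carried = ["m1"] if rng.random() < 0.4 else []
            if rng.random() < 0.1:
                carried = ["m1", "m2"]
            rows.append(
                read_row(f"r{i}", "nuc" if rng.random() < 0.5 else "cyt", ["m1"], carried)
            )
        counts, discarded = mut.count_alleles(pd.DataFrame(rows))
        rec = counts.set_index("mutation_id").loc["m1"]
        total = rec[["n_mut_nuc", "n_ref_nuc", "n_mut_cyt", "n_ref_cyt"]].sum()
        assert total + discarded == 300


def exact_fisher_oracle(a, b, c, d):
    """Exhaustive enumeration with exact integer hypergeometric weights."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {
        k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)
    }
    total = sum(weights.values())
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs * (1 + 1e-7))
    return num / total


class TestFisher:
    def test_symmetric_table(self):
        odds, p = mut.fisher_exact_2x2(5, 5, 5, 5)
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_known_small_table(self):
        # all margins 4, N=8: p = 34/70 by full hypergeometric enumeration
        _, p = mut.fisher_exact_2x2(3, 1, 1, 3)
        assert p == pytest.approx(34 / 70)

    def test_zero_margin_untestable(self):
        odds, p = mut.fisher_exact_2x2(0, 5, 0, 5)
        assert odds is None and p == 1.0

    def test_against_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = mut.fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-9, abs=1e-12
            )

    def test_against_enumeration_oracle_small_n(self):
        for n in range(1, 16):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                    for a in range(lo, hi + 1):
                        b, c = r1 - a, c1 - a
                        d = n - r1 - c1 + a
                        if min(b, c, d) < 0 or r1 in (0, n) or c1 in (0, n):
                            continue
                        _, p = mut.fisher_exact_2x2(a, b, c, d)
                        assert p == pytest.approx(
                            exact_fisher_oracle(a, b, c, d), rel=1e-9
                        ), (a, b, c, d)


class TestBh:
    def test_step_up_closed_form(self):
        q = mut.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert mut.bh_adjust([0.123]) == pytest.approx([0.123])

    def test_bounds_and_monotonicity(self, rng):
        p = rng.uniform(size=100)
        q = mut.bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1_000):
            p = rng.uniform(size=rng.integers(1, 40))
            q_ref = multipletests(p, method="fdr_bh")[1]
            assert mut.bh_adjust(p) == pytest.approx(q_ref)


class TestExportShift:
    def counts(self, rows):
        return pd.DataFrame(
            [
                dict(
                    mutation_id=f"m{i}", gene_id="g", n_mut_nuc=a, n_ref_nuc=b,
                    n_mut_cyt=c, n_ref_cyt=d,
                )
                for i, (a, b, c, d) in enumerate(rows)
            ]
        )

    def test_cytoplasm_enriched_mutant_called_increased_export(self):
        res = mut.test_export_shift(self.counts([(100, 100, 400, 100)]))
        assert res.iloc[0]["export_call"] == "increased_export"
        assert res.iloc[0]["q_bh"] < 0.05

    def test_zero_mutant_reads_untestable(self):
        res = mut.test_export_shift(self.counts([(0, 100, 0, 100)]))
        assert not res.iloc[0]["testable"]
        assert res.iloc[0]["export_call"] == "none"

    def test_flipping_fractions_flips_calls(self):
        rows = [(100, 100, 400, 100), (300, 100, 100, 120)]
        res = mut.test_export_shift(self.counts(rows))
        flipped = mut.test_export_shift(
            self.counts([(c, d, a, b) for a, b, c, d in rows])
        )
        swap = {"increased_export": "decreased_export",
                "decreased_export": "increased_export", "none": "none"}
        assert list(flipped["export_call"]) == [swap[c] for c in res["export_call"]]

    def test_null_type_i_error_controlled(self, rng):
        """No injected effect: allele and fraction independent."""
        rows = []
        for _ in range(400):
            n = 600
            alleles = rng.random(n) < 0.5
            nuc = rng.random(n) < 0.4
            rows.append(
                (
                    int((alleles & nuc).sum()),
                    int((~alleles & nuc).sum()),
                    int((alleles & ~nuc).sum()),
                    int((~alleles & ~nuc).sum()),
                )
            )
        res = mut.test_export_shift(self.counts(rows))
        rate = (res["export_call"] != "none").mean()
        # 2-sigma binomial slack above the nominal 5% level
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 400)

    def test_power_at_fourfold_odds_and_2000_reads(self):
        """Injected nuclear-odds multiplier 4 at depth 2,000 is detected in
        at least 90% of replicate simulations."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 2_000
            alleles = rng.random(n) < 0.5
            p_nuc = np.where(alleles, 0.8, 0.5)  # odds 4 vs odds 1
            nuc = rng.random(n) < p_nuc
            res = mut.test_export_shift(
                self.counts(
                    [(
                        int((alleles & nuc).sum()),
                        int((~alleles & nuc).sum()),
                        int((alleles & ~nuc).sum()),
                        int((~alleles & ~nuc).sum()),
                    )]
                )
            )
            hits += res.iloc[0]["export_call"] == "decreased_export"
        assert hits / n_rep >= 0.9


class TestSpliceShift:
    def junction(self, mid, j_ref, r_ref, j_mut, r_mut):
        return [
            dict(mutation_id=mid, allele="ref", intron_length=500,
                 junction_reads=j_ref, retention_reads=r_ref),
            dict(mutation_id=mid, allele="mut", intron_length=500,
                 junction_reads=j_mut, retention_reads=r_mut),
        ]

    def test_ten_point_psi_drop_called(self):
        res = mut.test_splice_shift(pd.DataFrame(self.junction("m1", 900, 100, 800, 200)))
        row = res.iloc[0]
        assert row["delta_psi"] == pytest.approx(-0.10)
        assert row["splice_call"] == "decreased_splicing"

    def test_small_delta_never_called(self):
        # delta 0.02 <= 0.05 rule blocks the call at any depth
        res = mut.test_splice_shift(
            pd.DataFrame(self.junction("m1", 90_000, 10_000, 88_000, 12_000))
        )
        assert res.iloc[0]["splice_call"] == "none"

    def test_identical_counts_p_one(self):
        res = mut.test_splice_shift(pd.DataFrame(self.junction("m1", 500, 50, 500, 50)))
        assert res.iloc[0]["p_raw_splice"] == pytest.approx(1.0)
        assert res.iloc[0]["splice_call"] == "none"


class TestU1FilterAndConcordance:
    def test_top_half_kept(self):
        df = pd.DataFrame(
            {"mutation_id": [f"m{i}" for i in range(10)], "du1_score": np.arange(10) - 5}
        )
        kept = mut.filter_u1_effects(df)
        assert len(kept) == 5
        assert set(kept["mutation_id"]) == {"m0", "m1", "m9", "m8", "m2"}

    def test_ties_and_scaling(self):
        df = pd.DataFrame({"mutation_id": ["b", "a", "c", "d"], "du1_score": [1.0] * 4})
        kept = mut.filter_u1_effects(df)
        assert list(kept["mutation_id"]) == ["a", "b"]
        df2 = df.assign(du1_score=df["du1_score"] * 100)
        assert list(mut.filter_u1_effects(df2)["mutation_id"]) == ["a", "b"]

    def test_all_concordant_is_100(self):
        df = pd.DataFrame(
            {
                "splice_call": ["increased_splicing", "decreased_splicing"],
                "export_call": ["increased_export", "decreased_export"],
            }
        )
        assert mut.concordance_summary(df) == (2, 2, 100.0)

    def test_mixed_concordance_percent(self):
        df = pd.DataFrame(
            {
                "splice_call": ["increased_splicing"] * 3 + ["none"],
                "export_call": ["increased_export", "increased_export",
                                "decreased_export", "increased_export"],
            }
        )
        assert mut.concordance_summary(df) == (3, 2, 66.7)
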