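"""Catalogue filters, directed binning, Fisher exact, matched-gene null."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_cohort
from fampoly.cohort import MISSING
from fampoly.eqtl import (
    ContingencyTable,
    _null_gene_pool,
    allele_frequency_table,
    build_contingency,
    case_control_allele_freq,
    classify_records,
    empirical_enrichment_p,
    filter_blood,
    filter_muther,
    fisher_exact_two_sided,
    run_directed_enrichment,
)
from fampoly.simulate import (
    EqtlCatalogueSpec,
    simulate_case_control_shift,
    simulate_eqtl_catalogue,
)


def _records(rows):
    return pd.DataFrame(
        rows, columns=["snp", "gene", "effect_allele", "beta", "p", "tissue", "fdr"]
    )


class TestFilters:
    def test_muther_keeps_lower_p_tissue(self):
        recs = _records(
            [
                ("s1", "G", "A", 0.5, 0.01, "LCL", np.nan),
                ("s1", "G", "A", 0.4, 0.001, "skin", np.nan),
            ]
        )
        out = filter_muther(recs)
        assert len(out) == 1 and out["tissue"].iloc[0] == "skin"

    def test_muther_effect_size_floor(self):
        recs = _records([("s1", "G", "A", 0.005, 0.04, "LCL", np.nan)])
        assert filter_muther(recs).empty

    def test_muther_p_boundary_inclusive(self):
        recs = _records([("s1", "G", "A", 0.5, 0.05, "LCL", np.nan)])
        assert len(filter_muther(recs)) == 1  # strict "> 0.05" exclusion

    def test_muther_duplicate_entry_rejected(self):
        recs = _records(
            [
                ("s1", "G", "A", 0.5, 0.01, "LCL", np.nan),
                ("s1", "G", "A", 0.5, 0.02, "LCL", np.nan),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            filter_muther(recs)

    def test_blood_fdr_threshold(self):
        recs = _records(
            [
                ("s1", "G", "A", 0.5, 0.01, "blood", 0.49),
                ("s2", "G", "A", 0.5, 0.01, "blood", 0.51),
                ("s3", "G", "A", 0.001, 0.9, "blood", 0.1),
            ]
        )
        out = filter_blood(recs)
        assert set(out["snp"]) == {"s1", "s3"}  # no effect-size limit

    def test_blood_empty_input_empty_output(self):
        assert filter_blood(_records([])).empty

    def test_blood_requires_fdr_column(self):
        recs = _records([("s1", "G", "A", 0.5, 0.01, "blood", 0.1)]).drop(
            columns=["fdr"]
        )
        with pytest.raises(ValueError, match="fdr"):
            filter_blood(recs)


class TestAlleleFreq:
    def _cohort(self):
        rows = [
            ("C1", "C1", "0", "0", 1, 2),
            ("C2", "C2", "0", "0", 1, 2),
            ("K1", "K1", "0", "0", 1, 1),
            ("K2", "K2", "0", "0", 1, 1),
        ]
        g = np.array([[2], [1], [0], [MISSING]], dtype=np.int8)
        return make_cohort(rows, g)

    def test_counting(self):
        c = self._cohort()
        f_case, f_ctrl = case_control_allele_freq(c, "m0", "A")
        assert f_case == pytest.approx(3 / 4)  # cases AA, AG
        assert f_ctrl == 0.0  # one called control GG

    def test_all_missing_group_rejected(self):
        c = self._cohort()
        c.genotypes[2, 0] = MISSING
        with pytest.raises(ValueError, match="missing"):
            case_control_allele_freq(c, "m0", "A")

    def test_foreign_allele_rejected(self):
        with pytest.raises(ValueError, match="not one of"):
            case_control_allele_freq(self._cohort(), "m0", "T")

    def test_unknown_snp_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            case_control_allele_freq(self._cohort(), "nope", "A")


class TestContingency:
    def _setup(self, case_dosages, ctrl_dosages, recs_rows):
        n_markers = len(recs_rows)
        rows = [(f"C{i}", f"C{i}", "0", "0", 1, 2) for i in range(len(case_dosages))]
        rows += [(f"K{i}", f"K{i}", "0", "0", 1, 1) for i in range(len(ctrl_dosages))]
        g = np.array(
            [list(d) for d in case_dosages] + [list(d) for d in ctrl_dosages],
            dtype=np.int8,
        )
        markers = pd.DataFrame(
            {
                "snp": [f"m{j}" for j in range(n_markers)],
                "chrom": 1,
                "pos": (np.arange(n_markers) + 1) * 100,
                "a1": "A",
                "a2": "G",
            }
        )
        cohort = make_cohort(rows, g, markers=markers)
        recs = _records(recs_rows)
        return cohort, recs

    def test_up_regulating_case_enriched_fills_up_plus(self):
        cohort, recs = self._setup(
            case_dosages=[(2, 2, 2)],
            ctrl_dosages=[(0, 0, 0)],
            recs_rows=[
                ("m0", "G", "A", 0.5, 0.01, "blood", 0.1),
                ("m1", "G", "A", 0.5, 0.01, "blood", 0.1),
                ("m2", "G", "A", 0.5, 0.01, "blood", 0.1),
            ],
        )
        t = build_contingency("G", recs, allele_frequency_table(cohort))
        assert (t.up_plus, t.up_minus, t.down_plus, t.down_minus) == (3, 0, 0, 0)

    def test_equal_frequencies_bin_minus(self):
        cohort, recs = self._setup(
            case_dosages=[(1,)],
            ctrl_dosages=[(1,)],
            recs_rows=[("m0", "G", "A", 0.5, 0.01, "blood", 0.1)],
        )
        t = build_contingency("G", recs, allele_frequency_table(cohort))
        assert t.up_minus == 1 and t.up_plus == 0

    def test_empty_gene_table_and_fisher_p_one(self):
        cohort, recs = self._setup(
            case_dosages=[(1,)],
            ctrl_dosages=[(1,)],
            recs_rows=[("m0", "OTHER", "A", 0.5, 0.01, "blood", 0.1)],
        )
        t = build_contingency("G", recs, allele_frequency_table(cohort))
        assert t.total == 0
        assert fisher_exact_two_sided(t) == 1.0

    def test_beta_zero_excluded_with_warning(self):
        cohort, recs = self._setup(
            case_dosages=[(2,)],
            ctrl_dosages=[(0,)],
            recs_rows=[("m0", "G", "A", 0.0, 0.01, "blood", 0.1)],
        )
        with pytest.warns(UserWarning, match="beta=0"):
            t = build_contingency("G", recs, allele_frequency_table(cohort))
        assert t.total == 0

    def test_effect_allele_a2_uses_complementary_frequency(self):
        cohort, recs = self._setup(
            case_dosages=[(0,)],  # allele G (a2) at frequency 1 in cases
            ctrl_dosages=[(2,)],
            recs_rows=[("m0", "G", "G", 0.5, 0.01, "blood", 0.1)],
        )
        t = build_contingency("G", recs, allele_frequency_table(cohort))
        assert t.up_plus == 1


class TestFisherExact:
    @pytest.mark.parametrize(
        "cells, printed",
        [
            ((1, 17, 4, 0), 0.00068),
            ((0, 10, 4, 2), 0.0082),
            ((25, 1, 5, 10), 2.51e-05),
        ],
    )
    def test_reference_tables(self, cells, printed):
        p = fisher_exact_two_sided(cells)
        assert p == pytest.approx(printed, rel=0.05)

    def test_balanced_table_p_one(self):
        assert fisher_exact_two_sided((5, 5, 5, 5)) == 1.0

    def test_zero_row_degenerate(self):
        assert fisher_exact_two_sided((0, 0, 3, 7)) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided((-1, 2, 3, 4))

    @settings(max_examples=150, deadline=None)
    @given(st.tuples(*(st.integers(0, 25),) * 4))
    def test_matches_scipy(self, cells):
        a, b, c, d = cells
        expected = stats.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_exact_two_sided(cells) == pytest.approx(expected, rel=1e-9)

    def test_matches_bruteforce_enumeration(self):
        """Minimum-likelihood definition vs direct factorial enumeration."""

        def oracle(a, b, c, d):
            n, r1, c1 = a + b + c + d, a + b, a + c
            if r1 in (0, n) or c1 in (0, n):
                return 1.0

            def prob(x):
                return (
                    math.comb(r1, x)
                    * math.comb(n - r1, c1 - x)
                    / math.comb(n, c1)
                )

            p_obs = prob(a)
            total = 0.0
            for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                px = prob(x)
                if px <= p_obs * (1 + 1e-7):
                    total += px
            return min(total, 1.0)

        rng = np.random.default_rng(4)
        for _ in range(300):
            cells = tuple(int(x) for x in rng.integers(0, 12, 4))
            assert fisher_exact_two_sided(cells) == pytest.approx(
                oracle(*cells), abs=1e-12
            )


class TestEmpiricalNull:
    def test_escalation_rule(self):
        counts = pd.Series(
            {"g1": 3, "g2": 3, "g3": 4, "g4": 5, "g5": 5, "g6": 9}
        )
        rng = np.random.default_rng(0)
        pool = _null_gene_pool(counts, n=3, n_required=4, rng=rng)
        assert set(pool[:2]) == {"g1", "g2"}  # exact-count genes first
        assert pool[2] == "g3"  # then n+1
        assert pool[3] in {"g4", "g5"}  # then n+2, randomly chosen
        assert len(pool) == 4

    def test_insufficient_pool_uses_all_with_warning(self):
        cohort = simulate_case_control_shift(100, 100, 60, seed=1)
        cat = simulate_eqtl_catalogue(
            EqtlCatalogueSpec(
                n_genes=10, snps_per_gene=(4, 8), significant_fraction=1.0, seed=2
            ),
            cohort.markers,
        )
        filt = filter_blood(cat)
        gene = filt["gene"].iloc[0]
        with pytest.warns(UserWarning, match="matched null genes"):
            res = empirical_enrichment_p(
                gene, filt, set(), allele_frequency_table(cohort), n_null=500, seed=3
            )
        assert res.n_null < 500
        assert res.empirical_p >= 1 / (res.n_null + 1)

    def test_empirical_p_formula_floor_and_arithmetic(self):
        # target beats all nulls -> 1/(N+1); with r nulls at or below the
        # target, (r+1)/(N+1)
        assert (1 + 0) / (500 + 1) == pytest.approx(0.002, abs=2e-5)
        assert (1 + 6) / (500 + 1) == pytest.approx(0.014, abs=5e-4)

    def test_reproducible_given_seed(self):
        cohort = simulate_case_control_shift(200, 200, 200, seed=5)
        cat = simulate_eqtl_catalogue(
            EqtlCatalogueSpec(
                n_genes=120, snps_per_gene=(6, 14), significant_fraction=1.0, seed=6
            ),
            cohort.markers,
        )
        filt = filter_blood(cat)
        ft = allele_frequency_table(cohort)
        gene = filt["gene"].iloc[0]
        a = empirical_enrichment_p(gene, filt, set(), ft, n_null=100, seed=42)
        b = empirical_enrichment_p(gene, filt, set(), ft, n_null=100, seed=42)
        assert a.empirical_p == b.empirical_p
        assert a.table == b.table

    def test_de_genes_removed_from_null_pool_only(self):
        counts = pd.Series({"g1": 3, "g2": 3, "g3": 3})
        rng = np.random.default_rng(0)
        pool = _null_gene_pool(counts.drop("g2"), 3, 2, rng)
        assert "g2" not in pool

    def test_planted_directed_gene_detected(self):
        shifted = {i: 0.1 for i in range(25)}
        cohort = simulate_case_control_shift(
            400, 400, 400, shifted=shifted, seed=7
        )
        cat = simulate_eqtl_catalogue(
            EqtlCatalogueSpec(
                n_genes=250, snps_per_gene=(25, 40), significant_fraction=1.0,
                seed=8,
            ),
            cohort.markers,
            cohort=cohort,
            planted={"TARGET": "down_in_cases"},
        )
        filt = filter_blood(cat)
        out = run_directed_enrichment(
            ["TARGET"], filt, set(), cohort, n_null=200, seed=9
        )
        assert out["empirical_p"].iloc[0] <= 0.05


def test_cell_sum_equals_surviving_records(founders_cohort):
    cat = simulate_eqtl_catalogue(
        EqtlCatalogueSpec(n_genes=30, snps_per_gene=(5, 15), seed=11),
        founders_cohort.markers,
    )
    filt = filter_blood(cat)
    ft = allele_frequency_table(founders_cohort)
    for gene, grp in filt.groupby("gene"):
        t = build_contingency(gene, filt, ft)
        assert t.total == len(grp)
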