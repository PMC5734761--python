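"""DFAM stratified CMH test and EMMAX mixed-model scan."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_cohort
from fampoly.cohort import MISSING
from fampoly.association import (
    _family_structure,
    dfam_scan,
    dfam_test,
    emmax_fit_null,
    emmax_scan,
    kinship_matrix,
)
from fampoly.simulate import CohortSpec, simulate_cohort


def _tdt_cohort(n_trios, n_transmit_a1):
    """Trios with father het, mother hom a2; child dosage = received allele."""
    rows, genos = [], []
    for i in range(n_trios):
        rows += [
            (f"F{i}", f"d{i}", "0", "0", 1, 1),
            (f"F{i}", f"m{i}", "0", "0", 2, 1),
            (f"F{i}", f"k{i}", f"d{i}", f"m{i}", 1, 2),
        ]
        child = 1 if i < n_transmit_a1 else 0
        genos += [[1], [0], [child]]
    return make_cohort(rows, np.array(genos, dtype=np.int8))


class TestDfam:
    def test_tdt_closed_form(self):
        # 10 informative transmissions, 8 transmitting allele 1:
        # T = (8 - 5)^2 / 2.5 = 3.6, the McNemar chi-square (b-c)^2/(b+c)
        c = _tdt_cohort(10, 8)
        res = dfam_test(c, "m0")
        assert res["obs"] == 8 and res["exp"] == 5
        b, cc = 8, 2
        assert stats.chi2.sf((b - cc) ** 2 / (b + cc), 1) == pytest.approx(
            res["p"], rel=1e-12
        )
        assert res["p"] == pytest.approx(0.0578, abs=2e-4)

    def test_allele_relabel_symmetry(self, family_cohort):
        res = dfam_scan(family_cohort)
        flipped = family_cohort.copy()
        g = flipped.genotypes
        nm = g != MISSING
        g[nm] = 2 - g[nm]
        flipped.markers[["a1", "a2"]] = flipped.markers[["a2", "a1"]].to_numpy()
        res_f = dfam_scan(flipped)
        np.testing.assert_allclose(res["p"], res_f["p"], rtol=1e-9)
        np.testing.assert_allclose(
            res["obs"] - res["exp"], -(res_f["obs"] - res_f["exp"]), atol=1e-9
        )

    def test_concordant_affected_sibs_uninformative(self):
        # one family, two affected sibs with identical genotypes, no
        # unaffected sib, parents ungenotyped: no within-cluster contrast
        rows = [
            ("F1", "s1", "dad", "mum", 1, 2),
            ("F1", "s2", "dad", "mum", 1, 2),
        ]
        g = np.array([[1], [1]], dtype=np.int8)
        res = dfam_scan(make_cohort(rows, g))
        assert res["p"].iloc[0] == 1.0
        assert not res["informative"].iloc[0]

    def test_marker_order_does_not_affect_results(self, family_cohort):
        res = dfam_scan(family_cohort).set_index("snp")
        rev = family_cohort.subset(
            marker_ids=family_cohort.markers["snp"].tolist()[::-1]
        )
        res_rev = dfam_scan(rev).set_index("snp")
        np.testing.assert_allclose(
            res["p"], res_rev.loc[res.index, "p"], rtol=1e-12
        )

    def test_strata_match_exhaustive_permutation_oracle(self):
        """O, E, V agree with brute-force enumeration per stratum.

        TDT: enumerate all 2^h transmission patterns from het parents.
        Sibship / unrelateds: enumerate all draws of the affected allele
        slots from the cluster's pooled alleles.
        """
        rows = [
            # trio family, both parents genotyped, one affected child
            ("F1", "d1", "0", "0", 1, 1),
            ("F1", "m1", "0", "0", 2, 1),
            ("F1", "k1", "d1", "m1", 1, 2),
            # sibship family, parents ungenotyped
            ("F2", "s1", "pa", "ma", 1, 2),
            ("F2", "s2", "pa", "ma", 2, 1),
            ("F2", "s3", "pa", "ma", 1, 1),
            # unrelated singletons
            ("U1", "u1", "0", "0", 1, 2),
            ("U2", "u2", "0", "0", 1, 1),
            ("U3", "u3", "0", "0", 2, 2),
            ("U4", "u4", "0", "0", 2, 1),
        ]
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = rng.integers(0, 3, size=(10, 1)).astype(np.int8)
            cohort = make_cohort(rows, g)
            res = dfam_scan(cohort).iloc[0]

            o_tot = e_tot = v_tot = 0.0
            # TDT stratum oracle
            f, m, c = int(g[0, 0]), int(g[1, 0]), int(g[2, 0])
            het = [p for p in (f, m) if p == 1]
            forced = sum(1 for p in (f, m) if p == 2)
            if het:
                h = len(het)
                o = min(max(c - forced, 0), h)
                trans = [
                    sum(pat) for pat in itertools.product((0, 1), repeat=h)
                ]
                e = np.mean(trans)
                v = np.var(trans)
                o_tot += o
                e_tot += e
                v_tot += v
            # sibship stratum oracle: alleles of genotyped sibs, affected
            # sib draws 2 allele slots; enumerate combinations
            sib_dos = [int(g[i, 0]) for i in (3, 4, 5)]
            alleles = [a for d in sib_dos for a in (1,) * d + (0,) * (2 - d)]
            n_aff_alleles = 2  # one affected genotyped sib
            if 0 < sum(alleles) < len(alleles):
                draws = [
                    sum(comb)
                    for comb in itertools.combinations(alleles, n_aff_alleles)
                ]
                o_tot += sib_dos[0]
                e_tot += np.mean(draws)
                v_tot += np.var(draws)
            # unrelated stratum oracle
            u_dos = [int(g[i, 0]) for i in (6, 7, 8, 9)]
            u_aff = [1, 0, 1, 0]
            alleles = [a for d in u_dos for a in (1,) * d + (0,) * (2 - d)]
            if 0 < sum(alleles) < len(alleles):
                n_case_alleles = 4
                draws = [
                    sum(comb)
                    for comb in itertools.combinations(alleles, n_case_alleles)
                ]
                o_tot += sum(d for d, a in zip(u_dos, u_aff) if a)
                e_tot += np.mean(draws)
                v_tot += np.var(draws)

            assert res["obs"] == pytest.approx(o_tot, abs=1e-12)
            assert res["exp"] == pytest.approx(e_tot, abs=1e-12)
            if v_tot > 0:
                t_expect = (o_tot - e_tot) ** 2 / v_tot
                t_got = stats.chi2.isf(res["p"], 1) if res["p"] < 1 else 0.0
                assert t_got == pytest.approx(t_expect, abs=1e-8)

    def test_null_type_i_error_moderate(self):
        spec = CohortSpec(
            n_families=150, n_children=2, n_unrelated_cases=75,
            n_unrelated_controls=75, n_markers=800, ld_block_length=1,
            within_block_r=0.0, seed=0,
        )
        res = dfam_scan(simulate_cohort(spec))
        rate = (res["p"] < 0.05).mean()
        assert 0.03 < rate < 0.07


class TestKinship:
    def test_unrelated_off_diagonal_near_zero(self):
        spec = CohortSpec(
            n_families=0, n_children=0, n_unrelated_controls=120,
            n_unrelated_cases=0, n_markers=3000, baseline_prevalence=0.5, seed=13,
        )
        k, _ = kinship_matrix(simulate_cohort(spec))
        off = k[~np.eye(len(k), dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_parent_child_near_half(self):
        spec = CohortSpec(n_families=80, n_children=1, n_markers=3000, seed=14)
        c = simulate_cohort(spec)
        k, ids = kinship_matrix(c)
        idx = {iid: i for i, iid in enumerate(ids)}
        vals = [
            k[idx[f"F{i:05d}_P1"], idx[f"F{i:05d}_C1"]] for i in range(80)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_duplicate_sample_off_diagonal_equals_diagonal(self, founders_cohort):
        c = founders_cohort.copy()
        c.genotypes[1] = c.genotypes[0]
        k, _ = kinship_matrix(c)
        assert k[0, 1] == pytest.approx(k[0, 0], abs=1e-10)


class TestEmmax:
    def test_identity_kinship_reduces_to_ols(self, founders_cohort):
        import statsmodels.api as sm

        y = (founders_cohort.samples["phenotype"].to_numpy() == 2).astype(float)
        null = emmax_fit_null(y, np.eye(founders_cohort.n_samples))
        res = emmax_scan(founders_cohort, null)
        codings = {"ADD": [0, 1, 2], "DOM": [0, 1, 1], "REC": [0, 0, 1]}
        rng = np.random.default_rng(2)
        for j in rng.choice(founders_cohort.n_markers, 12, replace=False):
            best_p, best_beta = np.inf, None
            for coding in codings.values():
                x = np.array(coding, float)[founders_cohort.genotypes[:, j]]
                if x.std() == 0:
                    continue
                fit = sm.OLS(y, sm.add_constant(x)).fit()
                if fit.pvalues[1] < best_p:
                    best_p, best_beta = fit.pvalues[1], fit.params[1]
            assert res["p"].iloc[j] == pytest.approx(best_p, abs=1e-9)
            assert res["beta"].iloc[j] == pytest.approx(best_beta, rel=1e-6)

    def test_heritability_recovery(self):
        ests = []
        for seed in range(10):
            spec = CohortSpec(
                n_families=0, n_children=0, n_unrelated_controls=300,
                n_unrelated_cases=0, n_markers=600, baseline_prevalence=0.5,
                seed=60 + seed,
            )
            c = simulate_cohort(spec)
            k, _ = kinship_matrix(c)
            lam, u = np.linalg.eigh(k)
            lam = np.maximum(lam, 0)
            rng = np.random.default_rng(seed)
            gen = u @ (rng.normal(size=len(lam)) * np.sqrt(lam * 0.5))
            y = gen + rng.normal(size=len(lam)) * np.sqrt(0.5)
            ests.append(emmax_fit_null(y, k).heritability)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.15)

    def test_constant_phenotype_rejected(self, founders_cohort):
        with pytest.raises(ValueError, match="constant"):
            emmax_fit_null(
                np.ones(founders_cohort.n_samples),
                np.eye(founders_cohort.n_samples),
            )

    def test_recessive_untestable_without_homozygotes(self):
        # marker with only dosages 0/1: recessive coding is constant
        rng = np.random.default_rng(5)
        g = rng.integers(0, 2, size=(60, 3)).astype(np.int8)
        rows = [(f"U{i}", f"U{i}", "0", "0", 1, 1 + (i % 2)) for i in range(60)]
        c = make_cohort(rows, g)
        y = (c.samples["phenotype"].to_numpy() == 2).astype(float)
        null = emmax_fit_null(y, np.eye(60))
        res = emmax_scan(c, null)
        assert set(res["model"]) <= {"ADD", "DOM"}

    def test_planted_additive_locus_wins_add_label(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = CohortSpec(
                n_families=0, n_children=0, n_unrelated_cases=150,
                n_unrelated_controls=150, n_markers=60, maf_range=(0.3, 0.3),
                risk_loci=[(30, 2.2, "additive")], seed=80 + seed,
            )
            c = simulate_cohort(spec)
            y = (c.samples["phenotype"].to_numpy() == 2).astype(float)
            null = emmax_fit_null(y, np.eye(c.n_samples))
            res = emmax_scan(c, null)
            wins += res["model"].iloc[30] == "ADD"
        assert wins >= 0.8 * n_seeds
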