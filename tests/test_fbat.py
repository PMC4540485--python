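"""Conditional score test: codings, transmission distributions, sibship
conditioning, invariances, interaction and haplotype variants."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import famassoc as fa
from famassoc.fbat import (GenotypeCoding, MendelianError, code_genotype,
                           offspring_distribution, sibship_distribution)
from tests.conftest import make_cohort


def enumeration_oracle(cf, cm, code):
    """Brute-force the 4 equiprobable transmissions of parental alleles."""
    def alleles(c):
        return [(0, 0), (0, 1), (1, 1)][c]
    vals = [code[ta + tm] for ta in alleles(cf) for tm in alleles(cm)]
    return np.mean(vals), np.var(vals)


class TestCoding:
    @pytest.mark.parametrize("geno,model,expect", [
        (("A", "G"), "additive", 1.0),
        (("A", "G"), "recessive", 0.0),
        (("A", "A"), "dominant", 1.0),
        (("G", "G"), "additive", 0.0),
        (("A", "A"), "recessive", 1.0),
    ])
    def test_codes(self, geno, model, expect):
        coding = GenotypeCoding(model, "A")
        assert code_genotype(geno, coding) == expect

    def test_missing_is_nan(self):
        assert math.isnan(code_genotype(None, GenotypeCoding("additive", "A")))


class TestOffspringDistribution:
    def test_double_homozygote_uninformative(self):
        d = offspring_distribution(2, 2, GenotypeCoding("additive", "A"))
        assert d.variance == 0.0 and d.mean == 2.0

    def test_het_by_het_additive(self):
        d = offspring_distribution(1, 1, GenotypeCoding("additive", "A"))
        assert d.mean == pytest.approx(1.0)
        assert d.variance == pytest.approx(0.5)
        assert dict(zip(d.support, d.probabilities)) == pytest.approx(
            {0.0: 0.25, 1.0: 0.5, 2.0: 0.25})

    def test_hom_by_het_additive(self):
        d = offspring_distribution(2, 1, GenotypeCoding("additive", "A"))
        assert d.mean == pytest.approx(1.5)
        assert d.variance == pytest.approx(0.25)

    @pytest.mark.parametrize("model", ["additive", "dominant", "recessive"])
    def test_all_nine_mating_types_match_enumeration(self, model):
        from famassoc.fbat import CODE_MAP
        code = CODE_MAP[model]
        for cf in range(3):
            for cm in range(3):
                d = offspring_distribution(cf, cm, GenotypeCoding(model, "A"))
                mean, var = enumeration_oracle(cf, cm, code)
                assert d.mean == pytest.approx(mean, abs=1e-12)
                assert d.variance == pytest.approx(var, abs=1e-12)
                assert d.probabilities.sum() == pytest.approx(1.0)


class TestSibshipDistribution:
    @pytest.mark.parametrize("codes,mean,var", [
        ([1, 1], 1.0, 0.0),
        ([0, 2], 1.0, 1.0),
        ([0, 1, 2], 1.0, 2 / 3),
    ])
    def test_permutation_moments(self, codes, mean, var):
        m, v = sibship_distribution(codes)
        assert m == pytest.approx(mean)
        assert v == pytest.approx(var)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            sibship_distribution([1])


class TestFbatTest:
    def test_hand_worked_single_family(self):
        # parents Aa x Aa, one child AA with residual 2:
        # U = 2*(2-1) = 2, V = 4*0.5 = 2, z = sqrt(2)
        snp = fa.SnpDef("rs1", "G", "A")
        inds = [
            fa.Individual("d", "F1", sex="male", genotypes=[("A", "G")]),
            fa.Individual("m", "F1", sex="female", genotypes=[("A", "G")]),
            fa.Individual("k", "F1", "d", "m", "male", [("A", "A")]),
        ]
        cohort = fa.FamilyCohort([snp], inds)
        res = fa.fbat_test(cohort, "rs1", pd.Series({"k": 2.0}))
        assert res.U == pytest.approx(2.0)
        assert res.V == pytest.approx(2.0)
        assert res.z == pytest.approx(math.sqrt(2.0))
        assert res.p == pytest.approx(2 * stats.norm.sf(math.sqrt(2.0)))
        assert res.n_informative_families == 1

    def test_zero_residuals_untestable(self, toy_trio_cohort):
        res = fa.fbat_test(toy_trio_cohort, "rs1",
                           pd.Series({"kid1": 0.0, "kid2": 0.0}))
        assert res.U == 0.0
        assert res.status == "untestable" or res.p == pytest.approx(1.0)

    def test_scale_invariance_of_z(self, small_cohort, sspg_spec):
        resid, _ = fa.residualize(small_cohort, sspg_spec)
        r1 = fa.fbat_test(small_cohort, "rs8191973", resid)
        r2 = fa.fbat_test(small_cohort, "rs8191973", resid * 3.7)
        assert r2.U == pytest.approx(3.7 * r1.U)
        assert r2.V == pytest.approx(3.7**2 * r1.V)
        assert r2.z == pytest.approx(r1.z, abs=1e-12)

    def test_mendelian_inconsistency_detected(self):
        snp = fa.SnpDef("rs1", "G", "A")
        inds = [
            fa.Individual("d", "F1", sex="male", genotypes=[("G", "G")]),
            fa.Individual("m", "F1", sex="female", genotypes=[("G", "G")]),
            fa.Individual("k", "F1", "d", "m", "male", [("A", "G")],
                          {"y": 1.0}),
        ]
        cohort = fa.FamilyCohort([snp], inds)
        with pytest.raises(MendelianError, match="F1"):
            fa.fbat_test(cohort, "rs1", pd.Series({"k": 1.0}))

    def test_parents_required_drops_parentless_sibships(self, small_cohort,
                                                        sspg_spec):
        resid, _ = fa.residualize(small_cohort, sspg_spec)
        res = fa.fbat_test(small_cohort, "rs8191973", resid,
                           parent_policy="parents_required")
        # default generator masks all parents -> nothing testable
        assert res.status == "untestable"
        assert res.n_informative_families == 0

    def test_power_increases_with_effect_size(self):
        zs = []
        for beta in (0.0, 15.0, 40.0):
            z_abs = []
            for s in range(8):
                cohort = make_cohort(n_families=150, seed=900 + s,
                                     beta_g=beta)
                spec = fa.TraitSpec("sspg", "continuous", "none",
                                    ("age", "bmi"))
                res = fa.fbat_test(cohort, "rs8191973", spec)
                z_abs.append(abs(res.z))
            zs.append(np.mean(z_abs))
        assert zs[0] < zs[1] < zs[2]


class TestConditionalTest:
    def test_condition_on_self_rejected(self, small_cohort, sspg_spec):
        with pytest.raises(ValueError, match="itself"):
            fa.conditional_fbat_test(small_cohort, "rs8191973", sspg_spec,
                                     "rs8191973")

    def test_conditioning_attenuates_correlated_signal(self):
        # the causal SNP's LD partner loses signal once the causal SNP
        # is in the covariate set
        raw_z, cond_z = [], []
        for s in range(10):
            cohort = make_cohort(n_families=250, seed=700 + s, beta_g=18.0)
            spec = fa.TraitSpec("sspg", "continuous", "none", ("age", "bmi"))
            raw = fa.fbat_test(cohort, "rs7323932", spec)        # r2 ~ 0.21
            cond = fa.conditional_fbat_test(cohort, "rs7323932", spec,
                                            "rs8191973")
            raw_z.append(abs(raw.z))
            cond_z.append(abs(cond.z))
        assert np.mean(cond_z) < np.mean(raw_z)


class TestInteractionTest:
    def test_constant_environment_untestable(self, small_cohort, sspg_spec):
        small_cohort = small_cohort.copy()
        for ind in small_cohort.individuals.values():
            if ind.phenotypes:
                ind.phenotypes["always_on"] = 1.0
        res = fa.interaction_fbat_test(small_cohort, "rs8191973", sspg_spec,
                                       "always_on")
        assert res.status == "untestable"

    def test_null_interaction_calibrated(self):
        rej = 0
        n = 40
        for s in range(n):
            cohort = make_cohort(n_families=120, seed=1100 + s, beta_g=12.0)
            spec = fa.TraitSpec("sspg", "continuous", "none", ("age", "bmi"))
            res = fa.interaction_fbat_test(cohort, "rs8191973", spec,
                                           "sedentary")
            rej += res.p < 0.05
        # 3 binomial SE around 0.05 at n=40 -> at most ~6 rejections
        assert rej <= 7

    def test_opposite_sign_strata_detected(self):
        # sedentary effect ~ -24, non-sedentary ~ +22 per allele
        rej = 0
        n = 25
        for s in range(n):
            cohort = make_cohort(n_families=400, seed=1300 + s, beta_g=22.0,
                                 beta_ge=-46.0)
            spec = fa.TraitSpec("sspg", "continuous", "none",
                                ("age", "sex", "bmi", "site", "ethnicity"))
            res = fa.interaction_fbat_test(cohort, "rs8191973", spec,
                                           "sedentary")
            rej += res.p < 0.05
        assert rej / n > 0.5


class TestHaplotypeTest:
    def test_reduces_to_pseudo_snp_when_phase_known(self):
        # two biallelic SNPs, parents doubly homozygous -> phase certain
        snps = [fa.SnpDef("s1", "A", "G"), fa.SnpDef("s2", "C", "T")]
        table = fa.HaplotypeTable(snps, [("AC", 0.5), ("GT", 0.5)])
        inds, resid = [], {}
        rng = np.random.default_rng(0)
        for k in range(40):
            fid = f"F{k}"
            hap = ("G", "T") if k % 2 else ("A", "C")
            g = [(hap[0], hap[0]), (hap[1], hap[1])]
            inds += [
                fa.Individual(f"{fid}d", fid, sex="male", genotypes=list(g)),
                fa.Individual(f"{fid}m", fid, sex="female", genotypes=list(g)),
                fa.Individual(f"{fid}k", fid, f"{fid}d", f"{fid}m", "male",
                              list(g)),
            ]
            resid[f"{fid}k"] = float(rng.normal())
        cohort = fa.FamilyCohort(snps, inds)
        hap_res = fa.haplotype_fbat_test(cohort, table,
                                         pd.Series(resid, name="y"),
                                         target_haplotype="GT")
        # pseudo-SNP: count of the minor allele at either marker equals
        # the GT-haplotype dosage here
        snp_res = fa.fbat_test(cohort, "s2", pd.Series(resid, name="y"))
        assert hap_res.U == pytest.approx(snp_res.U, abs=1e-10)
        assert hap_res.V == pytest.approx(snp_res.V, abs=1e-10)

    def test_zero_frequency_target_untestable(self, small_cohort, gas6_table,
                                              sspg_spec):
        res = fa.haplotype_fbat_test(small_cohort, gas6_table, sspg_spec,
                                     target_haplotype="AATC")
        assert res.status == "untestable"

    def test_null_per_haplotype_pvalues_calibrated(self, gas6_table,
                                                   null_trait_models):
        rej = tot = 0
        for s in range(20):
            cfg = fa.SimConfig(n_families=100, seed=1500 + s,
                               trait_models=null_trait_models)
            cohort = fa.derive_phenotypes(fa.simulate_cohort(cfg))
            spec = fa.TraitSpec("sspg", "continuous", "none", ("age", "bmi"))
            results, omni = fa.haplotype_fbat_test(cohort, gas6_table, spec)
            for r in results:
                if r.status == "ok":
                    tot += 1
                    rej += r.p < 0.05
        assert tot > 150
        assert 0.01 <= rej / tot <= 0.09   # ~3 SE band around 0.05

    def test_embedded_haplotype_effect_found(self, gas6_table):
        # raise SSPG for carriers of the AACG-like haplotype: put the
        # effect on rs8191974's minor allele only when on the AACG
        # background -- approximated by an rs8191974 x rs8191973 joint
        # effect; the AACG haplotype should rank among the most
        # significant in most replicates
        wins = 0
        n = 12
        for s in range(n):
            tm = [fa.TraitModel("sspg", intercept=168.0, snp="rs8191974",
                                genetic_effect=25.0, family_sd=30.0,
                                residual_sd=60.0)]
            cfg = fa.SimConfig(n_families=250, seed=1700 + s, trait_models=tm)
            cohort = fa.derive_phenotypes(fa.simulate_cohort(cfg))
            spec = fa.TraitSpec("sspg", "continuous", "none", ("age", "bmi"))
            results, _ = fa.haplotype_fbat_test(cohort, gas6_table, spec)
            ok = [r for r in results if r.status == "ok"]
            best = min(ok, key=lambda r: r.p)
            # the A-carrying common haplotype is AACG (f=0.154)
            if best.snp_id.startswith("A"):
                wins += 1
        assert wins / n > 0.5
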