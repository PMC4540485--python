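import numpy as np
import pytest
from hypothesis import settings

import famassoc as fa

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gas6_table():
    return fa.gas6_haplotype_table()


@pytest.fixture(scope="session")
def null_trait_models():
    """Trait models with no genetic effect anywhere."""
    return [
        fa.TraitModel("sspg", intercept=168.0, family_sd=30.0, residual_sd=60.0),
        fa.TraitModel("fpi", intercept=1.788, family_sd=0.25, residual_sd=0.65,
                      log_scale=True),
        fa.TraitModel("fpg_mgdl", intercept=90.5, family_sd=4.0, residual_sd=10.0),
        fa.TraitModel("t2d_followup", intercept=-1.607, link="logit",
                      family_sd=0.3),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """120 default-model families, phenotypes derived."""
    cohort = fa.simulate_cohort(fa.SimConfig(n_families=120, seed=42))
    return fa.derive_phenotypes(cohort)


@pytest.fixture(scope="session")
def sspg_spec():
    return fa.TraitSpec("sspg", "continuous", "none",
                        ("age", "sex", "bmi", "site", "ethnicity"))


def make_cohort(n_families=150, seed=0, beta_g=0.0, beta_ge=0.0,
                family_sd=30.0, residual_sd=60.0, snp="rs8191973",
                parent_missing=1.0):
    """Cohort with a single SSPG model of configurable genetic effect."""
    tm = [fa.TraitModel(
        "sspg", intercept=60.7, snp=snp, genetic_effect=beta_g,
        covariate_effects={"age": 0.8, "bmi": 2.5},
        interaction_covariate="sedentary" if beta_ge else None,
        interaction_effect=beta_ge, family_sd=family_sd,
        residual_sd=residual_sd)]
    cfg = fa.SimConfig(n_families=n_families, seed=seed, trait_models=tm,
                       parent_genotype_missing_rate=parent_missing)
    return fa.derive_phenotypes(fa.simulate_cohort(cfg))


@pytest.fixture(scope="session")
def toy_trio_cohort():
    """One family: parents AA x Aa typed at one SNP, two children."""
    snp = fa.SnpDef("rs1", "A", "G")
    inds = [
        fa.Individual("dad", "F1", sex="male", genotypes=[("A", "A")]),
        fa.Individual("mum", "F1", sex="female", genotypes=[("A", "G")]),
        fa.Individual("kid1", "F1", "dad", "mum", "male", [("A", "G")],
                      {"y": 1.0}),
        fa.Individual("kid2", "F1", "dad", "mum", "female", [("A", "A")],
                      {"y": -1.0}),
    ]
    return fa.FamilyCohort([snp], inds)
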