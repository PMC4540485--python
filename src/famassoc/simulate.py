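"""Synthetic sib-pair family cohorts with realistic LD and trait structure.

The generator emulates a hypertension/insulin-resistance family cohort of
nuclear families (two parents plus a sibship of 2-3), typed at a 4-SNP
panel on a single gene.  Founder chromosomes are drawn from a reference
14-haplotype frequency table for the panel, so pairwise LD among the
simulated markers matches the frequencies' implied structure; offspring
receive one whole haplotype from each parent (no recombination across the
panel).  Covariates are drawn from the cohort's reported marginal
distributions, and quantitative traits follow an additive genetic model
with an optional gene-by-lifestyle interaction and a shared family random
effect.

The :func:`gene_drop` primitive is reused by the Monte-Carlo min-p null,
which regenerates genotypes on the fixed family structures while keeping
observed trait values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .cohort import FamilyCohort, Individual, SnpDef

# ---------------------------------------------------------------------
# default panel: four Gas6 (13q34) SNPs in haplotype coordinate order
# ---------------------------------------------------------------------

GAS6_SNPS = [
    SnpDef("rs8191974", "G", "A", region="intron 8"),
    SnpDef("rs7323932", "A", "G", region="intron"),
    SnpDef("rs7331124", "C", "T", region="intron"),
    SnpDef("rs8191973", "G", "C", region="3'UTR"),
]

#: 14 four-SNP haplotypes with population frequencies (sum = 1.0000)
GAS6_HAPLOTYPE_FREQS = [
    ("GACG", 0.4258),
    ("AACG", 0.1541),
    ("GGCG", 0.1109),
    ("GGCC", 0.1029),
    ("GATG", 0.0670),
    ("AGCG", 0.0502),
    ("GACC", 0.0185),
    ("GGTC", 0.0156),
    ("AGCC", 0.0127),
    ("AACC", 0.0120),
    ("GGTG", 0.0117),
    ("AGTG", 0.0076),
    ("AATG", 0.0075),
    ("GATC", 0.0035),
]


@dataclass
class HaplotypeTable:
    """Ordered SNP panel plus multi-SNP haplotype frequencies."""

    snps: list[SnpDef]
    haplotypes: list[tuple[str, float]]

    def __post_init__(self):
        total = sum(f for _, f in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        seen = set()
        for h, f in self.haplotypes:
            if len(h) != len(self.snps):
                raise ValueError(f"haplotype {h!r} length != panel size")
            if h in seen:
                raise ValueError(f"duplicate haplotype {h!r}")
            seen.add(h)
            if f < 0:
                raise ValueError(f"negative frequency for {h!r}")
            for a, snp in zip(h, self.snps):
                if a not in snp.alleles:
                    raise ValueError(f"haplotype {h!r}: allele {a!r} not in {snp.snp_id}")

    @property
    def labels(self) -> list[str]:
        return [h for h, _ in self.haplotypes]

    @property
    def freqs(self) -> np.ndarray:
        return np.array([f for _, f in self.haplotypes])

    def effect_count_matrix(self) -> np.ndarray:
        """(n_haplotypes, n_snps) indicator of the effect allele."""
        eff = [s.effect_allele for s in self.snps]
        return np.array(
            [[1 if h[j] == eff[j] else 0 for j in range(len(self.snps))]
             for h in self.labels], dtype=np.int8)

    def frequency_of(self, label: str) -> float:
        for h, f in self.haplotypes:
            if h == label:
                return f
        return 0.0


def gas6_haplotype_table() -> HaplotypeTable:
    return HaplotypeTable(list(GAS6_SNPS), list(GAS6_HAPLOTYPE_FREQS))


# ---------------------------------------------------------------------
# trait and cohort configuration
# ---------------------------------------------------------------------

@dataclass
class TraitModel:
    """Generating model for one trait.

    continuous:  y = b0 + bg*X + sum_c bc*c + bge*X*E + b_fam + eps
    binary (logit link): P(y=1) = expit(linear predictor); family effect
    enters the linear predictor.

    ``log_scale`` simulates the model on the natural-log scale and stores
    exp(y), producing a right-skewed trait (e.g. fasting insulin).
    """

    trait: str
    intercept: float = 0.0
    snp: str | None = None
    genetic_effect: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    interaction_covariate: str | None = None
    interaction_effect: float = 0.0
    family_sd: float = 0.0
    residual_sd: float = 1.0
    link: str = "identity"  # or "logit"
    log_scale: bool = False

    def __post_init__(self):
        if self.family_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.link not in ("identity", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "logit" and self.log_scale:
            raise ValueError("log_scale applies to identity-link traits only")


def default_trait_models() -> list[TraitModel]:
    """Trait models calibrated to the reference cohort's marginals.

    SSPG (mg/dl): mean ~168, SD ~69; a per-C-allele effect of the 3'UTR
    SNP plus age and BMI effects.  FPI is lognormal with mean ~7.6 and SD
    ~6.0.  FPG (mg/dl) ~ N(90.5, 10.8).  Incident T2D has baseline rate
    ~0.167.
    """
    return [
        TraitModel("sspg", intercept=60.7, snp="rs8191973", genetic_effect=12.0,
                   covariate_effects={"age": 0.8, "bmi": 2.5},
                   family_sd=30.0, residual_sd=60.0),
        TraitModel("fpi", intercept=1.788, family_sd=0.25, residual_sd=0.65,
                   log_scale=True),
        TraitModel("fpg_mgdl", intercept=90.5, family_sd=4.0, residual_sd=10.0),
        TraitModel("t2d_followup", intercept=-1.607, link="logit",
                   family_sd=0.3),
    ]


@dataclass
class SimConfig:
    """Cohort-level simulation settings (defaults mirror the reference
    cohort: ~440 sib-pair families, ~980 phenotyped siblings)."""

    n_families: int = 440
    sibs_per_family: dict[int, float] = field(
        default_factory=lambda: {2: 0.77, 3: 0.23})
    parent_genotype_missing_rate: float = 1.0
    age_mean: float = 49.5
    age_sd: float = 8.8
    bmi_mean: float = 25.5
    bmi_sd: float = 3.72
    male_fraction: float = 0.44
    sedentary_fraction: float = 0.667
    smoking_fraction: float = 0.173
    drinker_fraction: float = 0.287
    hypertension_fraction: float = 0.652
    site_weights: dict[str, float] = field(
        default_factory=lambda: {"stanford": 0.25, "hawaii": 0.25, "taiwan": 0.50})
    ethnicity_weights: dict[str, float] = field(
        default_factory=lambda: {"chinese": 0.779, "japanese": 0.221})
    sspg_observed_fraction: float = 1.0
    followup_fraction: float = 1.0
    haplotypes: HaplotypeTable = field(default_factory=gas6_haplotype_table)
    trait_models: list[TraitModel] = field(default_factory=default_trait_models)
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("parent_genotype_missing_rate", "male_fraction",
                     "sedentary_fraction", "smoking_fraction", "drinker_fraction",
                     "hypertension_fraction", "sspg_observed_fraction",
                     "followup_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = sum(self.sibs_per_family.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("sibs_per_family probabilities must sum to 1")


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def draw_founder_haplotypes(table: HaplotypeTable, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n founder haplotype *pairs* i.i.d. from the table.

    Returns an (n, 2) array of haplotype indices into ``table.labels``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(len(table.haplotypes), size=(n, 2), p=table.freqs)


def gene_drop(father_haps: np.ndarray, mother_haps: np.ndarray,
              n_offspring: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Mendelian transmission of whole haplotypes, no recombination.

    ``father_haps``/``mother_haps``: (n_couples, 2) haplotype indices.
    ``n_offspring``: per-couple sibship sizes.  Returns an
    (total_offspring, 2) array of (paternal, maternal) haplotype indices;
    each offspring picks one of the father's two and one of the mother's
    two haplotypes uniformly and independently.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_offspring = np.asarray(n_offspring)
    couple_of = np.repeat(np.arange(len(n_offspring)), n_offspring)
    pick_f = rng.integers(0, 2, size=len(couple_of))
    pick_m = rng.integers(0, 2, size=len(couple_of))
    pat = father_haps[couple_of, pick_f]
    mat = mother_haps[couple_of, pick_m]
    return np.column_stack([pat, mat])


def _sedentary_beta_b(fraction: float) -> float:
    """Shape b of Beta(2, b) for the inactivity score s so that
    P(s > 0.5) equals the target sedentary fraction."""
    if fraction <= 0.0:
        return 50.0
    if fraction >= 1.0:
        return 1e-3
    return optimize.brentq(
        lambda b: stats.beta(2, b).sf(0.5) - fraction, 1e-3, 50.0)


def simulate_traits(cohort: FamilyCohort, models: list[TraitModel],
                    seed: int | np.random.Generator) -> FamilyCohort:
    """Apply trait-generating models to phenotyped individuals in place.

    A trait value is generated for every individual that already carries a
    phenotype record (the generator phenotypes siblings only by default).
    Family random effects are shared within fid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = [ind for ind in cohort.individuals.values() if ind.phenotypes]
    if not target:
        target = list(cohort.individuals.values())
    fids = sorted({ind.fid for ind in target})
    fid_idx = {f: i for i, f in enumerate(fids)}

    for model in models:
        counts = cohort.effect_allele_counts(model.snp) if model.snp is not None else None
        fam_eff = rng.normal(0.0, model.family_sd, size=len(fids)) \
            if model.family_sd > 0 else np.zeros(len(fids))
        for ind in target:
            lin = model.intercept
            if counts is not None:
                x = counts[ind.iid]
                if math.isnan(x):
                    ind.phenotypes[model.trait] = math.nan
                    continue
                lin += model.genetic_effect * x
            for cov, beta in model.covariate_effects.items():
                if cov not in ind.phenotypes:
                    raise KeyError(
                        f"trait model {model.trait!r} references unknown "
                        f"covariate {cov!r}")
                lin += beta * float(ind.phenotypes[cov])
            if model.interaction_covariate is not None and counts is not None:
                e = float(ind.phenotypes[model.interaction_covariate])
                lin += model.interaction_effect * counts[ind.iid] * e
            lin += fam_eff[fid_idx[ind.fid]]
            if model.link == "logit":
                p = special.expit(lin)
                ind.phenotypes[model.trait] = float(rng.random() < p)
            else:
                y = lin + rng.normal(0.0, model.residual_sd)
                ind.phenotypes[model.trait] = math.exp(y) if model.log_scale else y
    return cohort


def simulate_cohort(config: SimConfig) -> FamilyCohort:
    """Generate a full nuclear-family cohort per the configuration."""
    rng = np.random.default_rng(config.seed)
    table = config.haplotypes
    nf = config.n_families

    sizes = np.array(sorted(config.sibs_per_family))
    probs = np.array([config.sibs_per_family[s] for s in sizes], dtype=float)
    sibs = rng.choice(sizes, size=nf, p=probs)

    father_haps = draw_founder_haplotypes(table, nf, rng)
    mother_haps = draw_founder_haplotypes(table, nf, rng)
    off_haps = gene_drop(father_haps, mother_haps, sibs, rng)

    labels = table.labels
    hap_allele = [[h[j] for h in labels] for j in range(len(table.snps))]

    def geno_from_haps(h1: int, h2: int) -> list[tuple[str, str]]:
        return [(hap_allele[j][h1], hap_allele[j][h2])
                for j in range(len(table.snps))]

    b_sed = _sedentary_beta_b(config.sedentary_fraction)
    site_names = sorted(config.site_weights)
    site_p = np.array([config.site_weights[s] for s in site_names], dtype=float)
    site_p = site_p / site_p.sum()
    eth_names = sorted(config.ethnicity_weights)
    eth_p = np.array([config.ethnicity_weights[e] for e in eth_names], dtype=float)
    eth_p = eth_p / eth_p.sum()

    individuals: list[Individual] = []
    k = 0
    for i in range(nf):
        fid = f"F{i + 1:04d}"
        parent_geno = [geno_from_haps(*father_haps[i]), geno_from_haps(*mother_haps[i])]
        mask = rng.random(2) < config.parent_genotype_missing_rate
        for p, (pid, sex) in enumerate([("P1", "male"), ("P2", "female")]):
            genos = [None] * len(table.snps) if mask[p] else parent_geno[p]
            individuals.append(Individual(
                iid=f"{fid}_{pid}", fid=fid, sex=sex, genotypes=genos))
        # family-level site/ethnicity (siblings share household origin)
        site = site_names[rng.choice(len(site_names), p=site_p)]
        eth = eth_names[rng.choice(len(eth_names), p=eth_p)]
        for s in range(sibs[i]):
            h1, h2 = off_haps[k]
            k += 1
            phen = {
                "age": float(rng.normal(config.age_mean, config.age_sd)),
                "bmi": float(rng.normal(config.bmi_mean, config.bmi_sd)),
                "sex": "male" if rng.random() < config.male_fraction else "female",
                "site": site,
                "ethnicity": eth,
                "smoking": float(rng.random() < config.smoking_fraction),
                "alcohol": float(rng.random() < config.drinker_fraction),
                "hypertension": float(rng.random() < config.hypertension_fraction),
            }
            s_score = float(rng.beta(2.0, b_sed))
            phen["hours_basal"] = 8.0
            phen["hours_sedentary"] = s_score * 16.0
            # lifestyle indicator available to gene-by-environment models
            phen["sedentary"] = float(s_score > 0.5)
            individuals.append(Individual(
                iid=f"{fid}_S{s + 1}", fid=fid,
                father_iid=f"{fid}_P1", mother_iid=f"{fid}_P2",
                sex=phen["sex"], genotypes=geno_from_haps(h1, h2),
                phenotypes=phen))

    cohort = FamilyCohort(table.snps, individuals)
    simulate_traits(cohort, config.trait_models, rng)

    # observation masks for the optional sub-studies
    for ind in cohort.individuals.values():
        if not ind.phenotypes:
            continue
        if rng.random() >= config.sspg_observed_fraction:
            ind.phenotypes["sspg"] = math.nan
        if rng.random() >= config.followup_fraction:
            ind.phenotypes["t2d_followup"] = math.nan
    return cohort
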