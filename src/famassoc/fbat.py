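"""Family-based association score tests conditional on parental genotypes.

The statistic compares each offspring's genotype code X with its Mendelian
expectation under the null of no association, conditioning on the parents:

    U = sum_families sum_offspring  T_ij * (X_ij - E[X_ij | conditioning])
    V = sum_families  T' Sigma_f T          z = U / sqrt(V)

where T are covariate-adjusted trait residuals and Sigma_f is the
conditional covariance of the offspring codes within family f.  When both
parents are genotyped the conditioning is the exact transmission
distribution (offspring independent given parents, so Sigma_f is
diagonal).  When no parent is genotyped, sibships of two or more condition
on the observed multiset of sib codes: under the null the codes are
exchangeable across sibs, giving the permutation mean, variance, and
negative between-sib covariance.  Families with exactly one genotyped
parent are excluded (and counted).

Because the conditioning is on parental genotypes (or their sufficient
statistic), the test is robust to population stratification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FamilyCohort, TraitSpec
from .phenotypes import residualize
from .popgen import enumerate_phase_pairs, phase_posteriors, _label_to_bits
from .simulate import HaplotypeTable

CODING_MODELS = ("additive", "dominant", "recessive")
PARENT_POLICIES = ("parents_required", "parents_or_sibship")

#: genotype-code map per model, indexed by effect-allele count 0/1/2
CODE_MAP = {
    "additive": np.array([0.0, 1.0, 2.0]),
    "dominant": np.array([0.0, 1.0, 1.0]),
    "recessive": np.array([0.0, 0.0, 1.0]),
}

#: _TRANS[cf, cm, c] = P(offspring effect-allele count = c | parent counts)
_TRANS = np.zeros((3, 3, 3))
for _cf in range(3):
    for _cm in range(3):
        pf = _cf / 2.0
        pm = _cm / 2.0
        for tf in (0, 1):
            for tm in (0, 1):
                pr = (pf if tf else 1 - pf) * (pm if tm else 1 - pm)
                _TRANS[_cf, _cm, tf + tm] += pr


def transmission_tables(model: str) -> tuple[np.ndarray, np.ndarray]:
    """(E, Var) lookup tables over the 9 parental mating types."""
    code = CODE_MAP[model]
    e = (_TRANS * code).sum(axis=2)
    e2 = (_TRANS * code**2).sum(axis=2)
    return e, e2 - e**2


class MendelianError(ValueError):
    """Offspring genotype impossible given the parental genotypes."""


@dataclass(frozen=True)
class GenotypeCoding:
    model: str
    effect_allele: str

    def __post_init__(self):
        if self.model not in CODING_MODELS:
            raise ValueError(f"unknown genotype model {self.model!r}")


def code_genotype(genotype: tuple[str, str] | None, coding: GenotypeCoding) -> float:
    """Numeric genotype code; missing genotype codes to NaN."""
    if genotype is None:
        return math.nan
    count = sum(a == coding.effect_allele for a in genotype)
    return float(CODE_MAP[coding.model][count])


@dataclass
class TransmissionDistribution:
    support: np.ndarray
    probabilities: np.ndarray
    mean: float
    variance: float


def offspring_distribution(father_count: int, mother_count: int,
                           coding: GenotypeCoding) -> TransmissionDistribution:
    """Exact Mendelian distribution of the offspring genotype code given
    parental effect-allele counts (0/1/2 each)."""
    probs3 = _TRANS[father_count, mother_count]
    code = CODE_MAP[coding.model]
    support = np.unique(code[probs3 > 0])
    p = np.array([probs3[code == v].sum() for v in support])
    mean = float((p * support).sum())
    var = float((p * support**2).sum() - mean**2)
    return TransmissionDistribution(support, p, mean, max(var, 0.0))


def sibship_distribution(codes) -> tuple[float, float]:
    """Per-sib conditional mean and variance under permutation of the
    observed code multiset among the sibs."""
    codes = np.asarray(codes, dtype=float)
    if len(codes) < 2:
        raise ValueError("sibship conditioning needs >= 2 genotyped sibs")
    mean = codes.mean()
    return float(mean), float((codes**2).mean() - mean**2)


# ---------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------

@dataclass
class AssociationResult:
    """One association test: score, variance, z, two-sided normal p."""

    snp_id: str
    trait: str
    model: str
    n_informative_families: int
    U: float
    V: float
    z: float
    p: float
    covariate_set: str = ""
    stratum: str | None = None
    status: str = "ok"
    family_counts: dict = field(default_factory=dict)
    df: int = 1
    chi2: float | None = None

    @property
    def testable(self) -> bool:
        return self.status == "ok"

    def summary(self) -> str:
        lines = [
            "Family-based association score test",
            f"  marker/haplotype : {self.snp_id}",
            f"  trait            : {self.trait}",
            f"  genotype model   : {self.model}",
            f"  covariates       : {self.covariate_set or '(pre-residualized)'}",
        ]
        if self.stratum:
            lines.append(f"  stratum          : {self.stratum}")
        lines += [
            f"  informative fams : {self.n_informative_families}",
            f"  score U          : {self.U:.4f}",
            f"  variance V       : {self.V:.4f}",
        ]
        if self.status == "ok":
            if self.chi2 is not None:
                lines.append(f"  chi2 (df={self.df})   : {self.chi2:.4f}")
            else:
                lines.append(f"  z                : {self.z:.4f}")
            lines.append(f"  p (two-sided)    : {self.p:.4g}")
        else:
            lines.append(f"  status           : {self.status}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "snp": self.snp_id, "trait": self.trait, "model": self.model,
            "n_informative": self.n_informative_families, "U": self.U,
            "V": self.V, "z": self.z, "p": self.p,
            "covariates": self.covariate_set, "stratum": self.stratum or "",
            "status": self.status,
        }


# ---------------------------------------------------------------------
# family preparation
# ---------------------------------------------------------------------

@dataclass
class _Family:
    mode: str                      # "parents" or "sibship"
    values: np.ndarray             # per-offspring weight (residual etc.)
    codes: np.ndarray              # per-offspring genotype codes
    e: float                       # conditional per-offspring mean
    var: float                     # conditional per-offspring variance


def _classify_families(cohort: FamilyCohort, snp_counts: pd.Series,
                       values: pd.Series, coding: GenotypeCoding,
                       parent_policy: str, fid_subset=None):
    """Group offspring into per-family conditioning blocks.

    Returns (families, counts) where counts tallies how each family was
    used or why it was dropped.
    """
    if parent_policy not in PARENT_POLICIES:
        raise ValueError(f"unknown parent policy {parent_policy!r}")
    e_tab, v_tab = transmission_tables(coding.model)
    code = CODE_MAP[coding.model]
    counts = {"parents": 0, "sibship": 0, "one_parent_dropped": 0,
              "no_data": 0}
    fams: list[_Family] = []
    fids = sorted(cohort.families) if fid_subset is None else fid_subset
    for fid in fids:
        members = cohort.families[fid]
        offspring = [cohort.individuals[i] for i in members
                     if not cohort.individuals[i].is_founder]
        usable = [(o, snp_counts[o.iid], values.get(o.iid, math.nan))
                  for o in offspring]
        usable = [(o, c, t) for o, c, t in usable
                  if not math.isnan(c) and not math.isnan(t)]
        if not usable:
            counts["no_data"] += 1
            continue
        # parental genotypes at this SNP (both parents of the sibship)
        fathers = {o.father_iid for o, _, _ in usable}
        mothers = {o.mother_iid for o, _, _ in usable}
        cf = cm = math.nan
        if len(fathers) == 1 and len(mothers) == 1:
            f_iid, m_iid = next(iter(fathers)), next(iter(mothers))
            if f_iid is not None:
                cf = snp_counts[f_iid]
            if m_iid is not None:
                cm = snp_counts[m_iid]
        have_f, have_m = not math.isnan(cf), not math.isnan(cm)
        xs = np.array([c for _, c, _ in usable])
        ts = np.array([t for _, _, t in usable])
        if have_f and have_m:
            icf, icm = int(cf), int(cm)
            if np.any(_TRANS[icf, icm][xs.astype(int)] <= 0):
                raise MendelianError(
                    f"family {fid}: offspring genotype impossible given parents")
            fams.append(_Family("parents", ts, code[xs.astype(int)],
                                float(e_tab[icf, icm]), float(v_tab[icf, icm])))
            counts["parents"] += 1
        elif parent_policy == "parents_required":
            counts["one_parent_dropped" if (have_f or have_m) else "no_data"] += 1
        elif have_f or have_m:
            counts["one_parent_dropped"] += 1
        elif len(usable) >= 2:
            coded = code[xs.astype(int)]
            mean, var = sibship_distribution(coded)
            fams.append(_Family("sibship", ts, coded, mean, var))
            counts["sibship"] += 1
        else:
            counts["no_data"] += 1
    return fams, counts


def _score(fams: list[_Family]) -> tuple[float, float, int]:
    """Accumulate (U, V, n_informative) over family blocks."""
    U = V = 0.0
    informative = 0
    for f in fams:
        if f.var <= 0:
            continue
        dev = f.codes - f.e
        u = float(f.values @ dev)
        if f.mode == "parents":
            v = f.var * float(f.values @ f.values)
        else:
            n = len(f.values)
            st, st2 = f.values.sum(), float(f.values @ f.values)
            v = f.var * (st2 - (st * st - st2) / (n - 1))
        if v > 0:
            U += u
            V += v
            informative += 1
    return U, V, informative


def _finalize(snp_id, trait, model, U, V, informative, covariate_set="",
              stratum=None, counts=None) -> AssociationResult:
    if V <= 0:
        return AssociationResult(snp_id, trait, model, informative, U, V,
                                 math.nan, math.nan, covariate_set, stratum,
                                 status="untestable",
                                 family_counts=counts or {})
    z = U / math.sqrt(V)
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationResult(snp_id, trait, model, informative, U, V, z, p,
                             covariate_set, stratum,
                             family_counts=counts or {})


# ---------------------------------------------------------------------
# model object and test functions
# ---------------------------------------------------------------------

class FbatModel:
    """Family-based score test of one marker against one trait.

    ``trait`` may be a pre-computed residual series (indexed by iid) or a
    :class:`TraitSpec`, in which case covariate residualization is run
    first.  ``fit()`` returns an :class:`AssociationResult`.
    """

    def __init__(self, cohort: FamilyCohort, snp: str,
                 trait: pd.Series | TraitSpec, model: str = "additive",
                 parent_policy: str = "parents_or_sibship",
                 effect_allele: str | None = None, stratum: str | None = None,
                 extra_covariates: pd.DataFrame | None = None):
        self.cohort = cohort
        self.snp = snp
        self.model = model
        self.parent_policy = parent_policy
        snpdef = cohort.snps[cohort.snp_index(snp)]
        self.coding = GenotypeCoding(model, effect_allele or snpdef.effect_allele)
        self.stratum = stratum
        if isinstance(trait, TraitSpec):
            self.trait_name = trait.name
            self.covariate_set = ",".join(trait.covariates)
            self.residuals, self.excluded = residualize(
                cohort, trait, extra_covariates=extra_covariates)
        else:
            self.trait_name = trait.name or "trait"
            self.covariate_set = ""
            self.residuals, self.excluded = trait.astype(float), []

    def fit(self) -> AssociationResult:
        counts = self.cohort.effect_allele_counts(self.snp)
        if self.coding.effect_allele != \
                self.cohort.snps[self.cohort.snp_index(self.snp)].effect_allele:
            # re-count against the requested allele
            j = self.cohort.snp_index(self.snp)
            counts = pd.Series({
                iid: (float(g[j].count(self.coding.effect_allele))
                      if (g := ind.genotypes) is not None and g[j] is not None
                      else math.nan)
                for iid, ind in self.cohort.individuals.items()})
        fams, tallies = _classify_families(
            self.cohort, counts, self.residuals, self.coding, self.parent_policy)
        U, V, informative = _score(fams)
        return _finalize(self.snp, self.trait_name, self.model, U, V,
                         informative, self.covariate_set, self.stratum, tallies)


def fbat_test(cohort: FamilyCohort, snp: str, trait: pd.Series | TraitSpec,
              model: str = "additive",
              parent_policy: str = "parents_or_sibship",
              **kwargs) -> AssociationResult:
    """Single-marker family-based score test (see :class:`FbatModel`)."""
    return FbatModel(cohort, snp, trait, model, parent_policy, **kwargs).fit()


def conditional_fbat_test(cohort: FamilyCohort, snp: str, trait: TraitSpec,
                          condition_snp: str, model: str = "additive",
                          parent_policy: str = "parents_or_sibship"
                          ) -> AssociationResult:
    """Score test with the trait additionally residualized on the additive
    code of a conditioning marker (e.g. the top SNP of the gene)."""
    if condition_snp == snp:
        raise ValueError("cannot condition a SNP on itself")
    cond = cohort.effect_allele_counts(condition_snp).rename(
        f"cond_{condition_snp}").to_frame()
    res = FbatModel(cohort, snp, trait, model, parent_policy,
                    extra_covariates=cond).fit()
    res.covariate_set += f"+{condition_snp}"
    return res


def interaction_fbat_test(cohort: FamilyCohort, snp: str, trait: TraitSpec,
                          lifestyle: str, model: str = "additive",
                          parent_policy: str = "parents_or_sibship"
                          ) -> AssociationResult:
    """Gene-by-environment interaction score test.

    The trait is residualized on the covariates, the binary lifestyle
    factor E, and the marker's main additive effect; the score then weights
    each offspring's genotype deviation by (E_ij - mean(E)) * residual:

        U_ge = sum (E_ij - Ebar) * r_ij * (X_ij - E[X | conditioning])

    An untestable result is returned when E does not vary.
    """
    pheno = cohort.phenotype_frame()
    if lifestyle not in pheno.columns:
        raise KeyError(f"unknown lifestyle factor {lifestyle!r}")
    evals = pheno[lifestyle].astype(float)
    snp_code = cohort.effect_allele_counts(snp)
    if evals.dropna().nunique() <= 1:
        return AssociationResult(f"{snp}x{lifestyle}", trait.name, model, 0,
                                 0.0, 0.0, math.nan, math.nan,
                                 ",".join(trait.covariates),
                                 status="untestable")
    extra = pd.DataFrame({
        f"main_{snp}": snp_code,
        f"env_{lifestyle}": evals,
    })
    resid, _ = residualize(cohort, trait, extra_covariates=extra)
    coding = GenotypeCoding(model,
                            cohort.snps[cohort.snp_index(snp)].effect_allele)
    included = resid.index[resid.index.isin(
        [iid for iid, ind in cohort.individuals.items()
         if not ind.is_founder and not math.isnan(snp_code[iid])])]
    e_inc = evals[included].dropna()
    ebar = e_inc.mean()
    weights = (evals - ebar) * resid
    weights = weights.dropna()
    fams, tallies = _classify_families(cohort, snp_code, weights, coding,
                                       parent_policy)
    U, V, informative = _score(fams)
    res = _finalize(f"{snp}x{lifestyle}", trait.name, model, U, V,
                    informative, ",".join(trait.covariates), None, tallies)
    return res


# ---------------------------------------------------------------------
# haplotype dosage tests
# ---------------------------------------------------------------------

class _DosageCache:
    """Posterior expected dosages of target haplotypes per genotype."""

    def __init__(self, table: HaplotypeTable, targets: list[str]):
        self.freq_of = {_label_to_bits(h, table.snps): f
                        for h, f in table.haplotypes}
        self.targets = [_label_to_bits(t, table.snps) for t in targets]
        self._d: dict[tuple, np.ndarray] = {}
        self._phase: dict[tuple, list] = {}

    def dosage(self, counts: tuple) -> np.ndarray:
        if counts not in self._d:
            post = self.phases(counts)
            d = np.zeros(len(self.targets))
            for h1, h2, w in post:
                for k, t in enumerate(self.targets):
                    d[k] += w * ((h1 == t) + (h2 == t))
            self._d[counts] = d
        return self._d[counts]

    def phases(self, counts: tuple) -> list:
        if counts not in self._phase:
            self._phase[counts] = phase_posteriors(counts, self.freq_of)
        return self._phase[counts]


def _parent_dosage_moments(cache: _DosageCache, cf: tuple, cm: tuple):
    """Offspring dosage-vector moments conditional on parental genotypes.

    Enumerates parental phase configurations weighted by posterior, then
    the four equiprobable transmissions.  Returns (mean, within-offspring
    covariance, between-sib covariance)."""
    K = len(cache.targets)
    mean = np.zeros(K)
    s1 = np.zeros((K, K))   # E[d d'] marginally
    s2 = np.zeros((K, K))   # E_phase[mu mu']
    for hf1, hf2, wf in cache.phases(cf):
        for hm1, hm2, wm in cache.phases(cm):
            w = wf * wm
            mu = np.zeros(K)
            m2 = np.zeros((K, K))
            for hf in (hf1, hf2):
                for hm in (hm1, hm2):
                    child = tuple(a + b for a, b in zip(hf, hm))
                    d = cache.dosage(child)
                    mu += 0.25 * d
                    m2 += 0.25 * np.outer(d, d)
            mean += w * mu
            s1 += w * m2
            s2 += w * np.outer(mu, mu)
    within = s1 - np.outer(mean, mean)
    between = s2 - np.outer(mean, mean)
    return mean, within, between


def haplotype_fbat_test(cohort: FamilyCohort, hap_table: HaplotypeTable,
                        trait: pd.Series | TraitSpec,
                        target_haplotype: str | None = None,
                        freq_threshold: float = 0.01,
                        parent_policy: str = "parents_or_sibship"):
    """Haplotype-dosage family score tests.

    Each individual's expected dosage of every candidate haplotype is the
    posterior expectation over phase configurations (haplotype-frequency
    prior).  Conditioning follows the single-marker machinery on the
    dosage scale.  Returns a single :class:`AssociationResult` when
    ``target_haplotype`` is given; otherwise a (per-haplotype results,
    omnibus result) pair where the omnibus combines all haplotypes with
    frequency >= ``freq_threshold`` in a chi-square score test.
    """
    if [s.snp_id for s in hap_table.snps] != cohort.snp_ids:
        raise ValueError("haplotype table SNP order does not match cohort panel")
    if target_haplotype is not None:
        if hap_table.frequency_of(target_haplotype) <= 0:
            return AssociationResult(target_haplotype,
                                     getattr(trait, "name", "trait"), "dosage",
                                     0, 0.0, 0.0, math.nan, math.nan,
                                     status="untestable")
        targets = [target_haplotype]
    else:
        targets = [h for h, f in hap_table.haplotypes if f > 0]

    if isinstance(trait, TraitSpec):
        resid, _ = residualize(cohort, trait)
        trait_name = trait.name
        covset = ",".join(trait.covariates)
    else:
        resid, trait_name, covset = trait.astype(float), trait.name or "trait", ""

    cache = _DosageCache(hap_table, targets)
    K = len(targets)
    U = np.zeros(K)
    V = np.zeros((K, K))
    informative = 0
    counts_mat = cohort.count_matrix()
    row_of = {iid: i for i, iid in enumerate(cohort.individuals)}

    def geno_tuple(iid):
        row = counts_mat[row_of[iid]]
        if (row < 0).any():
            return None
        return tuple(int(c) for c in row)

    for fid in sorted(cohort.families):
        offspring = [cohort.individuals[i] for i in cohort.families[fid]
                     if not cohort.individuals[i].is_founder]
        usable = []
        for o in offspring:
            g = geno_tuple(o.iid)
            t = resid.get(o.iid, math.nan)
            if g is not None and not math.isnan(t):
                usable.append((o, g, t))
        if not usable:
            continue
        fathers = {o.father_iid for o, _, _ in usable}
        mothers = {o.mother_iid for o, _, _ in usable}
        gf = gm = None
        if len(fathers) == 1 and len(mothers) == 1:
            fi, mi = next(iter(fathers)), next(iter(mothers))
            gf = geno_tuple(fi) if fi is not None else None
            gm = geno_tuple(mi) if mi is not None else None
        ts = np.array([t for _, _, t in usable])
        D = np.array([cache.dosage(g) for _, g, _ in usable])
        if gf is not None and gm is not None:
            mean, within, between = _parent_dosage_moments(cache, gf, gm)
            dev = D - mean
            u = ts @ dev
            st2 = float(ts @ ts)
            st = float(ts.sum())
            v = st2 * within + (st * st - st2) * between
        elif parent_policy == "parents_required" or gf is not None or gm is not None:
            continue
        elif len(usable) >= 2:
            mean = D.mean(axis=0)
            dev = D - mean
            sig = dev.T @ dev / len(usable)
            n = len(usable)
            st, st2 = float(ts.sum()), float(ts @ ts)
            cfac = st2 - (st * st - st2) / (n - 1)
            u = ts @ dev
            v = cfac * sig
        else:
            continue
        if np.trace(v) > 1e-12:
            U += u
            V += v
            informative += 1

    results = []
    for k, label in enumerate(targets):
        results.append(_finalize(label, trait_name, "dosage",
                                 float(U[k]), float(V[k, k]), informative,
                                 covset))
    if target_haplotype is not None:
        return results[0]

    # omnibus over common haplotypes
    common = [k for k, bits in enumerate(cache.targets)
              if cache.freq_of.get(bits, 0.0) >= freq_threshold]
    Uc = U[common]
    Vc = V[np.ix_(common, common)]
    rank = np.linalg.matrix_rank(Vc, tol=1e-10) if len(common) else 0
    if rank == 0:
        omni = AssociationResult("omnibus", trait_name, "dosage", informative,
                                 0.0, 0.0, math.nan, math.nan, covset,
                                 status="untestable")
    else:
        chi2 = float(Uc @ np.linalg.pinv(Vc, rcond=1e-10) @ Uc)
        p = float(stats.chi2.sf(chi2, df=rank))
        omni = AssociationResult("omnibus", trait_name, "dosage", informative,
                                 float(np.linalg.norm(Uc)), float(np.trace(Vc)),
                                 math.nan, p, covset, df=rank, chi2=chi2)
    return results, omni
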