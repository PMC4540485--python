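"""Resampling procedures: Monte-Carlo min-p multiple-testing adjustment,
family-bootstrap power, and the insulin-resistance case/control haplotype
odds ratio.

The min-p null preserves everything about the observed cohort except the
genotypes: family structures, the parental-genotype missingness mask, and
every trait and covariate value are kept, while founder chromosomes are
redrawn from the estimated haplotype table and dropped through the
pedigrees.  Because trait values are fixed, correlations among the traits
are preserved; because whole haplotypes are dropped, the LD among markers
is preserved.  Each replicate reruns the full test battery, and the
adjusted p-value for an observed p_i is the fraction of replicates whose
minimum p over the battery falls strictly below p_i.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FamilyCohort, TraitSpec
from .fbat import CODE_MAP, fbat_test, transmission_tables
from .phenotypes import build_design, log_transform, residualize
from .popgen import phase_posteriors, _label_to_bits
from .simulate import HaplotypeTable


# ---------------------------------------------------------------------
# structural view of a cohort for vectorized scoring
# ---------------------------------------------------------------------

class _Structure:
    """Index arrays describing families, couples, offspring, and the
    genotype missingness mask of a nuclear-family cohort."""

    def __init__(self, cohort: FamilyCohort):
        self.cohort = cohort
        iid_row = {iid: i for i, iid in enumerate(cohort.individuals)}
        counts = cohort.count_matrix()
        self.present = counts >= 0              # (n_ind, n_snps)
        self.counts = counts
        self.fids = sorted(cohort.families)
        self.n_snps = len(cohort.snps)

        self.father_row = np.full(len(self.fids), -1)
        self.mother_row = np.full(len(self.fids), -1)
        self.off_rows: list[np.ndarray] = []
        for fi, fid in enumerate(self.fids):
            offs = [cohort.individuals[i] for i in cohort.families[fid]
                    if not cohort.individuals[i].is_founder]
            rows = np.array([iid_row[o.iid] for o in offs], dtype=int)
            self.off_rows.append(rows)
            fathers = {o.father_iid for o in offs if o.father_iid}
            mothers = {o.mother_iid for o in offs if o.mother_iid}
            if len(fathers) == 1:
                self.father_row[fi] = iid_row[next(iter(fathers))]
            if len(mothers) == 1:
                self.mother_row[fi] = iid_row[next(iter(mothers))]
        self.off_iids = [
            [cohort.families[fid][j] for j in range(len(cohort.families[fid]))
             if not cohort.individuals[cohort.families[fid][j]].is_founder]
            for fid in self.fids]


@dataclass
class _Cell:
    """Per-(snp, trait) classification of families for batch scoring."""
    snp_index: int
    # parent-conditioned block
    par_fam: np.ndarray       # family indices (into structure.fids)
    par_off: np.ndarray       # offspring rows, ordered by family
    par_off_fam: np.ndarray   # position of each offspring's family in par_fam
    # sibship-conditioned block (offspring ordered by family)
    sib_off: np.ndarray
    sib_sizes: np.ndarray
    t_par: np.ndarray         # residuals aligned to par_off
    t_sib: np.ndarray


def _classify_cell(struct: _Structure, snp_index: int, resid: pd.Series,
                   parent_policy: str) -> _Cell:
    iids = list(struct.cohort.individuals)
    rvals = np.full(len(iids), np.nan)
    idx = {iid: i for i, iid in enumerate(iids)}
    for iid, v in resid.items():
        rvals[idx[iid]] = v
    par_fam, par_off, par_off_fam = [], [], []
    sib_off, sib_sizes = [], []
    s = snp_index
    for fi in range(len(struct.fids)):
        rows = struct.off_rows[fi]
        ok = rows[(struct.present[rows, s]) & ~np.isnan(rvals[rows])]
        if len(ok) == 0:
            continue
        fr, mr = struct.father_row[fi], struct.mother_row[fi]
        have_f = fr >= 0 and struct.present[fr, s]
        have_m = mr >= 0 and struct.present[mr, s]
        if have_f and have_m:
            par_off_fam.extend([len(par_fam)] * len(ok))
            par_fam.append(fi)
            par_off.extend(ok)
        elif parent_policy == "parents_required" or have_f or have_m:
            continue
        elif len(ok) >= 2:
            sib_off.extend(ok)
            sib_sizes.append(len(ok))
    t_par = rvals[np.array(par_off, dtype=int)] if par_off else np.empty(0)
    t_sib = rvals[np.array(sib_off, dtype=int)] if sib_off else np.empty(0)
    return _Cell(s, np.array(par_fam, dtype=int), np.array(par_off, dtype=int),
                 np.array(par_off_fam, dtype=int), np.array(sib_off, dtype=int),
                 np.array(sib_sizes, dtype=int), t_par, t_sib)


def _cell_pvalues(cell: _Cell, ind_counts: np.ndarray,
                  struct: _Structure, model: str = "additive",
                  t_par: np.ndarray | None = None,
                  t_sib: np.ndarray | None = None) -> np.ndarray:
    """Two-sided p-values for one grid cell across R replicates.

    ``ind_counts``: (R, n_ind) regenerated effect-allele counts at the
    cell's SNP for every individual; untestable replicates yield p = 1.
    Residuals may be overridden per replicate via 2-D ``t_par``/``t_sib``.
    """
    e_tab, v_tab = transmission_tables(model)
    code = CODE_MAP[model]
    R = ind_counts.shape[0]
    U = np.zeros(R)
    V = np.zeros(R)
    tp = cell.t_par if t_par is None else t_par
    ts = cell.t_sib if t_sib is None else t_sib
    if len(cell.par_off):
        cf = ind_counts[:, struct.father_row[cell.par_fam]]
        cm = ind_counts[:, struct.mother_row[cell.par_fam]]
        e = e_tab[cf, cm][:, cell.par_off_fam]
        v = v_tab[cf, cm][:, cell.par_off_fam]
        X = code[ind_counts[:, cell.par_off]]
        U += ((X - e) * tp).sum(axis=1)
        V += (v * tp**2).sum(axis=1)
    if len(cell.sib_off):
        X = code[ind_counts[:, cell.sib_off]]
        offsets = np.concatenate([[0], np.cumsum(cell.sib_sizes)[:-1]])
        n = cell.sib_sizes
        S1 = np.add.reduceat(X, offsets, axis=1)
        S2 = np.add.reduceat(X * X, offsets, axis=1)
        mean = S1 / n
        var = np.clip(S2 / n - mean**2, 0.0, None)
        if ts.ndim == 1:
            ST = np.add.reduceat(ts, offsets)
            ST2 = np.add.reduceat(ts * ts, offsets)
            STX = np.add.reduceat(ts * X, offsets, axis=1)
        else:
            ST = np.add.reduceat(ts, offsets, axis=1)
            ST2 = np.add.reduceat(ts * ts, offsets, axis=1)
            STX = np.add.reduceat(ts * X, offsets, axis=1)
        U += (STX - mean * ST).sum(axis=1)
        V += (var * (ST2 - (ST**2 - ST2) / (n - 1))).sum(axis=1)
    p = np.ones(R)
    ok = V > 0
    z = np.zeros(R)
    z[ok] = U[ok] / np.sqrt(V[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    return p


def _drop_counts(table: HaplotypeTable, struct: _Structure, R: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Regenerate effect-allele counts for every individual in R
    replicates: founders from the table, offspring by gene dropping;
    the observed missingness mask is re-applied afterwards.

    Returns an (R, n_ind, n_snps) int8 array (missing = 0 count but the
    mask lives in ``struct.present``; callers use cells that already
    exclude masked entries).
    """
    eff = table.effect_count_matrix()          # (H, S)
    H = len(table.haplotypes)
    nf = len(struct.fids)
    n_ind = struct.counts.shape[0]
    fhap = rng.choice(H, size=(R, nf, 2), p=table.freqs)
    mhap = rng.choice(H, size=(R, nf, 2), p=table.freqs)
    out = np.zeros((R, n_ind, struct.n_snps), dtype=np.int8)
    fr, mr = struct.father_row, struct.mother_row
    has_f, has_m = fr >= 0, mr >= 0
    out[:, fr[has_f], :] = eff[fhap[:, has_f, 0]] + eff[fhap[:, has_f, 1]]
    out[:, mr[has_m], :] = eff[mhap[:, has_m, 0]] + eff[mhap[:, has_m, 1]]
    all_off = np.concatenate([r for r in struct.off_rows if len(r)])
    couple = np.concatenate([np.full(len(r), fi)
                             for fi, r in enumerate(struct.off_rows) if len(r)])
    pick_f = rng.integers(0, 2, size=(R, len(all_off)))
    pick_m = rng.integers(0, 2, size=(R, len(all_off)))
    ridx = np.arange(R)[:, None]
    pat = fhap[ridx, couple[None, :], pick_f]
    mat = mhap[ridx, couple[None, :], pick_m]
    out[:, all_off, :] = eff[pat] + eff[mat]
    return out


# ---------------------------------------------------------------------
# min-p adjustment
# ---------------------------------------------------------------------

@dataclass
class NullReplicateSet:
    R: int
    min_p: np.ndarray
    test_grid: list[tuple[str, str]]   # (snp, trait) labels
    seed: int


def minp_adjust(cohort: FamilyCohort, hap_table: HaplotypeTable,
                test_grid: list[tuple[str, TraitSpec]], R: int = 1000,
                seed: int = 0, parent_policy: str = "parents_or_sibship",
                model: str = "additive", smoothed: bool = False
                ) -> tuple[pd.DataFrame, NullReplicateSet]:
    """Monte-Carlo min-p multiple-testing adjustment.

    Runs the observed test battery, then R gene-dropping null replicates
    on the identical family structures with all trait values kept, and
    adjusts each observed p_i as #{r : m_r < p_i} / R (strict inequality;
    ``smoothed=True`` uses (#+1)/(R+1) instead).  Untestable tests inside
    a replicate contribute p = 1 to that replicate's minimum.
    """
    if R < 100:
        warnings.warn(f"R={R} gives coarse adjusted p-values (granularity 1/R)")
    rng = np.random.default_rng(seed)
    struct = _Structure(cohort)

    observed, cells, labels = [], [], []
    resid_cache: dict[str, pd.Series] = {}
    for snp_id, spec in test_grid:
        key = spec.name + "|" + ",".join(spec.covariates) + "|" + spec.transform
        if key not in resid_cache:
            resid_cache[key], _ = residualize(cohort, spec)
        resid = resid_cache[key]
        res = fbat_test(cohort, snp_id, resid, model=model,
                        parent_policy=parent_policy)
        res.trait = spec.name
        res.covariate_set = ",".join(spec.covariates)
        observed.append(res)
        cells.append(_classify_cell(struct, cohort.snp_index(snp_id), resid,
                                    parent_policy))
        labels.append((snp_id, spec.name))

    counts = _drop_counts(hap_table, struct, R, rng)
    pmat = np.column_stack([
        _cell_pvalues(cell, counts[:, :, cell.snp_index], struct, model)
        for cell in cells])
    min_p = pmat.min(axis=1)

    rows = []
    for res, (snp_id, trait) in zip(observed, labels):
        if res.testable:
            hits = int((min_p < res.p).sum())
            adj = (hits + 1) / (R + 1) if smoothed else hits / R
        else:
            adj = math.nan
        rows.append({"snp": snp_id, "trait": trait, "p_raw": res.p,
                     "p_adjusted": adj, "status": res.status,
                     "n_informative": res.n_informative_families})
    return (pd.DataFrame(rows),
            NullReplicateSet(R, min_p, labels, seed))


# ---------------------------------------------------------------------
# null calibration of the family score test
# ---------------------------------------------------------------------

def _calibration_cohort(n_families: int, parent_genotypes: bool,
                        hap_table: HaplotypeTable, seed: int) -> FamilyCohort:
    """Bare pedigree scaffold (2-3 sibs, placeholder genotypes) used by the
    batch null simulator; genotype *presence* matters, values do not."""
    from .cohort import Individual
    rng = np.random.default_rng(seed)
    snps = hap_table.snps
    placeholder = [(s.allele_major, s.allele_major) for s in snps]
    inds = []
    for i in range(n_families):
        fid = f"F{i:04d}"
        pg = list(placeholder) if parent_genotypes else [None] * len(snps)
        inds.append(Individual(f"{fid}_P1", fid, sex="male", genotypes=list(pg)))
        inds.append(Individual(f"{fid}_P2", fid, sex="female", genotypes=list(pg)))
        for k in range(2 + int(rng.random() < 0.25)):
            inds.append(Individual(
                f"{fid}_S{k}", fid, father_iid=f"{fid}_P1",
                mother_iid=f"{fid}_P2", genotypes=list(placeholder),
                phenotypes={"y": 0.0}))
    return FamilyCohort(list(snps), inds)


def null_rejection_rate(n_families: int = 200, n_replicates: int = 2000,
                        model: str = "additive",
                        parent_policy: str = "parents_or_sibship",
                        alpha: float = 0.05, seed: int = 0,
                        hap_table: HaplotypeTable | None = None,
                        snp: str | None = None,
                        return_details: bool = False):
    """Empirical type-I error of the family score test.

    Simulates ``n_replicates`` independent null cohorts (fixed pedigree
    scaffold; fresh Mendelian genotypes and fresh standard-normal traits
    each replicate, no genetic effect) and returns the fraction of
    replicates rejecting at ``alpha``.  With ``parents_required`` the
    scaffold has genotyped parents; with ``parents_or_sibship`` parents
    are ungenotyped, exercising the sibship-permutation conditioning.
    """
    from .simulate import gas6_haplotype_table
    table = hap_table or gas6_haplotype_table()
    snp = snp or table.snps[-1].snp_id
    parent_genotypes = parent_policy == "parents_required"
    cohort = _calibration_cohort(n_families, parent_genotypes, table, seed)
    struct = _Structure(cohort)
    rng = np.random.default_rng(seed + 1)

    offspring = [iid for iid, ind in cohort.individuals.items()
                 if not ind.is_founder]
    zeros = pd.Series(0.0, index=offspring)
    s = cohort.snp_index(snp)
    cell = _classify_cell(struct, s, zeros, parent_policy)

    counts = _drop_counts(table, struct, n_replicates, rng)[:, :, s]
    n_ind = struct.counts.shape[0]
    traits = rng.standard_normal((n_replicates, n_ind))
    # residualize on the intercept: center within each replicate's
    # offspring analysis set
    cols = np.concatenate([cell.par_off, cell.sib_off]).astype(int)
    center = traits[:, cols].mean(axis=1, keepdims=True)
    t_par = traits[:, cell.par_off] - center
    t_sib = traits[:, cell.sib_off] - center
    p = _cell_pvalues(cell, counts, struct, model, t_par=t_par, t_sib=t_sib)
    rate = float((p < alpha).mean())
    if return_details:
        return rate, p, counts, traits - center, cell, cohort
    return rate


# ---------------------------------------------------------------------
# bootstrap power
# ---------------------------------------------------------------------

def bootstrap_power(cohort: FamilyCohort, snp: str, trait: TraitSpec,
                    B: int = 1000, alpha: float = 0.05, seed: int = 0,
                    model: str = "additive",
                    parent_policy: str = "parents_or_sibship") -> dict:
    """Family-bootstrap power of one association test.

    Families are resampled with replacement to the original family count;
    for each replicate the trait is re-residualized on the covariates and
    the family score test rerun.  Power is the fraction of replicates with
    p < alpha; untestable replicates count as non-rejections.
    """
    if B < 100:
        warnings.warn(f"B={B} gives a coarse power estimate")
    rng = np.random.default_rng(seed)
    struct = _Structure(cohort)
    pheno = cohort.phenotype_frame()
    y = log_transform(pheno[trait.name].astype(float), trait)
    X = build_design(pheno, trait.covariates)
    common = y.dropna().index.intersection(X.index)
    y_all = pd.Series(np.nan, index=pheno.index)
    y_all[common] = y[common]

    # fixed per-offspring quantities
    iids = list(cohort.individuals)
    idx = {iid: i for i, iid in enumerate(iids)}
    yv = y_all.to_numpy(dtype=float)
    Xfull = np.full((len(iids), X.shape[1]), np.nan)
    Xfull[[idx[i] for i in X.index]] = X.to_numpy(dtype=float)

    e_tab, v_tab = transmission_tables(model)
    code = CODE_MAP[model]
    s = cohort.snp_index(snp)

    # per-family blocks: (offspring rows, mode, e, v, codes)
    blocks = []
    for fi in range(len(struct.fids)):
        rows = struct.off_rows[fi]
        ok = rows[struct.present[rows, s] & ~np.isnan(yv[rows])
                  & ~np.isnan(Xfull[rows].sum(axis=1))]
        if len(ok) == 0:
            continue
        fr, mr = struct.father_row[fi], struct.mother_row[fi]
        have_f = fr >= 0 and struct.present[fr, s]
        have_m = mr >= 0 and struct.present[mr, s]
        codes = code[struct.counts[ok, s]]
        if have_f and have_m:
            cf, cm = struct.counts[fr, s], struct.counts[mr, s]
            blocks.append((ok, codes - e_tab[cf, cm],
                           np.full(len(ok), v_tab[cf, cm]), None))
        elif parent_policy == "parents_required" or have_f or have_m:
            continue
        elif len(ok) >= 2:
            mean, var = codes.mean(), codes.var()
            blocks.append((ok, codes - mean, None, var))
    if not blocks:
        raise ValueError("no informative families for the requested test")

    nb = len(blocks)
    rejections = untestable = 0
    for _ in range(B):
        pick = rng.integers(0, nb, size=nb)
        rows_list = [blocks[b][0] for b in pick]
        rows_cat = np.concatenate(rows_list)
        Xb = Xfull[rows_cat]
        yb = yv[rows_cat]
        beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        T = yb - Xb @ beta
        U = Vt = 0.0
        pos = 0
        for b in pick:
            rows, dev, vvec, sibvar = blocks[b]
            n = len(rows)
            t = T[pos:pos + n]
            pos += n
            if vvec is not None:           # parent-conditioned
                U += float(t @ dev)
                Vt += float(vvec @ (t * t))
            else:                          # sibship permutation
                if sibvar <= 0:
                    continue
                st, st2 = t.sum(), float(t @ t)
                U += float(t @ dev)
                Vt += sibvar * (st2 - (st * st - st2) / (n - 1))
        if Vt <= 0:
            untestable += 1
            continue
        z = U / math.sqrt(Vt)
        if 2.0 * stats.norm.sf(abs(z)) < alpha:
            rejections += 1
    return {"power": rejections / B, "B": B, "alpha": alpha,
            "untestable_replicates": untestable, "snp": snp,
            "trait": trait.name}


# ---------------------------------------------------------------------
# SSPG case/control construction and haplotype odds ratio
# ---------------------------------------------------------------------

@dataclass
class CaseControlSet:
    cases: list[str]
    controls: list[str]
    threshold: float
    seed: int


def build_case_control(cohort: FamilyCohort, seed: int = 0,
                       trait: str = "sspg") -> CaseControlSet:
    """Insulin-resistance case/control set from the trait's upper quartile.

    The threshold is the 75th percentile (linear-interpolation quantile) of
    all observed values; cases are strictly above it.  One random case is
    drawn per family containing at least one case, and one random control
    per family consisting only of controls.
    """
    pheno = cohort.phenotype_frame()
    if trait not in pheno.columns:
        raise KeyError(f"trait {trait!r} not present")
    vals = pheno[trait].astype(float).dropna()
    if vals.empty:
        raise ValueError(f"no observed values for {trait!r}")
    threshold = float(np.quantile(vals, 0.75))
    is_case = vals > threshold
    if not is_case.any():
        raise ValueError("no cases above the 75th-percentile threshold")
    rng = np.random.default_rng(seed)
    cases, controls = [], []
    for fid in sorted(cohort.families):
        members = [i for i in cohort.families[fid] if i in vals.index]
        if not members:
            continue
        fam_cases = [i for i in members if is_case[i]]
        if fam_cases:
            cases.append(fam_cases[rng.integers(len(fam_cases))])
        else:
            controls.append(members[rng.integers(len(members))])
    if not controls:
        raise ValueError("no control families")
    return CaseControlSet(cases, controls, threshold, seed)


def haplotype_case_control_or(cohort: FamilyCohort, ccset: CaseControlSet,
                              hap_table: HaplotypeTable, target: str,
                              reference: str) -> dict:
    """Odds ratio of a haplotype versus the reference (major) haplotype.

    Each selected individual contributes posterior-expected counts of the
    target and reference haplotypes; the OR is the cross-product ratio of
    the 2x2 expected-count table, with a Woolf log-OR 95% CI.  A zero
    expected cell triggers a 0.5 continuity correction (flagged).
    """
    for h in (target, reference):
        if hap_table.frequency_of(h) <= 0:
            raise ValueError(f"haplotype {h!r} has zero frequency")
    bits_t = _label_to_bits(target, hap_table.snps)
    bits_r = _label_to_bits(reference, hap_table.snps)
    freq_of = {_label_to_bits(h, hap_table.snps): f
               for h, f in hap_table.haplotypes}
    counts = cohort.count_matrix()
    row_of = {iid: i for i, iid in enumerate(cohort.individuals)}

    def expected(iids):
        et = er = 0.0
        for iid in iids:
            row = counts[row_of[iid]]
            if (row < 0).any():
                continue
            for h1, h2, w in phase_posteriors(tuple(int(c) for c in row), freq_of):
                et += w * ((h1 == bits_t) + (h2 == bits_t))
                er += w * ((h1 == bits_r) + (h2 == bits_r))
        return et, er

    a, b = expected(ccset.cases)       # target, reference among cases
    c, d = expected(ccset.controls)
    cells = np.array([a, b, c, d], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt((1 / cells).sum())
    lo, hi = math.log(or_) - 1.96 * se, math.log(or_) + 1.96 * se
    return {"target": target, "reference": reference, "or": or_,
            "ci_low": math.exp(lo), "ci_high": math.exp(hi),
            "table": {"case_target": a, "case_reference": b,
                      "control_target": c, "control_reference": d},
            "continuity_corrected": corrected,
            "n_cases": len(ccset.cases), "n_controls": len(ccset.controls)}
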