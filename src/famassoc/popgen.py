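"""Marker QC and descriptive population genetics.

Allele frequencies and call rates, the exact conditional Hardy-Weinberg
test, EM estimation of multi-SNP haplotype frequencies from unphased
genotypes, and haplotype-based pairwise LD.

The HWE test and the haplotype EM operate on the one-per-family unrelated
subset (see :func:`famassoc.cohort.select_unrelated`): Hardy-Weinberg and
phase-frequency estimation both assume independent chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import FamilyCohort, SnpDef
from .simulate import HaplotypeTable


@dataclass
class MarkerSummary:
    snp_id: str
    allele_major: str
    allele_minor: str
    region: str
    maf: float
    call_rate: float
    hwe_p: float
    monomorphic: bool = False


def allele_and_call_stats(cohort: FamilyCohort, snp_id: str,
                          iids: list[str] | None = None) -> tuple[float, float, bool]:
    """(maf, call_rate, monomorphic) for one SNP over a subset of iids."""
    iids = list(cohort.individuals) if iids is None else iids
    if not iids:
        raise ValueError("empty subset")
    counts = cohort.effect_allele_counts(snp_id)[iids]
    obs = counts.dropna()
    call_rate = len(obs) / len(iids)
    if len(obs) == 0:
        return np.nan, 0.0, True
    p = obs.sum() / (2 * len(obs))
    maf = min(p, 1 - p)
    return float(maf), float(call_rate), bool(maf == 0.0)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed minor-allele total and sums, over the
    heterozygote-count support, the probabilities of all configurations no
    more likely than the observed one:

        P(h | n, m) ∝ 2^h · n! / (n_AA(h)! · h! · n_aa(h)!)

    where m is the minor-allele count, n_aa(h) = (m - h)/2 and
    n_AA(h) = n - h - n_aa(h).
    """
    for c in (n_hom_major, n_het, n_hom_minor):
        if c < 0:
            raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("empty genotype table")
    m = 2 * n_hom_minor + n_het
    m = min(m, 2 * n - m)  # orient to the rarer allele
    if m == 0:
        return 1.0
    hs = np.arange(m % 2, m + 1, 2)
    hs = hs[(m - hs) // 2 + hs <= n]
    n_rare = (m - hs) // 2
    n_common = n - hs - n_rare
    logw = hs * np.log(2.0) - gammaln(n_common + 1) - gammaln(hs + 1) - gammaln(n_rare + 1)
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[hs == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def qc_report(cohort: FamilyCohort, seed: int) -> pd.DataFrame:
    """Marker summary table over the unrelated one-per-family subset."""
    from .cohort import select_unrelated
    unrelated = select_unrelated(cohort, seed)
    rows = []
    for snp in cohort.snps:
        counts = cohort.effect_allele_counts(snp.snp_id)[unrelated].dropna()
        tab = counts.value_counts()
        maf, call_rate, mono = allele_and_call_stats(cohort, snp.snp_id, unrelated)
        hwe = 1.0 if mono else hwe_exact_test(
            int(tab.get(0.0, 0)), int(tab.get(1.0, 0)), int(tab.get(2.0, 0)))
        rows.append(MarkerSummary(snp.snp_id, snp.allele_major, snp.allele_minor,
                                  snp.region, maf, call_rate, hwe, mono))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------
# phase enumeration and EM haplotype frequencies
# ---------------------------------------------------------------------

def enumerate_phase_pairs(counts: tuple[int, ...]) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs compatible with an unphased genotype.

    ``counts`` is the per-SNP effect-allele count vector (0/1/2).  Each
    haplotype is a 0/1 tuple over the panel.  A genotype with k
    heterozygous sites yields max(1, 2^(k-1)) pairs.
    """
    het = [j for j, c in enumerate(counts) if c == 1]
    base = [1 if c == 2 else 0 for c in counts]
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    first, rest = het[0], het[1:]
    for assign in product((0, 1), repeat=len(rest)):
        h1, h2 = list(base), list(base)
        h1[first], h2[first] = 1, 0
        for j, a in zip(rest, assign):
            h1[j], h2[j] = a, 1 - a
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def haplotype_label(h: tuple[int, ...], snps: list[SnpDef]) -> str:
    return "".join(s.effect_allele if a else
                   (s.allele_major if s.effect_allele == s.allele_minor else s.allele_minor)
                   for a, s in zip(h, snps))


def _label_to_bits(label: str, snps: list[SnpDef]) -> tuple[int, ...]:
    return tuple(1 if a == s.effect_allele else 0 for a, s in zip(label, snps))


def phase_posteriors(counts: tuple[int, ...], freq_of: dict[tuple, float]
                     ) -> list[tuple[tuple, tuple, float]]:
    """Posterior weights over compatible phase pairs given haplotype
    frequencies: w(h1,h2) ∝ f_h1·f_h2 (×2 when h1 ≠ h2)."""
    pairs = enumerate_phase_pairs(counts)
    ws = []
    for h1, h2 in pairs:
        f1, f2 = freq_of.get(h1, 0.0), freq_of.get(h2, 0.0)
        w = f1 * f2 * (2.0 if h1 != h2 else 1.0)
        ws.append(w)
    total = sum(ws)
    if total <= 0:
        # fall back to uniform over compatible pairs (all-zero prior)
        ws = [1.0] * len(pairs)
        total = float(len(pairs))
    return [(h1, h2, w / total) for (h1, h2), w in zip(pairs, ws)]


def em_haplotype_frequencies(genotype_counts: np.ndarray, snps: list[SnpDef],
                             tol: float = 1e-8, max_iter: int = 2000,
                             seed: int | None = None,
                             return_trace: bool = False):
    """EM haplotype frequency estimation from unphased genotypes.

    ``genotype_counts``: (n, n_snps) effect-allele counts; rows containing
    -1 or NaN (missing) are excluded.  Initialization is the
    linkage-equilibrium product of allele frequencies, optionally jittered
    (``seed``) for robustness checks.  Returns a :class:`HaplotypeTable`
    sorted by descending frequency (and the log-likelihood trace when
    ``return_trace``).
    """
    G = np.asarray(genotype_counts, dtype=float)
    complete = ~np.any((G < 0) | np.isnan(G), axis=1)
    G = G[complete].astype(int)
    if len(G) == 0:
        raise ValueError("no individuals with complete genotypes")

    rows, mult = np.unique(G, axis=0, return_counts=True)
    pair_lists = [enumerate_phase_pairs(tuple(r)) for r in rows]
    universe = sorted({h for pl in pair_lists for pair in pl for h in pair})
    hidx = {h: i for i, h in enumerate(universe)}
    H = len(universe)

    # linkage-equilibrium initialization
    p = G.mean(axis=0) / 2.0
    p = np.clip(p, 1e-6, 1 - 1e-6)
    f = np.array([np.prod([p[j] if h[j] else 1 - p[j] for j in range(len(p))])
                  for h in universe])
    f /= f.sum()
    if seed is not None:
        rng = np.random.default_rng(seed)
        f = f * np.exp(rng.normal(0, 0.1, size=H))
        f /= f.sum()

    pair_idx = [np.array([(hidx[a], hidx[b]) for a, b in pl]) for pl in pair_lists]
    pair_het = [np.array([2.0 if a != b else 1.0 for a, b in pl]) for pl in pair_lists]

    trace = []
    for _ in range(max_iter):
        new = np.zeros(H)
        loglik = 0.0
        for idx, het, m in zip(pair_idx, pair_het, mult):
            w = het * f[idx[:, 0]] * f[idx[:, 1]]
            tot = w.sum()
            if tot <= 0:
                w = np.ones(len(w))
                tot = float(len(w))
            else:
                loglik += m * np.log(tot)
            w = w / tot * m
            np.add.at(new, idx[:, 0], w)
            np.add.at(new, idx[:, 1], w)
        new /= new.sum()
        trace.append(loglik)
        delta = np.abs(new - f).max()
        f = new
        if delta < tol:
            break
    else:
        warnings.warn(f"haplotype EM did not converge; last max |df| = {delta:.3g}")

    order = np.argsort(-f)
    haps = [(haplotype_label(universe[i], snps), float(f[i])) for i in order]
    # renormalize away accumulated floating error
    total = sum(fr for _, fr in haps)
    haps = [(h, fr / total) for h, fr in haps]
    table = HaplotypeTable(list(snps), haps)
    return (table, trace) if return_trace else table


# ---------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------

def pairwise_r2(table: HaplotypeTable, snp_i: str, snp_j: str) -> tuple[float, float]:
    """(D, r²) for one SNP pair, marginalized from the haplotype table."""
    ids = [s.snp_id for s in table.snps]
    i, j = ids.index(snp_i), ids.index(snp_j)
    eff = table.effect_count_matrix().astype(bool)
    f = table.freqs
    p_i = f[eff[:, i]].sum()
    p_j = f[eff[:, j]].sum()
    if p_i <= 0 or p_i >= 1 or p_j <= 0 or p_j >= 1:
        return np.nan, np.nan
    f_ij = f[eff[:, i] & eff[:, j]].sum()
    D = f_ij - p_i * p_j
    r2 = D * D / (p_i * (1 - p_i) * p_j * (1 - p_j))
    return float(D), float(r2)


def ld_matrix(table: HaplotypeTable) -> pd.DataFrame:
    """Long-format pairwise LD table (snp_i, snp_j, D, r²)."""
    ids = [s.snp_id for s in table.snps]
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            D, r2 = pairwise_r2(table, ids[a], ids[b])
            rows.append({"snp_i": ids[a], "snp_j": ids[b], "D": D, "r2": r2})
    return pd.DataFrame(rows)
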