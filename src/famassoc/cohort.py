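"""Family cohort data model and PLINK-text / TSV input-output.

The cohort object used throughout the package is a collection of nuclear
families (two parents plus a sibship) typed at a small ordered SNP panel,
with an arbitrary set of per-individual phenotype and covariate values.
Genotypes are unordered allele pairs; phase is never stored here.

File dialects follow PLINK conventions: whitespace-delimited PED with the
six leading pedigree columns and two allele columns per marker ("0" =
missing allele), a four-column MAP, and a separate tab-separated phenotype
table keyed by individual id ("" or "NA" = missing value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of the phenotype table
PHENO_COLUMNS = [
    "iid", "sspg", "fpg_mgdl", "fpi", "bmi", "age", "sex", "site",
    "ethnicity", "hours_basal", "hours_sedentary", "smoking", "alcohol",
    "hypertension", "t2d_followup",
]

#: phenotype columns carried as text categories rather than numbers
CATEGORICAL_PHENOS = frozenset({"sex", "site", "ethnicity"})


class PedigreeError(ValueError):
    """Referential or structural inconsistency in a pedigree."""


class FormatError(ValueError):
    """Malformed input file content."""


@dataclass(frozen=True)
class SnpDef:
    """A biallelic marker definition.

    ``effect_allele`` is the allele counted by genotype codings; by
    convention it is the minor allele unless stated otherwise.
    """

    snp_id: str
    allele_major: str
    allele_minor: str
    region: str = ""
    effect_allele: str | None = None

    def __post_init__(self):
        if self.allele_major == self.allele_minor:
            raise ValueError(f"{self.snp_id}: major and minor alleles identical")
        for a in (self.allele_major, self.allele_minor):
            if a not in VALID_ALLELES:
                raise FormatError(f"{self.snp_id}: invalid allele {a!r}")
        if self.effect_allele is None:
            object.__setattr__(self, "effect_allele", self.allele_minor)
        elif self.effect_allele not in (self.allele_major, self.allele_minor):
            raise ValueError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} not one of "
                f"{self.allele_major}/{self.allele_minor}"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_major, self.allele_minor)


@dataclass
class TraitSpec:
    """Analysis specification for one trait.

    ``transform='log'`` (natural log) is only meaningful for continuous
    traits; covariates are names of phenotype columns, with categorical
    columns expanded to indicator contrasts downstream.
    """

    name: str
    kind: str = "continuous"  # or "binary"
    transform: str = "none"  # or "log"
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "log" and self.kind != "continuous":
            raise ValueError("log transform only applies to continuous traits")
        self.covariates = tuple(self.covariates)


@dataclass
class Individual:
    iid: str
    fid: str
    father_iid: str | None = None
    mother_iid: str | None = None
    sex: str | None = None  # "male" / "female" / None
    genotypes: list[tuple[str, str] | None] = field(default_factory=list)
    phenotypes: dict[str, object] = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.father_iid is None and self.mother_iid is None


class FamilyCohort:
    """Ordered SNP panel + families of individuals.

    SNP order is the haplotype coordinate order used by every multi-marker
    operation in the package.
    """

    def __init__(self, snps: list[SnpDef], individuals: list[Individual]):
        self.snps = list(snps)
        self.individuals: dict[str, Individual] = {}
        self.families: dict[str, list[str]] = {}
        for ind in individuals:
            if ind.iid in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self.individuals[ind.iid] = ind
            self.families.setdefault(ind.fid, []).append(ind.iid)
        self._snp_index = {s.snp_id: i for i, s in enumerate(self.snps)}
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        for ind in self.individuals.values():
            if len(ind.genotypes) != len(self.snps):
                raise PedigreeError(
                    f"{ind.iid}: {len(ind.genotypes)} genotypes for "
                    f"{len(self.snps)} SNPs"
                )
            for snp, g in zip(self.snps, ind.genotypes):
                if g is None:
                    continue
                for a in g:
                    if a not in snp.alleles:
                        raise FormatError(
                            f"{ind.iid}: allele {a!r} not in {snp.snp_id} "
                            f"alleles {snp.alleles}"
                        )
            for role, pid in (("father", ind.father_iid), ("mother", ind.mother_iid)):
                if pid is None:
                    continue
                parent = self.individuals.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{ind.iid}: {role} {pid!r} not present in cohort"
                    )
                if parent.fid != ind.fid:
                    raise PedigreeError(
                        f"{ind.iid}: {role} {pid!r} belongs to family "
                        f"{parent.fid!r}, not {ind.fid!r}"
                    )
                want = "male" if role == "father" else "female"
                if parent.sex is not None and parent.sex != want:
                    raise PedigreeError(f"{ind.iid}: {role} {pid!r} has sex {parent.sex!r}")

    # -- accessors -----------------------------------------------------

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None

    @property
    def iids(self) -> list[str]:
        return list(self.individuals)

    def n_families(self) -> int:
        return len(self.families)

    def effect_allele_counts(self, snp_id: str) -> pd.Series:
        """Per-individual effect-allele count at one SNP (NaN = missing)."""
        j = self.snp_index(snp_id)
        eff = self.snps[j].effect_allele
        out = {}
        for iid, ind in self.individuals.items():
            g = ind.genotypes[j]
            out[iid] = float(g.count(eff)) if g is not None else math.nan
        return pd.Series(out, name=snp_id)

    def count_matrix(self) -> np.ndarray:
        """(n_individuals, n_snps) effect-allele counts, -1 = missing."""
        n, s = len(self.individuals), len(self.snps)
        mat = np.full((n, s), -1, dtype=np.int8)
        effs = [snp.effect_allele for snp in self.snps]
        for i, ind in enumerate(self.individuals.values()):
            for j, g in enumerate(ind.genotypes):
                if g is not None:
                    mat[i, j] = g.count(effs[j])
        return mat

    def phenotype_frame(self) -> pd.DataFrame:
        """All phenotype values as a DataFrame indexed by iid, plus fid."""
        rows = {iid: dict(ind.phenotypes) for iid, ind in self.individuals.items()}
        df = pd.DataFrame.from_dict(rows, orient="index").reindex(self.individuals)
        df.index.name = "iid"
        df.insert(0, "fid", [self.individuals[i].fid for i in df.index])
        return df

    def copy(self) -> "FamilyCohort":
        inds = [
            replace(ind, genotypes=list(ind.genotypes), phenotypes=dict(ind.phenotypes))
            for ind in self.individuals.values()
        ]
        return FamilyCohort(self.snps, inds)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FamilyCohort):
            return NotImplemented
        if self.snps != other.snps or set(self.individuals) != set(other.individuals):
            return False
        for iid, a in self.individuals.items():
            b = other.individuals[iid]
            if (a.fid, a.father_iid, a.mother_iid, a.sex) != (
                b.fid, b.father_iid, b.mother_iid, b.sex
            ):
                return False
            ga = [None if g is None else tuple(sorted(g)) for g in a.genotypes]
            gb = [None if g is None else tuple(sorted(g)) for g in b.genotypes]
            if ga != gb:
                return False
            if set(a.phenotypes) != set(b.phenotypes):
                return False
            for k in a.phenotypes:
                va, vb = a.phenotypes[k], b.phenotypes[k]
                if isinstance(va, float) and isinstance(vb, float):
                    if not (va == vb or (math.isnan(va) and math.isnan(vb))):
                        return False
                elif va != vb:
                    return False
        return True


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

_SEX_CODE = {"1": "male", "2": "female", "0": None}
_SEX_OUT = {"male": "1", "female": "2", None: "0"}


def read_map(map_path) -> list[SnpDef]:
    """Read a 4-column MAP file; alleles are filled in by the PED pass."""
    snps = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 MAP columns")
            snps.append(fields[1])
    return snps


def read_ped_map(ped_path, map_path, snp_defs: list[SnpDef] | None = None) -> FamilyCohort:
    """Read a PLINK text PED/MAP pair into a :class:`FamilyCohort`.

    If ``snp_defs`` is given it fixes allele identities and panel order;
    otherwise marker names come from the MAP and major/minor alleles are
    assigned by observed frequency (ties broken alphabetically).
    """
    snp_names = read_map(map_path)
    if snp_defs is not None:
        if [s.snp_id for s in snp_defs] != snp_names:
            raise FormatError("MAP marker names do not match supplied SNP definitions")

    raw: list[tuple] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(snp_names):
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(snp_names)} "
                    f"columns, found {len(fields)}"
                )
            fid, iid, father, mother, sex = fields[:5]
            if sex not in _SEX_CODE:
                raise FormatError(f"{ped_path}:{lineno}: invalid sex code {sex!r}")
            genos = []
            for j in range(len(snp_names)):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                for a in (a1, a2):
                    if a != "0" and a not in VALID_ALLELES:
                        raise FormatError(
                            f"{ped_path}:{lineno}: invalid allele {a!r} for "
                            f"{snp_names[j]}"
                        )
                if a1 == "0" or a2 == "0":
                    genos.append(None)
                else:
                    genos.append((a1, a2))
            raw.append((fid, iid, father, mother, _SEX_CODE[sex], genos))

    if snp_defs is None:
        snp_defs = _infer_snp_defs(snp_names, raw)

    individuals = []
    for fid, iid, father, mother, sex, genos in raw:
        individuals.append(Individual(
            iid=iid, fid=fid,
            father_iid=None if father == "0" else father,
            mother_iid=None if mother == "0" else mother,
            sex=sex, genotypes=genos,
        ))
    return FamilyCohort(snp_defs, individuals)


def _infer_snp_defs(snp_names, raw) -> list[SnpDef]:
    defs = []
    for j, name in enumerate(snp_names):
        counts: dict[str, int] = {}
        for row in raw:
            g = row[5][j]
            if g is not None:
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        if len(alleles) == 0:
            raise FormatError(f"{name}: no genotyped individuals")
        if len(alleles) == 1:  # monomorphic: invent a placeholder minor allele
            other = next(a for a in "ACGT" if a != alleles[0])
            alleles.append(other)
        defs.append(SnpDef(name, alleles[0], alleles[1]))
    return defs


def read_phenotypes(table_path, cohort: FamilyCohort) -> tuple[FamilyCohort, list[str]]:
    """Attach a tab-separated phenotype table to a cohort.

    Returns the (mutated) cohort and the list of table iids that matched no
    cohort individual.  Empty cells and "NA" become missing (NaN for numeric
    columns, None for categorical ones).
    """
    df = pd.read_csv(table_path, sep="\t", dtype=str, keep_default_na=False)
    if "iid" not in df.columns:
        raise FormatError(f"{table_path}: no 'iid' column")
    if df["iid"].duplicated().any():
        dups = df["iid"][df["iid"].duplicated()].tolist()
        raise FormatError(f"{table_path}: duplicate iid rows {dups}")
    warnings = []
    value_cols = [c for c in df.columns if c != "iid"]
    for rowno, row in enumerate(df.itertuples(index=False), 2):
        iid = row.iid
        ind = cohort.individuals.get(iid)
        if ind is None:
            warnings.append(iid)
            continue
        for col in value_cols:
            cell = getattr(row, col).strip()
            if col in CATEGORICAL_PHENOS:
                ind.phenotypes[col] = None if cell in ("", "NA") else cell
            elif cell in ("", "NA"):
                ind.phenotypes[col] = math.nan
            else:
                try:
                    ind.phenotypes[col] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{table_path}: row {rowno}, column {col!r}: "
                        f"non-numeric value {cell!r}"
                    ) from None
    return cohort, warnings


def select_unrelated(cohort: FamilyCohort, seed: int) -> list[str]:
    """One randomly chosen individual per family (uniform, seed-determined)."""
    if not cohort.families:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    chosen = []
    for fid in sorted(cohort.families):
        members = cohort.families[fid]
        chosen.append(members[rng.integers(len(members))])
    return chosen


def _fmt_pheno(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float) or hasattr(v, "dtype"):
        v = float(v)
        if math.isnan(v):
            return "NA"
        return repr(v)
    return str(v)


def write_cohort(cohort: FamilyCohort, ped_path, map_path, pheno_path) -> None:
    """Write PED/MAP/phenotype-TSV such that reading them back reproduces
    the cohort exactly."""
    with open(map_path, "w") as fh:
        for snp in cohort.snps:
            fh.write(f"0\t{snp.snp_id}\t0\t0\n")
    with open(ped_path, "w") as fh:
        for ind in cohort.individuals.values():
            cols = [
                ind.fid, ind.iid,
                ind.father_iid or "0", ind.mother_iid or "0",
                _SEX_OUT[ind.sex], "0",
            ]
            for g in ind.genotypes:
                cols.extend(sorted(g) if g is not None else ("0", "0"))
            fh.write("\t".join(cols) + "\n")
    columns: list[str] = []
    for ind in cohort.individuals.values():
        for k in ind.phenotypes:
            if k not in columns:
                columns.append(k)
    with open(pheno_path, "w") as fh:
        fh.write("\t".join(["iid"] + columns) + "\n")
        for ind in cohort.individuals.values():
            if not ind.phenotypes:
                continue
            vals = [_fmt_pheno(ind.phenotypes.get(c, math.nan)) for c in columns]
            fh.write("\t".join([ind.iid] + vals) + "\n")
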