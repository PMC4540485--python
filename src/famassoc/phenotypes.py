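"""Phenotype formulas, classification rules, and covariate residualization.

All classification operations are pointwise and missing-propagating: a
missing input yields a missing output, never an error, unless the value is
outside its physical domain.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_PHENOS, FamilyCohort, TraitSpec

#: molar mass of glucose, mg/mmol
GLUCOSE_MG_PER_MMOL = 18.0182


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def mgdl_to_mmol(fpg_mgdl: float) -> float:
    """Convert plasma glucose from mg/dl to mmol/l."""
    if _is_missing(fpg_mgdl):
        return math.nan
    if fpg_mgdl < 0:
        raise ValueError(f"negative glucose {fpg_mgdl}")
    return fpg_mgdl / GLUCOSE_MG_PER_MMOL


def homa_ir(fpi: float, fpg_mmol: float) -> float:
    """HOMA insulin-resistance index: FPI (uU/ml) x FPG (mmol/l) / 22.5."""
    if _is_missing(fpi) or _is_missing(fpg_mmol):
        return math.nan
    if fpi < 0 or fpg_mmol < 0:
        raise ValueError("negative insulin or glucose")
    return fpi * fpg_mmol / 22.5


def classify_obesity(bmi: float) -> float:
    """Obesity indicator: BMI >= 30 kg/m^2 (boundary inclusive)."""
    if _is_missing(bmi):
        return math.nan
    if bmi <= 0:
        raise ValueError(f"nonpositive BMI {bmi}")
    return float(bmi >= 30.0)


def inactivity_score(hours_sedentary: float, hours_basal: float) -> float:
    """Inactivity score s = sedentary hours / (24 - basal hours)."""
    if _is_missing(hours_sedentary) or _is_missing(hours_basal):
        return math.nan
    if hours_basal >= 24 or hours_basal < 0:
        raise ValueError(f"basal hours {hours_basal} outside [0, 24)")
    if hours_sedentary < 0:
        raise ValueError(f"negative sedentary hours {hours_sedentary}")
    return hours_sedentary / (24.0 - hours_basal)


def classify_sedentary(s: float) -> float:
    """Sedentary lifestyle indicator: inactivity score strictly above 0.5."""
    if _is_missing(s):
        return math.nan
    return float(s > 0.5)


def classify_t2d(fpg_mgdl: float, ogtt_2h_mgdl: float, on_oha) -> float:
    """Type-2-diabetes rule: FPG >= 126 mg/dl, or 2-hour post-challenge
    glucose >= 200 mg/dl, or use of oral hypoglycemic agents."""
    crit = []
    if not _is_missing(fpg_mgdl):
        crit.append(fpg_mgdl >= 126.0)
    if not _is_missing(ogtt_2h_mgdl):
        crit.append(ogtt_2h_mgdl >= 200.0)
    if not _is_missing(on_oha):
        crit.append(bool(on_oha))
    if not crit:
        return math.nan
    return float(any(crit))


def log_transform(values: pd.Series, spec: TraitSpec) -> pd.Series:
    """Natural-log transform of a continuous trait; missing preserved."""
    if spec.transform != "log":
        return values.astype(float)
    vals = values.astype(float)
    bad = vals.index[(vals <= 0) & vals.notna()]
    if len(bad):
        raise ValueError(
            f"{spec.name}: nonpositive values under log for {list(bad)}")
    return np.log(vals)


def derive_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add derived phenotype columns to a phenotype table.

    Adds fpg_mmol, homa_ir, log_fpi, log_homa, obesity, inactivity_s, and
    sedentary, from the raw columns where present.
    """
    out = pheno.copy()
    if "fpg_mgdl" in out:
        out["fpg_mmol"] = out["fpg_mgdl"].map(mgdl_to_mmol)
    if "fpi" in out and "fpg_mmol" in out:
        out["homa_ir"] = [homa_ir(i, g) for i, g in zip(out["fpi"], out["fpg_mmol"])]
        with np.errstate(invalid="ignore", divide="ignore"):
            out["log_fpi"] = np.log(out["fpi"].astype(float))
            out["log_homa"] = np.log(out["homa_ir"].astype(float))
    if "bmi" in out:
        out["obesity"] = out["bmi"].map(classify_obesity)
    if "hours_sedentary" in out and "hours_basal" in out:
        out["inactivity_s"] = [
            inactivity_score(s, b)
            for s, b in zip(out["hours_sedentary"], out["hours_basal"])]
        out["sedentary"] = out["inactivity_s"].map(classify_sedentary)
    return out


def derive_phenotypes(cohort: FamilyCohort) -> FamilyCohort:
    """Attach the derived phenotype columns to every phenotyped individual."""
    for ind in cohort.individuals.values():
        if not ind.phenotypes:
            continue
        p = ind.phenotypes
        fpg_mmol = mgdl_to_mmol(p.get("fpg_mgdl", math.nan))
        p["fpg_mmol"] = fpg_mmol
        h = homa_ir(p.get("fpi", math.nan), fpg_mmol)
        p["homa_ir"] = h
        fpi = p.get("fpi", math.nan)
        p["log_fpi"] = math.log(fpi) if not _is_missing(fpi) and fpi > 0 else math.nan
        p["log_homa"] = math.log(h) if not _is_missing(h) and h > 0 else math.nan
        p["obesity"] = classify_obesity(p.get("bmi", math.nan))
        s = inactivity_score(p.get("hours_sedentary", math.nan),
                             p.get("hours_basal", math.nan))
        p["inactivity_s"] = s
        p["sedentary"] = classify_sedentary(s)
    return cohort


# ---------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------

def build_design(pheno: pd.DataFrame, covariates) -> pd.DataFrame:
    """Intercept + covariate design matrix; categorical columns expanded to
    treatment-coded indicators.  Rows with any missing covariate dropped."""
    cols = {"const": pd.Series(1.0, index=pheno.index)}
    for cov in covariates:
        if cov not in pheno.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        col = pheno[cov]
        if cov in CATEGORICAL_PHENOS or col.dtype == object:
            cat = col.astype("category")
            levels = list(cat.cat.categories)
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (cat == lev).astype(float)
            cols[f"__miss_{cov}"] = cat.isna().map({True: math.nan, False: 0.0})
        else:
            cols[cov] = col.astype(float)
    X = pd.DataFrame(cols)
    miss_markers = [c for c in X.columns if c.startswith("__miss_")]
    X = X.dropna()
    return X.drop(columns=miss_markers)


def residualize(cohort: FamilyCohort, spec: TraitSpec,
                extra_covariates: pd.DataFrame | None = None
                ) -> tuple[pd.Series, list[str]]:
    """OLS residuals of a (possibly log-transformed) trait on covariates.

    Pools all phenotyped individuals (family correlation is handled by the
    downstream conditional test, not here).  Returns the residual series
    (indexed by iid) and the list of iids excluded for missing trait or
    covariate values.  ``extra_covariates`` columns (e.g. a conditioning
    SNP's genotype code) are appended to the design.
    """
    pheno = cohort.phenotype_frame()
    if spec.name not in pheno.columns:
        raise KeyError(f"trait {spec.name!r} not present in cohort phenotypes")
    y = pheno[spec.name].astype(float)
    y = log_transform(y, spec)

    X = build_design(pheno, spec.covariates)
    if extra_covariates is not None:
        X = X.join(extra_covariates, how="inner").dropna()

    keep = y.notna() & y.index.isin(X.index)
    excluded = [iid for iid in pheno.index if not keep.get(iid, False)]
    yk = y[keep]
    Xk = X.loc[yk.index]

    Xm = Xk.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify offending columns via incremental rank
        bad, got = [], 0
        for j in range(Xm.shape[1]):
            r = np.linalg.matrix_rank(Xm[:, :j + 1])
            if r == got:
                bad.append(Xk.columns[j])
            got = r
        raise np.linalg.LinAlgError(
            f"rank-deficient design for {spec.name}: collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(Xm, yk.to_numpy(dtype=float), rcond=None)
    resid = yk.to_numpy(dtype=float) - Xm @ beta
    return pd.Series(resid, index=yk.index, name=f"resid_{spec.name}"), excluded
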