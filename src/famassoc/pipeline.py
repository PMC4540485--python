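"""Study orchestration: the association battery, haplotype analyses,
multiple-testing adjustment, power, and the follow-up T2D analysis.

The default plan mirrors the reference study: four markers crossed with
obesity and three insulin-resistance measures (SSPG, FPI, HOMA-IR; the
latter two log-transformed), Model 1 covariates (age, sex, site,
ethnicity, plus BMI for the continuous traits) and Model 2 adding the
three lifestyle factors, an additive genotype coding with dominant and
recessive variants available, 16-test min-p adjustment, and family-
bootstrap power.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import FamilyCohort, TraitSpec, select_unrelated, write_cohort
from .fbat import fbat_test, haplotype_fbat_test, interaction_fbat_test
from .gee import adjusted_means, fit_gee, odds_ratios, stratified_effects, t2d_incidence_test
from .phenotypes import derive_phenotypes, residualize
from .popgen import em_haplotype_frequencies, ld_matrix, qc_report
from .resampling import bootstrap_power, build_case_control, haplotype_case_control_or, minp_adjust
from .simulate import SimConfig, simulate_cohort

MODEL1_COVARIATES = {
    "binary": ("age", "sex", "site", "ethnicity"),
    "continuous": ("age", "sex", "bmi", "site", "ethnicity"),
}
LIFESTYLE_FACTORS = ("sedentary", "smoking", "alcohol")
DEFAULT_SNPS = ("rs8191974", "rs7323932", "rs7331124", "rs8191973")


def default_traits(model: int = 1) -> list[TraitSpec]:
    """The four analysis traits with Model 1 or Model 2 covariate sets."""
    extra = LIFESTYLE_FACTORS if model == 2 else ()
    return [
        TraitSpec("obesity", "binary", "none",
                  MODEL1_COVARIATES["binary"] + extra),
        TraitSpec("sspg", "continuous", "none",
                  MODEL1_COVARIATES["continuous"] + extra),
        TraitSpec("fpi", "continuous", "log",
                  MODEL1_COVARIATES["continuous"] + extra),
        TraitSpec("homa_ir", "continuous", "log",
                  MODEL1_COVARIATES["continuous"] + extra),
    ]


@dataclass
class AnalysisPlan:
    snps: tuple[str, ...] = DEFAULT_SNPS
    traits: list[TraitSpec] = field(default_factory=default_traits)
    codings: tuple[str, ...] = ("additive",)
    include_model2: bool = True
    haplotype_hypertension_covariate: bool = True
    R: int = 1000
    B: int = 1000
    alpha: float = 0.05
    seeds: dict[str, int] = field(default_factory=lambda: {
        "unrelated": 11, "minp": 13, "power": 17, "case_control": 19})


def enumerate_tests(plan: AnalysisPlan) -> list[tuple[str, TraitSpec]]:
    """The single-marker test grid: every SNP crossed with every trait."""
    if not plan.snps or not plan.traits:
        raise ValueError("analysis plan needs at least one SNP and one trait")
    return [(snp, trait) for snp in plan.snps for trait in plan.traits]


def _model2_spec(spec: TraitSpec) -> TraitSpec:
    return TraitSpec(spec.name, spec.kind, spec.transform,
                     tuple(spec.covariates) + LIFESTYLE_FACTORS)


def run_phase1(cohort: FamilyCohort, plan: AnalysisPlan) -> dict[str, pd.DataFrame]:
    """Phase-I battery: single-marker score tests (Models 1 and 2, all
    requested codings), GEE odds ratios / adjusted means, interaction and
    stratified analyses, and the haplotype analysis."""
    out: dict[str, pd.DataFrame] = {}

    assoc_rows = []
    model_specs = [("model1", plan.traits)]
    if plan.include_model2:
        model_specs.append(("model2", [_model2_spec(t) for t in plan.traits]))
    for mlabel, specs in model_specs:
        for spec in specs:
            resid, _ = residualize(cohort, spec)
            for snp in plan.snps:
                for coding in plan.codings:
                    try:
                        res = fbat_test(cohort, snp, resid, model=coding)
                        res.trait = spec.name
                        row = res.to_dict()
                    except Exception as exc:   # surfaced, not silenced
                        row = {"snp": snp, "trait": spec.name, "model": coding,
                               "status": f"error: {exc}"}
                    row["covariates"] = ",".join(spec.covariates)
                    row["covariate_model"] = mlabel
                    assoc_rows.append(row)
    out["association"] = pd.DataFrame(assoc_rows)

    gee_rows, am_rows = [], []
    for snp in plan.snps:
        for spec in plan.traits:
            try:
                if spec.kind == "binary":
                    fit = fit_gee(cohort, spec.name, snp=snp,
                                  genotype_coding="categorical",
                                  covariates=spec.covariates, link="logit")
                    ors = odds_ratios(fit)
                    ors.insert(0, "snp", snp)
                    ors.insert(1, "trait", spec.name)
                    gee_rows.append(ors)
                else:
                    fit = fit_gee(cohort, spec.name, snp=snp,
                                  genotype_coding="categorical",
                                  covariates=spec.covariates, link="identity",
                                  log_outcome=spec.transform == "log")
                    am = adjusted_means(fit)
                    am.insert(0, "snp", snp)
                    am.insert(1, "trait", spec.name)
                    am_rows.append(am)
            except Exception as exc:
                gee_rows.append(pd.DataFrame(
                    [{"snp": snp, "trait": spec.name, "term": "",
                      "p": math.nan, "status": f"error: {exc}"}]))
    out["gee_odds_ratios"] = (pd.concat(gee_rows, ignore_index=True)
                              if gee_rows else pd.DataFrame())
    out["gee_adjusted_means"] = (pd.concat(am_rows, ignore_index=True)
                                 if am_rows else pd.DataFrame())

    inter_rows, strat_rows = [], []
    for snp in plan.snps:
        for spec in plan.traits:
            for factor in LIFESTYLE_FACTORS:
                try:
                    res = interaction_fbat_test(cohort, snp, spec, factor)
                    row = res.to_dict()
                except Exception as exc:
                    row = {"snp": f"{snp}x{factor}", "trait": spec.name,
                           "status": f"error: {exc}"}
                inter_rows.append(row)
            try:
                strat, warns = stratified_effects(
                    cohort, snp, spec.name, "sedentary",
                    covariates=tuple(c for c in spec.covariates
                                     if c != "sedentary"),
                    link="logit" if spec.kind == "binary" else "identity",
                    log_outcome=spec.transform == "log")
                strat.insert(0, "snp", snp)
                strat.insert(1, "trait", spec.name)
                strat_rows.append(strat)
            except Exception as exc:
                strat_rows.append(pd.DataFrame(
                    [{"snp": snp, "trait": spec.name,
                      "stratum": f"error: {exc}"}]))
    out["interaction"] = pd.DataFrame(inter_rows)
    out["stratified"] = (pd.concat(strat_rows, ignore_index=True)
                         if strat_rows else pd.DataFrame())

    # haplotype analysis on the SSPG-style trait
    sspg_spec = next((t for t in plan.traits if t.kind == "continuous"),
                     plan.traits[0])
    if plan.haplotype_hypertension_covariate:
        sspg_spec = TraitSpec(sspg_spec.name, sspg_spec.kind,
                              sspg_spec.transform,
                              tuple(sspg_spec.covariates) + ("hypertension",))
    unrelated = select_unrelated(cohort, plan.seeds["unrelated"])
    counts = cohort.count_matrix()
    iid_row = {iid: i for i, iid in enumerate(cohort.individuals)}
    sub = counts[[iid_row[i] for i in unrelated]]
    em_table = em_haplotype_frequencies(sub, cohort.snps)
    results, omni = haplotype_fbat_test(cohort, em_table, sspg_spec)
    hap_rows = [{"haplotype": r.snp_id,
                 "frequency": em_table.frequency_of(r.snp_id),
                 "p": r.p, "z": r.z, "status": r.status} for r in results]
    hap_rows.append({"haplotype": "omnibus", "frequency": math.nan,
                     "p": omni.p, "z": math.nan, "status": omni.status})
    out["haplotype"] = pd.DataFrame(hap_rows)
    out["_em_table"] = em_table   # carried for downstream stages
    return out


def run_phase2(cohort: FamilyCohort, plan: AnalysisPlan) -> pd.DataFrame:
    """Follow-up battery: incident T2D versus each marker (logistic GEE
    with demographic, BMI, and lifestyle covariates)."""
    covs = ("age", "sex", "bmi", "site", "ethnicity") + LIFESTYLE_FACTORS
    rows = []
    for snp in plan.snps:
        try:
            rows.append(t2d_incidence_test(cohort, snp, covariates=covs))
        except Exception as exc:
            rows.append({"snp": snp, "p": math.nan, "status": f"error: {exc}"})
    return pd.DataFrame(rows)


def run_full_replica(config: SimConfig, plan: AnalysisPlan, outdir) -> dict:
    """Simulate, derive, QC, Phase I, min-p, power, haplotype case/control,
    Phase II; write TSV artifacts and a JSON manifest.  Deterministic for a
    fixed config and plan."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"famassoc_version": __version__,
                      "seed": config.seed, "stage_seconds": {}, "rows": {},
                      "seeds": dict(plan.seeds)}

    def stage(name):
        t0 = time.perf_counter()
        return lambda: manifest["stage_seconds"].__setitem__(
            name, round(time.perf_counter() - t0, 3))

    done = stage("simulate")
    cohort = simulate_cohort(config)
    derive_phenotypes(cohort)
    write_cohort(cohort, outdir / "cohort.ped", outdir / "cohort.map",
                 outdir / "cohort.tsv")
    done()

    done = stage("qc")
    qc = qc_report(cohort, plan.seeds["unrelated"])
    qc.to_csv(outdir / "qc_markers.tsv", sep="\t", index=False)
    done()

    done = stage("phase1")
    phase1 = run_phase1(cohort, plan)
    em_table = phase1.pop("_em_table")
    ld = ld_matrix(em_table)
    ld.to_csv(outdir / "ld.tsv", sep="\t", index=False)
    for name, df in phase1.items():
        df.to_csv(outdir / f"phase1_{name}.tsv", sep="\t", index=False)
        manifest["rows"][name] = len(df)
    done()

    done = stage("minp")
    grid = enumerate_tests(plan)
    adj, nullset = minp_adjust(cohort, em_table, grid, R=plan.R,
                               seed=plan.seeds["minp"])
    adj.to_csv(outdir / "minp_adjusted.tsv", sep="\t", index=False)
    manifest["rows"]["minp"] = len(adj)
    done()

    done = stage("power")
    sspg_spec = next(t for t in plan.traits if t.name == "sspg")
    power_rows = [bootstrap_power(cohort, snp, sspg_spec, B=plan.B,
                                  alpha=plan.alpha,
                                  seed=plan.seeds["power"] + i)
                  for i, snp in enumerate(plan.snps)]
    pd.DataFrame(power_rows).to_csv(outdir / "power.tsv", sep="\t", index=False)
    done()

    done = stage("hapcc")
    try:
        ccset = build_case_control(cohort, plan.seeds["case_control"])
        major = em_table.haplotypes[0][0]
        second = em_table.haplotypes[1][0]
        hapcc = haplotype_case_control_or(cohort, ccset, em_table,
                                          second, major)
        (outdir / "hap_case_control.json").write_text(
            json.dumps(hapcc, indent=2))
    except ValueError as exc:
        (outdir / "hap_case_control.json").write_text(
            json.dumps({"error": str(exc)}))
    done()

    done = stage("phase2")
    phase2 = run_phase2(cohort, plan)
    phase2.to_csv(outdir / "phase2_t2d.tsv", sep="\t", index=False)
    manifest["rows"]["phase2"] = len(phase2)
    done()

    manifest["n_families"] = cohort.n_families()
    manifest["n_individuals"] = len(cohort.individuals)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
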