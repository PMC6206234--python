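"""Publication-style table rendering and the end-to-end pipeline.

Formatting conventions follow the published tables: odds ratios and CI
bounds rounded half-up to 2 decimals, p-values to 4 significant figures
with "< 0.0001" below 1e-4, and "/" for inestimable entries.  Every
output file starts with a comment header recording the seed, a config
hash and the column definitions; a JSON manifest lists every file with
a checksum.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import association as assoc
from . import haplotype as hap_mod
from . import hwe as hwe_mod
from .fprp import (
    DEFAULT_PRIORS,
    DEFAULT_THRESHOLD,
    FprpInput,
    FprpResult,
    fprp_table,
)
from .cohort import Cohort, tabulate_genotypes, write_cohort
from .simulate import SimulationConfig, simulate_cohort, write_phased_truth


# ---------------------------------------------------------------------------
# Formatting
# ---------------------------------------------------------------------------

INESTIMABLE = "/"


def fmt_num(x, decimals: int = 2) -> str:
    """Round half-up to fixed decimals (the printed-table convention)."""
    if x is None or not math.isfinite(float(x)):
        return INESTIMABLE
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_or_ci(res: assoc.OddsRatioResult) -> str:
    if not res.estimable:
        return INESTIMABLE
    if res.ci_low is None:
        return fmt_num(res.or_estimate)
    return f"{fmt_num(res.or_estimate)} ({fmt_num(res.ci_low)}-{fmt_num(res.ci_high)})"


def fmt_p(p) -> str:
    if p is None:
        return INESTIMABLE
    if p < 1e-4:
        return "< 0.0001"
    return f"{p:.4g}"


def fmt_count_pct(count, total) -> str:
    pct = 100.0 * count / total if total else 0.0
    return f"{count} ({fmt_num(pct)})"


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def demographics_table(cohort: Cohort) -> pd.DataFrame:
    """Case/control margins for age group, sex and tumor site, with the
    two-sided chi-square matching test for age and sex."""
    cases, controls = cohort.cases, cohort.controls
    nc, nt = len(cases), len(controls)
    rows = []

    def add(var, level, ccount, tcount, p=""):
        rows.append(
            {
                "variable": var,
                "level": level,
                "cases": fmt_count_pct(ccount, nc),
                "controls": fmt_count_pct(tcount, nt) if tcount is not None else "",
                "p": p,
            }
        )

    c_le = sum(1 for s in cases if s.age_months <= 18)
    t_le = sum(1 for s in controls if s.age_months <= 18)
    p_age = assoc.pearson_chi2([[c_le, nc - c_le], [t_le, nt - t_le]]).p_value
    add("age_months", "<=18", c_le, t_le, fmt_p(p_age))
    add("age_months", ">18", nc - c_le, nt - t_le)
    c_f = sum(1 for s in cases if s.sex == "F")
    t_f = sum(1 for s in controls if s.sex == "F")
    p_sex = assoc.pearson_chi2([[c_f, nc - c_f], [t_f, nt - t_f]]).p_value
    add("sex", "F", c_f, t_f, fmt_p(p_sex))
    add("sex", "M", nc - c_f, nt - t_f)
    for site in ("adrenal", "retroperitoneal", "mediastinum", "other"):
        add("site", site, sum(1 for s in cases if s.site == site), None)
    return pd.DataFrame(rows)


def hwe_table(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for snp in cohort.panel:
        counts = tabulate_genotypes(cohort, snp.rsid)
        res = hwe_mod.hwe_chi_square(counts.control_counts, snp.rsid)
        rows.append(
            {
                "rsid": snp.rsid,
                "q": f"{res.q:.4f}",
                "chi2": f"{res.chi2:.4f}",
                "p": fmt_p(res.p_value),
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows)


_MODEL_ROWS = ("het", "hom", "additive", "dominant", "recessive")


def association_table(
    cohort: Cohort, covariates: Sequence[str] = ("age_months", "sex")
) -> pd.DataFrame:
    """Genotype-model contrasts per SNP plus the combined protective-
    genotype contrast — crude and covariate-adjusted columns."""
    rows = []
    for snp in cohort.panel:
        counts = tabulate_genotypes(cohort, snp.rsid)
        for model in _MODEL_ROWS:
            crude = assoc.genotype_contrast(counts, model)
            adj = assoc.adjusted_contrast(cohort, snp.rsid, model, covariates)
            if model == "additive":
                dist_p = assoc.genotype_contrast(counts, "genotype_chi2").p_value
            else:
                try:
                    dist_p = assoc.model_pearson_p(counts, model).p_value
                except ValueError:
                    dist_p = None
            rows.append(
                {
                    "contrast": snp.rsid,
                    "model": model,
                    "dist_p": fmt_p(dist_p),
                    "crude_or_ci": fmt_or_ci(crude),
                    "crude_p": fmt_p(crude.p_value if crude.estimable else None),
                    "adj_or_ci": fmt_or_ci(adj),
                    "adj_p": fmt_p(adj.p_value if adj.estimable else None),
                }
            )
    cl, ch, tl, th = assoc.combined_group_counts(cohort)
    crude = assoc.combined_group_contrast(cl, ch, tl, th)
    adj = assoc.adjusted_contrast(cohort, assoc.COMBINED, "dominant", covariates)
    rows.append(
        {
            "contrast": "protective_4-5_vs_0-3",
            "model": "combined",
            "dist_p": fmt_p(assoc.pearson_chi2([[ch, cl], [th, tl]]).p_value),
            "crude_or_ci": fmt_or_ci(crude),
            "crude_p": fmt_p(crude.p_value if crude.estimable else None),
            "adj_or_ci": fmt_or_ci(adj),
            "adj_p": fmt_p(adj.p_value if adj.estimable else None),
        }
    )
    return pd.DataFrame(rows)


def stratified_table(
    cohort: Cohort,
    targets: Optional[Sequence[str]] = None,
    model: str = "dominant",
    covariates: Sequence[str] = ("age_months", "sex"),
) -> pd.DataFrame:
    if targets is None:
        targets = cohort.rsids + [assoc.COMBINED]
    rows = []
    for target in targets:
        for spec, res in assoc.stratified_contrasts(
            cohort, target, model, covariates=covariates
        ):
            rows.append(
                {
                    "contrast": target,
                    "stratum": f"{spec.variable}={spec.level}",
                    "adj_or_ci": fmt_or_ci(res),
                    "p": fmt_p(res.p_value if res.estimable else None),
                }
            )
    return pd.DataFrame(rows)


def fprp_report(results: Sequence[FprpResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {
            "label": res.label,
            "detectable_or": fmt_num(res.detectable_or),
            "power": f"{res.power:.3f}",
        }
        for pi, val, note in zip(res.priors, res.fprp_values, res.noteworthy):
            row[f"fprp_pi_{pi:g}"] = f"{val:.3f}" + ("*" if note else "")
        rows.append(row)
    return pd.DataFrame(rows)


def fprp_from_association(
    cohort: Cohort, alpha: float = 0.05, **kw
) -> list:
    """FPRP inputs for every significant crude genetic-model contrast."""
    inputs = []
    for snp in cohort.panel:
        counts = tabulate_genotypes(cohort, snp.rsid)
        for model in _MODEL_ROWS:
            res = assoc.genotype_contrast(counts, model)
            if res.estimable and res.p_value is not None and res.p_value < alpha:
                inputs.append(
                    FprpInput(
                        f"{snp.rsid}:{model}", res.or_estimate,
                        res.ci_low, res.ci_high, res.p_value,
                    )
                )
    cl, ch, tl, th = assoc.combined_group_counts(cohort)
    res = assoc.combined_group_contrast(cl, ch, tl, th)
    if res.estimable and res.p_value < alpha:
        inputs.append(
            FprpInput(
                "protective_4-5_vs_0-3", res.or_estimate,
                res.ci_low, res.ci_high, res.p_value,
            )
        )
    return fprp_table(inputs, **kw)


def haplotype_table(result: hap_mod.HaplotypePipelineResult) -> pd.DataFrame:
    n_case = result.case_freqs.n_chromosomes
    n_ctrl = result.control_freqs.n_chromosomes
    rows = []
    for row in result.associations:
        res = row.result
        adj = (result.adjusted or {}).get(row.haplotype)
        case_n = hap_mod._round_half_up(row.case_count)
        ctrl_n = hap_mod._round_half_up(row.control_count)
        rows.append(
            {
                "haplotype": row.haplotype,
                "case_n_pct": f"{case_n} ({fmt_num(100 * row.case_count / n_case)})",
                "control_n_pct": f"{ctrl_n} ({fmt_num(100 * row.control_count / n_ctrl)})",
                "crude_or_ci": "1.00" if row.is_reference else fmt_or_ci(res),
                "p": "" if row.is_reference else fmt_p(
                    res.p_value if res.estimable else None
                ),
                "adj_or_ci": (
                    "" if adj is None else fmt_or_ci(adj)
                ),
                "adj_p": "" if adj is None or not adj.estimable else fmt_p(adj.p_value),
            }
        )
    return pd.DataFrame(rows)


_LAYOUTS = {
    "demographics": demographics_table,
    "hwe": hwe_table,
    "association": association_table,
    "stratified": stratified_table,
    "fprp": fprp_report,
    "haplotype": haplotype_table,
}


def render_table(results, layout: str) -> str:
    """Render results for a named table layout as TSV text.

    ``results`` is the object the layout's builder expects (a Cohort for
    the cohort-level tables, FPRP results for ``fprp``, a haplotype
    pipeline result for ``haplotype``).
    """
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown table layout {layout!r}")
    return _LAYOUTS[layout](results).to_csv(sep="\t", index=False)


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    out_dir: str = "snpassoc_out"
    cohort_path: Optional[str] = None  # simulate when absent
    seed: int = 0
    n_cases: int = 313
    n_controls: int = 762
    reference_haplotype: Optional[str] = None
    priors: tuple = DEFAULT_PRIORS
    fprp_threshold: float = DEFAULT_THRESHOLD
    covariates: tuple = ("age_months", "sex")
    em_tol: float = 1e-9
    em_max_iter: int = 1000


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write(f"# columns: {', '.join(df.columns)}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dict.

    Stages: demographics, HWE QC, single-locus + combined association
    (crude and adjusted), stratified analysis, FPRP on significant crude
    findings, and the haplotype EM analysis.  One TSV per stage plus a
    JSON manifest; any stage error aborts and removes partial outputs.
    """
    from .cohort import read_cohort

    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    header = f"seed: {config.seed}\nconfig_hash: {chash}"
    written = []
    try:
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            sim = SimulationConfig(
                n_cases=config.n_cases,
                n_controls=config.n_controls,
                seed=config.seed,
            )
            cohort, truth = simulate_cohort(sim)
            write_cohort(cohort, out / "cohort.tsv", header)
            write_phased_truth(truth, out / "phased_truth.tsv", header)
            written += ["cohort.tsv", "phased_truth.tsv"]

        stage = "demographics"
        _write_tsv(demographics_table(cohort), out / "demographics.tsv", header)
        written.append("demographics.tsv")
        stage = "hwe"
        _write_tsv(hwe_table(cohort), out / "hwe.tsv", header)
        written.append("hwe.tsv")
        stage = "association"
        _write_tsv(
            association_table(cohort, config.covariates), out / "association.tsv", header
        )
        written.append("association.tsv")
        stage = "stratified"
        _write_tsv(
            stratified_table(cohort, covariates=config.covariates),
            out / "stratified.tsv", header,
        )
        written.append("stratified.tsv")
        stage = "fprp"
        results = fprp_from_association(
            cohort, priors=config.priors, threshold=config.fprp_threshold
        )
        _write_tsv(fprp_report(results), out / "fprp.tsv", header)
        written.append("fprp.tsv")
        stage = "haplotype"
        pipe = hap_mod.haplotype_pipeline(
            cohort,
            reference=config.reference_haplotype,
            tol=config.em_tol,
            max_iter=config.em_max_iter,
        )
        _write_tsv(haplotype_table(pipe), out / "haplotype.tsv", header)
        written.append("haplotype.tsv")
    except Exception as exc:
        for name in written:
            (out / name).unlink(missing_ok=True)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": chash,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "runtime_s": round(time.time() - t0, 3),
        "files": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in written
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
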