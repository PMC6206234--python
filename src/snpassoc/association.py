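"""Single-locus association under the standard genetic models.

Crude odds ratios come from 2x2 cross-product ratios with Woolf
(log-scale) confidence intervals and two-sided Wald p-values; the
additive (per-dose) model is a maximum-likelihood logistic regression
on grouped counts.  Adjusted odds ratios refit the same codings on
individual-level records with age (continuous months) and sex (male
indicator) covariates.  The protective-genotype score counts, per
subject, how many panel SNPs carry a protective genotype; the combined
analysis contrasts carriers of 4-5 protective genotypes against 0-3.

Wald and Pearson views of a table are both exposed: the genotype-row
p-values are Wald tests of log-OR, while the separate distribution
"P" column is the Pearson chi-square — the two conventions of the
published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, GenotypeCounts, Subject

#: z-quantile for 95% confidence intervals.
Z_95 = 1.959964

GENETIC_MODELS = ("het", "hom", "dominant", "recessive", "additive")

COMBINED = "combined"  # sentinel rsid for the protective-genotype score


@dataclass(frozen=True)
class OddsRatioResult:
    label: str
    or_estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    se_log_or: Optional[float]
    p_value: Optional[float]
    counts_used: tuple = ()
    estimable: bool = True

    @classmethod
    def inestimable(cls, label: str, counts=()) -> "OddsRatioResult":
        return cls(label, None, None, None, None, None, tuple(counts), False)


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class LogisticFit:
    names: tuple
    coef: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    converged: bool
    iterations: int

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def wald_or(self, name: str, label: str = "") -> OddsRatioResult:
        i = self.names.index(name)
        b = float(self.coef[i])
        se = self.se(name)
        p = 2 * float(stats.norm.sf(abs(b) / se))
        return OddsRatioResult(
            label or name,
            float(np.exp(b)),
            float(np.exp(b - Z_95 * se)),
            float(np.exp(b + Z_95 * se)),
            se,
            p,
        )


def two_by_two_or(a, b, c, d, label: str = "", haldane: bool = False) -> OddsRatioResult:
    """Odds ratio for a 2x2 table: a/b exposed/unexposed cases, c/d controls.

    Woolf CI on the log scale, two-sided Wald p.  Any zero cell yields an
    inestimable result unless the Haldane-Anscombe +0.5 correction is on.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in 2x2 table {cells}")
    if any(x == 0 for x in cells):
        if not haldane:
            return OddsRatioResult.inestimable(label, cells)
        a, b, c, d = (x + 0.5 for x in cells)
    with np.errstate(over="ignore"):
        log_or = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        p = 2 * float(stats.norm.sf(abs(log_or) / se))
        return OddsRatioResult(
        label,
        float(np.exp(log_or)),
        float(np.exp(log_or - Z_95 * se)),
        float(np.exp(log_or + Z_95 * se)),
        float(se),
        p,
        cells,
    )


def pearson_chi2(table) -> Chi2Result:
    """Classical Pearson chi-square for an r x k count table (no correction)."""
    arr = np.asarray(table, dtype=float)
    if arr.min() < 0:
        raise ValueError("negative counts")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return Chi2Result(float(chi2), int(df), float(p))


# ---------------------------------------------------------------------------
# Logistic regression (ML via iteratively reweighted least squares)
# ---------------------------------------------------------------------------

def fit_logistic(
    X,
    y,
    weights=None,
    names: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression, grouped or individual rows.

    ``weights`` are replicate (frequency) weights, so grouped count data
    and the equivalent row-expanded data give identical estimates.
    Covariance is the inverse observed information.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix not full rank")
    yy = y if w is None else y[w > 0]
    if yy.size == 0 or yy.min() == yy.max():
        raise ValueError("need at least one case and one control")
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    res = model.fit(maxiter=max_iter, tol=tol)
    coef = np.asarray(res.params, dtype=float)
    if np.abs(coef).max() > 15:
        raise ValueError("apparent complete separation (|coef| > 15)")
    if not res.converged:
        raise ValueError(f"logistic fit failed to converge in {max_iter} iterations")
    return LogisticFit(
        names=tuple(names),
        coef=coef,
        cov=np.asarray(res.cov_params(), dtype=float),
        log_likelihood=float(res.llf),
        converged=bool(res.converged),
        iterations=int(getattr(res, "fit_history", {}).get("iteration", max_iter) or 0),
    )


# ---------------------------------------------------------------------------
# Genetic-model contrasts
# ---------------------------------------------------------------------------

def _model_2x2(counts: GenotypeCounts, model: str):
    n0, n1, n2 = counts.case_counts
    m0, m1, m2 = counts.control_counts
    if model == "het":
        return n1, n0, m1, m0
    if model == "hom":
        return n2, n0, m2, m0
    if model == "dominant":
        return n1 + n2, n0, m1 + m2, m0
    if model == "recessive":
        return n2, n0 + n1, m2, m0 + m1
    raise ValueError(f"unknown 2x2 genetic model {model!r}")


def genotype_contrast(counts: GenotypeCounts, model: str, haldane: bool = False):
    """Per-SNP contrast under a genetic model.

    het/hom/dominant/recessive collapse to a 2x2 odds ratio; additive is
    the exponentiated dose coefficient of a grouped logistic fit;
    genotype_chi2 is the 2-df Pearson test over the 3x2 table.
    """
    label = f"{counts.rsid}:{model}"
    if model == "genotype_chi2":
        return pearson_chi2([counts.case_counts, counts.control_counts])
    if model == "additive":
        dose = [0.0, 1.0, 2.0, 0.0, 1.0, 2.0]
        y = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        w = list(counts.case_counts) + list(counts.control_counts)
        fit = fit_logistic(np.array(dose)[:, None], y, weights=w, names=["dose"])
        res = fit.wald_or("dose", label)
        return OddsRatioResult(
            label, res.or_estimate, res.ci_low, res.ci_high, res.se_log_or,
            res.p_value, tuple(w),
        )
    return two_by_two_or(*_model_2x2(counts, model), label=label, haldane=haldane)


def model_pearson_p(counts: GenotypeCounts, model: str) -> Chi2Result:
    """Pearson chi-square of the genotype distribution under a model's
    collapsing (the distribution "P" column convention)."""
    if model in ("additive", "genotype_chi2"):
        return pearson_chi2([counts.case_counts, counts.control_counts])
    a, b, c, d = _model_2x2(counts, model)
    return pearson_chi2([[a, b], [c, d]])


# ---------------------------------------------------------------------------
# Individual-level (adjusted) contrasts
# ---------------------------------------------------------------------------

def _genotype_coding(dose: int, model: str) -> Optional[float]:
    """Model coding for a dose; None drops the subject (het/hom contrasts)."""
    if model == "het":
        return {0: 0.0, 1: 1.0, 2: None}[dose]
    if model == "hom":
        return {0: 0.0, 1: None, 2: 1.0}[dose]
    if model == "dominant":
        return 1.0 if dose >= 1 else 0.0
    if model == "recessive":
        return 1.0 if dose == 2 else 0.0
    if model == "additive":
        return float(dose)
    raise ValueError(f"unknown genetic model {model!r}")


def _exposure_value(subj: Subject, cohort: Cohort, target: str, model: str):
    """Coded exposure for a subject, or None to exclude the subject."""
    if target == COMBINED:
        score = protective_genotype_count(subj, cohort.panel)
        if score is None:
            return None
        return 1.0 if score >= 4 else 0.0
    dose = subj.genotypes.get(target)
    if dose is None:
        return None
    return _genotype_coding(dose, model)


def adjusted_contrast(
    cohort: Cohort,
    target: str,
    model: str = "dominant",
    covariates: Sequence[str] = ("age_months", "sex"),
    subjects: Optional[Sequence[Subject]] = None,
    label: str = "",
) -> OddsRatioResult:
    """Covariate-adjusted odds ratio from an individual-level logistic fit.

    ``target`` is an rsid or the ``combined`` protective-score contrast
    (4-5 vs 0-3).  With no covariates this reduces to the crude contrast
    on tabulated counts.  Age enters as continuous months; sex as a male
    indicator.
    """
    if subjects is None:
        subjects = cohort.subjects
    rows, ys = [], []
    for subj in subjects:
        x = _exposure_value(subj, cohort, target, model)
        if x is None:
            continue
        row = [x]
        for cov in covariates:
            if cov == "age_months":
                row.append(subj.age_months)
            elif cov == "sex":
                row.append(1.0 if subj.sex == "M" else 0.0)
            else:
                raise ValueError(f"unknown covariate {cov!r}")
        rows.append(row)
        ys.append(1.0 if subj.is_case else 0.0)
    label = label or f"{target}:{model}:adj[{','.join(covariates)}]"
    if not rows or len(set(ys)) < 2:
        return OddsRatioResult.inestimable(label)
    names = ["exposure"] + list(covariates)
    try:
        fit = fit_logistic(np.array(rows), ys, names=names)
    except (ValueError, np.linalg.LinAlgError):
        return OddsRatioResult.inestimable(label)
    return fit.wald_or("exposure", label)


# ---------------------------------------------------------------------------
# Protective-genotype scoring and the combined contrast
# ---------------------------------------------------------------------------

def protective_genotype_count(subject: Subject, panel) -> Optional[int]:
    """Number of panel SNPs (0..len(panel)) at a protective genotype.

    Returns None (subject excluded) if any panel genotype is missing:
    the score is undefined under missingness.
    """
    score = 0
    for snp in panel:
        dose = subject.genotypes.get(snp.rsid)
        if dose is None:
            return None
        if dose in snp.protective_doses:
            score += 1
    return score


def combined_group_counts(cohort: Cohort, cut: int = 4):
    """(case_low, case_high, control_low, control_high) for score >= cut."""
    cl = ch = tl = th = 0
    for subj in cohort.subjects:
        score = protective_genotype_count(subj, cohort.panel)
        if score is None:
            continue
        high = score >= cut
        if subj.is_case:
            ch, cl = ch + high, cl + (not high)
        else:
            th, tl = th + high, tl + (not high)
    return cl, ch, tl, th


def combined_group_contrast(
    case_low, case_high, control_low, control_high, haldane: bool = False
) -> OddsRatioResult:
    """Odds ratio for carrying 4-5 vs 0-3 protective genotypes."""
    return two_by_two_or(
        case_high, case_low, control_high, control_low,
        label="combined:4-5_vs_0-3", haldane=haldane,
    )


# ---------------------------------------------------------------------------
# Stratified analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumSpec:
    variable: str  # "age_months" | "sex" | "site"
    level: str  # "le18"/"gt18", "F"/"M", or a site name

    def __post_init__(self):
        valid = {
            "age_months": {"le18", "gt18"},
            "sex": {"F", "M"},
            "site": {"adrenal", "retroperitoneal", "mediastinum", "other"},
        }
        if self.variable not in valid:
            raise ValueError(f"unknown stratification variable {self.variable!r}")
        if self.level not in valid[self.variable]:
            raise ValueError(f"invalid level {self.level!r} for {self.variable}")

    def members(self, subjects) -> list:
        if self.variable == "age_months":
            if self.level == "le18":
                return [s for s in subjects if s.age_months <= 18]
            return [s for s in subjects if s.age_months > 18]
        if self.variable == "sex":
            return [s for s in subjects if s.sex == self.level]
        # site strata: site-specific cases against ALL controls
        return [s for s in subjects if (not s.is_case) or s.site == self.level]


DEFAULT_STRATA = tuple(
    StratumSpec(var, lvl)
    for var, lvl in [
        ("age_months", "le18"), ("age_months", "gt18"),
        ("sex", "F"), ("sex", "M"),
        ("site", "adrenal"), ("site", "retroperitoneal"),
        ("site", "mediastinum"), ("site", "other"),
    ]
)


def stratified_contrasts(
    cohort: Cohort,
    target: str,
    model: str = "dominant",
    strata: Sequence[StratumSpec] = DEFAULT_STRATA,
    covariates: Sequence[str] = ("age_months", "sex"),
) -> list:
    """One adjusted contrast per stratum; degenerate strata yield
    inestimable rows rather than a crash."""
    out = []
    for spec in strata:
        members = spec.members(cohort.subjects)
        label = f"{target}:{model}:{spec.variable}={spec.level}"
        res = adjusted_contrast(
            cohort, target, model, covariates, subjects=members, label=label
        )
        out.append((spec, res))
    return out
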