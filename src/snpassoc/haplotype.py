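"""EM estimation of multilocus haplotype frequencies from unphased
genotypes, and haplotype-level case-control association.

Phase is unobserved: a subject heterozygous at h loci is compatible
with 2^(h-1) unordered haplotype pairs.  Under random mating
(Hardy-Weinberg at the haplotype level) the standard EM iteration
assigns each subject posterior weights over its compatible pairs
proportional to theta_h1 * theta_h2 (doubled for heterozygous pairs)
and re-estimates each frequency as its expected chromosome count over
2N.  The log-likelihood is non-decreasing every iteration and is
asserted to be so.

Association contrasts each haplotype's expected chromosome counts
against a reference haplotype in a 2x2 odds ratio; haplotypes absent
from either group are inestimable (rendered "/" in reports).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .association import OddsRatioResult, fit_logistic, two_by_two_or
from .cohort import Cohort, SnpDef


def haplotype_space(panel: Sequence[SnpDef]) -> list:
    """All 2^L haplotype strings over the panel alleles, lexicographic."""
    alleles = [(s.common_allele, s.variant_allele) for s in panel]
    return sorted("".join(h) for h in itertools.product(*alleles))


def haplotype_dose_vector(hap: str, panel: Sequence[SnpDef]) -> tuple:
    """Per-locus variant-allele indicator (0/1) of a haplotype string."""
    out = []
    for ch, snp in zip(hap, panel):
        if ch == snp.variant_allele:
            out.append(1)
        elif ch == snp.common_allele:
            out.append(0)
        else:
            raise ValueError(f"allele {ch!r} invalid at {snp.rsid}")
    return tuple(out)


def enumerate_pairs(doses: Sequence[int], panel: Sequence[SnpDef]) -> list:
    """All unordered haplotype pairs consistent with a dose vector.

    A genotype with h heterozygous loci has max(1, 2^(h-1)) compatible
    unordered pairs; the first heterozygous locus is fixed on the first
    haplotype to avoid double counting.
    """
    if len(doses) != len(panel):
        raise ValueError("dose vector length != panel size")
    het = [i for i, d in enumerate(doses) if d == 1]
    base1 = [d // 2 for d in doses]  # 1 iff dose==2
    base2 = list(base1)
    pairs = []
    if not het:
        hap = "".join(
            s.variant_allele if b else s.common_allele for b, s in zip(base1, panel)
        )
        return [(hap, hap)]
    first, rest = het[0], het[1:]
    for bits in itertools.product((0, 1), repeat=len(rest)):
        h1, h2 = list(base1), list(base2)
        h1[first], h2[first] = 1, 0
        for locus, bit in zip(rest, bits):
            h1[locus], h2[locus] = bit, 1 - bit
        s1 = "".join(s.variant_allele if b else s.common_allele for b, s in zip(h1, panel))
        s2 = "".join(s.variant_allele if b else s.common_allele for b, s in zip(h2, panel))
        pairs.append((min(s1, s2), max(s1, s2)))
    return pairs


@dataclass(frozen=True)
class HaplotypeFrequencySet:
    group: str
    n_chromosomes: int
    freqs: dict  # haplotype string -> frequency, lexicographic keys
    log_likelihood: float
    iterations: int
    converged: bool


def _allele_freq_init(patterns, counts, L):
    """Product-of-allele-frequencies initialization (linkage equilibrium)."""
    n = counts.sum()
    dose_sums = (patterns * counts[:, None]).sum(axis=0)
    q = np.clip(dose_sums / (2 * n), 1e-6, 1 - 1e-6)
    return q


def em_estimate(
    genotypes,
    panel: Sequence[SnpDef],
    tol: float = 1e-9,
    max_iter: int = 1000,
    init: Optional[dict] = None,
    restarts: int = 0,
    seed: Optional[int] = None,
    group: str = "",
) -> HaplotypeFrequencySet:
    """EM haplotype frequency estimation from unphased dose vectors.

    ``genotypes`` is an iterable of length-L dose vectors (no missing
    entries).  Convergence when the log-likelihood improves by less than
    ``tol``; optional seeded random restarts guard against local maxima
    (the best log-likelihood wins).
    """
    G = np.asarray(list(genotypes), dtype=int)
    if G.ndim != 2 or G.shape[0] == 0:
        raise ValueError("need at least one complete genotype")
    L = len(panel)
    n = G.shape[0]
    haps = haplotype_space(panel)
    hap_index = {h: i for i, h in enumerate(haps)}

    patterns, counts = np.unique(G, axis=0, return_counts=True)
    counts = counts.astype(float)
    # support sets: per distinct pattern, index pairs into the haplotype space
    support = []
    for pat in patterns:
        pairs = enumerate_pairs(pat, panel)
        i1 = np.array([hap_index[a] for a, _ in pairs])
        i2 = np.array([hap_index[b] for _, b in pairs])
        mult = np.where(i1 != i2, 2.0, 1.0)
        support.append((i1, i2, mult))

    hap_doses = np.array([haplotype_dose_vector(h, panel) for h in haps])

    def run(theta0):
        theta = theta0.copy()
        prev_ll = -np.inf
        for it in range(1, max_iter + 1):
            expected = np.zeros(len(haps))
            ll = 0.0
            for (i1, i2, mult), cnt in zip(support, counts):
                w = mult * theta[i1] * theta[i2]
                tot = w.sum()
                if tot <= 0:
                    # degenerate initialization: restart uniformly on support
                    w = mult.copy()
                    tot = w.sum()
                    ll += cnt * -np.inf
                else:
                    ll += cnt * np.log(tot)
                post = cnt * w / tot
                np.add.at(expected, i1, post)
                np.add.at(expected, i2, post)
            theta = expected / (2 * n)
            if np.isfinite(ll) and ll < prev_ll - 1e-7:
                raise AssertionError("EM log-likelihood decreased")
            if np.isfinite(ll) and ll - prev_ll < tol:
                return theta, ll, it, True
            prev_ll = ll
        return theta, prev_ll, max_iter, False

    inits = []
    if init is not None:
        theta0 = np.zeros(len(haps))
        for h, f in init.items():
            theta0[hap_index[h]] = f
        inits.append(theta0 / theta0.sum())
    else:
        q = _allele_freq_init(patterns, counts, L)
        theta0 = np.prod(np.where(hap_doses == 1, q, 1 - q), axis=1)
        inits.append(theta0 / theta0.sum())
    if restarts:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            inits.append(rng.dirichlet(np.ones(len(haps))))

    best = None
    for theta0 in inits:
        theta, ll, its, conv = run(theta0)
        if best is None or ll > best[1] + 1e-12:
            best = (theta, ll, its, conv)
    theta, ll, its, conv = best
    freqs = {h: float(theta[i]) for h, i in hap_index.items()}
    return HaplotypeFrequencySet(group, 2 * n, freqs, float(ll), its, conv)


def expected_counts(freqs: HaplotypeFrequencySet) -> dict:
    """Expected chromosome counts theta_h * 2N per haplotype."""
    return {h: f * freqs.n_chromosomes for h, f in freqs.freqs.items()}


@dataclass(frozen=True)
class HaplotypeAssociation:
    haplotype: str
    case_count: float
    control_count: float
    result: OddsRatioResult
    is_reference: bool = False

    @property
    def estimable(self) -> bool:
        return self.result.estimable


def haplotype_association(
    case_counts: dict,
    control_counts: dict,
    reference: str,
    haldane: bool = False,
) -> list:
    """Per-haplotype 2x2 odds ratios against a reference haplotype.

    Counts may be unrounded expected chromosome counts.  A haplotype
    with a zero count in either group is inestimable; the reference row
    carries OR 1.00 by definition.
    """
    if case_counts.get(reference, 0) <= 0 or control_counts.get(reference, 0) <= 0:
        raise ValueError(f"reference haplotype {reference!r} absent from a group")
    ref_case = case_counts[reference]
    ref_ctrl = control_counts[reference]
    out = []
    for hap in sorted(set(case_counts) | set(control_counts)):
        ca = case_counts.get(hap, 0.0)
        co = control_counts.get(hap, 0.0)
        if hap == reference:
            res = OddsRatioResult(f"{hap}:reference", 1.0, None, None, None, None)
            out.append(HaplotypeAssociation(hap, ca, co, res, is_reference=True))
            continue
        label = f"{hap}_vs_{reference}"
        # estimability follows the displayed integer counts: a group whose
        # expected count rounds to zero cannot support an odds ratio
        if not haldane and (_round_half_up(ca) == 0 or _round_half_up(co) == 0):
            res = OddsRatioResult.inestimable(label, (ca, ref_case, co, ref_ctrl))
        else:
            res = two_by_two_or(ca, ref_case, co, ref_ctrl, label=label,
                                haldane=haldane)
        out.append(HaplotypeAssociation(hap, ca, co, res))
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class HaplotypePipelineResult:
    case_freqs: HaplotypeFrequencySet
    control_freqs: HaplotypeFrequencySet
    associations: list  # HaplotypeAssociation rows
    adjusted: Optional[dict] = None  # haplotype -> OddsRatioResult


def _complete_dose_vectors(subjects, rsids):
    out = []
    for subj in subjects:
        doses = [subj.genotypes.get(r) for r in rsids]
        if any(d is None for d in doses):
            continue
        out.append(doses)
    return out


def haplotype_pipeline(
    cohort: Cohort,
    reference: Optional[str] = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
    restarts: int = 0,
    seed: Optional[int] = None,
    printed_counts: bool = False,
    adjusted: bool = False,
    min_expected: float = 0.5,
) -> HaplotypePipelineResult:
    """End-to-end haplotype analysis of a cohort (complete-case).

    EM runs separately on cases and controls.  Association uses
    unrounded expected counts by default; ``printed_counts`` rounds
    half-up to integers first (the published-table convention).
    Haplotypes whose expected count is below ``min_expected`` in both
    groups are suppressed from the report.  ``adjusted`` adds
    age/sex-adjusted odds ratios from posterior haplotype dosages
    (pooled-EM posteriors, chromosome-expanded logistic fit).
    """
    rsids = cohort.rsids
    case_doses = _complete_dose_vectors(cohort.cases, rsids)
    ctrl_doses = _complete_dose_vectors(cohort.controls, rsids)
    kw = dict(tol=tol, max_iter=max_iter, restarts=restarts, seed=seed)
    case_f = em_estimate(case_doses, cohort.panel, group="case", **kw)
    ctrl_f = em_estimate(ctrl_doses, cohort.panel, group="control", **kw)
    case_counts = expected_counts(case_f)
    ctrl_counts = expected_counts(ctrl_f)
    keep = {
        h
        for h in case_counts
        if case_counts[h] >= min_expected or ctrl_counts[h] >= min_expected
    }
    if reference is None:
        reference = max(ctrl_counts, key=ctrl_counts.get)
    keep.add(reference)
    case_counts = {h: c for h, c in case_counts.items() if h in keep}
    ctrl_counts = {h: c for h, c in ctrl_counts.items() if h in keep}
    if printed_counts:
        case_counts = {h: _round_half_up(c) for h, c in case_counts.items()}
        ctrl_counts = {h: _round_half_up(c) for h, c in ctrl_counts.items()}
    assoc = haplotype_association(case_counts, ctrl_counts, reference)
    adj = None
    if adjusted:
        adj = _adjusted_haplotype_ors(cohort, reference, keep, kw)
    return HaplotypePipelineResult(case_f, ctrl_f, assoc, adj)


def _posterior_dosages(doses, panel, theta_by_hap):
    """Expected copies of each haplotype for one subject's genotype."""
    pairs = enumerate_pairs(doses, panel)
    weights = []
    for h1, h2 in pairs:
        w = theta_by_hap.get(h1, 0.0) * theta_by_hap.get(h2, 0.0)
        if h1 != h2:
            w *= 2
        weights.append(w)
    tot = sum(weights)
    if tot <= 0:
        weights = [2.0 if h1 != h2 else 1.0 for h1, h2 in pairs]
        tot = sum(weights)
    dos = {}
    for (h1, h2), w in zip(pairs, weights):
        dos[h1] = dos.get(h1, 0.0) + w / tot
        dos[h2] = dos.get(h2, 0.0) + w / tot
    return dos


def _adjusted_haplotype_ors(cohort, reference, keep, em_kw):
    """Age/sex-adjusted OR per haplotype vs the reference.

    Pooled-EM posterior dosages expand each subject into weighted
    chromosome rows (haplotype h vs reference), so with no covariates
    the fit reduces to the crude expected-count 2x2.
    """
    rsids = cohort.rsids
    rows = []  # (subject, dosages)
    all_doses = []
    subs = []
    for subj in cohort.subjects:
        doses = [subj.genotypes.get(r) for r in rsids]
        if any(d is None for d in doses):
            continue
        subs.append(subj)
        all_doses.append(doses)
    pooled = em_estimate(all_doses, cohort.panel, group="pooled", **em_kw)
    dosages = [
        _posterior_dosages(d, cohort.panel, pooled.freqs) for d in all_doses
    ]
    out = {}
    for hap in sorted(keep):
        if hap == reference:
            continue
        X, y, w = [], [], []
        for subj, dos in zip(subs, dosages):
            dh = dos.get(hap, 0.0)
            dr = dos.get(reference, 0.0)
            for ind, wt in ((1.0, dh), (0.0, dr)):
                if wt > 0:
                    X.append([ind, subj.age_months, 1.0 if subj.sex == "M" else 0.0])
                    y.append(1.0 if subj.is_case else 0.0)
                    w.append(wt)
        label = f"{hap}_vs_{reference}:adj"
        try:
            fit = fit_logistic(np.array(X), y, weights=w,
                               names=["hap", "age_months", "sex"])
            out[hap] = fit.wald_or("hap", label)
        except (ValueError, np.linalg.LinAlgError):
            out[hap] = OddsRatioResult.inestimable(label)
    return out
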