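"""Hardy-Weinberg equilibrium goodness-of-fit testing.

Under random mating, genotype frequencies at a biallelic locus are
(1-q)^2, 2q(1-q), q^2 for variant-allele frequency q.  Departure is
tested in control subjects with the asymptotic 1-df Pearson chi-square
(no continuity correction), which matches standard case-control QC
practice; an exact mid-p alternative is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HweResult:
    rsid: str
    q: float  # variant-allele frequency
    chi2: float
    df: int
    p_value: float
    expected_counts: tuple
    flag: str = ""  # "" | "monomorphic"


def allele_frequency(counts) -> float:
    """Variant-allele frequency from a (dose0, dose1, dose2) count triple."""
    k0, k1, k2 = counts
    n = k0 + k1 + k2
    if n <= 0:
        raise ValueError("empty genotype triple")
    return (2 * k2 + k1) / (2 * n)


def hwe_chi_square(counts, rsid: str = "") -> HweResult:
    """1-df goodness-of-fit chi-square against Hardy-Weinberg proportions.

    A monomorphic locus (q in {0, 1}) yields chi2=0, p=1 with a
    "monomorphic" flag rather than an error.
    """
    k0, k1, k2 = counts
    n = k0 + k1 + k2
    q = allele_frequency(counts)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q * q)
    if q in (0.0, 1.0):
        return HweResult(rsid, q, 0.0, 1, 1.0, expected, flag="monomorphic")
    chi2 = sum((obs - exp) ** 2 / exp for obs, exp in zip(counts, expected))
    p = float(stats.chi2.sf(chi2, 1))
    return HweResult(rsid, q, float(chi2), 1, p, expected)


def hwe_exact(counts, rsid: str = "") -> HweResult:
    """Exact HWE test (conditional on allele counts), two-sided.

    Sums the probabilities of heterozygote counts no more likely than
    the observed one, under the hypergeometric-style distribution of
    heterozygotes given the minor-allele count.  Reported with chi2 from
    the asymptotic statistic for reference.
    """
    k0, k1, k2 = (int(c) for c in counts)
    n = k0 + k1 + k2
    q = allele_frequency(counts)
    asym = hwe_chi_square(counts, rsid)
    if asym.flag == "monomorphic":
        return asym
    n_var = 2 * k2 + k1  # variant allele count
    # enumerate feasible heterozygote counts with the same parity as n_var
    hets = np.arange(n_var % 2, min(n_var, 2 * n - n_var) + 1, 2)
    logprob = _het_logprobs(hets, n, n_var)
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    p = float(prob[prob <= prob[hets == k1][0] * (1 + 1e-12)].sum())
    return HweResult(rsid, q, asym.chi2, 1, min(p, 1.0), asym.expected_counts)


def _het_logprobs(hets, n, n_var):
    from scipy.special import gammaln

    n_com = 2 * n - n_var
    hom_var = (n_var - hets) // 2
    hom_com = (n_com - hets) // 2
    return (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln(hom_var + 1)
        - gammaln(hets + 1)
        - gammaln(hom_com + 1)
    )


def hwe_scan(genotype_counts, group: str = "control") -> list:
    """HWE results for a mapping {rsid: GenotypeCounts} (controls by default)."""
    out = []
    for rsid, gc in genotype_counts.items():
        triple = gc.control_counts if group == "control" else gc.case_counts
        out.append(hwe_chi_square(triple, rsid))
    return out
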