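"""Seeded synthetic case-control cohort generator.

Each individual draws two haplotypes independently from a configured
haplotype frequency pool (so every locus is in Hardy-Weinberg
equilibrium in the source population, and linkage disequilibrium is
induced solely by the joint haplotype frequencies).  Disease status is
Bernoulli with

    logit P(case) = baseline_logit + sum_l effect(l, genotype_l)
                    + beta_age * age_months + beta_male * male

and individuals are accumulated by rejection sampling until the exact
case and control quotas are reached, mirroring case-control ascertainment.
Defaults emulate the three-center neuroblastoma study: 313 cases, 762
controls, the published control-group haplotype frequencies over the
five-SNP LMO1 panel, dominant protective effects of odds ratio 0.6 at
four of the five SNPs, and the published age/sex/tumor-site margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import studydata
from .cohort import Cohort, SnpDef, Subject, STUDY_PANEL
from .haplotype import haplotype_dose_vector


def default_effect_model() -> dict:
    """Dominant protective log-ORs ln(0.6) at the four associated SNPs."""
    b = math.log(0.6)
    return {
        "rs110419": (b, b),
        "rs4758051": (b, b),
        "rs10840002": (b, b),
        "rs204938": (0.0, 0.0),
        "rs2168101": (b, b),
    }


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated case-control cohort.

    ``effect_model`` maps rsid -> (log-OR for dose 1, log-OR for dose 2)
    relative to dose 0.  Ages are truncated-normal in months.
    """

    n_cases: int = studydata.N_CASES
    n_controls: int = studydata.N_CONTROLS
    haplotype_freqs: dict = field(default_factory=lambda: dict(studydata.CONTROL_HAPLOTYPE_FREQS))
    effect_model: dict = field(default_factory=default_effect_model)
    baseline_logit: float = -2.0
    beta_age: float = 0.0  # per month
    beta_male: float = 0.0
    age_mean: float = studydata.AGE_MEAN_CONTROLS
    age_sd: float = studydata.AGE_SD_CONTROLS
    age_min: float = studydata.AGE_MIN
    age_max: float = studydata.AGE_MAX
    p_male: float = studydata.P_MALE_CONTROLS
    site_proportions: tuple = studydata.SITE_PROPORTIONS
    seed: int = 0
    panel: Sequence[SnpDef] = STUDY_PANEL
    max_attempts: int = 5_000_000

    def __post_init__(self):
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls == 0:
            raise ValueError("need positive group sizes")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total!r}, not 1")
        for hap in self.haplotype_freqs:
            haplotype_dose_vector(hap, self.panel)  # validates alleles/length
        for rsid in self.effect_model:
            if rsid not in {s.rsid for s in self.panel}:
                raise ValueError(f"effect for unknown SNP {rsid!r}")


@dataclass
class PhasedTruth:
    """Ground-truth transmitted haplotype pairs, for EM-recovery checks."""

    pairs: dict  # subject_id -> (hap1, hap2)

    def frequencies(self) -> dict:
        tally: dict = {}
        for h1, h2 in self.pairs.values():
            tally[h1] = tally.get(h1, 0) + 1
            tally[h2] = tally.get(h2, 0) + 1
        n = 2 * len(self.pairs)
        return {h: c / n for h, c in sorted(tally.items())}


def simulate_dose_arrays(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Vectorized core of the generator; returns per-group numpy arrays.

    Returns a dict with keys ``haps`` (haplotype list), and per group
    ("case"/"control") ``doses`` (n x L), ``hap_idx`` (n x 2), ``age``,
    ``male``.  Used directly by simulation studies that do not need
    Subject objects.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    haps = sorted(config.haplotype_freqs)
    freqs = np.array([config.haplotype_freqs[h] for h in haps])
    cum = np.cumsum(freqs)
    cum[-1] = 1.0
    D = np.array([haplotype_dose_vector(h, config.panel) for h in haps], dtype=np.int64)
    rsids = [s.rsid for s in config.panel]
    eff1 = np.array([config.effect_model.get(r, (0.0, 0.0))[0] for r in rsids])
    eff2 = np.array([config.effect_model.get(r, (0.0, 0.0))[1] for r in rsids])
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd

    need = {"case": config.n_cases, "control": config.n_controls}
    got = {
        g: {"doses": [], "hap_idx": [], "age": [], "male": []}
        for g in ("case", "control")
    }
    drawn = 0
    batch = max(1024, 2 * (config.n_cases + config.n_controls))
    while need["case"] > 0 or need["control"] > 0:
        if drawn >= config.max_attempts:
            raise RuntimeError(
                f"could not reach group sizes within {config.max_attempts} draws"
            )
        m = min(batch, config.max_attempts - drawn)
        drawn += m
        hap_idx = np.searchsorted(cum, rng.random((m, 2)))
        doses = D[hap_idx[:, 0]] + D[hap_idx[:, 1]]
        age = stats.truncnorm.ppf(
            rng.random(m), a, b, loc=config.age_mean, scale=config.age_sd
        )
        male = rng.random(m) < config.p_male
        logit = (
            config.baseline_logit
            + (doses == 1) @ eff1
            + (doses == 2) @ eff2
            + config.beta_age * age
            + config.beta_male * male
        )
        is_case = rng.random(m) < 1.0 / (1.0 + np.exp(-logit))
        for g, mask in (("case", is_case), ("control", ~is_case)):
            if need[g] <= 0:
                continue
            idx = np.flatnonzero(mask)[: need[g]]
            got[g]["doses"].append(doses[idx])
            got[g]["hap_idx"].append(hap_idx[idx])
            got[g]["age"].append(age[idx])
            got[g]["male"].append(male[idx])
            need[g] -= len(idx)
    out = {"haps": haps}
    for g in ("case", "control"):
        out[g] = {
            k: (np.concatenate(v) if v else np.empty((0,), dtype=float))
            for k, v in got[g].items()
        }
    return out


def simulate_cohort(config: SimulationConfig):
    """Simulate a cohort; returns (Cohort, PhasedTruth).

    Deterministic under a fixed config seed.  Tumor sites are assigned
    to cases multinomially with the configured proportions, with no
    dependence on genotype.
    """
    rng = np.random.default_rng(config.seed)
    arrays = simulate_dose_arrays(config, rng)
    haps = arrays["haps"]
    rsids = [s.rsid for s in config.panel]
    site_p = np.asarray(config.site_proportions, dtype=float)
    site_p = site_p / site_p.sum()
    site_names = ("adrenal", "retroperitoneal", "mediastinum", "other")

    subjects, pairs = [], {}
    counter = 0
    for group in ("case", "control"):
        arr = arrays[group]
        n = len(arr["age"])
        sites = (
            rng.choice(len(site_names), size=n, p=site_p)
            if group == "case"
            else None
        )
        for i in range(n):
            counter += 1
            sid = f"S{counter:06d}"
            subjects.append(
                Subject(
                    subject_id=sid,
                    status=group,
                    age_months=float(arr["age"][i]),
                    sex="M" if arr["male"][i] else "F",
                    site=site_names[sites[i]] if group == "case" else "NA",
                    genotypes={r: int(d) for r, d in zip(rsids, arr["doses"][i])},
                )
            )
            h1, h2 = arr["hap_idx"][i]
            pairs[sid] = (haps[int(h1)], haps[int(h2)])
    return Cohort(panel=list(config.panel), subjects=subjects), PhasedTruth(pairs)


def simulate_null_cohort(n_cases: int, n_controls: int, seed: int) -> Cohort:
    """Cohort with all genetic effects zero (type-I-error studies)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("need at least one case and one control")
    config = SimulationConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        effect_model={},
        seed=seed,
    )
    cohort, _ = simulate_cohort(config)
    return cohort


def write_phased_truth(truth: PhasedTruth, path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("subject_id\thap1\thap2\n")
        for sid, (h1, h2) in truth.pairs.items():
            fh.write(f"{sid}\t{h1}\t{h2}\n")
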