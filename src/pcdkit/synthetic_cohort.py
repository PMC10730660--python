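"""Seeded synthetic neonatal cohorts with the structure the analysis assumes.

The study's raw newborn data is access-restricted, so every downstream
module is exercised on generated cohorts that reproduce the *statistical*
structure of the real one:

* **Genotypes** — for each newborn and each pathogenic variant, two alleles
  are drawn independently Bernoulli(AF) (Hardy–Weinberg with independence
  across variants).  True status is patient (≥2 pathogenic alleles), carrier
  (exactly 1) or negative.  Default AFs put the three hotspot variants at
  their published cohort frequencies (1/239, 1/1,275, 1/1,322) and spread
  the remaining mass evenly over the other panel sites so that the summed
  allele frequency matches a configured total carrier frequency of 1/66
  (carrier frequency ≈ 2·Σ AF for rare alleles).

* **Free carnitine (C0)** — lognormal per class (C0 is positive and
  right-skewed); the class *medians* default to the published subgroup
  means: patients 5.27 µmol/L, low-C0 carriers 6.47 µmol/L, with the
  negative-class center at 25 µmol/L (not published; chosen well above the
  10 µmol/L cutoff) and a log-scale sd of 0.25.  Most carriers draw from
  the negative distribution; a configurable fraction (default 10/72, the
  reported share of carriers with low C0) draws from the low-carrier
  distribution.

* **Maternal-transfer masking** — a fraction of true patients (default
  2/17, the reported screening false-negative share) draws its *initial*
  C0 from the negative-class distribution, emulating transplacental
  carnitine normalizing the newborn's first measurement.  Their second-tier
  C0 reverts to the patient distribution once the maternal supply clears.

* **Second tier** — class-wise multiplicative drift toward the published
  second-tier means (patients 5.27 → 4.28, low-C0 carriers 6.47 → 9.01).

Everything is driven by a single ``numpy`` Generator, so a fixed seed gives
a bit-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel_screening import DEFAULT_CUTOFF, NewbornRecord, default_panel_sites
from .prevalence import (
    CohortCounts,
    AlleleCount,
    PriorSpec,
    JEFFREYS,
    bayesian_prevalence,
    hw_prevalence,
    permutation_prevalence,
)

#: Published cohort allele frequencies of the three hotspot variants.
HOTSPOT_AFS = {
    "c.1400C>G": 1 / 239,
    "c.51C>G": 1 / 1275,
    "c.760C>T": 1 / 1322,
}

MAX_AF = 0.05  # disease-allele regime; higher AFs reject at validation


def default_variant_afs(total_carrier_frequency: float = 1 / 66) -> dict[str, float]:
    """Hotspots at their published AFs; remaining panel sites share the rest.

    The summed AF is total_carrier_frequency / 2, so that the generated
    carrier fraction approximates the configured carrier frequency.
    """
    total_af = total_carrier_frequency / 2.0
    afs = dict(HOTSPOT_AFS)
    rest = [s for s in default_panel_sites() if s not in afs]
    remainder = total_af - sum(afs.values())
    if remainder <= 0:
        raise ValueError("total carrier frequency too small for the hotspot AFs")
    for site in rest:
        afs[site] = remainder / len(rest)
    return afs


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator (units: µmol/L for C0)."""

    n_newborns: int = 17_864
    female_fraction: float = 7_333 / 17_864
    variant_afs: Mapping[str, float] = field(default_factory=default_variant_afs)
    panel_sites: tuple[str, ...] = ()
    c0_medians: Mapping[str, float] = field(
        default_factory=lambda: {"patient": 5.27, "carrier_low": 6.47, "negative": 25.0}
    )
    c0_sigma: float = 0.25
    carrier_low_fraction: float = 10 / 72
    maternal_mask_rate: float = 2 / 17
    second_tier_ratio: Mapping[str, float] = field(
        default_factory=lambda: {
            "patient": 4.28 / 5.27,
            "carrier_low": 9.01 / 6.47,
            "negative": 1.0,
        }
    )
    treated_c0_medians: Mapping[str, float] = field(
        default_factory=lambda: {"patient": 20.21, "carrier": 18.61}
    )
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.n_newborns <= 0:
            raise ValueError("n_newborns must be positive")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        for v, af in self.variant_afs.items():
            if not 0 < af < MAX_AF:
                raise ValueError(f"AF of {v} outside (0, {MAX_AF})")
        if not 0 <= self.maternal_mask_rate < 1:
            raise ValueError("maternal_mask_rate must lie in [0, 1)")
        if not 0 <= self.carrier_low_fraction <= 1:
            raise ValueError("carrier_low_fraction must lie in [0, 1]")
        if self.c0_sigma < 0:
            raise ValueError("c0_sigma must be non-negative")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not self.panel_sites:
            object.__setattr__(self, "panel_sites", tuple(default_panel_sites()))

    @property
    def total_af(self) -> float:
        return float(sum(self.variant_afs.values()))

    @property
    def true_prevalence(self) -> float:
        """(Σ AF)², the nominal random-mating biallelic rate."""
        return self.total_af**2


def _rng(seed: np.random.Generator | int | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(
    config: SimulationConfig, seed: np.random.Generator | int | None = 0
) -> pd.DataFrame:
    """Draw per-newborn genotypes; columns: id, sex, one per variant,
    total_alleles, panel_alleles, status."""
    rng = _rng(seed)
    n = config.n_newborns
    variants = list(config.variant_afs)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    geno = np.column_stack(
        [rng.binomial(2, config.variant_afs[v], size=n) for v in variants]
    ).astype(np.int8)
    total = geno.sum(axis=1).astype(np.int16)
    panel_cols = [i for i, v in enumerate(variants) if v in set(config.panel_sites)]
    panel = geno[:, panel_cols].sum(axis=1).astype(np.int16) if panel_cols else np.zeros(
        n, dtype=np.int16
    )
    status = np.where(total >= 2, "patient", np.where(total == 1, "carrier", "negative"))
    df = pd.DataFrame(geno, columns=variants)
    df.insert(0, "sex", sex)
    df.insert(0, "id", [f"N{i:07d}" for i in range(n)])
    df["total_alleles"] = total
    df["panel_alleles"] = panel
    df["status"] = status
    return df


def _lognormal(
    rng: np.random.Generator, median: float, sigma: float, size: int
) -> np.ndarray:
    if median <= 0:
        raise ValueError("lognormal median must be positive")
    return np.exp(math.log(median) + sigma * rng.standard_normal(size))


def simulate_c0(
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    seed: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Attach initial and second-tier C0 draws to a genotype table.

    Returns the newborn screening table: id, true_status, c0_initial,
    c0_second, panel_hits, total_plp_alleles.
    """
    rng = _rng(seed)
    n = len(genotypes)
    status = genotypes["status"].to_numpy()
    med = config.c0_medians
    ratio = config.second_tier_ratio
    sigma = config.c0_sigma

    # sampling class per newborn: patient / masked patient / low carrier /
    # negative-like (plain carriers and true negatives share a distribution)
    is_patient = status == "patient"
    is_carrier = status == "carrier"
    masked = is_patient & (rng.random(n) < config.maternal_mask_rate)
    low_carrier = is_carrier & (rng.random(n) < config.carrier_low_fraction)

    c0_initial = _lognormal(rng, med["negative"], sigma, n)
    c0_initial[is_patient & ~masked] = _lognormal(
        rng, med["patient"], sigma, int((is_patient & ~masked).sum())
    )
    c0_initial[low_carrier] = _lognormal(
        rng, med["carrier_low"], sigma, int(low_carrier.sum())
    )

    # second tier: maternal carnitine has cleared, so masked patients revert
    # to the patient distribution at its second-tier location
    c0_second = _lognormal(rng, med["negative"] * ratio["negative"], sigma, n)
    patient_second_median = med["patient"] * ratio["patient"]
    c0_second[is_patient] = _lognormal(
        rng, patient_second_median, sigma, int(is_patient.sum())
    )
    c0_second[low_carrier] = _lognormal(
        rng, med["carrier_low"] * ratio["carrier_low"], sigma, int(low_carrier.sum())
    )

    return pd.DataFrame(
        {
            "id": genotypes["id"],
            "true_status": status,
            "c0_initial": c0_initial,
            "c0_second": c0_second,
            "panel_hits": np.minimum(genotypes["panel_alleles"], 2).astype(int),
            "total_plp_alleles": np.minimum(genotypes["total_alleles"], 2).astype(int),
        }
    )


def simulate_treated_c0(
    n_patients: int,
    n_carriers: int,
    config: SimulationConfig,
    seed: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Post-L-carnitine-supplementation C0 draws for patients and carriers."""
    rng = _rng(seed)
    med = config.treated_c0_medians
    return (
        _lognormal(rng, med["patient"], config.c0_sigma, n_patients),
        _lognormal(rng, med["carrier"], config.c0_sigma, n_carriers),
    )


def to_newborn_records(cohort: pd.DataFrame) -> list[NewbornRecord]:
    """Convert a simulated newborn table into NewbornRecord objects."""
    return [
        NewbornRecord(
            id=row.id,
            true_status=row.true_status,
            c0_initial=float(row.c0_initial),
            c0_second=float(row.c0_second),
            panel_hits=int(row.panel_hits),
            total_plp_alleles=int(row.total_plp_alleles),
        )
        for row in cohort.itertuples(index=False)
    ]


def cohort_counts_from_genotypes(genotypes: pd.DataFrame) -> CohortCounts:
    """Summarize a simulated cohort as the prevalence modules expect.

    Genotype-identified patients (≥2 pathogenic alleles) are excluded
    first, mirroring the study design; carriers then each carry exactly one
    pathogenic allele.
    """
    kept = genotypes[genotypes["status"] != "patient"]
    female = kept["sex"] == "F"
    carrier = kept["status"] == "carrier"
    return CohortCounts(
        n_total=len(kept),
        n_female=int(female.sum()),
        n_male=int((~female).sum()),
        carriers_female=int((carrier & female).sum()),
        carriers_male=int((carrier & ~female).sum()),
    )


def hardy_weinberg_gof(genotype_counts: Sequence[int], af: float) -> float:
    """Chi-squared goodness-of-fit p of (n0, n1, n2) against HW at ``af``."""
    n0, n1, n2 = genotype_counts
    n = n0 + n1 + n2
    expected = n * np.array([(1 - af) ** 2, 2 * af * (1 - af), af**2])
    res = stats.chisquare([n0, n1, n2], expected)
    return float(res.pvalue)


def end_to_end_recovery(
    config: SimulationConfig,
    n_replicates: int = 100,
    seed: np.random.Generator | int | None = 0,
    prior: PriorSpec = JEFFREYS,
    ci_level: float = 0.95,
) -> dict:
    """Run the three estimators on replicate cohorts and report recovery.

    Each replicate simulates genotypes, excludes genotype-identified
    patients, and estimates prevalence by all three methods; the report
    holds per-method mean rates, Monte-Carlo standard errors of those
    means, relative bias against the nominal (Σ AF)², and the empirical
    coverage of the Bayesian ``ci_level`` interval.
    """
    rng = _rng(seed)
    true_rate = config.true_prevalence
    rates: dict[str, list[float]] = {"hw": [], "permutation": [], "bayesian": []}
    covered = 0
    for _ in range(n_replicates):
        genotypes = simulate_genotypes(config, rng)
        cohort = cohort_counts_from_genotypes(genotypes)
        rates["hw"].append(hw_prevalence(cohort).rate)
        rates["permutation"].append(permutation_prevalence(cohort).rate)
        bayes = bayesian_prevalence(
            AlleleCount(cohort.carriers, 2 * cohort.n_total, "sim"),
            prior=prior,
            ci_level=ci_level,
        )
        rates["bayesian"].append(bayes.rate)
        if bayes.ci_low_rate <= true_rate <= bayes.ci_high_rate:
            covered += 1
    report: dict = {"true_rate": true_rate, "n_replicates": n_replicates}
    for method, vals in rates.items():
        arr = np.asarray(vals)
        mean = float(arr.mean())
        mc_se = float(arr.std(ddof=1) / np.sqrt(n_replicates))
        report[method] = {
            "mean_rate": mean,
            "mc_se": mc_se,
            "relative_bias": mean / true_rate - 1.0,
        }
    report["ci_coverage"] = covered / n_replicates
    return report


__all__ = [
    "SimulationConfig",
    "HOTSPOT_AFS",
    "MAX_AF",
    "default_variant_afs",
    "simulate_genotypes",
    "simulate_c0",
    "simulate_treated_c0",
    "to_newborn_records",
    "cohort_counts_from_genotypes",
    "hardy_weinberg_gof",
    "end_to_end_recovery",
]
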