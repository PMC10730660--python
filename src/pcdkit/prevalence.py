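"""Autosomal-recessive prevalence estimators from carrier counts and AC/AN.

Three estimators of the birth prevalence of a recessive disease from a
population cohort of unaffected individuals, plus their average:

* **Hardy–Weinberg (Method 1)** — the pathogenic allele frequency is taken as
  q = carriers / (2 n) (each carrier contributes exactly one pathogenic
  allele; affected/suspected individuals are excluded upstream), and the
  affected-birth rate is q² under random mating.

* **Permutation–combination (Method 2)** — the probability that a randomly
  chosen male carrier and female carrier pair produces an affected child:
  rate = (carriers_m / n_m) · (carriers_f / n_f) / 4.  The product is
  symmetric in the two strata, so mislabelling the sexes cannot change it.

* **Bayesian (Method 3)** — with a Beta(α, β) prior on q and an observed
  allele count AC out of AN alleles, the posterior is
  Beta(α + AC, β + AN − AC).  The point estimate is the square of the
  posterior mean of q; a credible interval on the rate is obtained by
  squaring posterior quantiles of q (a monotone transform), either from the
  Beta quantile function (default, deterministic) or from seeded Monte-Carlo
  posterior draws.  The default prior is Jeffreys Beta(1/2, 1/2).

Rates are rendered in the conventional "1:N" form with N = 1/rate rounded
half-up to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import nearest_int_half_up


@dataclass(frozen=True)
class CohortCounts:
    """Cohort totals and sex-stratified carrier counts."""

    n_total: int
    n_female: int
    n_male: int
    carriers_female: int
    carriers_male: int

    def __post_init__(self) -> None:
        if self.n_female + self.n_male != self.n_total:
            raise ValueError("n_female + n_male must equal n_total")
        if not 0 <= self.carriers_female <= self.n_female:
            raise ValueError("carriers_female outside [0, n_female]")
        if not 0 <= self.carriers_male <= self.n_male:
            raise ValueError("carriers_male outside [0, n_male]")

    @property
    def carriers(self) -> int:
        return self.carriers_female + self.carriers_male


@dataclass(frozen=True)
class AlleleCount:
    """Pathogenic allele count (AC) out of AN sequenced alleles."""

    allele_count: int
    allele_number: int
    population: str = ""

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError("allele_count must lie in [0, allele_number]")

    @property
    def af(self) -> float:
        return self.allele_count / self.allele_number


@dataclass(frozen=True)
class PriorSpec:
    """Beta(alpha, beta) prior on the pathogenic allele frequency."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("prior parameters must be strictly positive")


JEFFREYS = PriorSpec(0.5, 0.5)
FLAT = PriorSpec(1.0, 1.0)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """An affected-births-per-birth rate with its "1:N" rendering."""

    rate: float
    method: str
    population: str = ""
    ci_low_rate: float | None = None
    ci_high_rate: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must lie in [0, 1]")
        if self.ci_low_rate is not None and self.ci_high_rate is not None:
            if not self.ci_low_rate <= self.rate <= self.ci_high_rate:
                raise ValueError("credible interval must bracket the rate")

    @property
    def ratio_n(self) -> int | None:
        """N in "1:N" (nearest integer, ties up); None for a zero rate."""
        if self.rate == 0:
            return None
        return nearest_int_half_up(1.0 / self.rate)

    def ratio_string(self) -> str:
        n = self.ratio_n
        return "0" if n is None else f"1:{n:,}"

    def ci_ratio_ns(self) -> tuple[int, int] | None:
        """Credible interval as (N_low_rate, N_high_rate) denominators."""
        if self.ci_low_rate is None or self.ci_high_rate is None:
            return None
        if self.ci_low_rate == 0:
            return None
        return (
            nearest_int_half_up(1.0 / self.ci_low_rate),
            nearest_int_half_up(1.0 / self.ci_high_rate),
        )


def hw_prevalence(cohort: CohortCounts) -> PrevalenceEstimate:
    """Method 1: Hardy–Weinberg rate q² with q = carriers / (2 n_total)."""
    if cohort.n_total <= 0:
        raise ValueError("n_total must be positive")
    q = cohort.carriers / (2 * cohort.n_total)
    return PrevalenceEstimate(rate=q * q, method="hw")


def carrier_frequency(cohort: CohortCounts) -> PrevalenceEstimate:
    """Fraction of individuals carrying ≥1 pathogenic allele, as 1:N."""
    if cohort.n_total <= 0:
        raise ValueError("n_total must be positive")
    return PrevalenceEstimate(rate=cohort.carriers / cohort.n_total, method="carrier")


def permutation_prevalence(cohort: CohortCounts) -> PrevalenceEstimate:
    """Method 2: sex-stratified carrier-pairing rate.

    rate = (carriers_male/n_male) · (carriers_female/n_female) / 4, the
    probability that a random male-carrier × female-carrier mating yields an
    affected child.  Invariant under swapping the stratum labels.
    """
    if cohort.n_female <= 0 or cohort.n_male <= 0:
        raise ValueError("both sex strata must be non-empty")
    rate = (
        (cohort.carriers_male / cohort.n_male)
        * (cohort.carriers_female / cohort.n_female)
        / 4.0
    )
    return PrevalenceEstimate(rate=rate, method="permutation")


def bayesian_prevalence(
    ac: AlleleCount,
    prior: PriorSpec = JEFFREYS,
    ci_level: float = 0.95,
    ci_method: str = "quantile",
    n_draws: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> PrevalenceEstimate:
    """Method 3: Beta-posterior point estimate and credible interval.

    Posterior on q is Beta(alpha + AC, beta + AN − AC).  The point rate is
    the *square of the posterior mean* of q.  The interval squares posterior
    quantiles of q; ``ci_method="montecarlo"`` instead squares seeded
    posterior draws and takes empirical quantiles.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    a = prior.alpha + ac.allele_count
    b = prior.beta + ac.allele_number - ac.allele_count
    q_mean = a / (a + b)
    tail = (1.0 - ci_level) / 2.0
    if ci_method == "quantile":
        q_lo, q_hi = stats.beta.ppf([tail, 1.0 - tail], a, b)
    elif ci_method == "montecarlo":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        draws = gen.beta(a, b, size=n_draws)
        q_lo, q_hi = np.quantile(draws, [tail, 1.0 - tail])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return PrevalenceEstimate(
        rate=q_mean**2,
        method="bayesian",
        population=ac.population,
        ci_low_rate=float(q_lo) ** 2,
        ci_high_rate=float(q_hi) ** 2,
    )


def average_prevalence(estimates: Sequence[PrevalenceEstimate]) -> PrevalenceEstimate:
    """Arithmetic mean of the input rates."""
    if not estimates:
        raise ValueError("need at least one estimate to average")
    rate = float(np.mean([e.rate for e in estimates]))
    return PrevalenceEstimate(rate=rate, method="average")


def multi_population_bayesian(
    counts: Iterable[AlleleCount],
    prior: PriorSpec = JEFFREYS,
    ci_level: float = 0.95,
) -> dict[str, PrevalenceEstimate]:
    """Per-population Bayesian estimates keyed by population label."""
    out: dict[str, PrevalenceEstimate] = {}
    for ac in counts:
        if ac.population in out:
            raise ValueError(f"duplicate population label {ac.population!r}")
        out[ac.population] = bayesian_prevalence(ac, prior=prior, ci_level=ci_level)
    return out


def cohort_to_allele_count(cohort: CohortCounts, population: str = "") -> AlleleCount:
    """AC = total carriers (one allele each), AN = 2 · n_total."""
    return AlleleCount(
        allele_count=cohort.carriers,
        allele_number=2 * cohort.n_total,
        population=population,
    )


# --------------------------------------------------------------------------
# Tabular I/O


def load_cohort_counts(path: str | Path) -> CohortCounts:
    """Read a one-row cohort-counts TSV (see ``COHORT_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) != 1:
        raise ValueError(f"{path}: expected exactly one data row, got {len(df)}")
    row = df.iloc[0]
    return CohortCounts(*(int(row[c]) for c in COHORT_COLUMNS))


COHORT_COLUMNS = ("n_total", "n_female", "n_male", "carriers_female", "carriers_male")


def load_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-variant, per-population AC/AN TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad = df["allele_count"] > df["allele_number"]
    if bad.any():
        raise ValueError(f"{path}: allele_count > allele_number for {bad.sum()} row(s)")
    return df


ALLELE_COLUMNS = ("variant", "population", "allele_count", "allele_number")


def aggregate_population_counts(counts: pd.DataFrame) -> list[AlleleCount]:
    """Collapse a per-variant table to one AlleleCount per population.

    Allele counts are summed across variants; the allele number is the
    shared sequencing denominator and must be identical across a
    population's variants.
    """
    out: list[AlleleCount] = []
    for pop, grp in counts.groupby("population", sort=True):
        ans = grp["allele_number"].unique()
        if len(ans) != 1:
            raise ValueError(
                f"population {pop!r} has differing allele_number values {sorted(ans)}"
            )
        out.append(
            AlleleCount(
                allele_count=int(grp["allele_count"].sum()),
                allele_number=int(ans[0]),
                population=str(pop),
            )
        )
    return out


#: Carrier and cohort counts of the reference neonatal cohort (17,864
#: genotyped newborns after excluding identified/suspected patients;
#: 125 female and 144 male carriers of a pathogenic allele).
CNGP_COHORT = CohortCounts(
    n_total=17_864,
    n_female=7_333,
    n_male=10_531,
    carriers_female=125,
    carriers_male=144,
)


__all__ = [
    "CohortCounts",
    "AlleleCount",
    "PriorSpec",
    "PrevalenceEstimate",
    "JEFFREYS",
    "FLAT",
    "CNGP_COHORT",
    "COHORT_COLUMNS",
    "ALLELE_COLUMNS",
    "hw_prevalence",
    "carrier_frequency",
    "permutation_prevalence",
    "bayesian_prevalence",
    "average_prevalence",
    "multi_population_bayesian",
    "cohort_to_allele_count",
    "load_cohort_counts",
    "load_allele_counts",
    "aggregate_population_counts",
]
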