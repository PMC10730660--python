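"""Genotype–phenotype association screen over literature-curated patients.

Patients (each carrying exactly two pathogenic alleles) are grouped three
ways — homozygosity for a given variant site, unordered mutation-type
combination of the two alleles, or zygosity — and each group is tested for
over-representation of each phenotype against the remaining patients in a
2×2 table.  The p-value rule is shared with the allele-frequency module
(chi-squared with continuity correction when valid, Fisher's exact test
otherwise).  The odds ratio is the conditional maximum-likelihood estimate
from the exact test, so tables with a zero cell yield exactly 0 or +inf
rather than a continuity-corrected finite value — matching how such
associations are conventionally reported.  Screens are Benjamini–Hochberg
adjusted as a whole.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from statsmodels.stats.multitest import multipletests

from ._rounding import percent
from .population_af import two_by_two_p
from .variant_catalog import MUTATION_TYPES, normalize_hgvs

logger = logging.getLogger(__name__)

AGE_GROUPS = ("infant_child", "adult")
ZYGOSITIES = ("homozygous", "compound_het")
SCHEMES = ("variant_homozygous", "type_combination", "zygosity")

#: Default phenotype vocabulary (user-extensible).  Seeded with the
#: manifestations recurrently reported for carnitine-transport deficiency.
DEFAULT_PHENOTYPES = (
    "cardiomyopathy",
    "cardiac_failure",
    "hypoglycemia",
    "hyperammonemia",
    "hepatomegaly",
    "elevated_alt",
    "fatigue",
    "asymptomatic",
    "growth_retardation",
    "metabolic_decompensation",
)


@dataclass(frozen=True)
class Allele:
    hgvs_c: str
    mutation_type: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "hgvs_c", normalize_hgvs(self.hgvs_c))
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation_type {self.mutation_type!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One published patient: two pathogenic alleles plus phenotype flags."""

    id: str
    age_group: str
    allele1: Allele
    allele2: Allele
    phenotypes: frozenset[str] = frozenset()
    treated_before_onset: bool = False

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"{self.id}: unknown age_group {self.age_group!r}")
        object.__setattr__(self, "phenotypes", frozenset(self.phenotypes))

    @property
    def zygosity(self) -> str:
        return (
            "homozygous"
            if self.allele1.hgvs_c == self.allele2.hgvs_c
            else "compound_het"
        )

    @property
    def type_pair(self) -> tuple[str, str]:
        """Unordered mutation-type combination of the two alleles."""
        return tuple(sorted((self.allele1.mutation_type, self.allele2.mutation_type)))


def load_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read the patient TSV (phenotypes semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "id",
        "age_group",
        "allele1_hgvs",
        "allele1_type",
        "allele2_hgvs",
        "allele2_type",
        "phenotypes",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for row in df.to_dict("records"):
        phen = frozenset(p.strip() for p in row["phenotypes"].split(";") if p.strip())
        records.append(
            PatientRecord(
                id=row["id"],
                age_group=row["age_group"],
                allele1=Allele(row["allele1_hgvs"], row["allele1_type"]),
                allele2=Allele(row["allele2_hgvs"], row["allele2_type"]),
                phenotypes=phen,
                treated_before_onset=row.get("treated_before_onset", "")
                .strip()
                .lower()
                in {"1", "true", "yes"},
            )
        )
    return records


def group_patients(
    records: Sequence[PatientRecord], scheme: str, key=None
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Split patients into in-group / out-group under a grouping scheme.

    * ``variant_homozygous`` (key = hgvs_c site): homozygotes for the site
      vs patients with any other variant combination;
    * ``type_combination`` (key = unordered pair of mutation types): exact
      pair matches vs the rest;
    * ``zygosity``: homozygous vs compound heterozygous.
    """
    if scheme == "variant_homozygous":
        site = normalize_hgvs(str(key))
        pred = lambda r: r.zygosity == "homozygous" and r.allele1.hgvs_c == site
    elif scheme == "type_combination":
        pair = tuple(sorted(key))
        pred = lambda r: r.type_pair == pair
    elif scheme == "zygosity":
        pred = lambda r: r.zygosity == "homozygous"
    else:
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    in_group = [r for r in records if pred(r)]
    out_group = [r for r in records if not pred(r)]
    return in_group, out_group


def contingency_table(
    in_group: Sequence[PatientRecord],
    out_group: Sequence[PatientRecord],
    phenotype: str,
) -> np.ndarray:
    """2×2 table [[in & phen, in & not], [out & phen, out & not]]."""
    a = sum(phenotype in r.phenotypes for r in in_group)
    c = sum(phenotype in r.phenotypes for r in out_group)
    return np.array(
        [[a, len(in_group) - a], [c, len(out_group) - c]], dtype=np.int64
    )


@dataclass(frozen=True)
class AssociationResult:
    group_label: str
    phenotype: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    test_used: str
    q_value: float = float("nan")


def conditional_odds_ratio(table: np.ndarray | list) -> float:
    """Conditional MLE of the odds ratio from the exact test.

    Zero cells give exactly 0.0 or +inf; tables with a zero margin (the
    conditional distribution is degenerate) give NaN.
    """
    t = np.asarray(table, dtype=np.int64)
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        return float("nan")
    return float(_scipy_odds_ratio(t, kind="conditional").statistic)


def test_association(
    table: np.ndarray | list,
    group_label: str = "",
    phenotype: str = "",
) -> AssociationResult:
    """Exact/chi-squared association test with conditional-MLE odds ratio."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if t.sum() == 0:
        warnings.warn("all-zero 2x2 table: association undefined", stacklevel=2)
        p, test, or_ = 1.0, "fisher", float("nan")
    else:
        p, test = two_by_two_p(t)
        or_ = conditional_odds_ratio(t)
    return AssociationResult(
        group_label=group_label,
        phenotype=phenotype,
        table=tuple(map(tuple, t.tolist())),
        odds_ratio=or_,
        p_value=p,
        test_used=test,
    )


test_association.__test__ = False  # plain library function, not a pytest item


def _group_labels(records: Sequence[PatientRecord], scheme: str) -> list:
    if scheme == "variant_homozygous":
        sites = {r.allele1.hgvs_c for r in records if r.zygosity == "homozygous"}
        return [("variant_homozygous", s) for s in sorted(sites)]
    if scheme == "type_combination":
        pairs = {r.type_pair for r in records}
        return [("type_combination", p) for p in sorted(pairs)]
    if scheme == "zygosity":
        return [("zygosity", None)]
    raise ValueError(f"unknown grouping scheme {scheme!r}")


def run_association_screen(
    records: Sequence[PatientRecord],
    schemes: Iterable[str] = SCHEMES,
    phenotypes: Iterable[str] | None = None,
    exclude_treated: bool = False,
) -> list[AssociationResult]:
    """One test per (group, phenotype), BH-adjusted across the screen.

    Phenotypes absent from every record are skipped with a log entry.
    ``exclude_treated`` drops patients treated before symptom onset from
    the tables (treatment masks phenotypes); the default keeps them.
    """
    if exclude_treated:
        records = [r for r in records if not r.treated_before_onset]
    phenotypes = list(phenotypes) if phenotypes is not None else list(DEFAULT_PHENOTYPES)
    observed = set().union(*(r.phenotypes for r in records)) if records else set()
    results: list[AssociationResult] = []
    for scheme in schemes:
        for scheme_name, key in _group_labels(records, scheme):
            in_g, out_g = group_patients(records, scheme_name, key)
            if key is None:
                label = scheme_name
            elif isinstance(key, tuple):
                label = f"{scheme_name}:{'+'.join(key)}"
            else:
                label = f"{scheme_name}:{key}"
            for phen in phenotypes:
                if phen not in observed:
                    logger.info("phenotype %s absent from all records; skipped", phen)
                    continue
                results.append(
                    test_association(
                        contingency_table(in_g, out_g, phen),
                        group_label=label,
                        phenotype=phen,
                    )
                )
    if not results:
        return []
    _, qvals, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    results = [replace(r, q_value=float(q)) for r, q in zip(results, qvals)]
    return sorted(results, key=lambda r: (r.q_value, r.p_value, r.group_label))


def phenotype_frequencies(
    records: Sequence[PatientRecord],
    age_group: str,
    phenotypes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-phenotype counts and percentages within one age group.

    Percentages are exact count/denominator arithmetic rounded half-up to
    one decimal (no attempt is made to reproduce rounding quirks of
    published tables).
    """
    strat = [r for r in records if r.age_group == age_group]
    if not strat:
        raise ValueError(f"no records in age group {age_group!r}")
    phenotypes = (
        list(phenotypes)
        if phenotypes is not None
        else sorted(set().union(*(r.phenotypes for r in strat)) | set(DEFAULT_PHENOTYPES))
    )
    n = len(strat)
    rows = []
    for phen in phenotypes:
        count = sum(phen in r.phenotypes for r in strat)
        rows.append(
            {"phenotype": phen, "count": count, "percent": percent(count, n, 1)}
        )
    return pd.DataFrame(rows, columns=["phenotype", "count", "percent"])


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group_label,
                "phenotype": r.phenotype,
                "a_in_with": r.table[0][0],
                "b_in_without": r.table[0][1],
                "c_out_with": r.table[1][0],
                "d_out_without": r.table[1][1],
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "test_used": r.test_used,
            }
            for r in results
        ]
    )


__all__ = [
    "Allele",
    "PatientRecord",
    "AssociationResult",
    "AGE_GROUPS",
    "SCHEMES",
    "DEFAULT_PHENOTYPES",
    "load_patient_table",
    "group_patients",
    "contingency_table",
    "conditional_odds_ratio",
    "test_association",
    "run_association_screen",
    "phenotype_frequencies",
    "results_to_frame",
]
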