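"""Curated pathogenic-variant catalog: loading, validation, spectrum summaries.

The catalog holds manually curated *SLC22A5* variants (or any user-supplied
set) with their gene location, affected protein domain, mutation type and
ACMG pathogenicity class.  HGVS coding-DNA names are treated as opaque
identifiers after a light syntactic normalization — published tables space
intronic offsets inconsistently ("c.497 + 1G>T" vs "c.497+1G>T") — and no
attempt is made to parse or validate HGVS grammar.

Spectrum summaries partition the catalog four ways (exon, exon/intron
location, protein domain, mutation type) with half-up percentages to two
decimals, matching the reporting style of published variant spectra.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._rounding import percent

logger = logging.getLogger(__name__)

LOCATION_KINDS = ("exon", "intron")
DOMAINS = ("transmembrane", "non_transmembrane", "unassigned")
MUTATION_TYPES = (
    "missense",
    "frameshift",
    "nonsense",
    "splicing",
    "inframe_indel",
    "start_loss",
)
ACMG_CLASSES = ("P", "LP", "VUS", "LB", "B")
PLP_CLASSES = frozenset({"P", "LP"})

#: Number of coding exons of the gene; exon annotations must fall in 1..10.
N_EXONS = 10

TABLE_COLUMNS = (
    "hgvs_c",
    "hgvs_p",
    "location_kind",
    "exon_number",
    "domain",
    "mutation_type",
    "acmg_class",
)


class CatalogFormatError(ValueError):
    """The variant table file does not have the expected shape."""


class CatalogValidationError(ValueError):
    """A variant record violates a catalog invariant."""


_OFFSET_SPACES = re.compile(r"\s*([+\-])\s*")


def normalize_hgvs(name: str) -> str:
    """Strip whitespace and collapse spaces around intronic-offset signs."""
    return _OFFSET_SPACES.sub(r"\1", name.strip())


@dataclass(frozen=True)
class VariantRecord:
    """One curated variant with its annotations."""

    hgvs_c: str
    hgvs_p: str | None = None
    location_kind: str = "exon"
    exon_number: int | None = None
    domain: str = "unassigned"
    mutation_type: str = "missense"
    acmg_class: str = "VUS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hgvs_c", normalize_hgvs(self.hgvs_c))
        if not self.hgvs_c:
            raise CatalogValidationError("hgvs_c must be non-empty")
        if self.location_kind not in LOCATION_KINDS:
            raise CatalogValidationError(
                f"{self.hgvs_c}: unknown location_kind {self.location_kind!r}"
            )
        if self.domain not in DOMAINS:
            raise CatalogValidationError(
                f"{self.hgvs_c}: unknown domain {self.domain!r}"
            )
        if self.mutation_type not in MUTATION_TYPES:
            raise CatalogValidationError(
                f"{self.hgvs_c}: unknown mutation_type {self.mutation_type!r}"
            )
        if self.acmg_class not in ACMG_CLASSES:
            raise CatalogValidationError(
                f"{self.hgvs_c}: unknown acmg_class {self.acmg_class!r}"
            )
        if self.location_kind == "exon":
            if self.exon_number is None:
                raise CatalogValidationError(
                    f"{self.hgvs_c}: exonic variant needs exon_number"
                )
            if not 1 <= self.exon_number <= N_EXONS:
                raise CatalogValidationError(
                    f"{self.hgvs_c}: exon_number {self.exon_number} outside 1..{N_EXONS}"
                )
        elif self.exon_number is not None:
            raise CatalogValidationError(
                f"{self.hgvs_c}: intronic variant must not carry exon_number"
            )

    @property
    def is_plp(self) -> bool:
        return self.acmg_class in PLP_CLASSES


def _record_from_row(row: Mapping[str, object]) -> VariantRecord:
    def txt(key: str) -> str:
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        return str(v).strip()

    exon_raw = txt("exon_number")
    exon_number = None
    if exon_raw:
        try:
            exon_number = int(float(exon_raw))
        except ValueError as exc:
            raise CatalogValidationError(
                f"{txt('hgvs_c')}: exon_number {exon_raw!r} is not an integer"
            ) from exc
    return VariantRecord(
        hgvs_c=txt("hgvs_c"),
        hgvs_p=txt("hgvs_p") or None,
        location_kind=txt("location_kind"),
        exon_number=exon_number,
        domain=txt("domain") or "unassigned",
        mutation_type=txt("mutation_type"),
        acmg_class=txt("acmg_class"),
    )


def load_variant_table(path: str | Path, strict: bool = True) -> list[VariantRecord]:
    """Read a tab-separated variant table into validated records.

    In strict mode any invalid row (or a duplicate ``hgvs_c``) rejects the
    whole file; otherwise bad rows are skipped with a logged warning and
    later duplicates are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(f"{path}: missing required column(s) {missing}")
    records: list[VariantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records")):
        try:
            rec = _record_from_row(row)
            if rec.hgvs_c in seen:
                raise CatalogValidationError(f"duplicate variant {rec.hgvs_c}")
        except CatalogValidationError as exc:
            if strict:
                raise CatalogValidationError(f"{path} row {i + 2}: {exc}") from exc
            logger.warning("skipping row %d of %s: %s", i + 2, path, exc)
            continue
        seen.add(rec.hgvs_c)
        records.append(rec)
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records to TSV; missing optionals become empty strings."""
    rows = [
        {
            "hgvs_c": r.hgvs_c,
            "hgvs_p": r.hgvs_p or "",
            "location_kind": r.location_kind,
            "exon_number": "" if r.exon_number is None else r.exon_number,
            "domain": r.domain,
            "mutation_type": r.mutation_type,
            "acmg_class": r.acmg_class,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def filter_plp(catalog: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep pathogenic / likely pathogenic records, preserving order."""
    return [r for r in catalog if r.is_plp]


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts and half-up percentages over the four catalog partitions."""

    total: int
    by_exon: dict[int, tuple[int, float]] = field(default_factory=dict)
    by_location: dict[str, tuple[int, float]] = field(default_factory=dict)
    by_domain: dict[str, tuple[int, float]] = field(default_factory=dict)
    by_type: dict[str, tuple[int, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for partition, mapping in (
            ("exon", self.by_exon),
            ("location", self.by_location),
            ("domain", self.by_domain),
            ("mutation_type", self.by_type),
        ):
            for cat, (n, pct) in mapping.items():
                rows.append(
                    {"partition": partition, "category": cat, "count": n, "percent": pct}
                )
        return pd.DataFrame(rows, columns=["partition", "category", "count", "percent"])


def summarize_spectrum(catalog: Sequence[VariantRecord]) -> SpectrumSummary:
    """Partition the catalog by exon, location, domain and mutation type.

    percent = 100 * count / total, rounded half-up to two decimals.  The exon
    partition covers exonic variants only; its counts sum to the exonic
    subtotal, while the other partitions each sum to the catalog size.
    """
    if not catalog:
        raise ValueError("cannot summarize an empty catalog")
    total = len(catalog)

    def tally(keys: Iterable[object]) -> dict:
        counts: dict = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        return {k: (n, percent(n, total)) for k, n in sorted(counts.items(), key=str)}

    by_exon = tally(r.exon_number for r in catalog if r.location_kind == "exon")
    by_location = tally(r.location_kind for r in catalog)
    by_domain = tally(r.domain for r in catalog)
    by_type = tally(r.mutation_type for r in catalog)
    return SpectrumSummary(
        total=total,
        by_exon=by_exon,
        by_location=by_location,
        by_domain=by_domain,
        by_type=by_type,
    )


def example_catalog() -> list[VariantRecord]:
    """A synthetic 128-variant P/LP catalog matching the published spectrum.

    The individual rows are invented (the real curated list lives in
    restricted supplementary material); only the category totals are
    meaningful: 117 exonic / 11 intronic (all splicing), 26 on exon 1 and 24
    on exon 8, mutation types 66 missense / 29 frameshift / 19 nonsense /
    11 splicing / 2 in-frame indel / 1 start loss.  The domain split is 75
    non-transmembrane / 53 transmembrane: the published count/percent pair
    for this category is internally inconsistent (74/128 = 57.81% yet the
    percent is printed as 58.59%, which is 75/128); the percent is taken as
    authoritative here.
    """
    records: list[VariantRecord] = []
    exon_types = (
        ["start_loss"] + ["missense"] * 66 + ["frameshift"] * 29
        + ["nonsense"] * 19 + ["inframe_indel"] * 2
    )
    exons = [1] * 26 + [8] * 24 + [2, 3, 4] * 9 + [5, 6, 7, 9, 10] * 8
    # 26 + 24 + 27 + 40 = 117 exonic slots
    domains = ["non_transmembrane"] * 75 + ["transmembrane"] * 53
    pos = iter(range(100, 4000, 3))
    for i, (etype, exon) in enumerate(zip(exon_types, exons)):
        records.append(
            VariantRecord(
                hgvs_c=f"c.{next(pos)}C>T",
                location_kind="exon",
                exon_number=exon,
                domain=domains[i],
                mutation_type=etype,
                acmg_class="P" if i % 2 == 0 else "LP",
            )
        )
    for j in range(11):
        records.append(
            VariantRecord(
                hgvs_c=f"c.{next(pos)}+1G>T",
                location_kind="intron",
                domain=domains[117 + j],
                mutation_type="splicing",
                acmg_class="LP",
            )
        )
    return records


__all__ = [
    "VariantRecord",
    "SpectrumSummary",
    "CatalogFormatError",
    "CatalogValidationError",
    "normalize_hgvs",
    "load_variant_table",
    "write_variant_table",
    "filter_plp",
    "summarize_spectrum",
    "example_catalog",
    "LOCATION_KINDS",
    "DOMAINS",
    "MUTATION_TYPES",
    "ACMG_CLASSES",
    "TABLE_COLUMNS",
]
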