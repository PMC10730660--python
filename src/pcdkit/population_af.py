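"""Cross-population allele-frequency comparison with FDR control.

Each variant's pathogenic allele frequency in a target population is
compared against one or more reference populations via a 2×2 allele table
[[AC_a, AN_a−AC_a], [AC_b, AN_b−AC_b]].  A chi-squared test with continuity
correction is the default; whenever any expected cell count falls below 5
(the standard validity convention) the test falls back to Fisher's exact
test, which also handles the zero-count cells typical of
population-restricted founder variants.  P-values from a screen are
adjusted by Benjamini–Hochberg, and a variant is called higher/lower only
when its q-value clears the significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rounding import nearest_int_half_up, round_half_up
from .prevalence import AlleleCount

logger = logging.getLogger(__name__)

DIRECTIONS = ("higher_in_a", "lower_in_a", "none")


def fisher_exact_p(table: np.ndarray | list) -> float:
    """Two-sided Fisher exact p for a 2×2 count table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def two_by_two_p(table: np.ndarray | list) -> tuple[float, str]:
    """Two-sided p for a 2×2 count table with the default/fallback rule.

    Chi-squared with Yates continuity correction when every expected count
    is ≥ 5, otherwise Fisher's exact test.  Degenerate tables (an all-zero
    row or column, where no association is testable) return p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        return 1.0, "fisher"
    expected = stats.contingency.expected_freq(t)
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(t, correction=True)
        return float(min(p, 1.0)), "chi_squared"
    return fisher_exact_p(t), "fisher"


@dataclass(frozen=True)
class AFComparisonResult:
    """One variant's AF contrast between populations a and b."""

    hgvs_c: str
    pop_a: str
    pop_b: str
    af_a: float
    af_b: float
    p_value: float
    test_used: str
    q_value: float = float("nan")
    direction: str = "none"

    @property
    def direction_candidate(self) -> str:
        """Sign of af_a − af_b, before any significance gating."""
        if self.af_a > self.af_b:
            return "higher_in_a"
        if self.af_a < self.af_b:
            return "lower_in_a"
        return "none"


def compare_af(hgvs_c: str, a: AlleleCount, b: AlleleCount) -> AFComparisonResult:
    """Test one variant's AF difference between two populations.

    The returned result carries the raw p-value; ``direction`` stays
    "none" until a screen assigns q-values (see :func:`screen_populations`).
    """
    table = [
        [a.allele_count, a.allele_number - a.allele_count],
        [b.allele_count, b.allele_number - b.allele_count],
    ]
    p, test = two_by_two_p(table)
    return AFComparisonResult(
        hgvs_c=hgvs_c,
        pop_a=a.population,
        pop_b=b.population,
        af_a=a.af,
        af_b=b.af,
        p_value=p,
        test_used=test,
    )


def screen_populations(
    counts: pd.DataFrame,
    target: str,
    refs: list[str] | None = None,
    threshold: float = 0.05,
    pool_refs: bool = True,
    catalog=None,
) -> list[AFComparisonResult]:
    """Screen every variant's AF in ``target`` against reference populations.

    ``counts`` is the per-variant AC/AN table (columns ``variant``,
    ``population``, ``allele_count``, ``allele_number``).  With
    ``pool_refs`` (default) the reference AC and AN are summed across
    ``refs`` per variant; otherwise each (variant, reference) pair is
    tested separately.  Variants absent from the target or from every
    reference are skipped with a log entry.  BH adjustment runs across the
    whole screen; ``direction`` is set only where q < ``threshold``.
    """
    if refs is None:
        refs = sorted(set(counts["population"]) - {target})
    if catalog is not None:
        wanted = {r.hgvs_c for r in catalog}
        counts = counts[counts["variant"].isin(wanted)]
    results: list[AFComparisonResult] = []
    for variant, grp in counts.groupby("variant", sort=True):
        by_pop = {p: g for p, g in grp.groupby("population")}
        if target not in by_pop:
            logger.info("variant %s absent from target %s; skipped", variant, target)
            continue
        trow = by_pop[target]
        a = AlleleCount(
            int(trow["allele_count"].sum()), int(trow["allele_number"].sum()), target
        )
        present = [r for r in refs if r in by_pop]
        if not present:
            logger.info("variant %s has no reference counts; skipped", variant)
            continue
        if pool_refs:
            ref_rows = grp[grp["population"].isin(present)]
            b = AlleleCount(
                int(ref_rows["allele_count"].sum()),
                int(ref_rows["allele_number"].sum()),
                "+".join(present),
            )
            results.append(compare_af(str(variant), a, b))
        else:
            for r in present:
                rrow = by_pop[r]
                b = AlleleCount(
                    int(rrow["allele_count"].sum()), int(rrow["allele_number"].sum()), r
                )
                results.append(compare_af(str(variant), a, b))
    if not results:
        return []
    pvals = [r.p_value for r in results]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for r, q in zip(results, qvals):
        direction = r.direction_candidate if q < threshold else "none"
        out.append(replace(r, q_value=float(q), direction=direction))
    return out


def af_ratio_string(af: float) -> str:
    """Render an allele frequency as "1:N or F" (F to 2 significant figures).

    Examples: 0.0041841 → "1:239 or 0.0042"; 0.5 → "1:2 or 0.50".
    """
    if not 0 < af <= 1:
        raise ValueError("allele frequency must lie in (0, 1]")
    n = nearest_int_half_up(1.0 / af)
    exponent = int(np.floor(np.log10(af)))
    decimals = max(0, 1 - exponent)
    value = round_half_up(af, decimals)
    # rounding can carry into the next decade (0.0995 → 0.10)
    if value > 0 and int(np.floor(np.log10(value))) > exponent:
        decimals -= 1
    return f"1:{n} or {value:.{decimals}f}"


def results_to_frame(results: list[AFComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hgvs_c": r.hgvs_c,
                "pop_a": r.pop_a,
                "pop_b": r.pop_b,
                "af_a": r.af_a,
                "af_b": r.af_b,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "test_used": r.test_used,
                "direction": r.direction,
            }
            for r in results
        ]
    )


__all__ = [
    "AFComparisonResult",
    "DIRECTIONS",
    "fisher_exact_p",
    "two_by_two_p",
    "compare_af",
    "screen_populations",
    "af_ratio_string",
    "results_to_frame",
]
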