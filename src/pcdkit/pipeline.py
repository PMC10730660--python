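"""Pipeline orchestration: desk-scale reproduction and multi-stage runs.

``reproduce_table1`` recomputes the cohort prevalence summary (carrier
frequency, the three estimators and their average) from a cohort-counts
input and compares each "1:N" rendering against the published reference
values.  ``run_all`` chains the stages — catalog summary, allele-frequency
screen, prevalence, association, panel design, screening — writing one TSV
per stage plus a JSON run manifest; every random draw descends from one
top-level seed split deterministically per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import genotype_phenotype, panel_screening, population_af, prevalence
from . import synthetic_cohort, variant_catalog

logger = logging.getLogger(__name__)

#: Published reference values ("1:N" denominators) for the cohort summary.
TABLE1_PRINTED = {
    "carrier_frequency": 66,
    "hw": 17_641,
    "permutation": 17_161,
    "bayesian": 17_576,
    "average": 17_456,
}
#: Tolerance on N per quantity (the averaged value is printed truncated, so
#: nearest-integer rounding may differ by one).
TABLE1_TOLERANCE = {"average": 1}


def reproduce_table1(
    cohort: prevalence.CohortCounts | str | Path | None = None,
    prior: prevalence.PriorSpec = prevalence.JEFFREYS,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Recompute the cohort prevalence summary and flag printed-value matches."""
    if cohort is None:
        cohort = prevalence.CNGP_COHORT
    elif not isinstance(cohort, prevalence.CohortCounts):
        cohort = prevalence.load_cohort_counts(cohort)
    estimates = {
        "carrier_frequency": prevalence.carrier_frequency(cohort),
        "hw": prevalence.hw_prevalence(cohort),
        "permutation": prevalence.permutation_prevalence(cohort),
        "bayesian": prevalence.bayesian_prevalence(
            prevalence.cohort_to_allele_count(cohort), prior=prior, ci_level=ci_level
        ),
    }
    estimates["average"] = prevalence.average_prevalence(
        [estimates["hw"], estimates["permutation"], estimates["bayesian"]]
    )
    rows = []
    for name, est in estimates.items():
        n = est.ratio_n
        printed = TABLE1_PRINTED[name]
        tol = TABLE1_TOLERANCE.get(name, 0)
        # zero observed carriers makes every estimate degenerate, including
        # the Bayesian one whose rate is then pure prior mass
        degenerate = est.rate == 0 or cohort.carriers == 0
        ci = est.ci_ratio_ns()
        rows.append(
            {
                "quantity": name,
                "rate": est.rate,
                "ratio": est.ratio_string(),
                "ci_low": "" if ci is None else f"1:{ci[0]:,}",
                "ci_high": "" if ci is None else f"1:{ci[1]:,}",
                "printed_ratio": f"1:{printed:,}",
                "flag": "degenerate" if degenerate else "ok",
                "matches_printed": (not degenerate) and abs(n - printed) <= tol,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RunManifest:
    command_line: str
    config_snapshot: str
    seed: int
    input_checksums: dict
    tool_version: str
    timestamp: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def run_all(config: dict | str | Path, out_dir: str | Path, seed: int = 0) -> Path:
    """Run every configured stage into ``out_dir``; returns the directory.

    Config keys (all optional): ``simulate`` (mapping of SimulationConfig
    overrides), ``catalog`` / ``af_counts`` / ``patients`` /
    ``cohort_counts`` / ``newborns`` (input TSV paths), ``af_target`` /
    ``af_refs`` / ``fdr``, ``panel_k``, ``cutoff``.  Stages without input
    are skipped with an explicit log line.  Randomness descends from
    ``seed`` via per-stage spawned generators.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_paths = {
        k: cfg[k]
        for k in ("catalog", "af_counts", "patients", "cohort_counts", "newborns")
        if cfg.get(k)
    }
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("genotypes", "c0"), np.random.SeedSequence(seed).spawn(2)
        )
    }

    # -- stage: catalog -----------------------------------------------------
    stage = "catalog"
    try:
        if "catalog" in input_paths:
            catalog = variant_catalog.load_variant_table(input_paths["catalog"])
        else:
            catalog = variant_catalog.example_catalog()
        plp = variant_catalog.filter_plp(catalog)
        logger.info("[catalog] %d variants in, %d P/LP kept", len(catalog), len(plp))
        variant_catalog.summarize_spectrum(plp).to_frame().to_csv(
            out / "spectrum.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError(stage, str(exc)) from exc

    # -- stage: simulate ----------------------------------------------------
    stage = "simulate"
    genotypes = newborns = None
    try:
        if "newborns" not in input_paths:
            sim_cfg = synthetic_cohort.SimulationConfig(**cfg.get("simulate", {}))
            genotypes = synthetic_cohort.simulate_genotypes(
                sim_cfg, streams["genotypes"]
            )
            newborns_df = synthetic_cohort.simulate_c0(
                genotypes, sim_cfg, streams["c0"]
            )
            newborns_df.to_csv(
                out / "cohort.tsv", sep="\t", index=False, float_format="%.6g"
            )
            newborns = synthetic_cohort.to_newborn_records(newborns_df)
            logger.info("[simulate] %d newborns generated", len(newborns))
        else:
            newborns = panel_screening.load_newborn_table(input_paths["newborns"])
            logger.info("[simulate] %d newborns loaded from file", len(newborns))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: af screen ---------------------------------------------------
    stage = "af_screen"
    try:
        if "af_counts" in input_paths:
            counts = prevalence.load_allele_counts(input_paths["af_counts"])
            target = cfg.get("af_target") or sorted(set(counts["population"]))[0]
            flags = population_af.screen_populations(
                counts,
                target=target,
                refs=cfg.get("af_refs"),
                threshold=float(cfg.get("fdr", 0.05)),
            )
            population_af.results_to_frame(flags).to_csv(
                out / "af_flags.tsv", sep="\t", index=False
            )
            logger.info("[af_screen] %d variants tested", len(flags))
        else:
            logger.info("[af_screen] no af_counts input; stage skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: prevalence --------------------------------------------------
    stage = "prevalence"
    try:
        if "cohort_counts" in input_paths:
            cohort = prevalence.load_cohort_counts(input_paths["cohort_counts"])
        elif genotypes is not None:
            cohort = synthetic_cohort.cohort_counts_from_genotypes(genotypes)
        else:
            cohort = None
        if cohort is not None:
            reproduce_table1(cohort).to_csv(
                out / "prevalence.tsv", sep="\t", index=False
            )
            logger.info(
                "[prevalence] cohort n=%d carriers=%d", cohort.n_total, cohort.carriers
            )
        else:
            logger.info("[prevalence] no cohort input; stage skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: association -------------------------------------------------
    stage = "association"
    try:
        if "patients" in input_paths:
            patients = genotype_phenotype.load_patient_table(input_paths["patients"])
            assoc = genotype_phenotype.run_association_screen(patients)
            genotype_phenotype.results_to_frame(assoc).to_csv(
                out / "association.tsv", sep="\t", index=False
            )
            logger.info(
                "[association] %d patients, %d tests", len(patients), len(assoc)
            )
        else:
            logger.info("[association] no patients input; stage skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: panel -------------------------------------------------------
    stage = "panel"
    try:
        if genotypes is not None:
            sim_cfg = synthetic_cohort.SimulationConfig(**cfg.get("simulate", {}))
            afs = dict(sim_cfg.variant_afs)
        elif "af_counts" in input_paths:
            counts = prevalence.load_allele_counts(input_paths["af_counts"])
            target = cfg.get("af_target") or sorted(set(counts["population"]))[0]
            tc = counts[counts["population"] == target]
            afs = {
                str(v): float(ac) / float(an)
                for v, ac, an in zip(
                    tc["variant"], tc["allele_count"], tc["allele_number"]
                )
                if ac > 0
            }
        else:
            afs = None
        if afs:
            k = min(int(cfg.get("panel_k", 10)), len(afs))
            spec = panel_screening.design_panel(afs, k)
            pd.DataFrame(
                {
                    "rank": range(1, k + 1),
                    "site": spec.sites,
                    "allele_coverage": spec.allele_coverage,
                    "one_allele_coverage": spec.patient_one_allele_coverage,
                    "two_allele_coverage": spec.patient_two_allele_coverage,
                }
            ).to_csv(out / "panel.tsv", sep="\t", index=False)
            logger.info("[panel] top-%d sites, allele coverage %.3f", k,
                        spec.allele_coverage)
        else:
            logger.info("[panel] no allele-frequency input; stage skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- stage: screening ---------------------------------------------------
    stage = "screening"
    try:
        if newborns:
            cutoff = float(cfg.get("cutoff", panel_screening.DEFAULT_CUTOFF))
            panel_screening.screen_outcomes(newborns, cutoff).to_csv(
                out / "outcomes.tsv", sep="\t", index=False, float_format="%.6g"
            )
            metrics = pd.concat(
                [
                    panel_screening.screen_cohort(newborns, cutoff, mode).to_frame()
                    for mode in ("combined", "msms_only")
                ]
            )
            metrics.to_csv(out / "screening_metrics.tsv", sep="\t", index=False)
            logger.info("[screening] %d newborns screened", len(newborns))
        else:
            logger.info("[screening] no newborn cohort; stage skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    checksums = {
        str(p): _sha256(Path(p)) for p in input_paths.values() if Path(p).exists()
    }
    RunManifest(
        command_line=" ".join(sys.argv),
        config_snapshot=yaml.safe_dump(cfg, sort_keys=True),
        seed=seed,
        input_checksums=checksums,
        tool_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    ).write(out / "manifest.json")
    return out


__all__ = [
    "TABLE1_PRINTED",
    "RunManifest",
    "StageError",
    "reproduce_table1",
    "load_config",
    "run_all",
]
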