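import numpy as np
import pytest

from oracles import conditional_mle_or_grid, fisher_two_sided_oracle
from pcdkit.genotype_phenotype import (
    Allele,
    PatientRecord,
    contingency_table,
    group_patients,
    phenotype_frequencies,
    run_association_screen,
    test_association,
)

MISSENSE = lambda site: Allele(site, "missense")
NONSENSE = lambda site: Allele(site, "nonsense")


def patient(i, a1, a2, phenotypes=(), age="infant_child"):
    return PatientRecord(
        id=f"pt{i}",
        age_group=age,
        allele1=a1,
        allele2=a2,
        phenotypes=frozenset(phenotypes),
    )


def cohort_with_zygosity_signal(n_hom=60, n_het=60, p_hom=0.6, p_het=0.1, seed=11):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_hom):
        phen = {"cardiomyopathy"} if rng.random() < p_hom else set()
        records.append(patient(i, MISSENSE("c.760C>T"), MISSENSE("c.760C>T"), phen))
    for i in range(n_het):
        phen = {"cardiomyopathy"} if rng.random() < p_het else set()
        records.append(
            patient(n_hom + i, MISSENSE("c.760C>T"), NONSENSE("c.51C>G"), phen)
        )
    return records


class TestPatientRecord:
    def test_zygosity_derived_from_allele_identity(self):
        hom = patient(0, MISSENSE("c.760C>T"), MISSENSE("c.760C>T"))
        het = patient(1, MISSENSE("c.760C>T"), MISSENSE("c.1400C>G"))
        assert hom.zygosity == "homozygous"
        assert het.zygosity == "compound_het"

    def test_type_pair_is_unordered(self):
        a = patient(0, MISSENSE("c.1A>G"), NONSENSE("c.2A>G"))
        b = patient(1, NONSENSE("c.3A>G"), MISSENSE("c.4A>G"))
        assert a.type_pair == b.type_pair == ("missense", "nonsense")


class TestGrouping:
    def test_variant_homozygous_in_group_by_construction(self):
        records = [
            patient(0, MISSENSE("c.760C>T"), MISSENSE("c.760C>T")),
            patient(1, MISSENSE("c.760C>T"), MISSENSE("c.760C>T")),
            patient(2, MISSENSE("c.760C>T"), MISSENSE("c.1400C>G")),
            patient(3, MISSENSE("c.844C>T"), MISSENSE("c.844C>T")),
            patient(4, NONSENSE("c.51C>G"), MISSENSE("c.1400C>G")),
        ]
        in_g, out_g = group_patients(records, "variant_homozygous", "c.760C>T")
        assert len(in_g) == 2 and len(out_g) == 3

    def test_type_combination_reproduces_published_proportion(self):
        """177 of 293 patients carry two missense alleles (60.4%)."""
        records = [
            patient(i, MISSENSE("c.1A>G"), MISSENSE("c.2A>G")) for i in range(177)
        ]
        records += [
            patient(177 + i, NONSENSE("c.3A>G"), NONSENSE("c.4A>G"))
            for i in range(43)
        ]
        records += [
            patient(220 + i, NONSENSE("c.3A>G"), MISSENSE("c.2A>G"))
            for i in range(34)
        ]
        records += [
            patient(254 + i, Allele("c.5+1G>A", "splicing"), MISSENSE("c.2A>G"))
            for i in range(39)
        ]
        in_g, out_g = group_patients(
            records, "type_combination", ("missense", "missense")
        )
        assert len(records) == 293
        assert len(in_g) == 177

    def test_all_homozygous_cohort_empties_zygosity_outgroup(self):
        records = [
            patient(i, MISSENSE("c.760C>T"), MISSENSE("c.760C>T")) for i in range(5)
        ]
        in_g, out_g = group_patients(records, "zygosity")
        assert len(in_g) == 5 and out_g == []

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            group_patients([], "by_horoscope")


class TestAssociationTest:
    def test_balanced_table_is_null(self):
        res = test_association([[1, 1], [1, 1]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_outgroup_cell_gives_infinite_odds_ratio(self):
        res = test_association([[4, 0], [6, 20]])
        assert np.isinf(res.odds_ratio) and res.odds_ratio > 0

    def test_zero_ingroup_cell_gives_zero_odds_ratio(self):
        res = test_association([[0, 4], [20, 6]])
        assert res.odds_ratio == 0.0

    def test_matches_enumeration_and_likelihood_grid_oracles(self):
        table = [[5, 5], [2, 8]]
        res = test_association(table)
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)
        or_grid, step = conditional_mle_or_grid(table)
        assert abs(np.log(res.odds_ratio) - np.log(or_grid)) <= step

    def test_all_zero_table_is_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            res = test_association([[0, 0], [0, 0]])
        assert res.p_value == 1.0 and np.isnan(res.odds_ratio)


class TestScreen:
    def test_single_test_q_equals_p(self):
        records = [
            patient(0, MISSENSE("c.1A>G"), MISSENSE("c.1A>G"), {"cardiomyopathy"}),
            patient(1, MISSENSE("c.1A>G"), MISSENSE("c.2A>G")),
        ]
        results = run_association_screen(
            records, schemes=["zygosity"], phenotypes=["cardiomyopathy"]
        )
        assert len(results) == 1
        assert results[0].q_value == results[0].p_value

    def test_null_cohorts_rarely_flagged(self):
        """Phenotypes independent of genotype: BH keeps discoveries near zero."""
        rng = np.random.default_rng(99)
        flagged = total = 0
        for _ in range(200):
            records = []
            for i in range(40):
                a1 = MISSENSE("c.760C>T") if rng.random() < 0.5 else NONSENSE("c.51C>G")
                a2 = MISSENSE("c.760C>T") if rng.random() < 0.5 else NONSENSE("c.51C>G")
                phen = {"cardiomyopathy"} if rng.random() < 0.2 else set()
                records.append(patient(i, a1, a2, phen))
            results = run_association_screen(
                records, phenotypes=["cardiomyopathy"]
            )
            flagged += sum(r.q_value < 0.05 for r in results)
            total += len(results)
        assert total > 0
        assert flagged / total < 0.02

    def test_planted_zygosity_signal_recovered(self):
        records = cohort_with_zygosity_signal()
        results = run_association_screen(
            records, schemes=["zygosity"], phenotypes=["cardiomyopathy"]
        )
        (res,) = results
        assert res.q_value < 0.05
        assert res.odds_ratio > 1

    def test_screen_invariant_to_record_order(self):
        records = cohort_with_zygosity_signal(seed=3)
        fwd = run_association_screen(records)
        rev = run_association_screen(records[::-1])
        key = lambda r: (r.group_label, r.phenotype)
        assert {key(r): (r.p_value, r.q_value) for r in fwd} == {
            key(r): (r.p_value, r.q_value) for r in rev
        }


class TestPhenotypeFrequencies:
    def test_published_infant_denominators(self):
        records = [
            patient(
                i,
                MISSENSE("c.1A>G"),
                MISSENSE("c.1A>G"),
                (["cardiomyopathy"] if i < 71 else [])
                + (["hypoglycemia"] if i < 32 else []),
            )
            for i in range(194)
        ]
        freq = phenotype_frequencies(records, "infant_child")
        by_phen = dict(zip(freq["phenotype"], zip(freq["count"], freq["percent"])))
        # exact arithmetic: 71/194 = 36.6% at one decimal
        assert by_phen["cardiomyopathy"] == (71, 36.6)
        assert by_phen["hypoglycemia"] == (32, 16.5)

    def test_empty_phenotype_sets_count_zero(self):
        records = [patient(i, MISSENSE("c.1A>G"), MISSENSE("c.1A>G")) for i in range(3)]
        freq = phenotype_frequencies(records, "infant_child")
        assert (freq["count"] == 0).all()

    def test_empty_stratum_rejected(self):
        records = [patient(0, MISSENSE("c.1A>G"), MISSENSE("c.1A>G"), age="adult")]
        with pytest.raises(ValueError):
            phenotype_frequencies(records, "infant_child")
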