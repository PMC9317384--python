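"""Retention cascade, Mendelian checks, trio phasing and classification."""

import itertools

import numpy as np
import pytest

from ocadx import datasets
from ocadx.variants import (
    AnnotatedVariant,
    FamilyInput,
    HYPOMORPHIC_PAIR,
    MendelianError,
    PhasedGenotype,
    TrioGenotype,
    check_mendelian,
    classify_genotype,
    filter_variants,
    phase_trio,
    prioritize_cohort,
)

DAMAGING6 = {t: "damaging" for t in
             ("polyphen2", "sift", "mutation_taster", "mutation_assessor",
              "fathmm", "fathmm_mkl")}


def compliant(name="V", gene="TYR", pos=1000, **kw):
    base = dict(
        name=name, gene=gene, chrom="chr11", pos=pos, ref="A", alt="G",
        consequence="missense", maf={"1000G": 0.0001},
        gnomad_hom_or_hemi_count=0, predictor_calls=dict(DAMAGING6),
        in_clinvar_or_hgmd_pathogenic=False, splice_predicted_damaging=False,
        acmg_class="LP",
    )
    base.update(kw)
    return AnnotatedVariant(**base)


class TestFilter:
    def test_each_rule_excludes_its_violator(self):
        # toy table: each variant violates exactly one retention rule
        violators = [
            compliant("bad_consequence", consequence="intronic"),
            compliant("off_panel", gene="BRCA1"),
            compliant("common_ar", maf={"1000G": 0.02}),
            compliant("common_ad", gene="PAX6", maf={"EVS": 0.005}),
            compliant("gnomad_hom", gnomad_hom_or_hemi_count=3),
            compliant(
                "weak_evidence",
                predictor_calls={**DAMAGING6, "sift": "benign",
                                 "fathmm": "benign", "fathmm_mkl": "missing",
                                 "mutation_assessor": "benign"},
            ),
            compliant("silent_no_splice", consequence="synonymous"),
            compliant("benign_acmg", acmg_class="B"),
        ]
        keepers = [
            compliant("good_missense"),
            compliant(
                "good_splice",
                consequence="splice_site_20bp",
                splice_predicted_damaging=True,
            ),
        ]
        overrides = [
            compliant(
                "Ser192Tyr",
                maf={"dbSNP": 0.254},
                gnomad_hom_or_hemi_count=18123,
                predictor_calls={t: "benign" for t in DAMAGING6},
                acmg_class="B",
            ),
            compliant(
                "Arg402Gln",
                maf={"dbSNP": 0.176},
                gnomad_hom_or_hemi_count=9205,
                predictor_calls={t: "benign" for t in DAMAGING6},
                acmg_class="B",
            ),
        ]
        retained, audit = filter_variants(violators + keepers + overrides)
        names = {v.name for v in retained}
        assert names == {"good_missense", "good_splice", "Ser192Tyr", "Arg402Gln"}
        by_name = {a.variant: a for a in audit}
        assert by_name["Ser192Tyr"].override and "manual-inspection" in by_name[
            "Ser192Tyr"
        ].notes
        expected_failures = {
            "bad_consequence": "consequence",
            "off_panel": "panel",
            "common_ar": "maf",
            "common_ad": "maf",
            "gnomad_hom": "gnomad_hom",
            "weak_evidence": "pathogenicity_evidence",
            "silent_no_splice": "splice_prediction",
            "benign_acmg": "acmg",
        }
        for name, rule in expected_failures.items():
            assert by_name[name].failed_rules == (rule,), name

    def test_common_polymorphism_retained_despite_maf(self):
        v = compliant(
            "Ser192Tyr", maf={"dbSNP": 0.254}, gnomad_hom_or_hemi_count=18000,
            acmg_class="B",
        )
        retained, audit = filter_variants([v])
        assert retained == [v] and audit[0].override

    def test_empty_input_empty_output(self):
        retained, audit = filter_variants([])
        assert retained == [] and audit == []

    def test_tightening_maf_threshold_is_monotone(self):
        rng = np.random.default_rng(0)
        variants = [
            compliant(f"v{i}", maf={"1000G": float(rng.uniform(0, 0.02))})
            for i in range(30)
        ]
        kept = None
        for thr in (0.02, 0.01, 0.005, 0.001, 0.0):
            names = {
                v.name
                for v in filter_variants(
                    variants, maf_thresholds={"AR": thr}
                )[0]
            }
            if kept is not None:
                assert names <= kept
            kept = names

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            compliant("bad", maf={"1000G": 1.5})


class TestMendelian:
    @pytest.mark.parametrize(
        "proband,father,mother,expected",
        [
            ("Hom", "WT", "Het", "inconsistent"),
            ("Het", "Het", "WT", "consistent"),
            ("Hom", "Het", "Het", "consistent"),
            ("WT", "Hom", "WT", "inconsistent"),
            ("Het", "WT", "WT", "inconsistent"),
        ],
    )
    def test_single_variant_cases(self, proband, father, mother, expected):
        trio = TrioGenotype("X", proband, father, mother)
        assert check_mendelian(trio) == expected

    def test_missing_genotype_is_untestable(self):
        assert check_mendelian(TrioGenotype("X", "Het", None, "WT")) == "untestable"

    def test_all_published_family_configurations_are_consistent(self):
        for fam, cfg in datasets.TABLE2_GENOTYPES.items():
            probands = [
                ind
                for ind in {i for roles in cfg.values() for i in roles}
                if not ind.endswith(("_F", "_M")) and ind not in ("P8",)
            ]
            parents = {
                "F1": ("P1_F", "P1_M"), "F2": ("P2_F", "P2_M"),
                "F3": ("P3_F", "P3_M"), "F45": ("F45_F", "F45_M"),
                "F6": ("P6_F", "P6_M"), "F78": ("P8", "P7_M"),
            }[fam]
            for pid in probands:
                for var, roles in cfg.items():
                    trio = TrioGenotype(
                        var,
                        roles.get(pid, "WT"),
                        roles.get(parents[0], "WT"),
                        roles.get(parents[1], "WT"),
                    )
                    assert check_mendelian(trio) == "consistent", (fam, pid, var)


def brute_force_phase(trios):
    """Enumerate every allele assignment consistent with the trio genotypes.

    Independent oracle: for each variant, list all (on_paternal,
    on_maternal) placements compatible with one transmissible allele per
    parent; the variant's phase is resolved iff all joint assignments
    agree.  Returns (paternal, maternal, ambiguous) or None if no
    assignment exists.
    """
    dose = {"WT": (0,), "Het": (0, 1), "Hom": (1,)}
    target = {"WT": 0, "Het": 1, "Hom": 2}
    per_variant = []
    carried = []
    for trio in trios:
        if trio.proband == "WT":
            continue
        opts = sorted(
            {
                (bool(p), bool(m))
                for p in dose[trio.father]
                for m in dose[trio.mother]
                if p + m == target[trio.proband]
            }
        )
        if not opts:
            return None
        per_variant.append(opts)
        carried.append(trio.variant)
    paternal, maternal, ambiguous = set(), set(), set()
    for var, opts in zip(carried, per_variant):
        pats = {o[0] for o in opts}
        mats = {o[1] for o in opts}
        if len(opts) == 1:
            if opts[0][0]:
                paternal.add(var)
            if opts[0][1]:
                maternal.add(var)
        else:
            assert pats == {True, False} or mats == {True, False}
            ambiguous.add(var)
    return paternal, maternal, ambiguous


def random_consistent_trios(rng, n_variants):
    trios = []
    for i in range(n_variants):
        father, mother = rng.choice(["WT", "Het", "Hom"], size=2)
        dose = {"WT": (0,), "Het": (0, 1), "Hom": (1,)}
        p = int(rng.choice(dose[father]))
        m = int(rng.choice(dose[mother]))
        proband = ("WT", "Het", "Hom")[p + m]
        trios.append(TrioGenotype(f"v{i}", proband, str(father), str(mother)))
    return trios


class TestPhasing:
    def test_family1_resolves_to_published_alleles(self):
        cfg = datasets.TABLE2_GENOTYPES["F1"]
        trios = [
            TrioGenotype(v, r["P1"], r["P1_F"], r["P1_M"]) for v, r in cfg.items()
        ]
        phased = phase_trio(trios)
        assert phased.phase_status == "resolved"
        assert phased.paternal == {"Ser192Tyr", "Arg77Gln"}
        assert phased.maternal == {"Ser192Tyr", "Arg402Gln"}

    def test_family45_polymorphism_is_ambiguous(self):
        cfg = datasets.TABLE2_GENOTYPES["F45"]
        trios = [
            TrioGenotype(v, r["P4"], r["F45_F"], r["F45_M"]) for v, r in cfg.items()
        ]
        phased = phase_trio(trios)
        assert phased.phase_status == "ambiguous"
        assert phased.ambiguous == {"Arg402Gln"}
        assert "Ser192Tyr" in phased.paternal  # forced by Hom father
        assert "Gly47Asp" in phased.maternal

    def test_homozygous_variant_lands_on_both_alleles(self):
        phased = phase_trio([TrioGenotype("X", "Hom", "Het", "Het")])
        assert "X" in phased.paternal and "X" in phased.maternal
        assert phased.phase_status == "resolved"

    def test_obligate_transmitter_forces_phase(self):
        # Het proband, Hom father, Het mother: father must have transmitted
        phased = phase_trio([TrioGenotype("X", "Het", "Hom", "Het")])
        assert phased.paternal == {"X"} and not phased.ambiguous

    def test_inconsistent_trio_raises_naming_variant(self):
        with pytest.raises(MendelianError, match="badvar"):
            phase_trio([TrioGenotype("badvar", "Hom", "WT", "Het")])

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            trios = random_consistent_trios(rng, int(rng.integers(1, 5)))
            expected = brute_force_phase(trios)
            assert expected is not None
            phased = phase_trio(trios)
            assert (phased.paternal, phased.maternal, phased.ambiguous) == expected


PATHOGENIC = {"Arg77Gln", "Cys247Arg", "Met96Asnfs*73", "Gly109Arg",
              "Gly47Asp", "Met1Val", "Pro152Arg"}


class TestClassification:
    def test_patient3_is_biallelic_pathogenic(self):
        phased = PhasedGenotype(
            paternal={"Gly109Arg"}, maternal={"Met96Asnfs*73"}
        )
        cls = classify_genotype(phased, PATHOGENIC)
        assert cls.classification == "biallelic_pathogenic"

    def test_patient7_is_pathogenic_trans_hypomorphic(self):
        phased = PhasedGenotype(
            paternal={"Arg402Gln", "Pro152Arg"},
            maternal={"Arg402Gln", "Ser192Tyr"},
        )
        cls = classify_genotype(phased, PATHOGENIC)
        assert cls.classification == "pathogenic_trans_hypomorphic"

    def test_incomplete_haplotype_is_carrier_only(self):
        phased = PhasedGenotype(paternal={"Pro152Arg"}, maternal={"Ser192Tyr"})
        assert classify_genotype(phased, PATHOGENIC).classification == "carrier_only"

    def test_polymorphisms_in_trans_alone_are_not_a_diagnosis(self):
        phased = PhasedGenotype(paternal={"Ser192Tyr"}, maternal={"Arg402Gln"})
        assert classify_genotype(phased, PATHOGENIC).classification == "none"

    def test_unresolved_phase_that_matters_is_flagged(self):
        # family 4/5 pattern: polymorphism placement decides the diagnosis
        phased = PhasedGenotype(
            paternal={"Ser192Tyr"}, maternal={"Gly47Asp"}, ambiguous={"Arg402Gln"}
        )
        cls = classify_genotype(phased, PATHOGENIC)
        assert cls.classification == "ambiguous_requires_haplotyping"

    def test_symmetric_under_parental_label_swap(self):
        rng = np.random.default_rng(5)
        pool = sorted(PATHOGENIC | HYPOMORPHIC_PAIR)
        for _ in range(100):
            pat = {v for v in pool if rng.random() < 0.3}
            mat = {v for v in pool if rng.random() < 0.3}
            amb = {v for v in pool if rng.random() < 0.1} - pat - mat
            a = classify_genotype(PhasedGenotype(pat, mat, amb), PATHOGENIC)
            b = classify_genotype(PhasedGenotype(mat, pat, amb), PATHOGENIC)
            assert a.classification == b.classification


class TestCohort:
    def test_full_published_cohort_with_phase_resolution(self):
        families, _, _, pathogenic = datasets.load_table2_cohort()
        resolution = {"Arg402Gln": "paternal"}
        reports, counts = prioritize_cohort(
            families, pathogenic,
            resolutions={"P4": resolution, "P5": resolution},
        )
        assert counts == {
            "pathogenic_trans_hypomorphic": 7,
            "biallelic_pathogenic": 1,
        }
        by_id = {r.proband_id: r for r in reports}
        assert by_id["P3"].classification.classification == "biallelic_pathogenic"

    def test_without_resolution_sisters_are_ambiguous(self):
        families, _, _, pathogenic = datasets.load_table2_cohort()
        reports, counts = prioritize_cohort(families, pathogenic)
        assert counts["ambiguous_requires_haplotyping"] == 2
        flagged = {
            r.proband_id
            for r in reports
            if r.classification is not None
            and r.classification.classification == "ambiguous_requires_haplotyping"
        }
        assert flagged == {"P4", "P5"}

    def test_father_is_phased_through_his_child(self):
        families, _, _, pathogenic = datasets.load_table2_cohort()
        reports, _ = prioritize_cohort(families, pathogenic)
        p8 = next(r for r in reports if r.proband_id == "P8")
        assert p8.classification.classification == "pathogenic_trans_hypomorphic"
        alleles = {frozenset(p8.phased.paternal), frozenset(p8.phased.maternal)}
        assert frozenset({"Arg402Gln", "Pro152Arg"}) in alleles
        assert frozenset({"Arg402Gln", "Ser192Tyr"}) in alleles

    def test_empty_cohort(self):
        reports, counts = prioritize_cohort([], PATHOGENIC)
        assert reports == [] and counts == {}

    def test_per_family_errors_do_not_abort_cohort(self):
        bad = FamilyInput(
            "FX", "PX", (TrioGenotype("v", "Hom", "WT", "WT"),)
        )
        good = FamilyInput(
            "FY", "PY", (TrioGenotype("Pro152Arg", "Het", "Het", "WT"),)
        )
        reports, counts = prioritize_cohort([bad, good], PATHOGENIC)
        by_id = {r.proband_id: r for r in reports}
        assert by_id["PX"].error is not None
        assert by_id["PY"].classification.classification == "carrier_only"
        assert counts.get("error") == 1
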