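"""Packaged fixtures: the published cohort tables and default configs.

Ships the eight-patient phenotype table, the six-family TYR trio
genotypes (as VCF + PED plus an annotation sidecar), the gene panel with
inheritance modes, a default occipital montage, and a *synthetic*
microsatellite table for the sister pair (the original fragment sizes are
not public; the synthetic table reproduces the published verdict that the
sisters are haplo-identical across the block).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import io as ocio
from .variants import FamilyInput, TrioGenotype, filter_variants


def _data_path(name: str) -> Path:
    return Path(resources.files("ocadx.data") / name)


def table1_phenotypes_path() -> Path:
    return _data_path("table1_phenotypes.tsv")


def trio_vcf_path() -> Path:
    return _data_path("table2_trios.vcf")


def trio_ped_path() -> Path:
    return _data_path("table2_trios.ped")


def annotations_path() -> Path:
    return _data_path("tyr_variant_annotations.tsv")


def gene_panel_path() -> Path:
    return _data_path("gene_panel.tsv")


def montage_path() -> Path:
    return _data_path("montage.yaml")


def str_table_path() -> Path:
    """Synthetic STR genotypes for the sister pair and their parents."""
    return _data_path("str_family45_synthetic.tsv")


#: Trio genotype configurations of the six families (eight patients).
#: Per family: {variant name -> {individual -> WT|Het|Hom}}; individuals
#: absent from a variant's map are WT.
TABLE2_GENOTYPES: dict[str, dict[str, dict[str, str]]] = {
    "F1": {
        "Arg402Gln": {"P1": "Het", "P1_F": "WT", "P1_M": "Hom"},
        "Ser192Tyr": {"P1": "Hom", "P1_F": "Hom", "P1_M": "Het"},
        "Arg77Gln": {"P1": "Het", "P1_F": "Het", "P1_M": "WT"},
    },
    "F2": {
        "Arg402Gln": {"P2": "Hom", "P2_F": "Hom", "P2_M": "Het"},
        "Ser192Tyr": {"P2": "Het", "P2_F": "Het", "P2_M": "WT"},
        "Cys247Arg": {"P2": "Het", "P2_F": "WT", "P2_M": "Het"},
    },
    "F3": {
        "Met96Asnfs*73": {"P3": "Het", "P3_F": "WT", "P3_M": "Het"},
        "Gly109Arg": {"P3": "Het", "P3_F": "Het", "P3_M": "WT"},
    },
    "F45": {
        "Arg402Gln": {"P4": "Het", "P5": "Het", "F45_F": "Het", "F45_M": "Het"},
        "Ser192Tyr": {"P4": "Het", "P5": "Het", "F45_F": "Hom", "F45_M": "WT"},
        "Gly47Asp": {"P4": "Het", "P5": "Het", "F45_F": "WT", "F45_M": "Het"},
    },
    "F6": {
        "Arg402Gln": {"P6": "Hom", "P6_F": "Het", "P6_M": "Het"},
        "Ser192Tyr": {"P6": "Het", "P6_F": "Hom", "P6_M": "Het"},
        "Met1Val": {"P6": "Het", "P6_F": "WT", "P6_M": "Het"},
    },
    "F78": {
        "Arg402Gln": {"P7": "Hom", "P8": "Hom", "P7_M": "Het"},
        "Ser192Tyr": {"P7": "Het", "P8": "Het", "P7_M": "Hom"},
        "Pro152Arg": {"P7": "Het", "P8": "Het", "P7_M": "WT"},
    },
}

#: family membership: individual -> (family, father, mother, sex, affected)
TABLE2_PED: tuple[tuple[str, str, str, str, int, int], ...] = (
    ("F1", "P1", "P1_F", "P1_M", 2, 2),
    ("F1", "P1_F", "0", "0", 1, 1),
    ("F1", "P1_M", "0", "0", 2, 1),
    ("F2", "P2", "P2_F", "P2_M", 1, 2),
    ("F2", "P2_F", "0", "0", 1, 1),
    ("F2", "P2_M", "0", "0", 2, 1),
    ("F3", "P3", "P3_F", "P3_M", 1, 2),
    ("F3", "P3_F", "0", "0", 1, 1),
    ("F3", "P3_M", "0", "0", 2, 1),
    ("F45", "P4", "F45_F", "F45_M", 2, 2),
    ("F45", "P5", "F45_F", "F45_M", 2, 2),
    ("F45", "F45_F", "0", "0", 1, 1),
    ("F45", "F45_M", "0", "0", 2, 1),
    ("F6", "P6", "P6_F", "P6_M", 1, 2),
    ("F6", "P6_F", "0", "0", 1, 1),
    ("F6", "P6_M", "0", "0", 2, 1),
    ("F78", "P7", "P8", "P7_M", 1, 2),
    ("F78", "P8", "0", "0", 1, 2),
    ("F78", "P7_M", "0", "0", 2, 1),
)


def table2_sample_genotypes() -> dict[str, dict[str, str]]:
    """Flatten the family configurations to {sample -> {variant -> state}}.

    Individuals are explicitly WT for variants segregating in their own
    family but untyped (absent) for other families' variants.
    """
    samples: dict[str, dict[str, str]] = {}
    members: dict[str, set[str]] = {}
    for fam, cfg in TABLE2_GENOTYPES.items():
        for roles in cfg.values():
            members.setdefault(fam, set()).update(roles)
    for fam, cfg in TABLE2_GENOTYPES.items():
        for ind in sorted(members[fam]):
            samples.setdefault(ind, {})
            for var, roles in cfg.items():
                samples[ind][var] = roles.get(ind, "WT")
    return samples


def load_table2_cohort(
    *,
    vcf_path=None,
    ped_path=None,
    annotation_path=None,
    panel_path=None,
):
    """Build the analysable cohort from VCF + PED + annotations.

    Returns (families, retained_variants, audit, pathogenic_names).  Each
    affected individual with both parents genotyped becomes a trio family;
    an affected individual without genotyped parents who is themself a
    parent of a trio proband is queued for reverse-segregation phasing
    through that child (the cascade-diagnosis path).
    """
    sites, genotypes = ocio.read_trio_vcf(vcf_path or trio_vcf_path())
    ped = ocio.read_ped(ped_path or trio_ped_path())
    annotations = ocio.read_annotation_table(annotation_path or annotations_path())
    panel = ocio.read_gene_panel(panel_path or gene_panel_path())

    retained, audit = filter_variants(annotations, panel)
    retained_names = [v.name for v in retained if v.name in {s["name"] for s in sites}]
    pathogenic = {v.name for v in retained if v.acmg_class in ("P", "LP")}

    rows = {r.individual: r for r in ped.itertuples()}
    families: list[FamilyInput] = []
    for r in ped.itertuples():
        if r.phenotype != 2:
            continue
        pid = r.individual
        if r.father in genotypes and r.mother in genotypes:
            trios = tuple(
                TrioGenotype(
                    variant=name,
                    proband=genotypes[pid].get(name),
                    father=genotypes[r.father].get(name),
                    mother=genotypes[r.mother].get(name),
                )
                for name in retained_names
                if genotypes[pid].get(name) is not None
            )
            families.append(FamilyInput(r.family, pid, trios))
        else:
            # affected parent of a trio proband -> reverse segregation
            child_row = next(
                (
                    c
                    for c in ped.itertuples()
                    if c.phenotype == 2 and pid in (c.father, c.mother)
                ),
                None,
            )
            if child_row is None:
                families.append(
                    FamilyInput(r.family, pid, (), genotypes=genotypes.get(pid, {}))
                )
                continue
            role = "father" if child_row.father == pid else "mother"
            families.append(
                FamilyInput(
                    r.family,
                    pid,
                    (),
                    phase_via_child_of=child_row.individual,
                    parental_role=role,
                    genotypes={
                        k: v
                        for k, v in genotypes.get(pid, {}).items()
                        if k in retained_names
                    },
                )
            )
    return families, retained, audit, pathogenic
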