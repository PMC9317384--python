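"""Trio variant prioritization, segregation phasing and genotype classification.

Implements the diagnostic logic for TYR-related albinism with the
hypomorphic haplotype: a retention cascade over annotated variants, a
Mendelian/segregation phaser that assigns each proband variant to the
paternal or maternal allele (or flags it phase-ambiguous), and a
classifier that recognises

* ``biallelic_pathogenic`` — a pathogenic variant on each allele
  (classical compound heterozygote or homozygote);
* ``pathogenic_trans_hypomorphic`` — a pathogenic variant in trans with an
  allele carrying BOTH common polymorphisms Ser192Tyr and Arg402Gln (the
  hypomorphic haplotype p.[Ser192Tyr;Arg402Gln]);
* ``ambiguous_requires_haplotyping`` — an unresolved phase that could
  yield either a diagnostic or a non-diagnostic configuration;
* ``carrier_only`` / ``none``.

Genotype states are coded WT / Het / Hom; hemizygous males for X-linked
genes are encoded Hom.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

GT_STATES = ("WT", "Het", "Hom")

#: the two common TYR polymorphisms forming the hypomorphic haplotype
HYPOMORPHIC_PAIR = frozenset({"Ser192Tyr", "Arg402Gln"})

PREDICTOR_TOOLS = (
    "polyphen2",
    "sift",
    "mutation_taster",
    "mutation_assessor",
    "fathmm",
    "fathmm_mkl",
)

ADMISSIBLE_CONSEQUENCES = {
    "missense",
    "frameshift",
    "inframe_indel",
    "nonsense",
    "synonymous",
    "splice_site_20bp",
    "start_loss",
}

_SPLICE_LIKE = {"synonymous", "splice_site_20bp"}

MAF_SOURCES = ("1000G", "EVS", "dbSNP", "in_house")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePanelEntry:
    gene: str
    inheritance: str  # AR | AD | XL


@dataclass
class AnnotatedVariant:
    """One annotated variant as consumed from a VCF/TSV annotation table."""

    name: str  # short protein-level label, e.g. "Ser192Tyr"
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_p: str = ""
    consequence: str = "missense"
    maf: dict = field(default_factory=dict)  # source -> frequency
    gnomad_hom_or_hemi_count: int = 0
    predictor_calls: dict = field(default_factory=dict)  # tool -> damaging|benign|missing
    in_clinvar_or_hgmd_pathogenic: bool = False
    splice_predicted_damaging: bool = False
    acmg_class: str = "VUS"  # P | LP | VUS | LB | B

    def __post_init__(self) -> None:
        for src, f in self.maf.items():
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.name}: MAF {f} from {src} outside [0, 1]")
        calls = dict(self.predictor_calls)
        for tool in PREDICTOR_TOOLS:
            calls.setdefault(tool, "missing")
        unknown = set(calls) - set(PREDICTOR_TOOLS)
        if unknown:
            raise ValueError(f"{self.name}: unknown predictor tools {sorted(unknown)}")
        self.predictor_calls = calls

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def max_maf(self) -> float:
        """Maximum MAF across the population sources; missing counts as 0."""
        vals = [self.maf.get(s) for s in MAF_SOURCES]
        vals = [v for v in vals if v is not None]
        return max(vals) if vals else 0.0

    def n_damaging(self) -> int:
        return sum(1 for t in PREDICTOR_TOOLS if self.predictor_calls[t] == "damaging")


@dataclass(frozen=True)
class TrioGenotype:
    """Genotype of one variant in proband, father and mother."""

    variant: str
    proband: str
    father: str | None = "WT"
    mother: str | None = "WT"


@dataclass
class PhasedGenotype:
    """Proband allele assignment produced by segregation analysis.

    ``paternal``/``maternal`` hold variant names placed on the respective
    allele; Hom variants appear in both.  Variants whose parental origin
    cannot be pinned down are listed in ``ambiguous`` (and belong to
    exactly one, unknown, allele).
    """

    paternal: set = field(default_factory=set)
    maternal: set = field(default_factory=set)
    ambiguous: set = field(default_factory=set)

    @property
    def phase_status(self) -> str:
        return "resolved" if not self.ambiguous else "ambiguous"

    def carried(self) -> set:
        return self.paternal | self.maternal | self.ambiguous


DIAGNOSTIC_CLASSES = ("biallelic_pathogenic", "pathogenic_trans_hypomorphic")


@dataclass
class DiagnosticClassification:
    classification: str
    supporting_variants: tuple = ()

    @property
    def is_molecular_diagnosis(self) -> bool:
        return self.classification in DIAGNOSTIC_CLASSES


class MendelianError(ValueError):
    """Raised when a trio genotype cannot arise by biparental transmission."""


# ---------------------------------------------------------------------------
# Retention cascade
# ---------------------------------------------------------------------------

#: MAF ceilings per inheritance mode; XL treated like AR (recessive in males)
MAF_THRESHOLDS = {"AR": 0.01, "AD": 0.001, "XL": 0.01}

DEFAULT_PANEL = (
    GenePanelEntry("TYR", "AR"),
    GenePanelEntry("OCA2", "AR"),
    GenePanelEntry("TYRP1", "AR"),
    GenePanelEntry("SLC45A2", "AR"),
    GenePanelEntry("SLC38A8", "AR"),
    GenePanelEntry("DCT", "AR"),
    GenePanelEntry("PAX6", "AD"),
    GenePanelEntry("GPR143", "XL"),
)

#: variants always retained for manual inspection, bypassing rules 3-6
OVERRIDE_VARIANTS = frozenset(HYPOMORPHIC_PAIR)


@dataclass
class FilterDecision:
    variant: str
    retained: bool
    override: bool
    failed_rules: tuple = ()
    notes: tuple = ()


def filter_variants(
    variants,
    panel=DEFAULT_PANEL,
    *,
    maf_thresholds: dict | None = None,
    min_damaging: int = 3,
    override_names=OVERRIDE_VARIANTS,
):
    """Apply the retention cascade; returns (retained, audit trail).

    A variant survives iff all of: (1) admissible consequence class;
    (2) gene on the panel; (3) maximum MAF across population sources below
    the inheritance-mode ceiling; (4) zero gnomAD homozygotes/hemizygotes;
    (5) known-pathogenic in ClinVar/HGMD OR called damaging by >= 3 of the
    6 predictors — and splice-relevant (synonymous/splice-site) variants
    additionally need a damaging splice prediction; (6) ACMG class P, LP
    or VUS.  The two common TYR polymorphisms are always retained and
    tagged for manual inspection regardless of rules 3-6.
    """
    thresholds = dict(MAF_THRESHOLDS)
    if maf_thresholds:
        thresholds.update(maf_thresholds)
    modes = {e.gene: e.inheritance for e in panel}
    retained, audit = [], []
    for v in variants:
        failed, notes = [], []
        if v.consequence not in ADMISSIBLE_CONSEQUENCES:
            failed.append("consequence")
        if v.gene not in modes:
            failed.append("panel")
        if v.name in override_names and v.gene == "TYR" and "panel" not in failed:
            if "consequence" not in failed:
                retained.append(v)
                audit.append(
                    FilterDecision(v.name, True, True, notes=("manual-inspection",))
                )
                continue
        if v.gene in modes:
            ceiling = thresholds[modes[v.gene]]
            if v.max_maf() > ceiling:
                failed.append("maf")
            missing = [s for s in MAF_SOURCES if v.maf.get(s) is None]
            if missing:
                notes.append(f"maf-missing-treated-as-0:{','.join(missing)}")
        if v.gnomad_hom_or_hemi_count > 0:
            failed.append("gnomad_hom")
        evidence = v.in_clinvar_or_hgmd_pathogenic or v.n_damaging() >= min_damaging
        if not evidence:
            failed.append("pathogenicity_evidence")
        if v.consequence in _SPLICE_LIKE and not v.splice_predicted_damaging:
            failed.append("splice_prediction")
        if v.acmg_class not in ("P", "LP", "VUS"):
            failed.append("acmg")
        ok = not failed
        if ok:
            retained.append(v)
        audit.append(
            FilterDecision(v.name, ok, False, tuple(failed), tuple(notes))
        )
    return retained, audit


# ---------------------------------------------------------------------------
# Mendelian consistency and phasing
# ---------------------------------------------------------------------------

_DOSE = {"WT": (0,), "Het": (0, 1), "Hom": (1,)}


def check_mendelian(trio: TrioGenotype) -> str:
    """'consistent', 'inconsistent' or 'untestable' (missing genotype).

    Consistent iff the proband's allele count equals one transmissible
    paternal plus one transmissible maternal allele.
    """
    if trio.proband is None or trio.father is None or trio.mother is None:
        return "untestable"
    target = {"WT": {0}, "Het": {1}, "Hom": {2}}[trio.proband]
    for p in _DOSE[trio.father]:
        for m in _DOSE[trio.mother]:
            if p + m in target:
                return "consistent"
    return "inconsistent"


def _origin_options(trio: TrioGenotype) -> list:
    """Possible (on_paternal, on_maternal) placements of a proband variant."""
    target = {"WT": 0, "Het": 1, "Hom": 2}[trio.proband]
    opts = []
    for p in _DOSE[trio.father if trio.father is not None else "Het"]:
        for m in _DOSE[trio.mother if trio.mother is not None else "Het"]:
            if p + m == target and (bool(p), bool(m)) not in opts:
                opts.append((bool(p), bool(m)))
    return opts


def phase_trio(trios) -> PhasedGenotype:
    """Assign each proband-carried variant to a parental allele.

    For every variant, all transmissions compatible with the trio
    genotypes are enumerated: Hom variants sit on both alleles; a Het
    variant is resolved when exactly one parental origin is compatible
    (the other parent being WT, or one parent being an obligate Hom
    transmitter) and flagged ambiguous when both origins remain possible.
    Raises :class:`MendelianError` naming the first inconsistent variant.
    """
    phased = PhasedGenotype()
    for trio in trios:
        if trio.proband in (None, "WT"):
            continue
        opts = _origin_options(trio)
        if not opts:
            raise MendelianError(
                f"variant {trio.variant}: proband {trio.proband} not producible "
                f"from father {trio.father} / mother {trio.mother}"
            )
        if len(opts) == 1:
            on_pat, on_mat = opts[0]
            if on_pat:
                phased.paternal.add(trio.variant)
            if on_mat:
                phased.maternal.add(trio.variant)
        else:
            phased.ambiguous.add(trio.variant)
    return phased


def apply_phase_resolution(phased: PhasedGenotype, resolution: dict) -> PhasedGenotype:
    """Move ambiguous variants to the allele named by an external resolution.

    ``resolution`` maps variant name -> 'paternal' | 'maternal' (e.g. from
    microsatellite haplo-identity analysis).  Unknown names are ignored.
    """
    out = PhasedGenotype(
        paternal=set(phased.paternal),
        maternal=set(phased.maternal),
        ambiguous=set(phased.ambiguous),
    )
    for var, side in resolution.items():
        if var in out.ambiguous:
            if side not in ("paternal", "maternal"):
                raise ValueError(f"resolution for {var} must be paternal/maternal")
            out.ambiguous.discard(var)
            (out.paternal if side == "paternal" else out.maternal).add(var)
    return out


def phase_parent_via_offspring(
    parent_genotypes: dict, transmitted: set
) -> PhasedGenotype:
    """Phase a parent from the allele they demonstrably passed to a child.

    Cascade-diagnosis logic: once a proband's allele of parental origin is
    resolved, that allele IS one of the parent's two alleles; the parent's
    other allele follows from their own genotypes (Hom -> on both; Het ->
    on whichever allele is consistent with the transmission).  The
    transmitted set is reported as 'paternal' purely as a container label.
    """
    allele1, allele2 = set(), set()
    for var, state in parent_genotypes.items():
        if state == "WT":
            if var in transmitted:
                raise MendelianError(
                    f"parent transmitted {var} but is WT for it"
                )
            continue
        if state == "Hom":
            if var not in transmitted:
                raise MendelianError(
                    f"parent is Hom for {var} but did not transmit it"
                )
            allele1.add(var)
            allele2.add(var)
        elif state == "Het":
            (allele1 if var in transmitted else allele2).add(var)
    missing = transmitted - set(parent_genotypes)
    if missing:
        raise MendelianError(f"transmitted variants absent from parent: {missing}")
    return PhasedGenotype(paternal=allele1, maternal=allele2)


# ---------------------------------------------------------------------------
# Diagnostic classification
# ---------------------------------------------------------------------------


def _classify_resolved(
    paternal: frozenset, maternal: frozenset, pathogenic: frozenset, pair: frozenset
) -> str:
    pat_path = bool(paternal & pathogenic)
    mat_path = bool(maternal & pathogenic)
    if pat_path and mat_path:
        return "biallelic_pathogenic"
    if pat_path and pair <= maternal:
        return "pathogenic_trans_hypomorphic"
    if mat_path and pair <= paternal:
        return "pathogenic_trans_hypomorphic"
    # a "disease allele" carries a pathogenic variant or the full
    # hypomorphic pair in cis; carrying one alone is a carrier state
    disease = [
        bool(a & pathogenic) or pair <= a for a in (paternal, maternal)
    ]
    if any(disease):
        return "carrier_only"
    return "none"


def classify_genotype(
    phased: PhasedGenotype,
    pathogenic_set,
    hypomorphic_pair=HYPOMORPHIC_PAIR,
) -> DiagnosticClassification:
    """Classify a (possibly partially phased) proband genotype.

    With unresolved variants every assignment of each ambiguous variant to
    one allele is enumerated.  If all assignments agree, that class is
    returned; if they disagree on whether a molecular diagnosis exists,
    ``ambiguous_requires_haplotyping``; if all are diagnostic but the
    mechanism differs, the less specific ``pathogenic_trans_hypomorphic``
    is reported.  Symmetric under swapping the paternal/maternal labels.
    """
    pathogenic = frozenset(pathogenic_set)
    pair = frozenset(hypomorphic_pair)
    amb = sorted(phased.ambiguous)
    classes = set()
    for placement in itertools.product((True, False), repeat=len(amb)):
        pat = set(phased.paternal)
        mat = set(phased.maternal)
        for var, to_pat in zip(amb, placement):
            (pat if to_pat else mat).add(var)
        classes.add(_classify_resolved(frozenset(pat), frozenset(mat), pathogenic, pair))
    support = tuple(sorted(phased.carried() & (pathogenic | pair)))
    if len(classes) == 1:
        return DiagnosticClassification(classes.pop(), support)
    diag = {c for c in classes if c in DIAGNOSTIC_CLASSES}
    if diag and classes - diag:
        return DiagnosticClassification("ambiguous_requires_haplotyping", support)
    if diag:
        return DiagnosticClassification("pathogenic_trans_hypomorphic", support)
    if "carrier_only" in classes:
        return DiagnosticClassification("carrier_only", support)
    return DiagnosticClassification("none", support)


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------


@dataclass
class FamilyInput:
    """One analysable patient: their trio genotypes (or a parental link)."""

    family_id: str
    proband_id: str
    trios: tuple = ()  # TrioGenotype per retained variant
    #: if the proband is an untrioed parent of another proband, name them
    phase_via_child_of: str | None = None
    #: which parent the proband is in that child's trio
    parental_role: str = "father"
    #: the proband's own genotypes (needed for the parental-cascade path)
    genotypes: dict = field(default_factory=dict)


@dataclass
class FamilyReport:
    family_id: str
    proband_id: str
    phased: PhasedGenotype | None
    classification: DiagnosticClassification | None
    error: str | None = None


def prioritize_cohort(
    families,
    pathogenic_set,
    *,
    resolutions: dict | None = None,
    hypomorphic_pair=HYPOMORPHIC_PAIR,
):
    """Phase and classify every family; per-family failures do not abort.

    ``resolutions`` maps proband_id -> {variant -> paternal|maternal},
    e.g. the cis-placement of Arg402Gln derived from microsatellite
    haplo-identity.  Probands whose parents are not genotyped but who are
    themselves a genotyped parent of another proband are phased by reverse
    segregation through that child.  Returns (reports, summary counts).
    """
    resolutions = resolutions or {}
    reports: list[FamilyReport] = []
    phased_by_id: dict[str, PhasedGenotype] = {}
    deferred: list[FamilyInput] = []

    for fam in families:
        if fam.phase_via_child_of is not None:
            deferred.append(fam)
            continue
        try:
            for trio in fam.trios:
                if check_mendelian(trio) == "inconsistent":
                    raise MendelianError(
                        f"variant {trio.variant} Mendelian-inconsistent in "
                        f"family {fam.family_id}"
                    )
            phased = phase_trio(fam.trios)
            phased = apply_phase_resolution(
                phased, resolutions.get(fam.proband_id, {})
            )
            cls = classify_genotype(phased, pathogenic_set, hypomorphic_pair)
            phased_by_id[fam.proband_id] = phased
            reports.append(FamilyReport(fam.family_id, fam.proband_id, phased, cls))
        except (MendelianError, ValueError) as exc:
            log.error("family %s: %s", fam.family_id, exc)
            reports.append(
                FamilyReport(fam.family_id, fam.proband_id, None, None, str(exc))
            )

    for fam in deferred:
        try:
            child = phased_by_id.get(fam.phase_via_child_of)
            if child is None or child.phase_status != "resolved":
                raise MendelianError(
                    f"cannot phase {fam.proband_id} via child "
                    f"{fam.phase_via_child_of}: child phase unresolved"
                )
            transmitted = (
                child.paternal if fam.parental_role == "father" else child.maternal
            )
            phased = phase_parent_via_offspring(fam.genotypes, transmitted)
            cls = classify_genotype(phased, pathogenic_set, hypomorphic_pair)
            reports.append(FamilyReport(fam.family_id, fam.proband_id, phased, cls))
        except (MendelianError, ValueError) as exc:
            log.error("family %s: %s", fam.family_id, exc)
            reports.append(
                FamilyReport(fam.family_id, fam.proband_id, None, None, str(exc))
            )

    summary: dict[str, int] = {}
    for rep in reports:
        key = rep.classification.classification if rep.classification else "error"
        summary[key] = summary.get(key, 0) + 1
    return reports, summary
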