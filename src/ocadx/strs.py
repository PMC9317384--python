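"""Microsatellite haplo-identity of two siblings across a linkage block.

Nine highly polymorphic STR markers flanking TYR (chr11:85907157-90375771
in the motivating analysis) are treated as a single non-recombinant block:
if the siblings received the same parental allele from each parent at an
informative marker, they are haplo-identical across the interval.  This
settles cis/trans phase questions that trio segregation alone cannot —
two haplo-identical affected siblings with the same genotypes must carry
their shared variants in the same phase, inherited from a single parental
origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Transmission:
    """Decomposition of a child's unordered genotype into parental alleles."""

    status: str  # resolved | ambiguous | inconsistent
    paternal: int | None = None
    maternal: int | None = None


def infer_transmission(child, father, mother) -> Transmission:
    """Which allele value each parent transmitted at one marker.

    Enumerates all (paternal, maternal) allele choices whose unordered
    union equals the child's genotype.  A unique value decomposition is
    'resolved'; multiple distinct decompositions 'ambiguous'; none
    'inconsistent'.
    """
    child_ms = tuple(sorted(child))
    combos = {
        (p, m)
        for p in father
        for m in mother
        if tuple(sorted((p, m))) == child_ms
    }
    if not combos:
        return Transmission("inconsistent")
    if len(combos) == 1:
        p, m = next(iter(combos))
        return Transmission("resolved", p, m)
    return Transmission("ambiguous")


@dataclass
class HaploIdentityResult:
    """Verdict plus per-marker detail of sibling haplo-identity.

    A marker is *concordant* when both parents are heterozygous, both
    siblings' transmissions are resolvable, and the transmitted allele
    matches for each parent; *discordant* when resolvable transmissions
    differ for either parent; *inconsistent* markers (non-Mendelian) are
    excluded from the verdict and reported.  Verdict: non_identical iff
    any discordant marker; identical iff >= 1 concordant and none
    discordant; uninformative otherwise.
    """

    verdict: str
    per_marker: dict = field(default_factory=dict)
    inconsistent_markers: tuple = ()


def haplo_identity(genotypes: dict, sib1: str, sib2: str,
                   father: str = "father", mother: str = "mother",
                   markers=None) -> HaploIdentityResult:
    """Compare two siblings' parental transmissions across the STR block.

    ``genotypes``: {individual -> {marker -> (allele1, allele2)}}.  All
    four individuals must be typed at the same markers (or pass an
    explicit marker list).  Symmetric in ``sib1``/``sib2``.
    """
    if markers is None:
        markers = list(genotypes[sib1])
    for ind in (sib1, sib2, father, mother):
        missing = [m for m in markers if m not in genotypes.get(ind, {})]
        if missing:
            raise KeyError(f"{ind} missing genotypes at markers {missing}")
    detail: dict[str, str] = {}
    bad = []
    for m in markers:
        f, mo = genotypes[father][m], genotypes[mother][m]
        t1 = infer_transmission(genotypes[sib1][m], f, mo)
        t2 = infer_transmission(genotypes[sib2][m], f, mo)
        if t1.status == "inconsistent" or t2.status == "inconsistent":
            detail[m] = "inconsistent"
            bad.append(m)
            continue
        if t1.status == "resolved" and t2.status == "resolved":
            same_pat = t1.paternal == t2.paternal
            same_mat = t1.maternal == t2.maternal
            if not (same_pat and same_mat):
                detail[m] = "discordant"
                continue
            # equality is informative only where the parent is heterozygous
            if f[0] != f[1] and mo[0] != mo[1]:
                detail[m] = "concordant"
                continue
        detail[m] = "uninformative"
    states = set(detail.values())
    if "discordant" in states:
        verdict = "non_identical"
    elif "concordant" in states:
        verdict = "identical"
    else:
        verdict = "uninformative"
    return HaploIdentityResult(verdict, detail, tuple(bad))


def resolve_polymorphism_phase(
    haplo: HaploIdentityResult,
    phased,
    pathogenic_set,
    hypomorphic_pair,
    *,
    genotypes_match: bool = True,
) -> dict:
    """Derive a cis-phase resolution for an ambiguous common polymorphism.

    When two affected siblings are haplo-identical across the block and
    share the proband's genotype configuration, an ambiguous member of the
    hypomorphic pair must travel with the shared parental haplotypes: it
    is placed on the allele already carrying the *other* pair member,
    provided a pathogenic variant is resolved to the opposite allele (the
    inference that the two common polymorphisms were inherited in cis).
    Returns {variant -> 'paternal'|'maternal'}, empty when the genetic
    evidence does not support a resolution.
    """
    if haplo.verdict != "identical" or not genotypes_match:
        return {}
    pair = set(hypomorphic_pair)
    pathogenic = set(pathogenic_set)
    resolution: dict[str, str] = {}
    for var in phased.ambiguous & pair:
        (other,) = pair - {var}
        if other in phased.paternal and phased.maternal & pathogenic:
            resolution[var] = "paternal"
        elif other in phased.maternal and phased.paternal & pathogenic:
            resolution[var] = "maternal"
    return resolution
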