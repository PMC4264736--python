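"""Parent-of-origin assignment on the X by phase-by-transmission.

The X outside the pseudo-autosomal regions is hemizygous in males, so the
father contributes exactly one allele; after genotypes are recoded to their
true ploidy, essentially every high-quality heterozygous site in a daughter
can be phased, because the father's single allele always breaks the tie that
makes double-heterozygous autosomal sites uninformative.

A child genotype missing an allele a parent must have transmitted is an
"out-of-phase" genotype: evidence that the region around the SNP is deleted
on that parental chromosome.  Aggregating such sites over a candidate region
phases a hemizygous deletion to its parent of origin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .datamodel import VariantSite


class RegionClass(str, Enum):
    X_NONPAR = "X_nonPAR"
    PAR = "PAR"
    AUTOSOME_LIKE = "autosome-like"


class PhaseStatus(str, Enum):
    PHASED = "phased"
    UNINFORMATIVE = "uninformative"
    MENDELIAN_ERROR = "mendelian_error"
    OUT_OF_PHASE = "out_of_phase"


class DeletionOrigin(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNDETERMINED = "undetermined"


@dataclass
class TrioGenotype:
    """Ploidy-recoded genotype triplet at one site."""

    site: VariantSite
    child: tuple[str, ...]
    mother: tuple[str, ...]
    father: tuple[str, ...]
    region_class: RegionClass = RegionClass.X_NONPAR

    def __post_init__(self) -> None:
        if self.region_class is RegionClass.X_NONPAR and len(self.father) != 1:
            raise ValueError(
                f"{self.site.chrom}:{self.site.pos}: father must be hemizygous "
                f"on X outside the PAR, got {self.father!r}"
            )


@dataclass
class PhaseResult:
    status: PhaseStatus
    maternal_allele: Optional[str] = None
    paternal_allele: Optional[str] = None
    deletion_origin: Optional[DeletionOrigin] = None
    note: str = ""


def recode_ploidy(
    alleles: tuple[str, ...],
    sex: str,
    region_class: RegionClass,
    in_deletion: bool = False,
) -> tuple[tuple[str, ...], Optional[str]]:
    """Collapse apparent diploid calls to their true ploidy.

    A male X genotype outside the PAR, or any genotype inside a hemizygous
    deletion, is a single chromosome: "A/A" is really "A".  A heterozygous
    male call on X_nonPAR cannot be real; it is collapsed arbitrarily and
    flagged (data-quality problem, not fatal).  PAR and autosome-like
    genotypes are untouched.  Returns (recoded alleles, optional flag).
    """
    haploid = in_deletion or (sex == "male" and region_class is RegionClass.X_NONPAR)
    if not haploid or len(alleles) == 1:
        return alleles, None
    if alleles[0] == alleles[1]:
        return (alleles[0],), None
    return (alleles[0],), "heterozygous call at a haploid locus"


def _legal_transmissions(
    child: tuple[str, ...], mother: tuple[str, ...], father: tuple[str, ...]
) -> set[tuple[str, str]]:
    """All (maternal, paternal) allele assignments consistent with the trio."""
    out = set()
    orderings = [child] if len(child) == 1 else [child, child[::-1]]
    for ordering in orderings:
        m_allele = ordering[0]
        p_allele = ordering[-1]
        if m_allele in mother and p_allele in father:
            out.add((m_allele, p_allele))
    return out


def phase_by_transmission(trio: TrioGenotype) -> PhaseResult:
    """Resolve the parental origin of each child allele.

    A unique legal transmission yields a phased result; zero legal
    transmissions is a Mendelian error (a de novo point change is
    indistinguishable from a genotype error here and maps to the same
    status); several legal transmissions leave the site uninformative.
    """
    legal = _legal_transmissions(trio.child, trio.mother, trio.father)
    if not legal:
        return PhaseResult(
            status=PhaseStatus.MENDELIAN_ERROR,
            note="no legal transmission (genotype error or de novo variant)",
        )
    if len(legal) > 1:
        return PhaseResult(status=PhaseStatus.UNINFORMATIVE)
    m_allele, p_allele = next(iter(legal))
    return PhaseResult(
        status=PhaseStatus.PHASED, maternal_allele=m_allele, paternal_allele=p_allele
    )


def detect_out_of_phase(trio: TrioGenotype) -> PhaseResult:
    """Deletion evidence from an apparently hemizygous child genotype.

    With the child carrying only allele g: a hemizygous father with allele
    a != g whose allele the mother could not have supplied twice means the
    paternal copy of this locus is missing; symmetrically, a homozygous
    mother a/a with a != g means the maternal copy is missing.
    """
    child = set(trio.child)
    if len(child) != 1:
        return PhaseResult(status=PhaseStatus.UNINFORMATIVE, note="child not hemizygous/homozygous")
    g = next(iter(child))
    father_allele = trio.father[0] if len(trio.father) == 1 else None
    # Paternal deletion: father must transmit his allele, child lacks it.
    if father_allele is not None and father_allele != g and g in trio.mother:
        return PhaseResult(
            status=PhaseStatus.OUT_OF_PHASE,
            maternal_allele=g,
            deletion_origin=DeletionOrigin.PATERNAL,
            note=f"child lacks obligate paternal allele {father_allele}",
        )
    # Maternal deletion: homozygous mother must transmit a, child lacks it.
    if len(set(trio.mother)) == 1 and trio.mother[0] != g and (
        father_allele == g or father_allele is None
    ):
        return PhaseResult(
            status=PhaseStatus.OUT_OF_PHASE,
            paternal_allele=g,
            deletion_origin=DeletionOrigin.MATERNAL,
            note=f"child lacks obligate maternal allele {trio.mother[0]}",
        )
    return PhaseResult(status=PhaseStatus.UNINFORMATIVE)


@dataclass
class DeletionPhasing:
    origin: DeletionOrigin
    supporting: int
    contradicting: int
    informative_sites: int


def phase_deletion(trios: Sequence[TrioGenotype]) -> DeletionPhasing:
    """Majority vote over out-of-phase sites inside a candidate deletion."""
    votes: Counter[DeletionOrigin] = Counter()
    for trio in trios:
        result = detect_out_of_phase(trio)
        if result.status is PhaseStatus.OUT_OF_PHASE and result.deletion_origin:
            votes[result.deletion_origin] += 1
    total = sum(votes.values())
    if total == 0:
        return DeletionPhasing(DeletionOrigin.UNDETERMINED, 0, 0, 0)
    (top, n_top), = votes.most_common(1)
    n_other = total - n_top
    if n_top == n_other:
        return DeletionPhasing(DeletionOrigin.UNDETERMINED, n_top, n_other, total)
    return DeletionPhasing(top, n_top, n_other, total)


def trio_from_vcf_site(
    site: VariantSite,
    child: str,
    mother: str,
    father: str,
    par=None,
    child_sex: str = "female",
    in_deletion: bool = False,
) -> TrioGenotype:
    """Build a ploidy-recoded TrioGenotype from a multi-sample VCF record."""
    from .datamodel import ParRegions

    par = par or ParRegions()
    if par.contains(site.chrom, site.pos):
        region = RegionClass.PAR
    elif site.chrom.removeprefix("chr") == "X":
        region = RegionClass.X_NONPAR
    else:
        region = RegionClass.AUTOSOME_LIKE
    gts = site.genotypes
    missing = [s for s in (child, mother, father) if s not in gts]
    if missing:
        raise ValueError(f"samples absent from VCF record {site.chrom}:{site.pos}: {missing}")
    c, _ = recode_ploidy(gts[child], child_sex, region, in_deletion=in_deletion)
    m, _ = recode_ploidy(gts[mother], "female", region)
    f, _ = recode_ploidy(gts[father], "male", region)
    return TrioGenotype(site=site, child=c, mother=m, father=f, region_class=region)
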