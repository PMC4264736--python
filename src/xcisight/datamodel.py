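"""Core domain types shared across the pipeline.

Coordinate convention: every user-facing coordinate (VCF, pileup, variant
tables) is 1-based inclusive, as in the source formats.  Window arithmetic in
the coverage module is 0-based half-open; conversion happens at the module
boundary, never ad hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

BASES = ("A", "C", "G", "T")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


class Phase(str, Enum):
    """Parental origin of the variant (alt) allele at a heterozygous locus."""

    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNPHASED = "unphased"


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP with per-sample genotypes.

    ``genotypes`` maps sample name to a tuple of allele strings; haploid
    samples (male X outside the PAR, or a locus inside a hemizygous deletion)
    carry exactly one allele, diploid samples exactly two.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str = ""
    filter: str = "PASS"
    genotypes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for sample, alleles in self.genotypes.items():
            if len(alleles) not in (1, 2):
                raise ValueError(
                    f"sample {sample} at {self.chrom}:{self.pos}: "
                    f"genotype must be haploid or diploid, got {alleles!r}"
                )

    def is_het(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        return gt is not None and len(gt) == 2 and gt[0] != gt[1]


@dataclass
class AlleleCount:
    """Quality-passing base counts at one position of a pileup."""

    chrom: str
    pos: int  # 1-based
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(BASES)
        if bad:
            raise ValueError(f"counts restricted to A/C/G/T, got {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative allele count")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class AllelicObservation:
    """Variant-allele fraction at one heterozygous locus.

    ``ratio`` is alt reads over total quality-passing reads; it is the raw
    count quotient, so ratio * depth is (up to float rounding) an integer.
    """

    site: VariantSite
    ratio: float
    depth: int
    phase: Phase = Phase.UNPHASED
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"ratio out of [0,1]: {self.ratio}")
        if self.depth < 0:
            raise ValueError("negative depth")

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos


# GRCh37 chrX pseudo-autosomal regions, 1-based inclusive.
GRCH37_PAR1 = (60_001, 2_699_520)
GRCH37_PAR2 = (154_931_044, 155_260_560)


@dataclass(frozen=True)
class ParRegions:
    """PAR1/PAR2 intervals (1-based inclusive) on chromosome X.

    Loci inside the PARs recombine and follow diploid inheritance, so they are
    excluded from XCI analysis.
    """

    chrom: str = "X"
    par1: tuple[int, int] = GRCH37_PAR1
    par2: tuple[int, int] = GRCH37_PAR2

    def __post_init__(self) -> None:
        for lo, hi in (self.par1, self.par2):
            if lo > hi:
                raise ValueError("malformed PAR interval")
        if self.par1[1] >= self.par2[0]:
            raise ValueError("PAR1 and PAR2 overlap")

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom.removeprefix("chr") != self.chrom.removeprefix("chr"):
            return False
        return self.par1[0] <= pos <= self.par1[1] or self.par2[0] <= pos <= self.par2[1]


def observations_frame(observations: Sequence[AllelicObservation]):
    """Tabulate observations as a pandas DataFrame (the TSV column layout)."""
    import pandas as pd

    rows = []
    for o in observations:
        alt_count = int(round(o.ratio * o.depth))
        rows.append(
            {
                "chrom": o.chrom,
                "pos": o.pos,
                "id": o.site.id,
                "ref": o.site.ref,
                "alt": o.site.alt,
                "refCount": o.depth - alt_count,
                "altCount": alt_count,
                "depth": o.depth,
                "ratio": o.ratio,
                "phase": o.phase.value,
                "gene": o.gene if o.gene is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "id", "ref", "alt", "refCount", "altCount",
            "depth", "ratio", "phase", "gene",
        ],
    )
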