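"""From pileup or attributed-read evidence to filtered allelic observations.

Implements the four-stage quality cascade applied to heterozygous X-linked
SNPs before XCI estimation: PAR exclusion, genotype-recalibration PASS,
dbSNP membership, and a minimum read depth (default 20X, "less than 20X"
excluded).  The allelic ratio denominator is the total quality-passing depth
over all four bases, not ref+alt only, so third-allele reads deflate both
allele fractions slightly; ``third_allele_in_denominator=False`` switches to
the ref+alt denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .datamodel import (
    AlleleCount,
    AllelicObservation,
    ParRegions,
    Phase,
    VariantSite,
    revcomp,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterCascadeReport:
    """Counts of loci surviving each stage of the filter cascade."""

    input: int = 0
    het_in_child: int = 0
    in_transcripts: int = 0
    outside_par: int = 0
    pass_quality: int = 0
    in_dbsnp: int = 0
    depth_ok: int = 0
    rejects: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "input": self.input,
            "het_in_child": self.het_in_child,
            "in_transcripts": self.in_transcripts,
            "outside_par": self.outside_par,
            "pass_quality": self.pass_quality,
            "in_dbsnp": self.in_dbsnp,
            "depth_ok": self.depth_ok,
            "rejects": dict(self.rejects),
        }


def allelic_ratio(
    count: AlleleCount,
    site: VariantSite,
    third_allele_in_denominator: bool = True,
) -> AllelicObservation:
    """Variant-allele fraction: alt reads over total reads at the locus."""
    if count.pos != site.pos or count.chrom != site.chrom:
        raise ValueError(
            f"count at {count.chrom}:{count.pos} does not match site "
            f"{site.chrom}:{site.pos}"
        )
    if third_allele_in_denominator:
        depth = count.depth
    else:
        depth = count.counts.get(site.ref, 0) + count.counts.get(site.alt, 0)
    if depth == 0:
        raise ValueError(f"zero depth at {site.chrom}:{site.pos}: ratio undefined")
    return AllelicObservation(
        site=site,
        ratio=count.counts.get(site.alt, 0) / depth,
        depth=depth,
        phase=Phase.UNPHASED,
    )


def apply_filters(
    observations: Sequence[AllelicObservation],
    par: ParRegions | None = None,
    min_depth: int = 20,
    require_pass: bool = True,
    require_dbsnp: bool = True,
    transcript_regions: Optional[Sequence[tuple[str, int, int]]] = None,
    child_sample: Optional[str] = None,
) -> tuple[list[AllelicObservation], FilterCascadeReport]:
    """Run the quality cascade in its canonical order.

    Stages: heterozygous in the child's DNA genotype (when ``child_sample``
    is given), inside transcripts (optional, 1-based inclusive intervals),
    outside PAR1/PAR2, recalibration filter PASS, dbSNP id present, and depth
    at least ``min_depth``.  Every rejected locus is tallied by its failing
    stage; surviving counts are monotone non-increasing by construction.
    """
    par = par or ParRegions()
    report = FilterCascadeReport(input=len(observations))
    kept = list(observations)

    def stage(name: str, predicate) -> list[AllelicObservation]:
        survivors = []
        for obs in kept:
            if predicate(obs):
                survivors.append(obs)
            else:
                report.rejects[name] = report.rejects.get(name, 0) + 1
                logger.debug("filtered %s:%d at stage %s", obs.chrom, obs.pos, name)
        return survivors

    if child_sample is not None:
        kept = stage("het_in_child", lambda o: o.site.is_het(child_sample))
    report.het_in_child = len(kept)

    if transcript_regions is not None:
        regions = list(transcript_regions)
        kept = stage(
            "in_transcripts",
            lambda o: any(c == o.chrom and lo <= o.pos <= hi for c, lo, hi in regions),
        )
    report.in_transcripts = len(kept)

    kept = stage("par", lambda o: not par.contains(o.chrom, o.pos))
    report.outside_par = len(kept)

    if require_pass:
        kept = stage("pass", lambda o: o.site.filter == "PASS")
    report.pass_quality = len(kept)

    if require_dbsnp:
        kept = stage("dbsnp", lambda o: bool(o.site.id) and o.site.id != ".")
    report.in_dbsnp = len(kept)

    kept = stage("depth", lambda o: o.depth >= min_depth)
    report.depth_ok = len(kept)
    return kept, report


def count_from_attributed_reads(
    pairs: Sequence["SimulatedPair"],  # noqa: F821 (simulator import is lazy)
    sites: Sequence[VariantSite],
    transcripts: Sequence["Transcript"],  # noqa: F821
    config: "SimulationConfig",  # noqa: F821
) -> list[AlleleCount]:
    """Alignment-free allele counting over simulated reads.

    Each read carries its source haplotype, transcript and fragment start, so
    the bases it covers are known exactly; every read contributes its base at
    every covered site (overlapping mates each contribute, matching the
    pileup route's both-mates behavior).  The contract is identical to
    counting from a pileup at the same loci.
    """
    from .datamodel import COMPLEMENT

    tx_by_name = {t.name: t for t in transcripts}
    # sites grouped per transcript, as (offset, site) in transcript coordinates
    per_tx: dict[str, list[tuple[int, VariantSite]]] = {}
    for site in sites:
        placed = False
        for t in transcripts:
            if t.chrom == site.chrom and t.start <= site.pos < t.start + len(t):
                per_tx.setdefault(t.name, []).append((t.offset_of(site.pos), site))
                placed = True
                break
        if not placed:
            continue
    tallies: dict[tuple[str, int], dict[str, int]] = {}
    outer = config.outer_distance
    for pair in pairs:
        if pair.transcript is None:
            raise ValueError("read pair lacks provenance; cannot attribute")
        t = tx_by_name[pair.transcript]
        targets = per_tx.get(pair.transcript)
        if not targets:
            continue
        frag_len = outer  # attribution assumes the fixed-length fragment design
        r1_lo, r1_hi = pair.start, pair.start + len(pair.read1.seq)
        r2_hi = pair.start + frag_len
        r2_lo = r2_hi - len(pair.read2.seq)
        read2_fwd = revcomp(pair.read2.seq)
        for offset, site in targets:
            for lo, hi, seq in ((r1_lo, r1_hi, pair.read1.seq), (r2_lo, r2_hi, read2_fwd)):
                if lo <= offset < hi:
                    tbase = seq[offset - lo]
                    gbase = tbase if t.strand == "+" else COMPLEMENT[tbase]
                    key = (site.chrom, site.pos)
                    tally = tallies.setdefault(key, {})
                    if gbase in "ACGT":
                        tally[gbase] = tally.get(gbase, 0) + 1
    return [
        AlleleCount(chrom=chrom, pos=pos, counts=counts)
        for (chrom, pos), counts in sorted(tallies.items())
    ]
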