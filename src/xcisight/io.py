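"""Readers and writers for the standard formats the pipeline touches.

VCF parsing goes through pysam, FASTA/FASTQ through Biopython; the
samtools-mpileup text dialect has no maintained Python reader so it is parsed
here.  All readers return the plain domain types from :mod:`xcisight.datamodel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    BASES,
    AlleleCount,
    AllelicObservation,
    ParRegions,
    Phase,
    VariantSite,
    observations_frame,
)

logger = logging.getLogger(__name__)

IUPAC_OK = set("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


def read_vcf(path: str | Path) -> list[VariantSite]:
    """Read biallelic SNPs from a VCF 4.x file.

    Multi-allelic records and indels are skipped (the skip count is logged);
    sample ploidy from the GT field is preserved, so a haploid "1" becomes a
    one-allele genotype.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    sites: list[VariantSite] = []
    skipped = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        if rec.ref not in BASES or alts[0] not in BASES:
            skipped += 1
            continue
        genotypes: dict[str, tuple[str, ...]] = {}
        for name, sample in rec.samples.items():
            gt = sample.get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            try:
                alleles = tuple(rec.alleles[a] for a in gt if a is not None)
            except (IndexError, TypeError) as exc:
                raise FormatError(
                    f"{path}: bad GT for sample {name} at {rec.chrom}:{rec.pos}"
                ) from exc
            genotypes[name] = alleles
        filters = list(rec.filter.keys())
        sites.append(
            VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alts[0],
                id=rec.id or "",
                filter=filters[0] if filters else ".",
                genotypes=genotypes,
            )
        )
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, skipped)
    read_vcf.last_skipped = skipped  # type: ignore[attr-defined]
    return sites


def _parse_pileup_bases(bases: str, ref: str, line_no: int) -> list[str]:
    """Expand an mpileup base string into one symbol per aligned base.

    Read-start (``^`` plus mapping-quality char) and read-end (``$``) markers
    and ``+n``/``-n`` indel insertions are consumed without emitting a symbol;
    ``*``/``#`` (deletion placeholder) and ``<``/``>`` (reference skip) emit a
    placeholder that pairs with a quality char but is never counted.
    """
    out: list[str] = []
    i = 0
    n = len(bases)
    ref = ref.upper()
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping quality char
        elif c == "$":
            i += 1
        elif c in "+-":
            i += 1
            j = i
            while j < n and bases[j].isdigit():
                j += 1
            if j == i:
                raise FormatError(f"pileup line {line_no}: bare '{c}' without length")
            length = int(bases[i:j])
            i = j + length
        elif c in ".,":
            out.append(ref)
            i += 1
        elif c.upper() in "ACGTN":
            out.append(c.upper())
            i += 1
        elif c in "*#<>":
            out.append("*")
            i += 1
        else:
            raise FormatError(f"pileup line {line_no}: unexpected character {c!r}")
    return out


def read_pileup(path: str | Path, min_base_qual: int = 20) -> list[AlleleCount]:
    """Parse samtools-mpileup text, counting bases with Phred quality strictly
    greater than ``min_base_qual`` (Phred+33 encoding)."""
    results: list[AlleleCount] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise FormatError(f"pileup line {line_no}: expected >=6 columns")
            chrom, pos_s, ref, _depth_s, bases, quals = fields[:6]
            symbols = _parse_pileup_bases(bases, ref, line_no)
            if len(symbols) != len(quals):
                raise FormatError(
                    f"pileup line {line_no}: {len(symbols)} bases vs "
                    f"{len(quals)} quality chars after token stripping"
                )
            counts: dict[str, int] = {}
            for sym, q in zip(symbols, quals):
                if sym not in BASES:
                    continue
                if ord(q) - 33 > min_base_qual:
                    counts[sym] = counts.get(sym, 0) + 1
            results.append(AlleleCount(chrom=chrom, pos=int(pos_s), counts=counts))
    return results


@dataclass
class SeqRead:
    """A named sequence with optional per-base Phred qualities."""

    name: str
    seq: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        bad = set(self.seq.upper()) - IUPAC_OK
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")


def read_fasta(path: str | Path) -> list[SeqRead]:
    return [SeqRead(name=r.id, seq=str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SeqRead], path: str | Path) -> None:
    recs = [SeqRecord(Seq(r.seq), id=r.name, description="") for r in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[SeqRead]:
    out = []
    for r in SeqIO.parse(str(path), "fastq"):
        out.append(
            SeqRead(name=r.id, seq=str(r.seq).upper(), quals=list(r.letter_annotations["phred_quality"]))
        )
    return out


def write_fastq(records: Iterable[SeqRead], path: str | Path) -> None:
    recs = []
    for r in records:
        quals = r.quals if r.quals is not None else [40] * len(r.seq)
        rec = SeqRecord(Seq(r.seq), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = quals
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_par_bed(path: str | Path, chrom: str = "X") -> ParRegions:
    """Override the built-in PAR coordinates from a 2-interval BED file.

    BED is 0-based half-open; intervals are converted to the 1-based inclusive
    convention used by :class:`ParRegions`.
    """
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            intervals.append((f[0], int(f[1]) + 1, int(f[2])))
    if len(intervals) != 2:
        raise FormatError(f"PAR BED must hold exactly 2 intervals, got {len(intervals)}")
    intervals.sort(key=lambda t: t[1])
    return ParRegions(chrom=chrom, par1=intervals[0][1:], par2=intervals[1][1:])


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Read a fragment table (chrom, outer start, outer end[, name]) in BED
    coordinates, standing in for proper mate-pair spans from a BAM."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_ratios_tsv(observations: Sequence[AllelicObservation], path: str | Path) -> None:
    observations_frame(observations).to_csv(path, sep="\t", index=False)


def read_ratios_tsv(path: str | Path) -> list[AllelicObservation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    out = []
    for row in df.itertuples(index=False):
        site = VariantSite(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
            id=str(row.id),
        )
        gene = str(getattr(row, "gene", "")) or None
        out.append(
            AllelicObservation(
                site=site,
                ratio=float(row.ratio),
                depth=int(row.depth),
                phase=Phase(getattr(row, "phase", "unphased")),
                gene=gene,
            )
        )
    return out
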