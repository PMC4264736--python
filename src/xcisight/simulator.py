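"""In-silico generation of allele-specific expression data.

Two routes are provided and agree on the quantity under study:

* a read-level route that builds two variant-bearing haplotype transcriptomes,
  draws error-bearing paired reads from each (wgsim-style: uniform fragment
  placement, fixed outer distance, uniform base quality) and mixes the two
  read pools at a target XCI ratio.  Each read remembers its source haplotype
  and coordinates, so allele counting can bypass alignment entirely
  ("direct attribution").
* a count-level shortcut that draws per-SNP allele counts directly from the
  binomial model implied by the mixing design.  This is the desk-scale route
  used for estimator calibration and the ratio panel.

The count-level generator models two realistic nuisances: reference bias
(an alt-carrying read lost to mapping with probability ``ref_bias``) and a
small symmetric cross-mapping rate (a read attributed to the wrong allele
because of sequence homology between transcripts and the rest of the
chromosome), which together reproduce the mild shrinkage of observed ratios
seen in real alignment-based pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datamodel import BASES, COMPLEMENT, AllelicObservation, Phase, VariantSite, revcomp
from .io import SeqRead

DEFAULT_PANEL = (1.0, 0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60, 0.55, 0.50)


@dataclass
class SimulationConfig:
    """Read-simulation and mixing parameters.

    Defaults mirror a wgsim-style design: 100 bp paired reads, 150 bp outer
    distance, uniform Q40 bases, a 1e-5 per-base error rate and no indels.
    """

    n_pairs: int = 10_000
    read_len: int = 100
    outer_distance: int = 150
    base_error_rate: float = 1e-5
    indel_rate: float = 0.0
    base_quality: int = 40
    xci_ratio: float = 0.5
    seed: int = 0
    min_transcript_len: int = 500
    fragment_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.xci_ratio <= 1.0:
            raise ValueError(f"xci_ratio out of [0,1]: {self.xci_ratio}")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        for name in ("base_error_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if self.read_len > self.outer_distance:
            raise ValueError("read_len cannot exceed outer_distance")


@dataclass(frozen=True)
class Transcript:
    """A transcript with its genome placement.

    ``seq`` is the mRNA-orientation sequence.  For ``strand == '+'`` transcript
    offset ``i`` (0-based) maps to genome position ``start + i`` and the genome
    base equals ``seq[i]``; on the minus strand offset ``i`` maps to
    ``start + len - 1 - i`` and the genome base is the complement.
    """

    name: str
    chrom: str
    start: int  # 1-based genome position of the transcript's lowest coordinate
    strand: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def genome_pos(self, offset: int) -> int:
        if self.strand == "+":
            return self.start + offset
        return self.start + len(self.seq) - 1 - offset

    def offset_of(self, pos: int) -> int:
        if self.strand == "+":
            return pos - self.start
        return self.start + len(self.seq) - 1 - pos

    def genome_base(self, pos: int) -> str:
        b = self.seq[self.offset_of(pos)]
        return b if self.strand == "+" else COMPLEMENT[b]


@dataclass
class PhasedSnpPool:
    """SNPs split into maternal-alt and paternal-alt bins."""

    alt_m: list[VariantSite] = field(default_factory=list)
    alt_p: list[VariantSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.alt_m) + len(self.alt_p)

    def phase_of(self, site: VariantSite) -> Phase:
        key = (site.chrom, site.pos)
        if key in {(s.chrom, s.pos) for s in self.alt_m}:
            return Phase.MATERNAL
        return Phase.PATERNAL


@dataclass
class SimulatedPair:
    """A read pair with full provenance for alignment-free counting."""

    transcript: str
    hap: str  # 'M' or 'P'
    start: int  # 0-based fragment start in transcript coordinates
    read1: SeqRead
    read2: SeqRead


def child_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-dataset RNG derived from (master seed, index)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def synthetic_transcriptome(
    n_transcripts: int = 40,
    mean_len: int = 2000,
    min_len: int = 500,
    chrom: str = "X",
    region_start: int = 3_000_000,
    gap: int = 10_000,
    seed: int = 0,
) -> list[Transcript]:
    """Generate random transcripts laid head-to-tail on a synthetic X.

    Lengths are geometric-tailed around ``mean_len`` but never below
    ``min_len``; strands alternate at random so minus-strand coordinate
    handling is always exercised.
    """
    rng = np.random.default_rng(seed)
    transcripts = []
    pos = region_start
    for i in range(n_transcripts):
        length = int(min_len + rng.exponential(max(mean_len - min_len, 1)))
        seq = "".join(rng.choice(list(BASES), size=length))
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            Transcript(name=f"TX{i:04d}", chrom=chrom, start=pos, strand=strand, seq=seq)
        )
        pos += length + gap
    return transcripts


def synthetic_snp_pool(
    transcripts: Sequence[Transcript],
    n_snps: int,
    seed: int = 0,
) -> list[VariantSite]:
    """Place heterozygous SNPs uniformly inside transcripts (genome-strand
    ref/alt, child genotype het)."""
    rng = np.random.default_rng(seed)
    lengths = np.array([len(t) for t in transcripts], dtype=float)
    probs = lengths / lengths.sum()
    used: set[tuple[str, int]] = set()
    sites: list[VariantSite] = []
    i = 0
    while len(sites) < n_snps:
        t = transcripts[int(rng.choice(len(transcripts), p=probs))]
        offset = int(rng.integers(len(t)))
        pos = t.genome_pos(offset)
        if (t.chrom, pos) in used:
            continue
        used.add((t.chrom, pos))
        ref = t.genome_base(pos)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        sites.append(
            VariantSite(
                chrom=t.chrom, pos=pos, ref=ref, alt=alt, id=f"rs{900000 + i}",
                filter="PASS", genotypes={"CHILD": (ref, alt)},
            )
        )
        i += 1
    sites.sort(key=lambda s: s.pos)
    return sites


def assign_phase_bins(snps: Sequence[VariantSite], seed: int = 0) -> PhasedSnpPool:
    """Randomly bin SNPs into maternal-alt / paternal-alt sets (p = 0.5 each)."""
    if len(snps) == 0:
        raise ValueError("assign_phase_bins: empty SNP pool")
    rng = np.random.default_rng(seed)
    draws = rng.random(len(snps)) < 0.5
    pool = PhasedSnpPool()
    for snp, is_m in zip(snps, draws):
        (pool.alt_m if is_m else pool.alt_p).append(snp)
    return pool


def _transcripts_by_name(transcripts: Sequence[Transcript]) -> dict[str, Transcript]:
    return {t.name: t for t in transcripts}


def _locate(transcripts: Sequence[Transcript], site: VariantSite) -> Transcript:
    for t in transcripts:
        if t.chrom == site.chrom and t.start <= site.pos < t.start + len(t):
            return t
    raise ValueError(f"SNP {site.chrom}:{site.pos} falls outside every transcript")


def build_haplotype_transcriptomes(
    transcripts: Sequence[Transcript],
    pool: PhasedSnpPool,
    min_transcript_len: int = 500,
) -> tuple[list[Transcript], list[Transcript]]:
    """Introduce the binned alt alleles into two copies of the transcriptome.

    The maternal copy carries alt bases at alt-M positions and ref everywhere
    else; symmetric for the paternal copy.  Substitutions on minus-strand
    transcripts are complemented.  Raises if a SNP's genome-strand ref base
    disagrees with the transcript sequence.
    """
    kept = [t for t in transcripts if len(t) >= min_transcript_len]
    out: list[list[Transcript]] = []
    for alt_set in (pool.alt_m, pool.alt_p):
        seqs = {t.name: list(t.seq) for t in kept}
        for site in alt_set:
            t = _locate(kept, site)
            if t.genome_base(site.pos) != site.ref:
                raise ValueError(
                    f"ref mismatch at {site.chrom}:{site.pos}: transcript {t.name} "
                    f"has {t.genome_base(site.pos)}, variant says {site.ref}"
                )
            offset = t.offset_of(site.pos)
            base = site.alt if t.strand == "+" else COMPLEMENT[site.alt]
            seqs[t.name][offset] = base
        out.append(
            [
                Transcript(t.name, t.chrom, t.start, t.strand, "".join(seqs[t.name]))
                for t in kept
            ]
        )
    return out[0], out[1]


def simulate_reads(
    transcripts: Sequence[Transcript],
    n_pairs: int,
    config: SimulationConfig,
    hap: str = "M",
    rng: np.random.Generator | None = None,
) -> list[SimulatedPair]:
    """wgsim-style paired reads from one haplotype transcriptome.

    Fragments are drawn uniformly over valid start positions pooled across
    transcripts, so longer transcripts yield proportionally more pairs; mate 2
    is the reverse complement of the fragment's 3' end; each base is flipped
    to a random different base with probability ``base_error_rate``.
    Transcripts shorter than the outer distance are skipped.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    outer, rl = config.outer_distance, config.read_len
    usable = [t for t in transcripts if len(t) >= outer]
    if not usable:
        raise ValueError("no transcript is at least outer_distance long")
    starts_per_t = np.array([len(t) - outer + 1 for t in usable], dtype=float)
    probs = starts_per_t / starts_per_t.sum()
    t_idx = rng.choice(len(usable), size=n_pairs, p=probs)
    quals = [config.base_quality] * rl
    pairs: list[SimulatedPair] = []
    for k in range(n_pairs):
        t = usable[int(t_idx[k])]
        frag_len = outer
        if config.fragment_sd > 0:
            frag_len = max(rl, int(round(rng.normal(outer, config.fragment_sd))))
            frag_len = min(frag_len, len(t))
        start = int(rng.integers(len(t) - frag_len + 1))
        frag = t.seq[start : start + frag_len]
        s1 = _mutate(frag[:rl], config.base_error_rate, rng)
        s2 = _mutate(revcomp(frag[-rl:]), config.base_error_rate, rng)
        name = f"{hap}:{t.name}:{start}:{k}"
        pairs.append(
            SimulatedPair(
                transcript=t.name, hap=hap, start=start,
                read1=SeqRead(name=name + "/1", seq=s1, quals=list(quals)),
                read2=SeqRead(name=name + "/2", seq=s2, quals=list(quals)),
            )
        )
    return pairs


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        chars[pos] = str(rng.choice([b for b in BASES if b != chars[pos]]))
    return "".join(chars)


def mix_at_ratio(
    pairs_m: Sequence[SimulatedPair],
    pairs_p: Sequence[SimulatedPair],
    xci_ratio: float,
    total_pairs: int,
    seed: int = 0,
) -> list[SimulatedPair]:
    """Subsample ``round(ratio * total)`` maternal and the remaining paternal
    pairs without replacement and shuffle the merged pool."""
    if not 0.0 <= xci_ratio <= 1.0:
        raise ValueError(f"xci_ratio out of [0,1]: {xci_ratio}")
    n_m = int(round(xci_ratio * total_pairs))
    n_p = total_pairs - n_m
    if n_m > len(pairs_m):
        raise ValueError(f"maternal pool short by {n_m - len(pairs_m)} pairs")
    if n_p > len(pairs_p):
        raise ValueError(f"paternal pool short by {n_p - len(pairs_p)} pairs")
    rng = np.random.default_rng(seed)
    take_m = rng.choice(len(pairs_m), size=n_m, replace=False)
    take_p = rng.choice(len(pairs_p), size=n_p, replace=False)
    merged = [pairs_m[i] for i in take_m] + [pairs_p[i] for i in take_p]
    rng.shuffle(merged)
    return merged


def default_depth_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-SNP read depths emulating a transcriptome-wide experiment.

    Roughly a third of loci sit in well-expressed, well-covered transcripts
    (gamma-Poisson depth, mean ~150); the rest fall in poorly covered or
    unretained transcripts (Poisson mean 3) and are removed by any sensible
    depth filter.  Under the default 20X cutoff about 32% of loci survive,
    i.e. ~1600 of a 4996-SNP pool.
    """
    expressed = rng.random(n) < 0.33
    depths = rng.poisson(3, size=n).astype(np.int64)
    n_expr = int(expressed.sum())
    if n_expr:
        lam = rng.gamma(shape=3.0, scale=50.0, size=n_expr)
        depths[expressed] = rng.poisson(lam)
    return depths


def simulate_counts(
    n_snps: int,
    xci_ratio: float,
    seed: int = 0,
    depth_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    ref_bias: float = 0.0,
    cross_map_rate: float = 0.004,
    chrom: str = "X",
    start_pos: int = 3_000_000,
    spacing: int = 1_000,
) -> list[AllelicObservation]:
    """Count-level shortcut: phased allelic observations without reads.

    For a maternal-phased SNP at depth ``d`` and maternal fraction ``m`` the
    alt count is Binomial(d, p') with ``p = m(1-b) / (m(1-b) + (1-m))`` (b =
    ``ref_bias``, the chance an alt-carrying read is lost to mapping) and
    ``p' = p(1-c) + (1-p)c`` (c = ``cross_map_rate``, symmetric allele
    mis-attribution from homologous sequence).  Paternal-phased SNPs are
    symmetric with ``1-m``.  True phase labels are recorded on the output.
    """
    if not 0.0 <= xci_ratio <= 1.0:
        raise ValueError(f"xci_ratio out of [0,1]: {xci_ratio}")
    if not 0.0 <= ref_bias < 1.0:
        raise ValueError(f"ref_bias out of [0,1): {ref_bias}")
    if not 0.0 <= cross_map_rate < 0.5:
        raise ValueError(f"cross_map_rate out of [0,0.5): {cross_map_rate}")
    rng = np.random.default_rng(seed)
    sampler = depth_sampler or default_depth_sampler
    depths = np.asarray(sampler(rng, n_snps), dtype=np.int64)
    maternal = rng.random(n_snps) < 0.5
    m, b, c = xci_ratio, ref_bias, cross_map_rate

    def alt_prob(frac: float) -> float:
        denom = frac * (1 - b) + (1 - frac)
        p = frac * (1 - b) / denom if denom > 0 else 0.0
        return p * (1 - c) + (1 - p) * c

    p_m, p_p = alt_prob(m), alt_prob(1 - m)
    probs = np.where(maternal, p_m, p_p)
    alt = rng.binomial(depths, probs)
    observations: list[AllelicObservation] = []
    ref_alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    for i in range(n_snps):
        d = int(depths[i])
        if d == 0:
            continue
        ref, a = ref_alt[i % 4]
        site = VariantSite(
            chrom=chrom, pos=start_pos + i * spacing, ref=ref, alt=a,
            id=f"rs{900000 + i}", filter="PASS", genotypes={"CHILD": (ref, a)},
        )
        observations.append(
            AllelicObservation(
                site=site, ratio=int(alt[i]) / d, depth=d,
                phase=Phase.MATERNAL if maternal[i] else Phase.PATERNAL,
            )
        )
    return observations


def run_ratio_panel(
    ratios: Sequence[float] = DEFAULT_PANEL,
    n_snps: int = 4996,
    seed: int = 0,
    mode: str = "counts",
    config: SimulationConfig | None = None,
    **count_kwargs,
) -> dict[float, list[AllelicObservation]]:
    """Simulate one dataset per XCI ratio with a shared seed policy.

    The default panel is the 11-point grid from completely skewed (100:0) to
    random (50:50).  In ``counts`` mode each dataset comes from
    :func:`simulate_counts`; in ``reads`` mode a small read-level experiment
    (haplotype construction, read simulation, mixing, direct-attribution
    counting) is run per ratio.
    """
    if any(not 0.0 <= r <= 1.0 for r in ratios):
        raise ValueError("ratios must lie in [0,1]")
    panel: dict[float, list[AllelicObservation]] = {}
    for i, ratio in enumerate(ratios):
        ds_seed = int(child_rng(seed, i).integers(2**31))
        if mode == "counts":
            panel[ratio] = simulate_counts(
                n_snps=n_snps, xci_ratio=ratio, seed=ds_seed, **count_kwargs
            )
        elif mode == "reads":
            panel[ratio] = _read_level_dataset(
                n_snps=n_snps, xci_ratio=ratio, seed=ds_seed,
                config=config or SimulationConfig(),
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return panel


def _read_level_dataset(
    n_snps: int,
    xci_ratio: float,
    seed: int,
    config: SimulationConfig,
) -> list[AllelicObservation]:
    """One read-level dataset: haplotypes -> reads -> mix -> attribution."""
    from .allele_counting import allelic_ratio, count_from_attributed_reads

    rng = np.random.default_rng(seed)
    transcripts = synthetic_transcriptome(
        n_transcripts=max(8, n_snps // 10), seed=int(rng.integers(2**31))
    )
    snps = synthetic_snp_pool(transcripts, n_snps, seed=int(rng.integers(2**31)))
    pool = assign_phase_bins(snps, seed=int(rng.integers(2**31)))
    hap_m, hap_p = build_haplotype_transcriptomes(
        transcripts, pool, config.min_transcript_len
    )
    surplus = int(config.n_pairs * 1.05) + 16
    reads_m = simulate_reads(hap_m, surplus, config, hap="M", rng=rng)
    reads_p = simulate_reads(hap_p, surplus, config, hap="P", rng=rng)
    mixed = mix_at_ratio(
        reads_m, reads_p, xci_ratio, config.n_pairs, seed=int(rng.integers(2**31))
    )
    counts = count_from_attributed_reads(mixed, snps, transcripts, config)
    by_pos = {(ct.chrom, ct.pos): ct for ct in counts}
    phase_m = {(s.chrom, s.pos) for s in pool.alt_m}
    observations = []
    for site in snps:
        ct = by_pos.get((site.chrom, site.pos))
        if ct is None or ct.depth == 0:
            continue
        obs = allelic_ratio(ct, site)
        obs.phase = Phase.MATERNAL if (site.chrom, site.pos) in phase_m else Phase.PATERNAL
        observations.append(obs)
    return observations


def write_pairs_fastq(pairs: Sequence[SimulatedPair], prefix: str) -> tuple[str, str]:
    """Write simulated pairs to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``."""
    from .io import write_fastq

    p1, p2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
    write_fastq([p.read1 for p in pairs], p1)
    write_fastq([p.read2 for p in pairs], p2)
    return p1, p2


def simulate_coverage_fragments(
    region_start: int,
    region_end: int,
    mean_fragments_per_window: float = 60.0,
    fragment_len: int = 250,
    window: int = 100,
    deletion: tuple[int, int] | None = None,
    deletion_fraction: float = 0.5,
    chrom: str = "X",
    seed: int = 0,
) -> pd.DataFrame:
    """Fragment spans (0-based half-open) for one exome-like sample.

    Fragment starts are uniform over the region.  A heterozygous deletion is
    emulated by dropping fragments whose midpoint falls inside ``deletion``
    with probability ``deletion_fraction`` (0.5 = one of two copies lost).
    """
    rng = np.random.default_rng(seed)
    span = region_end - region_start
    n_frags = int(round(mean_fragments_per_window * span / (fragment_len + window - 1)))
    starts = rng.integers(region_start - fragment_len + 1, region_end, size=n_frags)
    ends = starts + fragment_len
    if deletion is not None:
        mid = (starts + ends) // 2
        inside = (mid >= deletion[0]) & (mid < deletion[1])
        drop = inside & (rng.random(n_frags) < deletion_fraction)
        starts, ends = starts[~drop], ends[~drop]
    starts = np.clip(starts, region_start, None)
    ends = np.clip(ends, None, region_end)
    order = np.argsort(starts)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts[order], "end": ends[order]}
    )
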