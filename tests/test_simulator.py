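"""Read-level and count-level simulation of allele-specific expression."""

import numpy as np
import pytest

from xcisight.datamodel import Phase, VariantSite, revcomp
from xcisight.simulator import (
    DEFAULT_PANEL,
    PhasedSnpPool,
    SimulationConfig,
    Transcript,
    assign_phase_bins,
    build_haplotype_transcriptomes,
    mix_at_ratio,
    run_ratio_panel,
    simulate_counts,
    simulate_reads,
    synthetic_snp_pool,
    synthetic_transcriptome,
)


def _pool_of(snps):
    return {(s.chrom, s.pos) for s in snps}


class TestPhaseBins:
    def test_partition_is_exhaustive_and_disjoint(self):
        txs = synthetic_transcriptome(seed=0)
        snps = synthetic_snp_pool(txs, 300, seed=1)
        pool = assign_phase_bins(snps, seed=2)
        assert len(pool.alt_m) + len(pool.alt_p) == 300
        assert _pool_of(pool.alt_m).isdisjoint(_pool_of(pool.alt_p))
        # roughly even split under p=0.5
        assert 100 < len(pool.alt_m) < 200

    def test_deterministic_given_seed(self):
        txs = synthetic_transcriptome(seed=0)
        snps = synthetic_snp_pool(txs, 50, seed=1)
        a = assign_phase_bins(snps, seed=7)
        b = assign_phase_bins(snps, seed=7)
        assert _pool_of(a.alt_m) == _pool_of(b.alt_m)

    def test_single_snp(self):
        site = VariantSite(chrom="X", pos=10, ref="A", alt="G")
        pool = assign_phase_bins([site], seed=0)
        assert sorted([len(pool.alt_m), len(pool.alt_p)]) == [0, 1]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_phase_bins([], seed=0)


class TestHaplotypeConstruction:
    def test_plus_strand_substitution(self):
        t = Transcript(name="t", chrom="X", start=100, strand="+", seq="AAAA")
        snp = VariantSite(chrom="X", pos=102, ref="A", alt="G")
        hap_m, hap_p = build_haplotype_transcriptomes(
            [t], PhasedSnpPool(alt_m=[snp], alt_p=[]), min_transcript_len=1
        )
        assert hap_m[0].seq == "AAGA"
        assert hap_p[0].seq == "AAAA"

    def test_minus_strand_substitution_complemented(self):
        # transcript sequence is mRNA-orientation; genome-strand A->G at the
        # transcript's 3' coordinate must appear as complement(G)=C... i.e.
        # the substituted mRNA base is the complement of the genome alt.
        t = Transcript(name="t", chrom="X", start=100, strand="-", seq="TTTT")
        # genome bases are complement(reversed(seq)) = AAAA at 100..103
        snp = VariantSite(chrom="X", pos=100, ref="A", alt="G")
        hap_m, _ = build_haplotype_transcriptomes(
            [t], PhasedSnpPool(alt_m=[snp], alt_p=[]), min_transcript_len=1
        )
        # pos 100 maps to transcript offset 3; mRNA base complement(G)=C
        assert hap_m[0].seq == "TTTC"

    def test_empty_pool_is_identity(self):
        txs = synthetic_transcriptome(n_transcripts=3, seed=0)
        hap_m, hap_p = build_haplotype_transcriptomes(txs, PhasedSnpPool())
        assert [t.seq for t in hap_m] == [t.seq for t in txs]
        assert [t.seq for t in hap_p] == [t.seq for t in txs]

    def test_ref_mismatch_raises(self):
        t = Transcript(name="t", chrom="X", start=100, strand="+", seq="AAAA")
        snp = VariantSite(chrom="X", pos=102, ref="C", alt="G")
        with pytest.raises(ValueError, match="ref mismatch"):
            build_haplotype_transcriptomes(
                [t], PhasedSnpPool(alt_m=[snp], alt_p=[]), min_transcript_len=1
            )

    def test_alt_then_ref_substitution_is_involution(self):
        txs = synthetic_transcriptome(n_transcripts=5, seed=3)
        snps = synthetic_snp_pool(txs, 40, seed=4)
        pool = PhasedSnpPool(alt_m=list(snps), alt_p=[])
        hap_m, _ = build_haplotype_transcriptomes(txs, pool)
        # swap ref<->alt and apply again: must restore the original sequences
        swapped = [
            VariantSite(chrom=s.chrom, pos=s.pos, ref=s.alt, alt=s.ref) for s in snps
        ]
        restored, _ = build_haplotype_transcriptomes(
            hap_m, PhasedSnpPool(alt_m=swapped, alt_p=[])
        )
        assert [t.seq for t in restored] == [
            t.seq for t in txs if len(t) >= 500
        ]


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        txs = synthetic_transcriptome(n_transcripts=4, seed=0)
        config = SimulationConfig(n_pairs=500, base_error_rate=0.0, seed=1)
        pairs = simulate_reads(txs, 500, config, rng=np.random.default_rng(1))
        seqs = {t.name: t.seq for t in txs}
        for p in pairs:
            assert p.read1.seq in seqs[p.transcript]
            assert revcomp(p.read2.seq) in seqs[p.transcript]

    def test_mismatch_rate_matches_error_rate(self):
        txs = synthetic_transcriptome(n_transcripts=2, seed=0)
        err = 1e-3  # raised so 500 pairs give a measurable count
        config = SimulationConfig(n_pairs=500, base_error_rate=err, seed=2)
        pairs = simulate_reads(txs, 500, config, rng=np.random.default_rng(2))
        seqs = {t.name: t.seq for t in txs}
        mismatches = bases = 0
        for p in pairs:
            src = seqs[p.transcript][p.start : p.start + config.read_len]
            mismatches += sum(a != b for a, b in zip(p.read1.seq, src))
            bases += config.read_len
        observed = mismatches / bases
        # binomial 4-sigma envelope around the nominal rate
        sigma = (err / bases) ** 0.5
        assert abs(observed - err) < 4 * sigma

    def test_same_seed_reproduces(self):
        txs = synthetic_transcriptome(n_transcripts=3, seed=0)
        config = SimulationConfig(n_pairs=100, seed=5)
        a = simulate_reads(txs, 100, config, rng=np.random.default_rng(5))
        b = simulate_reads(txs, 100, config, rng=np.random.default_rng(5))
        assert [(p.read1.seq, p.read2.seq) for p in a] == [
            (p.read1.seq, p.read2.seq) for p in b
        ]

    def test_short_transcripts_skipped(self):
        short = Transcript(name="s", chrom="X", start=1, strand="+", seq="ACGT" * 10)
        with pytest.raises(ValueError, match="outer_distance"):
            simulate_reads([short], 10, SimulationConfig(n_pairs=10))


class TestMixing:
    def _pairs(self, hap, n):
        txs = synthetic_transcriptome(n_transcripts=2, seed=0)
        return simulate_reads(
            txs, n, SimulationConfig(n_pairs=n), hap=hap, rng=np.random.default_rng(ord(hap))
        )

    def test_mixing_conserves_exact_counts(self):
        m, p = self._pairs("M", 120), self._pairs("P", 120)
        merged = mix_at_ratio(m, p, 0.75, 100, seed=0)
        assert len(merged) == 100
        assert sum(q.hap == "M" for q in merged) == 75

    def test_pure_maternal(self):
        m, p = self._pairs("M", 60), self._pairs("P", 60)
        merged = mix_at_ratio(m, p, 1.0, 50, seed=0)
        assert all(q.hap == "M" for q in merged)

    def test_even_split(self):
        m, p = self._pairs("M", 60), self._pairs("P", 60)
        merged = mix_at_ratio(m, p, 0.5, 100, seed=0)
        assert sum(q.hap == "M" for q in merged) == 50

    def test_shortfall_is_reported(self):
        m, p = self._pairs("M", 10), self._pairs("P", 60)
        with pytest.raises(ValueError, match="short by 65"):
            mix_at_ratio(m, p, 0.75, 100, seed=0)


class TestSimulateCounts:
    def test_symmetric_at_half(self):
        obs = simulate_counts(3000, 0.5, seed=0, ref_bias=0.0, cross_map_rate=0.0)
        ratios = [o.ratio for o in obs if o.depth >= 20]
        assert abs(np.mean(ratios) - 0.5) < 0.01

    def test_complete_skew_is_monoallelic(self):
        obs = simulate_counts(500, 1.0, seed=0, ref_bias=0.0, cross_map_rate=0.0)
        for o in obs:
            expected = 1.0 if o.phase is Phase.MATERNAL else 0.0
            assert o.ratio == expected

    def test_reference_bias_closed_form(self):
        # alt fraction under bias b at maternal fraction m:
        # m(1-b) / (m(1-b) + (1-m))
        m, b = 0.85, 0.02
        expected = m * (1 - b) / (m * (1 - b) + (1 - m))
        obs = simulate_counts(
            1600, m, seed=3, ref_bias=b, cross_map_rate=0.0,
            depth_sampler=lambda rng, n: np.full(n, 50),
        )
        mat = [o.ratio for o in obs if o.phase is Phase.MATERNAL]
        se = np.std(mat) / len(mat) ** 0.5
        assert abs(np.mean(mat) - expected) < 3 * se

    def test_ratio_times_depth_is_integral(self):
        obs = simulate_counts(200, 0.7, seed=1)
        for o in obs:
            assert abs(o.ratio * o.depth - round(o.ratio * o.depth)) < 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(10, 1.5, seed=0)
        with pytest.raises(ValueError):
            simulate_counts(10, 0.5, seed=0, ref_bias=1.0)


class TestRatioPanel:
    def test_default_panel_has_eleven_datasets(self):
        panel = run_ratio_panel(n_snps=200, seed=0)
        assert len(panel) == 11
        assert set(panel) == set(DEFAULT_PANEL)

    def test_single_ratio_panel(self):
        panel = run_ratio_panel(ratios=[0.5], n_snps=100, seed=0)
        assert list(panel) == [0.5]

    def test_reproducible_across_runs(self):
        a = run_ratio_panel(ratios=[0.8, 0.6], n_snps=150, seed=9)
        b = run_ratio_panel(ratios=[0.8, 0.6], n_snps=150, seed=9)
        for r in a:
            assert [(o.pos, o.ratio, o.depth) for o in a[r]] == [
                (o.pos, o.ratio, o.depth) for o in b[r]
            ]

    def test_read_level_mode_recovers_mixing_ratio(self):
        # small end-to-end run through haplotypes, reads and attribution
        config = SimulationConfig(n_pairs=4000, seed=0)
        panel = run_ratio_panel(
            ratios=[0.8], n_snps=60, seed=2, mode="reads", config=config
        )
        obs = [o for o in panel[0.8] if o.depth >= 10]
        assert len(obs) > 20
        mat = [o.ratio for o in obs if o.phase is Phase.MATERNAL]
        pat = [o.ratio for o in obs if o.phase is Phase.PATERNAL]
        assert abs(np.mean(mat) - 0.8) < 0.06
        assert abs(np.mean(pat) - 0.2) < 0.06
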