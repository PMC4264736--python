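"""Estimate a skewed XCI ratio from simulated allele counts, both ways.

Simulates one 85:15 dataset at transcriptome-realistic coverage, filters to
20X, then estimates the ratio from phased ratios (beta fit) and from the
same ratios with phase hidden (semiparametric mixture).  The two estimates
should agree closely with each other and with the simulated truth.
"""

from xcisight import Phase, simulate_counts, xci_from_phased, xci_from_unphased

observations = [o for o in simulate_counts(4996, xci_ratio=0.85, seed=7) if o.depth >= 20]
maternal = [o for o in observations if o.phase is Phase.MATERNAL]
paternal = [o for o in observations if o.phase is Phase.PATERNAL]

phased = xci_from_phased(maternal, paternal)
unphased = xci_from_unphased([o.ratio for o in observations], seed=7)

print(f"SNPs at >=20X: {len(observations)} ({len(maternal)} maternal, {len(paternal)} paternal)")
print(
    f"phased beta estimate:   {phased.maternal_pct:.2f}:{phased.paternal_pct:.2f} "
    f"(sd {phased.maternal_sd:.1f}/{phased.paternal_sd:.1f}, {phased.skew_class.value})"
)
print(
    f"unphased SP estimate:   {unphased.maternal_pct:.2f}:{unphased.paternal_pct:.2f} "
    f"({unphased.skew_class.value}; components unlabeled)"
)
print("simulated truth:        85:15")
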