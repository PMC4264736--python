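"""Phase child alleles by transmission and phase a deletion from one SNP.

Two textbook situations: a heterozygous daughter whose father is hemizygous
(the X always phases), and an out-of-phase genotype — the child misses an
allele her father must have transmitted, betraying a deletion on the
paternal X.
"""

from xcisight.datamodel import VariantSite
from xcisight.trio_phasing import (
    TrioGenotype,
    detect_out_of_phase,
    phase_by_transmission,
    phase_deletion,
)

site = VariantSite(chrom="X", pos=48_000_000, ref="A", alt="T")
trio = TrioGenotype(site=site, child=("A", "T"), mother=("A", "T"), father=("A",))
result = phase_by_transmission(trio)
print(f"child A/T, mother A/T, father A -> maternal={result.maternal_allele} "
      f"paternal={result.paternal_allele} ({result.status.value})")

# child appears "G" where the father is "A": his allele never arrived
deleted = VariantSite(chrom="X", pos=7_270_694, id="rs5933863", ref="G", alt="A")
trio_del = TrioGenotype(site=deleted, child=("G",), mother=("G", "A"), father=("A",))
evidence = detect_out_of_phase(trio_del)
print(f"out-of-phase genotype at {deleted.id}: {evidence.status.value}, "
      f"deletion on the {evidence.deletion_origin.value} X")

phased = phase_deletion([trio_del])
print(f"deletion phased {phased.origin.value} with {phased.supporting}/"
      f"{phased.informative_sites} informative site(s)")
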