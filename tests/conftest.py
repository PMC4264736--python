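import textwrap

import pytest

TRIO_VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=X,length=155270560>
    ##FILTER=<ID=q10,Description="low quality">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCHILD\tMOTHER\tFATHER
    """
)


@pytest.fixture
def write_trio_vcf(tmp_path):
    """Write a trio VCF from (pos, id, ref, alt, filter, gt_child, gt_mother,
    gt_father) tuples and return its path."""

    def _write(records, name="trio.vcf"):
        lines = [TRIO_VCF_HEADER]
        for pos, rsid, ref, alt, filt, gc, gm, gf in records:
            lines.append(
                f"X\t{pos}\t{rsid or '.'}\t{ref}\t{alt}\t50\t{filt}\t.\tGT\t{gc}\t{gm}\t{gf}\n"
            )
        path = tmp_path / name
        path.write_text("".join(lines))
        return path

    return _write
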