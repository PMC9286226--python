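import io

import pytest

from vcfpipe.core import parse_header, read_vcf

HEADER_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=VALIDATED,Number=0,Type=Flag,Description="Validated by follow-up">
##INFO=<ID=GNOMAD_AF,Number=A,Type=Float,Description="Population frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">
##FORMAT=<ID=BCOUNT,Number=A,Type=Integer,Description="Alt-supporting reads">
##FILTER=<ID=LowQD,Description="Low quality by depth">
##GATKCommandLine=<ID=HaplotypeCaller,Version=4.1,CommandLine="HaplotypeCaller -R ref.fa">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttumor\tnormal
"""


@pytest.fixture
def header():
    return parse_header(HEADER_TEXT.splitlines())


def make_vcf(record_lines):
    return HEADER_TEXT + "".join(line + "\n" for line in record_lines)


@pytest.fixture
def read_records():
    """Parse record lines under the shared two-sample header."""

    def _read(record_lines):
        h, records = read_vcf(io.StringIO(make_vcf(record_lines)))
        return h, list(records)

    return _read
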