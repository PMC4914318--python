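import pytest

from mirmeta.registry import load_registry

ALIASES = """\
MIMAT0000001\thsa-miR-451;hsa-miR-451a;
MIMAT0000002\thsa-miR-144;hsa-miR-144-5p;
MIMAT0000003\thsa-miR-144*;hsa-miR-144-3p;
MIMAT0000004\thsa-miR-221;hsa-miR-221-5p;
MIMAT0000005\thsa-miR-221-3p;
MIMAT0000006\thsa-miR-222;hsa-miR-222-3p;
MIMAT0000007\thsa-miR-222;hsa-miR-222-5p;
MIMAT0000008\thsa-miR-146b;hsa-miR-146b-5p;
MIMAT0000009\thsa-miR-199a-3p;
MIMAT0000010\thsa-miR-214-3p;
"""

# mir-451a and mir-144 sit 100 bp apart on chr17(+): a genomic cluster.
# mir-221 hosts a -5p/-3p pair (shared precursor); mir-221 and mir-222 sit
# 7.9 kb apart on chrX(-).  mir-199a(+) and mir-214(-) are adjacent but on
# opposite strands, so they never cluster.  mir-221 and mir-146b share a
# family label.
GFF = """\
##gff-version 3
chr17\ttest\tmiRNA_primary_transcript\t100000\t100085\t.\t+\t.\tID=MI0000001;Name=hsa-mir-451a
chr17\ttest\tmiRNA_primary_transcript\t100185\t100260\t.\t+\t.\tID=MI0000002;Name=hsa-mir-144
chrX\ttest\tmiRNA_primary_transcript\t5000\t5100\t.\t-\t.\tID=MI0000003;Name=hsa-mir-221;family=mipf-test
chrX\ttest\tmiRNA_primary_transcript\t13000\t13100\t.\t-\t.\tID=MI0000004;Name=hsa-mir-222
chr10\ttest\tmiRNA_primary_transcript\t700\t800\t.\t+\t.\tID=MI0000005;Name=hsa-mir-146b;family=mipf-test
chr1\ttest\tmiRNA_primary_transcript\t2000\t2100\t.\t+\t.\tID=MI0000006;Name=hsa-mir-199a
chr1\ttest\tmiRNA_primary_transcript\t2200\t2300\t.\t-\t.\tID=MI0000007;Name=hsa-mir-214
chr17\ttest\tmiRNA\t100000\t100021\t.\t+\t.\tID=MIMAT0000001;Name=hsa-miR-451a;Derives_from=MI0000001
chr17\ttest\tmiRNA\t100185\t100206\t.\t+\t.\tID=MIMAT0000002;Name=hsa-miR-144-5p;Derives_from=MI0000002
chr17\ttest\tmiRNA\t100238\t100259\t.\t+\t.\tID=MIMAT0000003;Name=hsa-miR-144-3p;Derives_from=MI0000002
chrX\ttest\tmiRNA\t5000\t5021\t.\t-\t.\tID=MIMAT0000004;Name=hsa-miR-221-5p;Derives_from=MI0000003
chrX\ttest\tmiRNA\t5078\t5099\t.\t-\t.\tID=MIMAT0000005;Name=hsa-miR-221-3p;Derives_from=MI0000003
chrX\ttest\tmiRNA\t13000\t13021\t.\t-\t.\tID=MIMAT0000006;Name=hsa-miR-222-3p;Derives_from=MI0000004
chrX\ttest\tmiRNA\t13078\t13099\t.\t-\t.\tID=MIMAT0000007;Name=hsa-miR-222-5p;Derives_from=MI0000004
chr10\ttest\tmiRNA\t700\t721\t.\t+\t.\tID=MIMAT0000008;Name=hsa-miR-146b-5p;Derives_from=MI0000005
chr1\ttest\tmiRNA\t2000\t2021\t.\t+\t.\tID=MIMAT0000009;Name=hsa-miR-199a-3p;Derives_from=MI0000006
chr1\ttest\tmiRNA\t2200\t2221\t.\t-\t.\tID=MIMAT0000010;Name=hsa-miR-214-3p;Derives_from=MI0000007
"""


@pytest.fixture
def registry_files(tmp_path):
    aliases = tmp_path / "aliases.txt"
    gff = tmp_path / "precursors.gff3"
    aliases.write_text(ALIASES)
    gff.write_text(GFF)
    return aliases, gff


@pytest.fixture
def small_registry(registry_files):
    return load_registry(*registry_files, release_label="v21-test")
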