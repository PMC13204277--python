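from __future__ import annotations

import os
from typing import Iterable, Sequence, Tuple

import pytest

from recurvar import SimulationConfig, generate_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000000>\n"
    "##contig=<ID=chr2,length=100000000>\n"
    "##contig=<ID=chr10,length=100000000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
)


def write_vcf(
    path,
    rows: Sequence[Tuple],
    sample: str = "S01",
) -> str:
    """Write a small single-sample VCF from (chrom, pos, ref, alt, qual, gt, ad, dp) rows.

    ``alt`` may hold a comma-joined multi-allelic string; ``ad`` is an
    iterable of per-allele depths or None to omit the field.
    """
    path = str(path)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for chrom, pos, ref, alt, qual, gt, ad, dp in rows:
            if ad is None:
                fmt, values = "GT:DP", f"{gt}:{dp}"
            else:
                ad_str = ",".join(str(a) for a in ad)
                fmt, values = "GT:AD:DP", f"{gt}:{ad_str}:{dp}"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\t.\t{fmt}\t{values}\n")
    return path


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small default-config synthetic bundle shared across read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(n_background_variants=300, seed=11)
    manifest = generate_cohort(cfg, str(out))
    return str(out), manifest
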