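"""Shared fixtures: a hand-written toy VCF and small gene maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polypar.poly_composition import GenotypeMatrix

N_TOY_SAMPLES = 20


def _gt_line(chrom, pos, vid, ref, alt, gts):
    return f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)


@pytest.fixture()
def toy_vcf(tmp_path):
    """10 records over 20 samples: 1 indel, 1 triallelic, 2 low-call-rate,
    2 below 5% MAF, and 4 clean biallelic SNPs (hand-filterable)."""
    n = N_TOY_SAMPLES
    common = ["0/1"] * 8 + ["0/0"] * 12           # MAF 0.2, full call rate
    rare = ["0/1"] + ["0/0"] * (n - 1)            # MAF 0.025 < 5%
    lowcall = ["./."] * 6 + ["0/1"] * 6 + ["0/0"] * 8  # call rate 0.7 < 0.8
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"S{i:02d}" for i in range(n)),
        _gt_line(1, 100, "good1", "A", "G", common),
        _gt_line(1, 200, "indel", "AT", "A", common),
        _gt_line(1, 300, "good2", "C", "T", ["0/0"] * 10 + ["0/1"] * 6 + ["1/1"] * 4),
        _gt_line(1, 400, "tri", "G", "A,T", common),
        _gt_line(1, 500, "lowcall1", "T", "C", lowcall),
        _gt_line(1, 600, "good3", "G", "C", common),
        _gt_line(1, 700, "rare1", "A", "T", rare),
        _gt_line(1, 800, "lowcall2", "C", "G", ["./."] * 20),
        _gt_line(1, 900, "rare2", "T", "G", rare),
        _gt_line(1, 1000, "good4", "A", "C", common),
    ]
    path = tmp_path / "toy.vcf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def worked_example():
    """The hand-enumerable 3-SNP case: genotypes (AA, CT, AC) at SNPs
    A/G, C/T, A/C give alleles {A,A,C,T,A,C}."""
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "pos": [10, 20, 30],
            "id": ["s1", "s2", "s3"],
            "ref": ["A", "C", "A"],
            "alt": ["G", "T", "C"],
        }
    )
    # AA at A/G -> dosage 0; CT at C/T -> 1; AC at A/C -> 1
    genotypes = GenotypeMatrix(["ind1"], np.array([[0, 1, 1]], dtype=np.int8))
    return variants, genotypes


@pytest.fixture()
def toy_genes():
    """20 genes on one chromosome, 4 of them repair genes."""
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:02d}" for i in range(20)],
            "chrom": ["1"] * 20,
            "start": np.arange(20) * 100_000,
            "end": np.arange(20) * 100_000 + 50_000,
        }
    )
    repair = ["g01", "g03", "g05", "g07"]
    return genes, repair
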