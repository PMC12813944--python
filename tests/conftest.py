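import numpy as np
import pytest

from trioscan.ldpanel import HaplotypePanel, PanelVariant
from trioscan.sumstats import AssociationRecord, TraitType


def make_record(
    rsid="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    pvalue=1e-8,
    trait="Testus taxon",
    trait_type=TraitType.MICROBE,
    study_id="s1",
):
    return AssociationRecord(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=effect_allele,
        pvalue=pvalue, trait=trait, trait_type=trait_type, study_id=study_id,
    )


def make_panel(columns, chrom="1", positions=None, rsids=None):
    """Build a phased panel from a list of 0/1 haplotype columns."""
    columns = [np.asarray(c, dtype=np.int8) for c in columns]
    n = len(columns)
    positions = positions or [1000 * (i + 1) for i in range(n)]
    rsids = rsids or [f"rs{i + 1}" for i in range(n)]
    chroms = [chrom] * n if isinstance(chrom, str) else list(chrom)
    variants = [
        PanelVariant(rsid=rsids[i], chrom=chroms[i], pos=positions[i], ref="A", alt="G")
        for i in range(n)
    ]
    return HaplotypePanel(variants, np.stack(columns, axis=1), mode="phased")


def r2_oracle(col_a, col_b):
    """Brute-force haplotype-count r²: tabulate n00, n01, n10, n11 directly."""
    n00 = n01 = n10 = n11 = 0
    for a, b in zip(col_a, col_b):
        if a == 0 and b == 0:
            n00 += 1
        elif a == 0 and b == 1:
            n01 += 1
        elif a == 1 and b == 0:
            n10 += 1
        else:
            n11 += 1
    n = n00 + n01 + n10 + n11
    p_a = (n10 + n11) / n
    p_b = (n01 + n11) / n
    p_ab = n11 / n
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        raise ZeroDivisionError("monomorphic")
    return (p_ab - p_a * p_b) ** 2 / denom


@pytest.fixture
def sumstats_file(tmp_path):
    """Write a small valid summary-statistics TSV and return its path."""

    def _write(rows, name="sumstats.tsv"):
        header = "rsid\tchrom\tpos\teffect_allele\tpvalue\ttrait\tstudy_id"
        path = tmp_path / name
        path.write_text("\n".join([header] + ["\t".join(map(str, r)) for r in rows]) + "\n")
        return path

    return _write


@pytest.fixture
def vcf_file(tmp_path):
    """Write a minimal VCF; rows are (chrom, pos, id, ref, alt, [gt strings])."""

    def _write(records, n_samples, name="panel.vcf"):
        lines = ["##fileformat=VCFv4.2"]
        for chrom in dict.fromkeys(r[0] for r in records):
            lines.append(f"##contig=<ID={chrom}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"S{i}" for i in range(n_samples))
        )
        for chrom, pos, rid, ref, alt, gts in records:
            lines.append(f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
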