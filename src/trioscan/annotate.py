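"""Candidate-gene assignment for overlap loci.

Each locus gets a gene either from an explicit override table
(literature-assigned genes win) or from the nearest gene to the anchoring
lead SNP, searching protein-coding genes first. Distance is measured to
the gene body on 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .overlap import OverlapLocus
from .sumstats import normalize_chrom

__all__ = [
    "GeneModel",
    "AnnotatedLocus",
    "load_genes_gtf",
    "load_genes_bed",
    "load_overrides",
    "nearest_gene",
    "annotate_loci",
]

logger = logging.getLogger(__name__)

PROTEIN_CODING = "protein_coding"


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene body interval; coordinates 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int
    biotype: str = PROTEIN_CODING

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be nonempty")
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def distance_to(self, pos: int) -> int:
        if self.start <= pos <= self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


@dataclass(frozen=True, slots=True)
class AnnotatedLocus:
    """An overlap locus with its assigned gene (or None if unannotatable)."""

    locus: OverlapLocus
    gene: str | None
    gene_distance_bp: int | None
    source: str  # "override" | "nearest" | "none"


def load_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Gene models from GTF ``gene`` features (attributes gene_name, gene_biotype)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        names = feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or []
        if not names:
            continue
        biotypes = feat.attributes.get("gene_biotype") or feat.attributes.get("gene_type") or ["other"]
        biotype = biotypes[0] if biotypes[0] == PROTEIN_CODING else "other"
        genes.append(
            GeneModel(name=names[0], chrom=feat.seqid, start=feat.start, end=feat.end, biotype=biotype)
        )
    return genes


def load_genes_bed(path: str | Path) -> list[GeneModel]:
    """Gene models from a 6-column BED: chrom, start, end, name, biotype, strand.

    BED is 0-based half-open; converted to 1-based inclusive on load.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "biotype", "strand"],
        dtype={"chrom": str, "name": str, "biotype": str},
    )
    return [
        GeneModel(
            name=row.name_,
            chrom=row.chrom,
            start=int(row.start) + 1,
            end=int(row.end),
            biotype=row.biotype if row.biotype == PROTEIN_CODING else "other",
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def load_overrides(path: str | Path) -> dict[str, str]:
    """rsid→gene-symbol override table (TSV with columns rsid, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"rsid", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: overrides TSV needs columns 'rsid' and 'gene'")
    return dict(zip(df["rsid"], df["gene"]))


def nearest_gene(
    chrom: str, pos: int, genes: Sequence[GeneModel]
) -> tuple[GeneModel, int] | None:
    """Nearest gene to a position, protein-coding genes searched first.

    Returns ``None`` when the chromosome has no genes at all. A gene of
    ``other`` biotype is returned only if no protein-coding gene exists on
    the chromosome. Ties break on smaller distance, then protein-coding
    over other, then lexicographically smaller symbol.
    """
    chrom = normalize_chrom(chrom)
    on_chrom = [g for g in genes if g.chrom == chrom]
    if not on_chrom:
        return None
    coding = [g for g in on_chrom if g.biotype == PROTEIN_CODING]
    pool = coding if coding else on_chrom
    starts = np.array([g.start for g in pool])
    ends = np.array([g.end for g in pool])
    inside = (starts <= pos) & (pos <= ends)
    dist = np.where(inside, 0, np.minimum(np.abs(pos - starts), np.abs(pos - ends)))
    best = min(range(len(pool)), key=lambda i: (dist[i], pool[i].biotype != PROTEIN_CODING, pool[i].name))
    return pool[best], int(dist[best])


def annotate_loci(
    loci: Sequence[OverlapLocus],
    genes: Sequence[GeneModel],
    overrides: Mapping[str, str] | None = None,
    *,
    anchor: str = "microbe",
) -> list[AnnotatedLocus]:
    """Assign one gene per locus.

    An override for either lead SNP wins (microbe-side checked first); an
    override naming a gene absent from the gene file is still applied, with
    a warning. Otherwise the gene nearest the anchoring lead SNP is used;
    ``anchor`` selects which position anchors the lookup: ``microbe``
    (default), ``metabolite`` or ``midpoint``. Loci on gene-less
    chromosomes are carried forward unannotated (source ``none``).
    """
    overrides = dict(overrides or {})
    known = {g.name for g in genes}
    if anchor not in ("microbe", "metabolite", "midpoint"):
        raise ValueError(f"unknown anchor {anchor!r}")

    out: list[AnnotatedLocus] = []
    for loc in loci:
        symbol = overrides.get(loc.microbe_assoc.rsid)
        if symbol is None:
            symbol = overrides.get(loc.metab_assoc.rsid)
        if symbol is not None:
            if symbol not in known:
                logger.warning("override gene %r absent from gene file; applied as bare symbol", symbol)
            out.append(AnnotatedLocus(locus=loc, gene=symbol, gene_distance_bp=None, source="override"))
            continue
        if anchor == "microbe":
            pos = loc.microbe_assoc.pos
        elif anchor == "metabolite":
            pos = loc.metab_assoc.pos
        else:
            pos = (loc.microbe_assoc.pos + loc.metab_assoc.pos) // 2
        hit = nearest_gene(loc.chrom, pos, genes)
        if hit is None:
            logger.warning("no genes on chromosome %s; locus left unannotated", loc.chrom)
            out.append(AnnotatedLocus(locus=loc, gene=None, gene_distance_bp=None, source="none"))
        else:
            gene, dist = hit
            out.append(AnnotatedLocus(locus=loc, gene=gene.name, gene_distance_bp=dist, source="nearest"))
    return out
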