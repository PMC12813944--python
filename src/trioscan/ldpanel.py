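"""Phased haplotype reference panels and linkage-disequilibrium (r²) queries.

The panel is the stand-in for an EUR-like reference (e.g. a 1000
Genomes-style VCF). Only biallelic SNPs are used; multi-allelic and
non-SNP records are skipped and counted. Two LD estimators are
available:

``phased``
    haplotype-frequency r² from 0/1 haplotype columns,
    r² = (p_AB − p_A·p_B)² / (p_A(1−p_A)·p_B(1−p_B));
``dosage``
    squared Pearson correlation of 0/1/2 genotype dosages, a fallback
    for unphased panels (clearly labeled on the panel object).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .errors import EmptyPanelError, MonomorphicVariantError, PanelLookupError, PhasingError
from .sumstats import AssociationRecord, chrom_sort_key, normalize_chrom

__all__ = [
    "PanelVariant",
    "HaplotypePanel",
    "LDConfig",
    "ProxyPair",
    "load_panel",
    "compute_r2",
    "find_proxies",
]

logger = logging.getLogger(__name__)

_SNP_ALLELES = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class PanelVariant:
    """Index entry for one biallelic SNP in the panel."""

    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True, slots=True)
class LDConfig:
    """Proxy-search parameters: window in bp (inclusive), strict r² floor."""

    window_bp: int = 250_000
    r2_min: float = 0.8

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError(f"window_bp must be positive, got {self.window_bp!r}")
        if not (0.0 <= self.r2_min <= 1.0):
            raise ValueError(f"r2_min must lie in [0, 1], got {self.r2_min!r}")


@dataclass(frozen=True, slots=True)
class ProxyPair:
    """Two same-chromosome variants with their r² and bp separation."""

    rsid_a: str
    rsid_b: str
    r2: float
    distance_bp: int

    def __post_init__(self) -> None:
        if self.rsid_a == self.rsid_b:
            raise ValueError("a proxy pair needs two distinct variants")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of range: {self.r2!r}")


class HaplotypePanel:
    """Allele matrix over an ordered index of biallelic SNPs.

    In ``phased`` mode the matrix holds one row per haplotype (two per
    diploid sample) with entries in {0, 1}. In ``dosage`` mode rows are
    samples and entries are alternate-allele dosages in {0, 1, 2}.
    """

    def __init__(
        self,
        variants: Sequence[PanelVariant],
        matrix: np.ndarray,
        *,
        mode: str = "phased",
        build: str = "GRCh37",
        population_tag: str = "synthetic",
    ):
        variants = list(variants)
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2 or matrix.shape[1] != len(variants):
            raise ValueError("matrix must be (n_rows, n_variants)")
        if mode not in ("phased", "dosage"):
            raise ValueError(f"unknown panel mode {mode!r}")
        if mode == "phased":
            if matrix.shape[0] < 2:
                raise ValueError("a phased panel needs at least 2 haplotypes")
            if not np.isin(matrix, (0, 1)).all():
                raise ValueError("phased haplotype entries must be 0/1")
        order = sorted(range(len(variants)), key=lambda i: (chrom_sort_key(variants[i].chrom), variants[i].pos))
        self.variants = [variants[i] for i in order]
        self.matrix = matrix[:, order]
        self.mode = mode
        self.build = build
        self.population_tag = population_tag
        self._index = {v.rsid: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate rsids in panel variant index")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def variant(self, rsid: str) -> PanelVariant:
        try:
            return self.variants[self._index[rsid]]
        except KeyError:
            raise PanelLookupError(f"variant {rsid!r} not in panel") from None

    def column(self, rsid: str) -> np.ndarray:
        """Allele (or dosage) column for one variant."""
        return self.matrix[:, self._index[self.variant(rsid).rsid]]


def load_panel(
    path: str | Path,
    *,
    allow_unphased: bool = False,
    population_tag: str = "EUR-like",
) -> HaplotypePanel:
    """Load a VCF into a :class:`HaplotypePanel`.

    Multi-allelic and non-SNP records are skipped (count logged). In the
    default strict mode any unphased genotype raises :class:`PhasingError`;
    with ``allow_unphased=True`` the whole panel falls back to dosage mode.
    """
    path = Path(path)
    variants: list[PanelVariant] = []
    columns: list[np.ndarray] = []
    skipped = 0
    unphased_seen = False
    with pysam.VariantFile(str(path)) as vcf:
        n_samples = len(vcf.header.samples)
        if n_samples == 0:
            raise EmptyPanelError(f"{path}: VCF has no samples")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or rec.ref is None:
                skipped += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
                skipped += 1
                continue
            alleles: list[int] = []
            for sample in rec.samples.values():
                gt = sample["GT"]
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    raise PhasingError(f"{path}: missing/non-diploid genotype at {rec.id or rec.pos}")
                if not sample.phased:
                    if not allow_unphased:
                        raise PhasingError(
                            f"{path}: unphased genotype at record {rec.id or f'{rec.chrom}:{rec.pos}'}"
                        )
                    unphased_seen = True
                alleles.extend(int(a) for a in gt)
            variants.append(
                PanelVariant(
                    rsid=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=normalize_chrom(rec.chrom),
                    pos=int(rec.pos),
                    ref=ref,
                    alt=alt,
                )
            )
            columns.append(np.array(alleles, dtype=np.int8))
    if skipped:
        logger.info("load_panel: skipped %d non-SNP/multi-allelic record(s) in %s", skipped, path)
    if not variants:
        raise EmptyPanelError(f"{path}: no usable biallelic SNP records")
    hap = np.stack(columns, axis=1)  # (2*n_samples, n_variants)
    if unphased_seen:
        dosage = hap[0::2] + hap[1::2]
        logger.info("load_panel: unphased genotypes present; falling back to dosage LD mode")
        return HaplotypePanel(variants, dosage, mode="dosage", population_tag=population_tag)
    return HaplotypePanel(variants, hap, mode="phased", population_tag=population_tag)


def _r2_columns(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        raise MonomorphicVariantError("r² undefined: variant has zero allele variance in panel")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def compute_r2(panel: HaplotypePanel, rsid_a: str, rsid_b: str) -> float:
    """Pairwise LD r² between two panel variants.

    Symmetric in its arguments; requires both variants on the same
    chromosome and neither monomorphic. For phased panels this equals the
    haplotype-frequency formula; for dosage panels it is the squared
    Pearson correlation of dosages.
    """
    va, vb = panel.variant(rsid_a), panel.variant(rsid_b)
    if va.chrom != vb.chrom:
        raise ValueError(f"r² across chromosomes is not defined ({va.chrom} vs {vb.chrom})")
    return _r2_columns(panel.column(rsid_a), panel.column(rsid_b))


def find_proxies(
    panel: HaplotypePanel,
    anchor: AssociationRecord,
    candidates: Sequence[AssociationRecord],
    cfg: LDConfig | None = None,
) -> list[ProxyPair]:
    """Window-constrained LD proxy search around one anchor association.

    Returns candidates on the anchor's chromosome with
    ``|Δpos| ≤ window_bp`` and ``r² > r2_min`` (strict), sorted by
    descending r², then ascending distance, then rsid. Candidates absent
    from the panel are skipped with a log line; a missing anchor raises
    :class:`PanelLookupError` so the caller can decide whether the screen
    continues.
    """
    cfg = cfg or LDConfig()
    if anchor.rsid not in panel:
        raise PanelLookupError(f"anchor {anchor.rsid!r} not in panel")
    out: list[ProxyPair] = []
    for cand in candidates:
        if cand.rsid == anchor.rsid:
            continue
        if normalize_chrom(cand.chrom) != normalize_chrom(anchor.chrom):
            continue
        dist = abs(int(cand.pos) - int(anchor.pos))
        if dist > cfg.window_bp:
            continue
        if cand.rsid not in panel:
            logger.info("find_proxies: candidate %s absent from panel; skipped", cand.rsid)
            continue
        r2 = compute_r2(panel, anchor.rsid, cand.rsid)
        if r2 > cfg.r2_min:
            out.append(ProxyPair(rsid_a=anchor.rsid, rsid_b=cand.rsid, r2=r2, distance_bp=dist))
    out.sort(key=lambda p: (-p.r2, p.distance_bp, p.rsid_b))
    return out
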