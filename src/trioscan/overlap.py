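"""Join filtered microbe and metabolite associations into overlap loci.

Two join modes, applied in order:

1. *exact* — same lead rsid reported in both layers (the panel is never
   consulted, so exact loci survive for variants missing from it);
2. *proxy* — among records not consumed by an exact match, same-chromosome
   cross-layer pairs within the LD window with r² strictly above the floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .errors import PanelLookupError
from .ldpanel import HaplotypePanel, LDConfig, compute_r2, find_proxies
from .sumstats import AssociationRecord, TraitType, chrom_sort_key

__all__ = ["OverlapLocus", "find_overlaps", "merge_loci", "validate_loci"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class OverlapLocus:
    """A microbe association and a metabolite association tagging one signal."""

    microbe_assoc: AssociationRecord
    metab_assoc: AssociationRecord
    mode: str  # "exact" | "proxy"
    r2: float
    distance_bp: int

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "proxy"):
            raise ValueError(f"unknown overlap mode {self.mode!r}")
        if TraitType(self.microbe_assoc.trait_type) is not TraitType.MICROBE:
            raise ValueError("microbe_assoc must be a microbe-layer record")
        if TraitType(self.metab_assoc.trait_type) is not TraitType.METABOLITE:
            raise ValueError("metab_assoc must be a metabolite-layer record")

    @property
    def chrom(self) -> str:
        return self.microbe_assoc.chrom

    @property
    def min_pos(self) -> int:
        return min(self.microbe_assoc.pos, self.metab_assoc.pos)

    def sort_key(self):
        return (
            chrom_sort_key(self.chrom),
            self.min_pos,
            self.microbe_assoc.rsid,
            self.metab_assoc.rsid,
            self.microbe_assoc.trait,
            self.metab_assoc.trait,
        )


def find_overlaps(
    microbe: Sequence[AssociationRecord],
    metab: Sequence[AssociationRecord],
    panel: HaplotypePanel | None,
    cfg: LDConfig | None = None,
) -> list[OverlapLocus]:
    """Emit every qualifying overlap locus between the two filtered layers.

    Inputs are assumed to already pass ``filter_significant``. When one
    anchor has several proxy partners, one locus is emitted per partner.
    Records whose rsid is absent from the panel are logged and remain
    eligible for exact matches only. Output order is deterministic:
    (chrom, min pos, rsids, traits).
    """
    cfg = cfg or LDConfig()
    loci: list[OverlapLocus] = []

    exact_microbe_rsids: set[str] = set()
    exact_metab_rsids: set[str] = set()
    metab_by_rsid: dict[str, list[AssociationRecord]] = {}
    for b in metab:
        metab_by_rsid.setdefault(b.rsid, []).append(b)
    for m in microbe:
        for b in metab_by_rsid.get(m.rsid, ()):
            loci.append(
                OverlapLocus(microbe_assoc=m, metab_assoc=b, mode="exact", r2=1.0, distance_bp=0)
            )
            exact_microbe_rsids.add(m.rsid)
            exact_metab_rsids.add(b.rsid)

    if panel is not None:
        rem_microbe = [m for m in microbe if m.rsid not in exact_microbe_rsids]
        rem_metab = [b for b in metab if b.rsid not in exact_metab_rsids]
        metab_by_rsid = {}
        for b in rem_metab:
            metab_by_rsid.setdefault(b.rsid, []).append(b)
        for m in rem_microbe:
            try:
                pairs = find_proxies(panel, m, rem_metab, cfg)
            except PanelLookupError:
                logger.info("find_overlaps: %s absent from panel; proxy search skipped", m.rsid)
                continue
            for p in pairs:
                for b in metab_by_rsid[p.rsid_b]:
                    loci.append(
                        OverlapLocus(
                            microbe_assoc=m,
                            metab_assoc=b,
                            mode="proxy",
                            r2=p.r2,
                            distance_bp=p.distance_bp,
                        )
                    )

    loci.sort(key=OverlapLocus.sort_key)
    return loci


def merge_loci(
    loci: Sequence[OverlapLocus],
    panel: HaplotypePanel | None,
    cfg: LDConfig | None = None,
) -> list[OverlapLocus]:
    """Collapse redundant loci tagging one region for one trait pair.

    Loci sharing (microbe trait, metabolite trait, chromosome) are merged
    when their lead SNPs are pairwise identical or mutual proxies
    (r² > r2_min within the window); the representative kept is the locus
    with the smallest product of the two p-values (ties broken by sort key).
    """
    cfg = cfg or LDConfig()

    def linked(rs_a: str, pos_a: int, rs_b: str, pos_b: int) -> bool:
        if rs_a == rs_b:
            return True
        if abs(pos_a - pos_b) > cfg.window_bp:
            return False
        if panel is None or rs_a not in panel or rs_b not in panel:
            return False
        return compute_r2(panel, rs_a, rs_b) > cfg.r2_min

    groups: dict[tuple, list[OverlapLocus]] = {}
    for loc in loci:
        key = (loc.microbe_assoc.trait, loc.metab_assoc.trait, loc.chrom)
        groups.setdefault(key, []).append(loc)

    out: list[OverlapLocus] = []
    for members in groups.values():
        # union-find over loci linked through both lead SNPs
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if linked(
                    a.microbe_assoc.rsid, a.microbe_assoc.pos, b.microbe_assoc.rsid, b.microbe_assoc.pos
                ) and linked(
                    a.metab_assoc.rsid, a.metab_assoc.pos, b.metab_assoc.rsid, b.metab_assoc.pos
                ):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[OverlapLocus]] = {}
        for i, loc in enumerate(members):
            clusters.setdefault(find(i), []).append(loc)
        for cluster in clusters.values():
            cluster.sort(
                key=lambda L: (L.microbe_assoc.pvalue * L.metab_assoc.pvalue, L.sort_key())
            )
            out.append(cluster[0])
    out.sort(key=OverlapLocus.sort_key)
    return out


def validate_loci(loci: Sequence[OverlapLocus], cfg: LDConfig | None = None) -> None:
    """Re-check every emitted locus against its mode's invariant."""
    cfg = cfg or LDConfig()
    for loc in loci:
        if loc.mode == "exact":
            if loc.microbe_assoc.rsid != loc.metab_assoc.rsid or loc.r2 != 1.0:
                raise ValueError(f"invalid exact locus: {loc}")
        else:
            if not (loc.r2 > cfg.r2_min and loc.distance_bp <= cfg.window_bp):
                raise ValueError(f"invalid proxy locus: {loc}")
        if loc.microbe_assoc.chrom != loc.metab_assoc.chrom:
            raise ValueError(f"cross-chromosome locus: {loc}")
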