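"""Disease-catalog cross-referencing and final trio assembly.

Catalogs are offline TSV snapshots (columns: entity, class, trait,
provenance) emulating GWAS-catalog-, gutMDisorder- and HMDB-style
entity→trait lookups. A trio is flagged allergy-relevant when ANY of its
three entities (gene, microbe, metabolite) carries a catalogued trait
matching an allergy term; matching is case-insensitive substring on
whitespace-normalized strings (an exact-match mode is available).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotate import AnnotatedLocus

__all__ = [
    "CatalogEntry",
    "DiseaseCatalog",
    "Trio",
    "DiseaseLink",
    "DEFAULT_ALLERGY_TERMS",
    "ENTITY_CLASSES",
    "load_catalog",
    "build_trios",
    "flag_allergy_relevance",
]

ENTITY_CLASSES = ("gene", "microbe", "metabolite")

DEFAULT_ALLERGY_TERMS = frozenset(
    {"asthma", "rhinitis", "eczema", "allergy", "allergic disease", "immune", "inflammation"}
)


def _norm(s: str) -> str:
    return re.sub(r"\s+", " ", str(s).strip()).lower()


@dataclass(frozen=True, slots=True)
class CatalogEntry:
    entity: str
    entity_class: str
    trait: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if not str(self.entity).strip():
            raise ValueError("catalog entity name must be nonempty")
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(f"entity class must be one of {ENTITY_CLASSES}, got {self.entity_class!r}")
        if not str(self.trait).strip():
            raise ValueError("catalog trait must be nonempty")


class DiseaseCatalog:
    """Entity→trait lookup, case-insensitive after whitespace normalization."""

    def __init__(self, entries: Iterable[CatalogEntry], provenance: str = ""):
        self.entries = list(entries)
        self.provenance = provenance
        self._by_key: dict[tuple[str, str], list[CatalogEntry]] = {}
        for e in self.entries:
            self._by_key.setdefault((e.entity_class, _norm(e.entity)), []).append(e)

    def lookup(self, entity_class: str, name: str) -> list[CatalogEntry]:
        return list(self._by_key.get((entity_class, _norm(name)), ()))

    def __len__(self) -> int:
        return len(self.entries)


def load_catalog(path: str | Path, provenance: str | None = None) -> DiseaseCatalog:
    """Read a catalog TSV (entity, class, trait[, provenance])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"entity", "class", "trait"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: catalog TSV needs columns {sorted(required)}")
    label = provenance if provenance is not None else Path(path).stem
    df = df.rename(columns={"class": "entity_class"})
    if "provenance" not in df.columns:
        df["provenance"] = label
    entries = [
        CatalogEntry(
            entity=row.entity,
            entity_class=row.entity_class,
            trait=row.trait,
            provenance=row.provenance or label,
        )
        for row in df.itertuples(index=False)
    ]
    return DiseaseCatalog(entries, provenance=label)


@dataclass(frozen=True, slots=True)
class DiseaseLink:
    entity_class: str
    trait: str
    provenance: str


@dataclass(frozen=True, slots=True)
class Trio:
    """One gene-microbe-metabolite trio with its supporting evidence."""

    gene: str
    microbe: str
    metabolite: str
    microbe_snp: str
    metab_snp: str
    microbe_p: float
    metab_p: float
    chrom: str = ""
    mode: str = ""
    r2: float = 1.0
    distance_bp: int = 0
    gene_source: str = ""
    disease_links: tuple[DiseaseLink, ...] = ()
    allergy_flag: bool = False
    assigned_condition: str = ""


def build_trios(annotated: Sequence[AnnotatedLocus]) -> list[Trio]:
    """Collapse annotated loci to one trio per (gene, microbe, metabolite).

    Duplicate keys keep the locus with the smallest product of the two
    p-values (ties broken by locus sort key). Output order is
    deterministic: (gene, microbe, metabolite).
    """
    best: dict[tuple[str, str, str], AnnotatedLocus] = {}
    for a in annotated:
        key = (a.gene or "", a.locus.microbe_assoc.trait, a.locus.metab_assoc.trait)
        cur = best.get(key)
        if cur is None or _trio_rank(a) < _trio_rank(cur):
            best[key] = a
    trios = []
    for (gene, microbe, metabolite), a in sorted(best.items()):
        loc = a.locus
        trios.append(
            Trio(
                gene=gene,
                microbe=microbe,
                metabolite=metabolite,
                microbe_snp=loc.microbe_assoc.rsid,
                metab_snp=loc.metab_assoc.rsid,
                microbe_p=loc.microbe_assoc.pvalue,
                metab_p=loc.metab_assoc.pvalue,
                chrom=loc.chrom,
                mode=loc.mode,
                r2=loc.r2,
                distance_bp=loc.distance_bp,
                gene_source=a.source,
            )
        )
    return trios


def _trio_rank(a: AnnotatedLocus):
    loc = a.locus
    return (loc.microbe_assoc.pvalue * loc.metab_assoc.pvalue, loc.sort_key())


def flag_allergy_relevance(
    trios: Sequence[Trio],
    catalogs: Sequence[DiseaseCatalog],
    allergy_terms: Iterable[str] = DEFAULT_ALLERGY_TERMS,
    *,
    exact: bool = False,
) -> list[Trio]:
    """Attach catalogued disease links and set the allergy flag per trio.

    The flag is true iff any of the trio's three entities has a catalogued
    trait matching any allergy term. All catalogued links are recorded with
    provenance; ``assigned_condition`` is the trait of the first matching
    link under a deterministic ordering (gene links before microbe before
    metabolite, then provenance, then trait).
    """
    terms = [_norm(t) for t in allergy_terms]
    if not terms:
        raise ValueError("allergy_terms must be nonempty")

    def matches(trait: str) -> bool:
        t = _norm(trait)
        if exact:
            return t in terms
        return any(term in t for term in terms)

    out: list[Trio] = []
    class_rank = {c: i for i, c in enumerate(ENTITY_CLASSES)}
    for trio in trios:
        links: list[DiseaseLink] = []
        for cls, name in (("gene", trio.gene), ("microbe", trio.microbe), ("metabolite", trio.metabolite)):
            if not name:
                continue
            for cat in catalogs:
                for e in cat.lookup(cls, name):
                    links.append(DiseaseLink(entity_class=cls, trait=e.trait, provenance=e.provenance))
        links = sorted(set(links), key=lambda L: (class_rank[L.entity_class], L.provenance, L.trait))
        matching = [L for L in links if matches(L.trait)]
        out.append(
            replace(
                trio,
                disease_links=tuple(links),
                allergy_flag=bool(matching),
                assigned_condition=matching[0].trait if matching else "",
            )
        )
    return out
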