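"""Access to the packaged ``allergy12`` example dataset.

A 12-trio gene-microbe-metabolite screening bundle: one microbe-layer and
one metabolite-layer suggestive association per trio, a stub panel in
which each trio's SNP pair is in perfect LD, gene models, rsid→gene
overrides, gene-function and condition sidecars, and offline mini
disease catalogs. See the bundled README for caveats (the panel's r²
values are stubs, not reference-panel estimates).
"""

from __future__ import annotations

import shutil
from importlib.resources import files
from pathlib import Path

import pandas as pd

from .annotate import GeneModel, load_genes_gtf, load_overrides
from .ldpanel import HaplotypePanel, load_panel
from .prioritize import DiseaseCatalog, load_catalog
from .sumstats import AssociationRecord, TraitType, load_sumstats

__all__ = [
    "example_dir",
    "example_paths",
    "load_example_sumstats",
    "load_example_panel",
    "load_example_genes",
    "load_example_overrides",
    "load_example_catalogs",
    "load_example_gene_info",
    "load_example_conditions",
    "materialize_example",
]

_DATASET = "allergy12"


def example_dir() -> Path:
    return Path(str(files("trioscan") / "data" / _DATASET))


def example_paths() -> dict[str, Path]:
    d = example_dir()
    return {
        "microbe": d / "microbe.tsv",
        "metabolite": d / "metabolite.tsv",
        "panel": d / "panel.vcf",
        "genes": d / "genes.gtf",
        "overrides": d / "overrides.tsv",
        "gene_info": d / "gene_info.tsv",
        "conditions": d / "conditions.tsv",
        "catalogs": sorted((d / "catalogs").glob("*.tsv")),
    }


def load_example_sumstats(trait_type: TraitType | str) -> list[AssociationRecord]:
    trait_type = TraitType(trait_type)
    name = "microbe.tsv" if trait_type is TraitType.MICROBE else "metabolite.tsv"
    return load_sumstats(example_dir() / name, trait_type)


def load_example_panel() -> HaplotypePanel:
    return load_panel(example_dir() / "panel.vcf", population_tag="stub-perfect-LD")


def load_example_genes() -> list[GeneModel]:
    return load_genes_gtf(example_dir() / "genes.gtf")


def load_example_overrides() -> dict[str, str]:
    return load_overrides(example_dir() / "overrides.tsv")


def load_example_catalogs() -> list[DiseaseCatalog]:
    return [load_catalog(p) for p in example_paths()["catalogs"]]


def load_example_gene_info() -> dict[str, str]:
    df = pd.read_csv(example_dir() / "gene_info.tsv", sep="\t", dtype=str)
    return dict(zip(df["gene"], df["function"]))


def load_example_conditions() -> dict[str, str]:
    df = pd.read_csv(example_dir() / "conditions.tsv", sep="\t", dtype=str)
    return dict(zip(df["gene"], df["condition"]))


def materialize_example(outdir: str | Path) -> Path:
    """Copy the packaged dataset into ``outdir`` (for CLI use)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    src = example_dir()
    for p in src.rglob("*"):
        rel = p.relative_to(src)
        if p.is_dir():
            (outdir / rel).mkdir(exist_ok=True)
        else:
            shutil.copyfile(p, outdir / rel)
    return outdir
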