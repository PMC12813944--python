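"""Seeded synthetic inputs: block-LD haplotype panels, paired summary
statistics with planted pleiotropic loci and margin-controlled distractors,
gene files and mini-catalogs.

The LD model is deliberately simple: within a block every variant is a
copy of a founder column with entries flipped at a per-variant
probability, which gives direct control of pairwise r²; across blocks
variants are independent. Planted positives satisfy all three screen
conditions (p below threshold, r² > 0.8, distance ≤ 250 kb) with margin;
each distractor violates exactly one condition, also with margin, so
finite-sample noise cannot flip outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .annotate import GeneModel
from .ldpanel import HaplotypePanel, PanelVariant
from .prioritize import CatalogEntry, DiseaseCatalog
from .sumstats import AssociationRecord, TraitType

__all__ = [
    "BlockSpec",
    "SimConfig",
    "PlantedTrio",
    "Distractor",
    "GroundTruth",
    "simulate_panel",
    "simulate_sumstats",
    "simulate_screen",
    "write_panel_vcf",
    "write_genes_gtf",
    "write_catalog",
    "write_screen",
]

# margin constants: planted r² kept above 0.9, low-LD distractors below 0.6,
# so the screen's 0.8 floor sits in the middle of a dead zone
PLANTED_R2_MIN = 0.9
DISTRACTOR_R2_MAX = 0.6
_MAX_ATTEMPTS = 1000

_ALLELES = "ACGT"

# invented organism / compound name pools (enough for default configs)
TAXON_NAMES = tuple(
    f"{genus} simulans_{i:02d}"
    for i, genus in enumerate(
        [
            "Simulibacter", "Testudomonas", "Fictococcus", "Mockella", "Pseudofirmus",
            "Synthetibacter", "Placebobium", "Dummybacterium", "Examplea", "Stublactobacillus",
        ]
        * 6
    )
)
METABOLITE_NAMES = tuple(
    f"sim-metabolite-{cls}-{i:02d}"
    for i, cls in enumerate(
        ["acylcarnitine", "sterol", "sphingolipid", "aminoacid", "xenobiotic", "lipid"] * 10
    )
)


@dataclass(frozen=True, slots=True)
class BlockSpec:
    """One LD block: two or more variants sharing a founder haplotype."""

    chrom: str
    start: int
    n_variants: int = 2
    spacing_bp: int = 40_000
    r2_target: float = 0.95
    role: str = "planted"  # planted | distract_p | distract_ld | distract_far

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("a block needs at least 2 variants")
        if not (0.0 <= self.r2_target <= 1.0):
            raise ValueError("r2_target must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class SimConfig:
    seed: int = 0
    n_haplotypes: int = 200
    planted_trios: int = 5
    distractors_pvalue: int = 0
    distractors_ld: int = 0
    distractors_distance: int = 0
    allele_freq_range: tuple[float, float] = (0.2, 0.8)
    blocks: tuple[BlockSpec, ...] | None = None

    def __post_init__(self) -> None:
        counts = (self.planted_trios, self.distractors_pvalue, self.distractors_ld, self.distractors_distance)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        lo, hi = self.allele_freq_range
        if not (0.05 <= lo < hi <= 0.95):
            raise ValueError("allele_freq_range must lie within (0.05, 0.95)")
        if self.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")


@dataclass(frozen=True, slots=True)
class PlantedTrio:
    gene: str
    microbe: str
    metabolite: str
    microbe_rsid: str
    metab_rsid: str
    microbe_p: float
    metab_p: float
    r2_realized: float
    distance_bp: int
    chrom: str


@dataclass(frozen=True, slots=True)
class Distractor:
    violated: str  # "pvalue" | "ld" | "distance"
    microbe_rsid: str
    metab_rsid: str
    microbe_p: float
    metab_p: float
    r2_realized: float
    distance_bp: int
    chrom: str


@dataclass
class GroundTruth:
    planted: list[PlantedTrio] = field(default_factory=list)
    distractors: list[Distractor] = field(default_factory=list)
    block_r2: dict[str, float] = field(default_factory=dict)  # "rsA|rsB" -> realized r²

    def planted_keys(self) -> set[tuple[str, str, str]]:
        return {(t.gene, t.microbe, t.metabolite) for t in self.planted}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [asdict(t) for t in self.planted],
            "distractors": [asdict(d) for d in self.distractors],
            "block_r2": self.block_r2,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def plan_blocks(cfg: SimConfig) -> tuple[BlockSpec, ...]:
    """Derive one block per planted trio / distractor, spread over autosomes."""
    if cfg.blocks is not None:
        return cfg.blocks
    roles = (
        ["planted"] * cfg.planted_trios
        + ["distract_p"] * cfg.distractors_pvalue
        + ["distract_ld"] * cfg.distractors_ld
        + ["distract_far"] * cfg.distractors_distance
    )
    blocks = []
    for i, role in enumerate(roles):
        chrom = str((i % 22) + 1)
        start = 1_000_000 + (i // 22) * 10_000_000
        spacing = 300_000 if role == "distract_far" else 40_000
        r2_target = 0.3 if role == "distract_ld" else 0.95
        blocks.append(
            BlockSpec(chrom=chrom, start=start, spacing_bp=spacing, r2_target=r2_target, role=role)
        )
    return tuple(blocks)


def _flip_prob(r2_target: float) -> float:
    # exact for allele frequency 0.5: corr(X, X xor F) = 1 - 2f
    return (1.0 - np.sqrt(r2_target)) / 2.0


def _pair_r2(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return -1.0  # monomorphic, force regeneration
    c = ((a - a.mean()) * (b - b.mean())).mean()
    return float(c * c / (va * vb))


def simulate_panel(cfg: SimConfig) -> tuple[HaplotypePanel, GroundTruth]:
    """Generate a phased panel with the planned block structure.

    Within each block the lead pair's realized r² is rejection-sampled into
    its role's margin regime (≥0.9 for high-LD roles, ≤0.6 for low-LD);
    realized values are recorded in the returned :class:`GroundTruth`.
    """
    rng = np.random.default_rng(cfg.seed)
    blocks = plan_blocks(cfg)
    truth = GroundTruth()
    variants: list[PanelVariant] = []
    columns: list[np.ndarray] = []
    rs_counter = 1_000_000

    for block in blocks:
        want_high = block.role != "distract_ld"
        lo, hi = (PLANTED_R2_MIN, 1.0) if want_high else (0.02, DISTRACTOR_R2_MAX)
        f = _flip_prob(block.r2_target)
        for attempt in range(_MAX_ATTEMPTS):
            freq = rng.uniform(*cfg.allele_freq_range)
            founder = (rng.random(cfg.n_haplotypes) < freq).astype(np.int8)
            cols = [founder]
            for _ in range(block.n_variants - 1):
                flips = rng.random(cfg.n_haplotypes) < f
                cols.append(np.where(flips, 1 - founder, founder).astype(np.int8))
            r2 = _pair_r2(cols[0].astype(float), cols[1].astype(float))
            if lo <= r2 <= hi and all(0 < c.mean() < 1 for c in cols):
                break
        else:
            raise GenerationError(
                f"could not realize r² in [{lo}, {hi}] for block {block} "
                f"with {cfg.n_haplotypes} haplotypes after {_MAX_ATTEMPTS} attempts"
            )
        rsids = []
        for j, col in enumerate(cols):
            ref, alt = rng.choice(list(_ALLELES), size=2, replace=False)
            rsid = f"rs{rs_counter}"
            rs_counter += 1
            rsids.append(rsid)
            variants.append(
                PanelVariant(
                    rsid=rsid,
                    chrom=block.chrom,
                    pos=block.start + j * block.spacing_bp,
                    ref=str(ref),
                    alt=str(alt),
                )
            )
            columns.append(col)
        truth.block_r2[f"{rsids[0]}|{rsids[1]}"] = r2

    if not variants:
        raise GenerationError("no blocks requested; nothing to simulate")
    matrix = np.stack(columns, axis=1)
    panel = HaplotypePanel(variants, matrix, mode="phased", population_tag="synthetic-EUR-like")
    return panel, truth


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def simulate_sumstats(
    panel: HaplotypePanel,
    truth: GroundTruth,
    cfg: SimConfig,
) -> tuple[list[AssociationRecord], list[AssociationRecord], GroundTruth]:
    """Plant association records on the panel's blocks per their roles.

    Planted trios draw p log-uniformly below threshold with ≥10× margin
    (microbe in [1e-14, 1e-7), metabolite in [1e-14, 1e-6)); p-value
    distractors sit ≥10× above their violated threshold. Trait and gene
    names are drawn without replacement from packaged pools.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    blocks = plan_blocks(cfg)
    n_blocks = len(blocks)
    if n_blocks > min(len(TAXON_NAMES), len(METABOLITE_NAMES)):
        raise GenerationError("more blocks than available trait names")
    taxa = list(rng.permutation(np.array(TAXON_NAMES, dtype=object))[:n_blocks])
    metabolites = list(rng.permutation(np.array(METABOLITE_NAMES, dtype=object))[:n_blocks])

    pair_keys = list(truth.block_r2)
    if len(pair_keys) != n_blocks:
        raise GenerationError("panel/ground-truth block count mismatch with config")

    microbe: list[AssociationRecord] = []
    metab: list[AssociationRecord] = []
    for i, block in enumerate(blocks):
        rs_m, rs_b = pair_keys[i].split("|")
        vm, vb = panel.variant(rs_m), panel.variant(rs_b)
        dist = abs(vm.pos - vb.pos)
        r2 = truth.block_r2[pair_keys[i]]
        taxon, compound = str(taxa[i]), str(metabolites[i])
        gene = f"SIMG{i:03d}"

        p_m = _log_uniform(rng, 1e-14, 1e-7)
        p_b = _log_uniform(rng, 1e-14, 1e-6)
        if block.role == "distract_p":
            # violate exactly the p-value condition, on one random side
            if rng.random() < 0.5:
                p_m = _log_uniform(rng, 1e-5, 1e-3)
            else:
                p_b = _log_uniform(rng, 1e-4, 1e-2)

        microbe.append(
            AssociationRecord(
                rsid=rs_m, chrom=vm.chrom, pos=vm.pos, effect_allele=vm.alt,
                pvalue=p_m, trait=taxon, trait_type=TraitType.MICROBE, study_id="sim",
            )
        )
        metab.append(
            AssociationRecord(
                rsid=rs_b, chrom=vb.chrom, pos=vb.pos, effect_allele=vb.alt,
                pvalue=p_b, trait=compound, trait_type=TraitType.METABOLITE, study_id="sim",
            )
        )
        if block.role == "planted":
            truth.planted.append(
                PlantedTrio(
                    gene=gene, microbe=taxon, metabolite=compound,
                    microbe_rsid=rs_m, metab_rsid=rs_b,
                    microbe_p=p_m, metab_p=p_b,
                    r2_realized=r2, distance_bp=dist, chrom=block.chrom,
                )
            )
        else:
            violated = {"distract_p": "pvalue", "distract_ld": "ld", "distract_far": "distance"}[block.role]
            truth.distractors.append(
                Distractor(
                    violated=violated,
                    microbe_rsid=rs_m, metab_rsid=rs_b,
                    microbe_p=p_m, metab_p=p_b,
                    r2_realized=r2, distance_bp=dist, chrom=block.chrom,
                )
            )
    _assert_margins(truth)
    return microbe, metab, truth


def _assert_margins(truth: GroundTruth) -> None:
    for t in truth.planted:
        assert t.r2_realized >= PLANTED_R2_MIN and t.distance_bp <= 250_000
        assert t.microbe_p < 1e-7 and t.metab_p < 1e-6
    for d in truth.distractors:
        if d.violated == "ld":
            assert d.r2_realized <= DISTRACTOR_R2_MAX
        elif d.violated == "distance":
            assert d.distance_bp > 250_000 and d.r2_realized >= PLANTED_R2_MIN
        else:
            assert d.microbe_p >= 1e-5 or d.metab_p >= 1e-4


def simulate_genes(cfg: SimConfig, panel: HaplotypePanel) -> list[GeneModel]:
    """One protein-coding gene spanning each block (±5 kb)."""
    blocks = plan_blocks(cfg)
    genes = []
    idx = 0
    for i, block in enumerate(blocks):
        span = (block.n_variants - 1) * block.spacing_bp
        genes.append(
            GeneModel(
                name=f"SIMG{i:03d}",
                chrom=block.chrom,
                start=max(1, block.start - 5_000),
                end=block.start + span + 5_000,
                biotype="protein_coding",
            )
        )
        idx += block.n_variants
    return genes


def simulate_catalog(truth: GroundTruth) -> DiseaseCatalog:
    """Catalog linking every planted gene to an allergy trait."""
    entries = [
        CatalogEntry(entity=t.gene, entity_class="gene", trait="asthma", provenance="sim-catalog")
        for t in truth.planted
    ]
    return DiseaseCatalog(entries, provenance="sim-catalog")


def simulate_screen(cfg: SimConfig):
    """Full synthetic bundle: panel, sumstats, genes, catalog, ground truth."""
    panel, truth = simulate_panel(cfg)
    microbe, metab, truth = simulate_sumstats(panel, truth, cfg)
    genes = simulate_genes(cfg, panel)
    catalog = simulate_catalog(truth)
    return panel, microbe, metab, genes, catalog, truth


# ---------------------------------------------------------------- writers

def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Serialize a phased panel to an uncompressed VCF 4.2 text file."""
    if panel.mode != "phased":
        raise ValueError("only phased panels can be written as phased VCF")
    n_samples = panel.n_rows // 2
    lines = ["##fileformat=VCFv4.2", "##source=trioscan-simulate"]
    for chrom in dict.fromkeys(v.chrom for v in panel.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = [f"SIM{i:04d}" for i in range(n_samples)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for j, v in enumerate(panel.variants):
        col = panel.matrix[:, j]
        gts = "\t".join(f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(n_samples))
        lines.append(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_genes_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = []
    for i, g in enumerate(genes):
        attrs = f'gene_id "{g.name}"; gene_name "{g.name}"; gene_biotype "{g.biotype}";'
        lines.append(f"{g.chrom}\ttrioscan\tgene\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_catalog(catalog: DiseaseCatalog, path: str | Path) -> None:
    lines = ["entity\tclass\ttrait\tprovenance"]
    for e in catalog.entries:
        lines.append(f"{e.entity}\t{e.entity_class}\t{e.trait}\t{e.provenance}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_screen(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full bundle under ``outdir``; returns paths."""
    from .sumstats import write_sumstats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "catalogs").mkdir(exist_ok=True)
    panel, microbe, metab, genes, catalog, truth = simulate_screen(cfg)
    paths = {
        "panel": outdir / "panel.vcf",
        "microbe": outdir / "microbe.tsv",
        "metabolite": outdir / "metabolite.tsv",
        "genes": outdir / "genes.gtf",
        "catalog": outdir / "catalogs" / "sim.tsv",
        "truth": outdir / "truth.json",
    }
    write_panel_vcf(panel, paths["panel"])
    write_sumstats(microbe, paths["microbe"])
    write_sumstats(metab, paths["metabolite"])
    write_genes_gtf(genes, paths["genes"])
    write_catalog(catalog, paths["catalog"])
    truth.to_json(paths["truth"])
    return paths
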