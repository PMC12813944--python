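"""End-to-end orchestration: filter → overlap → annotate → trios → flag.

``run_screen`` is the in-memory core; ``run_pipeline`` wraps it with file
I/O, a TSV trio report whose body is byte-stable across reruns, and a
machine-readable JSON run summary with per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import GeneModel, annotate_loci, load_genes_bed, load_genes_gtf, load_overrides
from .errors import PipelineStageError, TrioscanError
from .ldpanel import HaplotypePanel, LDConfig, load_panel
from .overlap import OverlapLocus, find_overlaps, merge_loci, validate_loci
from .prioritize import (
    DEFAULT_ALLERGY_TERMS,
    DiseaseCatalog,
    Trio,
    build_trios,
    flag_allergy_relevance,
    load_catalog,
)
from .sumstats import (
    AssociationRecord,
    ThresholdConfig,
    TraitType,
    dedupe_records,
    filter_significant,
    load_sumstats,
)

__all__ = ["RunConfig", "ScreenResult", "run_screen", "run_pipeline", "write_trio_report", "loci_to_frame"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "condition",
    "gene",
    "gene_function",
    "microbe_snp",
    "microbe",
    "microbe_p",
    "metab_snp",
    "metabolite",
    "metab_p",
    "chrom",
    "mode",
    "r2",
    "distance_bp",
    "gene_source",
    "allergy_flag",
    "disease_links",
]


@dataclass
class RunConfig:
    """File-level configuration for one pipeline run.

    Every default equals the screen's canonical parameter set
    (alpha 1e-6 / 1e-5, window 250 kb, r² floor 0.8).
    """

    microbe: Path
    metabolite: Path
    panel: Path | None = None
    genes: Path | None = None
    overrides: Path | None = None
    catalogs: tuple[Path, ...] = ()
    gene_info: Path | None = None
    outdir: Path = Path("trioscan_out")
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    ld: LDConfig = field(default_factory=LDConfig)
    allergy_terms: frozenset[str] = DEFAULT_ALLERGY_TERMS
    dedupe: bool = True
    merge: bool = True
    anchor: str = "microbe"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("microbe", "metabolite", "panel", "genes", "overrides", "gene_info", "outdir"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        if "catalogs" in raw:
            kwargs["catalogs"] = tuple(Path(p) for p in raw["catalogs"])
        th = {k: float(raw[k]) for k in ("alpha_microbe", "alpha_metabolite") if k in raw}
        if th:
            kwargs["thresholds"] = ThresholdConfig(**th)
        ld = {}
        if "window_bp" in raw:
            ld["window_bp"] = int(raw["window_bp"])
        if "r2_min" in raw:
            ld["r2_min"] = float(raw["r2_min"])
        if ld:
            kwargs["ld"] = LDConfig(**ld)
        for key in ("dedupe", "merge", "anchor", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "allergy_terms" in raw:
            kwargs["allergy_terms"] = frozenset(raw["allergy_terms"])
        return cls(**kwargs)


@dataclass
class ScreenResult:
    trios: list[Trio]
    loci: list[OverlapLocus]
    counts: dict[str, int]


def run_screen(
    microbe: Sequence[AssociationRecord],
    metab: Sequence[AssociationRecord],
    panel: HaplotypePanel | None,
    genes: Sequence[GeneModel],
    catalogs: Sequence[DiseaseCatalog],
    *,
    thresholds: ThresholdConfig | None = None,
    ld: LDConfig | None = None,
    overrides: Mapping[str, str] | None = None,
    allergy_terms=DEFAULT_ALLERGY_TERMS,
    dedupe: bool = True,
    merge: bool = True,
    anchor: str = "microbe",
) -> ScreenResult:
    """Run the full screen in memory and return trios plus stage counts."""
    thresholds = thresholds or ThresholdConfig()
    ld = ld or LDConfig()
    counts = {"microbe_loaded": len(microbe), "metab_loaded": len(metab)}
    try:
        if dedupe:
            microbe = dedupe_records(microbe)
            metab = dedupe_records(metab)
        microbe_f = filter_significant(microbe, thresholds)
        metab_f = filter_significant(metab, thresholds)
    except TrioscanError as exc:
        raise PipelineStageError("filter", str(exc)) from exc
    counts["microbe_filtered"] = len(microbe_f)
    counts["metab_filtered"] = len(metab_f)
    try:
        loci = find_overlaps(microbe_f, metab_f, panel, ld)
        validate_loci(loci, ld)
        counts["overlap_loci"] = len(loci)
        if merge:
            loci = merge_loci(loci, panel, ld)
        counts["merged_loci"] = len(loci)
    except TrioscanError as exc:
        raise PipelineStageError("overlap", str(exc)) from exc
    try:
        annotated = annotate_loci(loci, genes, overrides, anchor=anchor)
    except TrioscanError as exc:
        raise PipelineStageError("annotate", str(exc)) from exc
    try:
        trios = build_trios(annotated)
        counts["trios"] = len(trios)
        trios = flag_allergy_relevance(trios, catalogs, allergy_terms)
        counts["flagged"] = sum(t.allergy_flag for t in trios)
    except TrioscanError as exc:
        raise PipelineStageError("prioritize", str(exc)) from exc
    return ScreenResult(trios=trios, loci=loci, counts=counts)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_trio_report(
    trios: Sequence[Trio],
    path: str | Path,
    *,
    gene_info: Mapping[str, str] | None = None,
    conditions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Write the final trio table.

    ``condition`` is the catalog-derived assigned condition unless a
    conditions sidecar overrides it; ``gene_function`` is a free-text
    pass-through from the gene-info sidecar.
    """
    gene_info = dict(gene_info or {})
    conditions = dict(conditions or {})
    rows = []
    for t in trios:
        rows.append(
            {
                "condition": conditions.get(t.gene, t.assigned_condition),
                "gene": t.gene,
                "gene_function": gene_info.get(t.gene, ""),
                "microbe_snp": t.microbe_snp,
                "microbe": t.microbe,
                "microbe_p": _fmt(t.microbe_p),
                "metab_snp": t.metab_snp,
                "metabolite": t.metabolite,
                "metab_p": _fmt(t.metab_p),
                "chrom": t.chrom,
                "mode": t.mode,
                "r2": _fmt(t.r2),
                "distance_bp": t.distance_bp,
                "gene_source": t.gene_source,
                "allergy_flag": str(bool(t.allergy_flag)).lower(),
                "disease_links": ";".join(
                    f"{L.entity_class}:{L.trait}:{L.provenance}" for L in t.disease_links
                ),
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def loci_to_frame(loci: Sequence[OverlapLocus]) -> pd.DataFrame:
    rows = []
    for L in loci:
        rows.append(
            {
                "chrom": L.chrom,
                "microbe_rsid": L.microbe_assoc.rsid,
                "microbe_pos": L.microbe_assoc.pos,
                "microbe_ea": L.microbe_assoc.effect_allele,
                "microbe_trait": L.microbe_assoc.trait,
                "microbe_p": _fmt(L.microbe_assoc.pvalue),
                "metab_rsid": L.metab_assoc.rsid,
                "metab_pos": L.metab_assoc.pos,
                "metab_ea": L.metab_assoc.effect_allele,
                "metab_trait": L.metab_assoc.trait,
                "metab_p": _fmt(L.metab_assoc.pvalue),
                "mode": L.mode,
                "r2": _fmt(L.r2),
                "distance_bp": L.distance_bp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "microbe_rsid", "microbe_pos", "microbe_ea", "microbe_trait", "microbe_p",
            "metab_rsid", "metab_pos", "metab_ea", "metab_trait", "metab_p",
            "mode", "r2", "distance_bp",
        ],
    )


def frame_to_loci(df: pd.DataFrame) -> list[OverlapLocus]:
    loci = []
    for row in df.itertuples(index=False):
        m = AssociationRecord(
            rsid=row.microbe_rsid, chrom=str(row.chrom), pos=int(row.microbe_pos),
            effect_allele=row.microbe_ea, pvalue=float(row.microbe_p),
            trait=row.microbe_trait, trait_type=TraitType.MICROBE,
        )
        b = AssociationRecord(
            rsid=row.metab_rsid, chrom=str(row.chrom), pos=int(row.metab_pos),
            effect_allele=row.metab_ea, pvalue=float(row.metab_p),
            trait=row.metab_trait, trait_type=TraitType.METABOLITE,
        )
        loci.append(
            OverlapLocus(
                microbe_assoc=m, metab_assoc=b, mode=str(row.mode),
                r2=float(row.r2), distance_bp=int(row.distance_bp),
            )
        )
    return loci


def run_pipeline(cfg: RunConfig) -> ScreenResult:
    """File-level pipeline run; writes trios.tsv and run_summary.json.

    The report body depends only on inputs and parameters, so a rerun with
    an identical config is byte-identical; timestamps live in the log only.
    """
    for name in ("microbe", "metabolite", "panel", "genes", "overrides", "gene_info"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise PipelineStageError("config", f"input path for {name!r} does not exist: {p}")
    for p in cfg.catalogs:
        if not Path(p).exists():
            raise PipelineStageError("config", f"catalog path does not exist: {p}")

    microbe = load_sumstats(cfg.microbe, TraitType.MICROBE)
    metab = load_sumstats(cfg.metabolite, TraitType.METABOLITE)
    panel = load_panel(cfg.panel) if cfg.panel else None
    if cfg.genes is not None:
        loader = load_genes_bed if str(cfg.genes).endswith(".bed") else load_genes_gtf
        genes = loader(cfg.genes)
    else:
        genes = []
    overrides = load_overrides(cfg.overrides) if cfg.overrides else {}
    catalogs = [load_catalog(p) for p in cfg.catalogs]
    gene_info = None
    if cfg.gene_info:
        df = pd.read_csv(cfg.gene_info, sep="\t", dtype=str)
        gene_info = dict(zip(df["gene"], df["function"]))

    logger.info(
        "run_pipeline: alpha_microbe=%g alpha_metabolite=%g window_bp=%d r2_min=%g seed=%s",
        cfg.thresholds.alpha_microbe, cfg.thresholds.alpha_metabolite,
        cfg.ld.window_bp, cfg.ld.r2_min, cfg.seed,
    )
    result = run_screen(
        microbe, metab, panel, genes, catalogs,
        thresholds=cfg.thresholds, ld=cfg.ld, overrides=overrides,
        allergy_terms=cfg.allergy_terms, dedupe=cfg.dedupe, merge=cfg.merge, anchor=cfg.anchor,
    )

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trio_report(result.trios, outdir / "trios.tsv", gene_info=gene_info)
    loci_to_frame(result.loci).to_csv(outdir / "loci.tsv", sep="\t", index=False)
    summary = {
        "counts": result.counts,
        "parameters": {
            "alpha_microbe": cfg.thresholds.alpha_microbe,
            "alpha_metabolite": cfg.thresholds.alpha_metabolite,
            "window_bp": cfg.ld.window_bp,
            "r2_min": cfg.ld.r2_min,
            "dedupe": cfg.dedupe,
            "merge": cfg.merge,
            "anchor": cfg.anchor,
        },
        "seed": cfg.seed,
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return result
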