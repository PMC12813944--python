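# trioscan

Cross-reference gut-microbiome-GWAS and blood-metabolome-GWAS summary
statistics to discover **gene–microbe–metabolite trios**.

The screen runs in five stages:

1. **filter** — validate and threshold-filter per-layer association tables
   (strict suggestive significance: p < 1×10⁻⁶ for gene–microbe,
   p < 1×10⁻⁵ for gene–metabolite);
2. **overlap** — join the two layers into overlap loci by exact lead-SNP
   identity, or by LD proxies (r² > 0.8 within a 250 kb window) computed
   from a phased haplotype reference panel (VCF, EUR-like);
3. **annotate** — assign each locus its nearest protein-coding gene
   (GTF/BED gene models), with an rsid→gene override table for
   literature-assigned genes;
4. **prioritize** — collapse loci into trios and flag trios whose gene,
   microbe, or metabolite has a catalogued link to immune/allergy traits
   (offline TSV catalog snapshots);
5. **report** — a TSV trio table plus a JSON run summary with per-stage
   counts; the report body is byte-stable across reruns.

A seeded synthetic-data generator (`trioscan.simulate`) produces block-LD
haplotype panels, paired summary statistics with planted pleiotropic loci
and margin-controlled distractors, gene files and mini-catalogs, so every
stage is testable without downloads. A packaged example dataset
(`trioscan.datasets`, 12 trios with a stub perfect-LD panel) exercises the
whole pipeline end-to-end.

## CLI

```sh
# full run on the packaged example dataset
trioscan fixture --out fx/
trioscan run --microbe fx/microbe.tsv --metabolite fx/metabolite.tsv \
    --panel fx/panel.vcf --genes fx/genes.gtf --overrides fx/overrides.tsv \
    --gene-info fx/gene_info.tsv \
    --catalog fx/catalogs/gwas_catalog_like.tsv \
    --catalog fx/catalogs/gutmdisorder_like.tsv \
    --out out/

# synthetic screen with planted ground truth
trioscan simulate --seed 7 --planted 5 --distractors-ld 10 --out sim/
trioscan run --microbe sim/microbe.tsv --metabolite sim/metabolite.tsv \
    --panel sim/panel.vcf --genes sim/genes.gtf \
    --catalog sim/catalogs/sim.tsv --out simout/

# individual stages
trioscan filter --microbe M.tsv --metabolite B.tsv --alpha-microbe 1e-6 \
    --alpha-metabolite 1e-5 --out filtered/
trioscan ld --panel panel.vcf --anchor rs687289 --candidates cand.tsv \
    --window 250000 --r2 0.8
trioscan overlap --microbe filtered/microbe.tsv \
    --metabolite filtered/metabolite.tsv --panel panel.vcf --out loci.tsv
trioscan annotate --loci loci.tsv --genes genes.gtf --overrides ov.tsv \
    --out annotated.tsv
trioscan prioritize --loci annotated.tsv --catalog catalogs/gc.tsv \
    --out trios.tsv
```

`trioscan run` also accepts a YAML config (`--config run.yaml`) with CLI
flags overriding individual fields; all defaults equal the canonical
parameter set (1e-6 / 1e-5, 250 kb, r² 0.8).

## Input formats

- **Summary statistics**: TSV with header
  `rsid  chrom  pos  effect_allele  pvalue  trait  study_id`
  (GRCh37 positions, 1-based; one trait layer per file).
- **Panel**: VCF 4.x with phased GT (`|`); multi-allelic and non-SNP
  records are skipped. Unphased panels are accepted with
  `--allow-unphased` and fall back to a dosage-correlation LD estimator.
- **Genes**: GTF `gene` features (`gene_name`, `gene_biotype`) or
  6-column BED (`chrom start end name biotype strand`, 0-based half-open).
- **Catalogs**: TSV `entity  class  trait  provenance` with
  `class ∈ {gene, microbe, metabolite}`.

## Tests and acceptance report

```sh
python -m pytest tests/          # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reruns the pipeline on the packaged example dataset
and reports the end-to-end trio count and the extreme retained p-values
per layer.
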