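# allergy12 example dataset

A 12-trio gene-microbe-metabolite screening example with:

- `microbe.tsv`, `metabolite.tsv` — one suggestive association per layer per trio
  (canonical trioscan summary-statistics TSV dialect);
- `panel.vcf` — a STUB haplotype panel: the two SNPs of each trio are encoded
  with identical haplotype columns, i.e. perfect LD (r^2 = 1). Real reference-
  panel r^2 values for these pairs are not part of this dataset; the stub only
  guarantees that each pair passes an r^2 > 0.8 proxy screen.
- `genes.gtf`, `overrides.tsv`, `gene_info.tsv` — gene bodies spanning each SNP
  pair, literature-style rsid->gene overrides, and free-text gene functions;
- `catalogs/` — offline mini disease catalogs (gene/microbe/metabolite ->
  trait) sufficient to flag all 12 trios as allergy-relevant.

Positions are invented but internally consistent (GRCh37-style coordinates).
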