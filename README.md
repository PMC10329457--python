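# syncom

Analysis toolkit for deconstructing synthetic bacterial community (SynCom)
experiments on plants. It implements five pipeline stages plus generators
for synthetic inputs with recorded ground truth:

- **cooccurrence** — detect modules of co-occurring strains from a
  relative-abundance matrix (row-mean standardization, Pearson
  dissimilarity `d = 1 − r`, Ward.D2 hierarchical clustering, tree cut at
  `k`), and test per-module family overrepresentation (upper-tail
  hypergeometric test, Benjamini–Hochberg FDR, significant at q < 0.1).
- **hotspot** — find clade-specific genomic hotspots: select orthogroups
  present in 100% of a focal clade and in < 5% of background genomes, then
  assemble the selected genes on a reference genome into runs whose
  intervening gaps are < 10 kb, reporting runs with ≥ 10 orthogroups.
  Includes closed-interval helpers (kb length, intersection, containment).
- **phenotype** — classify root-growth-inhibition (RGI) inducers (pooled
  mean primary-root elongation strictly < 3 cm), test reversion of RGI by
  partner strains (one-sided Welch t-test, BH-FDR), standardize elongation
  to per-genotype no-bacteria controls, and compute treatment IQRs.
- **geneset** — resampling test for a shift in mean standardized
  expression of a marker gene set between two treatments (random
  equal-size gene sets, `p = (1 + #extreme) / (B + 1)`), plus per-treatment
  set-mean trajectories with 95% CIs. Row z-scoring is provided; upstream
  count normalization (e.g. a variance-stabilizing transform) is the
  caller's responsibility.
- **prevalence** — presence/widespread/core classification of ASVs across
  sites or plant species. All thresholds strict: samples kept when reads
  > 1,000; present when RA > 0.01%; widespread when present in > 80% of
  sites; per-species present when in > 70% of its samples; core when
  present in every species.
- **synthetic_data** — deterministic, seeded generators for every input
  above (abundance with planted modules, pangenomes with a planted
  contiguous clade-unique cluster plus isolated decoys, plate phenotypes,
  expression with a planted marker shift, surveys with planted core ASVs),
  each returning a ground-truth record.

## CLI

Every analysis is reachable through the `syncom` entry point; outputs are
plain TSV/GFF3/BED/Newick/JSON and each output directory gets a
`provenance.json` (version, config, input checksums, timestamp).

```sh
# generate inputs with recorded truth
syncom simulate pangenome --seed 3 --out sim/
syncom simulate abundance --seed 7 --out abund/

# analyses
syncom modules --abundance abund/abundance.tsv --taxonomy abund/taxonomy.tsv --k 4 --out mod/
syncom hotspots --gff sim/gff/focal_001.gff3 --orthogroups sim/orthogroups.tsv \
    --clades sim/clades.tsv --gap-kb 10 --min-genes 10 --out hs/
syncom rgi --phenotypes pheno/phenotypes.tsv --cutoff-cm 3.0
syncom reversion --phenotypes pheno/phenotypes.tsv --inducer strain_0001
syncom geneset-test --expr ex/expression.tsv --treatments ex/treatments.tsv \
    --set ex/marker_set.txt --t1 t1 --t2 t2 --b 10000 --seed 1 --out gs/
syncom prevalence --survey sv/survey.tsv --out prevalence.tsv
```

A YAML file of option defaults can be supplied with `--config run.yaml`
on the `modules` and `hotspots` subcommands; explicit flags win.

## Conventions

- Genomic coordinates are 1-based inclusive everywhere (GFF3 style); BED
  export converts to 0-based half-open.
- Hotspot gaps are intervening bases (`next.start − run.end − 1`), merged
  when strictly below the threshold; the size filter counts distinct
  orthogroups by default (`count="genes"` switches to gene copies, and
  `inclusive=False` gives a strict `>` filter).
- All generators take an explicit seed and are byte-deterministic.
- Welch t-tests + BH-FDR replace ANOVA + Tukey letter displays for the
  reversion decisions; drop-out style contrasts use the same machinery.
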