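# On-disk formats

All files are plain TSV/text; lines starting with `#` are comments and are
ignored by every reader.  Missing fields are written as `.`.

## Plate table (`plates.tsv`)

One row per grid position, as produced by colony-quantification software.

| column | type | notes |
|---|---|---|
| batch | label | independent screen repetition, e.g. `b1` |
| query | label | query strain name |
| plate | label | plate within the (batch, query), e.g. `p1` |
| row | int | 1-based, top-left origin |
| col | int | 1-based |
| size | float ≥ 0 | colony size in arbitrary units (pixel area); 0 = no growth |
| position_kind | `library` / `empty` / `reference` | |
| gene_id | string or `.` | present iff position_kind = library |

`(batch, query, plate, row, col)` must be unique.

## Genome map (`genome.bed`)

Standard 6-column BED: chrom, start, end, name, score, strand; 0-based
half-open coordinates; gene names unique.

## Library layout (`layout.tsv`)

Position → block assignment shared by all plates of a screen.

| column | notes |
|---|---|
| plate | 1-based plate index |
| row, col | 1-based position |
| block_id | 2×2 quadruplicate block label |
| position_kind | `library` / `empty` |
| gene_id | `.` for empty blocks |
| control_empty | 1 for deliberately empty control quadrants |

## Truth table (`truth.tsv`)

Simulator ground truth: `gene_id`, `query`, `delta` (true log2 interaction
effect), `linked` (0/1, inside the linkage window of that query's locus).

## Screen matrix (`screen_matrix.tsv`)

Long-format normalized observations: `gene_id`, `query`, `batch`,
`replicate` (1–4 within the quadruplicate), `value` (normalized log2
colony size), `weight`, `block_id`.

## Fit table (`fits.tsv`)

`gene_id`, `contrast` (e.g. `mutA-ctrl`), `effect` (normalized colony-size
difference, log2), `se`, `t` (moderated), `df`, `p`, `padj` (BH within
contrast).

## Gene sets (GMT) and disease slim

GMT: per line `term_id <TAB> description <TAB> gene1 <TAB> gene2 ...`.
Disease slim: per line `disease_id <TAB> disease_name <TAB> gene_id`; a
gene may appear under several diseases.

## Configuration (YAML)

```yaml
seed: 0
alpha: 0.05              # significance cut on BH-adjusted p-values
linkage_window: 500000   # bp
min_fraction: 0.1        # failed-mutant call on control plates
enrichment_fdr: 0.1
reference: mutA          # reference mutant for allele comparisons
simulation:
  n_genes: 1000
  n_chromosomes: 3
  spacing: 20000
  n_batches: 3
  quad: 4
  plate_rows: 32
  plate_cols: 48
  sigma0: 0.3
  trend_strength: 0.5
  rho: 0.25
  batch_sd: 0.3
  rowcol_sd: 0.1
  spatial_amplitude: 0.3
  dropout_p: 0.02
  control_empty_quadrants: 8
  queries:
    - {name: ctrl, control: true, fraction_positive: 0, fraction_negative: 0}
    - {name: mutA, fraction_positive: 0.05, fraction_negative: 0.05}
```

Unknown keys are rejected; omitted keys take the defaults above.
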