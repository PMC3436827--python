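# Inter-stage file contracts

All coordinates in TSV/BED outputs are 0-based, half-open.  TSVs carry
a header line and are written/read with pandas.

## Inputs

- **FASTA** — reference and duplicated genome sequences.
- **GFF3** — gene models (`gene`/`mRNA`/`exon`/`CDS`); 1-based closed,
  converted internally; multi-transcript genes use union-of-exons and
  union-of-CDS, UTR = exon − CDS.
- **MAF** — pairwise alignment blocks, reference row first; minus-strand
  target rows are normalised to forward-strand coordinates on read.
- **BED6** — UCNE coordinates, `name` = UCNE id.
- **orthologs.tsv** — `ref_gene_id`, `species`, `ortholog_gene_id`,
  `orthology_confidence` (`ortholog` or `possible_ortholog`).

## Stage outputs

### ucnes.tsv
`ucne_id  chrom  start  end  position_class  genes`
— `position_class` ∈ {intronic, UTR, intergenic}; `genes` is the host
gene (intronic/UTR) or comma-separated flanking genes (intergenic).

### hits.tsv
`ucne_id  genome  chrom  start  end  strand  raw  bitscore  evalue  accepted  paralog_flag`
— one row per (UCNE, candidate region); `accepted` ⇔ E ≤ 1e-4;
paralog-flagged rows are excluded from all retention tallies.

### patterns.tsv
`gene  genome  a  b  c  label  major_id  major_tie`
— per (reference gene, genome) retention triplet and label
(winner/concordant/reciprocal).

### winner_scores.tsv
`gene  genome  c_total  c_major  W`

### null_histogram.tsv
`bin_lo  bin_hi  mean_freq  sd_freq` — permutation-null winner-score
histogram (mean ± sd over shuffles).

### clusters.tsv
`cluster_id  n_ucnes  chrom  start  end  genes`

### cluster_retention.tsv
`cluster_id  genome  a  b  c  label`

### gene_calls.tsv
`cluster_id  gene  call` — `target` or `bystander`.

### run_log.json
Parameters plus per-stage record counts.

## Ground truth (synthetic bundles)

`ground_truth.json` — per-UCNE positional class, host genes and
retaining copies; per-gene designated major copy; per-cluster
generating scenario.
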