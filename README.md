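# kanseek

Identify transcription-factor target genes by intersecting ChIP binding
evidence with induction time-course expression responses.

The pipeline:

1. **filter** — reduce called ChIP-enriched regions to those with at least
   three-fold read-count enrichment (any replicate, configurable);
2. **scan** — search region sequences for a degenerate IUPAC motif
   (default `VGAATAW`, reverse complement `WTATTCB`) on both strands;
3. **annotate** — assign motif-bearing regions to nearby gene models with a
   distance to the CDS and an UP / DOWN / in-CDS label (strand-aware,
   default window 10.5 kb), and summarize the genome-wide positional
   distribution of binding sites;
4. **call-expression** — call per-gene down/up-regulation at the 80 and
   160 min post-induction timepoints from probe-level log2 ratios,
   requiring a consistent response along the transcript (pre-computed
   `yes`/`-` call tables are accepted too);
5. **integrate** — intersect bound genes with regulation calls into
   direct-target tables;
6. **compare** — pair two factors' binding sites per gene and flag genes
   whose nearest sites lie less than 100 bp apart (proximal co-binding).

A synthetic-study generator (`kanseek simulate`) emits a motif-screened
genome, gene models, planted motif instances with a configurable positional
mixture, binding regions with replicate enrichments, probe tracks, and a
ground-truth table, so the whole pipeline is testable offline.  Verbatim
TSV transcriptions of the published target tables (comma-decimal cells
preserved) are packaged under `src/kanseek/data/`.

## CLI

```sh
kanseek simulate --outdir sim/                      # synthetic study, default config
kanseek run --config pipeline.yaml                  # full workflow + manifest
kanseek filter --regions sim/regions.tsv --out filtered.tsv
kanseek scan --fasta sim/genome.fa --regions filtered.tsv \
    --out-hits hits.tsv --out-regions annotated.tsv
kanseek annotate --gff3 sim/genes.gff3 --regions annotated.tsv \
    --out-assignments assign.tsv --out-distribution dist.tsv
kanseek call-expression --probes sim/probes.tsv --out calls.tsv
kanseek compare --sites-a a.tsv --sites-b b.tsv --out dual.tsv
```

`pipeline.yaml` is a flat key/value file mirroring
`kanseek.pipeline_cli.PipelineConfig` (paths to regions/fasta/gff3 and
probes or calls, thresholds, output directory).  `kanseek run` writes every
intermediate table plus `manifest.tsv` with input checksums, parameters and
per-stage record counts.

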