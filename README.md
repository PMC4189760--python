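# besurvey

A toolkit for BAC-end sequence (BES) genome surveys: load and QC paired end
reads, estimate GC content, mine perfect microsatellites (SSRs) with motif
canonicalization, account for repeat content, extrapolate gene content from
BLAST hits, compute clone-library coverage statistics, and classify paired-end
alignments against reference genomes into microsynteny categories. A
synthetic-data generator produces a toy genome, clone library, reads, a
rearranged reference and complete truth labels, so every stage is verifiable
at desk scale without external data.

## Modules

| module | role |
| --- | --- |
| `besurvey.besio` | BES FASTA I/O, F/R pairing, 100 nt length floor, redundancy, organellar screen |
| `besurvey.composition` | pooled GC content (ambiguity codes and N excluded) |
| `besurvey.ssrmine` | perfect SSR scanner (mono ≥ 10 nt, di ≥ 5 units, tri–hexa ≥ 3 units) and rotation/reverse-complement motif canonicalization |
| `besurvey.repeatacct` | repeat annotation parsing (`.out` and TSV dialects), masking, union-based density accounting, and a naive k-mer masker for self-contained tests |
| `besurvey.genecontent` | BLAST tabular parsing, coding calls, species ranking, genome-wide coding/gene-count extrapolation, GO-term accounting |
| `besurvey.libstats` | genome-equivalent coverage, Poisson recovery probability, insert-size summaries, contamination rates |
| `besurvey.synteny` | SAM parsing and paired-end classification (SE / non-co-localized / collinear / rearranged / gapped; 15–350 kb window) |
| `besurvey.simulate` | seeded synthetic genome/library/reference generator with truth tables |
| `besurvey.cli` | `besurvey` command-line interface |

## CLI

Every stage is independently invocable:

```sh
besurvey simulate --config spec.yaml --outdir sim/        # synthetic data + truth
besurvey qc sim/reads.fasta
besurvey gc sim/reads.fasta
besurvey ssr sim/reads.fasta --loci-out loci.tsv
besurvey repeats sim/reads.fasta --library sim/repeat_library.fasta \
    --features-out features.tsv
besurvey genes hits.tsv --n-total 9698 --species-map species.tsv
besurvey libstats --n-clones 82944 --mean-insert-kb 108 --n-chloroplast 36 \
    --n-mitochondrial 5
besurvey synteny sim/alignments.sam --classes-out classes.tsv
besurvey run-all --config run.yaml --outdir out/          # full survey + report.json
```

`run-all` executes stages in dependency order (QC → GC/SSR → repeat masking →
gene content → library stats → synteny); stages whose inputs are not
configured are marked `skipped` in the report. Reruns with identical inputs
produce byte-identical reports.

## Notes and caveats

- Redundancy is the exact-duplicate fraction of uppercased sequences; no
  similarity clustering is performed.
- The SSR scanner reports perfect repeats only; loci span whole units and
  each nucleotide belongs to at most one locus (leftmost, then longest, then
  smallest primitive unit).
- Whether to exclude N from the GC denominator is a convention; this package
  excludes it.
- GC and repeat densities over sets pool nucleotide counts rather than
  averaging per-read percentages.
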