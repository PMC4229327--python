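# culturegap

Culturability scoring and cultivation-gap prioritization for 16S rRNA
microbiome surveys.

Most members of complex microbial communities — the rumen bacterial
microbiome is the motivating case — have never been grown in the
laboratory, so they have no genome sequence and no physiology.  Given
several published 16S rRNA amplicon surveys and a reference set of
cultured-isolate 16S sequences, `culturegap` answers two questions for
every species-level OTU: *how far is it from anything in culture?* and
*how much does it matter?* — and turns the answers into a ranked list of
cultivation and genome-sequencing targets.  It is aimed at microbiologists
planning isolation campaigns and at bioinformaticians reproducing
culturability meta-analyses.

## The method

1. Reads from each survey are orientation-screened, trimmed to a
   homologous region between dataset-derived conserved anchors, and
   length- and region-filtered (surveys must cover a required window,
   V1+V2 by default).
2. Each survey and the cultured pool are clustered greedily at 97%
   identity; chimeric clusters are removed by a parent-crossover screen.
   Representatives, cut to the window shared by all surveys, are
   clustered again at 97% into **universal OTUs** that carry per-survey
   member counts and a contains-cultured flag.
3. On a phylogeny over universal OTUs (neighbor joining by default, or an
   ingested tree), each OTU receives the patristic distance to the
   nearest cultured tip, **zero if its own cluster contains a cultured
   isolate**.
4. Survey counts are depth-normalized by trimmed-mean-of-M (TMM) scaling
   factors; each OTU gets its mean percent abundance across all surveys
   and its prevalence (fraction of surveys where it occurs).
5. With d̂ = d / max d the scaled distance and â = a / max a the scaled
   abundance, each OTU is placed in the unit square and ranked by
   √(d̂² + â²).  Flags: **core** (present in ≥ ⌈5D/7⌉ of D surveys),
   **abundant** (â > 0.25), **novel** (d̂ > 0.25).  Flagged OTUs with
   > 93% identity to a cultured rumen isolate become sequencing
   candidates (one per isolate); the rest require new cultivation effort.

A synthetic-data module generates complete multi-survey studies — master
16S-like gene with conserved/variable blocks, cultured pool, community
lineages at controlled divergence, log-normal abundances with a planted
core, chimeric and reverse-complemented reads — with full ground truth,
so the whole pipeline is testable without downloading anything.  See
`docs/methods.md` for model details and assumptions.

## Worked example

Simulate a seven-survey study and run every stage:

```
$ culturegap --log-level WARNING all --workdir demo --seed 42
simulated 7 datasets in demo
preprocessed 7 datasets
clustered 7 datasets plus the cultured pool
43 universal OTUs
tree over 43 tips written
distances for 43 OTUs written
TMM reference dataset: ds00
10 core, 6 abundant, 8 novel (19 flagged OTUs in total)
13 clades over 35 rumen OTUs
```

The 43 universal OTUs combine the survey OTUs with the cultured-isolate
pool; 35 of them contain survey reads and enter the metrics table.  Ten
are core (seen in at least five of the seven surveys), six exceed the
0.25 scaled-abundance cut-off, and eight sit more than a quarter of the
maximum observed distance away from any cultured isolate — the
cultivation gap.  `demo/metrics.tsv` holds one row per OTU:

```
otu_id     scaled_distance  scaled_abundance  prevalence  euclidean   ...  is_core  is_abundant  is_novel
UOTU00002  0                0.30241317        0.28571429  0.30241317  ...  False    True         False
UOTU00003  0                0.02450359        1           0.02450359  ...  True     False        False
```

`UOTU00003` appears in all seven surveys (prevalence 1) and its cluster
contains a cultured isolate (distance 0): a core organism already in
culture.  `UOTU00002` is abundant but rare across surveys.  The run also
writes `candidates.tsv` (flagged OTUs matched to a cultured isolate at
> 93%, one candidate per isolate), `needs_cultivation.tsv`,
`report_summary.txt` (phylum roll-ups per category), `clades.tsv`, and a
JSON manifest per stage with input/output checksums — rerunning with the
same seed reproduces every file byte for byte.

Stages can be run individually (`simulate`, `preprocess`, `cluster`,
`merge`, `tree`, `distances`, `abundance`, `classify`, `report`); each
names the stage to run first when an upstream artifact is missing, and
`tree --newick FILE` ingests an externally built phylogeny instead of
running neighbor joining.  The library surface mirrors the stages
(`culturegap.run_pipeline` and the per-module functions).

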