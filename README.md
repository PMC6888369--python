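# rnacomposite

Composite RNA secondary-structure inference for long transcripts from three
probing modalities plus minimum-free-energy (MFE) folding:

* **nuclease ratio tracks** (S1:V1 read-count ratio; > 1 calls single-stranded,
  < 1 double-stranded),
* **chemical reactivity** (DMS stop counts on A/C; > 20 calls unprotected),
* **crosslink-ligation duplex groups** (accepted when reads > 3 in at least
  two of three datasets, or > 5 in any one),

reconciled per nucleotide under explicit precedence (duplex evidence >
channel agreement > MFE tiebreak > default-unstructured), with pseudoknot
layer calling, 5′→3′ element naming (H*/PK*/nWJ), agreement/coverage
statistics, helix-conservation and covariation scoring over Stockholm
homolog alignments, and a functional-annotation overlay (binding-site
context, modification matrices, differential-duplex "structural switch"
candidates, mutation/SNP refolding impact).

A first-class synthetic-data module generates ground-truth transcripts,
probing tracks, duplex tables, homolog alignments, and annotations with the
statistical structure the analysis assumes; it is the test substrate for the
whole pipeline.

## CLI

One entry point, `rnacomposite`, with subcommands:

```sh
rnacomposite simulate  --seed 1 --outdir out/sim          # synthetic bundle
rnacomposite calibrate --track t.tsv --refs refs.tsv --outdir out/cal
rnacomposite compose   --fasta tx.fa --track t.tsv --duplexes d.tsv --outdir out/model
rnacomposite stats     --fasta tx.fa --track t.tsv --duplexes d.tsv --outdir out/stats
rnacomposite conserve  --stockholm homologs.sto --fasta tx.fa --dotbracket model.db --outdir out/cons
rnacomposite annotate  --fasta tx.fa --dotbracket model.db --annotations ann.tsv --outdir out/ann
rnacomposite switch    --duplexes-a a.tsv --duplexes-b b.tsv --outdir out/switch
rnacomposite mutate    --fasta tx.fa --dotbracket model.db --edit U4056C --outdir out/mut
```

Every run writes `effective_config.json` (flags + config-file keys + input
SHA-256 hashes) and a `run.log`. Seeds are always explicit flags. Config
files (JSON or YAML) address module parameters by dotted keys, e.g.
`cutoffs.pars_ratio`, `paris.single_dataset_reads`, `fold.window`.

### File formats

* probing track: TSV `position base s1 v1 dms`, `NA` for missing, 1-based
  positions, DMS defined only on A/C;
* duplex table: TSV `dataset_id left_start left_end right_start right_end reads`;
* structures: dot-bracket with pseudoknot tiers `()[]{}<>Aa..Zz`, CT, BED6
  (0-based half-open only in BED/bedGraph output);
* homolog alignments: Stockholm with `#=GC SS_cons`.

All coordinates elsewhere are 1-based inclusive.

## Folding backends

The default backend is an exact dynamic program maximizing canonical pair
weights (G-C 3, A-U 2, G-U 1) with a stacking bonus of 1 and a minimum
hairpin loop of 3 nt — an approximate, fully reproducible energy model that
also supports the pairing constraints the composite builder needs. A
`vienna` backend (ViennaRNA python bindings) is used for unconstrained folds
when importable, and falls back to the builtin model otherwise.

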