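# orthoverlap

Integration of genetic-screen hit lists for neurodegeneration models across
worm, yeast and fly: hits are normalized within their species namespace,
projected onto the *C. elegans* reference gene space through packaged orthology
maps, unioned into a deduplicated regulator catalog, and scanned for genes
identified in two or more independent studies. Overlapping regulators can be
annotated with functional classes, human orthologues and neuronal-expression
flags; the interaction subnetwork among the chaperone/ubiquitin-related
regulators is extracted via connected components; and a permutation null model
quantifies whether the observed overlap count exceeds chance.

The package ships curated fixtures (study catalog, overlap table, functional
classes, interaction edges, orthology groups, aliases, expression flags) as
plain TSV/text data files with per-row provenance, plus a deterministic
synthetic-data generator that emits complete, ground-truthed input bundles for
testing every stage offline.

## CLI

A single entry point with subcommands (`--help` on each for details):

```sh
# full pipeline over an input bundle
orthoverlap integrate --studies studies.tsv --genes-dir genes/ \
    --groups groups.txt --aliases aliases.tsv --out outdir/

# render the packaged curated overlap table (34 entries, annotated)
orthoverlap report --out overlaps.tsv

# interaction component around a seed protein (packaged network by default)
orthoverlap network --seed-node CHIP

# permutation null for the >=2-study overlap count
orthoverlap stats --universe-size 500 --observed-from outdir/ --n-perm 10000 --seed 17

# ground-truthed synthetic input bundle
orthoverlap simulate --config sim.yaml --seed 7 --out bundle/
```

`integrate` writes `catalog.tsv`, `overlaps.tsv` and a `summary.json` of stage
counts (studies, raw calls, unmapped calls, distinct genes, overlaps) under the
output directory. The overlap null statistics are an explicit extension and are
off unless requested.

## Library

```python
import orthoverlap as ov

studies = ov.load_fixture("table1_catalog")        # 28 studies
print(ov.summarize_catalog(studies).total_reported)  # 950

entries = ov.load_fixture("table2_overlaps")       # one entry per worm gene
print(len(ov.group_paralogue_entries(entries)))    # 34 after paralogue grouping
```

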