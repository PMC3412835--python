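# mitoarch

Architecture, strand-asymmetry, tandem-repeat and gene-order analysis of
circular (mitochondrial) genomes.

Insect mitogenomes are compact circles of ~37 genes (13 protein-coding
genes, 22 tRNAs, 2 rRNAs) plus an A+T-rich control region. Most species
share a single ancestral gene arrangement (identical to *Drosophila*),
an A- and C-skewed major strand, and a genome size of 14–19 kb — so the
exceptions carry real evolutionary signal. The package was built around
one such exception, the free-living earwig *Challia fletcheri*
(GenBank JN651407): at 20,456 bp the largest insect mitogenome on
record, carrying a 2,856-bp tandem repeat unit inside one intergenic
spacer, a *reversed* strand asymmetry (T- and G-skew on the major
strand, read as evidence of an inverted replication origin), and seven
rearranged tRNAs. `mitoarch` turns the analyses behind such a genome
description into a reusable, tested toolkit for anyone annotating or
comparing mitogenomes.

## What it computes

* **Genome architecture** — a 1-based, circular, wrap-aware coordinate
  model; feature-table (TSV), GenBank and FASTA I/O; signed
  intergenic-spacer/overlap accounting (`g = start(next) − end(prev) − 1`);
  non-fatal annotation validation (published tables contain typos; the
  validator flags them and keeps going).
* **Strand asymmetry** — base composition and the skew statistics
  AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), per whole genome
  and per strand-partitioned PCG set (minor-strand genes are measured on
  their coding strand), with the sign-pattern classifier used in
  comparative surveys (A- and C-skewed, T- and G-skewed, …).
* **Tandem repeat units** — a self-alignment period scan reporting unit
  length ℓ, full copies c, partial copy p and the identity
  span = c·ℓ + p, with deterministic tie-breaking and a brute-force
  oracle for small instances.
* **Non-coding motifs** — combinatorial cloverleaf (tRNA-like) search
  with anticodon/isotype inference, stem-loop search with the conserved
  TATA / G(A)nT control-region flanks, poly-T stretch detection, and
  ORF scanning with alternative starts (TTG, GTG, ATA, …) and
  incomplete stops (T/TA).
* **Gene-order rearrangement** — signed circular gene orders, the
  built-in ancestral insect arrangement, per-gene classification into
  in-place / translocated / locally inverted / shuffled-with-remote-
  inversion via an exact minimum-backbone search, breakpoint counts, and
  scripted duplication/random-loss, inversion and translocation
  operators.
* **Synthetic data** — a seeded generator that plants all of the above
  (per-strand base biases, repeat units with partial copies, cloverleaf
  motifs, rearrangement scripts with ground truth) so every stage is
  testable without downloads.

## Worked example

The published *C. fletcheri* feature table ships with the package:

```python
from mitoarch import (challia_fletcheri_genome, spacer_summary,
                      order_from_genome, ancestral_insect_order,
                      compare_orders, breakpoint_count)

g = challia_fletcheri_genome()
s = spacer_summary(g)
print(f"genome: {g.genome_length} bp, {len(g.features)} features")
print(f"positive spacers: {s['n_positive']} ({s['total_positive']} bp), "
      f"longest {s['max_positive']} bp "
      f"({s['longest_pair'].upstream}-{s['longest_pair'].downstream})")

rep = compare_orders(order_from_genome(g), ancestral_insect_order())
print("rearrangement counts:", rep.summary["counts"])
print("translocated:", sorted(rep.genes_in_class("translocated")))
print("breakpoints:", breakpoint_count(order_from_genome(g),
                                       ancestral_insect_order()))
```

prints

```
genome: 20456 bp, 39 features
positive spacers: 24 (3783 bp), longest 2888 bp (trnI-trnW)
rearrangement counts: {'in_place': 31, 'translocated': 3, 'local_inversion': 1, 'shuffle_with_remote_inversion': 3}
translocated: ['trnI', 'trnN', 'trnR']
breakpoints: 11
```

That is the genome description in four lines: 24 intergenic spacers
totalling 3,783 bp, the largest (2,888 bp, between *trnI* and *trnW*)
hosting the giant repeat; and, against the ancestral arrangement, three
translocated tRNAs (*trnI*, *trnN*, *trnR* — the products of two
duplication/random-loss events), one local inversion (*trnE*) and three
tRNAs shuffled with remote inversion (*trnQ*, *trnY*, *trnC*), with
every protein-coding and rRNA gene in place.

The same analyses are available from the shell:

```sh
mitoarch simulate --seed 7 --out-prefix sim/x     # synthetic genome
mitoarch spacers  --table t.tsv --out spacers.json
mitoarch skew     --table t.tsv --fasta g.fa --out skew.json
mitoarch repeats  --fasta g.fa --region 1295:4150 --out tru.json
mitoarch scan     --fasta g.fa --mode polyt --out runs.json
mitoarch rearrange --observed t.tsv --out events.json
mitoarch report   --table t.tsv --fasta g.fa --text
```

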