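# repliclass

Plasmids are extra-chromosomal, autonomously replicating DNA elements of
bacteria and the main vectors of horizontal gene transfer — including the
spread of antibiotic-resistance genes. Most public bacterial genomes are
only partially assembled, so telling which contigs of a draft assembly
come from a plasmid and which from the chromosome is a routine but hard
problem: homology search alone is precise but insensitive, and k-mer
signatures fail on short contigs.

`repliclass` classifies contigs as **plasmid** or **chromosome** with a
random forest fed by features summarising a homology search against a
plasmid reference database. For each query contig, every BLAST-style local
alignment ("hit") against the database with e-value ≤ 10⁻³ is reduced to
its *overlap* — the fraction of the query covered by the hit's aligned
span — and the contig is described by seven predictors:

1. number of hits,
2. maximum overlap,
3. average overlap,
4. median overlap,
5. (population) variance of overlaps,
6. contig size (bp),
7. G+C content.

A 500-tree random forest trained on these features calls a contig plasmid
when the fraction of trees voting plasmid exceeds 0.5. The package also
ships the full training machinery: a *shredder* that cuts complete
replicons into artificial contigs following a draft-genome contig-size
distribution, per-size-bin down-sampling of the training set to ~10%
plasmid contigs, a genome-level 70/30 train/test split, the
confusion-matrix indices (sensitivity, precision, F1, MCC), Cohen's κ for
inter-classifier agreement, and the two 50-replicate bootstrap
sensitivity analyses (resampling the reference database, resampling the
training rows). A synthetic fixture generator makes the whole pipeline
trainable and testable offline, with no reference download.

## Worked example

Generate a synthetic study system, train, and classify:

```sh
repliclass make-fixture --out-dir fixture --n-genomes 8 --n-db-plasmids 8 --seed 9
repliclass train --genomes fixture/replicons.fasta --truth fixture/truth.csv \
    -d fixture/database.fasta --out-model model.joblib \
    --out-metrics metrics.csv --n-trees 50 --seed 4
```

which prints:

```
trained on 154 contigs (6 genomes); held-out MCC 1.000 on 39 contigs
```

— the forest was trained on 154 balanced contigs from 6 genomes and
classified all 39 contigs of the 2 held-out genomes correctly (MCC, the
Matthews correlation coefficient, is 1 for a perfect prediction, 0 for a
random one). Then classify new contigs:

```sh
repliclass shred -i fixture/replicons.fasta --truth fixture/truth.csv \
    -o contigs.fasta --out-truth contig_truth.csv --seed 2
repliclass classify -i contigs.fasta -d fixture/database.fasta \
    -m model.joblib -o calls.csv -r -f
```

`calls.csv` has one row per contig with its predicted label, the
provenance of the call (`annotation` if the FASTA header already named a
plasmid or chromosome, `classifier` otherwise), the plasmid vote
fraction, and — with `-f` — the seven feature values. The same steps are
available as library functions (`repliclass.make_fixture`,
`repliclass.run_train`, `repliclass.classify_contigs`).

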