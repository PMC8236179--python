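# Methods

## The classification model

A contig is classified from evidence of homology with a plasmid reference
database. Let the contig have length *L* and let its filtered hits
(local pair-alignments with e-value ≤ 10⁻³) have query spans
[q₁s, q₁e), …, [qₖs, qₖe). Each hit *i* contributes an *overlap*
oᵢ = (qᵢe − qᵢs)/L ∈ (0, 1]. The contig's feature vector is

    (k, max oᵢ, mean oᵢ, median oᵢ, var oᵢ, L, GC)

with the four overlap statistics all 0 when k = 0, population
(divide-by-n) variance, even-count medians taken as the midpoint of the
two central values, and GC = (#G + #C + #S)/L (the IUPAC "strong" code S
counts as G+C, matching the classic Biopython GC utility; all other
ambiguity codes count only toward the denominator).

The classifier is a random forest of 500 trees (scikit-learn
`RandomForestClassifier`; impurity splits, unbounded depth, √p features
per split, no class weighting — imbalance is handled by balancing the
training data instead). A contig is called plasmid when the fraction of
trees voting plasmid strictly exceeds the decision threshold (default
0.5; a vote exactly at the threshold is chromosome). Class imbalance,
hit counting (one hit = one HSP; an optional switch collapses to the
best hit per subject) and the e-value cutoff are all configurable but
default to the conventions above.

Before classification, contigs whose FASTA description already names a
plasmid or a chromosome are passed through with that label
(case-insensitive substring keywords, default `{"plasmid"}` vs
`{"chromosome", "complete genome"}`; a header matching both is treated as
unannotated). This avoids re-identifying already-described sequences; the
`reassign` option disables it.

## Homology backends

Two backends produce identical `Hit` records. The `external_blastn`
backend shells out to NCBI blastn with default scoring and `-outfmt 6`,
converting the 1-based inclusive tabular coordinates to the package's
0-based half-open convention and normalising reversed subject coordinates
to start < end with an explicit strand.

The `builtin` backend is a self-contained seed-and-extend nucleotide
aligner: exact-match seeding at word size 11 on both strands, ungapped
extension with +1/−2 match/mismatch scores and X-drop 20, and a
simplified Karlin–Altschul e-value E = m·n·2^(−S) with S the raw score,
m the query length and n the total database length. It reliably finds the
near-exact homologies that matter here (≥ 98% identity over dozens of
bases clears the 10⁻³ cutoff at fixture scale; chance 11-mer seeds
extend to scores far below it) but makes no attempt to reproduce BLAST's
e-values, gapped alignments or translated searches. All hit lists are
sorted (query id, e-value, subject id, coordinates) so downstream feature
extraction is order-independent by construction.

## Training-data simulation

**Shredding.** Complete replicons are cut left-to-right into contigs
whose target sizes are drawn from a configurable size distribution
(uniform within the chosen bin). Replicons are treated as linear; a
terminal fragment shorter than 50 bp is discarded, so the contigs tile a
prefix of the replicon and every contig records its source coordinates
(an exact-substring invariant that is tested). Two modes exist: the
default draws each target size independently (`per_draw`); `quota` mode
pre-draws and shuffles a global list of target sizes, fixing per-bin
counts near their expectation. Both match the requested distribution; the
per-draw mode is the default because it is simpler and each contig's size
is exchangeable.

**Balancing.** Training contigs are grouped into seven size bins
(50 bp–1 kb, 1–2, 2–5, 5–10, 10–50, 50–100, > 100 kb) and the
over-represented class in each bin is randomly down-sampled — never
duplicated — so the plasmid fraction is as close as achievable to the
10% target. A bin occupied by a single class cannot be balanced; it is
kept unchanged and flagged in the returned report. The test set is never
manipulated.

**Split.** Genomes are split 70/30 into train/test at the genome level,
so no genome contributes contigs to both sides.

**Synthetic fixtures.** `make_fixture` emulates the study system without
any download: the plasmid database is i.i.d. uniform random sequences;
each genome is one random chromosome plus 1–3 plasmids, each a copy of a
random database sequence with i.i.d. substitutions. Defaults — the
package's study conditions — are 40 database plasmids of 2–10 kb,
50 genomes with 40–60 kb chromosomes, and a 2% per-base substitution
rate, shredding into roughly 1,200 contigs; the default contig-size
distribution is short-contig dominated ([50 bp,1 kb): 0.35,
[1,2 kb): 0.25, [2,5 kb): 0.25, [5,10 kb): 0.15), as in real draft
assemblies but capped at 10 kb so fixture replicons shred into enough
contigs. What the fixture does **not** emulate: shared backbone genes and
mosaicism between distinct plasmids, chromosome–plasmid recombination,
compositional (GC, k-mer) differences between replicon classes, and
realistic genome sizes. Chromosome contigs consequently have essentially
no database homology, so the synthetic task is close to separable —
passing the recovery test shows the pipeline is wired correctly and that
homology features carry the signal, not that real-data accuracy equals
the fixture's.

## Evaluation

Sensitivity tp/(tp+fn), precision tp/(tp+fp), F1 = their harmonic mean,
and MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)), with plasmid
as the positive class. A 0/0 rate is reported as undefined with a reason;
MCC with any zero marginal is reported as 0 and flagged (the convention
of standard implementations). Size-stratified reports use five strata
([50 bp,1 kb), [1,2 kb), [2,5 kb), [5,50 kb), [50 kb,∞)) plus an Overall
row computed on pooled counts, never by averaging per-bin rates. Cohen's
κ = (p₀ − pₑ)/(1 − pₑ) measures chance-corrected agreement between two
classifiers' plasmid calls and is undefined when pₑ = 1.

Two bootstrap analyses (default 50 replicates each) probe stability:
resampling the plasmid database (with replacement, original cardinality;
features recomputed and a fresh forest trained per replicate) and
resampling the balanced training rows (features unchanged, test set
fixed). On the fixtures, database resampling degrades and spreads the
MCC — a resample drops ~37% of database sequences, and with them the
only homolog of some plasmids — while training-row resampling barely
moves it; the tests assert exactly this ordering. Tests and the
acceptance script run the bootstraps at 5–10 replicates on miniature
systems (12 genomes, 12 database plasmids); the replicate count and
system size are stated in each run's output (`n`).

## Numerical and design choices

- E-value filtering keeps hits with e-value **≤** 10⁻³ (the inclusive
  convention of blastn's `-evalue` flag).
- Internal coordinates are 0-based half-open everywhere; conversions
  happen only at format boundaries (BLAST tabular is 1-based inclusive).
- Seeded determinism end to end: one seed drives shredding, balancing,
  the genome split and the forest; the same seed gives byte-identical
  FASTA fixtures, identical models and identical predictions. Classify
  results are invariant to thread count and batch size because batches
  are pure functions assembled in input order.
- Model persistence is a single joblib artifact embedding the feature
  names, tree count, threshold, training seed and a format version;
  loading a mismatched version fails loudly rather than mispredicting.
- Degenerate inputs: empty FASTA records, duplicate ids, single-class
  training labels, foreign hits in feature extraction, and id mismatches
  in evaluation all raise validation errors naming the offender.

## Known limitations

- The builtin aligner is ungapped and insensitive below ~90% identity;
  diverged homologies require the blastn backend and a real reference
  database.
- The synthetic fixtures are nearly separable (see above), so measured
  fixture performance is an upper bound, not an estimate, of real-data
  performance.
- Keyword-based annotation labelling is a heuristic over free-text
  headers; the keyword lists are configurable and ambiguous headers fall
  through to the classifier.
- Circularity of replicons is ignored when shredding; the first and last
  fragments of a circular replicon are never joined.
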