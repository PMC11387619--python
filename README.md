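# strainvar

Minority strain-variant calling in marker genes from noisy long reads.

## The problem

When two or more strains of the same bacterial species are present in a
sample — a contaminated clinical isolate, a low-complexity metagenomic bin —
the minority strain reveals itself as minority variants: non-consensus
nucleotides at marker-gene positions carried by a few percent of the reads.
On long-read platforms with per-base error rates of a few percent, plain
abundance thresholding cannot separate these true strain variants from
sequencing noise: error hotspots routinely exceed a 5% positional abundance,
while real minority strains can sit at 1–10%.

`strainvar` scores every candidate variant with four kinds of evidence and
retains it only while its abundance clears a per-candidate threshold:

* **novelty penalty (np)** — the substitution appears in *no* database allele
  of the gene; errors are strongly enriched for novelty:
  `threshold += MAF × np`
* **proximity penalty (pp)** — another candidate lies within 5 bp:
  `threshold += threshold × pp`
* **density penalty (dp)** — each additional candidate position `M` within a
  15 bp window: `threshold += MAF × dp × M`
* **co-occurrence reward (cor)** — the candidate rides the same reads as
  another candidate at a joint frequency above `MAF / 2`, the signature of a
  real minority haplotype: `threshold -= MAF × cor`

starting from the user's minimum allele frequency (MAF). The call set is then
iterated: proximity, density and co-occurrence are recomputed over the
survivors while `cor` and `dp` escalate by the iteration-increase factor
`ii` per round, until the retained count stabilizes. Dense error clusters are
progressively priced out while linked true variants keep their reward.

The five values (cor, ii, pp, np, dp) come from bundled trained parameter
models (`clean`, `contaminated`, `combined` — the default) stored as per-MAF
knot tables and served by cubic spline interpolation for any MAF in
[0.01, 0.05]. A grid-search trainer can refit them on your own data.

The package also ships a multi-strain sample simulator with known truth
(mixture design, depth targets, and an ONT-flavoured error model with
deletions at twice the mismatch rate), an error profiler, and
precision/recall/F1 benchmarking — so the whole method is testable without
any external data.

## Worked example

```python
import strainvar as sv

# a synthetic 12-gene marker database and a 93/7 two-strain mixture at 220x
db = sv.make_synthetic_db(n_genes=12, gene_len=300, alleles_per_gene=3,
                          divergence=0.01, seed=101)
genes = db.gene_ids()
majority = sv.StrainSpec("majA", {g: "1" for g in genes})
minority = sv.StrainSpec("minB", {g: "2" for g in genes})
mix = sv.MixSpec([majority, minority], [0.93, 0.07], depth=220, seed=303)
sample = sv.simulate_sample(mix, db, sv.ErrorModel())

results = sv.MinorityVariantModel(sample.alignments, db, maf=0.05,
                                  model_name="clean").fit()
print(results.summary())
bench = results.score(sample.truth)
print(f"precision={bench.precision:.3f} recall={bench.recall:.3f} "
      f"f1={bench.f1:.3f}")
```

prints (abridged):

```
Minority variant calling summary
================================
genes with alignments : 12
alignments            : 3108
MAF                   : 0.05
parameters            : cor=0.459 ii=0.0497 pp=0.186 np=2.009 dp=0.144
initial candidates    : 41
final variants        : 36
iterations            : 2

      gene  position ref alt  count  depth  abundance  novel  proximal  density_M  cooccurring  threshold
BACT000001        49   T   A     15    224   0.066964  False     False          0         True   0.025909
BACT000001       218   A   C     15    249   0.060241  False     False          1         True   0.033467
...
precision=1.000 recall=1.000 f1=1.000
```

41 candidates cleared the entry gate; five error candidates were priced out
(novelty pushes their threshold to ~0.15 against abundances near 0.05) while
all 36 true strain variants — non-novel and co-occurring, so their thresholds
drop to ~0.026 — survive both iterations. Calling the same sample with all
five parameters at zero (plain 5% thresholding) keeps an error candidate
above 5% abundance and loses a borderline true variant, dropping F1 to
0.972.

The same pipeline is available from the shell on standard formats
(FASTA allele database, FASTQ reads, SAM alignments):

```bash
strainvar simulate --outdir sample --seed 100
strainvar call --sam sample/alignments.sam --db sample/alleles.fasta \
    --fastq sample/reads.fastq --outdir out --maf 0.05
strainvar benchmark --calls out/calls.tsv --truth sample/truth.tsv \
    --out bench.tsv
```

plus `strainvar profile` (zero-parameter error profiling of a sample) and
`strainvar train` (grid-search refitting of the parameter knot tables).

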