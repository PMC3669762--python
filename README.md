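# matbin

Composition-based community analysis of metagenome assemblies:
oligonucleotide-frequency binning of scaffolds by Monte-Carlo consensus
k-means with a co-clustering support network, G+C/taxon spectra, PCA/PCoA
ordination, Gower-based environmental vector fitting, alpha-diversity
estimation, and functional-category profiling — validated end-to-end on a
built-in synthetic community generator.

## Modules

| module | what it does |
| --- | --- |
| `matbin.seqio` | FASTA, annotation-table, report-table and network (SIF/GraphML) I/O; `ScaffoldRecord` |
| `matbin.composition` | 3–6-mer frequency vectors (per-k probability simplices), G+C content, taxon-stratified G+C spectra |
| `matbin.binning` | length filter (≥10 kb), consensus k-means (k=8, 100 trials by default), pairwise co-clustering support, connected-component bin demarcation (support ≥0.90, ≥10 scaffolds), per-bin summaries |
| `matbin.ordination` | PCA (SVD, deterministic signs) and PCoA (double centering, negative eigenvalues dropped and noted) |
| `matbin.ecostats` | Gower dissimilarity for mixed numeric/categorical site tables, envfit-style r²/permutation fitting, Chao1, ACE, Shannon, reciprocal Simpson, Fisher's alpha, analytic rarefaction |
| `matbin.funcprofile` | category × site abundance matrices, relative abundance, row standardization, PCA, two-way hierarchical clustering (Pearson/average or Euclidean/complete), Newick export |
| `matbin.synthetic_data` | seeded Markov genome models with calibrated G+C, planted-bin scaffold sets, OTU counts (log-series / lognormal), environmental tables with planted gradients, functional matrices with planted site groups |

## CLI

```sh
# simulate a 3-population community with truth labels
matbin simulate community --models 3 --gc 0.35,0.50,0.65 --n 300 --seed 11 --out-prefix sim

# composition matrix and G+C spectrum
matbin compose --fasta sim.fasta --kmin 3 --kmax 6 --out comp.tsv
matbin gcspec  --fasta sim.fasta --annot sim.truth.tsv --out spectrum.tsv

# consensus binning (membership, summary, SIF + GraphML support network)
matbin bin --fasta sim.fasta --k 8 --trials 100 --support 0.90 \
           --min-size 10 --min-len 10000 --seed 17 --out-prefix run1

# ordination, environment fitting, diversity, functional profiling
matbin ordinate --matrix comp.tsv --method pca --axes 3 --out ord.tsv
matbin envfit --env table1.tsv --perms 999 --seed 7 --out envfit.tsv
matbin diversity --counts otus.tsv --out div.tsv
matbin funcprofile --counts tigrfam.tsv --cluster euclidean:complete --out-prefix fp
```

Other generators: `matbin simulate otus|env|func`. Every generator writes a
truth table next to its data and is byte-reproducible from its seed.

## Notes

- k-means trials default to random-partition (MacQueen-style) initialization
  with empty clusters dropped; `k-means++` seeding and farthest-point
  reseeding are available via `ConsensusConfig(init=..., empty_policy=...)`.
- Two hierarchical-clustering recipes are supported on purpose
  (Pearson/average and Euclidean/complete); the CLI default is
  Euclidean/complete.
- Environment tables may contain below-detection entries (`<x`), parsed as
  x/2 with a provenance note.
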