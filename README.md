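# proxisig

Multi-tissue transcriptomic screening pipeline: per-tissue differential
expression, cross-study fold-change signature correlation, and a
network-based drug-target proximity statistic with permutation FDR and a
two-source consensus rule — runnable end to end on synthetic data with
planted, recoverable structure.

## Stages

| Module | What it does |
|---|---|
| `proxisig.synthetic` | Seeded generators for every pipeline input: NB count matrices with planted per-tissue DEGs, a scale-free directed network, two-source drug-target sets planted at controlled hop distance from DEGs, and reference signatures rank-blended to target Spearman correlations. |
| `proxisig.readsqc` | FASTQ filter: reject reads with >10% unknown bases or >50% bases at Phred ≤ 20 (strict inequalities, Phred+33/64). |
| `proxisig.expression` | FPKM normalization, per-tissue DEG calling with a negative-binomial exact test (median-of-ratios size factors, Pearson pseudo-likelihood common dispersion, moment tagwise dispersions shrunk toward it), DEG summaries (sharing histogram, signed-indicator cosine tissue modules), hierarchical clustering/PCA, and DEG-vs-rest centrality comparison. |
| `proxisig.signatures` | log2 fold-change signature construction for four platform designs, Spearman correlation on shared genes with Bonferroni correction, same-topic redundancy pruning, tissue-matched drug-signature correlation. |
| `proxisig.network` | dist(D,T) = mean over DEGs of the hop distance to the nearest drug target; permutation null from uniform redraws of equally sized target sets, add-one empirical p, BH FDR per (tissue, DEG-kind, source) stratum, and the consensus rule (retained iff ≥1 significant DEG kind in *both* target sources). |
| `proxisig.enrichment` | Hypergeometric gene-set over-representation, Fisher-exact drug class / side-effect / interaction enrichment, ortholog mapping. |
| `proxisig.pipeline` / `proxisig.cli` | YAML-configured orchestration with a run manifest (checksums, row counts, timings) and a CLI. |

## CLI

```bash
proxisig demo --outdir demo_run --seed 0           # full synthetic run (<5 min)
proxisig simulate --config sim.yaml --seed 1 --outdir inputs/
proxisig qc --in reads.fastq.gz --out passed.fastq.gz --n-frac 0.10 \
    --q-cutoff 20 --lowq-frac 0.50 --phred 33
proxisig normalize --counts counts.tsv --annotations ann.tsv \
    --gene-lengths lengths.tsv --out fpkm.tsv
proxisig deg --counts counts.tsv --annotations ann.tsv --tissue tissue01 \
    --alpha 0.05 --out deg_tissue01.tsv
proxisig summarize --deg-table tissue01 deg_tissue01.tsv \
    --deg-table tissue02 deg_tissue02.tsv --out summary.json
proxisig cluster --fpkm fpkm.tsv --outdir cluster/
proxisig signature build|correlate|prune ...
proxisig proximity --network net.tsv --degs tissue01 deg_tissue01.tsv \
    --targets targets.tsv --n-perm 1000 --seed 7 --outdir prox/
proxisig enrich genes|drugs|orthomap ...
proxisig run --config pipeline.yaml
```

All inputs and outputs are plain text (TSV/MTX/GMT/JSON/Newick/FASTQ).

## Notes

- Determinism: one integer seed drives independent per-component generators;
  identical (config, seed) gives byte-identical outputs.
- The DEG test is an edgeR-style NB exact test, not edgeR itself; exact
  count-level agreement with edgeR on real data is not a contract.
- The proximity statistic is lattice-valued, so the default (conservative)
  add-one empirical p is super-uniform under ties; `tie_break="random"`
  gives exactly uniform p-values on the permutation grid.
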