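# lpsmotif

Transcriptomic classification and consensus TF-binding-motif prediction
for LPS-tolerant macrophages.

Macrophages stimulated with bacterial lipopolysaccharide (LPS) for a
prolonged period become *tolerant*: re-stimulation fails to re-induce many
inflammatory genes ("pro-inflammatory" / tolerizable) while antibacterial
genes keep being expressed ("antibacterial" / non-tolerizable).  Given a
three-condition expression matrix — untreated (N), naive + 4 h LPS (N+L),
24 h LPS + 4 h re-stimulation (T+L), duplicate arrays — this package:

1. **classifies** each gene by its condition-average ratios
   (Y/X = (N+L)/N, Z/Y = (T+L)/(N+L)) and an unequal-variance Welch
   t-test: pro-inflammatory iff Y/X > 1, Z/Y < 1, p < 0.05; antibacterial
   iff Y/X > 1, Z/Y > 1, p < 0.05;
2. predicts discriminating TF-binding motifs with **three independent
   engines**: EM/ZOOPS de-novo discovery (two-component mixture, both
   strands, sequential extraction with Monte-Carlo E-values), a
   motif-expression linear model producing transcription contribution
   scores (TCS) from iterated random-subset least squares, and a
   binding-affinity engine that minimizes an iterated hypergeometric tail
   over rank cutoffs;
3. maps de-novo motifs onto a TRANSFAC-style PWM library by ungapped
   column correlation, retains each engine's **top 70%**, and intersects
   the three sets into a **consensus**, with a seeded random-gene
   companion run for a test-vs-random score contrast;
4. **validates** curated TF→target lists against the relaxed two-fold
   expression signature, with relative expression profiles, a
   four-condition cross-dataset tolerizability check, and random gene-set
   nulls.

A seeded synthetic-data generator (expression matrix, promoters with
planted PWM sites, an information-content-matched decoy library,
consistent curated-target files, and a ground-truth manifest) stands in
for the deposited microarray and promoter data, making every claim
testable.  See `docs/methods.md` for the model details and the study
conditions.

## Worked example

```python
from lpsmotif import PipelineParams, run_pipeline
from lpsmotif.simulate import SyntheticConfig, generate_bundle

bundle = generate_bundle(SyntheticConfig(n_genes=400, seed=1))
params = PipelineParams(seed=1)
result = run_pipeline(bundle.matrix, bundle.promoters, bundle.library,
                      bundle.targets, params=params)
print(result.manifest["counts"])
print(result.consensus_accessions, bundle.planted_accessions)
```

On the 400-gene bundle at seed 1 this prints (engine settings as in
`PipelineParams`):

```
{'pro_probes': 41, 'anti_probes': 10, 'pro_genes': 41, 'anti_genes': 10,
 'signature_genes': 38, 'retained': {'discovery': 1, 'tcs': 9, 'affinity': 7},
 'consensus': 1}
['PLT001'] ['PLT001']
```

41 genes classify as pro-inflammatory (40 were planted), the two-fold
signature holds 38 genes, and the single accession surviving all three
engines' top-70% sets is exactly the planted PWM, `PLT001`.  The
`examples/` directory has one short script per capability — phenotype
classification, de-novo discovery, TCS, affinity association, the full
pipeline with a random-background contrast, and target validation — each
printing its numbers with a line on what they mean.

A thin CLI mirrors the library:

```bash
lpsmotif simulate --seed 1 --out-dir bundle/
lpsmotif run --matrix bundle/expression.tsv --promoters bundle/promoters.fasta \
             --library bundle/library.transfac --targets bundle/targets.tsv \
             --random-background 40 --seed 1 --out-dir run/
```

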