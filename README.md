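# tftargets

Multiomic nomination of the genes a transcription factor directly regulates,
with downstream signature scoring and survival stratification.

## The problem

Occupancy assays (CUT&Tag, ChIP-seq) report where a factor binds; expression
assays report which genes change. Neither alone identifies *direct* targets:
binding is often non-functional and expression changes are often indirect.
`tftargets` implements the integration workflow used in regulatory genomics
to bridge that gap:

1. **Differential occupancy.** Peak fragment counts from two conditions are
   compared with a negative-binomial Wald test (median-of-ratios
   normalization, method-of-moments dispersion, Benjamini–Hochberg); peaks
   are classed *gained*, *lost* or *unchanged* at padj < 0.05. Peaks with
   RPKM < 10 are removed first and surviving peaks are union-merged into
   consensus intervals (book-ended intervals merge).
2. **Peak-to-gene annotation.** A peak links to a gene when its midpoint
   falls in the gene body or lies strictly closer than 10 kb to the
   strand-aware TSS.
3. **Binding–expression integration (BETA-style).** Each gene *g* gets a
   regulatory potential
   `RP(g) = Σᵢ exp(−(0.5 + 4·Δᵢ/w))` over binding sites with midpoint
   distance Δᵢ ≤ w (default w = 100 kb) from its TSS. Genes are ranked by
   RP and the RP-rank distributions of up-, down- and non-regulated genes
   (DEGs at padj < 0.01, |log2FC| > 1) are compared by two-sided two-sample
   Kolmogorov–Smirnov tests. A small `ks_up` p with a null `ks_down` p is
   the *activator* verdict.
4. **Evidence intersection.** Genes with gained factor binding, gained
   histone acetylation, gained accessibility **and** transcriptional
   up-regulation are nominated as direct targets (directional overlap
   percentages `100·|A∩B|/|B|` are reported for every pair).
5. **Signature scoring and survival.** A nominated-gene signature is scored
   per sample by rank-based ssGSEA (weighted in-set vs out-of-set ECDF
   difference, exponent 0.25), cohorts are split at the median score, and
   the groups compared by Mantel-Cox log-rank; tumor-vs-normal shifts use
   the two-sided Mann-Whitney U and score–score association the two-tailed
   Spearman test.

A first-class synthetic-data generator (`tftargets.simulate`) produces all
of these inputs with planted truth — NB peak counts with a known gained
fraction, expression fold-changes coupled to proximal gained binding, and
survival times coupled to a latent signature activity — so the whole
pipeline is testable without any external download.

## Worked example

```python
from tftargets import SimulationConfig, run_target_nomination

res = run_target_nomination(SimulationConfig(seed=1))
print("nominated genes:", len(res.nominated))
print("precision vs planted truth:", round(res.precision, 3))
print("recall vs planted truth:", round(res.recall, 3))
print("BETA ks_up:   D=%.3f p=%.2e" % res.beta.ks_up)
print("BETA ks_down: D=%.3f p=%.3f" % res.beta.ks_down)
print("activator verdict:", res.beta.activator_verdict)
```

prints

```
nominated genes: 55
precision vs planted truth: 1.0
recall vs planted truth: 0.917
BETA ks_up:   D=0.503 p=1.62e-22
BETA ks_down: D=0.095 p=0.890
activator verdict: True
```

The default simulation plants 60 direct-target genes (gained binding within
10 kb of the TSS in all three modalities plus a ~4-fold expression
increase). The run recovers 55 of them with no false positives; up-regulated
genes sit at far better regulatory-potential ranks than unaffected genes
(`ks_up`), down-regulated genes do not (`ks_down`) — the factor is called an
activator.

The same pipeline runs from the shell on files:

```sh
tftargets --config config.yaml all    # simulate → … → survive, with manifests
```

Each stage writes plain-text outputs (BED/TSV/GMT/JSON) plus a JSON run
manifest (inputs, outputs, config hash, seed, version) under the configured
output directory.

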