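# chromkd

Integration of chromatin and expression readouts of a transcription-factor
(TF) knockdown. Given peak calls, coverage tracks (ChIP, input, ATAC) in
control and knockdown conditions, differential-expression tables and gene
models, the package answers the questions a TF-knockdown multiomics study
asks:

- **Where does the epigenetic signal change?** Summit-centered signal
  matrices (log2(ChIP/Input) per condition, log2(KD/Control) between
  conditions) are clustered with deterministic k-means, and each cluster is
  characterized by its metaprofile and genomic feature distribution
  (promoter / exon / intron / downstream / distal intergenic).
- **Do the changes matter for expression?** DEG sets thresholded at
  |log2FC| ≥ log2(1.5) and adjusted p ≤ 0.05 are tested against peak-cluster
  gene sets with the one-sided hypergeometric (Fisher) enrichment test,
  p = P(X ≥ |A∩B|), X ~ Hypergeom(N, |A|, |B|), BH-corrected per family.
- **How does the TF work with HDACs?** Staged set-intersection classifiers
  for the two mechanism models: *repression* (TF keeps HDACs off chromatin:
  candidates = down-in-KD ∩ H3K27ac-loss, confirmed by HDAC-inhibitor
  rescue net of TF-independent responders) and *recruitment* (TF brings
  HDACs in: candidates = up-in-KD ∩ H3K27ac-gain, staged through TF binding
  and inhibitor non-response).
- **How does it share sites with a partner TF?** Motif scanning (log-odds
  PWM scores on both strands) around summits, center-vs-flanking positional
  preference via binomial tails against the uniform expectation, and
  cooperative / competitive / independent binding-mode classification from
  reciprocal-knockdown differential binding (exact conditional binomial
  test on region counts).

Everything runs end-to-end on a synthetic-data module that plants ground
truth (signal-change classes, mechanism genes, motif geometries, binding
modes), so the whole pipeline is validated by recovery, with no downloads.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study into
`results/run/`. After `python analysis/01_simulate.py` (90 peaks with 30
stable / 30 gain / 30 loss planted classes), clustering the knockdown
difference matrix:

```
$ python analysis/02_cluster_signal.py
cluster x planted-class cross-tab:
class    gain  loss  stable
cluster
1          30     0       0
2           0     2      30
3           0    28       0
adjusted Rand index vs planted classes: 0.934
```

Cluster 1 (highest mean log2(KD/Control)) is exactly the gained peaks;
the lost peaks separate into cluster 3 with two borderline escapes into
the stable cluster — an ARI of 0.93 against the planted truth. The
mechanism classifiers recover their planted genes exactly:

```
$ python analysis/05_mechanism_models.py
repression model stages: {'candidate': 30, 'confirmed': 30}
  confirmed == planted truth: True (30 genes)
recruitment model stages: {'candidate': 10, 'bound': 10, 'confirmed': 10}
  confirmed == planted truth: True (10 genes)
```

and the motif and binding-mode stages report, e.g., a forkhead-motif
z-score of +7.5 in the loss cluster (where it was planted) and 99.3%
binding-mode accuracy over 300 planted regions
(`analysis/06_motif_preference.py`, `analysis/07_binding_modes.py`).

The same pipeline is available as a CLI:

```sh
chromkd run --outdir out --seed 1       # simulate + all stages
chromkd simulate --outdir out --seed 1  # inputs only
chromkd validate --config config.yaml
```

Re-running with the same seed reproduces the output tree byte for byte
(`out/manifest.json` records the config hash and per-file checksums).

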