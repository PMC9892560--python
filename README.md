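# nichefx

Quantifying how much of the aged stem-cell transcriptome the niche
environment can restore.

Muscle stem cells (MuSCs) accumulate expression changes with age. When aged
MuSCs are transplanted into the muscle of a young host and re-isolated three
weeks later, some of those changes revert and some persist. `nichefx`
implements the statistical pipeline for this 2×2 heterochronic-transplant
design — donor age (young/aged) × time (pre-/post-transplant, T0/T21) — and
the downstream epigenomic integration, exercised end-to-end on a bundled
synthetic-data generator with known ground truth.

## The model

For each gene, counts are modelled with a negative-binomial GLM with log
link and median-of-ratios size-factor offsets:

```
count ~ time + age + time:age (+ batch)
```

The coefficients map onto three named effects (all log2):

- **age**: Δage = AgedT0 − YoungT0 — the cell-intrinsic aging signature;
- **engraftment**: Δeng = YoungT21 − YoungT0 — the transplantation
  procedure itself, measured in young-into-young controls;
- **niche**: Δniche = (AgedT21 − AgedT0) − (YoungT21 − YoungT0) — the
  interaction coefficient: what the young niche does to aged cells beyond
  engraftment.

Effects are moderated by empirical-Bayes shrinkage (zero-centred normal
prior, scale by marginal maximum likelihood) and ranked by **s-values**, the
estimated rate of false sign. A gene significant for age and for niche with
*opposing* signs is Age-Related Reversible (**ARR**); age-significant with
no niche response is Age-Related Irreversible (**ARI**). Two threshold
profiles are built in: strict (moderated |LFC| > 1, s < 0.05) and
permissive (|LFC| > 1, s < 0.15, plus a batch-LFC filter).

Around this core the package provides:

- **stability**: transcription vs mRNA-stability deconvolution from paired
  exonic/intronic counts (condition × read-type NB interaction);
- **methylation**: a windowed bisulfite DMR caller — fixed 100-bp tiles,
  ≥ 4 CpGs, beta regression per window, and hard filters |Δ| ≥ 40% with
  BH-adjusted p < 0.01;
- **regulatory**: ATAC summit merging (200 bp, ± 500 bp peaks),
  background-normalized (± 10 kb) differential accessibility (|LFC| > 1,
  padj < 0.05), basal-plus-extension regulatory domains (5 kb up / 1 kb
  down, ≤ 1 Mb extension) for peak–gene association, TSS-distance-binned
  peak counts, pileups, and CpG-island proximity;
- **integration**: cross-tabulation of ARR/ARI categories against DMR
  burden and direction-matched accessible peaks, with Fisher-exact
  enrichment and a machine-readable report;
- **synthetic_data**: generators for every input layer with planted truth,
  so every stage is testable against known effects.

## Worked example

```python
from nichefx import synthetic_data, reversibility

cfg = synthetic_data.SimConfig(n_genes=1000, seed=7)
counts, design, truth = synthetic_data.simulate_transplant_counts(cfg)

effects = reversibility.decompose_effects(counts, design)
labels, categories = reversibility.classify_effect_categories(
    effects, reversibility.STRICT
)
labels = reversibility.call_arr_ari(labels, effects, reversibility.STRICT)
summary = reversibility.reversibility_summary(labels)

print("category counts:", categories)
print("overall:", summary["overall"])
age_set = labels.index[labels["AGE"]]
r, slope, n = reversibility.effect_concordance(
    effects["age"]["lfc_moderated"],
    effects["niche"]["lfc_moderated"],
    subset=age_set,
)
print(f"niche-vs-age over {n} age-affected genes: r = {r:.2f}, slope = {slope:.2f}")
```

prints

```
category counts: {'AGE': 156, 'ENGRAFT': 63, 'NICHE': 59, 'AGE+ENGRAFT': 1,
'AGE+NICHE': 150, 'ENGRAFT+NICHE': 3, 'AGE+ENGRAFT+NICHE': 7, 'unchanged': 561}
overall: {'n_arr': 155, 'n_ari': 157, 'pct_reversible': 49.67948717948718}
niche-vs-age over 314 age-affected genes: r = -0.74, slope = -0.51
```

Half the simulated age-affected genes (which planted 20% reversible vs 15%
irreversible classes) are called reversible, and the niche effect
anti-correlates with the age effect over age-affected genes — the signature
of niche-driven restoration.

The same pipeline runs from the shell:

```sh
nichefx simulate --out bundle/ --seed 7
nichefx classify --counts bundle/counts.tsv --design bundle/design.tsv
nichefx call-dmrs --young bundle/meth_young_r1.tsv ... --aged bundle/meth_aged_r1.tsv ...
nichefx run --config configs/default.yaml --run-dir out/
```

`nichefx run` executes simulate → classify → stability → dmrs → atac →
integrate → report with checkpointed intermediates and writes
`out/report.json`.

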