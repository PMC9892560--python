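# Methods

## Count model

Each gene (or peak, or peak/background pair) is modelled as

    K_gj ~ NB(mu_gj = s_j * q_gj,  Var = mu + alpha_g * mu^2)
    log q_gj = x_j' beta_g

Size factors `s_j` are median-of-ratios over genes expressed in every
sample, rescaled to geometric mean 1, and enter as offsets; when no gene is
expressed everywhere the package falls back to total-count scaling with a
warning. Dispersions are estimated in a first pass — a pooled within-cell
method-of-moments estimate per gene, shrunk toward a fitted `a0 + a1/mu`
mean–dispersion trend by an equal-weight arithmetic blend, floored at 1e-8 —
and held fixed while the per-gene GLM is maximized (statsmodels IRLS, log
link, at most 100 iterations, tolerance 1e-8; non-converged genes keep their
last iterate, are flagged, and are excluded from shrinkage). Genes constant
within every design cell carry no overdispersion evidence and sit at the
floor; all-zero genes are undefined and excluded downstream. Coefficients
and standard errors are reported in log2; the natural-log internals are
converted only at the boundary.

## Moderation and s-values

Per contrast, a zero-centred normal prior `beta ~ N(0, tau^2)` is fitted by
marginal maximum likelihood across genes (`beta_hat_i ~ N(0, se_i^2 +
tau^2)`); with fewer than 50 genes the scale falls back to a fixed default
of 1 log2 with a warning. The moderated LFC is the conjugate posterior mean,
so `|moderated| <= |MLE|` always. The local false-sign rate (lfsr) is the
posterior probability the reported sign is wrong; the s-value of a gene is
the running mean of lfsr over all genes at least as confidently signed (ties
share a value). These follow the apeglm-style semantics qualitatively;
exact numerical agreement with apeglm/ashr is deliberately not a goal — the
prior family differs (normal here vs heavy-tailed there), which shrinks
large effects somewhat more.

## Effect decomposition and reversibility calling

The factorial fit `count ~ time + age + time:age (+ batch)` is only
attempted when all four age × time cells are populated. The interaction
coefficient *is* Δniche = (AgedT21 − AgedT0) − (YoungT21 − YoungT0); the
worked identity on noiseless group means (100, 200, 150, 600) gives exactly
1.0 log2. With more than one batch, treatment-coded batch dummies join the
design; the reported per-gene batch effect is the dummy of largest absolute
moderated LFC.

An effect is called at a profile iff `|moderated LFC| > lfc_min`
(strictly — a gene at exactly the floor is not called) and
`s-value < s_max`. ARR requires a significant niche effect *opposing* the
age effect; a concordant significant niche effect is reported as SAME_SIGN,
not ARR, since restoration toward the youthful state implies sign reversal.
The permissive profile's batch rule (default `|batch LFC| > 0.5`, direction
configurable to `< 0.5`) restricts the age-affected set before
reversibility is assigned. Reversibility calls are binary at threshold; no
partial-restoration scoring is attempted.

## Stability deconvolution

Intronic reads proxy transcription; exonic reads proxy transcription ×
stability. Stacking both layers and fitting `condition × read_type`
interactions per gene makes the intronic-level condition coefficients the
transcription effects and the interactions the stability effects. Size
factors are estimated separately per read type, absorbing the global
intron-capture difference between libraries — the package's documented
choice where the co-normalization of the two layers is otherwise
unspecified. Genes with mean intronic coverage below 5 reads/sample are
excluded (logged): below that, the exon/intron ratio is shot-noise-dominated
and its LFC estimate is unbounded. Driver calls use a dedicated profile
(lfc_min = 0.5 log2, s_max = 0.05): the LFC floor is half the smallest
planted effect, the package's a-priori choice for a "measurable" stability
shift.

## DMR calling

Fixed, non-overlapping 100-bp tiles aligned to coordinate 0 (deterministic;
no sliding phase) are candidate windows when they hold ≥ 4 distinct CpG
sites across all samples, both strands pooled per position. Per window,
per-replicate pooled proportions receive +0.5/+1.0 pseudo-counts (beta
regression is undefined at 0/1) and are regressed on condition
(statsmodels BetaModel); the two-sided Wald p of the condition coefficient
is the window p, and a Welch t-test on logit proportions is the logged
fallback when the beta fit fails. Replicates with zero window coverage are
dropped; fewer than 2 usable replicates per condition leaves the window
untested. After BH adjustment over all tested windows, a DMR requires
|Δ| ≥ 0.40 *and* padj < 0.01 — absolute filters asserted on every run.
Adjacent significant windows are not merged. cCRE annotation expands each
DMR by ± 300 bp and assigns PLS > ELS > other on ties.

## Accessibility and regulatory domains

Peak summits within 200 bp chain by single linkage; the merged summit is
the midpoint of the cluster's summit span and the peak is redefined as
summit ± 500 bp ("± 500 bp" is the default reading of a 500-bp range from
the summit; a total-width-500 variant is selectable). Differential
accessibility stacks peak and background (± 10 kb, peak intervals excluded
so a peak never contaminates its own background) counts with a
condition × region interaction: the interaction LFC is the peak change
beyond its background, significant at |LFC| > 1 and BH padj < 0.05. Peaks
with all-zero background fall back to size-factor-only normalization and
are flagged.

Regulatory domains are strand-aware basal intervals (5 kb upstream, 1 kb
downstream of the TSS) extended each way to at most 1 Mb, stopping at the
nearest neighbouring basal domain and chromosome bounds; association is any
≥ 1-bp overlap of a peak with the extended domain (many-to-many). Distance
profiles count significant (optionally direction-matched) peaks with
|summit − TSS| within 10 kb / 100 kb / 1 Mb. Pileups average
depth-normalized (counts-per-million) coverage in ± 2 kb around anchor
midpoints — CPM rather than quantile normalization is the package's choice.
CpG-island proximity flags a TSS with an island overlapping or within 5 kb.

## Integration

Genes collapse to five categories (ARR-up/down, ARI-up/down, unchanged).
DMR burden per gene counts DMRs overlapping the gene's extended regulatory
domain, averaged over *all* genes of a category (means may be < 1); the
DMR→gene link via regulatory domains is the package's choice where only the
cCRE annotation is otherwise defined, with an option to require cCRE
co-annotation. Peak overlap is direction-matched (up-genes vs
age-accessible peaks, down-genes vs age-inaccessible) with an optional
reproducibility filter (per-gene effect SD < 1). Enrichment uses two-sided
Fisher exact tests, BH-adjusted across the whole category × feature
battery at 0.05. The report is plain JSON with deterministic content (no
timestamps); absent stages are marked, not fatal.

## Synthetic data: what it emulates, and what not

The generator reproduces the *statistical structure* of the experiment,
not its biology. Per layer (each on its own RNG stream derived from the
master seed by a fixed offset, so layers are independently reproducible):

- **Transplant counts** — four-group factorial NB counts, 3
  replicates/group, 2 batches. Gene classes: NULL (50%), AGE_REVERSIBLE
  (20%, `beta_interaction = -beta_age` exactly), AGE_IRREVERSIBLE (15%),
  ENGRAFT_ONLY (10%), NICHE_ONLY (5%). |age effects| ~ U[1, 3] log2 with
  Bernoulli(1/2) signs; baseline log2 expression ~ N(5, 2); dispersion
  trend `alpha = 0.05 + 5/mu`; batch effects additive N(0, 0.3) log2;
  library factors U[0.7, 1.4]. All are configuration-exposed.
- **Exon/intron counts** — two-group (young/aged) layers sharing a
  per-sample, per-gene biological factor (log2 sd 0.3) that cancels in the
  exon/intron ratio, exactly as paired measurements from one library do;
  residual NB dispersion is technical (0.01) on top of shot noise. The
  baseline (log2 ~ N(8, 1.5), intron capture 0.2) emulates the
  post-filtering gene set that stability deconvolution actually runs on —
  genes with adequate intronic coverage — not the whole transcriptome.
- **Methylome** — CpG positions from a clustered point process (~1 cluster
  / 1.5 kb, ~8 CpGs each, ~12 bp spacing), per-CpG binomial counts at
  Poisson(10) coverage, 3 replicates/condition; planted DMR windows shift
  the aged proportion by ± 0.5 inside windows guaranteed ≥ 4 CpGs, balanced
  gain/loss. A planted Δ below the caller's 40% filter warns that truth is
  undiscoverable by design.
- **Peak landscape** — genes spaced 50–120 kb apart on one chromosome,
  Poisson(3)+1 peaks/gene at log-normal TSS distances, NB peak counts
  (dispersion 0.05) with a planted fraction (20%) at |LFC| 1.5, and
  condition-stable background counts. An enrichment knob plants extra
  age-accessible peaks near ARI-up-labelled genes to reproduce the
  irreversible-up pattern on demand; coverage tracks can couple depressed
  aged accessibility to methylation-gain windows.

Not emulated: read-level data, UMI/droplet structure, genomic sequence,
trans effects, correlated gene modules, or any engraftment biology beyond
mean shifts. Passing recovery tests therefore demonstrates statistical
correctness of the estimators and callers on data matching the model's
assumptions — not robustness to real-data pathologies (outlier samples,
composition bias, mappability artefacts).

## Problem sizes and numerical choices

Default analysis conditions are 2000 genes × 12 samples; the bundled
end-to-end configuration (`configs/default.yaml`) runs 600 genes, a 150-kb
methylome and a 50-gene peak landscape, completing in well under a minute
on one CPU — sizes chosen so the full pipeline and its determinism check
remain quick to iterate. Tolerances: GLM convergence `max |dbeta| < 1e-8`;
saturated-model identities asserted at 1e-4–1e-6; BH and interval oracles
exact. Tie-breaks: summit midpoints round down; equal lfsr values share an
s-value; cCRE ties resolve PLS > ELS > other. Degenerate inputs (all-zero
genes, zero-coverage replicates, all-zero backgrounds, empty DMR sets) are
excluded or flagged, never silently imputed.

## Known limitations

- With 3 replicates/group and the default noise level (`alpha = 0.05 +
  5/mu`, baseline log2 ~ N(5, 2)), the moderated Δniche has a median
  standard error near 0.8 log2. Planted effects starting at exactly 1 log2
  are therefore only partially recoverable at the strict call (measured
  ARR recovery ≈ 60–65%, ARI ≈ 70–75%): genes near the LFC floor fall
  under it by sampling noise, and no estimator at this information level
  can avoid that. The recovery figures reported by `scripts/acceptance.py`
  quantify this honestly rather than presenting an idealized rate; the
  anti-correlation, null-control, confusion-rate and formula-identity
  properties are unaffected. The analogous exact-threshold effect caps
  recovery of exactly-2-fold stability changes near 82–86%.
- The s-value gate is an FDR-style (rate) guarantee: in mixtures with many
  strong effects, individual null genes can pass it; the LFC floor is the
  operative per-gene filter.
- Beta regression on 3+3 replicate proportions relies on asymptotic Wald
  p-values; the hard 40% delta filter, not the p-value, provides most of
  the DMR specificity at low coverage.
- The permissive profile's batch-LFC filter direction is configurable
  because both readings (above/below 0.5) appear plausible; the default
  keeps `|batch LFC| > 0.5`.
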