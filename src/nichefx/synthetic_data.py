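"""Generators for every input layer the pipeline consumes, with ground truth.

The generators emulate the statistical structure of a 2x2 heterochronic
transplant experiment: bulk RNA-seq counts from a factorial
(age in {young, aged}) x (time in {T0, T21}) design with batches, paired
exonic/intronic count layers, clustered-CpG bisulfite methylomes with
planted differentially methylated windows, and a TSS-anchored ATAC peak
landscape with planted accessibility shifts.

Gene classes and their planted coefficients (log2):

==================  ======================================================
NULL                all effect betas 0
AGE_REVERSIBLE      beta_age != 0, beta_interaction = -beta_age (exactly)
AGE_IRREVERSIBLE    beta_age != 0, beta_interaction = 0
ENGRAFT_ONLY        beta_time != 0 only
NICHE_ONLY          beta_interaction != 0 only
==================  ======================================================

Every layer draws from its own RNG stream, derived from the master seed by a
fixed offset, so layers are independently reproducible.  Identical configs
(including the seed) give byte-identical outputs after serialization.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats_io

logger = logging.getLogger("nichefx.synthetic_data")

GENE_CLASSES = ("NULL", "AGE_REVERSIBLE", "AGE_IRREVERSIBLE", "ENGRAFT_ONLY", "NICHE_ONLY")
STABILITY_CLASSES = ("NULL", "TRANSCRIPTION", "STABILITY", "BOTH")

# fixed per-layer RNG stream offsets (spawn keys off the master seed)
_STREAM_COUNTS = 1
_STREAM_EXON_INTRON = 2
_STREAM_METHYLOME = 3
_STREAM_ATAC = 4
_STREAM_COVERAGE = 5


class ConfigurationError(ValueError):
    """The simulation configuration violates an invariant."""


@dataclass
class SimConfig:
    """Study conditions for all synthetic layers.

    Defaults mirror the transplant design (four age x time cells, 3
    replicates each, 2 batches) with planted log2 age effects in [1, 3],
    additive N(0, 0.3) log2 batch effects and an RNA-seq-like 1/mu
    mean-dispersion trend.  The class mix leaves half the genes null and
    splits the rest across reversible/irreversible/engraftment/niche-only.
    """

    n_genes: int = 2000
    replicates_per_group: int = 3
    n_batches: int = 2
    class_proportions: dict = field(
        default_factory=lambda: {
            "NULL": 0.50,
            "AGE_REVERSIBLE": 0.20,
            "AGE_IRREVERSIBLE": 0.15,
            "ENGRAFT_ONLY": 0.10,
            "NICHE_ONLY": 0.05,
        }
    )
    effect_size_range: tuple = (1.0, 3.0)   # |beta_age| in log2
    batch_sd: float = 0.3                   # log2
    dispersion_a0: float = 0.05             # alpha = a0 + a1/mu
    dispersion_a1: float = 5.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    library_size_range: tuple = (0.7, 1.4)
    seed: int = 0
    # exon/intron layer
    stability_class_proportions: dict = field(
        default_factory=lambda: {"NULL": 0.6, "TRANSCRIPTION": 0.2, "STABILITY": 0.2}
    )
    # the exon/intron layer emulates the post-filtering gene set stability
    # deconvolution actually runs on (adequate intronic coverage), hence the
    # higher baseline than the transplant layer
    ei_baseline_log2_mean: float = 8.0
    ei_baseline_log2_sd: float = 1.5
    intron_capture_rate: float = 0.2
    # per-sample gene-level biological factor shared by the exonic and
    # intronic reads of one library (it cancels in the exon/intron ratio);
    # residual NB dispersion is technical only
    ei_bio_log2_sd: float = 0.3
    ei_tech_dispersion: float = 0.01
    # methylome layer
    chrom: str = "chr1"
    chrom_length: int = 300_000
    cpg_cluster_rate: float = 1 / 1500.0    # cluster centres per bp
    cpg_per_cluster: float = 8.0            # Poisson mean (min 4)
    meth_coverage_mean: float = 10.0
    n_dmrs: int = 60
    dmr_delta: float = 0.5
    meth_replicates: int = 3
    # ATAC layer
    n_atac_genes: int = 80
    peaks_per_gene_mean: float = 3.0
    atac_fraction_differential: float = 0.2
    atac_lfc: float = 1.5
    atac_base_log2_mean: float = 7.0
    atac_dispersion: float = 0.05
    ari_up_enrichment: float = 1.0          # >1 plants extra up-peaks near up-ARI genes

    def validate(self) -> "SimConfig":
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class proportions must sum to 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown gene class(es): {sorted(unknown)}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ConfigurationError("class proportions must be non-negative")
        if self.replicates_per_group < 2:
            raise ConfigurationError(
                "replicates_per_group < 2: factorial decomposition unidentifiable"
            )
        for name in ("n_genes", "n_batches", "meth_replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if abs(sum(self.stability_class_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("stability class proportions must sum to 1")
        return self

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), int(stream))))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw: NB with Var = mu + alpha mu^2."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape=shape, scale=mean / shape)
    return rng.poisson(lam).astype(np.int64)


def _assign_classes(rng, n: int, proportions: dict, classes: tuple) -> np.ndarray:
    """Deterministic rounded class counts, shuffled; largest class absorbs remainder."""
    counts = {c: int(round(proportions.get(c, 0.0) * n)) for c in classes}
    drift = n - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    labels = np.repeat(
        np.array(list(counts.keys()), dtype=object), list(counts.values())
    )
    rng.shuffle(labels)
    return labels


# ---------------------------------------------------------------------------
# transplant counts
# ---------------------------------------------------------------------------

def simulate_transplant_counts(cfg: SimConfig):
    """Four-group factorial NB counts with planted gene classes.

    Returns ``(counts, design, truth)``: a genes x samples integer frame, a
    sample-design frame (sample_id, age, time, batch) and the per-gene truth
    table (class_label, beta_age, beta_time, beta_interaction, beta_batch,
    baseline_log2).
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_COUNTS)
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(cfg.n_genes)], name="gene_id")

    labels = _assign_classes(rng, cfg.n_genes, cfg.class_proportions, GENE_CLASSES)
    lo, hi = cfg.effect_size_range
    mags = rng.uniform(lo, hi, size=cfg.n_genes)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    effect = mags * signs

    beta_age = np.where(np.isin(labels, ["AGE_REVERSIBLE", "AGE_IRREVERSIBLE"]), effect, 0.0)
    beta_time = np.where(labels == "ENGRAFT_ONLY", effect, 0.0)
    beta_int = np.where(labels == "AGE_REVERSIBLE", -beta_age, 0.0)
    beta_int = np.where(labels == "NICHE_ONLY", effect, beta_int)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=cfg.n_genes)
    batch_eff = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, cfg.n_batches))
    batch_eff[:, 0] = 0.0  # batch 0 is the reference level

    rows = []
    for age in formats_io.AGE_LEVELS:
        for time in formats_io.TIME_LEVELS:
            for rep in range(cfg.replicates_per_group):
                rows.append(
                    {
                        "sample_id": f"{age}_{time}_r{rep + 1}",
                        "age": age,
                        "time": time,
                        "batch": f"b{rep % cfg.n_batches + 1}",
                    }
                )
    design = pd.DataFrame(rows)
    lib = rng.uniform(*cfg.library_size_range, size=len(design))

    counts = np.empty((cfg.n_genes, len(design)), dtype=np.int64)
    for j, row in design.iterrows():
        is_aged = float(row["age"] == "aged")
        is_t21 = float(row["time"] == "T21")
        b = int(row["batch"][1:]) - 1
        log2mu = (
            baseline
            + beta_age * is_aged
            + beta_time * is_t21
            + beta_int * is_aged * is_t21
            + batch_eff[:, b]
        )
        mu = lib[j] * np.exp2(log2mu)
        alpha = cfg.dispersion_a0 + cfg.dispersion_a1 / np.maximum(mu, 1e-8)
        counts[:, j] = _nb_draw(rng, mu, alpha)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design["sample_id"])
    truth = pd.DataFrame(
        {
            "class_label": labels,
            "beta_age": beta_age,
            "beta_time": beta_time,
            "beta_interaction": beta_int,
            "beta_batch": batch_eff[:, min(1, cfg.n_batches - 1)],
            "baseline_log2": baseline,
        },
        index=gene_ids,
    )
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# exon / intron counts
# ---------------------------------------------------------------------------

def simulate_exon_intron_counts(cfg: SimConfig):
    """Paired exonic/intronic NB counts for a young/aged two-group design.

    Intronic means track the transcription rate; exonic means track
    transcription x mRNA stability, so STABILITY genes alter exonic counts
    only.  Returns ``(exonic, intronic, design, truth)`` with truth columns
    transcription_lfc and stability_lfc (aged vs young, log2).
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_EXON_INTRON)
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(cfg.n_genes)], name="gene_id")
    labels = _assign_classes(
        rng, cfg.n_genes, cfg.stability_class_proportions, STABILITY_CLASSES
    )
    lo, hi = cfg.effect_size_range
    t_eff = rng.uniform(lo, hi, cfg.n_genes) * rng.choice([-1.0, 1.0], cfg.n_genes)
    s_eff = rng.uniform(lo, hi, cfg.n_genes) * rng.choice([-1.0, 1.0], cfg.n_genes)
    transcription = np.where(np.isin(labels, ["TRANSCRIPTION", "BOTH"]), t_eff, 0.0)
    stability = np.where(np.isin(labels, ["STABILITY", "BOTH"]), s_eff, 0.0)

    baseline = rng.normal(cfg.ei_baseline_log2_mean, cfg.ei_baseline_log2_sd, cfg.n_genes)
    rows = [
        {"sample_id": f"{age}_r{rep + 1}", "age": age, "time": "T0", "batch": "b1"}
        for age in formats_io.AGE_LEVELS
        for rep in range(cfg.replicates_per_group)
    ]
    design = pd.DataFrame(rows)
    lib = rng.uniform(*cfg.library_size_range, size=len(design))

    exonic = np.empty((cfg.n_genes, len(design)), dtype=np.int64)
    intronic = np.empty_like(exonic)
    for j, row in design.iterrows():
        is_aged = float(row["age"] == "aged")
        bio = rng.normal(0.0, cfg.ei_bio_log2_sd, size=cfg.n_genes)
        mu_t = np.exp2(baseline + transcription * is_aged + bio)
        mu_e = lib[j] * mu_t * np.exp2(stability * is_aged)
        mu_i = lib[j] * cfg.intron_capture_rate * mu_t
        exonic[:, j] = _nb_draw(rng, mu_e, cfg.ei_tech_dispersion)
        intronic[:, j] = _nb_draw(rng, mu_i, cfg.ei_tech_dispersion)

    cols = design["sample_id"]
    truth = pd.DataFrame(
        {
            "class_label": labels,
            "transcription_lfc": transcription,
            "stability_lfc": stability,
            "baseline_log2": baseline,
        },
        index=gene_ids,
    )
    return (
        pd.DataFrame(exonic, index=gene_ids, columns=cols),
        pd.DataFrame(intronic, index=gene_ids, columns=cols),
        design,
        truth,
    )


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def simulate_methylome(cfg: SimConfig):
    """Clustered-CpG methylomes with planted 100-bp DMR windows.

    CpG positions follow a clustered point process (Poisson cluster centres,
    geometric within-cluster spacing).  Per-CpG methylated counts are
    binomial around a window-level proportion; planted windows shift the
    aged proportion by +/- ``dmr_delta`` and are guaranteed >= 4 CpGs.

    Returns ``(tracks, truth)`` where tracks is a dict
    ``{(condition, replicate): DataFrame}`` in the internal methylation
    layout and truth is a per-planted-window frame (chrom, start, end,
    is_dmr, delta, direction).
    """
    cfg.validate()
    if cfg.dmr_delta < 0.40:
        logger.warning(
            "planted DMR delta %.2f is below the caller's 40%% filter; "
            "truth will not be discoverable by design",
            cfg.dmr_delta,
        )
    rng = cfg.rng(_STREAM_METHYLOME)
    n_windows = cfg.chrom_length // 100

    # clustered CpG point process
    n_clusters = rng.poisson(cfg.cpg_cluster_rate * cfg.chrom_length)
    centres = np.sort(rng.integers(0, cfg.chrom_length, size=n_clusters))
    positions: list[int] = []
    for c in centres:
        k = max(4, rng.poisson(cfg.cpg_per_cluster))
        offsets = np.cumsum(rng.geometric(1 / 12.0, size=k))  # ~12 bp spacing
        positions.extend((c + offsets - offsets[0]).tolist())
    positions = np.unique(np.array(positions, dtype=np.int64))
    positions = positions[(positions >= 0) & (positions < cfg.chrom_length)]

    win_of = positions // 100
    cpg_per_window = np.bincount(win_of, minlength=n_windows)

    # plant DMRs in windows that satisfy the caller's >= 4 CpG rule
    eligible = np.flatnonzero(cpg_per_window >= 4)
    n_dmrs = min(cfg.n_dmrs, eligible.size)
    if n_dmrs < cfg.n_dmrs:
        logger.warning("only %d eligible windows for %d requested DMRs", eligible.size, cfg.n_dmrs)
    dmr_windows = rng.choice(eligible, size=n_dmrs, replace=False)
    gain = rng.random(n_dmrs) < 0.5

    # window-level baseline proportions (young)
    base_p = rng.beta(2.0, 2.0, size=n_windows)
    young_p = base_p.copy()
    aged_p = base_p.copy()
    for w, g in zip(dmr_windows, gain):
        if g:
            young_p[w] = rng.uniform(0.05, 0.95 - cfg.dmr_delta)
            aged_p[w] = young_p[w] + cfg.dmr_delta
        else:
            young_p[w] = rng.uniform(0.05 + cfg.dmr_delta, 0.95)
            aged_p[w] = young_p[w] - cfg.dmr_delta

    tracks: dict[tuple[str, int], pd.DataFrame] = {}
    for cond, p_window in (("young", young_p), ("aged", aged_p)):
        for rep in range(1, cfg.meth_replicates + 1):
            total = rng.poisson(cfg.meth_coverage_mean, size=positions.size)
            p_site = np.clip(
                p_window[win_of] + rng.normal(0.0, 0.02, size=positions.size), 0.0, 1.0
            )
            meth = rng.binomial(total, p_site)
            frame = pd.DataFrame(
                {
                    "chrom": cfg.chrom,
                    "pos0": positions,
                    "strand": "+",
                    "context": "CpG",
                    "count_methylated": meth,
                    "count_total": total,
                }
            )
            # uncovered CpGs yield no methylation calls on disk
            tracks[(cond, rep)] = frame[frame["count_total"] > 0].reset_index(drop=True)

    order = np.argsort(dmr_windows, kind="stable")
    truth = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": dmr_windows[order] * 100,
            "end": dmr_windows[order] * 100 + 100,
            "is_dmr": True,
            "delta": np.where(gain[order], cfg.dmr_delta, -cfg.dmr_delta),
            "direction": np.where(gain[order], "gain", "loss"),
        }
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# ATAC landscape
# ---------------------------------------------------------------------------

ATAC_GENE_CATEGORIES = ("ARR-up", "ARR-down", "ARI-up", "ARI-down", "unchanged")


def simulate_atac_landscape(cfg: SimConfig):
    """TSS-anchored peak landscape with planted accessibility shifts.

    Genes are placed along one chromosome with random strands; each gene gets
    a Poisson number of peaks at log-normally distributed distances from its
    TSS.  A configured fraction of peaks is differential (planted |LFC| =
    ``atac_lfc``); background (+/- 10 kb) counts are condition-stable.  With
    ``ari_up_enrichment`` > 1, extra age-accessible peaks are planted near
    genes carrying the ARI-up category label, reproducing on demand the
    pattern of irreversible up-genes acquiring accessible chromatin.

    Returns ``(peaks, peak_counts, bg_counts, genes, design, truth)``.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_ATAC)

    # gene models along one chromosome
    gaps = rng.integers(50_000, 120_000, size=cfg.n_atac_genes)
    tss = 1_000_000 + np.cumsum(gaps)
    strands = rng.choice(["+", "-"], size=cfg.n_atac_genes)
    categories = rng.choice(ATAC_GENE_CATEGORIES, size=cfg.n_atac_genes,
                            p=[0.15, 0.15, 0.15, 0.15, 0.40])
    genes = pd.DataFrame(
        {
            "gene_id": [f"agene{i:04d}" for i in range(cfg.n_atac_genes)],
            "chrom": cfg.chrom,
            "tss": tss,
            "strand": strands,
            "category": categories,
        }
    )

    summits: list[int] = []
    owner: list[int] = []
    for i in range(cfg.n_atac_genes):
        n_peaks = rng.poisson(cfg.peaks_per_gene_mean) + 1
        if cfg.ari_up_enrichment > 1.0 and categories[i] == "ARI-up":
            n_peaks += rng.poisson((cfg.ari_up_enrichment - 1.0) * cfg.peaks_per_gene_mean)
        dist = rng.lognormal(mean=9.0, sigma=1.6, size=n_peaks)  # median ~8 kb
        dist = np.clip(dist, 200, 900_000).astype(np.int64)
        side = rng.choice([-1, 1], size=n_peaks)
        for d, s in zip(dist, side):
            pos = int(tss[i] + s * d)
            attempts = 0
            while any(abs(pos - q) < 1200 for q in summits[-50:]) and attempts < 10:
                pos += 1500  # resolve collisions by re-sampling rightward
                attempts += 1
                if attempts == 10:
                    logger.info("peak collision unresolved near %d", pos)
            summits.append(pos)
            owner.append(i)
    summits = np.array(summits)
    owner = np.array(owner)
    n_peaks = summits.size

    # planted differential status
    lfc = np.zeros(n_peaks)
    n_diff = int(round(cfg.atac_fraction_differential * n_peaks))
    diff_idx = rng.choice(n_peaks, size=n_diff, replace=False)
    lfc[diff_idx] = cfg.atac_lfc * rng.choice([-1.0, 1.0], size=n_diff)
    # direction-matched peaks near labelled genes (the planted pattern of
    # up-genes with accessible / down-genes with closed chromatin); inactive
    # when no differential fraction is requested
    if cfg.atac_fraction_differential > 0:
        for i in range(cfg.n_atac_genes):
            mine = np.flatnonzero(owner == i)
            if mine.size == 0:
                continue
            cat = categories[i]
            if cat in ("ARR-up", "ARI-up"):
                lfc[mine[0]] = cfg.atac_lfc
            elif cat in ("ARR-down", "ARI-down"):
                lfc[mine[0]] = -cfg.atac_lfc
            if cat == "ARI-up" and cfg.ari_up_enrichment > 1.0:
                lfc[mine] = np.where(lfc[mine] == 0, cfg.atac_lfc, lfc[mine])

    peaks = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": np.maximum(summits - 500, 0),
            "end": summits + 500,
            "name": [f"peak{i:05d}" for i in range(n_peaks)],
            "score": 0,
            "strand": ".",
            "summit": summits,
        }
    )

    rows = [
        {"sample_id": f"{age}_r{rep + 1}", "age": age, "time": "T0", "batch": "b1"}
        for age in formats_io.AGE_LEVELS
        for rep in range(cfg.replicates_per_group)
    ]
    design = pd.DataFrame(rows)
    lib = rng.uniform(*cfg.library_size_range, size=len(design))

    base = np.exp2(rng.normal(cfg.atac_base_log2_mean, 1.0, size=n_peaks))
    bg_base = base * rng.uniform(2.0, 4.0, size=n_peaks)  # 20 kb of background
    pk = np.empty((n_peaks, len(design)), dtype=np.int64)
    bg = np.empty_like(pk)
    for j, row in design.iterrows():
        is_aged = float(row["age"] == "aged")
        mu_p = lib[j] * base * np.exp2(lfc * is_aged)
        mu_b = lib[j] * bg_base
        pk[:, j] = _nb_draw(rng, mu_p, cfg.atac_dispersion)
        bg[:, j] = _nb_draw(rng, mu_b, cfg.atac_dispersion)

    idx = pd.Index(peaks["name"], name="peak_id")
    cols = design["sample_id"]
    peak_counts = pd.DataFrame(pk, index=idx, columns=cols)
    bg_counts = pd.DataFrame(bg, index=idx, columns=cols)
    truth = pd.DataFrame(
        {
            "peak_id": peaks["name"],
            "gene_id": genes["gene_id"].to_numpy()[owner],
            "true_lfc": lfc,
            "summit": summits,
        }
    ).set_index("peak_id")
    return peaks, peak_counts, bg_counts, genes, design, truth


# ---------------------------------------------------------------------------
# coverage tracks coupled to DMR direction
# ---------------------------------------------------------------------------

def simulate_dmr_coverage(
    cfg: SimConfig,
    dmr_truth: pd.DataFrame,
    depression: float = 0.5,
    base_level: float = 10.0,
):
    """Per-condition accessibility coverage coupled to methylation direction.

    Aged coverage over methylation-gain windows is multiplied by
    ``depression`` (< 1: gains of methylation depress accessibility) and
    over loss windows by 1/``depression``; young coverage is flat.  Returns
    ``{condition: bedGraph DataFrame}``.
    """
    rng = cfg.rng(_STREAM_COVERAGE)
    step = 50
    starts = np.arange(0, cfg.chrom_length, step)
    young = base_level * rng.uniform(0.8, 1.2, size=starts.size)
    aged = base_level * rng.uniform(0.8, 1.2, size=starts.size)
    for _, row in dmr_truth.iterrows():
        sel = (starts + step > row["start"] - 500) & (starts < row["end"] + 500)
        factor = depression if row["direction"] == "gain" else 1.0 / depression
        aged[sel] *= factor
    out = {}
    for cond, vec in (("young", young), ("aged", aged)):
        out[cond] = pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "start": starts,
                "end": np.minimum(starts + step, cfg.chrom_length),
                "value": vec,
            }
        )
    return out


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(cfg: SimConfig, outdir) -> pd.DataFrame:
    """Run all simulators and write every layer plus a checksum manifest.

    Files use the standard on-disk formats of :mod:`nichefx.formats_io` and
    round-trip losslessly.  Returns the manifest (file, sha256).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, design, truth = simulate_transplant_counts(cfg)
    formats_io.write_counts(counts, outdir / "counts.tsv")
    formats_io.write_design(design, outdir / "design.tsv")
    truth.to_csv(outdir / "truth_genes.tsv", sep="\t")

    exonic, intronic, ei_design, ei_truth = simulate_exon_intron_counts(cfg)
    formats_io.write_counts(exonic, outdir / "exonic_counts.tsv")
    formats_io.write_counts(intronic, outdir / "intronic_counts.tsv")
    formats_io.write_design(ei_design, outdir / "ei_design.tsv")
    ei_truth.to_csv(outdir / "truth_stability.tsv", sep="\t")

    tracks, meth_truth = simulate_methylome(cfg)
    for (cond, rep), track in sorted(tracks.items()):
        formats_io.write_methylation(track, outdir / f"meth_{cond}_r{rep}.tsv")
    meth_truth.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)

    peaks, pk, bg, genes, atac_design, atac_truth = simulate_atac_landscape(cfg)
    formats_io.write_bed(peaks, outdir / "peaks.bed")
    formats_io.write_counts(pk, outdir / "peak_counts.tsv")
    formats_io.write_counts(bg, outdir / "background_counts.tsv")
    gene_bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["tss"],
            "end": genes["tss"] + 1,
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    formats_io.write_bed(gene_bed, outdir / "genes_tss.bed")
    formats_io.write_design(atac_design, outdir / "atac_design.tsv")
    atac_truth.to_csv(outdir / "truth_atac.tsv", sep="\t")

    cov = simulate_dmr_coverage(cfg, meth_truth)
    for cond, frame in sorted(cov.items()):
        formats_io.write_bedgraph(frame, outdir / f"coverage_{cond}.bedgraph")

    files = sorted(p for p in outdir.iterdir() if p.name != "manifest.tsv")
    manifest = pd.DataFrame(
        {
            "file": [p.name for p in files],
            "sha256": [hashlib.sha256(p.read_bytes()).hexdigest() for p in files],
        }
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
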