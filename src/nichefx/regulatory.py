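"""Peak processing, background-normalized differential accessibility, and
peak-gene association via basal-plus-extension regulatory domains.

Differential accessibility is the condition-by-region interaction of an NB
GLM on stacked peak and background (+/- 10 kb, excluding peak intervals)
counts: the peak's change beyond the change of its local background, so
copy-number or depth artefacts shared with the neighbourhood cancel.  A peak
is significant at |LFC| > 1 and BH padj < 0.05.

Gene regulatory domains follow the basal-plus-extension construction: a
strand-aware basal domain of 5 kb upstream / 1 kb downstream of the TSS,
extended on each side up to 1 Mb but never into a neighbouring gene's basal
domain; a peak associates with every gene whose extended domain it overlaps
by at least one base.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import countmodel

logger = logging.getLogger("nichefx.regulatory")

SUMMIT_MERGE_DIST = 200
PEAK_HALF_WIDTH = 500
BASAL_UPSTREAM = 5000
BASAL_DOWNSTREAM = 1000
MAX_EXTENSION = 1_000_000
DA_LFC_MIN = 1.0
DA_PADJ_MAX = 0.05
DISTANCE_WINDOWS = (10_000, 100_000, 1_000_000)


# ---------------------------------------------------------------------------
# peak merging
# ---------------------------------------------------------------------------

def merge_peaks(
    peaks: pd.DataFrame,
    merge_dist: int = SUMMIT_MERGE_DIST,
    half_width: int = PEAK_HALF_WIDTH,
) -> pd.DataFrame:
    """Single-linkage merge of summits within ``merge_dist``; fixed-width peaks.

    Summits closer than ``merge_dist`` chain transitively into one cluster
    per chromosome; the merged summit is the midpoint of the cluster's summit
    span and the peak is redefined as summit +/- ``half_width`` (clipped at 0).
    Idempotent: merging the output changes nothing.
    """
    out = []
    for chrom, sub in peaks.groupby("chrom", sort=True):
        s = np.sort(sub["summit"].to_numpy())
        if s.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(s) > merge_dist)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, s.size - 1]
        for a, b in zip(starts, ends):
            summit = int((s[a] + s[b]) // 2)
            out.append(
                {
                    "chrom": chrom,
                    "start": max(summit - half_width, 0),
                    "end": summit + half_width,
                    "summit": summit,
                }
            )
    merged = pd.DataFrame(out, columns=["chrom", "start", "end", "summit"])
    merged["name"] = [f"peak{i:05d}" for i in range(len(merged))]
    return merged[["chrom", "start", "end", "name", "summit"]]


# ---------------------------------------------------------------------------
# differential accessibility
# ---------------------------------------------------------------------------

def differential_accessibility(
    peak_counts: pd.DataFrame,
    background_counts: pd.DataFrame,
    design: pd.DataFrame,
    lfc_min: float = DA_LFC_MIN,
    padj_max: float = DA_PADJ_MAX,
) -> pd.DataFrame:
    """Background-normalized per-peak differential accessibility (aged vs young).

    Fits the stacked background/peak NB GLM with a condition x region-type
    interaction; the interaction LFC is the accessibility change beyond the
    background change.  Peaks whose background is all zero fall back to
    peak-only size-factor normalization and are flagged.

    Output columns: lfc (MLE, log2), lfc_moderated, se, svalue, pvalue, padj,
    significant, background_fallback.
    """
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(design)),
            "age": (design["age"] == "aged").astype(float).to_numpy(),
        },
        index=design["sample_id"],
    )
    bg_ok = (background_counts.sum(axis=1) > 0).reindex(peak_counts.index, fill_value=False)
    fit = countmodel.fit_stacked_interaction(
        background_counts[bg_ok],
        peak_counts[bg_ok],
        X,
        base_label="background",
        alt_label="peak",
    )
    eff = countmodel.moderate_effects(fit, "peak:age")
    out = pd.DataFrame(
        {
            "lfc": eff["lfc_mle"],
            "lfc_moderated": eff["lfc_moderated"],
            "se": eff["se"],
            "svalue": eff["svalue"],
            "pvalue": eff["pvalue"],
        },
        index=eff.index,
    )
    n_fallback = int((~bg_ok).sum())
    if n_fallback:
        logger.warning(
            "%d peak(s) with all-zero background: size-factor-only normalization", n_fallback
        )
        sub_pk = peak_counts[~bg_ok]
        sf = countmodel.estimate_size_factors(peak_counts)
        disp = countmodel.estimate_dispersions(sub_pk, design[["age"]], sf)
        fb_fit = countmodel.fit_nb_glm(sub_pk, X, sf, disp)
        fb = countmodel.moderate_effects(fb_fit, "age")
        fb_out = pd.DataFrame(
            {
                "lfc": fb["lfc_mle"],
                "lfc_moderated": fb["lfc_moderated"],
                "se": fb["se"],
                "svalue": fb["svalue"],
                "pvalue": fb["pvalue"],
            },
            index=fb.index,
        )
        out = pd.concat([out, fb_out])
    out = out.reindex(peak_counts.index)
    out["background_fallback"] = ~bg_ok
    out["padj"] = countmodel.bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = (out["lfc"].abs() > lfc_min) & (out["padj"] < padj_max)
    out["significant"] = out["significant"].fillna(False)
    return out


# ---------------------------------------------------------------------------
# regulatory domains and association
# ---------------------------------------------------------------------------

def build_regulatory_domains(
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    basal_upstream: int = BASAL_UPSTREAM,
    basal_downstream: int = BASAL_DOWNSTREAM,
    max_extension: int = MAX_EXTENSION,
) -> pd.DataFrame:
    """Basal-plus-extension domains per gene.

    ``genes`` needs gene_id, chrom, tss, strand.  + strand basal is
    [tss - upstream, tss + downstream); - strand is mirrored.  Each side
    extends to min(1 Mb from the TSS, the nearest neighbouring basal
    boundary), clipped at chromosome bounds, and never shrinks below the
    gene's own basal domain.  Duplicate TSSs are kept; their extensions meet
    at the shared basal boundary.
    """
    rows = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        sub = sub.sort_values(["tss", "gene_id"], kind="stable").reset_index(drop=True)
        clen = chrom_lengths.get(chrom) if chrom_lengths else None
        basal = []
        for _, g in sub.iterrows():
            if g["strand"] == "-":
                b0, b1 = g["tss"] - basal_downstream + 1, g["tss"] + basal_upstream + 1
            else:
                b0, b1 = g["tss"] - basal_upstream, g["tss"] + basal_downstream
            b0 = max(b0, 0)
            if clen is not None:
                b1 = min(b1, clen)
            basal.append((int(b0), int(b1)))
        for i, (_, g) in enumerate(sub.iterrows()):
            b0, b1 = basal[i]
            left_limit = max((basal[j][1] for j in range(len(sub)) if j != i and basal[j][1] <= b0), default=0)
            right_limit = min((basal[j][0] for j in range(len(sub)) if j != i and basal[j][0] >= b1), default=np.inf)
            e0 = max(int(g["tss"]) - max_extension, left_limit, 0)
            e1 = min(int(g["tss"]) + max_extension, right_limit)
            if clen is not None:
                e1 = min(e1, clen)
            e0, e1 = min(e0, b0), max(int(e1), b1)
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "chrom": chrom,
                    "basal_start": b0,
                    "basal_end": b1,
                    "ext_start": int(e0),
                    "ext_end": int(e1),
                    "tss": int(g["tss"]),
                    "strand": g["strand"],
                }
            )
    return pd.DataFrame(rows)


def assign_peaks_to_genes(peaks: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """Many-to-many peak-gene associations by >= 1 bp extended-domain overlap."""
    trees: dict[str, IntervalTree] = {}
    for _, d in domains.iterrows():
        trees.setdefault(d["chrom"], IntervalTree()).addi(
            d["ext_start"], d["ext_end"], d["gene_id"]
        )
    rows = []
    for _, p in peaks.iterrows():
        tree = trees.get(p["chrom"])
        if tree is None:
            continue
        for hit in sorted(tree.overlap(p["start"], p["end"]), key=lambda h: str(h.data)):
            rows.append({"peak_id": p["name"], "gene_id": hit.data})
    return pd.DataFrame(rows, columns=["peak_id", "gene_id"])


def peaks_per_gene_by_distance(
    diff_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    windows: tuple[int, ...] = DISTANCE_WINDOWS,
    direction: str | None = None,
) -> pd.DataFrame:
    """Counts of significant peaks with |summit - TSS| <= w per gene per window.

    ``diff_peaks`` needs chrom, summit, significant and (for direction
    matching) lfc.  ``direction`` of "up"/"down" restricts to
    age-accessible / age-inaccessible peaks.  Nested windows are cumulative:
    count(10 kb) <= count(100 kb) <= count(1 Mb).
    """
    sig = diff_peaks[diff_peaks["significant"]]
    if direction == "up":
        sig = sig[sig["lfc"] > 0]
    elif direction == "down":
        sig = sig[sig["lfc"] < 0]
    out = pd.DataFrame(index=genes["gene_id"], columns=[f"within_{w}" for w in windows], dtype=int)
    for _, g in genes.iterrows():
        d = np.abs(
            sig.loc[sig["chrom"] == g["chrom"], "summit"].to_numpy() - g["tss"]
        )
        for w in windows:
            out.loc[g["gene_id"], f"within_{w}"] = int((d <= w).sum())
    return out


# ---------------------------------------------------------------------------
# pileups and CpG-island proximity
# ---------------------------------------------------------------------------

def pileup(
    coverage_tracks: dict[str, dict[str, np.ndarray]],
    anchors: pd.DataFrame,
    flank: int = 2000,
) -> pd.DataFrame:
    """Library-normalized mean coverage around anchor midpoints per condition.

    ``coverage_tracks`` maps condition -> {chrom: dense per-base vector}.
    Each track is scaled to counts-per-million of its own total before
    averaging, so doubling a library's depth leaves its profile unchanged.
    Anchors whose +/- flank window leaves the chromosome are skipped (count
    logged).  Returns offset x condition.
    """
    offsets = np.arange(-flank, flank + 1)
    result = {}
    for cond, chrom_vecs in coverage_tracks.items():
        total = sum(float(v.sum()) for v in chrom_vecs.values())
        scale = 1e6 / total if total > 0 else 0.0
        acc = np.zeros(offsets.size)
        n_used = n_skipped = 0
        for _, a in anchors.iterrows():
            vec = chrom_vecs.get(a["chrom"])
            mid = int((a["start"] + a["end"]) // 2)
            if vec is None or mid - flank < 0 or mid + flank + 1 > vec.size:
                n_skipped += 1
                continue
            acc += vec[mid - flank: mid + flank + 1]
            n_used += 1
        if n_skipped:
            logger.info("pileup(%s): skipped %d off-chromosome anchor(s)", cond, n_skipped)
        result[cond] = acc * scale / max(n_used, 1)
    return pd.DataFrame(result, index=pd.Index(offsets, name="offset"))


def cpg_island_proximity(
    genes: pd.DataFrame, islands: pd.DataFrame, max_dist: int = 5000
) -> pd.Series:
    """Flag per gene: a CpG island overlaps or lies within ``max_dist`` of the TSS.

    Distance from the TSS to an interval [s, e) is 0 inside, s - tss to the
    right, tss - (e - 1) to the left (distance to the nearest island base).
    """
    flags = []
    for _, g in genes.iterrows():
        sub = islands[islands["chrom"] == g["chrom"]]
        if sub.empty:
            flags.append(False)
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        tss = g["tss"]
        dist = np.where(
            (s <= tss) & (tss < e), 0, np.where(tss < s, s - tss, tss - (e - 1))
        )
        flags.append(bool(dist.min() <= max_dist))
    return pd.Series(flags, index=genes["gene_id"], name="cpg_island_near_tss")
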