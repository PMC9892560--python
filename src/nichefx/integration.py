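"""Cross-tabulation of reversibility classes against epigenomic features.

Gene categories (ARR-up, ARR-down, ARI-up, ARI-down, unchanged) are related
to DMR burden, differentially accessible peaks (direction-matched: up-genes
vs age-accessible peaks, down-genes vs age-inaccessible), CpG-island
proximity, and Fisher-exact enrichment, producing one machine-readable
report.  DMR-to-gene linkage uses regulatory-domain membership (the gene
association the accessibility analysis already defines); an option restricts
it to cCRE-co-annotated DMRs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .countmodel import bh_adjust

logger = logging.getLogger("nichefx.integration")

GENE_CATEGORIES = ("ARR-up", "ARR-down", "ARI-up", "ARI-down", "unchanged")


def gene_categories(labels: pd.DataFrame) -> pd.Series:
    """Collapse reversibility + direction into the five report categories."""
    rev = labels["reversibility"].astype(str)
    direction = labels["age_direction"].astype(str)
    cat = np.where(
        rev.isin(["ARR", "ARI"]), rev.str.cat(direction, sep="-"), "unchanged"
    )
    cat = np.where(np.isin(cat, GENE_CATEGORIES), cat, "unchanged")
    return pd.Series(cat, index=labels.index, name="category")


def dmrs_per_gene(
    dmrs: pd.DataFrame,
    domains: pd.DataFrame,
    categories: pd.Series,
) -> dict:
    """Mean number of DMRs per gene for each gene category.

    A DMR counts toward a gene when its interval overlaps the gene's extended
    regulatory domain; the mean is over all genes of the category (genes with
    zero DMRs included, so means may be below 1).
    """
    per_gene = pd.Series(0, index=categories.index, dtype=int)
    for _, dom in domains.iterrows():
        if dom["gene_id"] not in per_gene.index:
            continue
        hits = (
            (dmrs["chrom"] == dom["chrom"])
            & (dmrs["start"] < dom["ext_end"])
            & (dmrs["end"] > dom["ext_start"])
        ).sum()
        per_gene.loc[dom["gene_id"]] += int(hits)
    out = {}
    for cat in GENE_CATEGORIES:
        members = categories[categories == cat].index
        out[cat] = {
            "n_genes": int(len(members)),
            "mean_dmrs_per_gene": float(per_gene.loc[members].mean())
            if len(members)
            else float("nan"),
        }
    return out


def peak_overlap_by_category(
    diff_peaks: pd.DataFrame,
    associations: pd.DataFrame,
    categories: pd.Series,
    genes: pd.DataFrame,
    effect_sd: pd.Series | None = None,
    sd_max: float | None = None,
    windows: tuple[int, ...] = (10_000, 100_000, 1_000_000),
) -> dict:
    """Direction-matched peak overlap per category.

    For up-categories, a gene "overlaps" when associated with >= 1 significant
    age-accessible peak (lfc > 0); down-categories use age-inaccessible peaks.
    Also reports mean significant direction-matched peaks per gene within each
    TSS-distance window.  ``effect_sd``/``sd_max`` optionally restrict to
    reproducible genes (per-gene effect SD below the cutoff).
    """
    from .regulatory import peaks_per_gene_by_distance

    cats = categories.copy()
    if effect_sd is not None and sd_max is not None:
        keep = effect_sd.reindex(cats.index) < sd_max
        cats = cats[keep.fillna(False)]
    sig = diff_peaks[diff_peaks["significant"]]
    out = {}
    for cat in GENE_CATEGORIES:
        members = cats[cats == cat].index
        direction = "up" if cat.endswith("-up") else ("down" if cat.endswith("-down") else None)
        if direction == "up":
            matched = sig[sig["lfc"] > 0]
        elif direction == "down":
            matched = sig[sig["lfc"] < 0]
        else:
            matched = sig
        with_peak = associations[
            associations["peak_id"].isin(matched.index)
            & associations["gene_id"].isin(members)
        ]["gene_id"].nunique()
        gsub = genes[genes["gene_id"].isin(members)]
        if len(gsub):
            counts = peaks_per_gene_by_distance(
                diff_peaks, gsub, windows=windows, direction=direction
            )
            means = {c: float(counts[c].mean()) for c in counts.columns}
        else:
            means = {f"within_{w}": float("nan") for w in windows}
        out[cat] = {
            "n_genes": int(len(members)),
            "pct_with_matched_peak": (
                100.0 * with_peak / len(members) if len(members) else float("nan")
            ),
            "mean_peaks_per_gene": means,
        }
    return out


def category_enrichment_test(
    set_a: set, feature: set, universe: set
) -> tuple[float, float]:
    """2x2 Fisher exact test of feature membership between a set and its complement.

    Table: [[|A & F|, |A \\ F|], [|A' & F|, |A' \\ F|]] within the universe.
    Returns (odds ratio, two-sided p); an empty margin gives (NaN, 1.0).
    """
    a = set_a & universe
    f = feature & universe
    n11 = len(a & f)
    n12 = len(a - f)
    n21 = len(f - a)
    n22 = len(universe - a - f)
    table = np.array([[n11, n12], [n21, n22]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def enrichment_battery(
    categories: pd.Series, features: dict[str, set]
) -> pd.DataFrame:
    """Fisher tests for every category x feature pair, BH-adjusted together."""
    universe = set(categories.index)
    rows = []
    for cat in GENE_CATEGORIES:
        members = set(categories[categories == cat].index)
        for fname, fset in features.items():
            oddsr, p = category_enrichment_test(members, fset, universe)
            rows.append(
                {"category": cat, "feature": fname, "odds_ratio": oddsr, "pvalue": p}
            )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def build_report(
    outpath=None,
    *,
    category_counts: dict | None = None,
    reversibility: dict | None = None,
    concordance: dict | None = None,
    stability: dict | None = None,
    dmr_summary: dict | None = None,
    accessibility: dict | None = None,
    dmrs_by_category: dict | None = None,
    peak_overlap: dict | None = None,
    enrichment: pd.DataFrame | None = None,
    truth_confusion: dict | None = None,
) -> dict:
    """Assemble the machine-readable run report.

    Absent stages are marked ``"absent"`` rather than failing; the report is
    deterministic for identical inputs (no timestamps).  When simulation
    truth was available, the ARR/ARI vs planted-class confusion matrix is
    included.  Written as sorted-key JSON when ``outpath`` is given.
    """
    sections = {
        "category_counts": category_counts,
        "reversibility": reversibility,
        "concordance": concordance,
        "stability": stability,
        "dmr_summary": dmr_summary,
        "accessibility": accessibility,
        "dmrs_by_category": dmrs_by_category,
        "peak_overlap": peak_overlap,
        "enrichment": (
            enrichment.to_dict(orient="records") if enrichment is not None else None
        ),
        "truth_confusion": truth_confusion,
    }
    report = {k: (v if v is not None else "absent") for k, v in sections.items()}
    if outpath is not None:
        Path(outpath).write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n"
        )
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def truth_confusion_matrix(labels: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Called reversibility vs planted gene class, as nested counts."""
    called = labels["reversibility"].astype(str)
    planted = truth["class_label"].reindex(labels.index).astype(str)
    out: dict[str, dict[str, int]] = {}
    for t in sorted(planted.unique()):
        sub = called[planted == t]
        out[t] = {c: int((sub == c).sum()) for c in sorted(sub.unique())}
    return out
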