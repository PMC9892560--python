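"""Window-based differential-methylation calling and DMR annotation.

The genome is tiled into fixed, non-overlapping 100-bp windows aligned to
coordinate 0 (no sliding, no phase search); windows with fewer than 4
distinct CpG sites (union across samples) are never tested.  For each tested
window, per-replicate methylation proportions (CpG counts pooled within the
window, +0.5/+1.0 pseudo-counts so beta regression is defined at the
boundaries) are regressed on condition via beta regression; the reported
delta is the difference of raw pooled condition proportions (aged - young).
A window is a DMR when |delta| >= 0.40 and its BH-adjusted p < 0.01 — both
hard filters, never relaxed.  CpG calls from both strands are pooled per
position.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

logger = logging.getLogger("nichefx.methylation")

WINDOW_SIZE = 100
MIN_CPG = 4
MIN_ABS_DELTA = 0.40
PADJ_MAX = 0.01
PSEUDO_METH = 0.5
PSEUDO_TOTAL = 1.0

CCRE_PRECEDENCE = ("PLS", "ELS", "other")


def tile_windows(
    tracks: dict, window: int = WINDOW_SIZE, min_cpg: int = MIN_CPG
) -> pd.DataFrame:
    """Fixed non-overlapping tiles from position 0 with >= ``min_cpg`` CpGs.

    ``tracks`` maps ``(condition, replicate)`` to internal methylation frames
    (chrom, pos0, ...).  CpG sites are the union of distinct positions across
    all tracks.  Returns (chrom, start, end, n_cpg).
    """
    if not tracks:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpg"])
    sites = pd.concat(
        [t[["chrom", "pos0"]] for t in tracks.values()], ignore_index=True
    ).drop_duplicates()
    if sites.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpg"])
    sites["win"] = sites["pos0"] // window
    counts = sites.groupby(["chrom", "win"], sort=True).size().reset_index(name="n_cpg")
    counts = counts[counts["n_cpg"] >= min_cpg].reset_index(drop=True)
    counts["start"] = counts["win"] * window
    counts["end"] = counts["start"] + window
    return counts[["chrom", "start", "end", "n_cpg"]]


def _window_proportions(track: pd.DataFrame, chrom: str, start: int, end: int):
    sub = track[
        (track["chrom"] == chrom) & (track["pos0"] >= start) & (track["pos0"] < end)
    ]
    meth = int(sub["count_methylated"].sum())
    total = int(sub["count_total"].sum())
    return meth, total


def test_window(
    window: pd.Series,
    replicates_young: list[pd.DataFrame],
    replicates_aged: list[pd.DataFrame],
) -> tuple[float, float]:
    """Beta-regression test of one window; returns (delta, p).

    delta = pooled aged proportion - pooled young proportion (raw counts);
    p is the two-sided Wald p of the condition coefficient from a beta
    regression on per-replicate pseudo-counted proportions.  Replicates with
    zero coverage are dropped; fewer than 2 usable replicates in either
    condition leaves the window untested (NaN, NaN).  If the beta fit fails
    to converge, a Welch t-test on logit proportions is the logged fallback.
    """
    chrom, start, end = window["chrom"], window["start"], window["end"]
    props, cond, pooled = [], [], {"young": [0, 0], "aged": [0, 0]}
    for label, reps in (("young", replicates_young), ("aged", replicates_aged)):
        for track in reps:
            meth, total = _window_proportions(track, chrom, start, end)
            if total == 0:
                continue
            props.append((meth + PSEUDO_METH) / (total + PSEUDO_TOTAL))
            cond.append(1.0 if label == "aged" else 0.0)
            pooled[label][0] += meth
            pooled[label][1] += total
    cond = np.array(cond)
    if (cond == 0).sum() < 2 or (cond == 1).sum() < 2:
        return float("nan"), float("nan")
    delta = pooled["aged"][0] / pooled["aged"][1] - pooled["young"][0] / pooled["young"][1]
    y = np.clip(np.array(props), 1e-6, 1 - 1e-6)
    X = np.column_stack([np.ones_like(cond), cond])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = BetaModel(y, X).fit(disp=False)
        p = float(res.pvalues[1])
        if not np.isfinite(p):
            raise ValueError("non-finite p from beta regression")
    except Exception:
        logger.debug("beta regression failed at %s:%d-%d; logit t-test fallback", chrom, start, end)
        logit = np.log(y / (1 - y))
        t = stats.ttest_ind(logit[cond == 1], logit[cond == 0], equal_var=False)
        p = float(t.pvalue)
    return float(delta), p


def test_windows(
    windows: pd.DataFrame,
    replicates_young: list[pd.DataFrame],
    replicates_aged: list[pd.DataFrame],
) -> pd.DataFrame:
    """Vectorized per-window testing over all candidate tiles.

    Aggregates per-replicate (meth, total) per window with one pass over each
    track, then applies the :func:`test_window` model window by window.
    """
    out = windows.copy()
    if out.empty:
        out["delta"] = out["p"] = np.array([], dtype=float)
        return out
    # per-track pooled counts per window (fast path over the per-window scan)
    agg = []
    for label, reps in (("young", replicates_young), ("aged", replicates_aged)):
        for track in reps:
            t = track.copy()
            t["win"] = t["pos0"] // WINDOW_SIZE
            g = t.groupby(["chrom", "win"], sort=False)[
                ["count_methylated", "count_total"]
            ].sum()
            agg.append((label, g))
    key = list(zip(out["chrom"], out["start"] // WINDOW_SIZE))
    deltas = np.full(len(out), np.nan)
    pvals = np.full(len(out), np.nan)
    for i, k in enumerate(key):
        props, cond = [], []
        pooled = {"young": [0, 0], "aged": [0, 0]}
        for label, g in agg:
            if k not in g.index:
                continue
            meth, total = int(g.loc[k, "count_methylated"]), int(g.loc[k, "count_total"])
            if total == 0:
                continue
            props.append((meth + PSEUDO_METH) / (total + PSEUDO_TOTAL))
            cond.append(1.0 if label == "aged" else 0.0)
            pooled[label][0] += meth
            pooled[label][1] += total
        cond_arr = np.array(cond)
        if (cond_arr == 0).sum() < 2 or (cond_arr == 1).sum() < 2:
            continue
        deltas[i] = (
            pooled["aged"][0] / pooled["aged"][1]
            - pooled["young"][0] / pooled["young"][1]
        )
        y = np.clip(np.array(props), 1e-6, 1 - 1e-6)
        X = np.column_stack([np.ones_like(cond_arr), cond_arr])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = BetaModel(y, X).fit(disp=False)
            p = float(res.pvalues[1])
            if not np.isfinite(p):
                raise ValueError
        except Exception:
            logit = np.log(y / (1 - y))
            t = stats.ttest_ind(logit[cond_arr == 1], logit[cond_arr == 0], equal_var=False)
            p = float(t.pvalue)
        pvals[i] = p
    out["delta"] = deltas
    out["p"] = pvals
    return out


def call_dmrs(tested: pd.DataFrame) -> pd.DataFrame:
    """BH over all tested windows, then the hard DMR filters.

    Retains |delta| >= 0.40 and padj < 0.01; direction is ``gain`` iff
    delta > 0 (aged more methylated than young).  Adjacent significant
    windows are not merged.
    """
    from .countmodel import bh_adjust

    out = tested.copy()
    out["padj"] = bh_adjust(out["p"].to_numpy())
    dmrs = out[
        (out["delta"].abs() >= MIN_ABS_DELTA) & (out["padj"] < PADJ_MAX)
    ].copy()
    dmrs["direction"] = np.where(dmrs["delta"] > 0, "gain", "loss")
    return dmrs.reset_index(drop=True)


def summarize_gain_loss(dmrs: pd.DataFrame) -> dict:
    """Percent of DMRs that are gains vs losses of methylation (NaN if empty)."""
    n = len(dmrs)
    if n == 0:
        return {"n": 0, "pct_gain": float("nan"), "pct_loss": float("nan")}
    gains = int((dmrs["direction"] == "gain").sum())
    return {
        "n": n,
        "pct_gain": 100.0 * gains / n,
        "pct_loss": 100.0 * (n - gains) / n,
    }


def annotate_dmrs(
    dmrs: pd.DataFrame, ccres: pd.DataFrame, max_dist: int = 300
) -> pd.Series:
    """Assign each DMR a cCRE class when one lies within ``max_dist`` bp.

    The DMR interval is expanded by ``max_dist`` on both sides; any
    overlapping cCRE assigns its class, with precedence PLS > ELS > other on
    ties.  DMRs with no cCRE within range are ``other``.
    """
    classes = []
    for _, d in dmrs.iterrows():
        lo, hi = d["start"] - max_dist, d["end"] + max_dist
        near = ccres[
            (ccres["chrom"] == d["chrom"]) & (ccres["start"] < hi) & (ccres["end"] > lo)
        ]
        hit = "other"
        for cls in CCRE_PRECEDENCE:
            if (near["name"] == cls).any():
                hit = cls
                break
        classes.append(hit)
    return pd.Series(classes, index=dmrs.index, name="ccre_class")
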