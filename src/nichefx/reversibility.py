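"""Decomposition of age, engraftment and niche effects, and ARR/ARI calling.

For the 2x2 transplant design (age in {young, aged}, time in {T0, T21}) a
gene-wise NB GLM ``count ~ time + age + time:age (+ batch)`` separates

* the **age effect**       Delta_age  = AgedT0 - YoungT0   (the ``age`` coefficient),
* the **engraftment effect** Delta_eng = YoungT21 - YoungT0 (the ``time`` coefficient),
* the **niche effect**     Delta_niche = (AgedT21 - AgedT0) - (YoungT21 - YoungT0),
  which is exactly the fitted interaction coefficient — the residual change
  in aged cells beyond what engraftment alone produces.

Genes significant for both age and niche with opposing signs are
Age-Related Reversible (ARR: the young niche pushes expression back toward
the youthful state); age-significant genes without a niche effect are
Age-Related Irreversible (ARI).  Concordant significant niche effects are
reported separately as SAME_SIGN rather than folded into ARR.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import countmodel

logger = logging.getLogger("nichefx.reversibility")

EFFECTS = ("age", "engraftment", "niche", "batch")


@dataclass(frozen=True)
class ThresholdProfile:
    """Significance profile for effect calling.

    ``batch_lfc_rule`` is ``None`` or ``(mode, cutoff)`` with mode
    ``"abs_above"`` / ``"abs_below"``: an extra filter on the absolute
    moderated batch LFC applied when calling reversibility.
    """

    name: str
    lfc_min: float = 1.0
    s_max: float = 0.05
    batch_lfc_rule: tuple | None = None

    def __post_init__(self):
        if not self.lfc_min > 0:
            raise ValueError("lfc_min must be > 0")
        if not 0 < self.s_max < 1:
            raise ValueError("s_max must be in (0, 1)")
        if self.batch_lfc_rule is not None and self.batch_lfc_rule[0] not in (
            "abs_above",
            "abs_below",
        ):
            raise ValueError("batch_lfc_rule mode must be abs_above or abs_below")


STRICT = ThresholdProfile("strict", lfc_min=1.0, s_max=0.05)
PERMISSIVE = ThresholdProfile(
    "permissive", lfc_min=1.0, s_max=0.15, batch_lfc_rule=("abs_above", 0.5)
)


def build_design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded design matrix for ``~ time + age + time:age (+ batch)``."""
    age = (design["age"] == "aged").astype(float)
    time = (design["time"] == "T21").astype(float)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "time": time.to_numpy(),
            "age": age.to_numpy(),
            "age:time": (age * time).to_numpy(),
        },
        index=design["sample_id"],
    )
    batches = sorted(design["batch"].unique())
    for b in batches[1:]:
        X[f"batch[{b}]"] = (design["batch"] == b).astype(float).to_numpy()
    return X


def decompose_effects(
    counts: pd.DataFrame, design: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Fit the factorial model and return moderated effect tables.

    Returns ``{"age": ..., "engraftment": ..., "niche": ..., "batch": ...}``,
    each a frame from :func:`nichefx.countmodel.moderate_effects` (lfc_mle,
    lfc_moderated, se, lfsr, svalue, pvalue, padj).  ``batch`` is present when
    the design has more than one batch; with several batch dummies, the
    per-gene dummy of largest absolute moderated LFC is reported.

    Raises if any of the four age x time cells is empty — the decomposition
    is unidentifiable without the full factorial.
    """
    cells = design.groupby(["age", "time"], observed=True).size()
    if len(cells) < 4:
        have = set(cells.index)
        missing = [
            c
            for c in itertools.product(("young", "aged"), ("T0", "T21"))
            if c not in have
        ]
        raise ValueError(f"missing factorial cell(s) {missing}: decomposition unidentifiable")
    X = build_design_matrix(design)
    sf = countmodel.estimate_size_factors(counts)
    disp = countmodel.estimate_dispersions(counts, design[["age", "time", "batch"]], sf)
    fit = countmodel.fit_nb_glm(counts, X, sf, disp)
    effects = {
        "age": countmodel.moderate_effects(fit, "age"),
        "engraftment": countmodel.moderate_effects(fit, "time"),
        "niche": countmodel.moderate_effects(fit, "age:time"),
    }
    batch_cols = [c for c in fit.coef_names if c.startswith("batch[")]
    if batch_cols:
        tables = [countmodel.moderate_effects(fit, c) for c in batch_cols]
        stacked = np.stack([t["lfc_moderated"].to_numpy() for t in tables])
        pick = np.nanargmax(
            np.where(np.isnan(stacked), -np.inf, np.abs(stacked)), axis=0
        )
        effects["batch"] = pd.DataFrame(
            {
                col: np.choose(pick, [t[col].to_numpy() for t in tables])
                for col in tables[0].columns
            },
            index=tables[0].index,
        )
    return effects


def classify_effect_categories(
    effects: dict[str, pd.DataFrame], profile: ThresholdProfile
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Call AGE/ENGRAFT/NICHE per gene and count all category combinations.

    An effect is present iff |moderated LFC| > lfc_min (strictly) and
    s-value < s_max.  Returns the per-gene label frame (boolean columns AGE,
    ENGRAFT, NICHE and a ``category`` string like ``"AGE+NICHE"``) and the
    counts over the 7 non-empty combinations plus ``"unchanged"``.
    """
    calls = {}
    for name, key in (("AGE", "age"), ("ENGRAFT", "engraftment"), ("NICHE", "niche")):
        t = effects[key]
        calls[name] = (
            (t["lfc_moderated"].abs() > profile.lfc_min) & (t["svalue"] < profile.s_max)
        ).fillna(False)
    labels = pd.DataFrame(calls)
    parts = [
        np.where(labels[n], n, "") for n in ("AGE", "ENGRAFT", "NICHE")
    ]
    cat = ["+".join(x for x in triple if x) or "unchanged" for triple in zip(*parts)]
    labels["category"] = cat
    combos = [
        "+".join(c)
        for r in (1, 2, 3)
        for c in itertools.combinations(("AGE", "ENGRAFT", "NICHE"), r)
    ]
    counts = {c: int((labels["category"] == c).sum()) for c in combos}
    counts["unchanged"] = int((labels["category"] == "unchanged").sum())
    return labels, counts


def call_arr_ari(
    labels: pd.DataFrame,
    effects: dict[str, pd.DataFrame],
    profile: ThresholdProfile,
) -> pd.DataFrame:
    """Assign reversibility (ARR / ARI / SAME_SIGN) among age-affected genes.

    ARR requires a significant niche effect of opposite sign to the age
    effect; a significant same-sign niche effect is reported as SAME_SIGN;
    no niche effect is ARI.  Non-AGE genes get NA.  The profile's
    batch_lfc_rule (permissive profile) additionally restricts the
    age-affected set to genes passing the batch-LFC magnitude filter.
    """
    out = labels.copy()
    age_lfc = effects["age"]["lfc_moderated"]
    niche_lfc = effects["niche"]["lfc_moderated"]
    is_age = labels["AGE"].copy()
    if profile.batch_lfc_rule is not None:
        if "batch" not in effects:
            logger.warning("profile %s has a batch rule but no batch effect was fit", profile.name)
        else:
            mode, cut = profile.batch_lfc_rule
            mag = effects["batch"]["lfc_moderated"].abs()
            keep = (mag > cut) if mode == "abs_above" else (mag < cut)
            is_age &= keep.fillna(False)
    rev = np.full(len(out), "NA", dtype=object)
    direction = np.full(len(out), "NA", dtype=object)
    same_sign = np.sign(niche_lfc) == np.sign(age_lfc)
    rev[is_age & labels["NICHE"] & ~same_sign] = "ARR"
    rev[is_age & labels["NICHE"] & same_sign] = "SAME_SIGN"
    rev[is_age & ~labels["NICHE"]] = "ARI"
    direction[is_age.to_numpy()] = np.where(age_lfc[is_age] > 0, "up", "down")
    out["reversibility"] = rev
    out["age_direction"] = direction
    return out


def reversibility_summary(labels: pd.DataFrame) -> dict:
    """Reversible fractions (ARR / (ARR + ARI), in percent) overall and by direction.

    Also accepts plain counts via :func:`reversible_fraction` for worked
    arithmetic on reported tallies.
    """
    out = {}
    for stratum, sub in (
        ("overall", labels),
        ("up", labels[labels["age_direction"] == "up"]),
        ("down", labels[labels["age_direction"] == "down"]),
    ):
        n_arr = int((sub["reversibility"] == "ARR").sum())
        n_ari = int((sub["reversibility"] == "ARI").sum())
        out[stratum] = {
            "n_arr": n_arr,
            "n_ari": n_ari,
            "pct_reversible": reversible_fraction(n_arr, n_ari),
        }
    return out


def reversible_fraction(n_arr: int, n_ari: int) -> float:
    """Percent reversible among age-affected genes; NaN when none."""
    total = n_arr + n_ari
    if total == 0:
        return float("nan")
    return 100.0 * n_arr / total


def effect_concordance(
    lfc_x: pd.Series | np.ndarray,
    lfc_y: pd.Series | np.ndarray,
    subset=None,
) -> tuple[float, float, int]:
    """Pearson r and least-squares slope of y on x over a gene subset.

    Used both for the niche-vs-age comparison (anti-correlation expected when
    reversibility is widespread) and for cluster-vs-cluster age-effect
    concordance (positive).  Returns (r, slope, n); degenerate variance gives
    NaN statistics.
    """
    x = pd.Series(lfc_x)
    y = pd.Series(lfc_y)
    if subset is not None:
        x, y = x.loc[subset], y.loc[subset]
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired finite values for concordance")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), n
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return r, slope, n
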