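"""End-to-end orchestration: simulate -> fit -> classify -> stability ->
dmrs -> atac -> integrate -> report, with checkpointed intermediates.

A :class:`PipelineConfig` aggregates the simulation conditions, the two
threshold profiles, stage toggles and the master seed.  Each stage writes
versioned intermediates into the run directory plus a stage marker carrying
a hash of the config, so ``resume=True`` skips stages whose marker matches.
The whole run is deterministic given config + seed (hash-stable outputs; the
report carries the seed for provenance and no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    formats_io,
    integration,
    methylation,
    regulatory,
    reversibility,
    stability,
    synthetic_data,
)

logger = logging.getLogger("nichefx.pipeline")

STAGES = ("simulate", "classify", "stability", "dmrs", "atac", "integrate", "report")


class ConfigError(ValueError):
    """The pipeline configuration failed validation."""


@dataclass
class PipelineConfig:
    """Structured pipeline configuration; unknown keys are rejected."""

    sim: synthetic_data.SimConfig = field(default_factory=synthetic_data.SimConfig)
    strict_profile: reversibility.ThresholdProfile = reversibility.STRICT
    permissive_profile: reversibility.ThresholdProfile = reversibility.PERMISSIVE
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"sim", "stages", "seed", "log_level", "strict_profile", "permissive_profile"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        if "sim" in raw:
            sim_fields = {f.name for f in dataclasses.fields(synthetic_data.SimConfig)}
            bad = set(raw["sim"]) - sim_fields
            if bad:
                raise ConfigError(f"unknown sim key(s): {sorted(bad)}")
            sim = raw["sim"]
            for key in ("effect_size_range", "library_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["sim"] = synthetic_data.SimConfig(**sim)
        for key in ("stages", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("strict_profile", "permissive_profile"):
            if key in raw:
                prof = dict(raw[key])
                if "batch_lfc_rule" in prof and prof["batch_lfc_rule"] is not None:
                    prof["batch_lfc_rule"] = tuple(prof["batch_lfc_rule"])
                kwargs[key] = reversibility.ThresholdProfile(**prof)
        return cls(**kwargs)

    def to_yaml(self) -> str:
        """Serialize the configuration (re-loadable via :meth:`from_yaml`)."""
        blob = {
            "sim": dataclasses.asdict(self.sim),
            "strict_profile": dataclasses.asdict(self.strict_profile),
            "permissive_profile": dataclasses.asdict(self.permissive_profile),
            "stages": dict(self.stages),
            "seed": self.seed,
            "log_level": self.log_level,
        }
        for prof in ("strict_profile", "permissive_profile"):
            rule = blob[prof]["batch_lfc_rule"]
            if rule is not None:
                blob[prof]["batch_lfc_rule"] = list(rule)
        for key in ("effect_size_range", "library_size_range"):
            blob["sim"][key] = list(blob["sim"][key])
        return yaml.safe_dump(blob, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "sim": dataclasses.asdict(self.sim),
                "strict": dataclasses.asdict(self.strict_profile),
                "permissive": dataclasses.asdict(self.permissive_profile),
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _marker(run_dir: Path, stage: str) -> Path:
    return run_dir / f".{stage}.done"


def _stage_fresh(run_dir: Path, stage: str, digest: str) -> bool:
    m = _marker(run_dir, stage)
    return m.exists() and m.read_text().strip() == digest


def run_pipeline(config: PipelineConfig, run_dir, resume: bool = False) -> Path:
    """Execute enabled stages in dependency order; returns the run directory.

    A stage failure stops its downstream stages only; the report marks absent
    sections rather than failing.
    """
    logging.getLogger("nichefx").setLevel(config.log_level)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    on = config.stages
    results: dict = {"seed": config.seed, "config_digest": digest}
    (run_dir / "config_used.yaml").write_text(config.to_yaml())

    # --- simulate -----------------------------------------------------------
    if on.get("simulate", True):
        if resume and _stage_fresh(run_dir, "simulate", digest):
            logger.info("simulate: checkpoint fresh, skipping")
        else:
            synthetic_data.write_fixture_bundle(config.sim, run_dir / "inputs")
            _marker(run_dir, "simulate").write_text(digest)

    inputs = run_dir / "inputs"
    labels = categories = None
    effects = None
    truth = None

    # --- classify -----------------------------------------------------------
    if on.get("classify", True):
        counts = formats_io.read_counts(inputs / "counts.tsv")
        design = formats_io.read_design(inputs / "design.tsv", counts)
        truth = pd.read_csv(inputs / "truth_genes.tsv", sep="\t", index_col=0)
        effects = reversibility.decompose_effects(counts, design)
        for name, table in effects.items():
            table.to_csv(run_dir / f"effects_{name}.tsv", sep="\t")
        labels, counts_by_cat = reversibility.classify_effect_categories(
            effects, config.strict_profile
        )
        labels = reversibility.call_arr_ari(labels, effects, config.strict_profile)
        labels.to_csv(run_dir / "labels_strict.tsv", sep="\t")
        perm_labels, _ = reversibility.classify_effect_categories(
            effects, config.permissive_profile
        )
        perm_labels = reversibility.call_arr_ari(
            perm_labels, effects, config.permissive_profile
        )
        perm_labels.to_csv(run_dir / "labels_permissive.tsv", sep="\t")
        age_set = labels.index[labels["AGE"]]
        r, slope, n = (
            reversibility.effect_concordance(
                effects["age"]["lfc_moderated"],
                effects["niche"]["lfc_moderated"],
                subset=age_set,
            )
            if len(age_set) >= 3
            else (float("nan"), float("nan"), int(len(age_set)))
        )
        results["category_counts"] = counts_by_cat
        results["reversibility"] = {
            "strict": reversibility.reversibility_summary(labels),
            "permissive": reversibility.reversibility_summary(perm_labels),
        }
        results["concordance"] = {"niche_vs_age_r": r, "slope": slope, "n": n}
        results["truth_confusion"] = integration.truth_confusion_matrix(labels, truth)
        categories = integration.gene_categories(labels)
        _marker(run_dir, "classify").write_text(digest)

    # --- stability ----------------------------------------------------------
    if on.get("stability", True):
        exonic = formats_io.read_counts(inputs / "exonic_counts.tsv")
        intronic = formats_io.read_counts(inputs / "intronic_counts.tsv")
        ei_design = formats_io.read_design(inputs / "ei_design.tsv", exonic)
        se = stability.deconvolve_stability(exonic, intronic, ei_design)
        drivers = stability.classify_stability_drivers(se)
        se.join(drivers).to_csv(run_dir / "stability_effects.tsv", sep="\t")
        results["stability"] = drivers.value_counts().to_dict()
        _marker(run_dir, "stability").write_text(digest)

    # --- dmrs ---------------------------------------------------------------
    dmrs = None
    if on.get("dmrs", True):
        tracks = {}
        for p in sorted(inputs.glob("meth_*.tsv")):
            cond, rep = p.stem.split("_")[1], int(p.stem.split("_r")[1])
            tracks[(cond, rep)] = formats_io.read_methylation(p)
        young = [t for (c, _), t in sorted(tracks.items()) if c == "young"]
        aged = [t for (c, _), t in sorted(tracks.items()) if c == "aged"]
        windows = methylation.tile_windows(tracks)
        tested = methylation.test_windows(windows, young, aged)
        dmrs = methylation.call_dmrs(tested)
        tested.to_csv(run_dir / "windows_tested.tsv", sep="\t", index=False)
        dmrs.to_csv(run_dir / "dmrs.tsv", sep="\t", index=False)
        results["dmr_summary"] = methylation.summarize_gain_loss(dmrs)
        _marker(run_dir, "dmrs").write_text(digest)

    # --- atac ---------------------------------------------------------------
    diff = associations = atac_genes = None
    if on.get("atac", True):
        peaks = formats_io.read_bed(inputs / "peaks.bed")
        pk = formats_io.read_counts(inputs / "peak_counts.tsv")
        bg = formats_io.read_counts(inputs / "background_counts.tsv")
        atac_design = formats_io.read_design(inputs / "atac_design.tsv", pk)
        gene_bed = formats_io.read_bed(inputs / "genes_tss.bed")
        atac_genes = pd.DataFrame(
            {
                "gene_id": gene_bed["name"],
                "chrom": gene_bed["chrom"],
                "tss": gene_bed["start"],
                "strand": gene_bed["strand"],
            }
        )
        diff = regulatory.differential_accessibility(pk, bg, atac_design)
        diff.to_csv(run_dir / "diff_accessibility.tsv", sep="\t")
        domains = regulatory.build_regulatory_domains(atac_genes)
        domains.to_csv(run_dir / "regulatory_domains.tsv", sep="\t", index=False)
        peaks_named = peaks.set_index("name", drop=False).loc[diff.index].reset_index(drop=True)
        associations = regulatory.assign_peaks_to_genes(peaks_named, domains)
        associations.to_csv(run_dir / "peak_gene_associations.tsv", sep="\t", index=False)
        results["accessibility"] = {
            "n_peaks": int(len(diff)),
            "n_significant": int(diff["significant"].sum()),
        }
        _marker(run_dir, "atac").write_text(digest)

    # --- integrate ----------------------------------------------------------
    if on.get("integrate", True) and diff is not None and dmrs is not None:
        # the ATAC layer carries its own planted gene categories
        atac_truth = pd.read_csv(inputs / "truth_atac.tsv", sep="\t", index_col=0)
        sim_peaks, *_rest, sim_genes, _d, _t = _atac_truth_layers(config)
        atac_cats = pd.Series(
            sim_genes["category"].to_numpy(), index=sim_genes["gene_id"], name="category"
        )
        domains = regulatory.build_regulatory_domains(
            sim_genes[["gene_id", "chrom", "tss", "strand"]]
        )
        results["dmrs_by_category"] = integration.dmrs_per_gene(dmrs, domains, atac_cats)
        diff_peaks = diff.join(
            sim_peaks.set_index("name")[["chrom", "summit"]], how="left"
        )
        results["peak_overlap"] = integration.peak_overlap_by_category(
            diff_peaks,
            associations,
            atac_cats,
            sim_genes[["gene_id", "chrom", "tss", "strand"]],
        )
        _marker(run_dir, "integrate").write_text(digest)

    # --- report -------------------------------------------------------------
    if on.get("report", True):
        integration.build_report(
            run_dir / "report.json",
            category_counts=results.get("category_counts"),
            reversibility=results.get("reversibility"),
            concordance=results.get("concordance"),
            stability=results.get("stability"),
            dmr_summary=results.get("dmr_summary"),
            accessibility=results.get("accessibility"),
            dmrs_by_category=results.get("dmrs_by_category"),
            peak_overlap=results.get("peak_overlap"),
            truth_confusion=results.get("truth_confusion"),
        )
        _marker(run_dir, "report").write_text(digest)
    return run_dir


def _atac_truth_layers(config: PipelineConfig):
    """Re-derive the ATAC simulation layers (deterministic in the seed)."""
    return synthetic_data.simulate_atac_landscape(config.sim)


def run_digest(run_dir, patterns=("*.tsv", "*.json")) -> str:
    """Content hash over a run directory's text outputs (order-stable)."""
    run_dir = Path(run_dir)
    h = hashlib.sha256()
    files = sorted(p for pat in patterns for p in run_dir.rglob(pat))
    for p in sorted(set(files)):
        h.update(p.relative_to(run_dir).as_posix().encode())
        h.update(p.read_bytes())
    return h.hexdigest()
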