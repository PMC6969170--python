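"""End-to-end orchestration: config validation, staged execution, reports.

``run_pipeline`` executes sample exclusions -> feature engineering ->
diversity/PERMANOVA -> per-cohort association models (single- and multi-drug)
-> inverse-variance meta-analysis with the significance gate -> resistome
contrasts -> post-hoc follow-ups, writing one TSV per stage into the output
directory.  Every result TSV carries the config hash in a comment header;
fixed config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic_data as synth
from .association_models import run_cohort_associations
from .community_ecology import (bray_curtis_matrix, permanova,
                                richness_drug_associations, shannon_per_sample)
from .feature_engineering import (extract_endpoints, filter_taxa,
                                  prepare_pathways, transform_taxa)
from .io_profiles import (apply_sample_exclusions, read_metadata,
                          read_profile_table, summarize_drug_usage,
                          taxa_to_proportions, write_metadata,
                          write_profile_table, write_usage_summary)
from .meta_analysis import meta_analyze
from .posthoc import group_contrast, stratified_contribution_test
from .resistome import aggregate_markers, resistome_association

log = logging.getLogger(__name__)

PRESETS = ("null", "effects", "confounded", "reference")


class PipelineError(RuntimeError):
    """Raised with the failing stage's name and context."""


@dataclass
class PipelineConfig:
    outdir: str = "results"
    # either a generator preset ...
    preset: str | None = None
    seed: int = 0
    sizes: tuple = (600, 250, 150)
    # ... or input file paths
    taxa_path: str | None = None
    pathways_path: str | None = None
    ar_markers_path: str | None = None
    marker_map_path: str | None = None
    metadata_path: str | None = None
    # thresholds (defaults mirror the study's analysis settings)
    min_depth: float = 10_000_000
    taxa_prevalence: float = 0.10
    taxa_mean_abundance: float = 1e-4
    pathway_prevalence: float = 0.10
    fdr_significant: float = 0.05
    fdr_het_trigger: float = 0.10
    relaxed_fdr: float = 0.25
    n_permutations: int = 10_000
    permanova_drugs: tuple = ()  # drugs to test compositionally besides n_drugs
    min_users: int = 5
    modes: tuple = ("single", "multi")
    run_posthoc: bool = True

    def __post_init__(self) -> None:
        for name in ("taxa_prevalence", "taxa_mean_abundance", "pathway_prevalence",
                     "fdr_significant", "fdr_het_trigger", "relaxed_fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        for mode in self.modes:
            if mode not in ("single", "multi"):
                raise ValueError(f"unknown mode {mode!r}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path) -> PipelineConfig:
    """Parse a YAML config file, fill defaults and check invariants."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
        )
    for key in ("sizes", "modes", "permanova_drugs"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    log.info("config: %s", asdict(cfg))
    return cfg


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, **to_csv_kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, **to_csv_kw)


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.preset is not None:
        maker = {"null": synth.null_preset, "effects": synth.effects_preset,
                 "confounded": synth.confounded_preset}.get(config.preset)
        if maker is not None:
            gen_cfg = maker(config.seed, sizes=tuple(config.sizes))
        else:
            gen_cfg = synth.reference_preset(config.seed)
        ds = synth.generate(gen_cfg)
        synth.write_truth(ds.truth, outdir / "truth.tsv", gen_cfg)
        write_profile_table(ds.taxa, outdir / "input_taxa.tsv",
                            header_comment=f"config_hash: {gen_cfg.hash()}")
        write_metadata(ds.meta, outdir / "input_metadata.tsv")
        return ds.taxa, ds.pathways, ds.stratified, ds.ar_markers, ds.marker_map, ds.meta
    if not (config.taxa_path and config.metadata_path):
        raise ValueError("config must provide either a preset or input paths "
                         "(taxa_path and metadata_path at minimum)")
    taxa = read_profile_table(config.taxa_path, "taxa")
    meta = read_metadata(config.metadata_path)
    pathways = stratified = ar = marker_map = None
    if config.pathways_path:
        pathways, stratified = read_profile_table(
            config.pathways_path, "pathway", split_stratified=True
        )
    if config.ar_markers_path and config.marker_map_path:
        ar = read_profile_table(config.ar_markers_path, "ar_marker")
        marker_map = pd.read_csv(config.marker_map_path, sep="\t", comment="#")
    return taxa, pathways, stratified, ar, marker_map, meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the stage results keyed by name."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    results: dict = {}
    stage = "setup"
    try:
        stage = "load-inputs"
        taxa, pathways, stratified, ar, marker_map, meta = _load_inputs(config, outdir)
        log.info("%s: %d samples, %d taxa rows", stage, len(meta.sample_ids),
                 len(taxa.feature_ids))

        stage = "sample-exclusions"
        taxa, meta, excl_report = apply_sample_exclusions(taxa, meta, config.min_depth)
        keep = taxa.sample_ids
        if pathways is not None:
            pathways = type(pathways)(pathways.data.loc[keep], pathways.kind)
            stratified = type(stratified)(stratified.data.loc[keep], stratified.kind)
        if ar is not None:
            ar = type(ar)(ar.data.loc[keep], ar.kind)
        _write(excl_report, outdir / "exclusions.tsv", cfg_hash)
        log.info("%s: %d removed, %d kept", stage, len(excl_report), len(keep))

        stage = "drug-usage-summary"
        usage = summarize_drug_usage(meta)
        write_usage_summary(usage, outdir / "drug_usage.tsv")
        results["usage"] = usage

        stage = "feature-engineering"
        props = taxa_to_proportions(taxa)
        endpoints, endpoint_report = extract_endpoints(props)
        filtered, filter_report = filter_taxa(
            endpoints, meta.cohorts, config.taxa_prevalence, config.taxa_mean_abundance
        )
        features_taxa = transform_taxa(filtered)
        taxa_reports = [r for r in (endpoint_report, filter_report) if not r.empty]
        _write(pd.concat(taxa_reports) if taxa_reports
               else pd.DataFrame(columns=["feature", "decision"]),
               outdir / "taxa_filters.tsv", cfg_hash)
        features_pwy = None
        if pathways is not None:
            features_pwy, pwy_report = prepare_pathways(
                pathways, meta.cohorts, config.pathway_prevalence
            )
            _write(pwy_report, outdir / "pathway_filters.tsv", cfg_hash)
        results["features_taxa"] = features_taxa
        results["features_pathways"] = features_pwy
        log.info("%s: %d end-points kept, %d pathways kept", stage,
                 features_taxa.data.shape[1],
                 0 if features_pwy is None else features_pwy.data.shape[1])

        stage = "community-ecology"
        h = shannon_per_sample(filtered.data)
        richness = richness_drug_associations(h, meta)
        _write(richness, outdir / "richness_associations.tsv", cfg_hash)
        dist = bray_curtis_matrix(filtered.data)
        perma_rows = []
        n_drugs = meta.drugs.sum(axis=1).astype(float).rename("n_drugs")
        for cohort, idx in meta.frame.groupby("cohort").groups.items():
            sub = dist.loc[idx, idx]
            variables = [("n_drugs", n_drugs.loc[idx])]
            for drug in config.permanova_drugs:
                variables.append((drug, meta.drugs.loc[idx, drug].astype("category")))
            for name, grouping in variables:
                if pd.Series(grouping).nunique() < 2:
                    continue
                res = permanova(sub, pd.Series(grouping, name=name),
                                config.n_permutations, seed=config.seed)
                perma_rows.append({"cohort": cohort, "variable": name,
                                   "r2": res.r2, "pseudo_f": res.pseudo_f,
                                   "p": res.p, "n_perm": res.n_permutations,
                                   "seed": config.seed})
        permadf = pd.DataFrame(perma_rows)
        _write(permadf, outdir / "permanova.tsv", cfg_hash)
        results["shannon"] = h
        results["permanova"] = permadf

        stage = "association-models"
        assoc_frames = []
        for mode in config.modes:
            t = run_cohort_associations(features_taxa, meta, mode, config.min_users)
            t["feature_kind"] = "taxa"
            assoc_frames.append(t)
            if features_pwy is not None:
                pw = run_cohort_associations(features_pwy, meta, mode, config.min_users)
                pw["feature_kind"] = "pathway"
                assoc_frames.append(pw)
        assoc = pd.concat(assoc_frames, ignore_index=True)
        _write(assoc, outdir / "cohort_associations.tsv", cfg_hash)
        results["associations"] = assoc

        stage = "meta-analysis"
        meta_frames = []
        for kind, grp in assoc.groupby("feature_kind"):
            m = meta_analyze(grp, family=("mode",),
                             fdr_significant=config.fdr_significant,
                             fdr_het_trigger=config.fdr_het_trigger)
            m["feature_kind"] = kind
            meta_frames.append(m)
        meta_table = pd.concat(meta_frames, ignore_index=True)
        _write(meta_table, outdir / "meta_associations.tsv", cfg_hash)
        results["meta"] = meta_table

        stage = "summary"
        sig = meta_table[meta_table["status"] == "significant"]
        summary = (
            sig.groupby(["mode", "feature_kind", "drug"])
            .size().rename("n_significant").reset_index()
        )
        _write(summary, outdir / "summary.tsv", cfg_hash)
        results["summary"] = summary

        if ar is not None and marker_map is not None:
            stage = "resistome"
            genes = aggregate_markers(ar, marker_map)
            ar_results, ar_relaxed = resistome_association(
                genes, meta, relaxed_fdr=config.relaxed_fdr
            )
            _write(ar_results, outdir / "resistome.tsv", cfg_hash)
            _write(ar_relaxed, outdir / "resistome_relaxed.tsv", cfg_hash)
            results["resistome"] = ar_results

        if config.run_posthoc and stratified is not None and not sig.empty:
            stage = "posthoc"
            contrib_frames = []
            contrast_rows = []
            pwy_hits = sig[sig["feature_kind"] == "pathway"]
            for _, row in pwy_hits.iterrows():
                try:
                    c = stratified_contribution_test(
                        stratified, row["feature"], meta, row["drug"]
                    )
                except ValueError:
                    continue
                c["drug"] = row["drug"]
                contrib_frames.append(c)
            for _, row in sig.iterrows():
                fm = (results["features_taxa"] if row["feature_kind"] == "taxa"
                      else results["features_pathways"])
                if fm is None or row["feature"] not in fm.data.columns:
                    continue
                y = fm.data[row["feature"]]
                for contrast in ("dose", "subtype"):
                    for r in group_contrast(y, meta, row["drug"], contrast):
                        contrast_rows.append({
                            "cohort": r.cohort, "feature": r.feature,
                            "drug": row["drug"], "contrast": r.contrast,
                            "group_a": r.group_a, "group_b": r.group_b,
                            "n_a": r.n_a, "n_b": r.n_b, "p": r.p,
                            "fdr": r.fdr, "direction": r.direction})
            if contrib_frames:
                _write(pd.concat(contrib_frames, ignore_index=True),
                       outdir / "pathway_contributions.tsv", cfg_hash)
            _write(pd.DataFrame(contrast_rows), outdir / "dose_subtype_contrasts.tsv",
                   cfg_hash)

        (outdir / "run.log").write_text(
            json.dumps({"config": asdict(config), "config_hash": cfg_hash,
                        "n_samples": len(keep),
                        "n_taxa_features": int(features_taxa.data.shape[1]),
                        "n_significant": int(len(sig))},
                       indent=2, default=str) + "\n"
        )
        return results
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
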