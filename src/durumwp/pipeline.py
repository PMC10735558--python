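"""End-to-end pipeline driver.

Chains phenotype processing, mega-environment clustering, AMMI/AWAI
stability, water-productivity classification, GWAS per context, QTL
assembly, haplotype effect testing and KASP-style validation; writes a
per-stage artifact set plus a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ammi as ammi_mod
from . import assoc, envclim, haplokasp, phenostats, waterprod
from . import io as dio

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    phenotype_file: str
    climate_file: str
    genotype_file: str | None = None       # HapMap TSV or VCF
    design: str = "augmented"
    mega_env_k: int = 2
    alpha_classification: float = 0.01
    alpha_ammi: float = 0.05
    alpha_lsd: float = 0.05
    lod_cutoff: float = 2.69
    r2_cutoff: float = 0.024
    merge_distance: float | None = None    # default: 2 × estimated LD distance
    freeze_group_slopes: bool = False
    n_extreme: int = 20
    n_qtl_for_haplotypes: int = 3
    seed: int = 0
    out_dir: str = "pipeline_out"

    def validate(self):
        for a in (self.alpha_classification, self.alpha_ammi, self.alpha_lsd):
            if not 0 < a < 1:
                raise ValueError("alpha levels must be in (0, 1)")
        for f in (self.phenotype_file, self.climate_file):
            if not Path(f).exists():
                raise FileNotFoundError(f)
        if self.genotype_file and not Path(self.genotype_file).exists():
            raise FileNotFoundError(self.genotype_file)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory result bundle and
    writes per-stage CSV/JSON artifacts plus a manifest under
    ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name, fn):
        logger.info("pipeline stage: %s", name)
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 - rewrap with stage context
            raise StageError(name, err) from err

    plots = stage("phenostats.load", lambda: dio.read_phenotypes(cfg.phenotype_file))
    plots = stage("phenostats.derive_components", lambda: phenostats.derive_components(plots))
    blues = stage("phenostats.compute_blues",
                  lambda: phenostats.compute_blues(plots, cfg.design))
    bundle["blues"] = blues
    blues.to_csv(out / "blues.csv", index=False)

    varpart = stage("phenostats.variance_partition",
                    lambda: phenostats.variance_partition(plots, "GY"))
    bundle["variance_partition"] = varpart
    dio.write_json({k: v for k, v in dataclasses.asdict(varpart).items()},
                   out / "variance_partition.json")

    climate = stage("envclim.load", lambda: dio.read_climate(cfg.climate_file))
    gy = blues[blues["trait"] == "GY"]
    env_mean_gy = gy.groupby("environment_id")["value"].mean()
    climreg = stage("envclim.climate_regression",
                    lambda: envclim.climate_regression(climate, env_mean_gy))
    assignment = stage("envclim.cluster_environments",
                       lambda: envclim.cluster_environments(climate, climreg, k=cfg.mega_env_k))
    bundle["climate_regression"] = climreg
    bundle["assignment"] = assignment
    climreg.to_csv(out / "climate_regression.csv", index=False)
    assignment.to_csv(out / "mega_environments.csv", index=False)

    corr = stage("phenostats.trait_gy_correlations",
                 lambda: phenostats.trait_gy_correlations(blues, assignment=assignment))
    corr.to_csv(out / "trait_gy_correlations.csv", index=False)
    bundle["correlations"] = corr

    two_way = gy.pivot_table(index="genotype_id", columns="environment_id", values="value")
    res = stage("ammi.fit", lambda: ammi_mod.awai(
        ammi_mod.fit_ammi(two_way, alpha=cfg.alpha_ammi)))
    ratio = phenostats.ratio_to_max(blues, "GY")
    surface = stage("ammi.selection_surface", lambda: ammi_mod.selection_surface(
        ratio.reindex(res.awai.index), res.awai))
    bundle["ammi"] = res
    bundle["selection_surface"] = surface
    surface.to_csv(out / "selection_surface.csv")
    pd.DataFrame({"awai": res.awai, "awai_ratio_to_min": res.awai_ratio_to_min}).to_csv(
        out / "awai.csv")

    moisture = climate.groupby("environment_id")["total_moisture"].first()
    counts = assignment["group"].value_counts()
    if counts.min() < 3 or counts.size < 2:
        # a cluster too small to regress cannot anchor group slopes;
        # fall back to the moisture pivot
        logger.warning("pipeline: degenerate mega-environment clustering (%s); "
                       "reassigning groups by the %d mm moisture pivot",
                       counts.to_dict(), int(envclim.MOISTURE_PIVOT_MM))
        assignment = pd.DataFrame({
            "environment_id": moisture.index,
            "group": np.where(moisture < envclim.MOISTURE_PIVOT_MM,
                              "moisture_stressed", "non_moisture_stressed"),
        })
        bundle["assignment"] = assignment
        assignment.to_csv(out / "mega_environments.csv", index=False)
    slopes = (waterprod.GroupSlopes() if cfg.freeze_group_slopes
              else stage("waterprod.group_slopes",
                         lambda: waterprod.group_slopes(env_mean_gy, moisture, assignment)))
    profile = stage("waterprod.classify", lambda: waterprod.classify_genotypes(
        blues, moisture, assignment, slopes, alpha=cfg.alpha_classification))
    bundle["group_slopes"] = slopes
    bundle["wp_profile"] = profile
    profile.to_csv(out / "wp_profile.csv", index=False)
    dio.write_json(waterprod.class_frequencies(profile).to_dict(), out / "wp_class_freq.json")

    if cfg.genotype_file:
        _genetics_stages(cfg, stage, bundle, out, blues, assignment, moisture)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_genotypes": int(gy["genotype_id"].nunique()),
        "n_environments": int(gy["environment_id"].nunique()),
        "stages": sorted(bundle.keys()),
    }
    dio.write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def _genetics_stages(cfg, stage, bundle, out, blues, assignment, moisture):
    gfile = str(cfg.genotype_file)
    if gfile.endswith(".vcf") or gfile.endswith(".vcf.gz"):
        dosage, marker_map = stage("assoc.read_vcf", lambda: dio.read_vcf(gfile))
    else:
        dosage, marker_map = stage("assoc.read_hapmap", lambda: dio.read_hapmap(gfile))
    panel = assoc.MarkerPanel(dosage=dosage, marker_map=marker_map)
    panel, report = stage("assoc.curate_markers", lambda: assoc.curate_markers(panel))
    bundle["curation_report"] = report
    Q, K = stage("assoc.structure_and_kinship", lambda: assoc.structure_and_kinship(panel))

    try:
        ld = stage("assoc.ld_decay", lambda: assoc.ld_decay(panel, critical_r2=cfg.r2_cutoff))
        bundle["ld"] = ld
        ld.curve.to_csv(out / "ld_decay.csv", index=False)
    except StageError:
        ld = None
    merge_distance = cfg.merge_distance
    if merge_distance is None:
        merge_distance = 2 * ld.ld_distance if ld is not None else 102.6e6

    gy = blues[blues["trait"] == "GY"]
    dth = blues[blues["trait"] == "DTH"]
    dth_mean = (dth.groupby("genotype_id")["value"].mean()
                if not dth.empty else None)
    gmap = assignment.set_index("environment_id")["group"]
    thresholds = assoc.SignificanceThresholds(lod_cutoff=cfg.lod_cutoff,
                                              r2_cutoff=cfg.r2_cutoff)

    contexts: dict[str, pd.Series] = {}
    for grp, sub in gy.assign(group=gy["environment_id"].map(gmap)).groupby("group"):
        contexts[f"combined_{grp}"] = sub.groupby("genotype_id")["value"].mean()
    for eid, sub in gy.groupby("environment_id"):
        contexts[str(eid)] = sub.set_index("genotype_id")["value"]

    mtas = []
    scans = {}
    for ctx, pheno in contexts.items():
        cov = (dth_mean.rename("DTH").to_frame()
               if dth_mean is not None else None)
        scan = stage(f"assoc.gwas[{ctx}]", lambda p=pheno, c=ctx, cv=cov: assoc.gwas(
            panel, p, Q=Q, covariates=cv, K=K, model="auto", context=c))
        scans[ctx] = scan
        mtas.append(assoc.significant_mtas(scan, thresholds))
    mta_table = pd.concat(mtas, ignore_index=True) if mtas else pd.DataFrame()
    bundle["mtas"] = mta_table
    mta_table.to_csv(out / "mtas.csv", index=False)

    combined_ctx = {c for c in contexts if c.startswith("combined_")}
    qtl = stage("assoc.assemble_qtl", lambda: assoc.assemble_qtl(
        mta_table, merge_distance, combined_contexts=combined_ctx))
    bundle["qtl"] = qtl
    qtl.to_csv(out / "qtl.csv", index=False)

    if qtl.empty:
        logger.info("pipeline: no QTL found; haplotype/KASP stages skipped")
        return
    top_qtl = qtl.sort_values("n_mtas", ascending=False).head(cfg.n_qtl_for_haplotypes)
    rep_markers = top_qtl["representative_marker"].tolist()
    mta_idx = mta_table.set_index(["marker_id", "context"])
    sign = {}
    for m in rep_markers:
        eff = mta_table[mta_table["marker_id"] == m]["effect"]
        sign[m] = +1 if eff.mean() >= 0 else -1

    try:
        haplos = stage("haplokasp.build_haplotypes", lambda: haplokasp.build_haplotypes(
            panel.dosage, rep_markers, sign))
    except StageError as err:
        logger.warning("haplotype stage skipped: %s", err)
        return
    bundle["haplotypes"] = haplos
    haplos.to_csv(out / "haplotypes.csv", index=False)

    gy_mean = gy.groupby("genotype_id")["value"].mean()
    try:
        effects = stage("haplokasp.effect_test", lambda: haplokasp.haplotype_effect_test(
            haplos, gy_mean, alpha=cfg.alpha_lsd))
        bundle["haplotype_effects"] = effects
        effects.to_csv(out / "haplotype_effects.csv", index=False)
    except StageError as err:
        logger.warning("haplotype effect test skipped: %s", err)

    try:
        metrics = stage("haplokasp.kasp_validate", lambda: haplokasp.kasp_validate_panel(
            panel.dosage, gy_mean, rep_markers, sign, n_extreme=cfg.n_extreme))
        bundle["kasp_metrics"] = metrics
        metrics.to_csv(out / "kasp_metrics.csv", index=False)
    except StageError as err:
        logger.warning("KASP validation skipped: %s", err)
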