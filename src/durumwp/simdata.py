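"""Synthetic multi-environment trial generator.

Emulates the statistical structure of a Mediterranean durum wheat trial
network: a few hundred inbred genotypes grown across 10-20 environments
whose total in-season moisture spans roughly 200-650 mm, with the
environment main effect dominating the variance of grain yield
(E >> G×E > G), per-genotype moisture-response slopes around distinct
group-level trends in moisture-stressed vs non-stressed environments,
and a handful of biallelic QTL whose effects interact with moisture.

Everything is driven by one explicitly threaded ``numpy.random.Generator``;
fixed seed implies byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import GROUP_SLOPE_NONSTRESSED, GROUP_SLOPE_STRESSED

logger = logging.getLogger(__name__)

#: Moisture (mm) separating stressed from non-stressed environments.
MOISTURE_PIVOT_MM = 400.0

#: Growth-stage windows carried by the climate table.
GROWTH_STAGES = ("pre_sowing", "vegetative", "flowering", "grain_fill", "maturity")

# Mean share of total moisture falling in each growth-stage window.
_STAGE_MOISTURE_SHARES = np.array([0.10, 0.35, 0.20, 0.25, 0.10])

WP_CLASS_NAMES = {
    1: "Stable water response",
    2: "Responsive to low moisture",
    3: "Responsive to high moisture",
    4: "Highly water responsive",
    5: "No water response",
}


@dataclass
class SimConfig:
    """Configuration of one synthetic trial network.

    Variances are plot-level variance components in (kg/ha)^2; their
    relative sizes set the target G / E / G×E / residual shares of the
    total sum of squares.  Defaults reproduce the canonical structure of
    the study system: E share ~0.73, G ~0.10, G×E ~0.12, residual ~0.05.
    """

    n_genotypes: int = 200
    n_environments: int = 18
    moisture_range: tuple[float, float] = (200.0, 650.0)
    n_markers: int = 1500
    n_chromosomes: int = 14
    chromosome_length: int = 600_000_000
    n_qtl: int = 6
    qtl_main_effect: float = 120.0          # kg/ha per allele
    qtl_moisture_interaction: float = 0.8   # kg/ha/mm per allele
    n_subpopulations: int = 2
    var_G: float = 100_000.0
    var_E: float = 730_000.0
    var_GxE: float = 120_000.0
    var_resid: float | None = 50_000.0
    heritability_target: float = 0.8
    design: str = "augmented"               # or "alpha_lattice"
    n_checks: int = 4
    n_blocks: int = 12
    seed: int = 0
    # genome realism knobs
    maf_floor: float = 0.05
    het_call_rate: float = 0.02
    missing_rate: float = 0.0
    n_violating_markers: int = 0
    subpop_drift: float = 0.15              # Fst-like divergence
    ld_block_length: float = 30e6           # bp scale of founder mosaics
    n_founders: int = 24
    # trial structure knobs
    grand_mean_gy: float = 3500.0           # kg/ha
    group_slope_stressed: float = GROUP_SLOPE_STRESSED
    group_slope_nonstressed: float = GROUP_SLOPE_NONSTRESSED
    frac_unresponsive: float = 0.0          # planted class-5 genotypes
    gxe_slope_share: float = 0.15           # G×E fraction in moisture-slope deviations
    trait_gy_correlation: float = 0.5

    def validate(self) -> None:
        for name in ("var_G", "var_E", "var_GxE"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.var_resid is not None and self.var_resid < 0:
            raise ValueError("var_resid must be >= 0")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl must not exceed n_markers")
        lo, hi = self.moisture_range
        if not lo < hi:
            raise ValueError("moisture_range must satisfy min < max")
        if not 0 < self.heritability_target <= 1:
            raise ValueError("heritability_target must be in (0, 1]")
        if self.design not in ("augmented", "alpha_lattice"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class SimTruth:
    """Ground truth planted by the generator."""

    qtl_markers: list[str]
    qtl_positions: list[tuple[str, int]]
    qtl_allele_effects: list[tuple[float, float]]   # (main, moisture interaction)
    genotype_slopes: pd.DataFrame   # genotype_id, b_stressed, b_nonstressed
    class_labels: pd.Series         # genotype_id -> 1..5
    subpopulation_assignment: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "qtl_markers": self.qtl_markers,
            "qtl_positions": [[c, int(p)] for c, p in self.qtl_positions],
            "qtl_allele_effects": [list(map(float, e)) for e in self.qtl_allele_effects],
            "genotype_slopes": self.genotype_slopes.to_dict(orient="list"),
            "class_labels": {k: int(v) for k, v in self.class_labels.items()},
            "subpopulation_assignment": {k: int(v) for k, v in self.subpopulation_assignment.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _genotype_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Simulate an inbred-line dosage matrix with structure and local LD.

    Returns ``(dosage, marker_map, subpop)`` where ``dosage`` is a
    genotype × marker DataFrame of 0/1/2 calls (NaN = missing),
    ``marker_map`` has columns marker_id/chromosome/position/alleles and
    ``subpop`` maps genotype to subpopulation index.

    Mechanics: per-marker ancestral frequencies are drifted between
    subpopulations (Balding-Nichols beta model); each line's single
    haplotype is a mosaic of founder haplotypes with switch probability
    growing with inter-marker distance, which induces LD on the scale of
    ``ld_block_length``; the haplotype is doubled (inbreds) and a small
    fraction of calls is made heterozygous.  A built-in curation pass
    drops markers below the MAF floor; ``n_violating_markers`` rule
    violators (low MAF or high heterozygosity) are then appended so that
    downstream curation can be exercised.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_g, n_m = cfg.n_genotypes, cfg.n_markers
    genos = _genotype_ids(n_g)
    subpop = rng.integers(0, cfg.n_subpopulations, size=n_g)

    # marker map: even split across chromosomes, sorted positions
    chroms = np.repeat(np.arange(cfg.n_chromosomes), _chrom_counts(n_m, cfg.n_chromosomes))
    positions = np.empty(n_m, dtype=np.int64)
    for c in range(cfg.n_chromosomes):
        idx = np.flatnonzero(chroms == c)
        pos = np.sort(rng.integers(1, cfg.chromosome_length + 1, size=idx.size))
        positions[idx] = pos
    chrom_names = [f"chr{c + 1}" for c in chroms]

    p0 = rng.uniform(0.15, 0.85, size=n_m)
    F = max(cfg.subpop_drift, 1e-6)
    a, b = p0 * (1 - F) / F, (1 - p0) * (1 - F) / F
    pop_freq = np.stack(
        [np.clip(rng.beta(a, b), 0.01, 0.99) for _ in range(cfg.n_subpopulations)]
    )  # (n_subpop, n_m)

    # founder haplotypes per subpopulation, generated as Markov chains
    # along each chromosome (allele copied from the previous marker with
    # probability exp(-d/L)) so founders carry block-scale LD
    founders = np.empty((cfg.n_subpopulations, cfg.n_founders, n_m), dtype=np.int8)
    fresh = (rng.random((cfg.n_subpopulations, cfg.n_founders, n_m))
             < pop_freq[:, None, :]).astype(np.int8)
    for c in range(cfg.n_chromosomes):
        idx = np.flatnonzero(chroms == c)
        d = np.diff(positions[idx].astype(float), prepend=np.inf)
        persist = np.exp(-d / cfg.ld_block_length)
        persist[0] = 0.0
        keep = rng.random((cfg.n_subpopulations, cfg.n_founders, idx.size)) < persist[None, None, :]
        founders[:, :, idx[0]] = fresh[:, :, idx[0]]
        for j in range(1, idx.size):
            founders[:, :, idx[j]] = np.where(
                keep[:, :, j], founders[:, :, idx[j - 1]], fresh[:, :, idx[j]]
            )

    # mosaic assembly: each line copies one founder, switching founder
    # with probability 1 - exp(-d / L)
    hap = np.empty((n_g, n_m), dtype=np.int8)
    for c in range(cfg.n_chromosomes):
        idx = np.flatnonzero(chroms == c)
        d = np.diff(positions[idx].astype(float), prepend=-np.inf)
        p_switch = 1.0 - np.exp(-d / cfg.ld_block_length)
        p_switch[0] = 1.0
        switch = rng.random((n_g, idx.size)) < p_switch[None, :]
        draws = rng.integers(0, cfg.n_founders, size=(n_g, idx.size))
        # carry the founder forward between switch points
        founder_idx = np.where(switch, draws, 0)
        for j in range(1, idx.size):
            carry = ~switch[:, j]
            founder_idx[carry, j] = founder_idx[carry, j - 1]
        hap[:, idx] = founders[subpop[:, None], founder_idx, idx[None, :]]

    dosage = (2 * hap).astype(float)
    het = rng.random(dosage.shape) < cfg.het_call_rate
    dosage[het] = 1.0
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = np.nan

    # built-in curation: MAF floor, heterozygosity cap, missingness cap
    freq = np.nanmean(dosage, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    het = np.nanmean(dosage == 1.0, axis=0)
    miss = np.isnan(dosage).mean(axis=0)
    keep = (maf >= cfg.maf_floor) & (het <= 0.05) & (miss < 0.01)
    logger.info("simulate_genotypes: curation kept %d/%d markers", keep.sum(), n_m)

    marker_ids = np.array([f"AXS-{c + 1:02d}{i:05d}" for i, c in enumerate(chroms)])
    dosage = dosage[:, keep]
    marker_map = pd.DataFrame(
        {
            "marker_id": marker_ids[keep],
            "chromosome": np.array(chrom_names)[keep],
            "position": positions[keep],
            "alleles": "A/B",
        }
    )

    if cfg.n_violating_markers > 0:
        dosage, marker_map = _append_violators(cfg, rng, dosage, marker_map)

    order = np.lexsort((marker_map["position"].to_numpy(),
                        marker_map["chromosome"].to_numpy()))
    marker_map = marker_map.iloc[order].reset_index(drop=True)
    dosage = dosage[:, order]

    dosage_df = pd.DataFrame(dosage, index=genos, columns=marker_map["marker_id"].tolist())
    subpop_s = pd.Series(subpop, index=genos, name="subpopulation")
    return dosage_df, marker_map, subpop_s


def _chrom_counts(n_m: int, n_c: int) -> np.ndarray:
    counts = np.full(n_c, n_m // n_c)
    counts[: n_m % n_c] += 1
    return counts


def _append_violators(cfg, rng, dosage, marker_map):
    """Append markers that deliberately violate curation rules."""
    n_g = dosage.shape[0]
    n_v = cfg.n_violating_markers
    cols = []
    rows = []
    for k in range(n_v):
        if k % 2 == 0:  # rare-allele marker: MAF ~ 1/n < floor
            col = np.zeros(n_g)
            col[rng.integers(0, n_g)] = 2.0
        else:           # hyper-heterozygous marker
            col = rng.choice([0.0, 2.0], size=n_g)
            het_idx = rng.choice(n_g, size=max(1, int(0.2 * n_g)), replace=False)
            col[het_idx] = 1.0
        cols.append(col)
        rows.append(
            {
                "marker_id": f"VIO-{k:04d}",
                "chromosome": f"chr{rng.integers(1, cfg.n_chromosomes + 1)}",
                "position": int(rng.integers(1, cfg.chromosome_length + 1)),
                "alleles": "A/B",
            }
        )
    dosage = np.concatenate([dosage, np.column_stack(cols)], axis=1)
    marker_map = pd.concat([marker_map, pd.DataFrame(rows)], ignore_index=True)
    return dosage, marker_map


# ---------------------------------------------------------------------------
# trials


def _environment_moisture(cfg: SimConfig, rng) -> pd.DataFrame:
    """Total moisture per environment, quantile-matched to the real
    18-environment Mediterranean network (a right-shifted mass of
    moisture-stressed sites below 400 mm), rescaled to the configured
    range."""
    from .reference import discovery_environments

    lo, hi = cfg.moisture_range
    ref = np.sort(discovery_environments()["total_moisture"].to_numpy())
    q = np.linspace(0.0, 1.0, cfg.n_environments)
    base = np.quantile(ref, q)
    base = lo + (base - ref.min()) * (hi - lo) / (ref.max() - ref.min())
    jitter = rng.uniform(-0.25, 0.25, cfg.n_environments) * (hi - lo) / max(
        cfg.n_environments - 1, 1)
    moist = np.clip(base + jitter, lo, hi)
    env_ids = [f"E{j + 1:02d}" for j in range(cfg.n_environments)]
    group = np.where(moist < MOISTURE_PIVOT_MM, "moisture_stressed", "non_moisture_stressed")
    return pd.DataFrame({"environment_id": env_ids, "total_moisture": moist, "group": group})


def true_wp_class(b_s: float, b_ns: float, slope_s: float, slope_ns: float,
                  responsive: bool = True) -> int:
    """Map a pair of true slopes onto the five-class rule (ties go to <=)."""
    if not responsive:
        return 5
    hi_s, hi_ns = b_s > slope_s, b_ns > slope_ns
    if hi_s and not hi_ns:
        return 2
    if not hi_s and hi_ns:
        return 3
    if hi_s and hi_ns:
        return 4
    return 1


def simulate_trials(cfg: SimConfig, dosage: pd.DataFrame,
                    subpop: pd.Series | None = None,
                    marker_map: pd.DataFrame | None = None,
                    rng: np.random.Generator | None = None):
    """Simulate plot-level phenotypes, the climate table and ground truth.

    Plot grain yield is built as grand mean + genotype effect +
    environment effect (affine in moisture, with a distinct slope per
    moisture group) + genotype-specific slope deviation × centred
    moisture + unstructured G×E noise + QTL main and QTL×moisture
    effects + block effect + residual.  TKW/SPK/DTH are generated with a
    configurable genetic correlation to the GY genotype effect.

    Returns ``(plots, climate, truth)``.
    """
    cfg.validate()
    if cfg.var_E == 0:
        raise ValueError("var_E must be > 0 when moisture-driven environment effects are requested")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    genos = list(dosage.index)
    n_g = len(genos)

    env = _environment_moisture(cfg, rng)
    moist = env["total_moisture"].to_numpy()
    stressed = env["group"].to_numpy() == "moisture_stressed"

    # environment main effect: affine in moisture within each group
    e_eff = np.empty(cfg.n_environments)
    e_eff[stressed] = cfg.group_slope_stressed * moist[stressed]
    e_eff[~stressed] = cfg.group_slope_nonstressed * moist[~stressed] - (
        (cfg.group_slope_nonstressed - cfg.group_slope_stressed) * MOISTURE_PIVOT_MM
    )  # continuous at the pivot
    e_eff -= e_eff.mean()
    var_E_real = float(np.var(e_eff))

    # rescale the other components so variance *shares* match the config
    scale = var_E_real / cfg.var_E if cfg.var_E > 0 else 1.0
    var_G = cfg.var_G * scale
    var_GxE = cfg.var_GxE * scale
    if cfg.var_resid is None:
        r = 2 if cfg.design == "alpha_lattice" else 1
        h = cfg.heritability_target
        var_res = r * var_G * (1 - h) / h
    else:
        var_res = cfg.var_resid * scale

    m_center = np.empty(cfg.n_environments)
    m_center[stressed] = moist[stressed] - moist[stressed].mean()
    m_center[~stressed] = moist[~stressed] - moist[~stressed].mean()
    var_m = float(np.mean(m_center ** 2))

    # QTL layer (its variance counts against the var_G / var_GxE budgets)
    qtl_markers, qtl_eff = [], []
    qtl_contrib = np.zeros(n_g)
    qtl_slope_contrib = np.zeros(n_g)
    if cfg.n_qtl > 0 and dosage.shape[1] > 0:
        n_qtl = min(cfg.n_qtl, dosage.shape[1])
        pick = np.linspace(0, dosage.shape[1] - 1, n_qtl).round().astype(int)
        qtl_markers = [dosage.columns[i] for i in pick]
        X = dosage[qtl_markers].to_numpy(dtype=float)
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X) - 1.0  # centred dosage
        mains = np.full(n_qtl, cfg.qtl_main_effect)
        inters = np.full(n_qtl, cfg.qtl_moisture_interaction)
        qtl_contrib = X @ mains                       # (n_g,)
        qtl_slope_contrib = X @ inters                # per-genotype slope add-on
        # QTL variance may not exceed its component budget
        v_main = float(np.var(qtl_contrib))
        if v_main > var_G > 0 or var_G == 0:
            sc = np.sqrt(var_G / v_main) if v_main > 0 else 0.0
            mains, qtl_contrib = mains * sc, qtl_contrib * sc
        v_slope = float(np.var(qtl_slope_contrib)) * var_m
        slope_budget = cfg.gxe_slope_share * var_GxE
        if (v_slope > slope_budget > 0) or slope_budget == 0:
            sc = (np.sqrt(slope_budget / v_slope) if v_slope > 0 else 0.0)
            inters, qtl_slope_contrib = inters * sc, qtl_slope_contrib * sc
        qtl_eff = list(zip(mains, inters))

    # polygenic main effect fills the remaining var_G budget
    var_g_poly = max(var_G - float(np.var(qtl_contrib)), 0.0)
    g_eff = rng.normal(0.0, np.sqrt(var_g_poly), n_g)

    # G×E: a configurable share from genotype-specific moisture-slope
    # deviations (QTL interaction counts against that budget), the rest
    # as unstructured noise
    var_qtl_slope = float(np.var(qtl_slope_contrib)) * var_m
    slope_budget = cfg.gxe_slope_share * var_GxE
    sd_slope = (np.sqrt(max(slope_budget - var_qtl_slope, 0.0) / var_m)
                if var_GxE > 0 and var_m > 0 else 0.0)
    slope_dev = rng.normal(0.0, sd_slope, n_g)
    unresp = rng.random(n_g) < cfg.frac_unresponsive
    gxe_noise = rng.normal(0.0, np.sqrt((1.0 - cfg.gxe_slope_share) * var_GxE),
                           (n_g, cfg.n_environments))

    b_s = cfg.group_slope_stressed + slope_dev + np.atleast_1d(qtl_slope_contrib)
    b_ns = cfg.group_slope_nonstressed + slope_dev + np.atleast_1d(qtl_slope_contrib)
    b_s = np.where(unresp, 0.0, b_s)
    b_ns = np.where(unresp, 0.0, b_ns)

    # cell means (genotype × environment)
    total_slope = slope_dev + np.atleast_1d(qtl_slope_contrib)
    cell = (
        cfg.grand_mean_gy
        + g_eff[:, None]
        + np.atleast_1d(qtl_contrib)[:, None]
        + e_eff[None, :]
        + np.where(unresp[:, None],
                   -e_eff[None, :] * 0.0,  # unresponsive keep flat genotype deviation
                   total_slope[:, None] * m_center[None, :])
        + gxe_noise
    )
    # unresponsive genotypes: cancel the shared environment trend for them
    if unresp.any():
        cell[unresp, :] = (
            cfg.grand_mean_gy + g_eff[unresp, None]
            + np.atleast_1d(qtl_contrib)[unresp][:, None]
            + gxe_noise[unresp, :]
        )

    plots = _layout_plots(cfg, rng, genos, env, cell, var_res)
    plots = _add_secondary_traits(cfg, rng, plots, g_eff, genos)
    climate = _climate_table(cfg, rng, env)

    classes = pd.Series(
        [
            true_wp_class(bs, bn, cfg.group_slope_stressed, cfg.group_slope_nonstressed,
                          responsive=not u)
            for bs, bn, u in zip(b_s, b_ns, unresp)
        ],
        index=genos,
        name="wp_class",
    )
    if subpop is None:
        subpop = pd.Series(np.zeros(n_g, dtype=int), index=genos, name="subpopulation")
    if marker_map is not None and qtl_markers:
        mm = marker_map.set_index("marker_id")
        qtl_positions = [(mm.loc[m, "chromosome"], int(mm.loc[m, "position"])) for m in qtl_markers]
    else:
        qtl_positions = [("NA", 0) for _ in qtl_markers]
    truth = SimTruth(
        qtl_markers=list(qtl_markers),
        qtl_positions=qtl_positions,
        qtl_allele_effects=[(float(a), float(b)) for a, b in qtl_eff],
        genotype_slopes=pd.DataFrame(
            {"genotype_id": genos, "b_stressed": b_s, "b_nonstressed": b_ns}
        ),
        class_labels=classes,
        subpopulation_assignment=subpop,
    )
    return plots, climate, truth


def _layout_plots(cfg, rng, genos, env, cell, var_res):
    """Emit plot records under the configured field design."""
    sd = np.sqrt(var_res)
    rows = []
    cell_df = pd.DataFrame(cell, index=genos, columns=env["environment_id"])
    checks = genos[: cfg.n_checks]
    tests = genos[cfg.n_checks:] if cfg.design == "augmented" else genos
    for _, erow in env.iterrows():
        eid = erow["environment_id"]
        block_eff = rng.normal(0.0, 0.3 * sd if sd > 0 else 0.0, cfg.n_blocks)
        if cfg.design == "augmented":
            per_block = np.array_split(np.arange(len(tests)), cfg.n_blocks)
            for b in range(cfg.n_blocks):
                bid = f"B{b + 1:02d}"
                for g in checks:
                    y = cell_df.loc[g, eid] + block_eff[b] + rng.normal(0, sd)
                    rows.append((g, eid, bid, True, y))
                for gi in per_block[b]:
                    g = tests[gi]
                    y = cell_df.loc[g, eid] + block_eff[b] + rng.normal(0, sd)
                    rows.append((g, eid, bid, False, y))
        else:  # alpha_lattice: 2 replicates, n_blocks incomplete blocks each
            for rep in (1, 2):
                rep_eff = rng.normal(0.0, 0.2 * sd if sd > 0 else 0.0)
                order = rng.permutation(len(tests))
                per_block = np.array_split(order, cfg.n_blocks)
                iblock_eff = rng.normal(0.0, 0.3 * sd if sd > 0 else 0.0, cfg.n_blocks)
                for b in range(cfg.n_blocks):
                    bid = f"R{rep}B{b + 1:02d}"
                    for gi in per_block[b]:
                        g = tests[gi]
                        y = cell_df.loc[g, eid] + rep_eff + iblock_eff[b] + rng.normal(0, sd)
                        rows.append((g, eid, bid, False, y))
    plots = pd.DataFrame(
        rows, columns=["genotype_id", "environment_id", "block_id", "is_check", "GY"]
    )
    plots["GY"] = plots["GY"].clip(lower=0.0)
    if cfg.design == "alpha_lattice":
        plots["replicate"] = plots["block_id"].str[:2]
    else:
        plots["replicate"] = "R1"
    return plots


def _add_secondary_traits(cfg, rng, plots, g_eff, genos):
    """TKW, SPK, DTH, harvested weight with genetic correlation to GY."""
    rho = cfg.trait_gy_correlation
    gz = (g_eff - g_eff.mean()) / (g_eff.std() + 1e-12)
    gmap = dict(zip(genos, gz))
    z = plots["genotype_id"].map(gmap).to_numpy()
    n = len(plots)

    def corr_trait(mean, sd_g, sd_e):
        indep = rng.normal(0.0, 1.0, n)
        return mean + sd_g * (rho * z + np.sqrt(max(1 - rho ** 2, 0.0)) * indep) + rng.normal(0, sd_e, n)

    plots = plots.copy()
    plots["TKW"] = np.clip(corr_trait(40.0, 3.0, 1.5), 15.0, None)
    plots["SPK"] = np.clip(corr_trait(350.0, 40.0, 25.0), 50.0, None)
    plots["DTH"] = np.clip(corr_trait(100.0, 5.0, 1.0), 70.0, None).round()
    plots["plot_area"] = 6.0
    # harvested weight consistent with GY over the plot area: kg/ha -> g
    plots["harvested_weight"] = plots["GY"] * plots["plot_area"] * 0.1  # g per plot
    return plots


def _climate_table(cfg, rng, env) -> pd.DataFrame:
    """Five growth-stage moisture splits plus stage max temperatures."""
    rows = []
    for _, erow in env.iterrows():
        shares = _STAGE_MOISTURE_SHARES + rng.uniform(-0.02, 0.02, 5)
        shares = np.clip(shares, 0.01, None)
        shares /= shares.sum()
        moist = erow["total_moisture"] * shares
        # hotter where drier, with noise
        tmax = 28.0 - 0.015 * (erow["total_moisture"] - 400.0) + rng.normal(0, 1.0, 5) \
            + np.array([-4.0, -2.0, 2.0, 4.0, 6.0])
        for s, stage in enumerate(GROWTH_STAGES):
            rows.append((erow["environment_id"], stage, "moisture", float(moist[s]),
                         erow["total_moisture"]))
            rows.append((erow["environment_id"], stage, "max_temperature", float(tmax[s]),
                         erow["total_moisture"]))
    return pd.DataFrame(
        rows, columns=["environment_id", "stage", "variable", "value", "total_moisture"]
    )


def simulate_dataset(cfg: SimConfig):
    """One-call convenience: genotypes + trials + truth."""
    rng = np.random.default_rng(cfg.seed)
    dosage, marker_map, subpop = simulate_genotypes(cfg, rng)
    plots, climate, truth = simulate_trials(cfg, dosage, subpop, marker_map, rng)
    return dosage, marker_map, plots, climate, truth


# ---------------------------------------------------------------------------
# focused generator for water-productivity classification studies


def simulate_wp_panel(
    n_per_class: int = 20,
    n_null: int = 20,
    slope_offset: float = 1.5,
    noise_sd: float = 100.0,
    base_gy: float = 1200.0,
    environments: pd.DataFrame | None = None,
    slope_stressed: float = GROUP_SLOPE_STRESSED,
    slope_nonstressed: float = GROUP_SLOPE_NONSTRESSED,
    seed: int = 0,
):
    """Plant genotypes in each of the four responsive classes (slopes
    offset ±``slope_offset`` kg/ha/mm from the group trends) plus
    ``n_null`` moisture-unresponsive genotypes, and emit per-environment
    genotype-mean GY with Gaussian noise.

    Returns ``(gy_long, environments, true_classes)`` where ``gy_long``
    has columns genotype_id/environment_id/trait/value.
    """
    rng = np.random.default_rng(seed)
    if environments is None:
        from .reference import discovery_environments

        environments = discovery_environments()
    env = environments
    moist = env["total_moisture"].to_numpy()
    stressed = env["group"].to_numpy() == "moisture_stressed"

    # class -> (offset sign stressed, offset sign non-stressed)
    signs = {1: (-1, -1), 2: (+1, -1), 3: (-1, +1), 4: (+1, +1)}
    rows, true_cls = [], {}
    gi = 0
    for cls, (ss, sn) in signs.items():
        for _ in range(n_per_class):
            gid = f"W{gi:04d}"
            gi += 1
            bs = slope_stressed + ss * slope_offset
            bn = slope_nonstressed + sn * slope_offset
            mu = np.where(stressed, bs * moist, bn * moist - (bn - bs) * MOISTURE_PIVOT_MM)
            y = base_gy + mu + rng.normal(0, noise_sd, len(moist))
            rows.extend(zip([gid] * len(moist), env["environment_id"], y))
            true_cls[gid] = cls
    for _ in range(n_null):
        gid = f"W{gi:04d}"
        gi += 1
        y = base_gy + np.mean(moist) * slope_stressed + rng.normal(0, noise_sd, len(moist))
        rows.extend(zip([gid] * len(moist), env["environment_id"], y))
        true_cls[gid] = 5
    gy = pd.DataFrame(rows, columns=["genotype_id", "environment_id", "value"])
    gy["trait"] = "GY"
    return gy, env, pd.Series(true_cls, name="wp_class")
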