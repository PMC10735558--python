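"""Plot-level phenotype processing.

Derived yield components, design-adjusted per-environment genotype means
(BLUEs) for augmented and alpha-lattice layouts, sum-of-squares variance
partition with broad-sense heritability, ratio-to-max scaling, and
trait-vs-grain-yield correlation tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRAITS = ("GY", "TKW", "SPK", "GpS", "DTH")


def derive_components(records: pd.DataFrame) -> pd.DataFrame:
    """Add grains/m² (Grm2) and grains/spike (GpS) columns.

    Grm2 = harvested_weight / (plot_area × TKW/1000) with harvested
    weight in grams, plot area in m² and TKW the 1000-kernel weight in
    grams; GpS = Grm2 / SPK.  Missing inputs leave the component absent
    (NaN) for that plot; a measured GpS column is never overwritten.
    """
    out = records.copy()
    hw = out.get("harvested_weight")
    area = out.get("plot_area")
    tkw = out.get("TKW")
    if hw is not None and area is not None and tkw is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            grm2 = hw / (area * tkw / 1000.0)
        grm2 = grm2.where((area > 0) & (tkw > 0))
        out["Grm2"] = grm2
        n_missing = int(grm2.isna().sum())
        if n_missing:
            logger.info("derive_components: Grm2 absent for %d plots", n_missing)
    else:
        logger.info("derive_components: inputs for Grm2 missing; column not derived")
        if "Grm2" not in out:
            out["Grm2"] = np.nan

    spk = out.get("SPK")
    if spk is not None and "Grm2" in out:
        with np.errstate(divide="ignore", invalid="ignore"):
            gps = out["Grm2"] / spk
        gps = gps.where(spk > 0)
        if "GpS" in records.columns:
            out["GpS"] = records["GpS"].where(records["GpS"].notna(), gps)
        else:
            out["GpS"] = gps
    return out


# ---------------------------------------------------------------------------
# BLUEs


def _ls_cell_means(y, genotype, *block_factors):
    """Least-squares genotype cell means with deviation-coded nuisance
    factors.  Returns (means: Series, se: Series, sigma2, df_resid)."""
    genos = pd.unique(genotype)
    g_idx = pd.Categorical(genotype, categories=genos).codes
    G = np.zeros((len(y), len(genos)))
    G[np.arange(len(y)), g_idx] = 1.0
    blocks_cols = []
    for fac in block_factors:
        levels = pd.unique(fac)
        if len(levels) < 2:
            continue
        codes = pd.Categorical(fac, categories=levels).codes
        B = np.zeros((len(y), len(levels) - 1))
        for j in range(len(levels) - 1):
            B[codes == j, j] = 1.0
        B[codes == len(levels) - 1, :] = -1.0  # sum-to-zero coding
        blocks_cols.append(B)
    X = np.column_stack([G] + blocks_cols) if blocks_cols else G
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - rank
    sigma2 = float(resid @ resid / df) if df > 0 else 0.0
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv)[: len(genos)] * sigma2, 0, None))
    return (
        pd.Series(coef[: len(genos)], index=genos),
        pd.Series(se, index=genos),
        sigma2,
        df,
    )


def compute_blues(records: pd.DataFrame, design: str, traits=None) -> pd.DataFrame:
    """Per-environment design-adjusted genotype means.

    ``design='augmented'``: additive block effects estimated from the
    replicated checks (classic check-based adjustment, equivalently OLS
    on genotype + block with sum-to-zero blocks); every block must
    contain at least one check.  ``design='alpha_lattice'``: OLS with
    genotype fixed plus replicate and incomplete-block effects.

    Returns long table with columns genotype_id, environment_id, trait,
    value, se.
    """
    if design not in ("augmented", "alpha_lattice"):
        raise ValueError(f"unknown design {design!r}")
    if traits is None:
        traits = [t for t in TRAITS if t in records.columns]
    out = []
    for eid, sub in records.groupby("environment_id", sort=True):
        if design == "augmented":
            has_check = sub.groupby("block_id")["is_check"].any()
            missing = list(has_check.index[~has_check])
            if missing:
                raise ValueError(
                    f"augmented design in environment {eid}: blocks without a check: {missing}"
                )
        for trait in traits:
            s = sub.dropna(subset=[trait])
            if s.empty:
                continue
            y = s[trait].to_numpy(dtype=float)
            if design == "augmented":
                means, se, _, _ = _ls_cell_means(
                    y, s["genotype_id"].to_numpy(), s["block_id"].to_numpy()
                )
            else:
                means, se, _, _ = _ls_cell_means(
                    y,
                    s["genotype_id"].to_numpy(),
                    s["replicate"].to_numpy() if "replicate" in s else np.zeros(len(s)),
                    s["block_id"].to_numpy(),
                )
            for g in means.index:
                out.append((g, eid, trait, means[g], se[g]))
    return pd.DataFrame(out, columns=["genotype_id", "environment_id", "trait", "value", "se"])


# ---------------------------------------------------------------------------
# variance partition


@dataclass
class VariancePartition:
    trait: str
    ss_G: float
    ss_E: float
    ss_GxE: float
    ss_resid: float
    share_G: float
    share_E: float
    share_GxE: float
    H2_by_env: dict = field(default_factory=dict)

    @property
    def ss_total(self) -> float:
        return self.ss_G + self.ss_E + self.ss_GxE + self.ss_resid


def variance_partition(data: pd.DataFrame, trait: str = "GY",
                       value_col: str | None = None) -> VariancePartition:
    """Two-way G/E/G×E sum-of-squares partition with per-environment
    broad-sense heritability.

    ``data`` is either a plot table (columns genotype_id, environment_id
    and the trait) or a long BLUE table (trait/value columns).  Shares
    are each SS divided by the total SS.  H² per environment uses
    σ²g/(σ²g + σ²e/r) with r the average replicate count.
    """
    if value_col is None:
        if "value" in data.columns and "trait" in data.columns:
            df = data[data["trait"] == trait].rename(columns={"value": "_y"})
        else:
            df = data.rename(columns={trait: "_y"})
    else:
        df = data.rename(columns={value_col: "_y"})
    df = df.dropna(subset=["_y"])
    if df["genotype_id"].nunique() < 2:
        raise ValueError("variance_partition requires >= 2 genotypes")
    if df["environment_id"].nunique() < 2:
        raise ValueError("variance_partition requires >= 2 environments (G×E undefined otherwise)")

    grand = df["_y"].mean()
    g_means = df.groupby("genotype_id")["_y"].agg(["mean", "count"])
    e_means = df.groupby("environment_id")["_y"].agg(["mean", "count"])
    cell = df.groupby(["genotype_id", "environment_id"])["_y"].agg(["mean", "count"])

    ss_G = float((g_means["count"] * (g_means["mean"] - grand) ** 2).sum())
    ss_E = float((e_means["count"] * (e_means["mean"] - grand) ** 2).sum())
    cm = cell.reset_index()
    cm["g_mean"] = cm["genotype_id"].map(g_means["mean"])
    cm["e_mean"] = cm["environment_id"].map(e_means["mean"])
    ss_GxE = float(
        (cm["count"] * (cm["mean"] - cm["g_mean"] - cm["e_mean"] + grand) ** 2).sum()
    )
    cell_mean = df.set_index(["genotype_id", "environment_id"]).index.map(cell["mean"])
    ss_resid = float(((df["_y"].to_numpy() - cell_mean.to_numpy()) ** 2).sum())
    total = ss_G + ss_E + ss_GxE + ss_resid

    h2 = {}
    for eid, sub in df.groupby("environment_id"):
        counts = sub.groupby("genotype_id")["_y"].count()
        r = float(counts.mean())
        if r <= 1 or counts.size < 2:
            continue
        # one-way ANOVA within environment
        gm = sub.groupby("genotype_id")["_y"].mean()
        em = sub["_y"].mean()
        ssg = float((counts * (gm - em) ** 2).sum())
        sse = float(((sub["_y"] - sub["genotype_id"].map(gm)) ** 2).sum())
        dfg, dfe = counts.size - 1, len(sub) - counts.size
        if dfe <= 0:
            continue
        msg, mse = ssg / dfg, sse / dfe
        sg2 = max((msg - mse) / r, 0.0)
        h2[eid] = float(np.clip(sg2 / (sg2 + mse / r), 0.0, 1.0)) if (sg2 + mse / r) > 0 else 0.0

    return VariancePartition(
        trait=trait,
        ss_G=ss_G, ss_E=ss_E, ss_GxE=ss_GxE, ss_resid=ss_resid,
        share_G=ss_G / total, share_E=ss_E / total, share_GxE=ss_GxE / total,
        H2_by_env=h2,
    )


def broad_sense_h2(sigma2_g: float, sigma2_e: float, r: int) -> float:
    """H² = σ²g / (σ²g + σ²e / r)."""
    denom = sigma2_g + sigma2_e / r
    return sigma2_g / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# scaling and correlations


def ratio_to_max(blues: pd.DataFrame, trait: str = "GY") -> pd.Series:
    """Scale each genotype by the top entry per environment, then average
    across environments.  The top entry in every environment scores 1."""
    df = blues[blues["trait"] == trait] if "trait" in blues.columns else blues
    wide = df.pivot_table(index="genotype_id", columns="environment_id", values="value")
    maxima = wide.max(axis=0)
    bad = maxima.index[maxima <= 0]
    if len(bad):
        logger.warning("ratio_to_max: environments with non-positive maxima excluded: %s",
                       list(bad))
        wide = wide.drop(columns=bad)
        maxima = maxima.drop(bad)
    scaled = wide / maxima
    return scaled.mean(axis=1).rename("ratio_to_max")


def trait_gy_correlations(blues: pd.DataFrame, traits=("DTH", "TKW", "SPK", "GpS"),
                          assignment: pd.DataFrame | None = None,
                          alpha: float = 0.001) -> pd.DataFrame:
    """Pearson correlation of each trait against GY, per environment and
    (optionally) per mega-environment average.

    Output columns: context, trait, r, p, star where star is '•' when
    p < ``alpha``, 'ns' otherwise, and '-' when the trait is absent or
    constant in that context.
    """
    wide = blues.pivot_table(index="genotype_id", columns=["environment_id", "trait"],
                             values="value")
    rows = []

    def one_context(name, frame):
        gy = frame.get("GY")
        for t in traits:
            x = frame.get(t)
            if x is None or gy is None:
                rows.append((name, t, np.nan, np.nan, "-"))
                continue
            pair = pd.concat([gy, x], axis=1).dropna()
            if len(pair) < 3 or pair.iloc[:, 1].std() == 0 or pair.iloc[:, 0].std() == 0:
                rows.append((name, t, np.nan, np.nan, "-"))
                continue
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append((name, t, r, p, "•" if p < alpha else "ns"))

    for eid in wide.columns.get_level_values(0).unique():
        one_context(eid, wide[eid])
    if assignment is not None:
        for grp, sub in assignment.groupby("group"):
            envs = [e for e in sub["environment_id"] if e in wide.columns.get_level_values(0)]
            if not envs:
                continue
            avg = pd.concat({e: wide[e] for e in envs}, axis=1).T.groupby(level=1).mean().T
            one_context(f"average_{grp}", avg)
    return pd.DataFrame(rows, columns=["context", "trait", "r", "p", "star"])
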