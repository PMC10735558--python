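"""Climate matrix analysis and mega-environment clustering.

Regresses environment-mean grain yield on per-growth-stage climate
factors, then clusters environments on the significant factors via PCA
and Ward-linkage hierarchical clustering into mega-environments
(moisture-stressed vs non-moisture-stressed).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

MOISTURE_PIVOT_MM = 400.0


def climate_wide(climate: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long climate table to one row per environment with
    (stage, variable) columns."""
    return climate.pivot_table(index="environment_id", columns=["stage", "variable"],
                               values="value")


def climate_regression(climate: pd.DataFrame, env_mean_gy: pd.Series,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Simple linear regression of environment-mean GY on each
    (stage, variable) climate factor.

    Returns columns stage, variable, slope, r2, p, significant.
    Constant factors are skipped with a log entry.
    """
    wide = climate_wide(climate)
    common = wide.index.intersection(env_mean_gy.index)
    if len(common) < 4:
        raise ValueError("climate_regression requires >= 4 environments")
    wide = wide.loc[common]
    y = env_mean_gy.loc[common].to_numpy(dtype=float)
    rows = []
    for stage, variable in wide.columns:
        x = wide[(stage, variable)].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            logger.info("climate_regression: constant factor (%s, %s) skipped", stage, variable)
            continue
        res = stats.linregress(x, y)
        rows.append((stage, variable, res.slope, res.rvalue ** 2, res.pvalue,
                     res.pvalue < alpha))
    return pd.DataFrame(rows, columns=["stage", "variable", "slope", "r2", "p", "significant"])


def cluster_environments(climate: pd.DataFrame,
                         significant_factors: pd.DataFrame | list | None = None,
                         k: int = 2,
                         variance_retained: float = 0.80) -> pd.DataFrame:
    """Cluster environments into mega-environments on significant
    climate factors.

    Factors are standardized, projected onto principal components
    retaining at least ``variance_retained`` of the variance, then
    Ward-linkage hierarchical clustering is cut at ``k`` groups.  The
    group with lower mean total moisture is labelled
    ``moisture_stressed``.  With ``k=1`` all environments form one group
    labelled by their overall mean moisture against a 400 mm pivot.

    Returns columns environment_id, group, cluster.
    """
    wide = climate_wide(climate)
    n_env = len(wide)
    if k > n_env:
        raise ValueError(f"k={k} exceeds the number of environments ({n_env})")
    total_moisture = climate.groupby("environment_id")["total_moisture"].first()

    if significant_factors is not None:
        if isinstance(significant_factors, pd.DataFrame):
            sig = significant_factors
            if "significant" in sig.columns:
                sig = sig[sig["significant"]]
            keys = list(zip(sig["stage"], sig["variable"]))
        else:
            keys = list(significant_factors)
        keys = [kk for kk in keys if kk in wide.columns]
        if not keys:
            raise ValueError("no significant factors available for clustering")
        wide = wide[keys]

    X = wide.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))

    if k == 1:
        grp = ("moisture_stressed" if total_moisture.loc[wide.index].mean() < MOISTURE_PIVOT_MM
               else "non_moisture_stressed")
        return pd.DataFrame({"environment_id": wide.index, "group": grp, "cluster": 1})

    # PCA retaining >= variance_retained
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2 / (s ** 2).sum() if (s ** 2).sum() > 0 else np.ones_like(s) / len(s)
    n_pc = int(np.searchsorted(np.cumsum(var), variance_retained) + 1)
    scores = U[:, :n_pc] * s[:n_pc]

    Z = linkage(scores, method="ward")
    clusters = fcluster(Z, t=k, criterion="maxclust")

    moist_by_cluster = pd.Series(total_moisture.loc[wide.index].to_numpy(),
                                 index=clusters).groupby(level=0).mean()
    stressed_cluster = moist_by_cluster.idxmin()
    groups = np.where(clusters == stressed_cluster, "moisture_stressed",
                      "non_moisture_stressed")
    return pd.DataFrame({"environment_id": wide.index.to_numpy(), "group": groups,
                         "cluster": clusters})
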