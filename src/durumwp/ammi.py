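"""AMMI decomposition and the wide-adaptation stability index (AWAI).

The additive main effects and multiplicative interaction (AMMI) model
fits genotype and environment main effects to a two-way table of means
and decomposes the doubly-centred interaction residual by SVD into
interaction principal components (IPCs).  The AWAI stability score sums
s_i × |PC_i| over the significant IPCs, where s_i is the fraction of
G×E variance explained by axis i; 0 marks maximal stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AMMIResult:
    grand_mean: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    ipc_genotype_scores: pd.DataFrame    # genotype × IPC, scaled by sqrt(lambda)
    ipc_environment_scores: pd.DataFrame
    singular_values: np.ndarray
    s: np.ndarray                        # fraction of G×E variance per IPC
    significant_ipcs: int
    interaction_ss: float
    awai: pd.Series | None = None
    awai_ratio_to_min: pd.Series | None = None

    def reconstruct(self) -> pd.DataFrame:
        """Additive fit plus the sum of IPC outer products."""
        add = (self.grand_mean
               + self.genotype_effects.to_numpy()[:, None]
               + self.environment_effects.to_numpy()[None, :])
        inter = self.ipc_genotype_scores.to_numpy() @ self.ipc_environment_scores.to_numpy().T
        return pd.DataFrame(add + inter, index=self.genotype_effects.index,
                            columns=self.environment_effects.index)


def impute_two_way(table: pd.DataFrame, tol: float = 1e-6, max_iter: int = 200) -> pd.DataFrame:
    """Fill missing cells with the row+column expectation, iterated
    EM-style to convergence."""
    filled = table.copy()
    mask = filled.isna()
    if not mask.to_numpy().any():
        return filled
    filled = filled.fillna(filled.to_numpy()[~mask.to_numpy()].mean())
    for it in range(max_iter):
        grand = filled.to_numpy().mean()
        g = filled.mean(axis=1) - grand
        e = filled.mean(axis=0) - grand
        expect = grand + g.to_numpy()[:, None] + e.to_numpy()[None, :]
        new = filled.to_numpy().copy()
        new[mask.to_numpy()] = expect[mask.to_numpy()]
        delta = np.max(np.abs(new - filled.to_numpy()))
        filled = pd.DataFrame(new, index=table.index, columns=table.columns)
        if delta < tol:
            break
    logger.info("impute_two_way: %d cells imputed in %d iterations",
                int(mask.to_numpy().sum()), it + 1)
    return filled


def gollob_df(n_g: int, n_e: int, k: int) -> int:
    """Gollob degrees of freedom of the k-th IPC (1-based)."""
    return (n_g - 1) + (n_e - 1) - (2 * k - 1)


def fit_ammi(table: pd.DataFrame, alpha: float = 0.05,
             error_ms: float | None = None, error_df: float | None = None,
             zero_tol: float = 1e-9) -> AMMIResult:
    """Fit the AMMI model to a genotype × environment table of means.

    IPC significance uses an F-test with Gollob degrees of freedom; each
    axis is tested against ``error_ms`` when a plot-level pooled error is
    supplied, otherwise against the pooled mean square of the trailing
    axes.  Significant axes form the leading run of axes passing the
    test at ``alpha``.
    """
    if table.shape[0] < 3 or table.shape[1] < 3:
        raise ValueError("fit_ammi requires at least 3 genotypes and 3 environments")
    table = impute_two_way(table)
    Y = table.to_numpy(dtype=float)
    n_g, n_e = Y.shape
    grand = Y.mean()
    g_eff = Y.mean(axis=1) - grand
    e_eff = Y.mean(axis=0) - grand
    resid = Y - grand - g_eff[:, None] - e_eff[None, :]

    U, sv, Vt = np.linalg.svd(resid, full_matrices=False)
    n_axes = min(n_g - 1, n_e - 1)
    U, sv, Vt = U[:, :n_axes], sv[:n_axes], Vt[:n_axes]
    lam2 = sv ** 2
    ss_int = float(lam2.sum())
    s_frac = lam2 / ss_int if ss_int > zero_tol else np.zeros_like(lam2)

    # canonical sign: largest-|loading| genotype score positive per axis
    for k in range(n_axes):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
            Vt[k] *= -1

    sqrt_sv = np.sqrt(sv)
    g_scores = U * sqrt_sv[None, :]
    e_scores = Vt.T * sqrt_sv[None, :]

    n_sig = _significant_axes(lam2, n_g, n_e, alpha, error_ms, error_df, zero_tol, ss_int)

    cols = [f"IPC{k + 1}" for k in range(n_axes)]
    return AMMIResult(
        grand_mean=float(grand),
        genotype_effects=pd.Series(g_eff, index=table.index, name="genotype_effect"),
        environment_effects=pd.Series(e_eff, index=table.columns, name="environment_effect"),
        ipc_genotype_scores=pd.DataFrame(g_scores, index=table.index, columns=cols),
        ipc_environment_scores=pd.DataFrame(e_scores, index=table.columns, columns=cols),
        singular_values=sv,
        s=s_frac,
        significant_ipcs=n_sig,
        interaction_ss=ss_int,
    )


def _significant_axes(lam2, n_g, n_e, alpha, error_ms, error_df, zero_tol, ss_int):
    n_axes = len(lam2)
    dfs = np.array([gollob_df(n_g, n_e, k + 1) for k in range(n_axes)], dtype=float)
    n_sig = 0
    for k in range(n_axes):
        if lam2[k] <= zero_tol * max(ss_int, 1.0):
            break
        if error_ms is not None:
            ms_err, df_err = error_ms, error_df if error_df is not None else np.inf
        else:
            trail_ss = lam2[k + 1:].sum()
            trail_df = dfs[k + 1:].sum()
            if trail_df <= 0 or trail_ss <= zero_tol * max(ss_int, 1.0):
                # rank-deficient tail: a non-trivial axis with no error left
                n_sig += 1
                continue
            ms_err, df_err = trail_ss / trail_df, trail_df
        F = (lam2[k] / dfs[k]) / ms_err if ms_err > 0 else np.inf
        p = stats.f.sf(F, dfs[k], df_err)
        if p < alpha:
            n_sig += 1
        else:
            break
    return n_sig


def awai(result: AMMIResult) -> AMMIResult:
    """AWAI_g = Σ_{i ≤ significant} s_i × |PC_{g,i}|, plus a ratio-to-min
    form (min positive AWAI / AWAI, clipped to [0,1]; 1 = most stable)."""
    n_sig = result.significant_ipcs
    scores = result.ipc_genotype_scores.to_numpy()
    if n_sig == 0:
        vals = np.zeros(scores.shape[0])
    else:
        vals = (np.abs(scores[:, :n_sig]) * result.s[:n_sig][None, :]).sum(axis=1)
    aw = pd.Series(vals, index=result.ipc_genotype_scores.index, name="awai")
    positive = vals[vals > 0]
    if positive.size:
        ratio = np.where(vals > 0, np.clip(positive.min() / np.where(vals > 0, vals, 1.0), 0, 1), 1.0)
    else:
        ratio = np.ones_like(vals)
    result.awai = aw
    result.awai_ratio_to_min = pd.Series(ratio, index=aw.index, name="awai_ratio_to_min")
    return result


def selection_surface(gy_ratio_to_max: pd.Series, awai_values: pd.Series) -> pd.DataFrame:
    """Yield-potential (G) vs stability (G×E) selection coordinates.

    Flags genotypes strictly above the average ratio-to-max yield and
    strictly below the average AWAI.
    """
    missing = set(gy_ratio_to_max.index) ^ set(awai_values.index)
    if missing:
        raise ValueError(f"genotype sets differ between yield and stability inputs: {sorted(missing)}")
    df = pd.DataFrame({"gy_ratio_to_max": gy_ratio_to_max,
                       "awai": awai_values.reindex(gy_ratio_to_max.index)})
    df["selected"] = (df["gy_ratio_to_max"] > df["gy_ratio_to_max"].mean()) & (
        df["awai"] < df["awai"].mean()
    )
    return df
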