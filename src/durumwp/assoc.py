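"""Marker curation, structure/kinship, LD decay, GWAS and QTL assembly.

Single-marker association for inbred panels: a fixed-structure general
linear model (GLM with Q covariates) and a kinship mixed linear model
(MLM with Q + K) solved by one eigendecomposition of K with null-model
variance components reused for every marker (the population-parameters-
previously-determined approximation).  Significant marker-trait
associations (MTAs) pass both a LOD and a marker-r² gate and are merged
into QTL by single-linkage chaining within twice the LD decay distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class MarkerPanel:
    """Biallelic dosage matrix (genotype × marker, 0/1/2, NaN missing)
    with a physical marker map."""

    dosage: pd.DataFrame
    marker_map: pd.DataFrame  # marker_id, chromosome, position, alleles

    def __post_init__(self):
        self.marker_map = self.marker_map.sort_values(
            ["chromosome", "position"], kind="stable"
        ).reset_index(drop=True)
        self.dosage = self.dosage[self.marker_map["marker_id"].tolist()]

    @property
    def n_genotypes(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def stats(self) -> pd.DataFrame:
        """Per-marker MAF, missing rate and heterozygosity rate."""
        X = self.dosage.to_numpy(dtype=float)
        missing = np.isnan(X).mean(axis=0)
        freq = np.nanmean(X, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        het = np.nanmean(X == 1.0, axis=0)
        return pd.DataFrame(
            {"marker_id": self.dosage.columns, "maf": maf,
             "missing_rate": missing, "het_rate": het}
        )


@dataclass
class SignificanceThresholds:
    """LOD and marker-r² gates for declaring an MTA valid."""

    lod_cutoff: float = 2.69
    r2_cutoff: float = 0.024
    alpha: float = 0.05

    def __post_init__(self):
        if self.lod_cutoff <= 0:
            raise ValueError("lod_cutoff must be > 0")
        if not 0 < self.r2_cutoff < 1:
            raise ValueError("r2_cutoff must be in (0, 1)")


def curate_markers(panel: MarkerPanel, max_missing: float = 0.01,
                   min_maf: float = 0.05, max_het: float = 0.05):
    """Drop markers violating missing-rate, MAF or heterozygosity rules.

    Returns ``(curated_panel, report)`` where the report counts removals
    per filter (a marker failing several filters is counted under each).
    """
    st = panel.stats()
    fail_missing = st["missing_rate"] >= max_missing
    fail_maf = st["maf"] < min_maf
    fail_het = st["het_rate"] > max_het
    keep = ~(fail_missing | fail_maf | fail_het)
    report = {
        "n_input": int(len(st)),
        "n_removed_missing": int(fail_missing.sum()),
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed_het": int(fail_het.sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        raise ValueError("curation removed every marker")
    kept_ids = st.loc[keep, "marker_id"].tolist()
    out = MarkerPanel(
        dosage=panel.dosage[kept_ids],
        marker_map=panel.marker_map[panel.marker_map["marker_id"].isin(kept_ids)].copy(),
    )
    logger.info("curate_markers: %s", report)
    return out, report


# ---------------------------------------------------------------------------
# structure & kinship


def _imputed_dosage(panel: MarkerPanel) -> np.ndarray:
    X = panel.dosage.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X = X.copy()
    X[idx] = col_mean[idx[1]]
    return X


def structure_and_kinship(panel: MarkerPanel, n_components: int | None = None):
    """Population-structure covariates Q and a VanRaden kinship matrix K.

    Q is the leading principal components of the centred dosage matrix;
    the component count defaults to the variance elbow (largest drop in
    explained variance, at least 1).  K = M M' / (2 Σ p(1−p)) with M the
    dosage matrix centred by twice the allele frequency; symmetric PSD.
    """
    if panel.n_markers < panel.n_genotypes / 10:
        logger.warning("structure_and_kinship: marker count (%d) is low for %d genotypes",
                       panel.n_markers, panel.n_genotypes)
    X = _imputed_dosage(panel)
    p = X.mean(axis=0) / 2.0
    M = X - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = M @ M.T / denom if denom > 0 else np.eye(len(M))
    K = (K + K.T) / 2.0

    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    var = var / var.sum() if var.sum() > 0 else var
    if n_components is None:
        drops = var[:-1] - var[1:]
        n_components = int(np.argmax(drops) + 1) if len(drops) else 1
        n_components = max(1, min(n_components, 10))
    Q = pd.DataFrame(U[:, :n_components] * s[:n_components],
                     index=panel.dosage.index,
                     columns=[f"PC{i + 1}" for i in range(n_components)])
    Kdf = pd.DataFrame(K, index=panel.dosage.index, columns=panel.dosage.index)
    return Q, Kdf


# ---------------------------------------------------------------------------
# LD decay


@dataclass
class LDDecayResult:
    curve: pd.DataFrame          # columns distance, mean_r2, n_pairs
    ld_distance: float           # bp where fitted curve crosses critical_r2
    critical_r2: float
    fit_params: tuple | None = None


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.nan
    C = (Xc.T @ Xc) / len(X)
    R = C / np.outer(sd, sd)
    return R ** 2


def ld_decay(panel: MarkerPanel, critical_r2: float = 0.05,
             n_bins: int = 50, max_distance: float | None = None) -> LDDecayResult:
    """Within-chromosome pairwise allelic r² binned by physical distance,
    with an exponential-decay fit whose crossing of ``critical_r2``
    defines the LD decay distance."""
    dists, r2s = [], []
    mm = panel.marker_map
    X = _imputed_dosage(panel)
    col_of = {m: i for i, m in enumerate(panel.dosage.columns)}
    for chrom, sub in mm.groupby("chromosome"):
        if len(sub) < 2:
            continue
        idx = np.array([col_of[m] for m in sub["marker_id"]])
        pos = sub["position"].to_numpy(dtype=float)
        R2 = _pairwise_r2(X[:, idx])
        iu = np.triu_indices(len(idx), k=1)
        d = np.abs(pos[iu[0]] - pos[iu[1]])
        r2 = R2[iu]
        ok = ~np.isnan(r2)
        if max_distance is not None:
            ok &= d <= max_distance
        dists.append(d[ok])
        r2s.append(r2[ok])
    if not dists or sum(len(d) for d in dists) == 0:
        raise ValueError("ld_decay: no marker pairs available")
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)

    edges = np.linspace(0, d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        rows.append(((edges[b] + edges[b + 1]) / 2, float(r2[m].mean()), int(m.sum())))
    curve = pd.DataFrame(rows, columns=["distance", "mean_r2", "n_pairs"])

    # exponential decay fit r2(d) = a exp(-d/tau) + c
    xd, yd = curve["distance"].to_numpy(), curve["mean_r2"].to_numpy()
    scale = max(xd.max(), 1.0)
    params = None
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, tau, c: a * np.exp(-x / tau) + c,
            xd / scale, yd, p0=(max(yd.max() - yd.min(), 1e-3), 0.2, max(yd.min(), 1e-4)),
            bounds=([0, 1e-6, 0], [2, 50, 1]), maxfev=10000,
        )
        a, tau, c = popt
        params = (a, tau * scale, c)
        if critical_r2 <= c:
            ld_dist = float(xd.max())
        elif critical_r2 >= a + c:
            ld_dist = 0.0
        else:
            ld_dist = float(-tau * scale * np.log((critical_r2 - c) / a))
    except RuntimeError:
        ld_dist = np.nan
    if not np.isfinite(ld_dist) or ld_dist <= 0:
        # fall back to the first crossing of the binned means
        below = np.flatnonzero(yd <= critical_r2)
        ld_dist = float(xd[below[0]]) if below.size else float(xd.max())
    return LDDecayResult(curve=curve, ld_distance=ld_dist,
                         critical_r2=critical_r2, fit_params=params)


# ---------------------------------------------------------------------------
# GWAS


def genomic_inflation(p_values: np.ndarray) -> float:
    """λ_GC: median observed 1-df chi-square over its null median."""
    chi2 = stats.chi2.isf(np.clip(p_values, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def _design_matrix(n, Q=None, covariates=None):
    cols = [np.ones(n)]
    names = ["intercept"]
    if Q is not None:
        arr = np.asarray(Q, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols.extend(arr.T)
        names.extend([f"Q{i + 1}" for i in range(arr.shape[1])])
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"singular covariate set (rank {rank} < {X.shape[1]}): {names}")
    return X, names


def _marker_scan(yw, Xw, Gw):
    """Vectorised per-marker regression after projecting out covariates.

    All inputs already on the (possibly whitened) scale; returns effect,
    p and incremental r² relative to the total phenotypic SS on that
    scale.
    """
    n, p_cov = Xw.shape
    ss_total = float(((yw - yw.mean()) ** 2).sum())
    # residual-maker application via least squares
    coef_y, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    ry = yw - Xw @ coef_y
    coef_G, *_ = np.linalg.lstsq(Xw, Gw, rcond=None)
    rG = Gw - Xw @ coef_G
    gss = (rG ** 2).sum(axis=0)
    gss_safe = np.where(gss <= 1e-12, np.nan, gss)
    beta = (rG * ry[:, None]).sum(axis=0) / gss_safe
    sse_red = float(ry @ ry)
    sse_full = sse_red - beta ** 2 * gss_safe
    df = n - p_cov - 1
    sse_full = np.clip(sse_full, 1e-300, None)
    t2 = beta ** 2 * gss_safe * df / sse_full
    p = stats.t.sf(np.sqrt(t2), df) * 2.0
    r2 = (sse_red - sse_full) / ss_total if ss_total > 0 else np.zeros_like(beta)
    return beta, p, r2


def _reml_delta(d, yr, Xr):
    """Profile the variance ratio δ = σ²e/σ²g on eigen-rotated data."""

    def nll(log_delta):
        delta = np.exp(log_delta)
        w = 1.0 / (d + delta)
        sw = np.sqrt(w)
        Xw = Xr * sw[:, None]
        yw = yr * sw
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ coef
        n = len(yr)
        sg2 = (r @ r) / n
        return 0.5 * (n * np.log(max(sg2, 1e-300)) + np.sum(np.log(d + delta)) + n)

    res = optimize.minimize_scalar(nll, bounds=(-10.0, 10.0), method="bounded")
    return float(np.exp(res.x))


def gwas(panel: MarkerPanel, phenotype: pd.Series, Q: pd.DataFrame | None = None,
         covariates: pd.DataFrame | None = None, K: pd.DataFrame | None = None,
         model: str = "GLM_Q", context: str = "combined", trait: str = "GY") -> pd.DataFrame:
    """Single-marker association scan.

    ``GLM_Q``: fixed-effects regression of the phenotype on each marker
    with intercept, Q and covariates.  ``MLM_QK``: adds one random
    polygenic term with covariance K; variance components are estimated
    once on the null (marker-free) model via one eigendecomposition of K
    and reused for every marker.  ``auto`` runs both and keeps the model
    whose genomic inflation factor λ is nearer 1.

    Missing dosages are mean-imputed per marker.  Returns one row per
    marker: marker_id, chromosome, position, effect, p_value, lod,
    r2_marker, trait, context, model_used.
    """
    genos = [g for g in panel.dosage.index if g in phenotype.index
             and np.isfinite(phenotype.get(g, np.nan))]
    if covariates is not None:
        cov = pd.DataFrame(covariates).reindex(genos)
        genos = [g for g in genos if np.isfinite(cov.loc[g]).all()]
        cov = cov.loc[genos]
    else:
        cov = None
    y = phenotype.loc[genos].to_numpy(dtype=float)
    G = panel.dosage.loc[genos].to_numpy(dtype=float)
    col_mean = np.nanmean(G, axis=0)
    nan_idx = np.where(np.isnan(G))
    G[nan_idx] = col_mean[nan_idx[1]]
    Qm = Q.reindex(genos).to_numpy(dtype=float) if Q is not None else None
    X, _ = _design_matrix(len(genos), Qm, cov)

    if model == "auto":
        glm = gwas(panel, phenotype, Q, covariates, None, "GLM_Q", context, trait)
        if K is None:
            return glm
        mlm = gwas(panel, phenotype, Q, covariates, K, "MLM_QK", context, trait)
        lam_glm = genomic_inflation(glm["p_value"].to_numpy())
        lam_mlm = genomic_inflation(mlm["p_value"].to_numpy())
        chosen = glm if abs(lam_glm - 1) <= abs(lam_mlm - 1) else mlm
        logger.info("gwas auto: λ(GLM)=%.3f λ(MLM)=%.3f -> %s",
                    lam_glm, lam_mlm, chosen["model_used"].iloc[0])
        return chosen

    if model == "GLM_Q":
        beta, p, r2 = _marker_scan(y, X, G)
    elif model == "MLM_QK":
        if K is None:
            raise ValueError("MLM_QK requires a kinship matrix K")
        Km = K.reindex(index=genos, columns=genos).to_numpy(dtype=float)
        d, U = np.linalg.eigh((Km + Km.T) / 2.0)
        d = np.clip(d, 0.0, None)
        yr, Xr, Gr = U.T @ y, U.T @ X, U.T @ G
        delta = _reml_delta(d, yr, Xr)
        w = np.sqrt(1.0 / (d + delta))
        beta, p, r2 = _marker_scan(yr * w, Xr * w[:, None], Gr * w[:, None])
    else:
        raise ValueError(f"unknown model {model!r}")

    with np.errstate(divide="ignore"):
        lod = -np.log10(np.clip(p, 1e-300, 1.0))
    mm = panel.marker_map.set_index("marker_id")
    out = pd.DataFrame(
        {
            "marker_id": panel.dosage.columns,
            "chromosome": mm.loc[panel.dosage.columns, "chromosome"].to_numpy(),
            "position": mm.loc[panel.dosage.columns, "position"].to_numpy(),
            "effect": beta,
            "p_value": p,
            "lod": lod,
            "r2_marker": np.clip(r2, 0.0, 1.0),
            "trait": trait,
            "context": context,
            "model_used": model,
        }
    )
    return out


def significant_mtas(scan: pd.DataFrame, thresholds: SignificanceThresholds) -> pd.DataFrame:
    """Apply the LOD and marker-r² gates; both must pass."""
    keep = (scan["lod"] > thresholds.lod_cutoff) & (scan["r2_marker"] > thresholds.r2_cutoff)
    return scan[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# QTL assembly


def assemble_qtl(mtas: pd.DataFrame, merge_distance: float,
                 combined_contexts: set | None = None,
                 qtl_prefix: str = "Q.SYN",
                 other_panel_qtl: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge MTAs into QTL by single-linkage chaining.

    Same-chromosome MTAs whose neighbouring distance is strictly below
    ``merge_distance`` share a QTL identifier.  A QTL is ``consistent``
    when its member MTAs include a combined-context association and
    associations in more than one individual environment; it is
    ``true_positive`` when an ``other_panel_qtl`` span overlaps its span
    on the same chromosome (closed 1-based intervals).  The
    representative marker has the highest LOD (ties: highest r², then
    lowest position).
    """
    combined_contexts = combined_contexts or set()
    if mtas.empty:
        return pd.DataFrame(columns=[
            "qtl_id", "chromosome", "start", "end", "n_mtas", "traits", "contexts",
            "consistent", "true_positive", "representative_marker", "member_markers"])
    mtas = mtas.sort_values(["chromosome", "position", "marker_id"],
                            kind="stable").reset_index(drop=True)
    rows = []
    for chrom, sub in mtas.groupby("chromosome", sort=True):
        positions = np.sort(sub["position"].unique())
        gaps = np.diff(positions)
        breaks = np.flatnonzero(gaps >= merge_distance)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(positions) - 1]])
        for s_i, e_i in zip(starts, ends):
            lo, hi = positions[s_i], positions[e_i]
            members = sub[(sub["position"] >= lo) & (sub["position"] <= hi)]
            env_contexts = {c for c in members["context"] if c not in combined_contexts}
            has_combined = any(c in combined_contexts for c in members["context"])
            consistent = has_combined and len(env_contexts) > 1
            rep = members.sort_values(
                ["lod", "r2_marker", "position"], ascending=[False, False, True],
                kind="stable").iloc[0]["marker_id"]
            rows.append({
                "chromosome": chrom, "start": int(lo), "end": int(hi),
                "n_mtas": len(members),
                "traits": sorted(set(members["trait"])),
                "contexts": sorted(set(members["context"])),
                "consistent": bool(consistent),
                "representative_marker": rep,
                "member_markers": sorted(set(members["marker_id"])),
            })
    qtl = pd.DataFrame(rows).sort_values(["chromosome", "start"],
                                         kind="stable").reset_index(drop=True)
    qtl.insert(0, "qtl_id", [f"{qtl_prefix}.{i + 1:02d}" for i in range(len(qtl))])
    if other_panel_qtl is not None and not other_panel_qtl.empty:
        def overlaps(row):
            o = other_panel_qtl[other_panel_qtl["chromosome"] == row["chromosome"]]
            return bool(((o["start"] <= row["end"]) & (o["end"] >= row["start"])).any())
        qtl["true_positive"] = qtl.apply(overlaps, axis=1)
    else:
        qtl["true_positive"] = False
    return qtl
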