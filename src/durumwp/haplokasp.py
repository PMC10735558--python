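"""Haplotype classes over representative QTL markers and KASP-style
marker validation.

A "haplotype" here is the +/− pattern of favorable alleles at the
representative markers of the selected QTL.  Group effects are compared
with a least-significant-difference (LSD) test and a compact letter
display; single-marker validation scores each marker's ability to
separate the top-20 from the worst-20 yielding genotypes via standard
confusion-matrix accuracy / sensitivity / specificity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def favorable_dosage(dosage: pd.DataFrame, favorable_sign: dict) -> pd.DataFrame:
    """Orient dosages so 2 = homozygous favorable.

    ``favorable_sign`` maps marker -> +1 (allele coded 2 is favorable,
    e.g. positive MTA effect) or -1 (allele coded 0 is favorable).
    """
    out = {}
    for m, sign in favorable_sign.items():
        col = dosage[m]
        out[m] = col if sign >= 0 else 2.0 - col
    return pd.DataFrame(out, index=dosage.index)


def build_haplotypes(dosage: pd.DataFrame, representative_markers: list,
                     favorable_sign: dict, min_size: int = 3) -> pd.DataFrame:
    """Partition genotypes by their +/− pattern at the representative
    markers.

    A genotype is '+' at a marker when homozygous for the favorable
    allele; heterozygous or missing calls at any representative marker
    exclude the genotype (logged).  Haplotypes are numbered by
    descending count of favorable alleles, then lexicographic pattern.

    Returns columns genotype_id, haplotype_id, pattern,
    n_positive_alleles, small_group.
    """
    fav = favorable_dosage(dosage[representative_markers],
                           {m: favorable_sign[m] for m in representative_markers})
    arr = fav.to_numpy(dtype=float)
    complete = np.all((arr == 0.0) | (arr == 2.0), axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("build_haplotypes: %d genotypes excluded (het or missing calls)",
                    n_excluded)
    if not complete.any():
        raise ValueError("no genotype has complete homozygous calls at the representative markers")
    fav = fav.loc[complete]
    patterns = fav.apply(lambda row: "".join("+" if v == 2.0 else "-" for v in row), axis=1)

    uniq = sorted(patterns.unique(), key=lambda p: (-p.count("+"), p))
    hap_of = {p: f"Hap{i + 1}" for i, p in enumerate(uniq)}
    out = pd.DataFrame(
        {
            "genotype_id": fav.index,
            "haplotype_id": patterns.map(hap_of).to_numpy(),
            "pattern": patterns.to_numpy(),
        }
    )
    out["n_positive_alleles"] = out["pattern"].str.count(r"\+")
    sizes = out["haplotype_id"].value_counts()
    out["small_group"] = out["haplotype_id"].map(sizes) < min_size
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# LSD test and compact letter display


def lsd_value(mse: float, df_error: float, n_a: int, n_b: int,
              alpha: float = 0.05) -> float:
    """LSD = t(1−α/2, df) × sqrt(MSE (1/n_a + 1/n_b)) (unequal-n form)."""
    t = stats.t.ppf(1 - alpha / 2, df_error)
    return float(t * np.sqrt(mse * (1.0 / n_a + 1.0 / n_b)))


def _compact_letters(names, differ):
    """Insert-and-absorb compact letter display.

    ``differ[(a, b)]`` is True when groups a and b are significantly
    different.  Names must be ordered by descending mean.
    """
    letter_sets: list[set] = []
    for i, a in enumerate(names):
        placed = False
        for ls in letter_sets:
            if all(not differ[frozenset((a, b))] for b in ls if b != a):
                ls.add(a)
                placed = True
        if not placed:
            letter_sets.append({a})
        # ensure every ns pair eventually shares a set
        for b in names[:i]:
            if not differ[frozenset((a, b))] and not any(
                    a in ls and b in ls for ls in letter_sets):
                letter_sets.append({a, b})
    # absorb subsets
    letter_sets = [ls for i, ls in enumerate(letter_sets)
                   if not any(i != j and ls < other for j, other in enumerate(letter_sets))]
    # deduplicate
    uniq = []
    for ls in letter_sets:
        if ls not in uniq:
            uniq.append(ls)
    letters = {}
    for idx, ls in enumerate(uniq):
        ch = chr(ord("a") + idx)
        for name in ls:
            letters.setdefault(name, []).append(ch)
    return {name: "".join(sorted(v)) for name, v in letters.items()}


def haplotype_effect_test(groups: pd.DataFrame, phenotype: pd.Series,
                          alpha: float = 0.05,
                          group_col: str = "haplotype_id") -> pd.DataFrame:
    """One-way fixed-effects fit of the phenotype on haplotype group with
    pairwise LSD comparisons and a compact letter display.

    Groups sharing no letter differ at ``alpha``.  Requires >= 2 groups
    with >= 2 members and positive error degrees of freedom.
    """
    df = groups[["genotype_id", group_col]].merge(
        phenotype.rename("y"), left_on="genotype_id", right_index=True
    ).dropna(subset=["y"])
    counts = df[group_col].value_counts()
    valid = counts[counts >= 2].index
    if len(valid) < 2:
        raise ValueError("haplotype_effect_test requires >= 2 groups with >= 2 members")
    df = df[df[group_col].isin(valid)]
    means = df.groupby(group_col)["y"].mean()
    ns = df.groupby(group_col)["y"].count()
    sse = float(((df["y"] - df[group_col].map(means)) ** 2).sum())
    df_error = len(df) - len(means)
    if df_error <= 0:
        raise ValueError("zero error degrees of freedom")
    mse = sse / df_error

    order = means.sort_values(ascending=False).index.tolist()
    differ = {}
    for a, b in itertools.combinations(order, 2):
        lsd = lsd_value(mse, df_error, int(ns[a]), int(ns[b]), alpha)
        differ[frozenset((a, b))] = abs(means[a] - means[b]) > lsd
    letters = _compact_letters(order, differ)

    out = pd.DataFrame(
        {
            group_col: order,
            "mean": [means[g] for g in order],
            "n": [int(ns[g]) for g in order],
            "lsd_letter": [letters[g] for g in order],
        }
    )
    out.attrs["mse"] = mse
    out.attrs["df_error"] = df_error
    return out


# ---------------------------------------------------------------------------
# allele-yield profiling


def allele_gy_profile(dosage: pd.DataFrame, blues: pd.DataFrame, markers: list,
                      favorable_sign: dict | None = None,
                      critical_r2: float = 0.024,
                      assignment: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pearson correlation between favorable-allele dosage and GY per
    environment (plus mega-environment averages).

    Significance is declared when |r| exceeds sqrt(``critical_r2``).
    Monomorphic markers yield NaN with significant=False.
    """
    favorable_sign = favorable_sign or {m: +1 for m in markers}
    fav = favorable_dosage(dosage[markers], {m: favorable_sign[m] for m in markers})
    gy = blues[blues["trait"] == "GY"] if "trait" in blues.columns else blues
    wide = gy.pivot_table(index="genotype_id", columns="environment_id", values="value")
    contexts = {str(e): wide[e] for e in wide.columns}
    if assignment is not None:
        for grp, sub in assignment.groupby("group"):
            envs = [e for e in sub["environment_id"] if e in wide.columns]
            if envs:
                contexts[f"average_{grp}"] = wide[envs].mean(axis=1)
    crit_r = float(np.sqrt(critical_r2))
    rows = []
    for m in markers:
        x_all = fav[m]
        for ctx, yv in contexts.items():
            pair = pd.concat([x_all, yv], axis=1).dropna()
            if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                rows.append((m, ctx, np.nan, False))
                continue
            r, _ = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append((m, ctx, float(r), abs(r) > crit_r))
    return pd.DataFrame(rows, columns=["marker_id", "context", "r", "significant"])


# ---------------------------------------------------------------------------
# KASP validation


@dataclass
class ValidationMetrics:
    marker_id: str
    r2_vs_gy: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_top: int
    n_worst: int


def _carries_favorable(calls: pd.Series) -> pd.Series:
    """True when the (oriented) dosage indicates the favorable allele."""
    return calls >= 1.0


def kasp_validate(calls: pd.Series, gy: pd.Series, n_extreme: int = 20,
                  pooled_denominator: bool = False) -> ValidationMetrics:
    """Validate one marker over the phenotypic extremes.

    Genotypes are ranked by GY (ties broken by genotype id); the top
    ``n_extreme`` are the positive cases and the worst ``n_extreme`` the
    negative cases.  Carrying the favorable allele predicts positive.
    accuracy = (TP+TN)/(2n); sensitivity = TP/n among positives;
    specificity = TN/n among negatives (``pooled_denominator``
    switches sensitivity/specificity denominators to 2n).  ``r2_vs_gy``
    is the r² of GY on the allele call over the full panel.
    """
    common = gy.index.intersection(calls.dropna().index)
    gy_c, calls_c = gy.loc[common], calls.loc[common]
    if len(common) < 2 * n_extreme:
        raise ValueError(
            f"kasp_validate needs >= {2 * n_extreme} genotypes with calls and GY, got {len(common)}")
    order = gy_c.to_frame("gy").assign(gid=gy_c.index).sort_values(
        ["gy", "gid"], ascending=[False, True]).index
    top, worst = order[:n_extreme], order[-n_extreme:]
    carries = _carries_favorable(calls_c)
    tp = int(carries.loc[top].sum())
    fn = n_extreme - tp
    tn = int((~carries.loc[worst]).sum())
    fp = n_extreme - tn
    denom = 2 * n_extreme if pooled_denominator else n_extreme
    if calls_c.std() > 0:
        r, _ = stats.pearsonr(calls_c, gy_c)
        r2 = float(r ** 2)
    else:
        r2 = np.nan
    return ValidationMetrics(
        marker_id=str(calls.name) if calls.name else "marker",
        r2_vs_gy=r2,
        accuracy=(tp + tn) / (2 * n_extreme),
        sensitivity=tp / denom,
        specificity=tn / denom,
        n_top=n_extreme,
        n_worst=n_extreme,
    )


def kasp_validate_panel(dosage: pd.DataFrame, gy: pd.Series, markers: list,
                        favorable_sign: dict | None = None, n_extreme: int = 20,
                        combine: bool = True) -> pd.DataFrame:
    """Per-marker validation metrics plus an AND-rule combined row
    ('carries the favorable allele at every marker')."""
    favorable_sign = favorable_sign or {m: +1 for m in markers}
    fav = favorable_dosage(dosage[markers], {m: favorable_sign[m] for m in markers})
    rows = []
    for m in markers:
        vm = kasp_validate(fav[m].rename(m), gy, n_extreme)
        rows.append(vars(vm))
    if combine and len(markers) > 1:
        carried = _carries_favorable(fav).all(axis=1).astype(float) * 2.0
        carried = carried[fav.notna().all(axis=1)]
        vm = kasp_validate(carried.rename("combined_AND"), gy, n_extreme)
        rows.append(vars(vm))
    return pd.DataFrame(rows)
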