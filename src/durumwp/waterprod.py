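"""Water productivity and the five-class moisture-response typology.

Water productivity (WP) is grain yield divided by total in-season
moisture (kg/ha per mm).  Each genotype's yield response is regressed
on environment moisture separately within the moisture-stressed and
non-stressed mega-environments; the two slopes b_i are compared against
the group-level trends to assign one of four responsiveness classes,
with genotypes whose regressions are non-significant (P >= alpha)
collected in a fifth, water-unresponsive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import GROUP_SLOPE_NONSTRESSED, GROUP_SLOPE_STRESSED

logger = logging.getLogger(__name__)

CLASS_NAMES = {
    1: "Stable water response",
    2: "Responsive to low moisture",
    3: "Responsive to high moisture",
    4: "Highly water responsive",
    5: "No water response",
}

STRESSED = "moisture_stressed"
NONSTRESSED = "non_moisture_stressed"


@dataclass
class GroupSlopes:
    """Group-level slopes of grain yield on moisture (kg/ha/mm)."""

    b_stressed_group: float = GROUP_SLOPE_STRESSED
    b_nonstressed_group: float = GROUP_SLOPE_NONSTRESSED


def _gy_long(blues: pd.DataFrame, trait: str = "GY") -> pd.DataFrame:
    df = blues
    if "trait" in df.columns:
        df = df[df["trait"] == trait]
    return df[["genotype_id", "environment_id", "value"]]


def water_productivity(blues: pd.DataFrame, moisture: pd.Series,
                       assignment: pd.DataFrame | None = None,
                       trait: str = "GY") -> pd.DataFrame:
    """Per-genotype WP = GY / total moisture, averaged overall and
    within each mega-environment group.

    ``moisture`` maps environment_id -> total moisture (mm); environments
    without moisture are excluded with a log entry.  Returns columns
    genotype_id, wp_overall, wp_stressed, wp_nonstressed.
    """
    gy = _gy_long(blues, trait)
    known = gy["environment_id"].isin(moisture.index)
    if (~known).any():
        dropped = sorted(gy.loc[~known, "environment_id"].unique())
        logger.warning("water_productivity: environments without moisture excluded: %s", dropped)
        gy = gy[known]
    if (moisture <= 0).any():
        bad = list(moisture.index[moisture <= 0])
        raise ValueError(f"total moisture must be > 0; offending environments: {bad}")
    gy = gy.assign(wp=gy["value"] / gy["environment_id"].map(moisture))
    out = gy.groupby("genotype_id")["wp"].mean().rename("wp_overall").to_frame()
    if assignment is not None:
        gmap = assignment.set_index("environment_id")["group"]
        gy = gy.assign(group=gy["environment_id"].map(gmap))
        for grp, col in ((STRESSED, "wp_stressed"), (NONSTRESSED, "wp_nonstressed")):
            sub = gy[gy["group"] == grp].groupby("genotype_id")["wp"].mean()
            out[col] = sub
    return out.reset_index()


def group_slopes(env_mean_gy: pd.Series, moisture: pd.Series,
                 assignment: pd.DataFrame) -> GroupSlopes:
    """OLS slope of environment-mean GY on environment moisture within
    each mega-environment group (requires >= 3 environments per group)."""
    gmap = assignment.set_index("environment_id")["group"]
    slopes = {}
    for grp in (STRESSED, NONSTRESSED):
        envs = [e for e in env_mean_gy.index if gmap.get(e) == grp and e in moisture.index]
        if len(envs) < 3:
            raise ValueError(f"group_slopes: fewer than 3 environments in group {grp!r}")
        res = stats.linregress(moisture.loc[envs], env_mean_gy.loc[envs])
        slopes[grp] = res.slope
    return GroupSlopes(b_stressed_group=float(slopes[STRESSED]),
                       b_nonstressed_group=float(slopes[NONSTRESSED]))


def classify_genotypes(blues: pd.DataFrame, moisture: pd.Series,
                       assignment: pd.DataFrame, slopes: GroupSlopes | None = None,
                       alpha: float = 0.01, trait: str = "GY") -> pd.DataFrame:
    """Assign each genotype to one of the five WP classes.

    Per genotype and group, OLS of per-environment GY (BLUEs) on
    moisture gives (b_i, r², p).  The water-unresponsiveness gate is the
    genotype's single regression of GY on moisture over *all*
    environments: when that regression is non-significant at ``alpha``
    the genotype goes to class 5.  Otherwise the quadrant rule against
    the group slopes applies, with ties (b_i exactly equal to the group
    slope) on the "<=" side: (<=, <=) -> 1, (>, <=) -> 2, (<=, >) -> 3,
    (>, >) -> 4.

    Genotypes with fewer than 3 environments in a group are reported
    with class NaN and a reason.
    """
    if slopes is None:
        gy_all = _gy_long(blues, trait)
        env_mean = gy_all.groupby("environment_id")["value"].mean()
        slopes = group_slopes(env_mean, moisture, assignment)
    gmap = assignment.set_index("environment_id")["group"]
    gy = _gy_long(blues, trait)
    gy = gy[gy["environment_id"].isin(moisture.index)]
    gy = gy.assign(moist=gy["environment_id"].map(moisture),
                   group=gy["environment_id"].map(gmap))

    rows = []
    for gid, sub in gy.groupby("genotype_id", sort=True):
        rec = {"genotype_id": gid}
        ok = True
        if len(sub) >= 3 and sub["moist"].nunique() >= 2:
            overall = stats.linregress(sub["moist"], sub["value"])
            rec["p_overall"] = overall.pvalue
            rec["r2_overall"] = overall.rvalue ** 2
        else:
            rec["p_overall"] = np.nan
            rec["r2_overall"] = np.nan
            ok = False
        for grp, btag in ((STRESSED, "stressed"), (NONSTRESSED, "nonstressed")):
            s = sub[sub["group"] == grp]
            if len(s) < 3 or s["moist"].nunique() < 2:
                rec[f"b_{btag}"] = np.nan
                rec[f"r2_{btag}"] = np.nan
                rec[f"p_{btag}"] = np.nan
                ok = False
                continue
            res = stats.linregress(s["moist"], s["value"])
            rec[f"b_{btag}"] = res.slope
            rec[f"r2_{btag}"] = res.rvalue ** 2
            rec[f"p_{btag}"] = res.pvalue
        if not ok:
            rec["wp_class"] = np.nan
            rec["class_name"] = "unclassifiable: <3 environments in a group"
        else:
            if rec["p_overall"] >= alpha:
                cls = 5
            else:
                # exact ties sit on the "<=" side; tolerance guards the
                # comparison against floating-point slop
                tol_s = 1e-9 * max(1.0, abs(slopes.b_stressed_group))
                tol_ns = 1e-9 * max(1.0, abs(slopes.b_nonstressed_group))
                hi_s = rec["b_stressed"] > slopes.b_stressed_group + tol_s
                hi_ns = rec["b_nonstressed"] > slopes.b_nonstressed_group + tol_ns
                cls = 4 if (hi_s and hi_ns) else 2 if hi_s else 3 if hi_ns else 1
            rec["wp_class"] = cls
            rec["class_name"] = CLASS_NAMES[cls]
        rows.append(rec)
    profile = pd.DataFrame(rows)

    wp = water_productivity(blues, moisture, assignment, trait)
    profile = profile.merge(wp, on="genotype_id", how="left")
    return profile


def class_frequencies(profile: pd.DataFrame) -> pd.Series:
    """Fraction of classifiable genotypes in each class 1-5."""
    counts = profile["wp_class"].value_counts(normalize=True)
    return counts.reindex(range(1, 6), fill_value=0.0)
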