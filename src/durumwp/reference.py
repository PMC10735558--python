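"""Study metadata for the Mediterranean durum wheat trial network.

Per-environment total in-season moisture (mm) and mega-environment
membership for the 18 discovery-panel environments (Morocco, Lebanon,
Jordan; seasons 2014-15 to 2017-18).  These values are used as the
default moisture layout for synthetic trials and as frozen inputs for
water-productivity replication runs.
"""

from __future__ import annotations

import pandas as pd

#: (environment_id, total moisture mm, mega-environment group)
_DISCOVERY_ENVIRONMENTS = [
    ("SAD16", 210.0, "moisture_stressed"),
    ("MUS18", 247.0, "moisture_stressed"),
    ("MCH17N", 270.8, "moisture_stressed"),
    ("MCH17Z", 270.8, "moisture_stressed"),
    ("KFD16", 282.3, "moisture_stressed"),
    ("KFD18A", 346.2, "moisture_stressed"),
    ("KFD18B", 346.2, "moisture_stressed"),
    ("MCH15", 363.7, "moisture_stressed"),
    ("KFD17A", 370.0, "moisture_stressed"),
    ("KFD17B", 370.0, "moisture_stressed"),
    ("MCH16", 444.0, "moisture_stressed"),
    ("TES16", 455.4, "non_moisture_stressed"),
    ("TER16", 457.6, "non_moisture_stressed"),
    ("TES17", 484.6, "non_moisture_stressed"),
    ("MCH18N", 493.4, "non_moisture_stressed"),
    ("MCH18Z", 493.4, "non_moisture_stressed"),
    ("MKZ15", 634.8, "non_moisture_stressed"),
    ("TER15", 641.4, "non_moisture_stressed"),
]

#: Reference group-level slopes of grain yield on total moisture
#: (kg/ha per mm), usable as frozen replication values.
GROUP_SLOPE_STRESSED = 5.08
GROUP_SLOPE_NONSTRESSED = 4.85

#: Frozen association thresholds for the three germplasm panels.
DISCOVERY_LOD_CUTOFF = 2.69
CONFIRMATION_LOD_CUTOFF = 4.1
DISCOVERY_R2_CUTOFF = 0.024
CONFIRMATION_R2_CUTOFF = 0.05
VALIDATION_R2_CUTOFF = 0.053

#: Genome-wide LD decay distances (bp) and the derived QTL merge distance.
DISCOVERY_LD_BP = 51.3e6
CONFIRMATION_LD_BP = 21.2e6
DISCOVERY_MERGE_DISTANCE_BP = 2 * DISCOVERY_LD_BP  # 102.6 Mbp


def discovery_environments() -> pd.DataFrame:
    """Return the 18-environment moisture table.

    Columns: ``environment_id``, ``total_moisture`` (mm), ``group``.
    """
    return pd.DataFrame(
        _DISCOVERY_ENVIRONMENTS,
        columns=["environment_id", "total_moisture", "group"],
    )
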