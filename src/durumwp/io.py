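"""Readers and writers for the pipeline's tabular formats.

Genotypes travel as HapMap-style TSV (one marker per row, diploid base
calls per genotype column) or VCF; phenotypes and climate as long-format
CSV; nested results as JSON; pipeline configuration as YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_HAPMAP_META = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


def write_hapmap(dosage: pd.DataFrame, marker_map: pd.DataFrame, path) -> None:
    """Write a HapMap-style TSV; dosage 0/1/2 becomes AA/AB/BB (NN missing)."""
    mm = marker_map.set_index("marker_id")
    rows = []
    for m in dosage.columns:
        alleles = mm.loc[m, "alleles"] if "alleles" in mm.columns else "A/B"
        a, b = alleles.split("/")
        calls = dosage[m].map(lambda v: "NN" if pd.isna(v)
                              else (b + b if v == 2 else a + b if v == 1 else a + a))
        row = [m, alleles, str(mm.loc[m, "chromosome"]), int(mm.loc[m, "position"]),
               "+", "NA", "NA", "NA", "NA", "NA", "NA", *calls.tolist()]
        rows.append(row)
    header = _HAPMAP_META + list(dosage.index)
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def read_hapmap(path):
    """Read a HapMap-style TSV back into (dosage, marker_map).

    Dosage counts the second listed allele (the one written as 2 by
    :func:`write_hapmap`); unknown calls become NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    genos = [c for c in df.columns if c not in _HAPMAP_META]
    marker_map = pd.DataFrame({
        "marker_id": df["rs#"],
        "chromosome": df["chrom"],
        "position": df["pos"].astype(np.int64),
        "alleles": df["alleles"],
    })
    dosages = np.full((len(genos), len(df)), np.nan)
    for i, (_, row) in enumerate(df.iterrows()):
        a, b = row["alleles"].split("/")
        lut = {a + a: 0.0, a + b: 1.0, b + a: 1.0, b + b: 2.0}
        dosages[:, i] = [lut.get(row[g], np.nan) for g in genos]
    dosage = pd.DataFrame(dosages, index=genos, columns=df["rs#"].tolist())
    return dosage, marker_map


def write_vcf(dosage: pd.DataFrame, marker_map: pd.DataFrame, path) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT fields."""
    mm = marker_map.set_index("marker_id")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dosage.index) + "\n")
        order = mm.sort_values(["chromosome", "position"]).index
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for m in order:
            if m not in dosage.columns:
                continue
            a, b = (mm.loc[m, "alleles"] if "alleles" in mm.columns else "A/B").split("/")
            gts = [gt_of.get(v, "./.") for v in dosage[m]]
            fh.write(f"{mm.loc[m, 'chromosome']}\t{int(mm.loc[m, 'position'])}\t{m}\t"
                     f"{a}\t{b}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path):
    """Read genotype dosages (ALT-allele count) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, alleles, cols = [], [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        alleles.append(f"{var.REF}/{var.ALT[0] if var.ALT else '.'}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.array(var.gt_types, dtype=float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        cols.append(dos)
    dosage = pd.DataFrame(np.column_stack(cols) if cols else np.empty((len(samples), 0)),
                          index=samples, columns=ids)
    marker_map = pd.DataFrame({"marker_id": ids, "chromosome": chroms,
                               "position": np.asarray(poss, dtype=np.int64),
                               "alleles": alleles})
    return dosage, marker_map


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_phenotypes(path) -> pd.DataFrame:
    """Plot-level phenotype CSV; requires genotype_id and environment_id."""
    df = pd.read_csv(path)
    required = {"genotype_id", "environment_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def read_climate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"environment_id", "stage", "variable", "value", "total_moisture"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    return df
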