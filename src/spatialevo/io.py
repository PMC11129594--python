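"""Readers and writers for the tabular interchange formats.

MutationCall tables travel as TSV (one row per patient/region/variant) and
optionally as VCF 4.2 with one sample column per region (AD/DP format
fields).  Cell fractions and clinical covariates are TSV; configs are
YAML; truth bundles are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

PathLike = Union[str, Path]

CALL_COLUMNS = [
    "patient", "region", "chrom", "pos", "ref", "alt", "alt_reads",
    "total_reads", "purity", "cn_total", "multiplicity",
]


def write_calls_tsv(calls: pd.DataFrame, path: PathLike) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    return df


def write_cell_fractions_tsv(fractions: pd.DataFrame, path: PathLike) -> None:
    fractions.to_csv(path, sep="\t", index=False)


def read_cell_fractions_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clinical_tsv(clinical: pd.DataFrame, path: PathLike) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config_yaml(config: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_truth_json(truth: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# VCF-lite: one file per patient, one sample column per region

def write_vcf(calls: pd.DataFrame, path: PathLike, patient: Optional[str] = None) -> None:
    """Write one patient's calls as VCF 4.2 with AD/DP per region sample.

    ``AD`` holds ref,alt depths and ``DP`` the total depth.  Variants
    missing in a region are emitted as ``./.`` with zero depths.
    """
    df = calls
    if patient is not None:
        df = df[df["patient"] == patient]
    pats = df["patient"].unique()
    if len(pats) != 1:
        raise ValueError("write_vcf expects exactly one patient (pass patient=...)")
    regions = sorted(df["region"].unique())
    piv_alt = df.pivot_table(index=["chrom", "pos", "ref", "alt"], columns="region",
                             values="alt_reads", aggfunc="first")
    piv_tot = df.pivot_table(index=["chrom", "pos", "ref", "alt"], columns="region",
                             values="total_reads", aggfunc="first")

    def chrom_rank(c: str):
        c = str(c).removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    keys = sorted(piv_alt.index, key=lambda k: (chrom_rank(k[0]), int(k[1]), k[2], k[3]))
    contigs = sorted({str(k[0]) for k in keys}, key=chrom_rank)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=spatialevo",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(regions),
    ]
    for key in keys:
        chrom, pos, ref, alt = key
        fields = [str(chrom), str(int(pos)), ".", str(ref), str(alt), ".", "PASS", ".", "GT:AD:DP"]
        for r in regions:
            a = piv_alt.loc[key, r] if r in piv_alt.columns else np.nan
            t = piv_tot.loc[key, r] if r in piv_tot.columns else np.nan
            if pd.isna(a) or pd.isna(t):
                fields.append("./.:0,0:0")
            else:
                a, t = int(a), int(t)
                gt = "0/1" if a > 0 else "0/0"
                fields.append(f"{gt}:{t - a},{a}:{t}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: PathLike, patient: str = "P1") -> pd.DataFrame:
    """Read a per-region-sample VCF back into a MutationCall table.

    Uses pysam; purity/copy-number columns default to 1.0 / 2 / 1 and can
    be overwritten by the caller.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    regions = list(vf.header.samples)
    rows = []
    for rec in vf:
        for r in regions:
            smp = rec.samples[r]
            ad = smp.get("AD")
            dp = smp.get("DP")
            if ad is None or dp is None or not dp:
                continue
            alt_reads = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
            rows.append(
                {
                    "patient": patient,
                    "region": r,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "alt_reads": alt_reads,
                    "total_reads": int(dp),
                    "purity": 1.0,
                    "cn_total": 2,
                    "multiplicity": 1,
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
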