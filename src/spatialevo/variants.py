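"""Presence calling, CCF computation, trunk/branched/private
classification and burden/heterogeneity summaries.

A mutation is *trunk* when present in every sampled region of a patient,
*private* when present in exactly one, and *branched* otherwise.  Genetic
intra-tumor heterogeneity (gITH) is the heterogeneous (branched + private)
fraction of classified mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable

import numpy as np
import pandas as pd

VARIANT_KEY_COLS = ["chrom", "pos", "ref", "alt"]

DEFAULT_MIN_ALT = 3
DEFAULT_MIN_VAF = 0.02


def variant_key(df: pd.DataFrame) -> pd.Series:
    """Canonical ``chrom:pos:ref:alt`` key (1-based coordinates)."""
    return (
        df["chrom"].astype(str)
        + ":" + df["pos"].astype(str)
        + ":" + df["ref"].astype(str)
        + ":" + df["alt"].astype(str)
    )


@dataclass
class PresenceMatrix:
    """Boolean mutation x region matrix for one patient."""

    patient: str
    matrix: pd.DataFrame            # index: variant key, columns: region labels
    min_alt: int
    min_vaf: float
    n_dropped_absent: int = 0
    zero_depth_flagged: int = 0

    @property
    def regions(self):
        return list(self.matrix.columns)

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[1]


def compute_presence(
    calls: pd.DataFrame,
    min_alt: int = DEFAULT_MIN_ALT,
    min_vaf: float = DEFAULT_MIN_VAF,
) -> Dict[str, PresenceMatrix]:
    """Presence matrices per patient from a MutationCall table.

    A variant is present in a region iff ``alt_reads >= min_alt`` and
    ``VAF >= min_vaf``.  Variants observed in no region of a patient are
    dropped and counted.  Variant/region combinations missing from the
    table are imputed as 0 alt reads; rows with zero total reads are
    treated as absent and flagged.
    """
    if (calls["alt_reads"] > calls["total_reads"]).any():
        raise ValueError("alt_reads > total_reads")
    if (calls["alt_reads"] < 0).any():
        raise ValueError("negative alt_reads")
    key = calls["key"] if "key" in calls.columns else variant_key(calls)
    total = calls["total_reads"].to_numpy()
    vaf = np.where(total > 0, calls["alt_reads"].to_numpy() / np.clip(total, 1, None), 0.0)
    present = (calls["alt_reads"].to_numpy() >= min_alt) & (vaf >= min_vaf)
    flat = pd.DataFrame(
        {
            "patient": calls["patient"].to_numpy(),
            "region": calls["region"].to_numpy(),
            "_key": key.to_numpy(),
            "p": present,
            "zd": total == 0,
        }
    )
    out: Dict[str, PresenceMatrix] = {}
    for pat, sub in flat.groupby("patient", sort=True):
        kcodes, keys = pd.factorize(sub["_key"], sort=True)
        rcodes, regs = pd.factorize(sub["region"], sort=True)
        mat = np.zeros((len(keys), len(regs)), dtype=np.uint8)
        np.maximum.at(mat, (kcodes, rcodes), sub["p"].to_numpy(dtype=np.uint8))
        mat = pd.DataFrame(mat.astype(bool), index=keys, columns=list(regs))
        any_present = mat.any(axis=1)
        out[str(pat)] = PresenceMatrix(
            patient=str(pat),
            matrix=mat.loc[any_present],
            min_alt=min_alt,
            min_vaf=min_vaf,
            n_dropped_absent=int((~any_present).sum()),
            zero_depth_flagged=int(sub["zd"].sum()),
        )
    return out


def compute_ccf(vaf, purity, cn_total=2, multiplicity=1):
    """Cancer-cell fraction under the standard purity/copy-number model.

    ``CCF = VAF * (purity * cn_total + (1 - purity) * 2) / (purity * m)``,
    capped at 1.  Returns ``(ccf, capped_flag)``; array inputs broadcast.
    """
    vaf = np.asarray(vaf, dtype=float)
    purity = np.asarray(purity, dtype=float)
    cn_total = np.asarray(cn_total, dtype=float)
    multiplicity = np.asarray(multiplicity, dtype=float)
    if np.any(purity <= 0.0):
        raise ValueError("purity must be > 0")
    if np.any(purity > 1.0) or np.any(vaf < 0.0) or np.any(vaf > 1.0):
        raise ValueError("vaf/purity outside valid range")
    if np.any(cn_total < 1) or np.any(multiplicity < 1):
        raise ValueError("cn_total and multiplicity must be >= 1")
    raw = vaf * (purity * cn_total + (1.0 - purity) * 2.0) / (purity * multiplicity)
    capped = raw > 1.0
    ccf = np.minimum(raw, 1.0)
    if ccf.ndim == 0:
        return float(ccf), bool(capped)
    return ccf, capped


def add_ccf_column(calls: pd.DataFrame) -> pd.DataFrame:
    """MutationCall table with ``vaf``, ``ccf`` and ``ccf_capped`` columns."""
    out = calls.copy()
    total = out["total_reads"].to_numpy()
    vaf = np.where(total > 0, out["alt_reads"] / np.clip(total, 1, None), 0.0)
    mult = out["multiplicity"].to_numpy() if "multiplicity" in out else 1
    cn = out["cn_total"].to_numpy() if "cn_total" in out else 2
    ccf, capped = compute_ccf(vaf, out["purity"].to_numpy(), cn, mult)
    out["vaf"] = vaf
    out["ccf"] = ccf
    out["ccf_capped"] = capped
    return out


def classify_mutations(pm: PresenceMatrix) -> pd.Series:
    """Per-mutation class (``trunk`` / ``branched`` / ``private``).

    Refuses single-region patients: with one sample the trunk/private
    distinction is undefined.
    """
    if pm.n_regions < 2:
        raise ValueError(f"patient {pm.patient}: classification needs >= 2 regions")
    n_present = pm.matrix.sum(axis=1)
    cls = np.where(
        n_present == pm.n_regions, "trunk", np.where(n_present == 1, "private", "branched")
    )
    return pd.Series(cls, index=pm.matrix.index, name="class")


@dataclass
class BurdenSummary:
    """Per-sample and per-patient mutation burden plus gITH."""

    patient: str
    sample_burden: Dict[str, float]     # mutations / Mb per region
    patient_burden: float               # unique mutations / Mb
    n_trunk: int
    n_branched: int
    n_private: int
    gith: float

    @property
    def n_total(self) -> int:
        return self.n_trunk + self.n_branched + self.n_private


def burden_and_gith(
    pm: PresenceMatrix,
    classes: pd.Series,
    exome_size_mb: float = 38.0,
) -> BurdenSummary:
    """Burden (mutations/Mb) per sample and patient, and the gITH fraction."""
    if exome_size_mb <= 0:
        raise ValueError("exome_size_mb must be > 0")
    counts = classes.value_counts()
    n_trunk = int(counts.get("trunk", 0))
    n_branched = int(counts.get("branched", 0))
    n_private = int(counts.get("private", 0))
    total = n_trunk + n_branched + n_private
    gith = (n_branched + n_private) / total if total else float("nan")
    return BurdenSummary(
        patient=pm.patient,
        sample_burden={r: pm.matrix[r].sum() / exome_size_mb for r in pm.regions},
        patient_burden=pm.matrix.shape[0] / exome_size_mb,
        n_trunk=n_trunk,
        n_branched=n_branched,
        n_private=n_private,
        gith=gith,
    )


def cohort_burden_table(summaries: Iterable[BurdenSummary]) -> pd.DataFrame:
    rows = [
        {
            "patient": s.patient,
            "patient_burden_per_mb": s.patient_burden,
            "max_sample_burden_per_mb": max(s.sample_burden.values()),
            "n_trunk": s.n_trunk,
            "n_branched": s.n_branched,
            "n_private": s.n_private,
            "gith": s.gith,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
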