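"""Cohort-level directed-expansion statistics.

Subclones shared between the tumor center (T5) and a margin leave branched
clades containing both labels; if expansion is directionally biased toward
the oral side, T5+T1 clades outnumber T5+T3 clades.  The sharing
frequencies are compared with a patient-resampling bootstrap.  The same
machinery serves the minimal-immune-distance contrast (which margin's cell
composition is closest to the center's) and Fisher tests for covariate
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import hypergeom

from spatialevo.phylogeny import CladeTable

MARGINS = ("T1", "T2", "T3", "T4")


# ---------------------------------------------------------------------------
# clade sharing

@dataclass
class SharingFrequencies:
    """Fraction of center-involving branched clades shared with each margin."""

    clade_level: Dict[str, float]
    patient_level: Dict[str, float]      # fraction of patients with >= 1 such clade
    lateral_clade_level: float           # T2 and T4 pooled
    n_center_branched: int
    n_patients: int
    missing: bool = False


def _sharing_from_df(df: pd.DataFrame) -> Tuple[Dict[str, float], int]:
    b5 = df[(df["class"] == "branched") & df["involves_center"]]
    n = len(b5)
    if n == 0:
        return {m: float("nan") for m in MARGINS}, 0
    freq = {
        "T1": float(b5["involves_upper"].mean()),
        "T3": float(b5["involves_lower"].mean()),
        "T2": float(b5["regions"].str.split("|").apply(lambda r: "T2" in r).mean()),
        "T4": float(b5["regions"].str.split("|").apply(lambda r: "T4" in r).mean()),
    }
    return freq, n


def clade_sharing_frequencies(ct: CladeTable) -> SharingFrequencies:
    """Per-margin frequency of branched clades shared with the center.

    ``freq(X)`` is the fraction of branched clades containing T5 that also
    contain margin X; the patient-level version asks whether a patient has
    at least one T5+X branched clade.  With no center-involving branched
    clades the result is flagged missing.
    """
    freq, n = _sharing_from_df(ct.df)
    pats = ct.df["patient"].unique()
    b5 = ct.df[(ct.df["class"] == "branched") & ct.df["involves_center"]]
    lat = float("nan")
    if n > 0:
        split = b5["regions"].str.split("|")
        pat_freq = {
            m: len(b5[split.apply(lambda r, m=m: m in r)]["patient"].unique())
            / len(pats) if len(pats) else float("nan")
            for m in MARGINS
        }
        lat = float(split.apply(lambda r: "T2" in r or "T4" in r).mean())
    else:
        pat_freq = {m: (0.0 if len(pats) else float("nan")) for m in MARGINS}
    return SharingFrequencies(
        clade_level=freq,
        patient_level=pat_freq,
        lateral_clade_level=lat,
        n_center_branched=n,
        n_patients=len(pats),
        missing=n == 0,
    )


@dataclass
class DirectedStats:
    """Bootstrap test of upward-biased clade sharing."""

    frequencies: SharingFrequencies
    contrasts: Dict[str, float]          # observed freq(T1) - freq(margin)
    p_values: Dict[str, float]           # one-sided bootstrap p per contrast
    t_p_values: Dict[str, float]         # one-sample t over replicates
    boot_diffs: Dict[str, np.ndarray]
    n_boot: int
    seed: int
    two_sided: bool = False


def bootstrap_sharing_test(
    ct: CladeTable,
    n_boot: int = 100,
    seed: int = 0,
    two_sided: bool = False,
    resample: str = "patients",
) -> DirectedStats:
    """Patient-resampling bootstrap of freq(T1) minus each other margin.

    The one-sided p-value is the fraction of bootstrap replicates in which
    the difference is <= 0 (alternative: upward bias).  A one-sample
    Student's t over the replicate differences is reported alongside.
    ``resample="clades"`` bootstraps clade rows instead of patients.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    pats = np.array(sorted(ct.df["patient"].unique()))
    if resample == "patients" and pats.size < 5:
        raise ValueError("bootstrap needs >= 5 patients")
    obs = clade_sharing_frequencies(ct)
    rng = np.random.default_rng(seed)
    others = [m for m in MARGINS if m != "T1"]
    diffs = {m: np.full(n_boot, np.nan) for m in others}
    df = ct.df

    # per-unit counts: center-involving branched clades and their margin overlaps
    b5 = df[(df["class"] == "branched") & df["involves_center"]].copy()
    in_margin = {
        m: b5["regions"].str.split("|").apply(lambda r, m=m: m in r).to_numpy(dtype=np.int64)
        for m in MARGINS
    }
    if resample == "patients":
        pat_idx = {p: i for i, p in enumerate(pats)}
        codes = b5["patient"].map(pat_idx).to_numpy(dtype=np.int64)
        n_units = pats.size
        tot = np.bincount(codes, minlength=n_units).astype(np.int64)
        marg = {m: np.bincount(codes, weights=in_margin[m], minlength=n_units)
                for m in MARGINS}
    elif resample == "clades":
        n_units = len(b5)
        tot = np.ones(n_units, dtype=np.int64)
        marg = {m: in_margin[m].astype(float) for m in MARGINS}
    else:
        raise ValueError("resample must be 'patients' or 'clades'")
    if n_units:
        draws = rng.integers(n_units, size=(n_boot, n_units))
        tot_rep = tot[draws].sum(axis=1).astype(float)
        ok = tot_rep > 0
        f1 = np.where(ok, marg["T1"][draws].sum(axis=1) / np.where(ok, tot_rep, 1), np.nan)
        for m in others:
            fm = np.where(ok, marg[m][draws].sum(axis=1) / np.where(ok, tot_rep, 1), np.nan)
            diffs[m] = f1 - fm
    p_values: Dict[str, float] = {}
    t_p: Dict[str, float] = {}
    contrasts: Dict[str, float] = {}
    for m in others:
        d = diffs[m][~np.isnan(diffs[m])]
        contrasts[m] = obs.clade_level["T1"] - obs.clade_level[m] if not obs.missing else float("nan")
        if d.size == 0:
            p_values[m] = float("nan")
            t_p[m] = float("nan")
            continue
        p_low = float((d <= 0).mean())
        if two_sided:
            p_values[m] = float(2 * min(p_low, (d >= 0).mean()))
        else:
            p_values[m] = p_low
        if np.allclose(d, d[0]):
            t_p[m] = 1.0 if d[0] == 0 else 0.0
        else:
            t_res = stats.ttest_1samp(d, 0.0, alternative="two-sided" if two_sided else "greater")
            t_p[m] = float(t_res.pvalue)
    return DirectedStats(
        frequencies=obs,
        contrasts=contrasts,
        p_values=p_values,
        t_p_values=t_p,
        boot_diffs=diffs,
        n_boot=n_boot,
        seed=seed,
        two_sided=two_sided,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test

def fisher_2x2(table) -> Tuple[float, float, bool]:
    """Two-sided Fisher's exact test by hypergeometric enumeration.

    Sums the probabilities of all tables (with the observed margins) whose
    probability does not exceed the observed table's, using the customary
    relative tolerance guard against floating-point boundary misses.
    Returns ``(odds_ratio, p_value, haldane_flag)``; the odds ratio uses
    the Haldane 0.5 correction when any cell is zero (flagged).

    Raises on negative entries or an all-zero margin.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        raise ValueError("a margin of the table is zero")
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = float(hypergeom.pmf(a, n, c1, r1))
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    p = min(p, 1.0)
    haldane = (t == 0).any()
    if haldane:
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)
    odds = (a_ * d_) / (b_ * c_)
    return float(odds), p, bool(haldane)


# ---------------------------------------------------------------------------
# minimal immune distance

@dataclass
class ImmuneDistanceResult:
    per_patient: pd.DataFrame            # patient, nearest_margin, distance, tie
    frequencies: Dict[str, float]
    p_values: Dict[str, float]           # freq(T1) vs freq(margin), bootstrap
    n_boot: int
    seed: int
    skipped_patients: List[str]


def _manhattan(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.abs(u - v).sum())


def nearest_margin_bootstrap(
    cells: pd.DataFrame,
    metric: str = "manhattan",
    n_boot: int = 100,
    seed: int = 0,
) -> ImmuneDistanceResult:
    """Which margin's cell composition is closest to the center's?

    ``cells`` has columns ``patient``, ``region`` plus the cell-type
    fractions.  Per patient the margin minimising the Manhattan distance
    to T5's vector is chosen (ties -> lowest region index, flagged);
    patients without T5 or with fewer than two margins are skipped.  The
    cohort frequency of each margin is compared to T1's with the same
    patient-resampling bootstrap as the clade-sharing test.
    """
    if metric != "manhattan":
        raise ValueError("only the manhattan metric is built in")
    value_cols = [c for c in cells.columns if c not in ("patient", "region")]
    rows = []
    skipped: List[str] = []
    for pat, sub in cells.groupby("patient", sort=True):
        sub = sub.set_index("region")
        if "T5" not in sub.index:
            skipped.append(str(pat))
            continue
        margins = [m for m in MARGINS if m in sub.index]
        if len(margins) < 2:
            skipped.append(str(pat))
            continue
        t5 = sub.loc["T5", value_cols].to_numpy(dtype=float)
        dists = {m: _manhattan(t5, sub.loc[m, value_cols].to_numpy(dtype=float)) for m in margins}
        dmin = min(dists.values())
        nearest = [m for m in margins if dists[m] <= dmin + 1e-12]
        rows.append(
            {
                "patient": pat,
                "nearest_margin": sorted(nearest)[0],
                "distance": dmin,
                "tie": len(nearest) > 1,
            }
        )
    per_patient = pd.DataFrame(rows, columns=["patient", "nearest_margin", "distance", "tie"])
    n_pat = len(per_patient)
    freqs = {
        m: float((per_patient["nearest_margin"] == m).mean()) if n_pat else float("nan")
        for m in MARGINS
    }
    rng = np.random.default_rng(seed)
    others = [m for m in MARGINS if m != "T1"]
    p_values: Dict[str, float] = {}
    if n_pat:
        nearest_arr = per_patient["nearest_margin"].to_numpy()
        diffs = {m: np.empty(n_boot) for m in others}
        for i in range(n_boot):
            draw = nearest_arr[rng.integers(n_pat, size=n_pat)]
            for m in others:
                diffs[m][i] = (draw == "T1").mean() - (draw == m).mean()
        for m in others:
            p_values[m] = float((diffs[m] <= 0).mean())
    else:
        p_values = {m: float("nan") for m in others}
    return ImmuneDistanceResult(
        per_patient=per_patient,
        frequencies=freqs,
        p_values=p_values,
        n_boot=n_boot,
        seed=seed,
        skipped_patients=skipped,
    )
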