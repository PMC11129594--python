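"""Immune microenvironment typing and immunoediting scores.

Regions are typed hot/cold by cohort-wide agglomerative clustering of
their 11-type cell-fraction vectors (Manhattan distance, average linkage,
two clusters; hot = higher mean CD8+ T fraction).  A patient is hot or
cold when all regions agree and heterogeneous otherwise; immune ITH is the
mean pairwise Manhattan distance among a patient's region vectors.

The immunoediting (IM) score of a mutation set is the observed
neoantigenic yield divided by the expected yield under the set's
trinucleotide-context composition; values below 1 indicate neoantigen
depletion (strong immunoediting), values near 1 indicate no editing or
established immune evasion.  The cohort's strong/weak split is data driven
(two-component Gaussian mixture on log IM) with a deterministic IM = 1
fallback when the distribution is unimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.mixture import GaussianMixture

CD8_COLUMN = "CD8_T"


# ---------------------------------------------------------------------------
# hot/cold typing

@dataclass
class ImmuneTypeResult:
    region_labels: pd.Series             # index (patient, region) -> hot|cold
    patient_types: pd.Series             # patient -> hot|cold|het|undetermined
    iith: pd.Series                      # patient -> immune ITH
    linkage_method: str = "average"
    metric: str = "cityblock"


def cluster_hot_cold(cells: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Cohort-wide two-cluster cut of region cell fractions.

    Agglomerative clustering (Manhattan distance, average linkage) over
    ALL regions jointly; the cluster with the higher mean CD8+ T fraction
    is labelled hot.  Identical rows throughout are a degenerate state and
    raise.
    """
    value_cols = [c for c in cells.columns if c not in ("patient", "region")]
    X = cells[value_cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 regions to cluster")
    d = pdist(X, metric="cityblock")
    if np.all(d == 0):
        raise ValueError("degenerate input: all region vectors identical")
    Z = linkage(d, method="average")
    lab = fcluster(Z, t=2, criterion="maxclust")
    cd8 = cells[CD8_COLUMN].to_numpy(dtype=float)
    mean1 = cd8[lab == 1].mean()
    mean2 = cd8[lab == 2].mean() if (lab == 2).any() else -np.inf
    hot_cluster = 1 if mean1 >= mean2 else 2
    out = pd.Series(
        np.where(lab == hot_cluster, "hot", "cold"),
        index=pd.MultiIndex.from_frame(cells[["patient", "region"]]),
        name="immune_label",
    )
    return out


def patient_immune_type(
    region_labels: pd.Series,
    cells: Optional[pd.DataFrame] = None,
) -> ImmuneTypeResult:
    """Patient typing (hot / cold / het) and immune ITH.

    A patient is hot (cold) iff every region is hot (cold), heterogeneous
    otherwise; single-region patients are undetermined.  iITH is the mean
    pairwise Manhattan distance among the patient's region vectors (in
    [0, 2] for simplex rows); it requires ``cells``.
    """
    types = {}
    for pat, sub in region_labels.groupby(level=0):
        vals = set(sub)
        if len(sub) < 2:
            types[pat] = "undetermined"
        elif vals == {"hot"}:
            types[pat] = "hot"
        elif vals == {"cold"}:
            types[pat] = "cold"
        else:
            types[pat] = "het"
    iith = {}
    if cells is not None:
        value_cols = [c for c in cells.columns if c not in ("patient", "region")]
        for pat, sub in cells.groupby("patient", sort=True):
            X = sub[value_cols].to_numpy(dtype=float)
            iith[pat] = float(pdist(X, metric="cityblock").mean()) if len(X) > 1 else float("nan")
    return ImmuneTypeResult(
        region_labels=region_labels,
        patient_types=pd.Series(types, name="immune_type"),
        iith=pd.Series(iith, name="iith", dtype=float),
    )


# ---------------------------------------------------------------------------
# immunoediting score

DEFAULT_MIN_ELIGIBLE = 10


@dataclass
class IMResult:
    scope: str
    observed_neo: int
    eligible: int
    observed_rate: float
    expected_rate: float
    im_score: float
    low_confidence: bool
    status: Optional[str] = None         # strong | weak (set cohort-wide)


def flat_rate_table(rate: float) -> Dict[str, float]:
    """Expected neoantigen rate table that ignores context."""
    return {"*": rate}


def im_score(
    mutations: pd.DataFrame,
    expected_rate_table: Mapping[str, float],
    scope: str = "set",
    min_eligible: int = DEFAULT_MIN_ELIGIBLE,
    nonsyn_only: bool = True,
) -> IMResult:
    """Observed / expected neoantigen yield of a mutation set.

    ``mutations`` needs ``neoantigen_flag`` and ``context`` columns (plus
    ``consequence`` when ``nonsyn_only``).  The expected rate is the
    context-composition-weighted mean of the table's per-context rates; a
    table key ``"*"`` matches any context.  Sets smaller than
    ``min_eligible`` are flagged low confidence.
    """
    df = mutations
    if nonsyn_only and "consequence" in df.columns:
        df = df[df["consequence"] == "nonsyn"]
    eligible = len(df)
    if eligible == 0:
        return IMResult(scope, 0, 0, float("nan"), float("nan"), float("nan"), True)
    obs_neo = int(df["neoantigen_flag"].sum())
    obs_rate = obs_neo / eligible
    if "*" in expected_rate_table:
        exp_rate = float(expected_rate_table["*"])
    else:
        comp = df["context"].value_counts(normalize=True)
        missing = [c for c in comp.index if c not in expected_rate_table]
        if missing:
            raise ValueError(f"contexts missing from the rate table: {missing}")
        exp_rate = float(sum(w * expected_rate_table[c] for c, w in comp.items()))
    if exp_rate <= 0:
        raise ValueError("expected rate is zero: invalid rate table")
    return IMResult(
        scope=scope,
        observed_neo=obs_neo,
        eligible=eligible,
        observed_rate=obs_rate,
        expected_rate=exp_rate,
        im_score=obs_rate / exp_rate,
        low_confidence=eligible < min_eligible,
    )


def im_by_clade(
    clade_mutations: Mapping[str, pd.DataFrame],
    clade_regions: Mapping[str, Iterable[str]],
    expected_rate_table: Mapping[str, float],
    min_eligible: int = DEFAULT_MIN_ELIGIBLE,
    alternative: str = "less",
) -> Tuple[pd.DataFrame, float, float]:
    """IM score per clade plus the upper-margin contrast.

    Branched clades involving T1 are compared to the remaining branched
    clades with a Wilcoxon rank-sum test (default alternative: T1 clades
    have *lower* IM, i.e. stronger immunoediting).  Clades below the
    eligibility threshold are excluded and reported with NaN scores.

    Returns ``(per-clade table, rank-sum statistic, p-value)``; the
    contrast is NaN when either group has fewer than two clades.
    """
    rows = []
    for cid, muts in clade_mutations.items():
        res = im_score(muts, expected_rate_table, scope=f"clade:{cid}",
                       min_eligible=min_eligible)
        regions = set(clade_regions[cid])
        rows.append(
            {
                "clade": cid,
                "im_score": res.im_score if not res.low_confidence else float("nan"),
                "eligible": res.eligible,
                "excluded": res.low_confidence,
                "involves_t1": "T1" in regions,
            }
        )
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["im_score"])
    g1 = ok[ok["involves_t1"]]["im_score"]
    g0 = ok[~ok["involves_t1"]]["im_score"]
    if len(g1) < 2 or len(g0) < 2:
        return table, float("nan"), float("nan")
    res = stats.mannwhitneyu(g1, g0, alternative=alternative)
    return table, float(res.statistic), float(res.pvalue)


def im_status_threshold(
    im_scores: Mapping[str, float],
    seed: int = 0,
) -> Tuple[pd.Series, Dict[str, float]]:
    """Strong/weak immunoediting split of cohort trunk IM scores.

    Fits one- and two-component Gaussian mixtures to log IM and keeps the
    two-mode model when BIC prefers it; the strong (low-IM) side of the
    equal-posterior boundary is labelled ``strong``.  With a unimodal fit
    the deterministic fallback threshold IM = 1 applies (strong iff
    IM < 1).  Nonpositive scores are excluded and reported.

    Returns ``(labels, info)`` with the boundary and mode means in info.
    """
    s = pd.Series(im_scores, dtype=float)
    bad = s[(s <= 0) | ~np.isfinite(s)]
    ok = s.drop(bad.index)
    if len(ok) < 10:
        raise ValueError("need >= 10 positive IM scores")
    x = np.log(ok.to_numpy())[:, None]
    gm1 = GaussianMixture(1, random_state=seed, n_init=3).fit(x)
    gm2 = GaussianMixture(2, random_state=seed, n_init=10).fit(x)
    info: Dict[str, float] = {"n_excluded": float(len(bad))}
    if gm2.bic(x) < gm1.bic(x):
        means = gm2.means_.ravel()
        low = int(np.argmin(means))
        post = gm2.predict_proba(x)
        labels = np.where(post[:, low] >= 0.5, "strong", "weak")
        # equal-posterior boundary on the log scale, for reporting
        grid = np.linspace(x.min(), x.max(), 512)[:, None]
        pg = gm2.predict_proba(grid)[:, low]
        cross = np.nonzero(np.diff(pg >= 0.5))[0]
        boundary = float(np.exp(grid[cross[0], 0])) if cross.size else float("nan")
        info.update(
            bimodal=1.0, boundary=boundary,
            mode_low=float(np.exp(means[low])), mode_high=float(np.exp(means.max())),
        )
    else:
        labels = np.where(ok.to_numpy() < 1.0, "strong", "weak")
        info.update(bimodal=0.0, boundary=1.0,
                    mode_low=float("nan"), mode_high=float("nan"))
    out = pd.Series(labels, index=ok.index, name="im_status")
    return out, info
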