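"""Neutral-evolution testing, subclone reconstruction and selection scores.

Neutral exponential growth predicts a cumulative site-frequency spectrum
M(f) proportional to 1/f - 1/f_max over the subclonal frequency window;
the test fits that line and calls a tumor non-neutral when the fit is poor.
Subclonal structure is recovered with a binomial mixture over alt read
counts (component success probabilities purity * CCF / 2), selected by
BIC.  The regional clonality score (RCS) is the CCF of the most clonal
*subclonal* mixture component - high values mean a subclone swept close to
fixation in that region, the footprint of recent positive selection.
Between-region divergence uses the Hudson FST estimator on variant allele
frequencies with read depth as the sample-size proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

# ---------------------------------------------------------------------------
# 1/f neutrality test

DEFAULT_F_MIN = 0.12
DEFAULT_F_MAX = 0.24
DEFAULT_R2_THRESHOLD = 0.98
MIN_WINDOW_MUTATIONS = 12


@dataclass
class NeutralityResult:
    r_squared: float
    f_min: float
    f_max: float
    n_in_window: int
    verdict: str            # "neutral" | "non-neutral" | "indeterminate"
    threshold: float

    @property
    def neutral(self) -> bool:
        return self.verdict == "neutral"


def neutrality_test(
    vafs: Sequence[float],
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    evaluation: str = "points",
    grid_points: int = 50,
) -> NeutralityResult:
    """Cumulative 1/f site-frequency-spectrum test.

    ``M(f)`` counts mutations with VAF between ``f`` and ``f_max`` (so
    ``M(f_max) = 0``) and is regressed *through the origin* on
    ``1/f - 1/f_max``; the goodness of fit is the uncentered R-squared of
    the zero-intercept model, matching the convention of the established
    neutrality-test tooling.  ``evaluation="points"`` (default) evaluates
    M at the observed in-window VAFs; ``"grid"`` uses a uniform grid of
    ``grid_points`` frequencies.  Neutrality requires R-squared at or
    above the threshold; fewer than 12 mutations inside the window yield
    an ``indeterminate`` verdict.
    """
    if f_min >= f_max:
        raise ValueError("f_min must be < f_max")
    if f_min <= 0.0 or f_max > 0.5:
        raise ValueError("window must lie in (0, 0.5]")
    v = np.asarray(vafs, dtype=float)
    in_window = v[(v >= f_min) & (v <= f_max)]
    n_window = int(in_window.size)
    if n_window < MIN_WINDOW_MUTATIONS:
        return NeutralityResult(float("nan"), f_min, f_max, n_window,
                                "indeterminate", r2_threshold)
    if evaluation == "points":
        f_eval = np.sort(in_window)[::-1]
        M = np.arange(1, n_window + 1, dtype=float)
    elif evaluation == "grid":
        f_eval = np.linspace(f_min, f_max, grid_points)
        M = ((v[None, :] >= f_eval[:, None]) & (v[None, :] <= f_max)).sum(axis=1).astype(float)
    else:
        raise ValueError("evaluation must be 'points' or 'grid'")
    x = 1.0 / f_eval - 1.0 / f_max
    denom = float(x @ x)
    slope = float(x @ M) / denom if denom > 0 else 0.0
    resid = M - slope * x
    ss_res = float(resid @ resid)
    ss_tot = float(M @ M)
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    verdict = "neutral" if r2 >= r2_threshold else "non-neutral"
    return NeutralityResult(float(r2), f_min, f_max, n_window, verdict, r2_threshold)


# ---------------------------------------------------------------------------
# binomial mixture subclone clustering

@dataclass
class SubcloneClusterSet:
    """Binomial mixture fit of one region's alt read counts."""

    K: int
    ccf_means: np.ndarray       # descending
    weights: np.ndarray
    assigned_counts: np.ndarray
    log_likelihood: float
    bic_by_k: Dict[int, float]
    purity: float
    seed: int
    n_mutations: int


def _em_binomial(alt, tot, p_init, purity, tol, max_iter):
    """EM for a K-component binomial mixture, batched over restarts.

    ``p_init`` has shape (R, K); all R restarts iterate together (one big
    vectorised E/M step per iteration) and each stops contributing once its
    log-likelihood change falls below ``tol``.  Returns the best restart's
    ``(p, w, loglik)``.
    """
    p = np.atleast_2d(p_init).astype(float)          # (R, K)
    R, K = p.shape
    w = np.full((R, K), 1.0 / K)
    logcoef = gammaln(tot + 1) - gammaln(alt + 1) - gammaln(tot - alt + 1)
    lo, hi = 1e-6, purity / 2.0
    ll_old = np.full(R, -np.inf)
    active = np.ones(R, dtype=bool)
    for _ in range(max_iter):
        pc = np.clip(p[active], lo, hi)              # (A, K)
        logpmf = (
            logcoef[None, :, None]
            + alt[None, :, None] * np.log(pc[:, None, :])
            + (tot - alt)[None, :, None] * np.log1p(-pc[:, None, :])
        )                                            # (A, n, K)
        logr = np.log(np.maximum(w[active], 1e-300))[:, None, :] + logpmf
        mx = logr.max(axis=2, keepdims=True)
        norm = (mx + np.log(np.exp(logr - mx).sum(axis=2, keepdims=True)))[:, :, 0]
        ll = norm.sum(axis=1)
        r = np.exp(logr - norm[:, :, None])
        w_new = r.mean(axis=1)
        denom = np.einsum("ank,n->ak", r, tot)
        num = np.einsum("ank,n->ak", r, alt)
        p_new = np.where(denom > 0, num / np.maximum(denom, 1e-300), lo)
        idx = np.flatnonzero(active)
        w[idx] = w_new
        p[idx] = p_new
        done = np.abs(ll - ll_old[idx]) < tol
        ll_old[idx] = ll
        active[idx[done]] = False
        if not active.any():
            break
    best = int(np.argmax(ll_old))
    return np.clip(p[best], lo, hi), w[best], float(ll_old[best])


def fit_vaf_clusters(
    alt_reads: Sequence[int],
    total_reads: Sequence[int],
    purity: float,
    K_max: int = 5,
    n_restarts: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SubcloneClusterSet:
    """Binomial mixture over alt counts with BIC model selection.

    Component success probabilities are ``purity * CCF / 2`` with CCF in
    [0, 1].  Initialisation is k-means style (random data points as
    centres) with ``n_restarts`` restarts per K; K runs over 1..K_max.
    Rows with zero alt reads are dropped first; an empty or too-small
    (< 10) input raises.
    """
    alt = np.asarray(alt_reads, dtype=float)
    tot = np.asarray(total_reads, dtype=float)
    if alt.size != tot.size:
        raise ValueError("alt/total length mismatch")
    keep = alt > 0
    alt, tot = alt[keep], tot[keep]
    if alt.size == 0:
        raise ValueError("no mutations with alt reads > 0")
    if alt.size < 10:
        raise ValueError("need >= 10 mutations with alt reads")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    vaf = alt / tot
    n = alt.size

    best_by_k: Dict[int, Tuple[float, np.ndarray, np.ndarray]] = {}
    for K in range(1, K_max + 1):
        centers = rng.choice(vaf, size=(n_restarts, K), replace=True)
        centers = np.clip(centers + rng.normal(0, 0.01, (n_restarts, K)),
                          1e-4, purity / 2)
        p, w, ll = _em_binomial(alt, tot, centers, purity, tol, max_iter)
        best_by_k[K] = (ll, p, w)

    bic = {K: float(-2.0 * v[0] + (2 * K - 1) * np.log(n)) for K, v in best_by_k.items()}
    K_sel = min(bic, key=lambda k: (bic[k], k))
    ll, p, w = best_by_k[K_sel]

    logcoef = gammaln(tot + 1) - gammaln(alt + 1) - gammaln(tot - alt + 1)
    logpmf = (
        logcoef[:, None] + alt[:, None] * np.log(p[None, :])
        + (tot - alt)[:, None] * np.log1p(-p[None, :])
    )
    assign = np.argmax(np.log(np.maximum(w, 1e-300))[None, :] + logpmf, axis=1)
    counts = np.bincount(assign, minlength=K_sel)

    ccf = np.clip(2.0 * p / purity, 0.0, 1.0)
    order = np.argsort(-ccf, kind="stable")
    return SubcloneClusterSet(
        K=K_sel,
        ccf_means=ccf[order],
        weights=w[order],
        assigned_counts=counts[order],
        log_likelihood=float(ll),
        bic_by_k=bic,
        purity=purity,
        seed=seed,
        n_mutations=n,
    )


# ---------------------------------------------------------------------------
# regional clonality score

DEFAULT_CLONAL_CCF_CUT = 0.9


@dataclass
class RCSResult:
    per_region: Dict[str, float]
    tumor_median: float


def regional_clonality_score(
    clusters: SubcloneClusterSet,
    clonal_ccf_cut: float = DEFAULT_CLONAL_CCF_CUT,
) -> float:
    """CCF of the most clonal subclonal component (0 when purely clonal).

    Components at or above ``clonal_ccf_cut`` are considered clonal and
    skipped; the score is the mean CCF of the highest remaining component.
    """
    for c in clusters.ccf_means:
        if c < clonal_ccf_cut:
            return float(c)
    return 0.0


def summarize_rcs(per_region: Dict[str, float]) -> RCSResult:
    vals = [v for v in per_region.values() if np.isfinite(v)]
    med = float(np.median(vals)) if vals else float("nan")
    return RCSResult(per_region=dict(per_region), tumor_median=med)


def cohort_rcs_split(tumor_medians: Dict[str, float]) -> pd.DataFrame:
    """High/low split of per-tumor median RCS at the cohort median."""
    s = pd.Series(tumor_medians, name="rcs_median").dropna()
    cut = float(s.median())
    return pd.DataFrame(
        {"rcs_median": s, "rcs_group": np.where(s > cut, "high", "low")}
    ).rename_axis("patient")


# ---------------------------------------------------------------------------
# Hudson FST

@dataclass
class DivergenceResult:
    pairs: pd.DataFrame          # region_a, region_b, fst, n_sites, n_skipped
    longitudinal: float          # T1 vs T3
    transverse: float            # T2 vs T4


def fst_pairwise(
    vafs_a: Sequence[float],
    vafs_b: Sequence[float],
    depths_a: Optional[Sequence[float]] = None,
    depths_b: Optional[Sequence[float]] = None,
    corrected: bool = True,
) -> Tuple[float, int, int]:
    """Hudson FST between two regions' allele-frequency vectors.

    Per shared site: numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) -
    p2(1-p2)/(n2-1)`` (sampling terms dropped when ``corrected=False``),
    denominator ``p1(1-p2) + p2(1-p1)``; the estimate is the ratio of
    averages across sites, clamped to [0, 1].  Sites with depth < 2 (when
    correcting) or zero denominator are skipped and counted.

    Returns ``(fst, n_sites_used, n_skipped)``.
    """
    p1 = np.asarray(vafs_a, dtype=float)
    p2 = np.asarray(vafs_b, dtype=float)
    if p1.size != p2.size:
        raise ValueError("vaf vectors must share the variant universe")
    if corrected:
        if depths_a is None or depths_b is None:
            raise ValueError("corrected mode needs read depths")
        n1 = np.asarray(depths_a, dtype=float)
        n2 = np.asarray(depths_b, dtype=float)
        ok = (n1 >= 2) & (n2 >= 2)
    else:
        n1 = n2 = None
        ok = np.ones(p1.size, dtype=bool)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok &= den > 0
    n_skipped = int((~ok).sum())
    if not ok.any():
        return float("nan"), 0, n_skipped
    num = (p1 - p2) ** 2
    if corrected:
        num = num - p1 * (1 - p1) / np.maximum(n1 - 1, 1e-12) \
                  - p2 * (1 - p2) / np.maximum(n2 - 1, 1e-12)
    fst = float(np.clip(num[ok].sum() / den[ok].sum(), 0.0, 1.0))
    return fst, int(ok.sum()), n_skipped


def patient_fst_table(calls: pd.DataFrame, corrected: bool = True) -> DivergenceResult:
    """All pairwise region FSTs for one patient's MutationCall table."""
    from spatialevo.variants import variant_key

    df = calls.copy()
    df["_key"] = variant_key(df)
    alt = df.pivot_table(index="_key", columns="region", values="alt_reads", aggfunc="sum")
    dep = df.pivot_table(index="_key", columns="region", values="total_reads", aggfunc="sum")
    vaf = (alt / dep).fillna(0.0)
    dep = dep.fillna(0.0)
    regions = sorted(vaf.columns)
    rows = []
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            fst, n_used, n_skip = fst_pairwise(
                vaf[a], vaf[b], dep[a], dep[b], corrected=corrected
            )
            rows.append({"region_a": a, "region_b": b, "fst": fst,
                         "n_sites": n_used, "n_skipped": n_skip})
    pairs = pd.DataFrame(rows)

    def axis_val(a: str, b: str) -> float:
        hit = pairs[(pairs.region_a == a) & (pairs.region_b == b)]
        return float(hit.fst.iloc[0]) if len(hit) else float("nan")

    return DivergenceResult(
        pairs=pairs,
        longitudinal=axis_val("T1", "T3"),
        transverse=axis_val("T2", "T4"),
    )
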