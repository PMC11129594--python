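"""Pipeline orchestration: validation, staged analysis, reporting.

Stages run in dependency order — variants (presence / classification /
burden) feeds phylogeny (trees / clades) feeds the spatial
directed-expansion statistics, while selection (neutrality / subclones /
RCS / FST) and immune (typing / iITH / IM) run from the primary tables
independently — with a partial-failure policy: a failed stage halts its
dependents but not its siblings, and the bundle is always written with
per-stage status flags.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from spatialevo import immune, phylogeny, selection, spatial, variants
from spatialevo.simdata import SyntheticCohort

log = logging.getLogger("spatialevo.pipeline")

VALID_REGIONS = {"T1", "T2", "T3", "T4", "T5"} | {f"LN{i}" for i in range(1, 10)}


@dataclass
class AnalysisConfig:
    """Thresholds, switches and seeds for a full analysis run."""

    min_alt: int = variants.DEFAULT_MIN_ALT
    min_vaf: float = variants.DEFAULT_MIN_VAF
    exome_size_mb: float = 38.0
    f_min: float = selection.DEFAULT_F_MIN
    f_max: float = selection.DEFAULT_F_MAX
    r2_threshold: float = selection.DEFAULT_R2_THRESHOLD
    clonal_ccf_cut: float = selection.DEFAULT_CLONAL_CCF_CUT
    cluster_k_max: int = 4
    cluster_restarts: int = 10
    cluster_max_mutations: int = 800
    im_min_eligible: int = immune.DEFAULT_MIN_ELIGIBLE
    expected_neo_rate: float = 0.10
    n_boot: int = 100
    include_homoplastic: bool = False
    two_sided: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: List[str] = dc_field(default_factory=list)
    warnings: List[str] = dc_field(default_factory=list)
    excluded_patients: List[str] = dc_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    calls: pd.DataFrame,
    cell_fractions: Optional[pd.DataFrame] = None,
    clinical: Optional[pd.DataFrame] = None,
) -> ValidationReport:
    """Schema and consistency checks; hard failures vs warnings.

    Hard failures: missing columns, unknown region labels, read-count
    violations, cell-fraction rows off the simplex.  Warnings: patients
    with a single region (excluded from multi-region stages).
    """
    rep = ValidationReport()
    missing = [c for c in ("patient", "region", "alt_reads", "total_reads", "purity")
               if c not in calls.columns]
    if missing:
        rep.errors.append(f"mutation table missing columns: {missing}")
        return rep
    bad_regions = sorted(set(calls["region"].astype(str)) - VALID_REGIONS)
    if bad_regions:
        rep.errors.append(f"unknown region labels: {bad_regions}")
    if (calls["alt_reads"] > calls["total_reads"]).any():
        rep.errors.append("alt_reads exceed total_reads")
    if ((calls["purity"] <= 0) | (calls["purity"] > 1)).any():
        rep.errors.append("purity outside (0, 1]")
    for pat, sub in calls.groupby("patient"):
        n_primary = sub[~sub["region"].astype(str).str.startswith("LN")]["region"].nunique()
        if n_primary < 2:
            rep.warnings.append(f"patient {pat}: single primary region, excluded "
                                "from multi-region stages")
            rep.excluded_patients.append(str(pat))
        elif n_primary > 5:
            rep.errors.append(f"patient {pat}: {n_primary} primary regions (max 5)")
    if cell_fractions is not None:
        value_cols = [c for c in cell_fractions.columns if c not in ("patient", "region")]
        sums = cell_fractions[value_cols].sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            rep.errors.append(f"{int(off.sum())} cell-fraction rows off the simplex")
        if (cell_fractions[value_cols] < 0).any().any():
            rep.errors.append("negative cell fractions")
    return rep


@dataclass
class ReportBundle:
    """All stage outputs plus cohort summary and provenance."""

    tables: Dict[str, pd.DataFrame]
    summary: dict
    status: Dict[str, str]
    provenance: dict

    def digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=False).encode())
        h.update(json.dumps(self.summary, sort_keys=True, default=str).encode())
        return h.hexdigest()

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        payload = {
            "summary": self.summary,
            "status": self.status,
            "provenance": self.provenance,
            "digest": self.digest(),
        }
        (out / "summary.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1, default=str)
        )


def _patient_neutrality(calls_p: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Per-region 1/f tests; the patient verdict follows the center region
    (fallback: the region with the most in-window mutations)."""
    rows = {}
    for region, sub in calls_p.groupby("region"):
        vaf = (sub["alt_reads"] / sub["total_reads"].clip(lower=1)).to_numpy()
        rows[region] = selection.neutrality_test(
            vaf, cfg.f_min, cfg.f_max, cfg.r2_threshold
        )
    if not rows:
        return {"verdict": "indeterminate", "regions": rows}
    pick = "T5" if "T5" in rows else max(rows, key=lambda r: rows[r].n_in_window)
    return {"verdict": rows[pick].verdict, "region_used": pick,
            "r_squared": rows[pick].r_squared, "regions": rows}


def run_pipeline(
    cohort: SyntheticCohort | dict,
    config: Optional[AnalysisConfig] = None,
) -> ReportBundle:
    """Run the full analysis on a cohort (synthetic or user-assembled).

    ``cohort`` needs ``calls`` (a MutationCall table) and optionally
    ``cell_fractions`` / ``clinical`` frames; immune stages are skipped
    with a status flag when their inputs are absent.
    """
    from spatialevo import __version__

    if config is None:
        config = AnalysisConfig()
    calls = cohort.calls if hasattr(cohort, "calls") else cohort["calls"]
    cells = getattr(cohort, "cell_fractions", None) if hasattr(cohort, "cell_fractions") \
        else cohort.get("cell_fractions")
    clinical = getattr(cohort, "clinical", None) if hasattr(cohort, "clinical") \
        else cohort.get("clinical")

    status: Dict[str, str] = {}
    tables: Dict[str, pd.DataFrame] = {}
    summary: dict = {}

    report = validate_inputs(calls, cells, clinical)
    status["validation"] = "ok" if report.ok else "failed"
    summary["validation_warnings"] = len(report.warnings)
    if not report.ok:
        raise ValueError("validation failed: " + "; ".join(report.errors))
    excluded = set(report.excluded_patients)
    calls = calls[~calls["patient"].isin(excluded)]

    # ---- variants ---------------------------------------------------------
    pms: Dict[str, variants.PresenceMatrix] = {}
    clade_table = None
    try:
        pms = variants.compute_presence(calls, config.min_alt, config.min_vaf)
        burden_rows = []
        for pat, pm in pms.items():
            cls = variants.classify_mutations(pm)
            burden_rows.append(variants.burden_and_gith(pm, cls, config.exome_size_mb))
        burden = variants.cohort_burden_table(burden_rows)
        tables["burden"] = burden
        summary["n_patients"] = len(pms)
        summary["mean_gith"] = float(burden["gith"].mean())
        summary["median_patient_burden_per_mb"] = float(
            burden["patient_burden_per_mb"].median()
        )
        status["variants"] = "ok"
    except Exception as exc:
        status["variants"] = f"failed: {exc}"
        log.error("variants stage failed:\n%s", traceback.format_exc())

    # ---- phylogeny --------------------------------------------------------
    if status.get("variants") == "ok":
        try:
            clades = {}
            newicks = []
            for pat, pm in pms.items():
                tree = phylogeny.build_parsimony_tree(pm)
                clades[pat] = phylogeny.map_mutations_to_clades(tree)
                newicks.append({"patient": pat, "newick": tree.to_newick(),
                                "parsimony_score": tree.parsimony_score})
            clade_table = phylogeny.tabulate_clades(
                clades, include_homoplastic=config.include_homoplastic
            )
            tables["clades"] = clade_table.df
            tables["trees"] = pd.DataFrame(newicks)
            summary["clade_counts"] = clade_table.class_counts
            summary["branched_by_size"] = clade_table.branched_size_counts()
            summary["center_involvement_fraction"] = \
                clade_table.center_involvement_fraction()
            status["phylogeny"] = "ok"
        except Exception as exc:
            status["phylogeny"] = f"failed: {exc}"
            log.error("phylogeny stage failed:\n%s", traceback.format_exc())
    else:
        status["phylogeny"] = "skipped: variants failed"

    # ---- spatial ----------------------------------------------------------
    if status.get("phylogeny") == "ok" and clade_table is not None:
        try:
            ds = spatial.bootstrap_sharing_test(
                clade_table, n_boot=config.n_boot, seed=config.seed,
                two_sided=config.two_sided,
            )
            tables["sharing"] = pd.DataFrame(
                {
                    "margin": list(ds.frequencies.clade_level),
                    "clade_freq": list(ds.frequencies.clade_level.values()),
                    "patient_freq": [ds.frequencies.patient_level[m]
                                     for m in ds.frequencies.clade_level],
                    "p_vs_T1": [ds.p_values.get(m) for m in ds.frequencies.clade_level],
                }
            )
            summary["sharing_freq"] = {k: (round(v, 4) if v == v else None)
                                       for k, v in ds.frequencies.clade_level.items()}
            summary["sharing_p_upper_vs_lower"] = ds.p_values.get("T3")
            status["spatial"] = "ok"
        except Exception as exc:
            status["spatial"] = f"failed: {exc}"
            log.error("spatial stage failed:\n%s", traceback.format_exc())
    else:
        status["spatial"] = "skipped: phylogeny unavailable"

    # ---- selection --------------------------------------------------------
    try:
        neut_rows, rcs_rows, fst_rows = [], [], []
        rng = np.random.default_rng(config.seed)
        for pat, sub in calls.groupby("patient", sort=True):
            res = _patient_neutrality(sub, config)
            neut_rows.append({"patient": pat, "verdict": res["verdict"],
                              "region_used": res.get("region_used"),
                              "r_squared": res.get("r_squared", float("nan"))})
            per_region = {}
            pm = pms.get(str(pat))
            for region, rsub in sub.groupby("region"):
                if pm is not None and region in pm.matrix.columns:
                    present = set(pm.matrix.index[pm.matrix[region]])
                    key = rsub["key"] if "key" in rsub.columns else variants.variant_key(rsub)
                    rsub = rsub[key.isin(present)]
                if len(rsub) < 10:
                    continue
                if len(rsub) > config.cluster_max_mutations:
                    # subsample for the mixture fit: component means are
                    # unaffected and the cost is linear in the count
                    rsub = rsub.sample(config.cluster_max_mutations,
                                       random_state=int(rng.integers(2**31)))
                try:
                    cl = selection.fit_vaf_clusters(
                        rsub["alt_reads"], rsub["total_reads"],
                        purity=float(rsub["purity"].iloc[0]),
                        K_max=config.cluster_k_max,
                        n_restarts=config.cluster_restarts,
                        seed=int(rng.integers(2**31)),
                    )
                except ValueError:
                    continue
                per_region[region] = selection.regional_clonality_score(
                    cl, config.clonal_ccf_cut
                )
            rcs = selection.summarize_rcs(per_region)
            for region, val in rcs.per_region.items():
                rcs_rows.append({"patient": pat, "region": region, "rcs": val})
            rcs_rows.append({"patient": pat, "region": "_median",
                             "rcs": rcs.tumor_median})
            div = selection.patient_fst_table(sub)
            for row in div.pairs.itertuples():
                fst_rows.append({"patient": pat, "region_a": row.region_a,
                                 "region_b": row.region_b, "fst": row.fst})
        neut = pd.DataFrame(neut_rows)
        tables["neutrality"] = neut
        tables["rcs"] = pd.DataFrame(rcs_rows)
        tables["fst"] = pd.DataFrame(fst_rows)
        medians = {r["patient"]: r["rcs"] for r in rcs_rows if r["region"] == "_median"}
        tables["rcs_split"] = selection.cohort_rcs_split(medians).reset_index()
        summary["n_non_neutral"] = int((neut["verdict"] == "non-neutral").sum())
        summary["n_neutral"] = int((neut["verdict"] == "neutral").sum())
        summary["median_tumor_rcs"] = float(np.nanmedian(list(medians.values()))) \
            if medians else float("nan")
        status["selection"] = "ok"
    except Exception as exc:
        status["selection"] = f"failed: {exc}"
        log.error("selection stage failed:\n%s", traceback.format_exc())

    # ---- immune typing ----------------------------------------------------
    if cells is None or (hasattr(cells, "empty") and cells.empty):
        status["immune"] = "skipped: no cell fractions"
    else:
        try:
            labels = immune.cluster_hot_cold(cells, seed=config.seed)
            typing = immune.patient_immune_type(labels, cells)
            tables["immune_types"] = (
                typing.patient_types.rename_axis("patient").reset_index()
            )
            tables["iith"] = typing.iith.rename_axis("patient").reset_index()
            summary["immune_type_counts"] = typing.patient_types.value_counts().to_dict()
            idr = spatial.nearest_margin_bootstrap(cells, n_boot=config.n_boot,
                                                   seed=config.seed)
            tables["immune_distance"] = idr.per_patient
            summary["nearest_margin_freq"] = {k: round(v, 4) if v == v else None
                                              for k, v in idr.frequencies.items()}
            status["immune"] = "ok"
        except Exception as exc:
            status["immune"] = f"failed: {exc}"
            log.error("immune typing failed:\n%s", traceback.format_exc())

    # ---- immunoediting ----------------------------------------------------
    if "neoantigen_flag" in calls.columns and pms:
        try:
            rate_table = immune.flat_rate_table(config.expected_neo_rate)
            im_rows = []
            calls_by_patient = dict(tuple(calls.groupby("patient", sort=True)))
            for pat, pm in pms.items():
                cls = variants.classify_mutations(pm)
                trunk_keys = set(cls[cls == "trunk"].index)
                sub = calls_by_patient[pat]
                key = sub["key"] if "key" in sub.columns else variants.variant_key(sub)
                trunk_calls = sub[key.isin(trunk_keys)].drop_duplicates(
                    subset=["chrom", "pos", "ref", "alt"]
                )
                res = immune.im_score(trunk_calls, rate_table, scope=f"{pat}:trunk",
                                      min_eligible=config.im_min_eligible)
                im_rows.append({"patient": pat, "im_score": res.im_score,
                                "eligible": res.eligible,
                                "low_confidence": res.low_confidence})
            im_df = pd.DataFrame(im_rows)
            ok_scores = im_df[~im_df["low_confidence"]].set_index("patient")["im_score"]
            ok_scores = ok_scores.dropna()
            if len(ok_scores) >= 10:
                labels_im, _info = immune.im_status_threshold(
                    ok_scores.to_dict(), seed=config.seed
                )
                im_df["im_status"] = im_df["patient"].map(labels_im)
                summary["im_status_counts"] = labels_im.value_counts().to_dict()
            tables["im_scores"] = im_df
            summary["mean_trunk_im"] = float(np.nanmean(im_df["im_score"]))
            status["immunoediting"] = "ok"
        except Exception as exc:
            status["immunoediting"] = f"failed: {exc}"
            log.error("immunoediting stage failed:\n%s", traceback.format_exc())
    else:
        status["immunoediting"] = "skipped: no neoantigen flags"

    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    return ReportBundle(tables=tables, summary=summary, status=status,
                        provenance=provenance)
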