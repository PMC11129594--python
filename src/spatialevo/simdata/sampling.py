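"""Spatial disk sampling of simulated tumors and read-count sequencing.

Region anchors follow the clinical sampling scheme: T5 at the occupied-deme
centroid, T1 at the upper-most (oral) extreme, T3 at the lower-most
(gastric) extreme, T2/T4 at the two circumferential extremes.  True
cancer-cell fractions are computed over the cells inside a disk of demes
around each anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from spatialevo.simdata.engine import TumorState

PRIMARY_REGIONS = ("T1", "T2", "T3", "T4", "T5")

_SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class TruthTable:
    """Ground-truth mutation table for one sampled tumor.

    ``mutations`` has one row per mutation id (kind, neoantigen flag,
    origin step/deme); ``ccf`` holds the true cancer-cell fraction of each
    mutation in each sampled region.
    """

    mutations: pd.DataFrame
    ccf: pd.DataFrame
    region_cells: Dict[str, int]
    anchors: Dict[str, Tuple[int, int]]


def _circular_offset(cols: np.ndarray, ref: float, circumference: int) -> np.ndarray:
    """Signed shortest offset of each column from ``ref`` on the cylinder."""
    return (cols - ref + circumference / 2.0) % circumference - circumference / 2.0


def region_anchors(state: TumorState) -> Dict[str, Tuple[int, int]]:
    """Anchor demes for the five primary regions.

    T5 sits at the occupied deme nearest the tumor centroid (circular mean
    over the wraparound axis); T1/T3 at the upper-/lower-most occupied
    demes; T2/T4 at the extreme negative/positive circumferential offsets
    from the centroid column.
    """
    if state.n_cells == 0:
        raise ValueError("cannot anchor regions on an extinct tumor")
    C = state.config.lattice_circumference
    rows, cols = state.rows, state.cols
    ang = cols * (2.0 * np.pi / C)
    c_col = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) % (2.0 * np.pi)) * C / (2.0 * np.pi)
    c_row = rows.mean()

    off = _circular_offset(cols, c_col, C)
    d2 = (rows - c_row) ** 2 + off ** 2
    t5 = int(np.argmin(d2))

    def pick(mask_metric: np.ndarray, prefer_min: bool) -> int:
        best = mask_metric.min() if prefer_min else mask_metric.max()
        cand = np.flatnonzero(mask_metric == best)
        # among ties take the deme closest to the centroid axis
        return int(cand[np.argmin(d2[cand])])

    t1 = pick(rows, prefer_min=True)
    t3 = pick(rows, prefer_min=False)
    t2 = pick(off, prefer_min=True)
    t4 = pick(off, prefer_min=False)
    idx = {"T1": t1, "T2": t2, "T3": t3, "T4": t4, "T5": t5}
    return {k: (int(rows[i]), int(cols[i])) for k, i in idx.items()}


def _disk_cells(state: TumorState, anchor: Tuple[int, int], radius: int) -> np.ndarray:
    C = state.config.lattice_circumference
    dr = state.rows - anchor[0]
    dc = _circular_offset(state.cols, anchor[1], C)
    return np.flatnonzero(dr * dr + dc * dc <= radius * radius)


def _mutation_frame(state: TumorState, ids: Optional[np.ndarray] = None) -> pd.DataFrame:
    if ids is None:
        ids = np.arange(state.n_mutations)
    return pd.DataFrame(
        {
            "mut_id": ids,
            "kind": np.where(state.mut_is_driver[ids], "driver", "passenger"),
            "neoantigenic": state.mut_is_neo[ids],
            "origin_step": state.mut_origin_step[ids],
            "origin_row": state.mut_origin_row[ids],
            "origin_col": state.mut_origin_col[ids],
        }
    )


def sample_regions(
    state: TumorState,
    disk_radius: Optional[int] = None,
    labels: Iterable[str] = PRIMARY_REGIONS,
    min_ccf: Optional[float] = None,
) -> TruthTable:
    """Sample disk regions and compute true per-region CCFs.

    Regions whose disk contains no cells are dropped with a warning; if all
    requested disks are empty a ``ValueError`` is raised.  Mutations whose
    CCF is below ``min_ccf`` in every sampled region are dropped (they are
    unobservable at any realistic depth); pass ``min_ccf=0`` to keep all.
    """
    if state.extinct or state.n_cells == 0:
        raise ValueError("cannot sample an extinct tumor")
    if disk_radius is None:
        disk_radius = state.config.disk_radius
    if min_ccf is None:
        min_ccf = state.config.min_truth_ccf
    labels = [l for l in PRIMARY_REGIONS if l in set(labels)]
    anchors = region_anchors(state)

    counts = {}
    region_cells = {}
    for lab in labels:
        idx = _disk_cells(state, anchors[lab], disk_radius)
        if idx.size == 0:
            warnings.warn(f"region {lab}: empty sampling disk, dropped")
            continue
        counts[lab] = state.genotype_cell_counts(idx)
        region_cells[lab] = int(idx.size)
    if not counts:
        raise ValueError("all sampling disks are empty")

    labs = list(counts)
    leaf_mat = np.stack([counts[lab] for lab in labs], axis=1)
    sub = state.subtree_counts(leaf_mat)
    totals = leaf_mat.sum(axis=0).astype(float)
    frac = sub / totals
    # prune at the genotype level before expanding to mutations
    gkeep = np.flatnonzero((frac.max(axis=1) >= min_ccf) & (state.mut_count > 0))
    lengths = state.mut_count[gkeep]
    starts = state.mut_start[gkeep]
    offsets = np.arange(lengths.sum()) - np.repeat(
        np.concatenate([[0], np.cumsum(lengths)[:-1]]), lengths
    )
    keep = np.repeat(starts, lengths) + offsets
    ccf = pd.DataFrame(np.repeat(frac[gkeep], lengths, axis=0), index=keep, columns=labs)
    muts = _mutation_frame(state, keep)
    return TruthTable(
        mutations=muts,
        ccf=ccf,
        region_cells=region_cells,
        anchors={k: anchors[k] for k in counts},
    )


def sample_ln(
    state: TumorState,
    rng: np.random.Generator,
    n_private_mean: Optional[float] = None,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Simulate a lymph-node metastasis seeded by one migrant cell.

    The node is a clonal expansion of a randomly chosen cell's genotype:
    every mutation on that genotype's ancestry is clonal (CCF 1) in the
    node, plus ``Poisson(n_private_mean)`` node-private clonal mutations
    appended to the tumor's mutation id space.  Returns the node's CCF
    series (indexed by mut id) and a frame describing the new private
    mutations.
    """
    if state.n_cells == 0:
        raise ValueError("cannot seed a metastasis from an extinct tumor")
    if n_private_mean is None:
        n_private_mean = 8.0 * state.config.mutation_rate
    cell = int(rng.integers(state.n_cells))
    g = int(state.genotype[cell])
    carried = np.zeros(state.n_mutations, dtype=bool)
    while g >= 0:
        a, c = state.mut_start[g], state.mut_count[g]
        carried[a : a + c] = True
        g = int(state.parent[g])
    n_priv = int(rng.poisson(n_private_mean))
    priv_ids = state.n_mutations + np.arange(n_priv)
    ccf = pd.Series(
        np.concatenate([carried[carried].astype(float) if carried.any() else np.zeros(0),
                        np.ones(n_priv)]),
        index=np.concatenate([np.flatnonzero(carried), priv_ids]),
    )
    neo = rng.random(n_priv) < state.config.neoantigen_prob
    priv = pd.DataFrame(
        {
            "mut_id": priv_ids,
            "kind": "passenger",
            "neoantigenic": neo,
            "origin_step": state.steps,
            "origin_row": -1,
            "origin_col": -1,
        }
    )
    return ccf, priv


def variant_annotations(mut_ids: np.ndarray) -> pd.DataFrame:
    """Deterministic genomic coordinates and substitution class per mutation.

    Ids map to unique (chrom, pos, ref, alt) keys; the substitution class
    cycles through the six pyrimidine-context classes so context-weighted
    expected-rate tables have something to chew on.
    """
    mut_ids = np.asarray(mut_ids, dtype=np.int64)
    chrom = np.char.add("chr", ((mut_ids % 22) + 1).astype(str))
    pos = 100_000 + (mut_ids // 22) * 137 + (mut_ids % 22)
    cls = np.array(_SUB_CLASSES)[mut_ids % len(_SUB_CLASSES)]
    ref = np.array([c[0] for c in cls])
    alt = np.array([c[2] for c in cls])
    df = pd.DataFrame(
        {"mut_id": mut_ids, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "context": cls}
    )
    df["key"] = df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
    return df


def sequence_patient(
    ccf_df: pd.DataFrame,
    depth: float,
    purities: Dict[str, float],
    seed: int,
    patient: str = "P1",
    neoantigen_flags: Optional[pd.Series] = None,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Sequence every region of one patient in a single vectorised pass.

    Statistically identical to calling :func:`sequence_region` per region
    (Poisson total depth, binomial alt counts under the heterozygous
    diploid model) but draws all read counts at once and builds one long
    MutationCall frame.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    regions = list(ccf_df.columns)
    for r in regions:
        if not 0.0 < purities[r] <= 1.0:
            raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ccf = np.clip(ccf_df.to_numpy(dtype=float), 0.0, 1.0)
    nm, nr = ccf.shape
    pur = np.array([purities[r] for r in regions])
    total = rng.poisson(depth, (nm, nr)).clip(min=1)
    alt = rng.binomial(total, pur[None, :] * ccf / 2.0)
    if annotations is None:
        annotations = variant_annotations(np.asarray(ccf_df.index))
    ann = annotations.reset_index(drop=True)
    tile = np.tile(np.arange(nm), nr)
    out = ann.iloc[tile].reset_index(drop=True)
    out["patient"] = patient
    out["region"] = np.repeat(regions, nm)
    out["alt_reads"] = alt.T.ravel()
    out["total_reads"] = total.T.ravel()
    out["purity"] = np.repeat(pur, nm)
    out["cn_total"] = 2
    out["multiplicity"] = 1
    out["consequence"] = "nonsyn"
    out["true_ccf"] = ccf.T.ravel()
    cols = [
        "patient", "region", "chrom", "pos", "ref", "alt", "key", "alt_reads",
        "total_reads", "purity", "cn_total", "multiplicity", "context",
        "consequence", "mut_id", "true_ccf",
    ]
    if neoantigen_flags is not None:
        flags = neoantigen_flags.reindex(ccf_df.index, fill_value=False).to_numpy(dtype=bool)
        out["neoantigen_flag"] = np.tile(flags, nr)
        cols.insert(-2, "neoantigen_flag")
    return out[cols]


def sequence_region(
    truth_ccf: pd.Series,
    depth: float,
    purity: float,
    seed: int,
    patient: str = "P1",
    region: str = "T5",
    neoantigen_flags: Optional[pd.Series] = None,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Binomial read-count sequencing of one region.

    Expected VAF follows the heterozygous diploid model ``purity * CCF / 2``;
    per-site total depth is ``Poisson(depth)`` and alt reads are binomial.
    Rows with zero alt reads are retained — presence calling is downstream.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    ccf = np.asarray(truth_ccf, dtype=float)
    if ccf.size and (ccf.min() < 0.0 or ccf.max() > 1.0 + 1e-9):
        raise ValueError("CCF outside [0, 1]")
    rng = np.random.default_rng(seed)
    total = rng.poisson(depth, ccf.size).clip(min=1)
    vaf = purity * np.clip(ccf, 0.0, 1.0) / 2.0
    alt = rng.binomial(total, vaf)
    if annotations is not None:
        ann = annotations.reset_index(drop=True)
    else:
        ann = variant_annotations(np.asarray(truth_ccf.index))
    out = ann.assign(
        patient=patient,
        region=region,
        alt_reads=alt,
        total_reads=total,
        purity=purity,
        cn_total=2,
        multiplicity=1,
        consequence="nonsyn",
        true_ccf=ccf,
    )
    if neoantigen_flags is not None:
        out["neoantigen_flag"] = neoantigen_flags.reindex(
            truth_ccf.index, fill_value=False
        ).to_numpy(dtype=bool)
    cols = [
        "patient", "region", "chrom", "pos", "ref", "alt", "key", "alt_reads",
        "total_reads", "purity", "cn_total", "multiplicity", "context",
        "consequence", "mut_id", "true_ccf",
    ]
    if neoantigen_flags is not None:
        cols.insert(-2, "neoantigen_flag")
    return out[cols]
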