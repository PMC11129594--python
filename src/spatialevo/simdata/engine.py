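"""Stochastic branching-process tumor growth on a cylindrical deme lattice.

The state is kept per cell (arrays of deme coordinates and genotype ids)
with genotypes stored as a genealogy: each genotype records its parent and
the contiguous block of mutation ids it introduced.  All per-step dynamics
are vectorised; a step performs death, logistic birth (with hard per-deme
capacity), and capacity-respecting migration with a directional kernel.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from numba import njit

from spatialevo.simdata.config import SimulationConfig

_UP, _DOWN, _LEFT, _RIGHT = 0, 1, 2, 3


@njit(cache=True)
def _accumulate_subtrees(parent, out):
    # children always have larger ids than their parent, so one reverse
    # sweep pushes each genotype's counts into its ancestors
    for g in range(out.shape[0] - 1, 0, -1):
        p = parent[g]
        for r in range(out.shape[1]):
            out[p, r] += out[g, r]


@njit(cache=True)
def _chain_sums(parent, own):
    out = np.zeros(own.size, dtype=np.int64)
    out[0] = own[0]
    for g in range(1, own.size):
        out[g] = out[parent[g]] + own[g]
    return out


@dataclass
class TumorState:
    """Final state of a simulated tumor.

    Cell arrays are parallel (one entry per surviving cell); genotype and
    mutation arrays encode the genealogy.  ``outcome`` is one of
    ``"target"`` (reached ``target_cells``), ``"extinct"`` or
    ``"max_steps"``.
    """

    config: SimulationConfig
    rows: np.ndarray
    cols: np.ndarray
    genotype: np.ndarray
    # genealogy
    parent: np.ndarray          # (G,) parent genotype id, -1 for founder
    n_drivers: np.ndarray       # (G,) cumulative driver count
    n_neoantigens: np.ndarray   # (G,) cumulative neoantigen count
    mut_start: np.ndarray       # (G,) first mutation id introduced
    mut_count: np.ndarray       # (G,) number of mutations introduced
    # mutation attributes (global id = index)
    mut_is_driver: np.ndarray
    mut_is_neo: np.ndarray
    mut_origin_step: np.ndarray
    mut_origin_row: np.ndarray
    mut_origin_col: np.ndarray
    founder_deme: tuple
    steps: int
    outcome: str
    injected_genotype: Optional[int] = None

    @property
    def extinct(self) -> bool:
        return self.outcome == "extinct"

    @property
    def n_cells(self) -> int:
        return int(self.rows.size)

    @property
    def n_mutations(self) -> int:
        return int(self.mut_is_driver.size)

    @property
    def n_genotypes(self) -> int:
        return int(self.parent.size)

    def mut_origin_genotype(self) -> np.ndarray:
        """Genotype id in which each mutation arose (aligned with mut id)."""
        return np.repeat(np.arange(self.n_genotypes), self.mut_count)

    def genotype_cell_counts(self, cell_index: Optional[np.ndarray] = None) -> np.ndarray:
        """Cells per genotype, optionally restricted to a subset of cells."""
        geno = self.genotype if cell_index is None else self.genotype[cell_index]
        return np.bincount(geno, minlength=self.n_genotypes)

    def subtree_counts(self, leaf_counts: np.ndarray) -> np.ndarray:
        """Propagate per-genotype cell counts up the genealogy.

        Entry ``[g]`` (or row ``[g, :]`` for a 2-D input with one column per
        region) is the number of counted cells whose genotype is g or a
        descendant of g, i.e. the number of cells carrying the mutations
        introduced by g.
        """
        squeeze = leaf_counts.ndim == 1
        out = np.ascontiguousarray(
            leaf_counts.reshape(leaf_counts.shape[0], -1).astype(np.int64)
        )
        _accumulate_subtrees(self.parent, out)
        return out[:, 0] if squeeze else out

    def mutation_ccf(self, cell_index: Optional[np.ndarray] = None) -> np.ndarray:
        """True cancer-cell fraction of every mutation over the given cells."""
        counts = self.genotype_cell_counts(cell_index)
        total = counts.sum()
        if total == 0:
            raise ValueError("no cells in the requested set")
        sub = self.subtree_counts(counts)
        return sub[self.mut_origin_genotype()] / float(total)

    def per_cell_mutation_burden(self) -> np.ndarray:
        """Total mutation count per genotype (cumulative along ancestry)."""
        return _chain_sums(self.parent, np.ascontiguousarray(self.mut_count))

    def per_cell_neo_burden(self) -> np.ndarray:
        """Cumulative neoantigen count per genotype (founder load included)."""
        return np.asarray(self.n_neoantigens)

    def centroid_displacement(self) -> float:
        """Signed vertical displacement of the cell centroid from the
        founder deme, in demes; negative = toward the upper (oral) end."""
        return float(self.rows.mean() - self.founder_deme[0])

    def digest(self) -> str:
        h = hashlib.sha256()
        for arr in (self.rows, self.cols, self.genotype, self.parent,
                    self.mut_start, self.mut_count, self.mut_is_neo):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


class _Grow:
    """Amortised-growth typed array buffer."""

    def __init__(self, dtype, cap=1024):
        self.a = np.zeros(cap, dtype=dtype)
        self.n = 0

    def extend(self, vals):
        vals = np.asarray(vals)
        need = self.n + vals.size
        if need > self.a.size:
            cap = max(need, 2 * self.a.size)
            new = np.zeros(cap, dtype=self.a.dtype)
            new[: self.n] = self.a[: self.n]
            self.a = new
        self.a[self.n: need] = vals
        self.n = need

    def view(self):
        return self.a[: self.n]


class _GenoBuf:
    """Append-only genotype/mutation store with O(1) amortised growth."""

    GFIELDS = {
        "parent": np.int64, "n_drivers": np.int64, "n_neo": np.int64,
        "mut_start": np.int64, "mut_count": np.int64,
    }
    MFIELDS = {
        "m_driver": bool, "m_neo": bool, "m_step": np.int64,
        "m_row": np.int64, "m_col": np.int64,
    }

    def __init__(self):
        for name, dt in {**self.GFIELDS, **self.MFIELDS}.items():
            setattr(self, name, _Grow(dt))
        self.parent.extend([-1])
        self.n_drivers.extend([0])
        self.n_neo.extend([0])
        self.mut_start.extend([0])
        self.mut_count.extend([0])

    @property
    def n_geno(self):
        return self.parent.n

    @property
    def n_mut(self):
        return self.m_driver.n

    def cat(self, name):
        return getattr(self, name).view()


def _ranked_accept(demes: np.ndarray, capacity_left: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Accept at most ``capacity_left[d]`` of the candidates targeting deme d.

    Candidates are prioritised in a random order so no cell is favoured.
    Returns a boolean accept mask aligned with ``demes``.
    """
    n = demes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    counts = np.bincount(demes, minlength=capacity_left.size)
    if (counts <= capacity_left[: counts.size]).all():
        return np.ones(n, dtype=bool)
    prio = rng.permutation(n)
    order = np.lexsort((prio, demes))
    sorted_demes = demes[order]
    # rank within each run of equal demes
    first = np.zeros(n, dtype=np.int64)
    new_run = np.flatnonzero(sorted_demes[1:] != sorted_demes[:-1]) + 1
    first[new_run] = new_run
    np.maximum.accumulate(first, out=first)
    rank = np.arange(n) - first
    ok_sorted = rank < capacity_left[sorted_demes]
    accept = np.zeros(n, dtype=bool)
    accept[order] = ok_sorted
    return accept


def simulate_tumor(config: SimulationConfig, seed: Optional[int] = None) -> TumorState:
    """Grow a tumor from a single founder cell until ``target_cells`` is
    reached, the population goes extinct, or ``max_steps`` elapse.

    Extinction is a legal outcome and is reported through
    ``TumorState.outcome``, never raised.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    L, C, K = config.lattice_length, config.lattice_circumference, config.deme_capacity
    field = config.field_array(rng).ravel()
    b, d, m = config.birth_rate, config.death_rate, config.migration_rate
    beta, mu = config.upward_bias, config.mutation_rate
    p_d, p_neo, kappa = config.driver_prob, config.neoantigen_prob, config.immune_kill
    s = config.driver_fitness
    target = config.target_cells

    founder = (int(round(config.founder_row_fraction * L)), C // 2)
    rows = np.array([founder[0]], dtype=np.int64)
    cols = np.array([founder[1]], dtype=np.int64)
    geno = np.array([0], dtype=np.int64)

    gb = _GenoBuf()
    if config.n_founder_mutations:
        n0 = config.n_founder_mutations
        founder_neo = rng.random(n0) < p_neo
        gb.m_driver.extend(np.zeros(n0, dtype=bool))
        gb.m_neo.extend(founder_neo)
        gb.m_step.extend(np.zeros(n0, dtype=np.int64))
        gb.m_row.extend(np.full(n0, founder[0], dtype=np.int64))
        gb.m_col.extend(np.full(n0, founder[1], dtype=np.int64))
        gb.mut_count.a[0] = n0
        gb.n_neo.a[0] = int(founder_neo.sum())

    # concatenated genotype attribute caches, refreshed after appends
    parent_c = gb.cat("parent")
    ndrv_c = gb.cat("n_drivers")
    neo_c = gb.cat("n_neo")

    # migration direction thresholds: up, down, left, right
    dir_p = np.array([(1 + beta) / 4.0, (1 - beta) / 4.0, 0.25, 0.25])
    dir_cum = np.cumsum(dir_p)

    injected: Optional[int] = None
    inject_at = (None if config.driver_injection_fraction is None
                 else max(1, int(config.driver_injection_fraction * target)))

    step = 0
    outcome = "max_steps"
    # per-genotype count of *clonally expanded* neoantigens (see below);
    # refreshed every few steps because subtree frequencies move slowly
    punished = np.zeros(1, dtype=np.int64)
    immune_on = kappa > 0.0 and float(field.max()) > 0.0
    phi = config.immune_clonal_threshold
    refresh = 5

    while step < config.max_steps:
        step += 1
        n = rows.size

        if immune_on and (step % refresh == 1 or punished.size < gb.n_geno):
            # immune recognition requires antigen abundance: a neoantigen
            # attracts killing only once the clone carrying it exceeds a
            # fraction phi of the tumor
            parent_v = gb.cat("parent")
            counts_g = np.bincount(geno, minlength=gb.n_geno)
            sub = counts_g.astype(np.int64).reshape(-1, 1).copy()
            _accumulate_subtrees(parent_v, sub)
            clonal = sub[:, 0] >= max(1.0, phi * n)
            own_neo = neo_c.copy()
            own_neo[1:] -= neo_c[parent_v[1:]]
            punished = _chain_sums(parent_v, np.where(clonal, own_neo, 0))

        # --- deaths -----------------------------------------------------
        deme = rows * C + cols
        if immune_on:
            p_die = np.minimum(d + kappa * field[deme] * punished[geno], 0.98)
        else:
            p_die = np.full(n, d)
        alive = rng.random(n) >= p_die
        rows, cols, geno = rows[alive], cols[alive], geno[alive]
        if rows.size == 0:
            outcome = "extinct"
            break

        # --- births (logistic in occupancy, hard cap at K) --------------
        deme = rows * C + cols
        occ = np.bincount(deme, minlength=L * C)
        room = 1.0 - occ[deme] / K
        np.clip(room, 0.0, None, out=room)
        p_div = np.minimum(b * (1.0 + s) ** ndrv_c[geno] * room, 1.0)
        div = rng.random(rows.size) < p_div
        idx_div = np.flatnonzero(div)
        if idx_div.size:
            cap_left = np.maximum(K - occ, 0)
            acc = _ranked_accept(deme[idx_div], cap_left, rng)
            idx_div = idx_div[acc]
        if idx_div.size:
            # each division adds Poisson(mu) new mutations, carried by the
            # daughter cell (the dividing cell keeps its genotype)
            nb = idx_div.size
            n_new = rng.poisson(mu, nb)
            child_geno = geno[idx_div].copy()
            mutated = np.flatnonzero(n_new)
            if mutated.size:
                counts = n_new[mutated]
                total = int(counts.sum())
                is_drv = rng.random(total) < p_d
                is_neo = (~is_drv) & (rng.random(total) < p_neo)
                bounds = np.zeros(mutated.size + 1, dtype=np.int64)
                np.cumsum(counts, out=bounds[1:])
                drv_per = np.add.reduceat(is_drv.astype(np.int64), bounds[:-1])
                neo_per = np.add.reduceat(is_neo.astype(np.int64), bounds[:-1])
                pg = geno[idx_div[mutated]]
                new_ids = gb.n_geno + np.arange(mutated.size)
                starts = gb.n_mut + bounds[:-1]
                gb.parent.extend(pg)
                gb.n_drivers.extend(ndrv_c[pg] + drv_per)
                gb.n_neo.extend(neo_c[pg] + neo_per)
                gb.mut_start.extend(starts)
                gb.mut_count.extend(counts)
                gb.m_driver.extend(is_drv)
                gb.m_neo.extend(is_neo)
                gb.m_step.extend(np.full(total, step, dtype=np.int64))
                gb.m_row.extend(np.repeat(rows[idx_div[mutated]], counts))
                gb.m_col.extend(np.repeat(cols[idx_div[mutated]], counts))
                child_geno[mutated] = new_ids
                parent_c = gb.cat("parent")
                ndrv_c = gb.cat("n_drivers")
                neo_c = gb.cat("n_neo")
            rows = np.concatenate([rows, rows[idx_div]])
            cols = np.concatenate([cols, cols[idx_div]])
            geno = np.concatenate([geno, child_geno])

        # --- driver injection -------------------------------------------
        if inject_at is not None and injected is not None and p_d == 0.0:
            # drift can wipe the injected clone out; the selection arm
            # models a tumor that carries an established driver subclone,
            # so re-inject until one takes
            if not (ndrv_c[geno] > 0).any():
                injected = None
        if inject_at is not None and injected is None and rows.size >= inject_at:
            # inject into the active growth ring (demes with free capacity
            # but established occupancy): the clone can divide immediately
            # and rides the expansion annulus sideways across regions
            deme = rows * C + cols
            occ = np.bincount(deme, minlength=L * C)
            cell_occ = occ[deme]
            ring = np.flatnonzero((cell_occ >= max(1, K // 8)) & (cell_occ <= K // 2))
            if not ring.size:
                ring = np.flatnonzero(cell_occ == cell_occ.min())
            cell = int(rng.choice(ring))
            pg = geno[cell]
            gid = gb.n_geno
            gb.parent.extend([pg])
            gb.n_drivers.extend([ndrv_c[pg] + 1])
            gb.n_neo.extend([neo_c[pg]])
            gb.mut_start.extend([gb.n_mut])
            gb.mut_count.extend([1])
            gb.m_driver.extend([True])
            gb.m_neo.extend([False])
            gb.m_step.extend([step])
            gb.m_row.extend([rows[cell]])
            gb.m_col.extend([cols[cell]])
            geno[cell] = gid
            injected = gid
            parent_c = gb.cat("parent")
            ndrv_c = gb.cat("n_drivers")
            neo_c = gb.cat("n_neo")

        # --- migration ---------------------------------------------------
        if m > 0.0:
            nn = rows.size
            mig = np.flatnonzero(rng.random(nn) < m)
            if mig.size:
                u = rng.random(mig.size)
                direction = np.searchsorted(dir_cum, u)
                tr = rows[mig].copy()
                tc = cols[mig].copy()
                tr[direction == _UP] -= 1
                tr[direction == _DOWN] += 1
                tc[direction == _LEFT] -= 1
                tc[direction == _RIGHT] += 1
                tc %= C
                valid = (tr >= 0) & (tr < L)
                mig, tr, tc = mig[valid], tr[valid], tc[valid]
                if mig.size:
                    deme = rows * C + cols
                    occ = np.bincount(deme, minlength=L * C)
                    cap_left = np.maximum(K - occ, 0)
                    acc = _ranked_accept(tr * C + tc, cap_left, rng)
                    mig, tr, tc = mig[acc], tr[acc], tc[acc]
                    rows[mig] = tr
                    cols[mig] = tc

        if rows.size >= target:
            outcome = "target"
            break

    if rows.size == 0:
        outcome = "extinct"

    return TumorState(
        config=config,
        rows=rows,
        cols=cols,
        genotype=geno,
        parent=gb.cat("parent"),
        n_drivers=gb.cat("n_drivers"),
        n_neoantigens=gb.cat("n_neo"),
        mut_start=gb.cat("mut_start"),
        mut_count=gb.cat("mut_count"),
        mut_is_driver=gb.cat("m_driver"),
        mut_is_neo=gb.cat("m_neo"),
        mut_origin_step=gb.cat("m_step"),
        mut_origin_row=gb.cat("m_row"),
        mut_origin_col=gb.cat("m_col"),
        founder_deme=founder,
        steps=step,
        outcome=outcome,
        injected_genotype=injected,
    )
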