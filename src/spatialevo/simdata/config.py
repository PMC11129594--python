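"""Simulation configuration for the deme-lattice branching process."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np


@dataclass
class SimulationConfig:
    """Parameters of the spatial tumor growth simulator.

    The lattice is a 2-D cylinder: ``lattice_circumference`` demes wrap
    around the esophagus, ``lattice_length`` demes run along the
    oral--gastric axis (row 0 is the upper, oral, end).  Each deme holds at
    most ``deme_capacity`` cells; division is logistic in deme occupancy.

    Rates are per cell per time step.  ``upward_bias`` (beta) skews the
    migration direction kernel: the upper neighbour is weighted ``1 + beta``
    and the lower neighbour ``1 - beta`` (lateral neighbours 1), so beta = 0
    is isotropic and beta = 1 forbids downward moves.

    Each division adds ``Poisson(mutation_rate)`` new exonic mutations to
    the daughter cell; a new mutation is a driver with probability
    ``driver_prob`` (multiplying the birth rate by ``1 + driver_fitness``),
    otherwise a passenger that is neoantigenic with probability
    ``neoantigen_prob``.

    Immune killing is antigen-abundance driven: T-cell priming needs
    antigen dose, so a neoantigen attracts killing only while the clone
    carrying it exceeds a fraction ``immune_clonal_threshold`` of the
    tumor.  A cell's extra death hazard is ``immune_kill *
    immune_field(deme) * n`` with ``n`` its count of such clonally
    expanded neoantigens.  Founder (clonal) neoantigens therefore burden
    every cell equally, which selects across whole tumors: under a strong
    field most incipient tumors are eliminated and the ones that establish
    carry fewer clonal antigens — the elimination phase of immunoediting.
    Growth-phase antigenic clones are pushed back whenever they expand
    past the threshold, which keeps them out of the trunk.  Because rare
    mutations are invisible to this hazard, the accumulating passenger
    load never erodes viability.
    """

    lattice_circumference: int = 36
    lattice_length: int = 48
    deme_capacity: int = 40
    birth_rate: float = 0.65
    death_rate: float = 0.35
    migration_rate: float = 0.15
    upward_bias: float = 0.0
    mutation_rate: float = 6.0
    driver_prob: float = 0.0
    driver_fitness: float = 0.0
    neoantigen_prob: float = 0.10
    immune_kill: float = 0.0
    immune_field: float | np.ndarray = 0.0
    immune_hot_fraction: Optional[float] = None
    immune_clonal_threshold: float = 0.10
    n_founder_mutations: int = 50
    target_cells: int = 2500
    max_steps: int = 1500
    driver_injection_fraction: Optional[float] = None
    sequencing_depth: float = 310.0
    purity_range: Tuple[float, float] = (0.6, 0.9)
    exome_size_mb: float = 38.0
    min_truth_ccf: float = 0.02
    disk_radius: int = 3
    founder_row_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.lattice_circumference < 3 or self.lattice_length < 3:
            raise ValueError("lattice must be at least 3x3 demes")
        if self.deme_capacity < 1:
            raise ValueError("deme_capacity must be >= 1")
        for name in ("birth_rate", "death_rate", "migration_rate", "mutation_rate",
                     "immune_kill", "driver_fitness", "sequencing_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.upward_bias <= 1.0:
            raise ValueError("upward_bias must be in [0, 1]")
        for name in ("driver_prob", "neoantigen_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        if self.target_cells < 1:
            raise ValueError("target_cells must be >= 1")
        # the lattice must be able to hold the tumor comfortably
        cap = self.lattice_circumference * self.lattice_length * self.deme_capacity
        if cap < 10 * self.deme_capacity:
            raise ValueError("lattice too small")
        if cap < self.target_cells:
            raise ValueError("lattice cannot hold target_cells")
        fmax = float(np.max(self.immune_field))
        fmin = float(np.min(self.immune_field))
        if fmin < 0.0 or fmax > 1.0:
            raise ValueError("immune_field values must be in [0, 1]")
        if self.driver_injection_fraction is not None and not (
            0.0 < self.driver_injection_fraction < 1.0
        ):
            raise ValueError("driver_injection_fraction must be in (0, 1)")
        if self.exome_size_mb <= 0:
            raise ValueError("exome_size_mb must be > 0")
        if not 0.05 <= self.founder_row_fraction <= 0.95:
            raise ValueError("founder_row_fraction must be in [0.05, 0.95]")
        if self.immune_hot_fraction is not None and not 0.0 <= self.immune_hot_fraction <= 1.0:
            raise ValueError("immune_hot_fraction must be in [0, 1]")
        if not 0.0 < self.immune_clonal_threshold <= 1.0:
            raise ValueError("immune_clonal_threshold must be in (0, 1]")

    def field_array(self, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Immune intensity as a (length, circumference) array.

        With ``immune_hot_fraction`` set, the scalar ``immune_field`` is the
        intensity of immune-infiltrated demes and each deme is hot with
        that probability (immune-excluded pockets get zero), drawn from the
        simulation's own generator so a (config, seed) pair is reproducible.
        """
        shape = (self.lattice_length, self.lattice_circumference)
        arr = np.asarray(self.immune_field, dtype=float)
        if arr.ndim == 0:
            if self.immune_hot_fraction is not None:
                if rng is None:
                    rng = np.random.default_rng(self.seed)
                hot = rng.random(shape) < self.immune_hot_fraction
                return np.where(hot, float(arr), 0.0)
            return np.full(shape, float(arr))
        if arr.shape != shape:
            raise ValueError(f"immune_field shape {arr.shape} != lattice {shape}")
        return arr

    def with_updates(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)
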