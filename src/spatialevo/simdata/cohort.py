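"""Cohort-level synthetic data: cell fractions, clinical covariates, and
full multi-patient cohorts with ground truth.

The generator emulates the statistical structure of a multi-regional ESCC
sequencing study: 2-5 primary regions per patient plus occasional
lymph-node samples, exome-scale mutation tables with clonal and subclonal
VAF clusters at ~310x depth, spatially structured subclone sharing with an
optional upward (oral-direction) bias, and Dirichlet cell-fraction vectors
with immune-hot and immune-cold modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from spatialevo.simdata.config import SimulationConfig
from spatialevo.simdata.engine import TumorState, simulate_tumor
from spatialevo.simdata.sampling import (
    TruthTable,
    sample_ln,
    sample_regions,
    sequence_patient,
    variant_annotations,
)

#: The 11 cell types of the methylation-deconvolution panel.
CELL_TYPES = [
    "CD8_T", "CD4_Teff", "B", "NK", "Treg", "Monocyte", "Dendritic",
    "Neutrophil", "Fibroblast", "Endothelial", "Epithelial",
]

#: Mean composition of an immune-hot region: elevated CD8+ T, B and CD4+
#: effector fractions.
HOT_MEAN = np.array([0.18, 0.12, 0.08, 0.04, 0.05, 0.06, 0.03, 0.04, 0.10, 0.08, 0.22])

#: Mean composition of an immune-cold region: stromal (fibroblast /
#: endothelial) and epithelial dominated.
COLD_MEAN = np.array([0.03, 0.04, 0.02, 0.02, 0.03, 0.05, 0.02, 0.04, 0.25, 0.15, 0.35])

assert abs(HOT_MEAN.sum() - 1.0) < 1e-12 and abs(COLD_MEAN.sum() - 1.0) < 1e-12

#: Uniform immune-field intensity by patient type.  Intensities are small
#: because the viability margin of the high-turnover growth regime is a few
#: per-cent per step: clinically existing tumors are, by construction, the
#: ones immune surveillance failed to eliminate, so the per-step attrition
#: of antigenic lineages must sit below that margin while still suppressing
#: their fixation over the tens of steps it takes a clone to reach trunk.
FIELD_BY_TYPE = {"hot": (0.0007, None), "het": (0.0003, None), "cold": (0.00003, None)}


def generate_cell_fractions(
    profiles: Sequence[str],
    concentration: float = 150.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw one 11-type cell-fraction vector per region.

    ``profiles`` assigns each region ``"hot"`` or ``"cold"``; vectors are
    Dirichlet draws around the corresponding mean profile with the given
    concentration (``np.inf`` returns the means exactly).
    """
    if not np.isfinite(concentration) and concentration > 0:
        rows = [HOT_MEAN if p == "hot" else COLD_MEAN for p in profiles]
        return pd.DataFrame(rows, columns=CELL_TYPES)
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for p in profiles:
        if p not in ("hot", "cold"):
            raise ValueError(f"unknown immune profile {p!r}")
        mean = HOT_MEAN if p == "hot" else COLD_MEAN
        rows.append(rng.dirichlet(concentration * mean))
    return pd.DataFrame(rows, columns=CELL_TYPES)


DEFAULT_MARGINALS = {
    "male": 0.79,
    "drinking": 0.55,
    "smoking": 0.60,
    "advanced_stage": 0.59,
}


def generate_clinical(
    n_patients: int,
    seed: int | np.random.Generator = 0,
    marginals: Optional[dict] = None,
    couple: bool = True,
    beta_drinker: float = 0.45,
    beta_nondrinker: float = 0.15,
    beta_sd: float = 0.10,
) -> pd.DataFrame:
    """Clinical covariates plus coupled latent tumor parameters.

    Sex, age (40-80, centred on 63),
    drinking/smoking flags and TNM stage are drawn from configurable
    marginals.  With ``couple=True`` drinkers receive a higher upward
    migration bias ``beta`` and a colder immune prior (lower CD8+ T
    profiles), emulating the association between alcohol exposure and
    oral-direction expansion.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    m = dict(DEFAULT_MARGINALS)
    if marginals:
        m.update(marginals)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sex = np.where(rng.random(n_patients) < m["male"], "M", "F")
    age = np.clip(np.round(rng.normal(63, 9, n_patients)), 40, 80).astype(int)
    drinking = rng.random(n_patients) < m["drinking"]
    smoking = rng.random(n_patients) < m["smoking"]
    stage = np.where(rng.random(n_patients) < m["advanced_stage"], "III-IV", "I-II")
    if couple:
        beta_mean = np.where(drinking, beta_drinker, beta_nondrinker)
        p_hot = np.where(drinking, 0.08, 0.18)
    else:
        beta_mean = np.full(n_patients, beta_nondrinker)
        p_hot = np.full(n_patients, 0.13)
    beta = np.clip(rng.normal(beta_mean, beta_sd), 0.0, 1.0)
    p_het = 0.55
    u = rng.random(n_patients)
    immune_type = np.where(u < p_hot, "hot", np.where(u < p_hot + p_het, "het", "cold"))
    return pd.DataFrame(
        {
            "patient": [f"P{i+1:03d}" for i in range(n_patients)],
            "sex": sex,
            "age": age,
            "drinking": drinking,
            "smoking": smoking,
            "stage": stage,
            "beta": beta,
            "immune_type": immune_type,
        }
    )


@dataclass
class PatientTruth:
    """Ground truth for one synthetic patient."""

    truth: TruthTable
    beta: float
    immune_type: str
    region_profiles: Dict[str, str]
    immune_field: float
    outcome: str
    n_resampled: int = 0


@dataclass
class SyntheticCohort:
    """Simulator output bundle: observed tables plus ground truth."""

    calls: pd.DataFrame
    cell_fractions: pd.DataFrame
    clinical: pd.DataFrame
    truth: Dict[str, PatientTruth]
    n_extinct_resampled: int = 0

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for df in (self.calls, self.cell_fractions, self.clinical):
            h.update(df.to_csv(index=True).encode())
        return h.hexdigest()


# emulates an MRS cohort scale of ~4.5 primary regions per patient
REGION_COUNT_P = {2: 0.05, 3: 0.10, 4: 0.18, 5: 0.67}
LN_COUNT_P = {0: 0.65, 1: 0.25, 2: 0.10}


def _derived_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_patients: int,
    template: Optional[SimulationConfig] = None,
    seed: int = 0,
    couple_clinical: bool = True,
    fixed_beta: Optional[float] = None,
    fixed_immune_type: Optional[str] = None,
    concentration: float = 150.0,
    max_resample: int = 200,
) -> SyntheticCohort:
    """Generate a full synthetic multi-region cohort.

    Per patient: draw clinical covariates (which set the migration bias
    ``beta`` and immune type unless ``fixed_beta`` / ``fixed_immune_type``
    override them), simulate growth, sample 2-5 primary regions plus 0-2
    lymph nodes, sequence each region, and attach Dirichlet cell fractions.
    Patients whose tumor goes extinct are resampled with a fresh derived
    seed; the count is reported on the bundle.
    """
    if template is None:
        template = SimulationConfig()
    template.validate()
    root = np.random.SeedSequence(seed)
    ss_clin, ss_patients = root.spawn(2)
    clinical = generate_clinical(
        n_patients, np.random.default_rng(ss_clin), couple=couple_clinical
    )
    if fixed_beta is not None:
        clinical["beta"] = fixed_beta
    if fixed_immune_type is not None:
        clinical["immune_type"] = fixed_immune_type

    all_calls: List[pd.DataFrame] = []
    frac_rows: List[pd.DataFrame] = []
    truth: Dict[str, PatientTruth] = {}
    n_extinct = 0

    for i, pss in enumerate(ss_patients.spawn(n_patients)):
        pat = clinical.at[i, "patient"]
        beta = float(clinical.at[i, "beta"])
        itype = str(clinical.at[i, "immune_type"])
        rng = np.random.default_rng(pss)
        intensity, hot_frac = FIELD_BY_TYPE.get(itype, (0.0, None))
        cfg = template.with_updates(
            upward_bias=beta,
            immune_field=intensity,
            immune_hot_fraction=hot_frac,
        )

        state: Optional[TumorState] = None
        resampled = 0
        for _ in range(max_resample):
            sim_seed = _derived_seed(pss.spawn(1)[0])
            state = simulate_tumor(cfg, seed=sim_seed)
            if state.outcome != "extinct":
                break
            resampled += 1
        if state is None or state.outcome == "extinct":
            raise RuntimeError(f"patient {pat}: extinction persisted after {max_resample} resamples")
        n_extinct += resampled

        k = int(rng.choice(list(REGION_COUNT_P), p=list(REGION_COUNT_P.values())))
        margins = list(rng.choice(["T1", "T2", "T3", "T4"], size=k - 1, replace=False))
        labels = ["T5"] + margins
        tt = sample_regions(state, labels=labels)

        n_ln = int(rng.choice(list(LN_COUNT_P), p=list(LN_COUNT_P.values())))
        ln_labels = []
        for j in range(n_ln):
            ln_ccf, ln_priv = sample_ln(state, rng)
            lab = f"LN{j+1}"
            ln_labels.append(lab)
            tt.ccf = tt.ccf.join(ln_ccf.rename(lab), how="outer")
            tt.mutations = (
                pd.concat([tt.mutations, ln_priv], ignore_index=True)
                .drop_duplicates("mut_id")
                .reset_index(drop=True)
            )
        if ln_labels:
            tt.ccf = tt.ccf.fillna(0.0)

        neo = tt.mutations.set_index("mut_id")["neoantigenic"]
        ann = variant_annotations(np.asarray(tt.ccf.index))
        lo, hi = cfg.purity_range
        purities = {
            lab: float(np.round(rng.uniform(lo, hi), 3)) for lab in tt.ccf.columns
        }
        all_calls.append(
            sequence_patient(
                tt.ccf,
                depth=cfg.sequencing_depth,
                purities=purities,
                seed=_derived_seed(pss.spawn(1)[0]),
                patient=pat,
                neoantigen_flags=neo,
                annotations=ann,
            )
        )

        profiles = {}
        if itype == "het":
            labs = list(tt.ccf.columns)
            prim = [l for l in labs if not l.startswith("LN")]
            hot_mask = rng.random(len(prim)) < 0.5
            if hot_mask.all():
                hot_mask[int(rng.integers(len(prim)))] = False
            elif not hot_mask.any():
                hot_mask[int(rng.integers(len(prim)))] = True
            profiles = {l: ("hot" if h else "cold") for l, h in zip(prim, hot_mask)}
        else:
            profiles = {
                l: ("hot" if itype == "hot" else "cold")
                for l in tt.ccf.columns
                if not l.startswith("LN")
            }
        fr = generate_cell_fractions(list(profiles.values()), concentration, rng)
        fr.insert(0, "patient", pat)
        fr.insert(1, "region", list(profiles.keys()))
        frac_rows.append(fr)

        truth[pat] = PatientTruth(
            truth=tt,
            beta=beta,
            immune_type=itype,
            region_profiles=profiles,
            immune_field=FIELD_BY_TYPE.get(itype, (0.0, None))[0],
            outcome=state.outcome,
            n_resampled=resampled,
        )

    calls = pd.concat(all_calls, ignore_index=True)
    fractions = pd.concat(frac_rows, ignore_index=True)
    return SyntheticCohort(
        calls=calls,
        cell_fractions=fractions,
        clinical=clinical.drop(columns=[]),
        truth=truth,
        n_extinct_resampled=n_extinct,
    )
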