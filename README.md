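# spatialevo

Spatial tumor-evolution analysis for multi-regional sequencing (MRS) of
esophageal squamous cell carcinoma — and a deme-lattice branching-process
simulator that generates full synthetic MRS cohorts with known ground
truth.

MRS samples several spatially annotated regions per tumor (center T5,
upper/oral T1, lower/gastric T3, lateral T2/T4, plus lymph nodes).  From
the per-region somatic mutation tables this package computes, per patient
and per cohort:

- **Mutation classes and heterogeneity** — trunk (present in all regions),
  branched (some), private (one); gITH = (branched + private) / total;
  mutation burden per Mb; CCF via
  `VAF · (ρ·CN + (1−ρ)·2) / (ρ·m)` for purity ρ and multiplicity m.
- **Maximum-parsimony phylogenies and clades** — binary presence/absence
  characters, Fitch costs, germline root; each mutation-bearing edge is a
  *clade* classified like mutations; clades are tabulated cohort-wide with
  region-involvement flags.
- **Directed expansion** — the frequency with which center-involving
  branched clades also involve each margin, with a patient-resampling
  bootstrap of freq(T1) − freq(T3) (upward-bias alternative) and Fisher
  exact tests for covariate association.
- **Neutrality and selection** — the 1/f site-frequency-spectrum test
  (cumulative M(f) ∝ 1/f − 1/f_max over VAF ∈ [0.12, 0.24], through-origin
  fit, R² ≥ 0.98 for neutrality); binomial-mixture subclone reconstruction
  (BIC-selected K); the regional clonality score (RCS) = CCF of the most
  clonal subclonal component; Hudson F_ST between regions.
- **Immune microenvironment** — hot/cold typing of 11-cell-type fraction
  vectors (cohort-wide Manhattan/average-linkage clustering), patient
  typing (hot / cold / heterogeneous), immune ITH, the minimal-immune-
  distance margin, and the immunoediting (IM) score = observed/expected
  neoantigen yield with a mixture-based strong/weak split.

The simulator (`spatialevo.simdata`) grows tumors on a cylindrical lattice
(the esophageal wall) with logistic deme competition, directional
migration bias β toward the oral side, driver selection, and
antigen-abundance-driven immune killing; spatial disk sampling, Poisson ×
binomial read counts at 310×, Dirichlet cell fractions and clinical
covariates compose into cohorts.  See `docs/methods.md` for the model and
all defaults.

## Worked example

```python
from spatialevo.simdata import generate_cohort
from spatialevo.pipeline import AnalysisConfig, run_pipeline

cohort = generate_cohort(103, seed=777)        # synthetic MRS cohort
bundle = run_pipeline(cohort, AnalysisConfig(seed=777))
s = bundle.summary
print(s["clade_counts"], round(s["center_involvement_fraction"], 2))
print({k: round(v, 2) for k, v in s["sharing_freq"].items()},
      "p(T1 vs T3) =", s["sharing_p_upper_vs_lower"])
print(s["n_non_neutral"], "of", s["n_patients"], "tumors reject neutrality")
```

prints (this exact run):

```
{'trunk': 103, 'branched': 251, 'private': 500} 0.76
{'T1': 0.55, 'T3': 0.31, 'T2': 0.34, 'T4': 0.39} p(T1 vs T3) = 0.01
66 of 103 tumors reject neutrality
```

Read: every patient has one trunk clade; 76% of branched clades involve
the tumor center; center-involving branched clades share the upper margin
far more often than the lower one (55% vs 31%, bootstrap p = 0.01) —
the directed-expansion signature, present here because the generator
couples drinking to upward migration bias; and most tumors fail the 1/f
neutrality fit.  `bundle.tables` holds the per-patient tables behind every
summary number, and `bundle.write(out_dir)` writes them as TSV + JSON.

The same pipeline runs from files via the CLI:

```bash
spatial-evo simulate --n-patients 20 --seed 7 --out cohort/
spatial-evo run --calls cohort/calls.tsv --cells cohort/cell_fractions.tsv \
    --seed 7 --out results/
spatial-evo directed --clades results/clades.tsv --n-boot 100 --seed 7
```

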