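# Methods

`spatialevo` couples a spatial stochastic model of esophageal squamous cell
carcinoma (ESCC) growth with the statistical toolkit used to analyse
multi-regional sequencing (MRS) of such tumors.  This note documents the
model, the statistics, the default parameters and the design decisions, in
that order.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The growth model

Tumor growth is a branching process on a two-dimensional cylindrical deme
lattice representing the esophageal wall: `lattice_circumference` demes wrap
around the lumen, `lattice_length` demes run along the oral–gastric axis
(row 0 is the oral end), and each deme holds at most `deme_capacity` K
cells.  Per time step, each cell

1. dies with probability `d + kappa * field(deme) * n_clonal_neo` (see
   *Immune model*),
2. divides with probability `b * (1+s)^n_drivers * (1 - occupancy/K)`,
   capped so a deme never exceeds K (division is contact-inhibited),
3. migrates to a 4-neighbour deme with probability `m`, the oral-side
   neighbour weighted `1 + beta` and the gastric-side neighbour `1 - beta`
   (lateral neighbours 1), rejected if the target deme is full or off the
   open ends.

Each division gives the daughter cell Poisson(`mu`) new exonic mutations;
each is a driver with probability `driver_prob` (multiplying the birth rate
by `1 + driver_fitness`), otherwise a passenger, neoantigenic with
probability `neoantigen_prob`.  The founder cell carries
`n_founder_mutations` clonal mutations.  Growth stops at `target_cells`,
at extinction (a reported outcome, never an exception), or at `max_steps`.

Deaths precede births within a step, so supercriticality requires
`(1-d)(1+b) > 1`; the defaults sit deliberately close to that boundary
(high cell turnover), because turnover is what populates the subclonal
frequency band that the downstream site-frequency statistics read.

For the selection arm, a single driver can be injected when the tumor
reaches `driver_injection_fraction` of its target size.  The driver is
placed in the active growth ring (demes with established but sub-capacity
occupancy) where it can divide immediately, and is re-injected if drift
extinguishes the clone — the selection arm models a tumor that *carries*
an established driver subclone.

### Immune model

Immune killing is antigen-abundance driven: a neoantigen attracts killing
only while the clone carrying it exceeds a fraction
`immune_clonal_threshold` (default 0.10) of the tumor, reflecting that
T-cell priming requires antigen dose.  The extra death hazard is
`immune_kill * immune_field(deme)` per such clonally expanded neoantigen.
Two immunoediting routes emerge: founder-load selection (clonal antigens
burden every cell, so under a strong field most incipient tumors are
eliminated and the ones that establish carry fewer clonal antigens) and
trunk exclusion (an expanding antigenic clone is pushed back whenever it
crosses the threshold, keeping it out of the trunk).  Rare mutations are
invisible to the hazard, so the ever-growing passenger load does not erode
viability — the property that makes this formulation stable where a flat
per-neoantigen hazard is not.

Field intensities per immune type (hot 7e-4, heterogeneous 3e-4, cold
3e-5 at `immune_kill = 1`) look small but are set by the growth regime's
per-step viability margin of roughly 0.07: a clinically existing tumor is,
by construction, one that surveillance failed to eliminate, so the
sustained per-antigen attrition must sit well below that margin while
still suppressing fixation over the tens of steps a clone needs to reach
the trunk.

### Spatial sampling and sequencing

Five disk regions mimic the clinical sampling scheme: T5 at the
occupied-deme centroid, T1/T3 at the oral/gastric extremes, T2/T4 at the
circumferential extremes; disk radius 3 demes.  True cancer-cell fractions
(CCFs) are computed over the cells inside each disk.  Lymph-node samples
are clonal expansions of one randomly chosen cell plus node-private
mutations.  Sequencing draws per-site depth Poisson(310) and alt reads
Binomial(depth, `purity * CCF / 2`) under a heterozygous diploid model;
copy number is fixed at 2 in simulation although the CCF formula accepts
arbitrary copy number and multiplicity for real data.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| lattice | 36 x 48 demes, K = 40 | tumor (~140 occupied demes) fits without wrapping |
| b, d, m | 0.65, 0.35, 0.15 /cell/step | high turnover; margin `(1-d)(1+b)-1 = 0.07` |
| founder row | 0.4 of length | oral-side headroom; biased growth piles against the upper margin |
| mu | 6 exonic mutations/division | populates the VAF window used by the 1/f test |
| founder load | 50 clonal mutations | trunk scale comparable to MRS cohorts |
| neoantigen rate | 0.10 of passengers | in-silico HLA-binding prediction scale |
| target size | 2,500 cells | desk-scale: ~0.1 s/tumor; all window statistics are scale-free |
| regions/patient | 2–5, mean 4.47 | matches 461 regions over 103 patients |
| LN samples | 0–2 (p = .65/.25/.10) | ~0.45 nodes/patient |
| depth, purity | Poisson(310), U(0.6, 0.9) | WES-scale depth, surgical-specimen purity |
| exome | 38 Mb | burden denominator |

Per-patient clinical covariates (sex, age 40–80, drinking, smoking, stage)
come from configurable marginals; with coupling on, drinkers receive a
higher upward bias `beta` (Normal(0.45, 0.1) vs Normal(0.15, 0.1)) and a
lower immune-hot probability.

What the generator does **not** emulate: copy-number events, mutational
signatures, methylation or expression, 3-D growth, multi-step metastatic
dissemination, and realistic inter-patient mutation-rate variation.
Passing recovery tests on these cohorts therefore demonstrates that the
statistics read out the modelled causal structure, not that they would
behave identically on real MRS data.

## The analysis toolkit

**Presence and classes.**  A variant is present in a region when
`alt_reads >= 3` and VAF >= 0.02 (conventional for ~300x WES; the source
analyses do not state thresholds).  Trunk = present in all of a patient's
regions, private = exactly one, branched = otherwise; gITH is the
heterogeneous (branched + private) fraction.  LN samples participate
exactly like primary regions.  CCF = `VAF * (purity*CN + (1-purity)*2) /
(purity * multiplicity)`, capped at 1 with a flag.

**Phylogeny.**  Characters are binary presence/absence; gains and losses
cost 1 (Fitch) with the germline all-absent state as the root.  Compatible
(laminar) pattern sets take a direct perfect-phylogeny construction;
otherwise an exhaustive leaf-addition search with branch-and-bound finds
the minimum-score topology up to 8 regions (greedy insertion + NNI above
that), with Fitch state sets packed two bits per pattern into machine
integers.  Ties break deterministically (fixed enumeration order, first
optimum kept).  Because somatic mutations do not revert, a pattern is
assigned to an edge only when one gain and no loss explain it; patterns
needing more changes are flagged homoplastic, attached to the largest edge
whose leafset is contained in the pattern, and excluded from clade
tabulation by default (a switch includes them).

**Directed expansion.**  For branched clades containing the center,
`freq(X)` is the fraction also containing margin X (clade level) plus a
patient-indicator version.  The bootstrap resamples patients with
replacement (clade-level resampling is a flag), recomputes
`freq(T1) - freq(X)` per replicate, and reports the one-sided p as the
fraction of replicates at or below zero, alongside a Student's t over
replicates.  T2/T4 are also pooled as "lateral".  Fisher's exact test is
implemented by hypergeometric enumeration (two-sided: summing
probabilities not exceeding the observed table's, with the customary
1e-7 relative guard) with Haldane-corrected odds ratios.

**Neutrality.**  The cumulative count M(f) of mutations with VAF in
[f, f_max] is fitted through the origin against `1/f - 1/f_max` over the
window [0.12, 0.24], evaluated at the observed in-window VAFs, and the
uncentered R-squared of the zero-intercept fit (the convention of the
established neutrality-test tooling) is compared to 0.98.  Fewer than 12
in-window mutations give an indeterminate verdict.  The pipeline tests
each region and takes the patient verdict from the center region
(fallback: the region with the most in-window mutations).  A caveat
documented here deliberately: at any population size, a single
branching-process realization concentrates the window's mutation mass in
a handful of clones, so even truly neutral spatial tumors fail this test
in an appreciable fraction of realizations at 310x depth; the test's
false-alarm rate is reported by the acceptance suite rather than hidden.

**Subclones and RCS.**  Alt counts are fitted with a binomial mixture
(component success probabilities `purity * CCF / 2`), EM with k-means-style
random-data-point initialisation, restarts batched and vectorised, K
chosen by BIC over 1..K_max.  The regional clonality score is the CCF of
the most clonal *subclonal* component (components at or above the clonal
cut 0.9 are skipped; no subclonal component gives 0); the tumor value is
the median over regions and the cohort splits at the median.  The formula
is reconstructed from its textual definition and parameterised (clonal
cut, K_max, restarts) so it can be reconciled against an exact definition
later.

**FST.**  Hudson-style estimator on per-site VAF pairs with read depth as
the sample-size proxy, ratio-of-averages across sites, clamped to [0, 1];
an uncorrected mode supports closed-form checks.  Longitudinal (T1–T3)
and transverse (T2–T4) axis summaries are reported.

**Immune typing and IM.**  Cohort-wide agglomerative clustering (Manhattan
distance, average linkage, two clusters) labels regions; hot is the
cluster with the higher mean CD8+ T fraction; a patient is hot/cold only
when all regions agree, heterogeneous otherwise; iITH is the mean pairwise
Manhattan distance among a patient's region vectors (in [0, 2] for simplex
rows).  The immunoediting score is the observed neoantigenic yield over
the expected yield under the mutation set's trinucleotide-context
composition (a table with a `*` key gives a flat rate); scores are
computed on nonsynonymous mutations with at least 10 eligible by default.
The strong/weak split fits one- and two-component Gaussian mixtures to
log IM and keeps two modes when BIC prefers them (equal-posterior
boundary); a unimodal fit falls back to the deterministic threshold
IM = 1.

## Numerical and reproducibility notes

All randomness flows from `numpy` Generators; cohorts split one
SeedSequence per patient, and every derived integer seed stays below
2^31.  A fixed (config, seed) pair reproduces bit-identical tumors,
cohorts, and analysis bundles (the bundle digest hashes every output
table).  Genealogy traversals (subtree counts, ancestry sums) are numba
kernels; topology search uses packed-integer Fitch.  EM tolerance is 1e-6
on the log-likelihood with 500 iteration cap; cluster CCFs are clipped to
[1e-6, purity/2] on the success-probability scale.  Ties in the
minimal-immune-distance margin break toward the lowest region index with
a flag; FST sites with depth < 2 or zero denominator are skipped and
counted; degenerate identical-row inputs to hot/cold clustering raise an
explicit error.

Problem sizes used by the acceptance suite (tumor target 2,500 cells,
30-patient cohorts for the directed-expansion checks, 103 patients for
the end-to-end run) are the package's desk-scale study conditions; the
generator's statistics of record (window mutation counts, clade-sharing
frequencies) are insensitive to the absolute tumor size, which is why the
scale-down is legitimate.

## Known limitations

- The 1/f neutrality calibration has an irreducible false-alarm floor at
  this depth and window (see above); cohort-level neutral fractions should
  be read as upper bounds on selection prevalence.
- The regional clonality score inherits spatial-drift clusters: genuinely
  neutral spatial growth produces intermediate-CCF clusters in every
  region, so RCS contrasts across selection strengths are weak at desk
  scale even when the injected driver is recovered in the center region.
- Copy number is diploid throughout the simulator; CCFs for real data rely
  on caller-supplied CN and multiplicity columns.
- The immune model's field intensities are phenomenological (per-step
  hazards), not calibrated to any measured infiltration scale.
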