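# Methods

## Quantification model

Each protein × tissue × replicate observation is a vector of reporter-ion
intensities on the 8-plex label set (m/z 113–121). The stage assignment is
fixed by the experimental design: pericarp 10/20/33/46 DAP on channels
114–117, endosperm on 118–121, and a common control on 113. Relative
abundance at a stage is the ratio of the stage channel to the control
channel within the same record; records whose control intensity is absent
or zero are excluded with a per-protein reason code, never silently.

Reporter intensities are treated as multiplicative quantities, so
replicate ratios are merged by **geometric mean** (arithmetic mean is
available by configuration). Under the log-normal noise model below the
geometric mean is the maximum-likelihood consensus and is unbiased on the
log scale. A protein is *replicate-confirmed* when it is quantified in
both biological replicates.

Missing intensities are encoded as absent table cells, never as zero: zero
is a legal measured value, and the two must be distinguished wherever an
intensity lands in a denominator.

## Differential-expression calling

A stage ratio `r` is called **up** when `r ≥ 1.5` and **down** when
`r ≤ 0.67`, boundaries inclusive; both thresholds are configuration
parameters of `DepThresholds`. "Stage-exclusive up-regulation" means up at
that stage and at no other; the "always-up" set requires an up call at
every stage at which the protein was quantified. Venn partitions
(tissue-specific / shared; stage-common / stage-exclusive) are plain set
operations and satisfy inclusion–exclusion by construction.

Ratios are *not* normalized (e.g. median-centered per channel) before
thresholding by default; a normalization hook would change calls only
through a per-channel constant, and leaving it off keeps the ratio scale
interpretable. This choice is exposed rather than hidden.

## Temporal patterns

Profiles are log2 consensus ratios over the four stages, for proteins
quantified at all stages. Classification is rule-based on the signs of
consecutive differences, with differences of magnitude ≤ **0.1 log2
units** (the default tolerance) collapsed to flat:

* all steps ≥ 0 with at least one rise → monotone up (P1);
* a strict rise phase followed by a strict fall phase → up–down (P2);
* the mirror image → down–up (P3);
* all steps ≤ 0 with at least one fall → monotone down (P4);
* anything else (fully flat, multi-modal) → unclassified.

The unclassified bucket is explicit rather than forced into a partition,
because real cohorts contain flat and multi-modal profiles. Pattern
assignment is invariant under positive scaling of the raw ratio profile
(a log2 shift), which the tests check by property.

Hierarchical clustering of the profiles uses **uncentered Pearson
correlation distance with average linkage** by default (the conventions of
the Cluster 3.0 lineage of tools; Euclidean distance, centered Pearson and
complete linkage are options), implemented over
`scipy.cluster.hierarchy`. Patterns are *not* read off dendrogram
branches — the four patterns are trend categories, and the dendrogram is
kept for ordering and export. Zero-norm profiles (undefined uncentered
correlation) are excluded with a logged reason. The test suite checks the
agglomeration order and merge heights against a brute-force O(n³)
reference on random tie-free instances; exact tie-breaking among equal
merge distances is therefore not part of the contract.

## Functional tallies

GO (BP/CC/MF) and COG tallies are flat multi-membership counts over an
input annotation map: a protein with k categories contributes to k
tallies, unannotated proteins land in an explicit bucket, and equal counts
order lexicographically. No GO DAG propagation is performed — the map is
taken as an already-sliced flat classification, which keeps counts
independent of any ontology release.

## Interaction networks

Network seeds are proteins whose consensus ratio reaches **5-fold in
either direction** (`r ≥ 5` or `r ≤ 0.2`) at any stage — the "absolute
value" of the fold change is read as log-fold magnitude. Seeds map
protein → gene model (a trailing isoform suffix `_Pnn` is stripped when
needed) → KO; unmapped seeds are reported, never dropped.

"Interaction" is operationalized as **KO co-membership in a KEGG
pathway**: this is the central modeling choice, made because pathway
linking is the only integration mechanism specified — no physical
protein–protein-interaction database enters. First-degree interactors are
non-seed proteins whose KO shares ≥ 1 pathway with a seed KO (a KO
co-occurs with itself in any pathway containing it, so a non-seed protein
carrying a seed's KO is first-degree); second-degree interactors share a
pathway with a first-degree KO but with no seed. Shortest-hop labeling
keeps the roles a partition, matching a concentric seed / inner shell /
outer shell layout, and the expansion provably equals a depth-2 BFS on the
KO co-membership graph (tested against an independent BFS oracle on random
bipartite databases). Pathway link tables are consumed offline in the
exact two-column flat format of the KEGG REST `link` endpoint. Exports:
SIF, GraphML (roles, KO, witnessing pathways as node attributes) and a
node-attribute TSV.

## qPCR concordance

Relative mRNA expression is `2^−ΔΔCt` with
`ΔΔCt = (Ct_target,sample − Ct_ref,sample) − (Ct_target,cal − Ct_ref,cal)`,
technical replicates averaged on the Ct scale, and the earliest stage as
calibrator. Concordance between a gene's mRNA fold-change profile and its
protein ratio profile is Spearman rank correlation over shared stages
(≥ 3 required), with verdict *concordant* at ρ ≥ 0.5 — the cutoff is a
package choice, exposed in configuration, since discordance is otherwise
only qualitative. Constant profiles have undefined rank correlation and
yield an explicit undefined verdict.

## Synthetic-data generator

The generator emulates the study design: two tissues × four stages × two
replicates on the 8-plex layout, with per-protein planted truth.

* **Tissue membership**: 15% pericarp-specific, 10% endosperm-specific,
  the rest shared (defaults; configurable).
* **Temporal shape**: each protein/tissue draws one of the four trend
  patterns or flat (default mix 30/10/10/30/20%). Shapes are fixed unit
  vectors in log2 space — extremes ±1, interiors ±0.25 — scaled by an
  amplitude.
* **Amplitude**: differential profiles (20% of patterned proteins by
  default) draw their maximal fold change from 2–8×, a range that includes
  the ≥ 5-fold network seeds; background profiles stay at log2 amplitude
  0.20–0.35 (max fold 1.27). These margins are chosen so that, at the
  default noise, planted calls sit ≥ 2 consensus-noise standard deviations
  from the 1.5/0.67 thresholds: the planted truth is recoverable by
  design, and at σ = 0 recovery is exact.
* **Noise**: control intensity is log-normal; each stage channel is
  `control × planted_ratio × exp(ε)`, ε ~ N(0, σ²) independent per
  replicate (σ = 0.1 default). Multiplicative log-normal noise is the
  standard model for reporter-ion quantification and makes the
  geometric-mean consensus exact in expectation. Missing values are
  injected on stage channels only (never the control) at a configured
  rate.
* **Pathway database**: a miniature KO/pathway bipartite membership
  sampled at density 0.008 over 400 KOs × 80 pathways (mean pathway size
  ≈ 3 KOs), with every planted ≥ 5-fold seed guaranteed at least one
  pathway. The sparse default produces both first- and second-degree
  shells; dense or single-pathway limits degenerate exactly as the theory
  predicts (complete first shell / empty second shell) and are tested.
* **Annotations**: 1–2 flat categories per namespace per protein from
  small pools, plus planted tissue-exclusive categories as known positives
  for the exclusivity report.
* **Ct tables**: invert the ΔΔCt relation from the planted protein profile
  (one cycle per log2 unit around fixed target/reference baselines), with
  optional Gaussian Ct noise and deliberately discordant genes (negated
  profiles) plantable.

Everything is deterministic under (config, seed); derived sub-seeds are
fixed offsets of the master seed.

What the generator does **not** emulate: peptide/spectrum-level structure
(protein inference, FDR control — upstream of this pipeline), channel
cross-talk and ratio compression typical of isobaric quantification,
intensity-dependent variance, correlated annotation structure, or real
pathway topology. Passing tests therefore demonstrate the correctness of
the computations under the stated noise model, not robustness to every
artifact of real MS data.

## Problem sizes and numerical choices

The bundled analysis drivers use 1500 proteins at σ = 0.1; the recovery
and performance checks use 2000 proteins (noiseless and σ = 0.1 with
planted 3-fold changes); oracle-equivalence suites use 200 random
databases of ≤ 50 KOs and 6–10-profile linkage instances. TSV writers emit
floats at round-trip precision (`%.17g`) and readers parse with
round-trip precision, so read(write(x)) is exact and repeated runs are
byte-identical. Agglomeration tie policy follows scipy; classification
tolerance, thresholds, the concordance cutoff and the network fold cutoff
are all configuration with the defaults stated above.

## Known limitations

* The ≥ 5-fold network filter operates on consensus ratios; proteins
  quantified in only one replicate can still seed a network (their support
  is reported).
* Pattern classification requires a complete profile (all stages); partial
  profiles are listed but not classified.
* The KO co-membership interaction definition links any two KOs sharing a
  pathway, which over-connects large pathways relative to curated
  interaction databases; witnessing pathways are carried on every edge so
  downstream filtering remains possible.
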