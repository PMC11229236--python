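# Methods

This note documents the models, defaults and numerical choices behind
`peachbud`, and what the synthetic benchmark does and does not demonstrate.

## Study design being emulated

A single-block field experiment on peach: GA₄/₇ sprayed at five timepoints
(T1–T5 days after full bloom), with untreated control (UTC) trees. Buds
from the apical and basal halves of shoots are sampled at each timepoint;
RNA-seq covers T1, T3 and T5 (3 biological replicates per position ×
timepoint, 18 libraries), hormones are quantified at the same timepoints
on basal buds (n = 5), and efficacy is an *ex post* two-level factor on
basal samples: **high** at T3 (the stage of maximal bloom inhibition),
**low** at T1/T5. Return bloom is measured the following spring as
flower-covered image area per tree, expressed as a percentage of UTC, and
an AP1-like floral-identity marker is assayed by qPCR across blocks.

## Synthetic data generator

`simulate.SimulationConfig` holds every knob; one integer seed drives
independent, reproducible random streams per stage.

**Hormones.** Per-timepoint template means (arbitrary units — the source
assays report relative bar heights, not numeric concentrations) encode the
measured directions: GA₃ rises from T1 to T3, GA₇ peaks at T5, GA₄ is
nearly flat, ABA/JA/SA decrease, IAA peaks at T3, tZ is flat and 2-iP rises
at T5. Replicate noise is lognormal (cv 0.15 by default) and
mean-corrected, because mass-spectrometric concentrations are positive and
right-skewed.

**Counts.** Gene baselines are lognormal (median 150, log-sd 1.3);
per-gene per-sample expected means add, in log₂ space: a monotone
developmental trend on 35% of genes (sd 0.5 log₂ units — this is what PCA
and clustering see), an apical/basal offset on 20% (sd 0.4), planted
hormone modules (sign-respecting affine transforms of the hormone template,
peak-to-peak amplitude 1.5–2.5 log₂ units, i.e. a ~3–6-fold dynamic range
typical of strongly hormone-responsive transcripts; module genes are kept
at baseline mean ≥ 50 so their profiles are estimable from 3 replicates),
and the efficacy effect (±2 log₂ by default on 5% of genes, basal T3
only). Counts are negative binomial with Var = μ + αμ² (α = 0.05) over
per-sample lognormal depth factors; `count_noise=False` gives the
deterministic rounded-mean limit. Gene lengths are uniform on
[500, 5000] bp (the source is silent on lengths; they only feed RPKM).
All planted gene sets (modules, DEGs, trend, position) are disjoint, so
`TruthTable` labels are unambiguous. Genes with a planted time trend carry
a second-order efficacy confound of −log₂ cosh(δ ln 2) ≤ 0.09 at the
default trend sd (the T3 level sits at the geometric, not arithmetic,
midpoint of T1/T5); this is negligible against the ≥ 1 log₂FC call cutoff
and the truth table records the planted efficacy effect only.

**qPCR and bloom.** Block-level bloom follows a V-shaped template (UTC
100%, T1–T5 at 75/60/40/55/70%), so every treated block is below UTC with
the minimum at T3. Block-level marker expression is constructed by an
orthogonal-residual rotation to correlate with the true block bloom means
at exactly the configured level (default 0.99) *before* measurement noise;
it is then emitted as Ct values (marker + TEF2/UBQ10 references, 3
biological × 2 technical replicates, technical sd 0.05 cycles, biological
sd 0.1 log₂) and per-tree areas get 5% lognormal noise. The measured
correlation is therefore mildly attenuated (≈ 0.98 on average over seeds).

**What passing tests do not show.** The generator plants clean, disjoint,
mostly affine structure: no batch effects, no count outliers, no
gene–gene correlation beyond the shared profiles, no GO hierarchy, and
hormone/gene profiles restricted to 3 timepoints. Recovery rates measured
here are upper bounds on what the same methods achieve on real bud data.

## Differential expression

Median-of-ratios size factors use only genes with nonzero counts in every
sample. Dispersion is method-of-moments on normalized counts,
α = max(α_min, (s² − μ̄)/μ̄²) with α_min = 1e-8 and the variance pooled
(df-weighted) within design levels, so a true group difference is not
absorbed into α. No shrinkage of either dispersion or fold change is
applied — thresholds act on the maximum-likelihood log₂FC — which is a
deliberate simplification relative to the reference Bioconductor
implementation. The Wald statistic uses the delta-method variance
Var(log μ̂) ≈ (1/n²μ̂²) Σ_j (μ̂/s_j + αμ̂²). A group whose mean is exactly
zero gets a half-count continuity value (0.5/n) so one-sided-zero genes
report a finite fold change; genes all-zero in both groups are reported
untested. "Twofold cutoff" is read as |log₂FC| ≥ 1 inclusive. The time
design is fitted as pairwise two-level contrasts (T1–T3, T1–T5, T3–T5)
rather than one three-level model, matching how pairwise DEG counts are
conventionally reported. No independent filtering is applied.

## Pathway activity and enrichment

PGSEA activity uses the parametric one-sample z form: per-gene population
z-scores across samples (constant genes dropped), set score
mean(z)·√|S|; sets with fewer than `min_size = 2` mapped genes are skipped
(a one-gene "pathway" is just that gene's z). Significance is one-way
ANOVA of activity across sample groups — the default grouping is the six
position × timepoint groups — with BH over sets and a flag at FDR ≤ 0.05.
Over-representation is the upper-tail hypergeometric with BH across tested
terms; zero-overlap terms are reported but not tested. BH (not Bonferroni)
is used throughout, where only "FDR" is specified. Degenerate ANOVA cases
are resolved by limits: zero variance everywhere → F = 0, p = 1; zero
within-group variance with distinct means → p = 0.

## Sample structure

Clustering and PCA run on log₂-CPM (pseudocount 1). The heatmap-style
clustering uses the 2,000 most variable genes (deterministic tie-break by
gene ID); PCA uses all genes. Sample distance is 1 − Pearson with average
linkage; constant samples are rejected by name, and outliers are reported,
never dropped. PCA centers per gene and fixes each component's sign by
making its largest-magnitude loading positive, so results are reproducible
across SVD implementations. PC–factor association is one-way ANOVA of
scores on factor levels. The developmental ordering is the mean PC1
coordinate per position × timepoint group, oriented so the latest
timepoint (T5) carries the largest coordinate — a global PC1 sign flip
cannot change the reported order.

## Hormone–gene network

Correlations are computed on per-timepoint **means** (3 points): hormone
replicates (n = 5) and RNA replicates (n = 3) are unpaired, so a
replicate-level correlation is undefined. Only basal-bud expression at
T1/T3/T5 enters. Edges require |r| strictly greater than the threshold
(default 0.90) and are bipartite only (hormone↔gene); hormone–hormone
relations emerge exclusively through bridging genes. Edge weight for the
spanning forest is 1 − |r| (the strongest correlations survive
preferentially); Prim runs per component with a deterministic tie-break
(weight, then lexicographic endpoint pair). Every gene's strongest edge is
in the forest (cut property), so a non-bridge gene is assigned to its
best-correlated hormone; bridge genes (forest degree ≥ 2) take the
lexicographically smallest hormone as primary and are flagged. Two
counting modes are provided: primary (sizes sum to the gene-node count)
and bridge-in-all (reproducing the convention where per-subnetwork sums
exceed the node total). Eccentricity is all-sources BFS within components.
Interaction calls collect, for each bridge gene, the sign pairs of all its
retained graph edges: all-concordant → synergism, all-discordant →
antagonism, otherwise mixed. A geometric note: with 3 timepoints the
centered profiles live in a plane, and |r| > 0.9 to two hormones forces
each bridge's sign pair to equal the sign of the hormone–hormone
correlation — so on 3-point data verdicts are exactly the hormone-profile
sign structure, and `mixed` can only arise with more timepoints. Node
"mean expression" for export is mean log₂-CPM over the network's samples.

An important identifiability limit, documented rather than hidden: 3-point
profiles have two degrees of freedom, so the ten hormone profiles are
mutually highly correlated and |r| > 0.9 admits a wide band — on the
default fixture ~85–90% of genes join the network (as in the real study,
where nearly the whole transcriptome did), and per-hormone subnetwork
sizes are *not* attributable to the planted modules. The dedicated
`subnetwork_recovery_config` fixture therefore plants 50/20/10-gene
modules on the three most mutually separable profiles (GA₇, tZ, IAA),
uses noiseless hormone means, low dispersion and an unstructured
background (so library composition stays stable), and restricts the graph
to module genes and those hormones; there the planted sizes are recovered
within ±10%.

## qPCR, bloom and letter displays

MNE follows the two-reference convention: RQ = E^(−Ct) per well (default
efficiency E = 2.0, overridable per well), technical replicates averaged
on the RQ scale, normalization factor = geometric mean of the reference
RQs, MNE = RQ_target/NF. This makes MNE invariant to global per-sample Ct
shifts and reference order. Block-level marker means aggregate the 3 × 2
replicate wells (n = 6). Return bloom is 100 × block mean area / UTC mean
area. Compact letter displays come from one-way ANOVA + all-pairs Tukey
HSD (α = 0.05) with the insert-and-absorb algorithm; letters are assigned
in descending-mean order, groups sharing a letter are not significantly
different, and the all-identical degenerate case shares a single letter.

## Problem sizes

Defaults are scaled for fast, repeatable benchmarking: 2,000 genes
(configurable to 20,000), 18 RNA-seq samples, 50 simulation replicates for
DEG sensitivity/FDR, 5 for module-edge recovery, and 200 for the
marker–bloom correlation. The full acceptance run completes in seconds on
one CPU.

## Known limitations

- No GO DAG / true-path propagation; gene-set fixtures are toy collections.
- No fold-change or dispersion shrinkage; at n = 3 per level the
  method-of-moments dispersion is noisy and power is below what a
  shrinkage estimator would give.
- Network inference from 3 timepoints cannot distinguish hormones with
  near-collinear profiles; subnetwork membership is then a property of the
  spanning forest, not of biology.
- The headline dataset-specific results of the study this mirrors (e.g.
  exact DEG counts or an 18,146-node network) require the original
  sequencing data and are out of scope; the package reproduces the
  *procedures* and validates them on planted truth.
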