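# Methods

## Scope and model

The package implements a candidate-gene screen for endosymbiont-induced
feminization as a deterministic pipeline over four analysis layers —
comparative-genomics filtering, efficiency-corrected qPCR expression
profiling, cross-host lagged correlation, and f-element mapping — plus the
marker arithmetic used to quantify endosymbiont DNA enrichment. Raw
sequencing, assembly and annotation are out of scope: the pipeline starts
from an annotation table whose repeat/pseudogene/split-CDS flags are taken
as given, exactly as the original screen did.

## Homology engine

Pairwise protein comparison uses exact affine-gap dynamic programming
(Needleman–Wunsch and Smith–Waterman via Biopython's `PairwiseAligner`)
with BLOSUM62, gap open 11 and gap extend 1 (a gap of length *k* scores
−(11+*k*)). Identity is matches / alignment columns; query coverage is the
aligned fraction of the query. Bit scores use the gapped-BLOSUM62
Karlin–Altschul constants λ = 0.267, K = 0.041, and e-values are
E = m·n·2^(−S′) with the product of the two sequence lengths as search
space. These e-values only gate fixed thresholds (10⁻⁶ for clustering,
10⁻³ for the f-element search); they are not calibrated against a database
null model, which is irrelevant at the separation the thresholds operate
on. A heuristic is used only to decide *which* pairs to align: an inverted
4-mer index skips pairs sharing fewer than 3 exact 4-mers. Homologs at
≥ 70 % identity share dozens of 4-mers while unrelated desk-scale proteins
share ~0.06 on average, so the screen is lossless in practice; every
reported statistic comes from a full DP alignment.

Ortholog groups are connected components (≥ 2 members) of the
reciprocal-hit graph at ≥ 70 % identity and e-value ≤ 10⁻⁶; the core
genome is the subset of groups represented in every reference genome.
Markov clustering adds nothing at the identity separations generated here
(within-family ≥ 70 %, between-family background ~5 %), and component
recovery is exactly testable against brute-force graph search. The 70 %
identity floor is applied to the aligned region, not the full protein.

## Filter cascade

Removal order is fixed: repeat → pseudogene → short (< 150 bp; the
equivalent protein cut is < 50 aa) → split-CDS chunk → core-genome ortholog
→ 100 % identity to the non-feminizing strain over ≥ 90 % of the query.
A gene matching several categories is counted only under the first filter,
so removal counts partition the input; `FilterResult.check_partition`
enforces this on every call. "100 % similarity" is read strictly as 100 %
amino-acid identity of the aligned region with ≥ 90 % query coverage — a
hit at 99.9 % identity or 89 % coverage does not remove a gene.

## qPCR quantification

Amplification curves are reduced to (E, Ct) by a windowed log-linear fit:
baseline = mean of the first 5 cycles, detection threshold = 10× the
baseline standard deviation (floored at 1 % of the corrected maximum so
that noiseless synthetic curves remain analysable), efficiency from the
contiguous ≥ 4-cycle window maximizing R² of log F versus cycle inside the
exponential region (above threshold, below 90 % of plateau), and Ct as the
fractional cycle where the fitted exponential crosses the threshold. This
replaces the original iterative curve-fitting tool, whose full algorithm is
not public; the downstream analysis consumes only (E, Ct).

Relative expression follows the Pfaffl model with multiple references:

    ratio(s) = (1+E_t)^(Ct_t,cal − Ct_t,s) / geomean_r (1+E_r)^(Ct_r,cal − Ct_r,s)

with Ct_·,cal the mean Ct over calibrator-stage (stage 2) samples of the
same host and sampling campaign, technical replicates averaged at the Ct
level first, and E ∈ [0, 1] (amplification factor 1+E; all E = 1 reduces
the formula exactly to 2^−ΔΔCt, a tested invariant). Campaigns in which a
target was not assayed are skipped rather than treated as errors.

Reference genes are selected BestKeeper-style: Pearson r of each
housekeeping candidate's Ct against the per-sample geometric-mean Ct index,
keeping genes with r > 0.95 (a pairwise-correlation mode is available).
Selected genes are then verified to be stage-invariant relative to the
*wsp* genome-copy signal. A plain one-way ANOVA at p ≤ 0.05 would falsely
reject ~5 % of genuinely stable genes regardless of how small the drift is,
so the check requires both significance **and** practical relevance: a gene
is dropped only when p ≤ 0.05 *and* the span of its per-stage mean
Ct-differences exceeds 0.3 cycles (~1.23-fold). The 0.3-cycle margin is an
equivalence bound, not a fitted constant.

Differential expression uses inclusive thresholds (ratio ≥ 2 over,
≤ 0.5 under) on per-stage means over pools during the stages of sexual
differentiation (3–6 native host, 2–5 heterologous host); when a profile
crosses both thresholds the larger |log2| departure wins. The
second-sampling consistency rule retains a gene iff at least one individual
replicate crosses the same-direction threshold at ≥ 1 stage.

## Cross-host correlation

Per-stage mean log2 profiles (stages 1–7) are compared by the sample
cross-correlation function, ccf(l) = Σₜ(aₜ−ā)(b₍ₜ₊ₗ₎−b̄)/(n·s_a·s_b),
summed over the n−|l| overlapping stages but normalized by the full-series
standard deviations and n (the R `ccf` convention — values shrink at large
lags). Lags run over ±2 by default (7-point grids support little more).
best_lag maximizes |ccf| with ties broken toward smaller |l| then the
positive lag; significance uses the white-noise band 1.96/√n with n = 7,
i.e. |ccf| > 0.741. An autocorrelation pre-check (same centering and band)
flags series with serial structure but does not exclude them; η² =
SS_between/SS_total over the replicate matrix is reported per gene and
host, flagged informationally below 0.5, with no pass/fail threshold.

## Synthetic-data generator

The generator is first-class, tested code that defines the study
conditions; its defaults encode the screen's published funnel
(1888 → 1002 → 265 → 216 → 139 → 13+29 → 35 → 29 → 3 (2 at lag 1) →
27/20, copy numbers 1–5) as a `FunnelPreset`, every count of which can be
changed for scaled-down tests.

*Sequences.* Proteins are uniform over the 20 standard residues; short
genes are 20–48 aa (< 150 bp), all others 60–119 aa. Planted categories
are disjoint (the printed removal counts sum exactly through the funnel);
flag precedence on overlapping flags is unit-tested separately. Core genes
get homologs in all five reference genomes at 78–95 % identity;
conserved-in-sister-strain genes get full-length identical copies; ~60
other candidates get 92–97 %-identity sister-strain homologs that must
survive the 100 %-identity filter. Planted substitutions are spread across
the sequence interior (stratified positions, ≥ 5 residues from the ends) so
that local alignment can neither trim a terminal mismatch — which would
inflate an f-element copy to an apparent 100 % — nor find a long perfect
sub-block.

*qPCR structure.* Ct = base − (ln q·fold)/ln(1+E), where q is a latent
per-sample template quantity (SD 2.5 cycles at E = 1) shared by all genes
of a sample. Because log-concentration shifts divide by ln(1+E) in Ct and
multiply back in the ratio, q cancels exactly in calibrated ratios — with
zero measurement noise the pipeline recovers planted folds exactly (tested
round trip). The six stable housekeeping genes track q with 0.02-cycle
residual noise; the other nine (including the second marker *ftsZ*) add
independent noise of 0.85× the latent SD, which puts their index
correlation near 0.79 and the stable genes' near 0.985 — clear of the 0.95
selection threshold on both sides at the sample sizes of the design. The
*wsp* marker is emitted separately (it measures genome copies, tracks q
tightly, and would otherwise be selected as a seventh reference). Target
efficiencies are drawn per gene from [0.85, 1.0]; housekeeping assays use
E = 1. Per-well Gaussian noise is 0.1 cycles (the value is a package
default, exposed in `NoiseModel`; the original study reports none), with
two technical replicates per well. The sampling design is one pool per
stage 2–6 (first native-host sampling) and triplicate pools per stage 1–7
(second native-host and heterologous-host samplings).

*Planted expression.* Differentially expressed genes carry a ±2.1 log2
excursion at one differentiation stage with other stages within ±0.9; null
genes stay within ±0.32 (all comfortably clear of the log2 = ±1 thresholds
under the noise above). Second-sampling failures are capped at ±0.45.
Heterologous-host profiles of lag-assigned genes are the native profile
shifted circularly by the lag; all other final candidates' host pairs are
rejection-sampled against the package's own ccf statistic (planted lag:
best lag correct, |ccf| ≥ 0.9, other lags ≤ 0.55; everything else ≤ 0.55
at every lag), leaving a wide margin around the 0.741 significance bound.
Single-peak profiles in two hosts always align at some |lag| ≤ 2, so the
sampler refreshes the native profile every 40 failed draws.

*f element.* Planted members are represented by 1–5 copies; identical
members contribute one exact copy, all other copies are mutated to
≥ 95.35 % identity; non-member candidates appear as 80 %-identity decoys
(below the 90 % search floor) alongside unrelated proteins.

*What the generator does not emulate.* Real genome structure (prophage
architecture, operons, GC content), alignment ambiguity from indels,
inter-gene expression correlation, amplification failure structure, or
inhibition-dependent efficiency drift. Passing tests therefore demonstrate
that the pipeline's logic recovers planted structure at realistic noise,
not that the thresholds are optimal for any particular real dataset.

## Numerical conventions and degenerate inputs

Constant series raise explicit errors in acf/ccf; constant-Ct housekeeping
columns are excluded from selection with a warning rather than producing an
undefined correlation; missing Ct in one pool drops that pool from the
stage mean; a missing calibrator stage is an error naming the campaign.
Ortholog group ids are assigned by lexicographically smallest member, so
clustering output is independent of hit-table row order. All generators
derive their streams from `numpy.random.default_rng([seed, stream-tag])`;
identical seeds give byte-identical output files.

## Known limitations

- E-values are threshold gates, not calibrated significance statements.
- The Fisher enrichment test requires the caller to define the background
  gene set; no default background is assumed.
- Six-frame translated search of nucleotide scaffolds is not implemented;
  the f element is consumed as a protein set.
- The cross-correlation significance band uses n (not n−|l|) and no
  multiple-testing correction across genes, matching the original design.
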