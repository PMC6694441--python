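# Methods

## The analysis

`taunet` implements a group-level structural covariance analysis of regional
tau-PET uptake. The units of analysis are the 90 cortical/subcortical
regions of the AAL parcellation; subjects are grouped by APOE-ε4 carriage
crossed with CSF total-tau abnormality (abnormal when T-Tau ≥ 320 ng/L),
giving the four labels `A4-T-`, `A4+T+`, `A4+T-`, `A4-T+`.

For each group the pipeline:

1. **Residualizes** every region's uptake vector on an intercept, age, sex
   (0 = female, 1 = male) and whole-brain mean uptake by ordinary least
   squares. The regression is fitted per group, on that group's subjects
   only, which keeps groups statistically independent and lets the
   permutation engine rebuild pseudo-groups from scratch. Collinear
   covariates are dropped with a warning rather than failing the fit.
2. **Correlates**: the group network is the 90 × 90 Pearson correlation
   matrix `R` of the residuals (unit diagonal, symmetric).
3. **Binarizes at matched sparsity**: for sparsity `S`, the
   `K = round(S · N(N−1)/2)` edges of largest `|R_ij|` are kept as a 0/1
   graph. Sparsity-matched top-K selection (rather than a fixed correlation
   cutoff) equates edge counts across groups before topology is compared,
   and admits strong negative correlations as edges. Rounding is half away
   from zero; ties at the K-th edge break lexicographically on region
   indices, so binarization is deterministic and edge sets are nested in
   `S`.
4. **Computes graph metrics** on the binary graph:
   - *Cp*, average clustering coefficient (nodes of degree < 2 contribute
     0 — they are averaged in, not excluded, which lowers Cp on sparse
     graphs);
   - *Lp*, harmonic mean path length, the reciprocal of the mean inverse
     shortest-path distance over ordered pairs; disconnected pairs
     contribute an inverse distance of 0, so Lp is finite on fragmented
     graphs;
   - *Q*, modularity of a greedy agglomerative partition: starting from
     singletons, the connected community pair with the largest modularity
     gain is merged (ties to the smallest community-index pair), and the
     partition with the highest Q along the merge path is returned. The
     greedy optimum can fall below the exhaustive optimum; tests bound it
     by an exhaustive partition search on small graphs. Because merges
     depend on index-order tie-breaks, the partition is deterministic but
     not invariant to node relabeling when gains tie exactly.
   - *BC*, Brandes betweenness centrality with fractional shortest-path
     counting over unordered pairs, reported raw by default (normalization
     by (N−1)(N−2)/2 is an option); and nodal *degree*.

## Inference

Two groups are compared by a label-permutation test: subjects are pooled
and reassigned to two pseudo-groups of the original sizes, and the full
pipeline — residualization, correlation, binarization, metric — is re-run
on each pseudo-group. There is no shortcut estimator; the permutation
engine calls the same code path as the observed analysis. Global metrics
are tested at every sparsity in a grid (default 8%–30% in steps of 1%),
marginally per sparsity; nodal metrics at one fixed sparsity (default 8%)
with Benjamini–Hochberg FDR across the 90 regions. The default permutation
count is 5,000. Two-tailed p-values use the add-one estimator
`p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1)`, which cannot return zero and
is conservative by at most one rank. Internally the two group labels are
ordered canonically before permuting, so swapping the argument order
negates the observed differences and leaves p unchanged exactly.
Permutations that produce a zero-variance region in a pseudo-group are
redrawn with a logged count.

ROI-level group comparisons are a desk-scale analog of a voxel analysis:
one-way ANOVA per region across the four groups (optionally on
covariate-adjusted values), BH-FDR over the 90-region family, then pooled
two-sample t contrasts of each group against the reference restricted to
ANOVA-significant regions, again with BH-FDR within each comparison.
Pearson correlations relate regional uptake to the FAQ score within a
group (missing scores dropped pairwise) and CSF T-Tau to each region and
to whole-brain mean uptake. Demographic tables use the Pearson chi-square
without continuity correction (df = 1) for 2×2 count splits and
pooled-variance t-tests (from raw values or mean/SD/n summaries) for
continuous variables; these two choices reproduce the printed cohort-table
p-values where any standard test does (two printed cells are internally
inconsistent with their own counts under every standard 2×2 test variant
and are not used as checks).

## The synthetic cohort generator

Because the source cohort is not redistributable, the generator emulates
the statistical structure the analysis assumes. Regional uptake for
subject *i*, region *r* in module *m(r)* is

    x_ir = μ + β_age (age_i − ā) + β_sex sex_i + β_g g_i
           + σ [ √rb · u_i + √(rw−rb) · f_i,m(r) + √rsp · h_ir
                 + √(1−rw−rsp) · ε_ir ] + planted effects,

with all latent factors standard normal. Defaults: baseline μ = 1.5
(arbitrary SUVR-like units), structured scale σ = 0.25, five covariance
modules of 18 regions contiguous in atlas order (a stand-in for lobar
covariance), within-module correlation rw = 0.5, between-module rb = 0.1,
and a spatially smooth field `h` (moving average over atlas index,
rsp = 0.25 of variance) reflecting the spatial smoothness of PET uptake.
The smooth field matters structurally: whole-brain-mean residualization
strips the shared between-module factor, and without `h` the thresholded
graphs fall apart into module components at low sparsity. Even with it,
synthetic group networks typically first become fully connected at
sparsity ≈ 0.11–0.18 (smallest group n = 34); full connectivity at exactly
8% is a property of the real data, so analyses that require a connected
graph select the smallest connecting grid sparsity
(`min_connected_sparsity`) — the same criterion the study design uses to
pick its fixed sparsity — while the API default remains S = 0.08.

Group sizes default to 103/34/44/44 with per-group age, sex, diagnosis,
amyloid-status and MMSE distributions matching the printed cohort table;
CSF T-Tau is drawn truncated-normal on the correct side of the 320 ng/L
cut-off. Planted effects, all placed in the `A4+T+` group by default:

- a mean elevation of `effect_size` = 1.0 σ in ten temporal/limbic regions
  (bilateral parahippocampal, fusiform, middle/inferior temporal, right
  superior temporal, left amygdala);
- an FAQ coupling of 20 FAQ points per unit of mean uptake over the
  affected regions (FAQ is noise-added, rounded and clipped to the
  instrument's 0–30 range), chosen so the within-group uptake–FAQ Pearson
  r comes out ≈ 0.4–0.5, the scale of the reported correlations;
- a CSF coupling of 0.8 σ per within-group SD of T-Tau in the left
  olfactory and right parahippocampal regions.

What the generator does *not* emulate: voxel-level images, longitudinal
scans, site effects, heavy-tailed or floor-censored uptake distributions,
and any realistic anatomical adjacency beyond atlas-index smoothness.
Passing recovery tests therefore show the pipeline detects effects of the
planted kind at the planted scale — not that the effect sizes of any real
cohort are recoverable.

## Numerical and design choices

- K rounding half away from zero and lexicographic tie-breaks make
  binarization reproducible bit-for-bit; any fixed rule would do, this one
  is documented so tests can be exact.
- Degenerate inputs fail loudly and specifically: zero-variance regions
  are named; a disconnected network at the fixed nodal sparsity reports
  the smallest connecting sparsity; empty networks are rejected by Lp/Q
  and defined as 0 (with a warning) for Cp.
- The single run seed is expanded into independent per-task streams keyed
  by stage/metric/comparison, so any stage rerun in isolation reproduces
  its slice of the full run; two runs with the same seed and configuration
  are byte-identical (content hashes recorded in the run manifest).
- Permutation counts in the shipped tests and the acceptance script are
  scaled to the problem (100–2,000 permutations, 10–200 Monte-Carlo
  repetitions, groups of 15–100 subjects) — large enough for the
  calibration bands asserted, small enough to keep a full validation run
  in minutes on one CPU.

## Known limitations

- Nodal inference at FDR 0.05 across 90 regions requires a per-region
  permutation p below 0.05/90 for a lone discovery, i.e. n_perm ≳ 2,000;
  with fewer permutations the FDR stage cannot flag a single isolated
  change (the add-one p-value floors above the threshold).
- The greedy modularity partition is a heuristic lower bound on Q.
- Per-sparsity inference is marginal; no correction is applied across the
  sparsity grid.
- Post-hoc contrasts use pooled-variance t throughout; Welch variants are
  deliberately not offered because the demographic checks pin the pooled
  form.
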