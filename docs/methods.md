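# Methods

## Problem setting

Two patient groups (labelled GR and PR, for good and poor drug
responders) are profiled on the same expression platform. The
question is not which genes are differentially *expressed* — the
interesting regulators often are not — but which transcription
factors are differentially *connected*: whose regulatory influence,
as read from co-expression structure seeded by known TF → target
interactions, differs between groups. The pipeline estimates one
regulatory network per group, contrasts them per TF, and annotates
the differential targets with pathway over-representation.

## Preprocessing

Expression values are assumed non-negative intensities (or any
already-linearised measure). `variance_stabilize` applies
log2(x + offset) with offset 1.0 — a pluggable monotone stand-in for a
platform-specific variance-stabilizing transform. Because every
downstream quantity is built from Pearson correlations of within-gene
profiles, any strictly monotone choice changes results only through
rank-preserving warping; the exact VST used on a given array platform
can be substituted freely. `quantile_normalize` maps every sample
onto the across-sample mean order-statistic distribution; ties within
a sample receive the mean of the reference values over the tied ranks
(the common convention; the operation is then idempotent to floating
point). Feature exclusion (e.g. probes with unreliable annotation or
on sex chromosomes) is symbol-set based; building the exclusion list
is the caller's responsibility.

## Network inference

The inference core is a PANDA-style message passer. Inputs: a 0/1
TF × gene prior W₀ (intersected with the expression matrix so every
TF and target has a profile), an optional TF × TF co-operativity
prior P₀ (identity when no protein-interaction evidence is supplied),
and the gene–gene Pearson correlation C₀ over the prior's target
genes. All three are standardized by `znormalize`
(entry ↦ (row-z + column-z)/√2, population moments, zero-variance
rows/columns contributing 0).

Each iteration computes a responsibility message R = T(P, W) (is the
edge consistent with TF co-operativity?) and an availability message
A = T(W, C) (is it consistent with the target's co-expression
neighbourhood?), where T is the continuous Tanimoto similarity with
denominator floored at 1e-10. W steps toward the symmetric message
average with rate α, and P and C step toward the TF-side and
gene-side Tanimoto co-similarity of the updated W at the same rate.
The loop stops when the mean absolute edge change falls below `tol`
(default 1e-3) or after `max_iter` (default 200) iterations, in which
case the last iterate is returned with a warning. The loop contains
no randomness; runs are bitwise reproducible.

### Annealing and the choice of α

The Tanimoto kernel is not scale-invariant, so the P/C updates feed
their own growth back into the messages; undamped, the loop diverges.
Convergence is enforced by deterministic annealing: after each
iteration the self-similarity diagonals of P and C are reset to
dim × exp(2αt). Two properties of this schedule matter:

* **It is data-independent.** Schedules that scale the diagonal with
  the matrix's own row spread give the dataset with stronger
  correlation structure systematically stronger shrinkage. When two
  groups are contrasted by edge counts, that asymmetry biases the
  contrast — in testing it was strong enough to invert the sign of
  the planted-regulator enrichment. A fixed schedule applies the same
  effective regularisation to both groups.
* **It couples the freeze time to α.** The annealing clock advances
  at 2α per step, so α controls how much co-expression is assimilated
  before the network freezes. The landscape, measured by planted-TF
  recovery on synthetic cohorts: for α ≲ 0.12 the output is
  essentially the standardized prior (every TF's high-confidence
  out-degree equals its prior out-degree and the enrichment ranking
  degenerates into ties); for α in roughly 0.14–0.2 the network
  assimilates a moderate amount of data and group contrasts carry the
  correct sign; for α ≳ 0.3 (or slower annealing) *variance dilution*
  dominates — a strongly regulated regulon has higher target variance,
  hence *lower* correlation to everything outside itself, which
  depresses the strong group's off-regulon edge scores and inverts
  edge-count contrasts. The default α = 0.15 sits in the middle
  regime. Exact numeric agreement with any other implementation of
  the message passer is a non-goal; damping schedules differ between
  implementations, and step-size conventions do not transfer across
  them.

## Subsample aggregation

Each group is subsampled `n_reps` times (default 50), each replicate
taking ⌈fraction × group size⌉ samples without replacement (default
fraction 2/3; ceiling keeps at least two-thirds). Draws come from
per-group seeded substreams, so the two groups' draws are independent
and the whole plan is reproducible from one seed. Replicate networks
are averaged edge-wise; an edge is high-confidence when its mean Z
strictly exceeds the threshold (default 0 — "more than" read as
strict inequality). A replicate cache keyed by the configuration,
replicate and sample draw lets re-runs skip the inference loop.

## Edge enrichment score and differential subnetworks

EES_i = log₂[(k^g_i/k^p_i)/(N^g/N^p)] with per-TF high-confidence
out-degrees k and network totals N. The score is undefined when any
count is zero; such TFs are excluded from the ranking and reported
separately rather than patched with a pseudocount, which would reorder
ranks silently. The 5 highest- and 5 lowest-scoring TFs are selected,
ties broken by symbol. For each selected TF, an edge joins the GR
subnetwork when ΔZ = meanZ_GR − meanZ_PR > δ (default 0.75) *and* the
edge is high-confidence in the GR aggregate, symmetrically for PR; the
two conditions are mutually exclusive for δ > 0, so each TF–gene pair
lands in at most one subnetwork. Two documented alternatives are
switchable: requiring high confidence on the *opposite* network
(`hc_side="other"`), and an absolute-difference reading
(`mode="absolute"`, which assigns by high-confidence membership and
can place an edge in both subnetworks). Signed with
`hc_side="assigned"` is the default.

## Over-representation analysis

For each selected TF and subnetwork, the query is the TF itself plus
its differentially connected genes. Raw p is the upper-tail
hypergeometric probability of at least the observed overlap between
query and gene set, with every set first intersected with the
background. The background defaults to all genes of the preprocessed
expression matrix — the universe of genes the network could have
connected — rather than the genome. Adjustment is Benjamini–Hochberg
within each query's batch of tests; web-service tools that adjust
across a hierarchy of inter-related gene sets will give different
adjusted values, so adjusted p-values here are comparable within a
query, not to such tools' output. The significance report filters at
adjusted p < 0.001.

## Synthetic cohorts

The generator emulates the structure the inference assumes: per
sample, latent TF activities a_t ~ N(0,1) drive target genes through
x_g = Σ_t β_tg a_t + ε, with ε ~ N(0, noise_sd); TF expression rows
are the activities plus the same noise. β is `beta_base` (default
0.5) on true prior edges and `beta_base + beta_delta` (default 1.3
total) for planted TFs in their favoured group. Defaults: 20 TFs,
200 genes, 10 targets per TF, 28 + 19 samples (a realistic small
clinical cohort split), noise_sd 1. Unless fixed explicitly, the two
planted TFs per direction are drawn at random per seed as part of the
cohort draw, so recovery statistics cannot be confounded by symbol
tie-breaking. The prior handed to inference can be corrupted with
false-negative and false-positive edge rates; the uncorrupted edge
set, the group-specific coefficient tables and the planted labels are
stored as ground truth.

What the generator does *not* emulate: probe-level artefacts, batch
structure, cell-type composition shifts, non-linear regulation, and
heavy-tailed expression noise. Passing recovery tests therefore show
that the pipeline extracts planted linear-Gaussian signal at realistic
sample sizes — not that it would rank real regulators correctly on a
given clinical dataset.

### What recovery can and cannot show

The enrichment score is a *breadth* statistic: it counts edges above
a threshold and discards their magnitudes. In the linear model most
of the planted signal appears as larger Z-scores on edges that were
already high-confidence (prior-seeded), which the count cannot see;
the correctly-signed count signal comes from a handful of borderline
edges near the threshold. Measured under the default conditions
(10 subsamples per group, 20 seeds), mean recovery of planted TFs
into the correct extreme-5 is ≈ 0.82, and with `beta_delta = 0` each
planted candidate's score is positive in ≈ 45–55% of cohorts, as
exchangeability requires.

## Numerical choices

* Tanimoto denominator floored at 1e-10 (all-zero rows/columns map to
  similarity 0).
* Quantile-normalization ties averaged over tied ranks.
* Subsample size rounding: ceiling.
* High-confidence threshold: strict inequality.
* Top-TF ties broken by symbol, ascending.
* Undefined EES: excluded and reported, never imputed.
* Convergence metric: mean absolute edge change; diagnostics (per-
  iteration deltas, iteration count, convergence flag) are kept on the
  returned network object.

## Test problem sizes

The test suite runs the full pipeline at desk scale: cohorts of
20 TFs × 200 genes with 10 subsamples per group for recovery and
null-model checks (20 seeds each), and smaller instances elsewhere;
kernel-level operations are verified against scalar-loop and
enumeration oracles on instances small enough to check by hand.

## Known limitations

* The message passer's output is implementation-specific: it agrees
  with other PANDA implementations qualitatively (prior-seeded,
  co-expression-informed edge scores) but not numerically.
* The EES is undefined for TFs with zero high-confidence out-degree
  in either group; cohorts with very sparse aggregates may rank few
  TFs.
* BH-adjusted ORA p-values are not comparable to hierarchical
  web-service adjustments.
* With a clean prior and near-disjoint regulons, edge-count contrasts
  carry only a small fraction of the available signal (see above);
  magnitude-based contrasts (ΔZ) are more sensitive and feed the
  subnetwork step, but the TF ranking deliberately follows the
  count-based enrichment score.
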