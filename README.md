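# grndiff

Differential gene-regulatory-network analysis for small two-group
cohorts — for example, asthma patients stratified into good (GR) and
poor (PR) responders to inhaled corticosteroids by their 4-week FEV1
improvement. Given a genes × samples expression matrix, a two-group
sample annotation, and a curated TF → target prior (a TRRUST-style
edge list), the package asks: *which transcription factors regulate
differently in the two groups, and which pathways do their
differential targets fall into?*

## Method

1. **Network inference (message passing).** For each group a TF × gene
   regulatory network is inferred PANDA-style: the 0/1 prior W₀,
   a TF–TF co-operativity prior P₀ (identity by default) and the
   gene–gene Pearson co-expression C₀ are standardized and then
   assimilated by iterating

   W ← (1 − α)·W + α·(R + A)/2,  R = T(P, W),  A = T(W, C),

   where T is the continuous Tanimoto similarity
   T(x, y) = ⟨x, y⟩ / √(‖x‖² + ‖y‖² − |⟨x, y⟩|). P and C are moved
   toward the Tanimoto co-similarity of W at the same rate, with an
   annealed self-similarity diagonal that drives convergence. The
   converged W is the edge Z-score matrix.

2. **Subsample aggregation.** To tame outliers in small cohorts, each
   group is subsampled 50× (two-thirds of its samples, drawn without
   replacement), a network is inferred per subsample, and edge
   Z-scores are averaged into one aggregate network per group. Edges
   with mean Z > 0 are *high-confidence*.

3. **Edge enrichment score.** Each TF *i* is scored by

   EES_i = log₂[ (k^g_i / k^p_i) / (N^g / N^p) ],

   with k^g_i, k^p_i its high-confidence out-degrees in the GR and PR
   aggregates and N^g, N^p the total high-confidence edge counts.
   Positive scores mark GR-enriched regulators, negative PR-enriched.

4. **Differential subnetworks.** The 5 highest- and 5 lowest-scoring
   TFs are kept; an edge joins the GR subnetwork when
   ΔZ = meanZ_GR − meanZ_PR > 0.75 and the edge is high-confidence in
   the GR aggregate (symmetrically for PR).

5. **Over-representation analysis.** Each selected TF plus its
   differentially connected genes is tested against user-supplied GMT
   gene sets with the upper-tail hypergeometric probability,
   Benjamini–Hochberg adjusted within each query; significant hits are
   reported at adjusted p < 0.001.

A linear-Gaussian synthetic-cohort generator (`grndiff.simulate`)
plants group-specific regulation behind a known prior so the entire
pipeline can be exercised and validated without patient data.

## Worked example

```python
from grndiff import SimulationConfig, generate, truth_eval
from grndiff.model import DifferentialNetworkModel, PipelineConfig

ds = generate(SimulationConfig(seed=1))            # 28 GR vs 19 PR samples
res = DifferentialNetworkModel(
    ds.expression, ds.design, ds.prior,
    PipelineConfig(n_reps=10, delta=0.5, seed=1),
).fit()
print(res.summary())
```

```
Differential regulatory network analysis
========================================================
groups: GR (n=28) vs PR (n=19)
prior: 20 TFs, 200 interactions, 129 target genes
subsamples: 10 per group at fraction 0.6667, seed 1
converged message-passing runs: 20/20
high-confidence edges (mean Z > 0): N_g=213, N_p=223

top 5+5 TFs by edge enrichment score:
tf               k_g     k_p  n_diff  log2_ees
TF14              13      10       3     0.445
TF15              14      12       2     0.289
TF03              11      10       1     0.204
TF08              11      10       1     0.204
TF19              12      11       1     0.192
TF09              10      16      -6    -0.612
TF12              10      13      -3    -0.312
TF20              10      13      -3    -0.312
TF13              10      12      -2    -0.197
TF18              10      12      -2    -0.197

differential edges (|dZ| > 0.5): GR subnetwork 8, PR subnetwork 8
```

The table mirrors the method's headline output: per-TF high-confidence
out-degrees in each aggregate (`k_g`, `k_p`), their difference, and
the log₂ enrichment score. In this cohort the generator planted TF10
and TF15 as GR-strengthened and TF09 and TF20 as PR-strengthened;
checking against the stored truth:

```python
m = truth_eval(res.ees, ds.truth)
# planted GR TFs: ('TF10', 'TF15') -> recovered: ('TF15',)
# planted PR TFs: ('TF09', 'TF20') -> recovered: ('TF09', 'TF20')
# recovery fraction: 0.75
```

three of the four planted regulators land in the correct extreme-5 of
the ranking (TF09 and TF20 at the very bottom, TF15 near the top).
Note the demo lowers `delta` to 0.5: on desk-scale synthetic cohorts
the aggregate Z differences are smaller than on a full microarray
cohort, where the default 0.75 applies.

The same pipeline runs from the shell:

```sh
grndiff simulate --out data/ --seed 1
grndiff run --expression data/expression.tsv --design data/design.tsv \
            --prior data/prior.tsv --out results/ --n-reps 10 --seed 1
grndiff ees --aggregate-g results/aggregate_GR.tsv \
            --aggregate-p results/aggregate_PR.tsv --out ees.tsv
```

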