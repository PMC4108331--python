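# limits-infer

Inference of sparse, directed species-interaction networks from microbial
abundance timeseries, with the matching community simulator and evaluation
machinery.

## The problem

Metagenomic timeseries report how the (relative) abundances of the species
in a community — say, the daily composition of a human gut microbiome —
change over time. The ecological question is which species actually
*interact*: who benefits whom, who competes with whom, and which species
are "keystones" that drive a disproportionate share of the community.
Abundance correlations are poor proxies for interactions (indirect chains
and shared drivers correlate non-interacting pairs, and correlations are
forced to be symmetric), so this package fits a dynamical model instead.

Communities are modelled with the stochastic discrete-time Lotka-Volterra
(Ricker) map

```
x_i(t+1) = x_i(t) · exp( Σ_j c_ij (x_j(t) − x̄_j) + η_i(t) )
```

where `c_ij` is the effect of species *j* on the per-capita log-growth of
species *i* (`c_ij > 0`: *j* benefits *i*), `x̄_j` is the equilibrium
abundance, and `η_i ~ N(0, σ²)` is multiplicative environmental noise.
Taking logs turns each row of `c` into a linear regression of
`log(x_i(t+1)/x_i(t))` on the abundance deviations `x_j(t) − x̄_j`.

Three obstacles make the naive regression unreliable: sequencing yields
*relative* abundances whose sum constraint makes the full design matrix
singular; measurement error (sequencing noise, OTU mis-assignment) biases
coefficients through the errors-in-variables problem; and dense least-squares
solutions are uninterpretable. The estimator here — forward stepwise
regression with **median** bootstrap aggregation — addresses all three: the
self-interaction `c_ii` is always in the model and further covariate species
are added greedily only when they improve *held-out* prediction error by
more than a relative threshold (so the design stays non-singular and the
network sparse); the stepwise fit is repeated over many random half/half
train/test partitions and aggregated entrywise by the median, which
stabilises the greedy selection while keeping exact zeros exact.

## Worked example

`examples/simulate_and_infer.py` generates a random stable 10-species
community (20 off-diagonal couplings), simulates 10 initial conditions for
500 steps with process noise σ = 0.05, and runs the inference at a 5%
threshold with 50 bootstrap partitions:

```
coefficient recovery R^2 = 0.995
sensitivity = 0.80  specificity = 1.00
sign errors among detected true edges: 0.00
```

`R²` is the squared Pearson correlation between the vectorized true and
inferred coefficient matrices; sensitivity and specificity are the fractions
of truly interacting / truly non-interacting ordered species pairs whose
status was recovered. The other examples demonstrate why correlation is not
interaction (`correlation_vs_interaction.py`), topology recovery under
multiplicative measurement noise (`noise_robustness.py`), and keystone
identification by out-degree on a planted-hub community
(`keystone_workflow.py`).

The same workflows are scriptable from the shell:

```sh
limits simulate -M 10 -T 500 -R 10 --seed 4 -o run/sim
limits infer -i run/sim.tsv --threshold 0.05 --bootstraps 100 --seed 1 \
      -o run/edges.tsv --output-graphml run/net.graphml
limits evaluate --truth run/sim_true_edges.tsv --inferred run/edges.tsv
limits benchmark --mode noise --matrices 10 -o run/sweep.tsv
```

Abundance tables are TSV (species rows, `t<i>_r<j>` columns, JSON metadata
sidecar); networks are edge-list TSV and GraphML. A reported coefficient
`c_ij > 0` means species *j* benefits species *i* (edge *j* → *i*); on
relative-abundance input the coefficients are identified only up to a common
multiplicative constant.

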