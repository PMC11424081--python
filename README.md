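# latgrad

Phylogenetic comparative pipeline for latitudinal gradients of body-shape
diversification in (marine) species assemblages:

- **data_io** — Newick trees and species x trait tables, species matching,
  equal-count absolute-latitude quartile assignment.
- **synthetic** — birth–death trees, CTMC discrete histories, state-dependent
  multivariate Brownian traits with lognormal background rate variation,
  allometric raw measurements, occurrence grids (all seed-reproducible).
- **size_correction** — geometric-mean body size; phylogenetic GLS residuals
  of log traits on log size (Brownian covariance).
- **discrete** — Mk models with hidden rate classes (ER/ARD x 1–4 classes),
  Felsenstein-pruning likelihoods, AICc/AICw model comparison, joint and
  marginal ancestral states, stochastic character maps via endpoint-
  conditioned uniformization, state occupancy through time in 1-Myr bins.
- **morphospace** — covariance PCA, multivariate disparity (n-denominator,
  overall-mean centering), 6-D convex-hull volume, MST-based functional
  evenness, permutation p-values, within-group bootstrap, per-cell
  assemblage summaries.
- **rates** — state-dependent relaxed multivariate BM: random-local-clock
  background rates (spike-and-slab shifts), state rate multipliers with a
  Bernoulli(1/2) dependence indicator (reversible jump), joint MCMC with
  stochastic-map history redraws, tip rates, posterior fold-differences,
  and robust (Huber) phylogenetic regression of tip rates on latitude.

## CLI

```sh
latgrad match --tree t.nwk --traits x.csv --out matched/
latgrad quartiles --traits x.csv --out quartiled.csv
latgrad simulate --config sim.json --out sim/
latgrad sizecorrect --tree t.nwk --traits x.csv --out resid.csv
latgrad history fit|simmap|occupancy --tree t.nwk --states s.csv --out ...
latgrad morphospace --tree t.nwk --traits x.csv --axes 6 --nperm 1000 --seed 1 --out ms/
latgrad rates rlc|musscrat --tree t.nwk --traits x.csv --iters 300000 --out rates/
latgrad rates regress --tree t.nwk --tip-rates rates/tip_rates.csv --traits x.csv --out fit.csv
```

Trait tables are CSV/TSV with columns `species, std_length, jaw_length,
mouth_width, body_width, body_depth, ped_width, ped_depth, head_depth,
lat_centroid`.

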