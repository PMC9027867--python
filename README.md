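# cacyreus

Distribution modelling of the geranium bronze (*Cacyreus marshalli*),
the only alien butterfly established in Europe, in alpine landscapes
where its host plant — ornamental *Pelargonium* pots — exists only in
villages and cold temperatures cap its spread.  The package is aimed at
quantitative ecologists and protected-area analysts who want to compare
a standardized-survey analysis against an opportunistic-data analysis on
the same landscape, and to stress-test management scenarios before
applying them.

Two models share one landscape substrate:

- **Egg abundance** — a hierarchical binomial N-mixture model for
  repeated counts with imperfect detection.  Latent abundance
  N_i ~ P/NB/ZIP with log λ_i = x_i′β; visits observe
  y_ij ~ Binomial(N_i, p_i) with logit p_i = w_i′α; the likelihood
  marginalizes N_i.  Fitting, AICc model selection (two-step:
  detection first, abundance second, mixture third),
  parametric-bootstrap goodness of fit with overdispersion factor ĉ,
  and ĉ-inflated uncertainty.
- **Habitat suitability** — a presence-only MaxEnt model: a Gibbs
  density over cells (relative occurrence rate, ROR) constrained by
  covariate values at occurrences against a background sampled within
  2.5 km of the presences, with percent contribution, permutation
  importance, response curves, and TSS under repeated 80/20 splits.

A synthetic-landscape generator (250 m grid, lapse-rate temperatures,
village-bound host plants, stratified three-band survey with repeat
visits, biased opportunistic presences) makes every stage testable
without any field download, and a scenario engine projects the abundance
model under +1.5 °C warming and a 50% host-plant reduction.

## Worked example

```python
from cacyreus import (LandscapeConfig, NMixtureModel, make_landscape,
                      gof_bootstrap, simulate_counts, stratified_design,
                      default_truth)

grid = make_landscape(LandscapeConfig(n_rows=60, n_cols=60), seed=7)
design = stratified_design(grid, n_per_band=100, visits=3, seed=1)
print(design.n_sites, design.n_site_visits)      # 300 900

data = simulate_counts(grid, design, default_truth(), seed=3)
scaled = data.standardize(["bio01", "pel_abu", "pel_neigh", "pel_ava"])
res = NMixtureModel(scaled,
                    abundance=["bio01", "pel_abu", "pel_abu:bio01",
                               "pel_neigh"],
                    detection=["pel_ava"], mixture="ZIP").fit()
print(res.summary())
```

```
N-mixture model results
================================================================
structure : p(pel_ava) lam(bio01 + pel_abu + pel_abu:bio01 + pel_neigh) [ZIP]
sites     : 300    K truncation: 295
logLik    : -826.619    K params: 8
AICc      : 1669.73
psi (zero inflation): 0.5240
converged : True
----------------------------------------------------------------
                   estimate     se       z  p>|z|
lam:intercept        2.3886 0.4055  5.8900 0.0000
lam:bio01            0.5006 0.0460 10.8763 0.0000
lam:pel_abu          0.4938 0.0848  5.8215 0.0000
lam:pel_abu:bio01    0.5363 0.0623  8.6102 0.0000
lam:pel_neigh       -0.3551 0.0586 -6.0636 0.0000
p:intercept         -1.9318 0.4592 -4.2069 0.0000
p:pel_ava            0.3297 0.1006  3.2767 0.0011
psi:logit            0.0960 0.1260  0.7620 0.4460
```

The abundance block reads as the generative truth dictates (β =
0.446, 0.320, 0.592, −0.343 on the standardized scale): egg numbers rise
with temperature and host-plant pots, with a positive synergy and a
penalty for pots in neighbouring cells; detection improves with the pots
a surveyor can reach, and roughly half the sites are structural zeros
(ψ ≈ 0.5).  The two intercepts sit within sampling error of the truth
but are the least stable quantities — with per-visit detection around
0.07 the λ–p ridge is nearly flat (see `docs/methods.md`).
`gof_bootstrap(res, 1000, seed=0)` then gives the bootstrap χ² p-value
and ĉ; `res.inflate_vcov(c_hat)` widens the standard errors when ĉ > 1.

The same objects drive the rest of the pipeline: `MaxentModel(...)
.fit()` for the presence-only model, `project_map`/`categorize_changes`
for scenarios, and the `cacyreus` command line (`simulate`, `fit-nmix`,
`gof`, `fit-maxent`, `project`, `run-all`) for file-based runs.

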