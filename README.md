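# crcapture

Closed-population capture-recapture for multi-list epidemiological data.

Cancer registries, surveillance systems and outbreak investigations all face
the same question: several incomplete lists each record some of the cases —
how many cases did *every* list miss, how large is the true population N,
and how complete is each register?  `crcapture` estimates N from the overlap
pattern of the lists with three complementary estimator families:

* **Bayesian M0/Mt/Mh/Mth with model averaging** — capture probabilities
  follow logit(p_it) = μ + α_t + γ_i with episode (list) effects α_t and
  individual random effects γ_i ~ N(0, σ²_γ); the likelihood for unknown N is
  f(x | θ, γ) ∝ N!/(N−n)! Π_t Π_i p_it^{x_it}(1−p_it)^{1−x_it}.  A
  reversible-jump MCMC sampler moves between the four models while N is
  estimated by data augmentation, and estimates are averaged over models
  weighted by their posterior probabilities (BMA).  This is the route that
  can represent *individual capture heterogeneity* — e.g. metastatic cases
  being easier to capture — which classical methods fold into pairwise list
  dependence, and it needs no asymptotic approximation, so it remains honest
  for small case counts.
* **Hierarchical log-linear models** on the 2^T − 1 observed capture-pattern
  cells, with the unobserved cell projected from the fit (N̂ = M + x̂₀₀₀),
  nested G² tests and stepwise-descending model selection.
* **Lincoln–Petersen** two-list estimation (N̂ = n₁n₂/m) with an odds-ratio
  dependence screen and union-pooling of dependent sources.

A synthetic-data module generates capture histories with known ground truth
under any of the models (plus covariate-driven heterogeneity), so every
estimator is testable end-to-end, and the package bundles two validated
three-source cancer record-linkage tables (breast and colorectal cases aged
50–75: histopathological registry HR, multidisciplinary team meetings MTM,
screening programme CSP) used throughout the examples and tests.

## Worked example

```sh
python examples/registry_completeness.py
```

```
observed cases: 787 (HR 729, MTM 537, CSP 207)
  θ + HR + MTM + CSP + HR*MTM + HR*CSP + MTM*CSP          N =  793.2 [782-804]  G2 =  0.00 df = 0
  θ + HR + MTM + CSP + HR*MTM + HR*CSP                    N =  799.0 [779-819]  G2 = 14.61 df = 1
  θ + HR + MTM + CSP + HR*MTM + MTM*CSP                   N =  790.6 [784-797]  G2 =  2.15 df = 1 <-- selected
  θ + HR + MTM + CSP + HR*CSP + MTM*CSP                   N =  807.5 [796-819]  G2 =  2.66 df = 1
  θ + HR + MTM + CSP + HR*MTM                             N =  792.7 [783-802]  G2 = 19.53 df = 2
  θ + HR + MTM + CSP + HR*CSP                             N =  811.5 [799-824]  G2 = 15.56 df = 2
  θ + HR + MTM + CSP + MTM*CSP                            N =  803.2 [794-813]  G2 = 10.58 df = 2
  θ + HR + MTM + CSP                                      N =  806.1 [796-816]  G2 = 24.58 df = 3
selected model projects 3.6 cases missed by every list,
so the estimated population is 791 cases [784-797]
histopathological registry completeness: 92.2% (91.5%-92.9%)
```

Reading: 787 distinct breast-cancer cases were observed across the three
lists.  Stepwise G² descent from the saturated model keeps the two MTM
interactions and projects ~4 cases missed by all lists, i.e. a population of
791 cases, so the histopathological registry (729 cases) is about 92%
complete.  The other examples cover the remaining capabilities:

* `examples/dependent_sources.py` — pairwise Lincoln–Petersen estimates, the
  odds-ratio screen that flags the MTM–CSP pair as negatively dependent
  (OR 0.52, CI 0.37–0.72), and the pooled estimate N = 803.2 (793.8–812.5).
* `examples/bayesian_model_averaging.py` — reversible-jump BMA on the
  colorectal table: P(Mt) ≈ 0.96 and a model-averaged N ≈ 527.
* `examples/simulate_and_recover.py` — simulate N = 790 with known capture
  rates and recover it inside the 95% HPDI.
* `examples/covariate_episodes.py` — expand heterogeneity covariates (age
  band, gender, metastasis) into 24 capture episodes and refit.

The same operations are available from a thin CLI, with JSON run reports
that echo the seed and full resolved configuration:

```sh
crcapture fixture breast --out breast.csv
crcapture loglinear --input breast.csv --report ll.json
crcapture petersen --input breast.csv --pair MTM,CSP --pool --versus HR
crcapture independence --input breast.csv --pair MTM,CSP --third HR
crcapture mth-bma --input breast.csv --iters 25000 --burn-in 5000 --seed 1
crcapture simulate --scenario mh_strong --seed 7 --out sim.csv
```

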