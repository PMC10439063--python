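# latentnorm

Norming Likert-rated items via cumulative link mixed models (CLMMs).

Ratings on an ordinal scale are modelled as ordered regions of a continuous
latent variable, partitioned at estimated thresholds.  Item (and
participant) random intercepts on the latent mean give per-item norms —
latent means — that are disentangled from the overall response pattern; a
Bayesian distributional variant additionally norms per-item latent SDs via
a log-scale discrimination term (`latent SD = 1 / exp(disc)`).

## What's in the box

| Module | Purpose |
| --- | --- |
| `latentnorm.ordinal_core` | links (probit/logit), threshold patterns, latent→ordinal recoding, response probabilities |
| `latentnorm.simulate` | trial-level generators: items-only, crossed item×participant, discrimination effects, non-normal variants |
| `latentnorm.clmm_ml` | maximum-likelihood CLMM with crossed random intercepts (Laplace approximation), conditional modes = norms, Gauss–Hermite oracle |
| `latentnorm.clmm_bayes` | Bayesian distributional CLMM via Hamiltonian MCMC with analytic gradients; HDIs, posterior norm summaries |
| `latentnorm.norms_eval` | baselines (raw means, within-participant z-scores, Gaussian LMM), recovery metrics, split-half consistency, simulation-study runner |
| `latentnorm.io_cli` / `latentnorm.cli` | delimited-text trial/norm formats, fixtures, manifests, `latentnorm` CLI |

## CLI quick start

```sh
# simulate a crossed norming dataset (design in TOML, flags override)
latentnorm simulate --design design.toml --pattern edge-biased --seed 1 -o trials.csv

# per-item norms: raw | zscore | lmm | clmm_ml | clmm_bayes
latentnorm norms trials.csv --levels 5 --method clmm_ml -o norms.csv
latentnorm norms trials.csv --levels 5 --method clmm_bayes --seed 2 \
    --chains 4 --iter 2000 -o norms_bayes.csv

# full fit artifact (JSON for ML, long-format draw table for Bayes)
latentnorm fit trials.csv --levels 5 -o fit.json
latentnorm fit trials.csv --levels 5 --distributional --seed 3 -o draws.csv

# simulation studies at reduced scale
latentnorm evaluate --sim 1 --scale 0.1 --seed 4 -o report/
```

Trial tables are plain CSV with `participant_id,item_id,response` (plus
optional ground-truth columns emitted by the simulators).  `--levels` is
always required: the declared number of scale points changes the model when
extreme categories are unobserved, so it is never inferred from the data.
Norm tables use a fixed column order
(`item_id,n,raw_mean,raw_sd,latent_mean,latent_mean_lo,latent_mean_hi,latent_sd,latent_sd_lo,latent_sd_hi,method`).

## Python API sketch

```python
import latentnorm as ln

design = ln.SimulationDesign(n_items=100, n_participants=100,
                             ratings_per_item=25, items_per_participant=25,
                             seed=1)
trials = ln.simulate_crossed(design, pattern="edge-biased")

fit = ln.fit_clmm(trials, ln.CLMMSpec(n_levels=5,
                                      factors=("item", "participant")))
norms = ln.ranef(fit, "item")            # conditional modes = latent means

spec = ln.DistributionalSpec(n_levels=5, chains=4, iterations=2000,
                             warmup=1000, seed=2)
post = ln.fit_distributional(trials, spec)
table = ln.summarize_posterior_norms(post, trials)   # medians + 89% HDIs
```

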