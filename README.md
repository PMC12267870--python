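# sdart — stratified distributional analysis of response times

`sdart` fits full response-time *distributions* — not just mean RTs — as a
function of item properties, for psycholinguists and cognitive modellers
working with trial-level lexical-decision archives (ELP/BLP-style
megastudies) or any other speeded-RT data.

## The model

Every RT is split into a deterministic participant shift and a stochastic
component:

    Y_ijkl = theta_j + X_ijkl

with participant `j`, word-frequency band `k`, word length `l`, trial `i`.
`theta_j` (ms) is the participant's nondecision time; `X_ijkl > 0` follows
a shifted **lognormal**, **Wald** (inverse Gaussian) or **gamma**
distribution whose two parameters `rho_jkl` are estimated separately for
every (participant, band, length) cell, so nothing is assumed about how
the distribution scales with frequency or length.  A hierarchical gamma
prior ties the cells together:

    rho_jkl[m] ~ Gamma(alpha_l[m], beta_l[m])      m = 1, 2
    theta_j    ~ Gamma(alpha_theta, beta_theta)
    phi_i      ~ Gamma(a_i, b_i)   for every hyperparameter phi_i

Frequency bands are quantile bins of the trial-level word-occurrence
values (word-form frequency or contextual diversity), each holding at
least a configurable floor of observations, with ties resolved so every
occurrence value belongs to exactly one band.

Fitting is by seeded multi-chain MCMC (an adaptive Metropolis-within-Gibbs
sampler specialized to this model's shift/scale geometry; split-R-hat and
ESS diagnostics via arviz).  Model fit is checked with posterior
predictive p-values of cell means (ppp ≈ 0.5 means the model reproduces
the data), and competing families/measures are ranked by expected log
pointwise predictive density (PSIS-LOO), reported as Δelpd ± se against
the best model.  See `docs/methods.md` for the full account.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from sdart import (SimDesign, gen_trials, merge_lexicon, make_frequency_bands,
                   stratify, StratifiedRTModel, compare_models)

# 1. a synthetic lexical-decision archive with known truth
design = SimDesign(n_participants=8, lengths=(4, 5), n_bands=2,
                   trials_per_cell=40, family="lognormal", seed=1)
trials, truth = gen_trials(design)

# 2. preprocess: merge lexicon, band word frequency, stratify
ann = merge_lexicon(trials, truth.lexicon, measure="WF", lengths=design.lengths)
bands = make_frequency_bands(ann, "WF", min_count=500)
ds = stratify(ann, bands)
print(f"{ds.n_trials} trials in {len(ds.cell_sizes())} cells, {bands.k} bands")

# 3. fit the hierarchical model for one family
res = StratifiedRTModel(ds, "lognormal").fit(draws=600, warmup=800, chains=2, seed=2)
print(res.summary())

# 4. assess and compare against the other families
ppp = res.ppp(R=200, seed=3)
print(f"mean cell ppp: {ppp.values.mean():.3f}")
elpds = [res.elpd(label="lognormal")]
for fam in ("wald", "gamma"):
    other = StratifiedRTModel(ds, fam).fit(draws=600, warmup=800, chains=2, seed=2)
    elpds.append(other.elpd(label=fam))
print(compare_models(elpds))
```

This prints (abridged):

```
1280 trials in 32 cells, 2 bands
Stratified distributional analysis of response times
========================================================
family:        shifted lognormal
participants:  8
cells (j,k,l): 32   lengths: [4, 5]
trials:        1280
chains x draws: 2 x 600  (warmup 800)
max split R-hat: 1.0404   min ESS: 159

participant shift theta_j (ms): median [95% CI]
          P001:    286.1  [  240.4,   312.5]
          P002:    294.2  [  255.3,   324.8]
          P004:    224.8  [  188.2,   244.0]
          ...
mean cell ppp: 0.503
ModelComparison(reference='wald')
    model  delta_elpd       se
     wald    0.000000 0.000000
lognormal   -3.102192 2.980835
    gamma   -7.029940 3.003242
```

Reading the output: the shift posteriors bracket the generating truth
(e.g. P001 was simulated at 264 ms, P004 at 221 ms), and a mean ppp of
0.50 says the fitted distributions reproduce the observed cell means.
The comparison table illustrates an important honest caveat: at 1,280
trials the shifted Wald and lognormal are statistically tied (|Δelpd| ≈
se), and the gamma is already clearly worse.  Separating Wald from
lognormal reliably takes on the order of 10⁴ trials — distributional
model selection is data-hungry, which is exactly why megastudies matter.

For file-based workflows the same pipeline is available as a CLI:

```bash
sdart simulate --out data --seed 1
sdart run-all --config run.yaml --out results
sdart report results
```

`run-all` executes simulate/load → filter → band → fit → assess → compare
for every requested family × measure combination and writes delimited
tables (theta medians, cell means, ppp values, the Δelpd table) plus a
JSON manifest with seeds, counts and a config hash.

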