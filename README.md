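# cmrf

Comparative Markov-random-field analysis of two-group perturbation
experiments: which genes changed *because of the perturbation itself*, and
in only one of the two groups?

## The problem

Perturbation experiments (drug, radiation, disease) measure expression
before (*control*) and after (*non-control*) the stimulus, often in two
sample groups — two cohorts, phenotypes or treatment arms.  A gene that is
differentially expressed (DE) in exactly one group is *differentially
regulated* (DR).  A DR gene may respond to the perturbation directly
(*primarily* DR, PDR) or through its regulators in the gene network
(*secondarily* DR).  This package identifies and ranks PDR candidates from
the four expression matrices and a directed gene-interaction network; it is
aimed at computational biologists analysing two-group case/control
perturbation designs.

## The model

Each gene `g_i` carries hidden binary DE states `S_Ai, S_Bi`, summarized
per gene as `Z_i ∈ {1..4}` (`Z ∈ {2,3}` ⇔ DR), and per network edge as an
interaction value `X_ij = 4(Z_i − 1) + Z_j ∈ {1..16}`.  A *metagene* `g₀`
representing the perturbation has an edge to every gene and is DE by
definition, so `X_{0j} ∈ {2,3}` is the event "g_j is PDR".

The posterior couples

* a **hierarchical Gaussian likelihood**: within one sample set,
  measurements are `N(μ, σ²)` with `μ ~ N(μ₀, τ²)`; marginally
  `log L(z) = −(n/2)log 2π − (n−1)log σ − ½ log(σ² + nτ²) − ½[sse/σ² +
  n(z̄−μ₀)²/(σ² + nτ²)]`.  DE genes get independent set means for control
  and non-control, EE genes pool them;
* an **MRF prior** over the interaction variables with seven feature
  functions `F1..F7` (weights `γ₁..γ₇`) expressing that metagene-driven DR
  has characteristic frequency, that a gene and its regulator respond
  alike in both groups, and that most genes are equally regulated.

Fitting alternates a t-test initialization, differential-evolution
estimation of `θ_Y = (μ₀, σ, τ)` and `θ_X = (γ₁..γ₇)`, and iterated
conditional modes (ICM) over the gene states, maximizing the
pseudo-posterior `Σ_edges [log p(Y|X_ij) + log p(X_ij | neighbours)]`.
DR genes are then ranked by the reverse-hypothesis log-likelihood `LL_i`
(how badly the *opposite* group assignment fits — lower = stronger PDR
candidate).  See `docs/methods.md` for the full account.

## Worked example

Simulate a 60-gene benchmark with known ground truth, fit, and rank:

```python
import numpy as np
from cmrf import (CMRF, FitConfig, random_scale_free_network,
                  simulate_dataset_shift, rank_pdr)

rng = np.random.default_rng(1)
net = random_scale_free_network(60, rng=rng)
data, labels = simulate_dataset_shift(
    net, set_sizes=(3, 3, 3), d_p=2.0, d_s=1.0, n_samples=155, rng=rng)
print("planted PDR:", sorted(labels.pdr))

fit = CMRF(data, net, config=FitConfig(seed=1)).fit()
print(fit.summary())
print(rank_pdr(fit).to_frame().head(6).to_string(index=False))
```

Output:

```
planted PDR: ['g10', 'g21', 'g22', 'g46', 'g50', 'g53']
CMRF fit summary
============================================
genes: 60   interactions: 151 (incl. 60 metagene edges)
cycles: 4   converged: True
pseudo-log-likelihood: -991544.1455
--------------------------------------------
theta_Y:  mu0 = 478.7   sigma = 176.7   tau = 291
theta_X:  g1=-5.045  g2=-4.923  g3=-4.138  g4=+0.088  g5=+1.237  g6=+1.699  g7=+0.833
--------------------------------------------
regulation:  DE/DE (Z=1): 7   DR A-only (Z=2): 3   DR B-only (Z=3): 4   EE/EE (Z=4): 46
DR genes: 7

 rank gene        score  semantics
    1  g10 -4511.436772 reverse-LL
    2  g46 -4444.944835 reverse-LL
    3  g21 -4294.369286 reverse-LL
    4   g4 -4237.204840 reverse-LL
    5  g22 -4069.995036 reverse-LL
    6  g53 -3928.184397 reverse-LL
```

The generator planted three 3-primary affected sets (one in both groups,
one per group); `d_p = 2.0` / `d_s = 1.0` are the primary/secondary mean
shifts in units of each gene's sd.  The fit recovers 7 DR genes; five of
the six planted PDR genes lead the ranking (scores are reverse-hypothesis
log-likelihoods — the more negative, the more confidently PDR), with one
false positive (`g4`) and one planted gene (`g50`) missed.

The same pipeline is available from the shell:

```sh
cmrf simulate --config sim.yaml --out bench/
cmrf fit      --config fit.yaml --out results/   # states, params, trace, ranking
cmrf significance --config sig.yaml --out sig/   # LL_i across the d_p grid
cmrf permute  --config fit.yaml --out perm/      # group-shuffling null
```

Configs are small YAML files; every run writes a `manifest.yaml` that
replays it exactly.

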