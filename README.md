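# gensmr

Bayesian density estimation for camera-trap studies of animals that cannot
all be told apart — **generalized spatial mark–resight with incomplete
identification**.

## The problem

Spatial capture–recapture (SCR) estimates animal density from the spatial
pattern of detections, but it needs every detected animal identified.
Many species (foxes, coyotes, most unmarked mammals) carry no usable natural
marks, so field crews physically mark a subset (ear tags, collars) and then
resight the population with cameras. Two complications follow:

* the marked animals are **not** a spatially random sample — they live near
  the traps that caught them; and
* on camera you can often see *that* an animal is marked without reading
  *which* one it is.

`gensmr` implements a hierarchical model that handles both. Each of N
animals has a latent activity center s_i ~ Uniform(S); detection decays
with distance d through a half-normal kernel exp(−d²/2σ²). The marking
phase is modeled explicitly (per-occasion capture probability
λ0.mark·exp(−d²/2σ²)), full resighting counts are Poisson with rate
λ_ij = λ0.resight·exp(−d²/2σ²), and each detection of a marked animal is
identified with probability δ. By Poisson thinning the data decompose into
three streams with tractable likelihoods:

* identified counts y^m_ijk ~ Poisson(δ·λ_ij),
* summed unidentified-marked counts nnid_jk ~ Poisson((1−δ)·Σᵢ λ_ij),
* unmarked counts n_jk ~ Poisson(Σ over the unmarked part of λ_ij),

with GPS telemetry on marked animals (bivariate normal around s_i, SD σ)
keeping σ identifiable even at δ = 0. Unknown N is handled by data
augmentation (z_i ~ Bernoulli(ψ), N = Σz, density D = N/|S|), and the
posterior is sampled by an adaptive Metropolis-within-Gibbs sampler with
numba-compiled kernels (δ and ψ have exact conjugate updates).

## Worked example

Simulate one dataset from the reference design (50 animals, 25 live traps,
100 cameras, σ = 0.05, half the marked detections unidentifiable) and fit
it:

```python
from gensmr import ScenarioSpec, simulate_dataset, MCMCConfig, run_mcmc, summarize_fit

spec = ScenarioSpec(m_target=20, lam0_mark_true=0.35, delta_true=0.5, seed=1,
                    exact_m=False)  # marked count is a random outcome, as in the field
dataset, truth = simulate_dataset(spec, rep=1)   # this draw marks m = 34 animals
config = MCMCConfig(n_iter=5000, n_burn=1000, n_adapt=1000, n_chains=3, M=150, seed=3)
samples = run_mcmc(dataset, config)
print(summarize_fit(samples).table.round(3))
```

which prints (abridged):

```
                mean     sd  median    mode   q2.5   q97.5  hpd_low  hpd_high   rhat
lam0_mark      0.333  0.044   0.333   0.328  0.250   0.424    0.246     0.418  1.000
lam0_resight   0.543  0.040   0.542   0.535  0.466   0.627    0.463     0.623  1.003
sigma          0.049  0.000   0.049   0.049  0.049   0.050    0.049     0.050  1.000
delta          0.431  0.035   0.431   0.430  0.363   0.500    0.363     0.501  1.000
N             49.583  3.210  49.000  49.000 44.000  56.000   43.000    55.000  1.000
D             68.628  4.443  67.820  67.659 60.900  77.509   59.516    76.125  1.000
```

The generating values were λ0.mark = 0.35, λ0.resight = 0.5, σ = 0.05,
δ = 0.5 and N = 50 (density 69.2 per unit²; the state space is the
detector envelope plus a 2.5σ buffer, area 0.7225): every truth sits inside
its 95% HPD interval, and σ is pinned to about 1% by the telemetry. `N`
counts animals whose activity centers lie in S, so `D = N/area` is the
biologically meaningful output.

For field data, write the seven CSV tables documented in `gensmr.io`
(detectors, effort, marking, identified resights, counts, telemetry,
alive) and run the two-pass workflow from the shell — pass 1 buffers the
detector envelope with 2.5× the telemetry SD, pass 2 rebuilds the state
space from the posterior σ:

```bash
gensmr fit --data my_study/ --out results/ --seed 1
gensmr simulate --m 5 --delta 0.3 --seed 2 --out demo_data/
gensmr simstudy --cells m5,m20 --deltas 0,1 --reps 30 --out study/
```

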