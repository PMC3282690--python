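# smtrace

Hidden-Markov analysis of single-molecule intensity traces: simulate
multi-channel fluorescence time series with realistic shot noise and
photobleaching, fit user-specified kinetic models by maximum likelihood,
attach per-molecule error bars, select among candidate models, and detect
kinetic heterogeneity across a population of molecules.

## The science

A single fluorescent molecule (e.g. an smFRET donor/acceptor pair) hops
between a small number of conformational states. The recorded intensity trace
is a hidden Markov process: the state sequence is unobserved, and each state
emits photon counts with Poisson shot noise (or Gaussian noise for analog
detection). Two experimental constraints shape the analysis:

- **Signal-to-noise ratio (SNR).** For one Poisson channel with state means
  mu1, mu2, the SNR is `|mu2 - mu1| / sqrt((mu1 + mu2)/2)`; independent
  channels combine as the root sum of squares.
- **Photobleaching.** Brighter excitation (higher SNR) destroys the
  fluorophore sooner, so trace length trades off against noise as
  `T = c / SNR` with `c` a photon budget (default 10,000).

`smtrace` implements the full chain:

1. **Simulation** (`simulate`) — first-order Markov state paths from the
   stationary distribution, Poisson/Gaussian emissions, photobleaching-coupled
   lengths, multi-channel anti-correlated means.
2. **Fitting** (`hmm`) — Baum-Welch (EM) maximum likelihood with scaled
   forward-backward recursions. Models are declarative: restricted
   connectivity (forbidden transitions stay exactly zero), tied emissions
   (states sharing a signal level), and an optional detailed-balance
   (thermodynamic-equilibrium) constraint on the transition matrix.
3. **Error bars** (`confidence`) — likelihood-ratio confidence intervals per
   parameter, conditional or profile, with domain-edge clipping flags.
4. **Model selection** (`selection`) — BIC with exact free-parameter counting
   (a detailed-balance constraint removes one parameter per independent cycle;
   tied emissions pool parameters).
5. **Thresholding baseline** (`thresholding`) — cutoff idealization with
   dwell-time rate estimates, censored-dwell handling, and exclusion
   bookkeeping, for head-to-head comparison with the HMM.
6. **Population clustering** (`clustering`) — Gaussian-mixture EM over
   per-molecule parameter estimates in which every molecule is broadened by
   its own CI-derived measurement covariance, so true heterogeneity separates
   from fitting noise; mixture BIC picks the number of clusters.

## Worked example

```python
import smtrace as st

# a molecule with k12 = k21 = 0.3 per step, observed at SNR 5;
# photobleaching gives T = 10,000 / 5 = 2,000 steps
params = st.two_state_params(k12=0.3, k21=0.3, snr=5.0)
cfg = st.SimulationConfig(params=params, snr=5.0, c=10_000, n_traces=1, seed=42)
trace, hidden = st.simulate_trace(cfg, 0)

fit = st.fit_hmm(trace, st.builtin_models()["2-state"], seed=0)
print(fit.params.A[0, 1])                 # 0.306  (truth 0.3)
ci = st.confidence_interval(trace, fit, "k12", level=0.90)
print(ci.lo, ci.hi)                       # 0.282  0.331
```

Running `examples/01_simulate_and_fit.py` prints:

```
state means: [100.         156.63911093]
trace length T = 2000 (photobleaching: 10,000 / SNR 5)
converged in 8 iterations, loglik = -8821.3
fitted k12 = 0.306  (truth 0.3)
fitted k21 = 0.286  (truth 0.3)
posterior idealization matches the true path at 99.4% of steps
```

The other examples walk through confidence intervals (`02`), BIC model
selection on a 3-state linear chain (`03`), the thresholding-vs-HMM accuracy
comparison across SNR (`04`), and two-population clustering (`05`).

## Command line

The same chain is scriptable through the `smtrace` CLI:

```bash
smtrace simulate --k12 0.3 --k21 0.3 --snr 5 --n 50 --seed 1 --out traces.tsv
smtrace fit --traces traces.tsv --model two_state.yaml --out fits.json
smtrace ci --results fits.json --traces traces.tsv --params k12,k21
smtrace select --results fits.json --results fits1.json --traces traces.tsv --out ranking.tsv
smtrace threshold --traces traces.tsv --out thr.json
smtrace cluster --results fits.json --params k12,k21 --cmax 3 --out clusters.json
smtrace experiment snr-sweep --seed 0 --out-dir out/
```

Model specs are YAML (see `st.save_model(st.builtin_models()["2-state"], "two_state.yaml")`);
traces are a self-describing TSV; fits are JSON keyed by trace id.

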