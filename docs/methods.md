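# Methods

This document records the statistical model, the estimation procedures, the
numerical conventions, and the reasoning behind the defaults.

## 1. Model

### 1.1 Hidden Markov process

A molecule occupies one of K hidden states; the state sequence follows a
first-order Markov chain with a K×K transition matrix `A` in discrete time
(one step per camera frame, duration `dt`). The initial state is drawn from
`pi0`, which by default is the stationary distribution of `A` — molecules are
observed at equilibrium, so `pi0` carries no extra free parameters. A
`pi0_mode="free"` option estimates it instead.

Each of C detection channels emits one value per step conditioned on the
state:

- `poisson`: counts with mean `mu[state, channel]` (shot-noise-limited
  photon counting; the variance equals the mean).
- `gaussian`: mean `mu[state, channel]`, standard deviation
  `sigma[state, channel]` (analog readout).

Channels are conditionally independent given the state. Multi-channel
two-state simulations place the channel means anti-correlated (donor down,
acceptor up), emulating FRET.

### 1.2 Model specifications

A `ModelSpec` is declarative:

- **Topology** — the set of allowed directed transitions. Absent edges are
  structural zeros maintained exactly through fitting. Self-transitions are
  implicit: each diagonal entry absorbs the row's remaining probability.
- **Tied emissions** — per-channel partitions of the state set; states in one
  group share emission parameters (spectroscopically silent kinetics).
- **Detailed balance** — restricts `A` to reversible chains,
  `pi_i A_ij = pi_j A_ji`, the thermodynamic-equilibrium constraint.

### 1.3 Free-parameter counting

BIC needs exact counts:

- transitions: number of allowed directed edges (diagonals are residuals, so
  they are not counted; `pi0` is derived, so it is not counted);
- detailed balance removes one parameter per independent undirected cycle
  (Kolmogorov's criterion constrains products around cycles; trees lose
  nothing). The cycle rank is `E - V + components` of the undirected support.
  Hence the full 3-state model has 9 parameters and its detailed-balance
  variant 8;
- emissions: one parameter (`mu`) per tie group per Poisson channel, two
  (`mu`, `sigma`) per Gaussian channel group.

### 1.4 SNR and photobleaching

For one Poisson channel the two-state SNR is

```
SNR = |mu2 - mu1| / sqrt((mu1 + mu2) / 2)
```

i.e. the mean separation over the pooled shot-noise scale. This pooled-variance
convention reproduces the worked example "means 100 and 110 give SNR of about
one" (0.976). For Gaussian channels the denominator is
`sqrt((sigma1^2 + sigma2^2)/2)`. Independent channels combine as the root sum
of squares; `means_for_snr` inverts the Poisson formula in closed form
(quadratic in `mu2 - mu1`).

Photobleaching couples observation time to excitation intensity: trace length
is `T = round(c / SNR)` with photon-budget constant `c = 10,000` by default.
`length_mode="fixed"` decouples them.

## 2. Estimation

### 2.1 Likelihood and posteriors

Scaled forward and forward-backward recursions (per-step max-shift in log
space plus normalization) evaluate the exact log-likelihood and posterior
state marginals without underflow up to at least T = 30,000. Both are verified
against brute-force enumeration of all K^T hidden paths on small instances to
1e-9, and against hmmlearn (independent implementation) for Gaussian
emissions.

### 2.2 Baum-Welch

`fit_hmm` runs EM:

- **E-step**: posteriors `gamma` and expected transition counts `xi` from the
  forward-backward recursions.
- **M-step, transitions**: `A_ij = xi_ij / sum_k xi_ik` restricted to the
  allowed mask. Under detailed balance, the update is a fixed-point iteration
  on symmetric edge weights `w_ij` (`A_ij = w_ij / sum_k w_ik`,
  `w_ij <- (xi_ij + xi_ji) / (C_i/S_i + C_j/S_j)`), the standard reversible
  M-step; it preserves the likelihood ascent property of EM.
- **M-step, emissions**: posterior-weighted means pooled over tie groups;
  Gaussian sigmas floored at 1e-6 of the data range to avoid collapse.
- `pi0` is refreshed to the stationary distribution of the updated `A` each
  iteration (or re-estimated freely with `pi0_mode="free"`).

**Initialization** uses emission quantiles — state k starts at the
`(k+1)/(K+1)` data quantile per channel — with 0.1 off-diagonal transition
mass spread over allowed edges. Three restarts (first unjittered, others with
±10% multiplicative jitter) guard against local optima; convergence is
declared when the log-likelihood gain drops below 1e-6, capped at 1000
iterations. The per-iteration log-likelihood path is recorded and must be
non-decreasing (1e-8 numerical slack); tests enforce this on every fit.

`fixed_params` pins named parameters (e.g. `{"k12": 0.2}`) during EM, which
implements profile-likelihood scans. States of permutation-invariant models
are sorted by first-channel mean so that "state 1" is reproducible.

### 2.3 Confidence intervals

A level-`q` likelihood-ratio interval for one parameter is the set of values
where the log-likelihood lies within `Delta = chi2_1(q)/2` of its maximum
(1.353 at 90%). Bounds are located with Brent root-finding on the
log-likelihood drop:

- **conditional** (default): other parameters fixed at their MLE; setting a
  transition probability renormalizes its row diagonal and refreshes `pi0`.
- **profile**: the remaining parameters are re-maximized at every scan point
  (a constrained refit warm-started from the MLE); wider and slower, correct
  under parameter correlation.

If the likelihood never drops by `Delta` before the parameter's domain edge
(0 or the row's available probability for transitions, 0 for Poisson means and
sigmas), the bound is clipped to the edge and flagged (`clipped_lo/hi`).
Degenerate scan points (e.g. an absorbing chain at the edge) count as
rejected.

### 2.4 BIC model selection

`BIC = -2 loglik + k ln(T)` (natural log; T = number of time steps). Candidate
fits of one trace are ranked ascending with Delta-BIC relative to the best;
ties break by smaller k, then name. The built-in menu is 1-state, 2-state,
3-linear, 3-cycle, 3-thermo (detailed balance), 4-state linear.

### 2.5 Thresholding baseline

State 1 is at or below the cutoff, state 2 above; the default cutoff is the
midpoint of the two 1-d k-means centroids. Dwells abutting the trace ends are
censored and dropped; each transition probability is the reciprocal mean
completed dwell in the source state (the geometric-dwell MLE). Traces with
fewer than two transitions are excluded with a reason rather than estimated.
On pure one-state noise thresholded at its median, this estimator converges to
0.5 per step — the diagnostic signature of threshold failure.

### 2.6 Uncertainty-weighted clustering

Each molecule contributes a point estimate `theta_i` (one to three fitted
parameters, log10-transformed by default since rates are scale parameters) and
a diagonal measurement covariance `Sigma_i` obtained from its CI half-widths:
`sd = half-width / z(level)` with `z(0.90) = 1.645`, symmetrizing asymmetric
intervals by averaging and flooring a zero-clipped lower bound at MLE/100
before the log. The population model is a C-component mixture in which
component c has center `m_c` and each point carries its own covariance:

```
p(theta_i) = sum_c pi_c N(theta_i; m_c, Sigma_i)
```

EM with precision-weighted center updates, 10 random initializations, and a
recorded monotone log-likelihood path. Cluster number is chosen by mixture BIC
with `k = C(d+1) - 1` (d center coordinates per cluster plus C-1 weights);
the log-likelihood leveling-off table is reported alongside for inspection.
Partition accuracy against known labels maximizes over cluster-to-population
mappings.

## 3. Rate conversion

Per-parameter, `rate = p / dt` (first-order approximation, accurate for
p << 1). `matrix_prob_to_rate` computes the exact generator `Q = logm(A)/dt`
via the matrix logarithm and validates that Q is a proper generator
(non-negative off-diagonals, zero row sums); matrices without a real
generator are rejected. For the symmetric two-state chain with p = 0.3,
`Q[0,1] = -ln(0.4)/2 = 0.4581`, against the approximate 0.3 — the difference
is invisible at p ≲ 0.05.

## 4. Numerical and design choices

- **numba kernels.** The forward/backward/xi recursions and the reversible
  M-step fixed point are `@njit(cache=True)` compiled: studies run hundreds of
  EM fits on traces up to T = 30,000, which pure-Python loops cannot do within
  the runtime budgets.
- **Reproducibility.** Trace i of a population uses
  `default_rng(SeedSequence([seed % 2^31, i]))`; EM restarts and cluster
  initializations derive similarly. Identical seeds give identical tables.
- **k-means for the default threshold** and for one of the cluster-center
  initializations uses scikit-learn (standard primitives, not the
  contribution of this package).
- **Study defaults.** The 3-state identification study uses shared edge rate
  0.1 and outer-state SNR 4 (middle state halfway, so ~2 between neighbours);
  the heterogeneity study uses populations (0.1, 0.1) vs (0.1, 0.2) at SNR 2.
  Replication defaults (50–200 traces) are this package's own reduced choice
  to keep each study under ~10 minutes on one CPU; all are flags.
- **hmmlearn** appears only in the test suite as an independent cross-check
  of the likelihood; the implementation shares no code with it.

## 5. Limitations

- Discrete-time first-order kinetics only; no explicit photophysics (blinking,
  spectral crosstalk) beyond what the emission families capture.
- Emission channels are conditionally independent given the state; correlated
  noise between channels is not modeled.
- Profile CIs refit per scan point and are ~20× slower than conditional ones.
- The matrix-logarithm rate conversion requires an embeddable transition
  matrix; strongly oscillatory chains are rejected rather than approximated.
- Cluster covariances are diagonal (per-parameter CIs); parameter correlations
  within a molecule are ignored when weighting.
- No plotting; tables are plain TSV/JSON for downstream tools.
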