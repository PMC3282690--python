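"""Compare the thresholding baseline with the HMM across noise levels.

Thresholding idealizes a trace by an intensity cutoff and estimates each
transition probability as the reciprocal mean completed dwell time.  At high
SNR this works; as the noise grows, spurious threshold crossings masquerade as
transitions and the apparent rate climbs toward the 0.5-per-step flicker of
pure noise.  The HMM models the noise explicitly and stays accurate far lower.

Run:  python examples/04_thresholding_vs_hmm.py  (a few minutes)
"""

import numpy as np

import smtrace as st

TRUE_K = 0.3
model = st.builtin_models()["2-state"]

print(f"true k12 = {TRUE_K}; photobleaching keeps T * SNR = 10,000\n")
print(f"{'SNR':>5s} {'T':>6s} {'HMM k12':>9s} {'threshold k12':>14s}")
for snr in (0.5, 1.0, 2.0, 5.0, 10.0):
    params = st.two_state_params(TRUE_K, TRUE_K, snr)
    cfg = st.SimulationConfig(params=params, snr=snr, c=10_000, n_traces=10, seed=5)
    traces, _ = st.simulate_population(cfg)

    mu = params.emissions.mu[:, 0]
    cut = 0.5 * (mu[0] + mu[1])  # ideal threshold: midway between the states
    hmm_k, thr_k = [], []
    for i, tr in enumerate(traces):
        hmm_k.append(st.fit_hmm(tr, model, seed=i).params.A[0, 1])
        res = st.threshold_fit(tr, threshold=cut)
        if not res.excluded and res.p12_hat is not None:
            thr_k.append(res.p12_hat)
    print(
        f"{snr:5.1f} {traces[0].T:6d} {np.mean(hmm_k):9.3f} {np.mean(thr_k):14.3f}"
    )

# the limiting case: thresholded pure noise "transitions" every other step
rng = np.random.default_rng(0)
noise = st.Trace("noise", 1.0, rng.poisson(100.0, size=(10_000, 1)).astype(float))
res = st.threshold_fit(noise, threshold=float(np.median(noise.channels)))
print(f"\npure one-state noise: apparent rate = {res.pooled_rate():.3f} (-> 0.5)")
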